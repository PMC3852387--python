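import itertools
import math

import numpy as np
import pytest
from scipy import stats

from spotwing.codon import (CodonAlignment, DEFAULT_OPTIMAL_CODONS, cbi, gc3,
                            li93_kaks, mc_chisq, partition_compare,
                            rank_top_dN, KaKsResult)
from spotwing.simulate import evolve_codon_pair

# ---------------------------------------------------------------------------
# independent oracles

_CODE = {
    # independent copy of the standard code for the oracle
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_degeneracy(codon, pos):
    syn = sum(_CODE[codon[:pos] + b + codon[pos + 1:]] == _CODE[codon]
              for b in "ACGT" if b != codon[pos])
    return 0 if syn == 0 else (4 if syn == 3 else 2)


def oracle_site_counts(seq_a, seq_b):
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    for i in range(0, len(seq_a), 3):
        for pos in range(3):
            L[oracle_degeneracy(seq_a[i:i + 3], pos)] += 0.5
            L[oracle_degeneracy(seq_b[i:i + 3], pos)] += 0.5
    return L


def k2p_by_hand(P, Q):
    A = 0.5 * math.log(1 / (1 - 2 * P - Q)) - 0.25 * math.log(1 / (1 - 2 * Q))
    B = 0.5 * math.log(1 / (1 - 2 * Q))
    return A, B


class TestLi93:
    def test_identical_sequences_zero(self):
        a = "ATGGCTAAAGGTCCTTAT"
        r = li93_kaks(CodonAlignment(pair_id="p", seq_a=a, seq_b=a))
        assert r.dN == 0 and r.dS == 0

    def test_toy_pair_matches_site_class_oracle(self):
        # one synonymous transition (T->C) at the fourfold site of GGT
        seq_a = "GGTGCTAAAATGTTTCGT"
        seq_b = "GGCGCTAAAATGTTTCGT"
        r = li93_kaks(CodonAlignment(pair_id="toy", seq_a=seq_a, seq_b=seq_b))
        L = oracle_site_counts(seq_a, seq_b)
        assert r.site_counts == pytest.approx((L[0], L[2], L[4]))
        A4, _ = k2p_by_hand(1 / L[4], 0.0)
        expected_dS = (L[4] * A4) / (L[2] + L[4])
        assert r.dS == pytest.approx(expected_dS)
        assert r.dN == 0

    def test_nonsynonymous_transversion_counts_toward_dN(self):
        # GCT(Ala) -> GAT(Asp): transversion at a nondegenerate site
        seq_a = "GCTAAAGGTTTTCATACT"
        seq_b = "GATAAAGGTTTTCATACT"
        r = li93_kaks(CodonAlignment(pair_id="t", seq_a=seq_a, seq_b=seq_b))
        L = oracle_site_counts(seq_a, seq_b)
        # one transversion at a 0-fold site: P0 = 0, Q0 = 1/L0; note the
        # K2P transition distance A0 is slightly negative when Q0 > 0
        A0, B0 = k2p_by_hand(0.0, 1 / L[0])
        expected_dN = A0 + (L[0] * B0) / (L[0] + L[2])
        assert r.dN == pytest.approx(expected_dN)
        assert r.dS == 0

    def test_symmetry(self):
        a, b, _ = evolve_codon_pair(300, 0.3, 0.05, seed=7)
        r1 = li93_kaks(CodonAlignment(pair_id="p", seq_a=a.seq, seq_b=b.seq))
        r2 = li93_kaks(CodonAlignment(pair_id="p", seq_a=b.seq, seq_b=a.seq))
        assert r1.dS == pytest.approx(r2.dS)
        assert r1.dN == pytest.approx(r2.dN)

    def test_rotation_invariance(self):
        a, b, _ = evolve_codon_pair(200, 0.2, 0.02, seed=8)
        rot = 33 * 3
        ra = a.seq[rot:] + a.seq[:rot]
        rb = b.seq[rot:] + b.seq[:rot]
        r1 = li93_kaks(CodonAlignment(pair_id="p", seq_a=a.seq, seq_b=b.seq))
        r2 = li93_kaks(CodonAlignment(pair_id="p", seq_a=ra, seq_b=rb))
        assert r1.dS == pytest.approx(r2.dS)
        assert r1.dN == pytest.approx(r2.dN)

    def test_gapped_codons_skipped(self):
        x, y, _ = evolve_codon_pair(200, 0.2, 0.02, seed=9)
        gapped = li93_kaks(CodonAlignment(
            pair_id="p", seq_a=x.seq[:30] + "---" + x.seq[33:],
            seq_b=y.seq))
        dropped = li93_kaks(CodonAlignment(
            pair_id="p", seq_a=x.seq[:30] + x.seq[33:],
            seq_b=y.seq[:30] + y.seq[33:]))
        assert gapped.dS == pytest.approx(dropped.dS)
        assert gapped.dN == pytest.approx(dropped.dN)

    def test_simulation_recovery_at_moderate_divergence(self):
        est_s, est_n = [], []
        for seed in range(1, 13):
            a, b, _ = evolve_codon_pair(10_000, 0.2, 0.02, seed=seed)
            r = li93_kaks(CodonAlignment(pair_id="p", seq_a=a.seq,
                                         seq_b=b.seq))
            est_s.append(r.dS)
            est_n.append(r.dN)
        assert np.mean(est_s) == pytest.approx(0.2, rel=0.10)
        assert np.mean(est_n) == pytest.approx(0.02, rel=0.10)


class TestGC3:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCGAC", 1.0),
        ("AAAGGG", 0.5),
        ("ATGTGG", None),     # Met + Trp only: no synonymous codon
    ])
    def test_examples(self, seq, expected):
        assert gc3(seq) == expected

    def test_stop_codons_excluded(self):
        assert gc3("AAATAG") == 0.0   # TAG excluded; AAA third pos is A

    def test_bad_length_raises(self):
        with pytest.raises(ValueError):
            gc3("AAAA")


class TestCBI:
    def test_all_optimal_codons_give_one(self):
        seq = "".join(sorted(DEFAULT_OPTIMAL_CODONS))
        assert cbi(seq) == pytest.approx(1.0)

    def test_uniform_random_sequences_center_on_zero(self):
        rng = np.random.default_rng(23)
        sense = [c for c, aa in _CODE.items() if aa != "*"]
        vals = []
        for _ in range(300):
            seq = "".join(rng.choice(sense, 300))
            v = cbi(seq)
            vals.append(v)
        assert abs(np.mean(vals)) < 0.02

    def test_no_qualifying_codons_undefined(self):
        assert cbi("ATGTGG") is None

    def test_gc3_cbi_covariation_recovered(self):
        # genes built from optimal (GC-ending) codons score high on both
        rng = np.random.default_rng(29)
        opts = sorted(DEFAULT_OPTIMAL_CODONS)
        sense = [c for c, aa in _CODE.items() if aa != "*"]
        gc3s, cbis = [], []
        for frac in np.linspace(0, 1, 12):
            seq = "".join(
                (rng.choice(opts) if rng.random() < frac else
                 rng.choice(sense))
                for _ in range(400))
            gc3s.append(gc3(seq))
            cbis.append(cbi(seq))
        assert np.corrcoef(gc3s, cbis)[0, 1] > 0.9


class TestPartitionCompare:
    def _results(self, values, prefix):
        return [KaKsResult(gene_id=f"{prefix}{i}", dN=v, dS=v,
                           site_counts=(1, 1, 1))
                for i, v in enumerate(values)]

    def test_identical_samples_p_one_exact(self):
        res = self._results([1, 2, 3], "x") + self._results([1, 2, 3], "a")
        parts = {r.gene_id: ("X" if r.gene_id.startswith("x") else "autosome")
                 for r in res}
        rep = partition_compare(res, parts)
        assert rep["dN"]["p"] == pytest.approx(1.0)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(31)
        x = list(rng.normal(size=5))
        y = list(rng.normal(size=5))
        res = self._results(x, "x") + self._results(y, "a")
        parts = {r.gene_id: ("X" if r.gene_id.startswith("x") else "autosome")
                 for r in res}
        rep = partition_compare(res, parts)
        # enumerate all C(10,5) assignments of ranks to group X
        pooled = x + y
        order = sorted(range(10), key=lambda i: pooled[i])
        ranks = {i: r + 1 for r, i in enumerate(order)}
        obs_r1 = sum(ranks[i] for i in range(5))
        obs_u1 = obs_r1 - 5 * 6 / 2
        obs = min(obs_u1, 25 - obs_u1)
        count = 0
        total = 0
        for comb in itertools.combinations(range(10), 5):
            r1 = sum(ranks[i] for i in comb)
            u1 = r1 - 15
            if min(u1, 25 - u1) <= obs:
                count += 1
            total += 1
        assert rep["dN"]["p"] == pytest.approx(count / total)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(37)
        x = list(rng.normal(0, 0.01, 50))
        y = list(rng.normal(5, 0.01, 50))
        res = self._results(x, "x") + self._results(y, "a")
        parts = {r.gene_id: ("X" if r.gene_id.startswith("x") else "autosome")
                 for r in res}
        rep = partition_compare(res, parts)
        assert rep["dS"]["p"] < 1e-6

    def test_empty_group_raises(self):
        res = self._results([1.0], "x")
        with pytest.raises(ValueError):
            partition_compare(res, {"x0": "X"})


class TestMcChisq:
    def test_proportional_table(self):
        chi2, p = mc_chisq([[10, 20], [20, 40]], n_sims=10_000, seed=1)
        assert chi2 == pytest.approx(0.0)
        assert p > 0.99

    def test_statistic_matches_textbook_formula(self):
        t = [[12, 5], [8, 9]]
        chi2, _ = mc_chisq(t, n_sims=1000, seed=1)
        expected = stats.chi2_contingency(t, correction=False).statistic
        assert chi2 == pytest.approx(float(expected))

    def test_p_within_three_mc_se_of_exact(self):
        # N=20: enumerate all tables with fixed margins exactly
        table = [[7, 3], [2, 8]]
        n_sims = 200_000
        chi2, p_mc = mc_chisq(table, n_sims=n_sims, seed=29)
        r1, c1, N = 10, 9, 20
        exact = 0.0
        for a in range(max(0, r1 + c1 - N), min(r1, c1) + 1):
            t = np.array([[a, r1 - a], [c1 - a, N - r1 - c1 + a]], float)
            e = np.outer(t.sum(1), t.sum(0)) / N
            stat = ((t - e) ** 2 / e).sum()
            if stat >= chi2 - 1e-12:
                exact += (math.comb(c1, a) * math.comb(N - c1, r1 - a)
                          / math.comb(N, r1))
        se = math.sqrt(exact * (1 - exact) / n_sims)
        assert abs(p_mc - exact) <= 3 * se + 1 / n_sims

    def test_seed_reproducibility(self):
        a = mc_chisq([[5, 10], [10, 5]], n_sims=50_000, seed=3)
        b = mc_chisq([[5, 10], [10, 5]], n_sims=50_000, seed=3)
        assert a == b

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError):
            mc_chisq([[0, 0], [5, 5]])


class TestRankTopDN:
    def _results(self, n, rng):
        return [KaKsResult(gene_id=f"g{i:04d}", dN=float(rng.random()),
                           dS=0.2, site_counts=(1, 1, 1)) for i in range(n)]

    def test_top_k_matches_full_sort(self):
        rng = np.random.default_rng(41)
        res = self._results(4919, rng)
        top = rank_top_dN(res, k=25)
        oracle = sorted(res, key=lambda r: (-r.dN, r.gene_id))[:25]
        assert [r.gene_id for r in top] == [r.gene_id for r in oracle]

    def test_output_non_increasing(self):
        rng = np.random.default_rng(43)
        top = rank_top_dN(self._results(100, rng), k=10)
        dns = [r.dN for r in top]
        assert dns == sorted(dns, reverse=True)

    def test_k_larger_than_n_returns_all(self):
        rng = np.random.default_rng(47)
        res = self._results(5, rng)
        assert len(rank_top_dN(res, k=25)) == 5
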