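"""Codon-evolution statistics on pairwise coding alignments.

The centrepiece is the unbiased pairwise dN/dS estimator of Li (1993):
codon sites are classified into nondegenerate (L0), twofold (L2) and
fourfold (L4) degeneracy classes from the standard genetic code, averaged
over the two sequences; transitions and transversions are counted per class
(multi-substitution codons averaged over their minimal mutational pathways);
each class receives a Kimura two-parameter correction A_i (transitions) and
B_i (transversions); then

    dS = (L2*A2 + L4*A4)/(L2 + L4) + B4
    dN = A0 + (L0*B0 + L2*B2)/(L0 + L2)

The module also provides GC3 (GC at synonymous third positions), the codon
bias index (CBI), Mann-Whitney group comparisons, a Monte-Carlo chi-square
for 2x2 tables, and top-k ranking by dN.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._util import GENETIC_CODE, STOP_CODONS, is_transition

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "li93_kaks",
    "gc3",
    "cbi",
    "partition_compare",
    "mc_chisq",
    "rank_top_dN",
    "DEFAULT_OPTIMAL_CODONS",
    "site_degeneracy",
]

# Optimal codons for CBI, one per amino acid with >= 2 codons; a
# Drosophila-style C/G-ending preferred set.  Configurable per call.
DEFAULT_OPTIMAL_CODONS = frozenset({
    "TTC",  # Phe
    "CTG",  # Leu
    "ATC",  # Ile
    "GTG",  # Val
    "TCC",  # Ser
    "CCC",  # Pro
    "ACC",  # Thr
    "GCC",  # Ala
    "TAC",  # Tyr
    "CAC",  # His
    "CAG",  # Gln
    "AAC",  # Asn
    "AAG",  # Lys
    "GAC",  # Asp
    "GAG",  # Glu
    "TGC",  # Cys
    "CGC",  # Arg
    "GGC",  # Gly
})


@dataclasses.dataclass
class CodonAlignment:
    """A gap-aligned pair of coding sequences (lengths divisible by 3)."""

    pair_id: str
    seq_a: str
    seq_b: str
    partition: str = "unknown"   # X / autosome / unknown

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.pair_id}: aligned lengths differ")
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.pair_id}: length not divisible by 3")

    def codon_pairs(self) -> Iterable[tuple[str, str]]:
        """Ungapped, unambiguous, non-stop codon pairs."""
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i : i + 3], self.seq_b[i : i + 3]
            if ca in GENETIC_CODE and cb in GENETIC_CODE \
                    and ca not in STOP_CODONS and cb not in STOP_CODONS:
                yield ca, cb


@dataclasses.dataclass
class KaKsResult:
    gene_id: str
    dN: float
    dS: float
    site_counts: tuple[float, float, float]   # (L0, L2, L4)
    saturated: bool = False

    @property
    def ratio(self) -> Optional[float]:
        if self.dS <= 0 or math.isnan(self.dS) or math.isnan(self.dN):
            return None
        return self.dN / self.dS


def site_degeneracy(codon: str, pos: int) -> int:
    """Degeneracy class (0, 2 or 4) of one codon position.

    Counted as the number of the three possible substitutions that are
    synonymous: 0 -> nondegenerate, 3 -> fourfold, otherwise twofold
    (threefold-degenerate Ile sites follow the twofold convention).
    """
    aa = GENETIC_CODE[codon]
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if GENETIC_CODE[alt] == aa:
            syn += 1
    if syn == 0:
        return 0
    if syn == 3:
        return 4
    return 2


def _codon_path_counts(ca: str, cb: str) -> dict[int, list[float]]:
    """Transitions/transversions per degeneracy class between two codons.

    Multi-substitution codons are averaged over all minimal mutational
    pathways that avoid stop codons (all pathways if none avoids them).
    Each change is attributed half to the site class in the codon before the
    step and half to the class in the codon after, which keeps the count
    symmetric in the two sequences.
    """
    counts = {0: [0.0, 0.0], 2: [0.0, 0.0], 4: [0.0, 0.0]}  # class: [ts, tv]
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return counts
    paths = []
    for order in itertools.permutations(diff):
        cur = ca
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            steps.append((cur, nxt, pos))
            cur = nxt
        paths.append((ok, steps))
    valid = [s for ok, s in paths if ok]
    use = valid if valid else [s for _, s in paths]
    w = 1.0 / len(use)
    for steps in use:
        for cur, nxt, pos in steps:
            ts = is_transition(cur[pos], nxt[pos])
            for codon, weight in ((cur, 0.5), (nxt, 0.5)):
                counts[site_degeneracy(codon, pos)][0 if ts else 1] += w * weight
    return counts


def _k2p(P: float, Q: float) -> tuple[float, float, bool]:
    """Kimura two-parameter transition (A) and transversion (B) distances."""
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan, math.nan, True
    A = 0.5 * math.log(1 / w1) - 0.25 * math.log(1 / w2)
    B = 0.5 * math.log(1 / w2)
    return A, B, False


def li93_kaks(alignment: CodonAlignment) -> KaKsResult:
    """Li (1993) unbiased pairwise dN/dS estimate."""
    L = {0: 0.0, 2: 0.0, 4: 0.0}
    S = {0: 0.0, 2: 0.0, 4: 0.0}
    V = {0: 0.0, 2: 0.0, 4: 0.0}
    for ca, cb in alignment.codon_pairs():
        for pos in range(3):
            L[site_degeneracy(ca, pos)] += 0.5
            L[site_degeneracy(cb, pos)] += 0.5
        cc = _codon_path_counts(ca, cb)
        for cls in (0, 2, 4):
            S[cls] += cc[cls][0]
            V[cls] += cc[cls][1]
    if L[0] + L[2] + L[4] == 0:
        raise ValueError(f"{alignment.pair_id}: no comparable codons")

    A = {}
    B = {}
    saturated = False
    for cls in (0, 2, 4):
        if L[cls] == 0:
            A[cls], B[cls] = 0.0, 0.0
            continue
        a, b, sat = _k2p(S[cls] / L[cls], V[cls] / L[cls])
        saturated = saturated or sat
        A[cls], B[cls] = a, b

    if saturated:
        dS = dN = math.nan
    else:
        dS = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4] \
            if (L[2] + L[4]) > 0 else math.nan
        dN = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2]) \
            if (L[0] + L[2]) > 0 else math.nan
    return KaKsResult(gene_id=alignment.pair_id, dN=dN, dS=dS,
                      site_counts=(L[0], L[2], L[4]), saturated=saturated)


# ---------------------------------------------------------------------------
# codon-usage statistics

def gc3(coding_seq: str) -> Optional[float]:
    """GC fraction at third positions of synonymous codons.

    ATG, TGG and stop codons carry no synonymous third position and are
    excluded; a sequence with only such codons returns None.
    """
    seq = coding_seq.upper()
    if len(seq) % 3:
        raise ValueError("length not divisible by 3")
    gc = total = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon not in GENETIC_CODE or codon in STOP_CODONS \
                or codon in {"ATG", "TGG"}:
            continue
        total += 1
        gc += codon[2] in "GC"
    return gc / total if total else None


_AA_CODONS: dict[str, list[str]] = {}
for _c, _aa in GENETIC_CODE.items():
    if _aa != "*":
        _AA_CODONS.setdefault(_aa, []).append(_c)


def cbi(coding_seq: str,
        optimal_codons: frozenset[str] = DEFAULT_OPTIMAL_CODONS,
        ) -> Optional[float]:
    """Codon bias index: (N_opt − N_rand) / (N_tot − N_rand).

    Counted over amino acids with at least two codons (Met/Trp and stops
    excluded); N_rand is the optimal-codon count expected under uniform
    synonymous codon use.  1 means exclusively optimal codons; values near 0
    mean no bias.
    """
    seq = coding_seq.upper()
    if len(seq) % 3:
        raise ValueError("length not divisible by 3")
    n_opt = n_tot = 0
    n_rand = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = GENETIC_CODE.get(codon)
        if aa is None or aa == "*":
            continue
        fam = _AA_CODONS[aa]
        if len(fam) < 2:
            continue
        n_tot += 1
        n_opt += codon in optimal_codons
        n_rand += sum(c in optimal_codons for c in fam) / len(fam)
    if n_tot == 0 or n_tot == n_rand:
        return None
    return (n_opt - n_rand) / (n_tot - n_rand)


# ---------------------------------------------------------------------------
# group tests

def _mannwhitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    method = "exact" if len(x) <= 8 and len(y) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def partition_compare(results: Sequence[KaKsResult],
                      partitions: Mapping[str, str],
                      group_a: str = "X", group_b: str = "autosome") -> dict:
    """Two-sided Mann-Whitney U comparing dN and dS between two partitions.

    Exact enumeration when both groups have n <= 8, otherwise the normal
    approximation.  Reports U, p and group medians for each statistic.
    """
    ga = [r for r in results
          if partitions.get(r.gene_id) == group_a and not r.saturated]
    gb = [r for r in results
          if partitions.get(r.gene_id) == group_b and not r.saturated]
    if not ga or not gb:
        raise ValueError("both partitions must be non-empty")
    report = {"group_a": group_a, "group_b": group_b,
              "n_a": len(ga), "n_b": len(gb)}
    for stat in ("dN", "dS"):
        xa = [getattr(r, stat) for r in ga]
        xb = [getattr(r, stat) for r in gb]
        U, p = _mannwhitney(xa, xb)
        report[stat] = {
            "U": U, "p": p,
            "median_a": float(np.median(xa)),
            "median_b": float(np.median(xb)),
        }
    return report


def mc_chisq(table: Sequence[Sequence[int]], n_sims: int = 1_000_000,
             seed: int = 0) -> tuple[float, float]:
    """Chi-square statistic with a Monte-Carlo p for a 2x2 table.

    The null fixes both margins; simulated tables are drawn hypergeometrically
    and p = (#{simulated chi2 >= observed} + 1) / (n_sims + 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    N = t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin")
    expected = np.outer(rows, cols) / N
    chi2 = float(((t - expected) ** 2 / expected).sum())

    rng = np.random.default_rng(seed)
    a = rng.hypergeometric(int(cols[0]), int(cols[1]), int(rows[0]),
                           size=n_sims).astype(float)
    sim = np.empty((n_sims, 2, 2))
    sim[:, 0, 0] = a
    sim[:, 0, 1] = rows[0] - a
    sim[:, 1, 0] = cols[0] - a
    sim[:, 1, 1] = N - rows[0] - cols[0] + a
    stat = ((sim - expected) ** 2 / expected).sum(axis=(1, 2))
    p = (np.count_nonzero(stat >= chi2 - 1e-12) + 1) / (n_sims + 1)
    return chi2, float(p)


def rank_top_dN(results: Sequence[KaKsResult], k: int = 25) -> list[KaKsResult]:
    """Top-k results by dN descending, ties broken by gene id."""
    if not results:
        raise ValueError("no results to rank")
    usable = [r for r in results if not math.isnan(r.dN)]
    ranked = sorted(usable, key=lambda r: (-r.dN, r.gene_id))
    if k > len(ranked):
        import logging
        logging.getLogger("spotwing").warning(
            "rank_top_dN: k=%d exceeds %d results", k, len(ranked))
    return ranked[:k]
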