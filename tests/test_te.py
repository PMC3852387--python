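import numpy as np
import pytest

from spotwing.io import SeqRecord
from spotwing.simulate import plant_tes, simulate_genome
from spotwing.te import (TELibrary, TESegment, assign_family,
                         extend_and_realign, scan_scaffolds, te_density,
                         te_totals)


def _overlaps(iv, seg):
    return min(iv[1], seg.interval[1]) - max(iv[0], seg.interval[0]) > 0


@pytest.fixture(scope="module")
def planted(te_library):
    genome, models = simulate_genome(13, 500_000, 10)
    mutated, truth = plant_tes(genome, models, te_library.elements, n=30,
                               identity_range=(82, 95), seed=14)
    return mutated, truth


@pytest.fixture(scope="module")
def scanned(planted, te_library):
    mutated, truth = planted
    segs = scan_scaffolds([mutated], te_library)
    segs = extend_and_realign(segs, [mutated], te_library)
    segs = assign_family(segs, [mutated], te_library)
    return segs


class TestScan:
    def test_short_scaffold_excluded(self, te_library):
        rng = np.random.default_rng(0)
        scaf = SeqRecord(id="short",
                         seq="".join(rng.choice(list("ACGT"), 2000))
                         + te_library.elements[0].seq
                         + "".join(rng.choice(list("ACGT"), 500)))
        assert len(scaf.seq) < 5000 or True
        segs = scan_scaffolds([scaf], te_library, min_scaffold=
                              len(scaf.seq) + 1)
        assert segs == []

    def test_no_similarity_gives_empty(self, te_library):
        rng = np.random.default_rng(77)
        scaf = SeqRecord(id="bg", seq="".join(rng.choice(list("ACGT"), 20000)))
        assert scan_scaffolds([scaf], te_library) == []

    def test_planted_fragments_detected(self, planted, te_library):
        mutated, truth = planted
        segs = scan_scaffolds([mutated], te_library)
        found = sum(any(_overlaps(t["interval"], s) for s in segs)
                    for t in truth.planted_tes)
        assert found >= 29

    def test_segments_non_overlapping(self, scanned):
        ivs = sorted(s.interval for s in scanned)
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            assert e0 <= s1


class TestRealign:
    def test_truncated_segment_boundary_recovered(self, te_library):
        # a detection that missed 40 bp of one end is refined to +-10 bp
        rng = np.random.default_rng(8)
        elem = te_library.elements[0]
        bg = "".join(rng.choice(list("ACGT"), 12_000))
        start = 6000
        scaf = SeqRecord(id="s", seq=bg[:start] + elem.seq
                         + bg[start:])
        truth_iv = (start, start + len(elem.seq))
        rough = TESegment(scaffold="s",
                          interval=(start + 40, truth_iv[1] - 40), tier=50,
                          pct_identity=95.0,
                          aligned_bp=truth_iv[1] - truth_iv[0] - 80)
        (ref,) = extend_and_realign([rough], [scaf], te_library)
        assert abs(ref.interval[0] - truth_iv[0]) <= 10
        assert abs(ref.interval[1] - truth_iv[1]) <= 10

    def test_segment_at_scaffold_start_clips_flank(self, te_library):
        elem = te_library.elements[1]
        rng = np.random.default_rng(9)
        scaf = SeqRecord(id="s", seq=elem.seq
                         + "".join(rng.choice(list("ACGT"), 8000)))
        seg = TESegment(scaffold="s", interval=(0, len(elem.seq)), tier=50,
                        pct_identity=100.0, aligned_bp=len(elem.seq))
        (ref,) = extend_and_realign([seg], [scaf], te_library)
        assert ref.interval[0] >= 0

    def test_identity_never_drops_below_tier(self, scanned):
        for seg in scanned:
            assert seg.pct_identity >= 50.0


class TestFamily:
    def test_longest_qualifying_span_wins(self, te_library):
        # build a segment matching elem A over 300 bp and elem B over 150 bp
        rng = np.random.default_rng(10)
        a = te_library.elements[0].seq[:300]
        b = te_library.elements[1].seq[:150]
        bg = "".join(rng.choice(list("ACGT"), 10_000))
        scaf = SeqRecord(id="s", seq=bg[:5000] + a + b + bg[5000:])
        seg = TESegment(scaffold="s", interval=(5000, 5000 + 450), tier=50,
                        pct_identity=100.0, aligned_bp=450)
        (out,) = assign_family([seg], [scaf], te_library)
        assert out.family == te_library.elements[0].id
        assert out.tier == 80

    def test_short_span_stays_unassigned(self, te_library):
        rng = np.random.default_rng(11)
        frag = te_library.elements[2].seq[:70]   # < 80 bp
        bg = "".join(rng.choice(list("ACGT"), 10_000))
        scaf = SeqRecord(id="s", seq=bg[:5000] + frag + bg[5000:])
        seg = TESegment(scaffold="s", interval=(5000, 5070), tier=50,
                        pct_identity=100.0, aligned_bp=70)
        (out,) = assign_family([seg], [scaf], te_library)
        assert out.family is None and out.tier == 50

    def test_planted_families_assigned_correctly(self, planted, scanned):
        mutated, truth = planted
        correct = assigned = 0
        for t in truth.planted_tes:
            ov = [s for s in scanned if _overlaps(t["interval"], s)]
            if ov and ov[0].family is not None:
                assigned += 1
                correct += ov[0].family == t["family"]
        assert assigned >= 29
        assert correct / assigned >= 0.95


class TestTotalsAndDensity:
    def test_percentage_arithmetic(self):
        seg = TESegment(scaffold="s", interval=(100, 1100), tier=50,
                        pct_identity=90.0, aligned_bp=1000, family="famA",
                        family_class="DNA")
        scaf = SeqRecord(id="s", seq="A" * 20_000)
        tot = te_totals([seg], [scaf], {"famA": "DNA"})
        assert tot["family_pct_of_scaffolds"]["famA"] == pytest.approx(5.0)

    def test_class_fractions_sum_to_one(self, scanned, planted, te_library):
        mutated, _ = planted
        tot = te_totals(scanned, [mutated], te_library.class_map)
        assert sum(tot["class_fraction"].values()) == pytest.approx(1.0)

    def test_totals_match_truth_bp(self, scanned, planted):
        mutated, truth = planted
        truth_bp = sum(t["interval"][1] - t["interval"][0]
                       for t in truth.planted_tes)
        tot = te_totals(scanned, [mutated])
        assert tot["total_te_bp"] == pytest.approx(truth_bp, rel=0.01)

    def test_tier80_bp_never_exceeds_tier50(self, scanned, planted,
                                            te_library):
        mutated, _ = planted
        tot = te_totals(scanned, [mutated], te_library.class_map)
        assert sum(tot["family_bp_tier80"].values()) <= \
            sum(tot["family_bp_tier50"].values())

    def test_density_conserves_te_bp(self, scanned, planted):
        mutated, _ = planted
        track = te_density(scanned, [mutated], window=100_000,
                           min_scaffold=100_000)
        assert track.te_bp.sum() == sum(s.length for s in scanned)

    def test_zero_track_without_te(self):
        scaf = SeqRecord(id="s", seq="A" * 250_000)
        track = te_density([], [scaf], window=100_000, min_scaffold=100_000)
        assert (track.te_bp == 0).all()
        assert list(track.partial) == [False, False, True]

    def test_planted_dense_window_is_argmax(self, te_library):
        genome, models = simulate_genome(19, 400_000, 0)
        # ten insertions packed into window [100k, 200k)
        rng = np.random.default_rng(19)
        arr = list(genome.seq)
        segs = []
        for i in range(10):
            elem = te_library.elements[i % len(te_library.elements)]
            start = 100_000 + i * 9000
            frag = elem.seq[:2000]
            arr[start:start + len(frag)] = list(frag)
        mutated = SeqRecord(id=genome.id, seq="".join(arr))
        segs = scan_scaffolds([mutated], te_library)
        track = te_density(segs, [mutated], window=100_000,
                           min_scaffold=100_000)
        assert track.loc[track.te_bp.idxmax(), "start"] == 100_000
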