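"""Two-tier transposable-element detection, family assignment and density.

Tier 50: contiguous regions of a scaffold aligning to any library element at
>= 50% identity (scaffolds under 5 kb are skipped; hits overlapping or within
10 bp of one another are merged across elements).  Each region is then
re-aligned with 500 bp of flank to refine its boundaries.  Tier 80: a region
receives a family when some element aligns at >= 80% identity over >= 80
contiguous bp; the family with the longest qualifying span wins (ties: higher
identity, then name).  Summaries report per-family bp at both tiers, the
percentage of scaffold sequence occupied, the DNA/RNA split, and per-100-kb
density tracks for large scaffolds.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import AlignmentHit, local_align, _seed_index
from .io import SeqRecord

log = logging.getLogger("spotwing")

__all__ = [
    "TESegment",
    "TELibrary",
    "scan_scaffolds",
    "extend_and_realign",
    "assign_family",
    "te_totals",
    "te_density",
    "MIN_SCAFFOLD",
    "TIER50",
    "TIER80",
    "FAMILY_MIN_BP",
    "FLANK",
    "MERGE_GAP",
]

MIN_SCAFFOLD = 5000       # bp; scaffolds shorter than this are not scanned
TIER50 = 50.0             # detection identity threshold, percent
TIER80 = 80.0             # family-assignment identity threshold, percent
FAMILY_MIN_BP = 80        # minimum contiguous aligned bp for a family call
FLANK = 500               # bp of flank added before re-alignment
MERGE_GAP = 10            # bp; hits closer than this merge into one region


@dataclasses.dataclass
class TESegment:
    """A genomic interval assigned to an identity tier and optional family."""

    scaffold: str
    interval: tuple[int, int]
    tier: int
    pct_identity: float
    aligned_bp: int
    family: Optional[str] = None
    family_class: str = "unknown"

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclasses.dataclass
class TELibrary:
    """A set of reference TE sequences plus a family -> DNA/RNA class map."""

    elements: list[SeqRecord]
    class_map: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [e.id for e in self.elements if e.id not in self.class_map]
        if self.class_map and missing:
            raise ValueError(f"class_map missing families: {missing}")


def _scaffold_hits(scaffold: SeqRecord, library: Sequence[SeqRecord],
                   min_score: float = 25) -> list[AlignmentHit]:
    index = _seed_index(scaffold.seq)
    hits: list[AlignmentHit] = []
    for elem in library:
        hits.extend(local_align(elem, scaffold, min_score=min_score,
                                subject_index=index))
    return hits


def _merge_regions(hits: Iterable[AlignmentHit], min_identity: float,
                   gap: int = MERGE_GAP) -> list[tuple[int, int, float, int]]:
    """Merge qualifying hit subject-intervals into maximal contiguous regions.

    Returns (start, end, weighted identity, aligned bp) tuples.
    """
    ivs = sorted((h.s_interval[0], h.s_interval[1], h.pct_identity, h.aln_len)
                 for h in hits if h.pct_identity >= min_identity)
    merged: list[tuple[int, int, float, int]] = []
    for s, e, ident, alen in ivs:
        if merged and s <= merged[-1][1] + gap:
            ps, pe, pid, pal = merged[-1]
            total = pal + alen
            merged[-1] = (ps, max(pe, e),
                          (pid * pal + ident * alen) / total, total)
        else:
            merged.append((s, e, ident, alen))
    return merged


def scan_scaffolds(scaffolds: Sequence[SeqRecord], library: TELibrary,
                   min_scaffold: int = MIN_SCAFFOLD,
                   hits: Optional[Sequence[AlignmentHit]] = None,
                   ) -> list[TESegment]:
    """Tier-50 detection of TE-derived regions on scaffolds >= 5 kb."""
    segments: list[TESegment] = []
    for scaf in scaffolds:
        if len(scaf.seq) < min_scaffold:
            continue
        scaf_hits = ([h for h in hits if h.subject_id == scaf.id]
                     if hits is not None
                     else _scaffold_hits(scaf, library.elements))
        for s, e, ident, alen in _merge_regions(scaf_hits, TIER50):
            segments.append(TESegment(
                scaffold=scaf.id, interval=(s, e), tier=50,
                pct_identity=ident, aligned_bp=alen))
    log.info("scan_scaffolds: %d tier-50 segments", len(segments))
    return segments


def extend_and_realign(segments: Sequence[TESegment],
                       scaffolds: Sequence[SeqRecord], library: TELibrary,
                       flank: int = FLANK) -> list[TESegment]:
    """Re-align each segment with flanks and adopt the refined interval."""
    seqs = {s.id: s.seq for s in scaffolds}
    refined: list[TESegment] = []
    for seg in segments:
        scaf = seqs[seg.scaffold]
        lo = max(0, seg.interval[0] - flank)
        hi = min(len(scaf), seg.interval[1] + flank)
        window = SeqRecord(id=seg.scaffold, seq=scaf[lo:hi])
        hits = []
        for elem in library.elements:
            hits.extend(local_align(elem, window, min_score=25))
        regions = _merge_regions(hits, TIER50)
        if not regions:
            refined.append(seg)
            continue
        # region best overlapping the original segment, else the longest
        best = max(regions, key=lambda r: (
            min(r[1] + lo, seg.interval[1]) - max(r[0] + lo, seg.interval[0]),
            r[1] - r[0]))
        s, e, ident, alen = best
        refined.append(TESegment(
            scaffold=seg.scaffold, interval=(s + lo, e + lo), tier=seg.tier,
            pct_identity=max(ident, TIER50), aligned_bp=alen,
            family=seg.family, family_class=seg.family_class))
    return refined


def assign_family(segments: Sequence[TESegment],
                  scaffolds: Sequence[SeqRecord], library: TELibrary,
                  ) -> list[TESegment]:
    """Tier-80 family assignment by the longest qualifying aligned span."""
    seqs = {s.id: s.seq for s in scaffolds}
    out: list[TESegment] = []
    for seg in segments:
        window = SeqRecord(
            id=seg.scaffold,
            seq=seqs[seg.scaffold][seg.interval[0] : seg.interval[1]])
        best: Optional[tuple[int, float, str]] = None  # (span, identity, name)
        for elem in library.elements:
            for h in local_align(elem, window, min_score=25):
                span = h.s_len
                if h.pct_identity >= TIER80 and span >= FAMILY_MIN_BP:
                    cand = (span, h.pct_identity, elem.id)
                    if best is None or (cand[0], cand[1]) > (best[0], best[1]) \
                            or ((cand[0], cand[1]) == (best[0], best[1])
                                and cand[2] < best[2]):
                        best = cand
        seg = dataclasses.replace(seg)
        if best is not None:
            seg.family = best[2]
            seg.tier = 80
            seg.family_class = library.class_map.get(best[2], "unknown")
        out.append(seg)
    n_assigned = sum(s.family is not None for s in out)
    log.info("assign_family: %d/%d segments assigned", n_assigned, len(out))
    return out


def te_totals(segments: Sequence[TESegment], scaffolds: Sequence[SeqRecord],
              class_map: Optional[dict[str, str]] = None,
              min_scaffold: int = MIN_SCAFFOLD,
              denominator: str = "total") -> dict:
    """Per-family bp at each tier, scaffold percentages, DNA/RNA split."""
    if denominator not in {"total", "contig"}:
        raise ValueError("denominator must be 'total' or 'contig'")
    scafs = [s for s in scaffolds if len(s.seq) >= min_scaffold]
    if denominator == "contig":
        denom = sum(len(s.seq) - s.seq.count("N") for s in scafs)
    else:
        denom = sum(len(s.seq) for s in scafs)
    fam50: dict[str, int] = defaultdict(int)
    fam80: dict[str, int] = defaultdict(int)
    class_bp: dict[str, int] = defaultdict(int)
    cmap = class_map or {}
    for seg in segments:
        fam = seg.family or "unassigned"
        fam50[fam] += seg.length
        if seg.family is not None and seg.tier == 80:
            fam80[fam] += seg.length
        cls = seg.family_class if seg.family else "unknown"
        if cmap and seg.family:
            cls = cmap.get(seg.family, cls)
        class_bp[cls] += seg.length
    total = sum(fam50.values())
    return {
        "family_bp_tier50": dict(fam50),
        "family_bp_tier80": dict(fam80),
        "family_pct_of_scaffolds": {f: 100.0 * bp / denom
                                    for f, bp in fam50.items()},
        "total_te_bp": total,
        "pct_of_scaffolds": 100.0 * total / denom if denom else 0.0,
        "class_fraction": {c: bp / total for c, bp in class_bp.items()}
        if total else {},
    }


def te_density(segments: Sequence[TESegment], scaffolds: Sequence[SeqRecord],
               window: int = 100_000, min_scaffold: int = 5_000_000,
               ) -> pd.DataFrame:
    """TE bp per non-overlapping window for scaffolds above the size floor.

    The last, partial window of each scaffold is kept and flagged.  Window
    values conserve the total segment-scaffold overlap exactly.
    """
    by_scaffold: dict[str, list[TESegment]] = defaultdict(list)
    for seg in segments:
        by_scaffold[seg.scaffold].append(seg)
    rows = []
    for scaf in scaffolds:
        if len(scaf.seq) < min_scaffold:
            continue
        n_windows = (len(scaf.seq) + window - 1) // window
        for w in range(n_windows):
            ws, we = w * window, min((w + 1) * window, len(scaf.seq))
            bp = 0
            for seg in by_scaffold.get(scaf.id, ()):
                lo = max(ws, seg.interval[0])
                hi = min(we, seg.interval[1])
                bp += max(0, hi - lo)
            rows.append((scaf.id, ws, we, bp, we - ws < window))
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "te_bp", "partial"])
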