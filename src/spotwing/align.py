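"""Minimal seed-and-extend local aligner.

Seeds are exact 11-mer matches; each seed cluster is extended by an affine-gap
Smith-Waterman restricted to a window around the cluster.  Hits carry percent
identity over aligned columns (gap columns included), which is what every
downstream rule consumes; scores use match +1 / mismatch -1 / gap open -3 /
gap extend -1 by default.  Externally produced 12-column tabular hits can be
substituted anywhere AlignmentHits are accepted.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Optional

from Bio import Align

from ._util import revcomp
from .io import SeqRecord

__all__ = ["AlignmentHit", "local_align", "best_hits"]

SEED_LEN = 11


@dataclasses.dataclass
class AlignmentHit:
    """One local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    q_interval: tuple[int, int]   # 0-based half-open, query forward strand
    s_interval: tuple[int, int]   # 0-based half-open, subject forward strand
    s_strand: str                 # '+' or '-'
    score: float

    def __post_init__(self) -> None:
        if not 0 < self.pct_identity <= 100:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")

    @property
    def q_len(self) -> int:
        return self.q_interval[1] - self.q_interval[0]

    @property
    def s_len(self) -> int:
        return self.s_interval[1] - self.s_interval[0]


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # N never counts as a match: give it the mismatch score against everything.
    from Bio.Align import substitution_matrices
    import numpy as np

    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2,
                                      data=np.full((5, 5), mismatch))
    for i, a in enumerate("ACGT"):
        mat[a, a] = match
    aligner.substitution_matrix = mat
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _seed_index(seq: str, k: int = SEED_LEN) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _cluster_seeds(seeds: list[tuple[int, int]], band: int = 40,
                   max_gap: int = 300) -> list[list[tuple[int, int]]]:
    """Group (qpos, spos) seeds into candidate loci by diagonal and proximity."""
    seeds = sorted(seeds, key=lambda t: (t[1] - t[0], t[0]))
    clusters: list[list[tuple[int, int]]] = []
    for q, s in seeds:
        d = s - q
        placed = False
        for cl in reversed(clusters):
            lq, ls = cl[-1]
            if abs(d - (ls - lq)) <= band and abs(q - lq) <= max_gap:
                cl.append((q, s))
                placed = True
                break
        if not placed:
            clusters.append([(q, s)])
    return clusters


def _align_window(aligner, query: str, subject: str, q_win: tuple[int, int],
                  s_win: tuple[int, int]) -> Optional[tuple]:
    qs, qe = q_win
    ss, se = s_win
    qsub, ssub = query[qs:qe], subject[ss:se]
    if not qsub or not ssub:
        return None
    alns = aligner.align(qsub, ssub)
    try:
        aln = alns[0]
    except (IndexError, ValueError):
        return None
    # identity over aligned columns, gap columns included
    matches = 0
    columns = 0
    blocks_q, blocks_s = aln.aligned
    prev_q = prev_s = None
    for (qa, qb), (sa, sb) in zip(blocks_q, blocks_s):
        if prev_q is not None:
            columns += max(qa - prev_q, sa - prev_s)
        for x, y in zip(qsub[qa:qb], ssub[sa:sb]):
            matches += x == y and x != "N"
        columns += qb - qa
        prev_q, prev_s = qb, sb
    if columns == 0:
        return None
    q0, q1 = int(blocks_q[0][0]) + qs, int(blocks_q[-1][1]) + qs
    s0, s1 = int(blocks_s[0][0]) + ss, int(blocks_s[-1][1]) + ss
    return (aln.score, matches, columns, (q0, q1), (s0, s1))


def local_align(query: SeqRecord, subject: SeqRecord, min_score: float = 20,
                match: float = 1, mismatch: float = -1, gap_open: float = -3,
                gap_extend: float = -1,
                subject_index: Optional[dict[str, list[int]]] = None,
                ) -> list[AlignmentHit]:
    """Seed-and-extend local alignment of query against both subject strands.

    ``subject_index`` allows reusing a precomputed 11-mer index of the
    subject's forward strand across many queries.
    """
    qseq, sseq = query.seq, subject.seq
    if not qseq or not sseq:
        return []
    if subject_index is None:
        subject_index = _seed_index(sseq)
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    hits: list[AlignmentHit] = []
    slen = len(sseq)

    for strand in "+-":
        q = qseq if strand == "+" else revcomp(qseq)
        seeds = []
        for i in range(len(q) - SEED_LEN + 1):
            kmer = q[i : i + SEED_LEN]
            if "N" in kmer:
                continue
            for pos in subject_index.get(kmer, ()):
                seeds.append((i, pos))
        for cl in _cluster_seeds(seeds):
            q_lo = min(p for p, _ in cl)
            q_hi = max(p for p, _ in cl) + SEED_LEN
            s_lo = min(p for _, p in cl)
            s_hi = max(p for _, p in cl) + SEED_LEN
            margin = 60
            q_win = (max(0, q_lo - margin), min(len(q), q_hi + margin))
            s_win = (max(0, s_lo - margin), min(slen, s_hi + margin))
            res = _align_window(aligner, q, sseq, q_win, s_win)
            if res is None:
                continue
            score, matches, columns, (q0, q1), (s0, s1) = res
            if score < min_score or matches == 0:
                continue
            if strand == "-":
                q0, q1 = len(q) - q1, len(q) - q0
            hits.append(AlignmentHit(
                query_id=query.id, subject_id=subject.id,
                pct_identity=100.0 * matches / columns, aln_len=columns,
                q_interval=(q0, q1), s_interval=(s0, s1),
                s_strand=strand, score=float(score)))

    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.score, -h.pct_identity, h.q_interval[0]))
    return hits


def _dedupe(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose subject interval is largely contained in a better hit."""
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        redundant = False
        for k in kept:
            if k.s_strand != h.s_strand:
                continue
            lo = max(k.s_interval[0], h.s_interval[0])
            hi = min(k.s_interval[1], h.s_interval[1])
            if hi - lo > 0.8 * h.s_len:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def best_hits(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    """Group hits per query, ordered by score, identity, query start."""
    grouped: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    for hs in grouped.values():
        hs.sort(key=lambda h: (-h.score, -h.pct_identity, h.q_interval[0]))
    return dict(grouped)
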