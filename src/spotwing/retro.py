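"""Retrogene detection: a cascade of filters over gene-vs-genome alignments.

A retrogene is an intronless genomic copy of a multi-exon parental gene,
created by reverse transcription of a processed mRNA.  The cascade:

1. build a nonredundant gene set, discarding genes whose longest ORF is
   under 100 amino acids;
2. keep genes with two or more genomic loci at >= 75% identity covering
   > 70% of the query (the gene's own annotated locus counts as one);
3. call a retrogene when the duplicate locus covers >= 70% of the parental
   CDS in one contiguous block (gaps <= 30 bp, i.e. no intron-sized breaks),
   the parent has >= 2 exons, an ORF is present at the copy, and no outgroup
   set contains a homolog passing the same duplicate thresholds.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from typing import Iterable, Optional, Sequence

from ._util import longest_orf_aa
from .align import AlignmentHit, best_hits, local_align, _seed_index
from .io import GeneModel, SeqRecord

log = logging.getLogger("spotwing")

__all__ = [
    "RetrogeneCall",
    "build_gene_set",
    "find_young_duplicates",
    "call_retrogenes",
    "chromosome_bias_summary",
    "MIN_IDENTITY",
    "MIN_QUERY_COV",
    "MIN_CDS_COV",
    "MIN_ORF_AA",
    "MAX_CONTIG_GAP",
]

MIN_IDENTITY = 75.0    # percent identity for a duplicate locus
MIN_QUERY_COV = 0.70   # query coverage for a duplicate locus
MIN_CDS_COV = 0.70     # parental CDS coverage for a retrogene call
MIN_ORF_AA = 100       # minimum ORF length, amino acids
MAX_CONTIG_GAP = 30    # bp; larger breaks on the copy indicate introns


@dataclasses.dataclass
class RetrogeneCall:
    """One called retrogene: parent gene plus its intronless genomic copy."""

    parent_gene_id: str
    parent_scaffold: str
    copy_scaffold: str
    copy_interval: tuple[int, int]
    pct_identity: float
    cds_coverage: float
    intronless: bool = True
    lineage_specific: bool = True


def build_gene_set(annotated: Sequence[tuple[GeneModel, str]],
                   transcripts: Sequence[SeqRecord] = (),
                   min_orf_aa: int = MIN_ORF_AA,
                   ) -> list[tuple[str, str]]:
    """Nonredundant (gene_id, sequence) set from annotation plus transcripts.

    Sequences identical to, or fully contained in, an earlier entry are
    dropped; so are entries whose longest ORF is under ``min_orf_aa``.
    """
    entries = [(m.gene_id, seq.upper()) for m, seq in annotated]
    entries += [(t.id, t.seq) for t in transcripts]
    entries = [(gid, s) for gid, s in entries
               if longest_orf_aa(s) >= min_orf_aa]
    # longest first so containment checks see the keeper first
    entries.sort(key=lambda e: -len(e[1]))
    kept: list[tuple[str, str]] = []
    for gid, s in entries:
        if any(s in ks for _, ks in kept):
            continue
        kept.append((gid, s))
    log.info("build_gene_set: %d nonredundant genes", len(kept))
    return kept


def _merge_loci(hits: list[AlignmentHit], gap: int = 1000,
                ) -> list[list[AlignmentHit]]:
    """Group hits into loci: same scaffold, overlapping/nearby subject spans."""
    by_scaffold: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_scaffold[h.subject_id].append(h)
    loci: list[list[AlignmentHit]] = []
    for hs in by_scaffold.values():
        hs.sort(key=lambda h: h.s_interval[0])
        cur = [hs[0]]
        end = hs[0].s_interval[1]
        for h in hs[1:]:
            if h.s_interval[0] <= end + gap:
                cur.append(h)
                end = max(end, h.s_interval[1])
            else:
                loci.append(cur)
                cur = [h]
                end = h.s_interval[1]
        loci.append(cur)
    return loci


def _locus_stats(locus: list[AlignmentHit], query_len: int,
                 ) -> tuple[float, float, tuple[int, int], int]:
    """(identity, query coverage, subject span, max internal subject gap)."""
    qcov = set()
    for h in locus:
        qcov.update(range(*h.q_interval))
    ident = sum(h.pct_identity * h.aln_len for h in locus) \
        / sum(h.aln_len for h in locus)
    s_ivs = sorted(h.s_interval for h in locus)
    span = (s_ivs[0][0], max(e for _, e in s_ivs))
    gap = 0
    end = s_ivs[0][1]
    for s, e in s_ivs[1:]:
        if s > end:
            gap = max(gap, s - end)
        end = max(end, e)
    return ident, len(qcov) / query_len, span, gap


def find_young_duplicates(genes: Sequence[tuple[str, str]],
                          hits: Iterable[AlignmentHit],
                          min_identity: float = MIN_IDENTITY,
                          min_query_cov: float = MIN_QUERY_COV,
                          ) -> dict[str, list[list[AlignmentHit]]]:
    """Genes with >= 2 genomic loci at the identity/coverage thresholds."""
    lengths = {gid: len(s) for gid, s in genes}
    grouped = best_hits(h for h in hits if h.query_id in lengths)
    candidates: dict[str, list[list[AlignmentHit]]] = {}
    for gid, hs in grouped.items():
        loci = _merge_loci(hs)
        qualifying = []
        for locus in loci:
            ident, cov, _, _ = _locus_stats(locus, lengths[gid])
            if ident >= min_identity and cov > min_query_cov:
                qualifying.append(locus)
        if len(qualifying) >= 2:
            candidates[gid] = qualifying
    log.info("find_young_duplicates: %d/%d genes with >=2 loci",
             len(candidates), len(lengths))
    return candidates


def _self_locus(locus: list[AlignmentHit], model: GeneModel) -> bool:
    _, _, span, _ = _locus_stats(locus, 1)
    if locus[0].subject_id != model.scaffold:
        return False
    gs, ge = model.span
    return not (span[1] <= gs or span[0] >= ge)


def _outgroup_has_homolog(gene_seq: str, gene_id: str,
                          outgroup: Sequence[SeqRecord],
                          min_identity: float, min_query_cov: float) -> bool:
    query = SeqRecord(id=gene_id, seq=gene_seq)
    for og in outgroup:
        hits = local_align(query, og)
        if not hits:
            continue
        for locus in _merge_loci(hits):
            ident, cov, _, _ = _locus_stats(locus, len(gene_seq))
            if ident >= min_identity and cov > min_query_cov:
                return True
    return False


def call_retrogenes(candidates: dict[str, list[list[AlignmentHit]]],
                    genes: Sequence[tuple[str, str]],
                    gene_models: Sequence[GeneModel],
                    genome: Sequence[SeqRecord],
                    outgroup_homolog_sets: Sequence[Sequence[SeqRecord]] = (),
                    min_cds_cov: float = MIN_CDS_COV,
                    max_gap: int = MAX_CONTIG_GAP,
                    min_orf_aa: int = MIN_ORF_AA,
                    ) -> list[RetrogeneCall]:
    """Apply the parental / coverage / intronless / lineage filters."""
    models = {m.gene_id: m for m in gene_models}
    seqs = dict(genes)
    scaffolds = {s.id: s.seq for s in genome}
    calls: list[RetrogeneCall] = []
    for gid, loci in candidates.items():
        model = models.get(gid)
        if model is None or model.n_exons < 2:
            continue  # parent must be a multi-exon gene
        gene_seq = seqs[gid]
        cds_len = model.cds_length
        for locus in loci:
            if _self_locus(locus, model):
                continue
            ident, _, span, gap = _locus_stats(locus, len(gene_seq))
            # coverage of the parental CDS by the aligned copy
            covered = set()
            for h in locus:
                covered.update(range(*h.q_interval))
            cds_cov = min(len(covered), cds_len) / cds_len
            if cds_cov < min_cds_cov:
                continue
            if gap > max_gap:
                continue  # intron-sized break on the copy
            copy_scaffold = locus[0].subject_id
            copy_seq = scaffolds[copy_scaffold][span[0] : span[1]]
            if longest_orf_aa(copy_seq) < min_orf_aa:
                continue
            if outgroup_homolog_sets and any(
                    _outgroup_has_homolog(gene_seq, gid, og,
                                          MIN_IDENTITY, MIN_QUERY_COV)
                    for og in outgroup_homolog_sets):
                continue
            calls.append(RetrogeneCall(
                parent_gene_id=gid, parent_scaffold=model.scaffold,
                copy_scaffold=copy_scaffold, copy_interval=span,
                pct_identity=ident, cds_coverage=cds_cov))
    log.info("call_retrogenes: %d calls", len(calls))
    return calls


def chromosome_bias_summary(calls: Sequence[RetrogeneCall],
                            scaffold_to_element: dict[str, str],
                            ) -> dict[tuple[str, str], int]:
    """Contingency counts of parent X/autosome vs copy X/autosome.

    Muller element A is the X chromosome; all other elements are autosomal.
    The map may give 'X'/'A' directly or Muller element letters.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for c in calls:
        p = scaffold_to_element.get(c.parent_scaffold)
        q = scaffold_to_element.get(c.copy_scaffold)
        if p is None or q is None:
            log.warning("unmapped scaffold in call %s", c.parent_gene_id)
            counts[("unknown", "unknown")] += 1
            continue
        p = "X" if p.upper() in {"X", "MULLER_A"} else "A"
        q = "X" if q.upper() in {"X", "MULLER_A"} else "A"
        counts[(p, q)] += 1
    return dict(counts)
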