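"""Readers and writers for the standard formats the pipeline touches.

Internal convention: all coordinates are 0-based half-open.  Conversion to the
1-based inclusive conventions of GFF3 and tabular BLAST-style hit files
happens here and only here.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger("spotwing")

__all__ = [
    "SeqRecord",
    "GeneModel",
    "RunConfig",
    "read_sequences",
    "write_sequences",
    "read_hits",
    "write_hits",
    "read_gene_models",
    "write_gene_models",
    "write_bed",
]


@dataclasses.dataclass
class SeqRecord:
    """A named nucleotide sequence with optional Phred qualities."""

    id: str
    seq: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.seq):
            raise ValueError(f"record {self.id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass
class GeneModel:
    """A gene with its exon structure on a scaffold (0-based half-open exons)."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    cds_length: int = 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        self.exons = sorted(tuple(e) for e in self.exons)
        last = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
            if last is not None and s < last:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            last = e
        if self.cds_length == 0:
            self.cds_length = self.exon_span
        if self.cds_length > self.exon_span:
            raise ValueError(f"{self.gene_id}: cds_length exceeds exon span")

    @property
    def exon_span(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def spliced_seq(self, scaffold_seq: str) -> str:
        """Concatenated exon sequence in transcription order."""
        from ._util import revcomp

        s = "".join(scaffold_seq[a:b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_DEFAULTS: dict[str, object] = {
    "kmer_size": 17,              # k-mer length for the genome-size estimate
    "canonical_kmers": False,
    "seed": 0,
    "min_scaffold_bp": 5000,      # TE scan scaffold floor
    "te_flank_bp": 500,
    "te_window_bp": 100_000,
    "te_density_min_scaffold_bp": 5_000_000,
    "retro_min_identity": 75.0,
    "retro_min_query_cov": 0.70,
    "retro_min_cds_cov": 0.70,
    "retro_min_orf_aa": 100,
    "delta_threshold": 2,
    "ease_threshold": 0.1,
    "fold_min": 2.0,
    "fpkm_min": 2.0,
}


@dataclasses.dataclass
class RunConfig:
    """Flat key/value run settings; unknown keys are rejected."""

    values: dict[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_CONFIG_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str) -> object:
        return self.values[key]

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        return cls(values=data)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_sequences(path: str | Path, format: str = "fasta") -> list[SeqRecord]:
    """Read FASTA or FASTQ (Phred+33) records in file order."""
    if format not in {"fasta", "fastq"}:
        raise ValueError(f"unsupported format {format!r}")
    records: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(str(path), format):
            qual = None
            if format == "fastq":
                qual = list(rec.letter_annotations["phred_quality"])
            records.append(SeqRecord(id=rec.id, seq=str(rec.seq), quality=qual))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {format} record: {exc}") from exc
    return records


def write_sequences(path: str | Path, records: Iterable[SeqRecord],
                    format: str = "fasta") -> None:
    bio = []
    for r in records:
        rec = _BioSeqRecord(Seq(r.seq), id=r.id, description="")
        if format == "fastq":
            if r.quality is None:
                raise ValueError(f"record {r.id!r}: FASTQ output needs qualities")
            rec.letter_annotations["phred_quality"] = list(r.quality)
        bio.append(rec)
    SeqIO.write(bio, str(path), format)


# ---------------------------------------------------------------------------
# 12-column tabular alignment hits (BLAST outfmt-6 style)

def read_hits(path: str | Path):
    """Parse a 12-column tabular hit file into AlignmentHit objects.

    File coordinates are 1-based inclusive; subject start > end encodes the
    minus strand.  Internally everything becomes 0-based half-open with an
    explicit strand flag.
    """
    from .align import AlignmentHit

    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            (qid, sid, pident, length, _mm, _go,
             qstart, qend, sstart, send, _ev, bits) = cols
            qs, qe = int(qstart), int(qend)
            ss, se = int(sstart), int(send)
            if ss <= se:
                strand, s_iv = "+", (ss - 1, se)
            else:
                strand, s_iv = "-", (se - 1, ss)
            hits.append(AlignmentHit(
                query_id=qid, subject_id=sid,
                pct_identity=float(pident), aln_len=int(length),
                q_interval=(qs - 1, qe), s_interval=s_iv,
                s_strand=strand, score=float(bits),
            ))
    return hits


def write_hits(path: str | Path, hits) -> None:
    with open(path, "w") as fh:
        for h in hits:
            qs, qe = h.q_interval
            ss, se = h.s_interval
            if h.s_strand == "+":
                sstart, send = ss + 1, se
            else:
                sstart, send = se, ss + 1
            n_mismatch = round(h.aln_len * (1 - h.pct_identity / 100))
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_len,
                n_mismatch, 0, qs + 1, qe, sstart, send, "0.0",
                f"{h.score:.1f}",
            ])) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models

def write_gene_models(path: str | Path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gs, ge = m.span
            attrs = f"ID={m.gene_id};cds_length={m.cds_length}"
            fh.write("\t".join(map(str, [
                m.scaffold, "spotwing", "gene", gs + 1, ge, ".", m.strand,
                ".", attrs])) + "\n")
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write("\t".join(map(str, [
                    m.scaffold, "spotwing", "exon", s + 1, e, ".", m.strand,
                    ".", f"ID={m.gene_id}.e{i};Parent={m.gene_id}"])) + "\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            scaffold, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[attr["ID"]] = {
                    "scaffold": scaffold, "strand": strand, "exons": [],
                    "cds_length": int(attr.get("cds_length", 0)),
                }
            elif ftype == "exon":
                parent = attr["Parent"]
                genes.setdefault(parent, {
                    "scaffold": scaffold, "strand": strand, "exons": [],
                    "cds_length": 0})
                genes[parent]["exons"].append((int(start) - 1, int(end)))
    models = []
    for gid, g in genes.items():
        exons = g["exons"] or [(0, 1)]
        models.append(GeneModel(gene_id=gid, scaffold=g["scaffold"],
                                strand=g["strand"], exons=exons,
                                cds_length=g["cds_length"]))
    return models


def write_bed(path: str | Path, rows: Iterable[tuple]) -> None:
    """Write (chrom, start, end, value, ...) rows as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")
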