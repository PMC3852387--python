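"""Synthetic genomes, reads, expression tables, family matrices and codon
pairs with planted ground truth.

Every generator is a pure function of its seed and parameters.  The mutation
model for identity planting is uniform random substitution (no indels), so
Hamming identity of a planted copy is unambiguous for oracle checks.
Retrocopies are spliced (intron-free) parental CDS, matching the biology of
retroposition; substitutions that would create an in-frame stop are redrawn
because the emulated retrogenes carry complete ORFs.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, is_transition, revcomp
from .io import GeneModel, SeqRecord

__all__ = [
    "SyntheticTruth",
    "simulate_genome",
    "plant_retrogenes",
    "plant_tes",
    "simulate_reads",
    "simulate_expression",
    "simulate_family_matrix",
    "evolve_codon_pair",
]

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth sufficient to score every downstream caller."""

    planted_retrogenes: list[tuple[str, tuple[int, int], float]] = \
        dataclasses.field(default_factory=list)
    planted_tes: list[dict] = dataclasses.field(default_factory=list)
    sexbias_labels: dict[str, str] = dataclasses.field(default_factory=dict)
    family_events: dict[str, float] = dataclasses.field(default_factory=dict)
    codon_truth: dict[str, tuple[float, float]] = \
        dataclasses.field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# genome + gene models

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    body = "".join(SENSE_CODONS[i] for i in codons)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + body + stop


def simulate_genome(seed: int, length: int, n_genes: int,
                    exons_per_gene: tuple[int, int] = (2, 6),
                    scaffold_id: str = "scaffold1",
                    ) -> tuple[SeqRecord, list[GeneModel]]:
    """Uniform-random background with non-overlapping multi-exon genes.

    Gene CDSs are ATG-initiated open reading frames split across exons by
    introns of 60-200 bp; exon/intron structure is recorded in the returned
    GeneModels (coordinates 0-based half-open).
    """
    rng = np.random.default_rng(seed)
    genome = rng.choice(_BASES, size=length)
    models: list[GeneModel] = []
    occupied: list[tuple[int, int]] = []
    margin = 200

    for gi in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        n_codons = int(rng.integers(120, 400))
        cds = _random_cds(rng, n_codons)
        # split the CDS into exon pieces of >= 60 nt (alignable); cap the
        # exon count by what the CDS length can host
        min_piece = 60
        n_ex = max(min(n_ex, len(cds) // min_piece),
                   1 if exons_per_gene[0] <= 1 else 2)
        cuts = np.array([], dtype=int)
        if n_ex > 1:
            slack = (len(cds) - min_piece * n_ex) // 3
            extra = rng.multinomial(slack, [1 / n_ex] * n_ex) * 3
            plens0 = min_piece + extra
            plens0[-1] += len(cds) - plens0.sum()
            cuts = np.cumsum(plens0[:-1])
        pieces = np.split(np.arange(len(cds)), cuts)
        introns = [int(rng.integers(60, 201)) for _ in range(n_ex - 1)]
        footprint = len(cds) + sum(introns)
        if footprint + 2 * margin >= length:
            raise ValueError("genome too short for requested genes")
        start = _place(rng, length, footprint, occupied, margin)
        if start is None:
            raise ValueError(
                f"infeasible packing: could not place gene {gi} "
                f"({n_genes} genes in {length} bp)")
        strand = "+" if rng.random() < 0.5 else "-"
        gene_seq = cds if strand == "+" else revcomp(cds)
        exons = []
        pos = start
        # exon lengths follow the CDS pieces; on '-' the genomic order of
        # pieces is reversed so the spliced sequence reads as the CDS
        plens = [len(p) for p in pieces]
        if strand == "-":
            plens = plens[::-1]
        for i, plen in enumerate(plens):
            exons.append((pos, pos + plen))
            pos += plen
            if i < len(introns):
                pos += introns[i]
        genomic = gene_seq  # spliced sequence in genomic orientation
        cursor = 0
        for (a, b) in exons:
            genome[a:b] = list(genomic[cursor : cursor + (b - a)])
            cursor += b - a
        occupied.append((start, pos))
        models.append(GeneModel(
            gene_id=f"g{gi:04d}", scaffold=scaffold_id, strand=strand,
            exons=exons, cds_length=len(cds)))

    return SeqRecord(id=scaffold_id, seq="".join(genome)), models


def _place(rng: np.random.Generator, length: int, footprint: int,
           occupied: list[tuple[int, int]], margin: int,
           tries: int = 2000) -> Optional[int]:
    for _ in range(tries):
        start = int(rng.integers(margin, length - footprint - margin))
        iv = (start - margin, start + footprint + margin)
        if all(iv[1] <= s or iv[0] >= e for s, e in occupied):
            return start
    return None


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float,
                        keep_frame_open: bool = False) -> str:
    """Point-mutate ``seq`` with per-base probability 1 - identity/100.

    With ``keep_frame_open`` the start codon is preserved and substitutions
    creating an in-frame stop codon are redrawn (a different base, or
    reverted if no alternative), so the copy keeps a complete ORF.
    """
    p = 1 - identity / 100.0
    arr = list(seq)
    sites = np.flatnonzero(rng.random(len(arr)) < p)
    for i in sites:
        if keep_frame_open and i < 3:
            continue
        old = arr[i]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for b in choices:
            arr[i] = b
            if not keep_frame_open:
                break
            c0 = (i // 3) * 3
            if "".join(arr[c0 : c0 + 3]) not in STOP_CODONS:
                break
        else:
            arr[i] = old
    return "".join(arr)


def _intergenic_slots(genome_len: int, models: Sequence[GeneModel],
                      taken: list[tuple[int, int]], size: int,
                      rng: np.random.Generator, margin: int = 1100,
                      tries: int = 4000) -> Optional[int]:
    blocked = [m.span for m in models] + list(taken)
    for _ in range(tries):
        start = int(rng.integers(0, genome_len - size))
        iv = (start - margin, start + size + margin)
        if all(iv[1] <= s or iv[0] >= e for s, e in blocked):
            return start
    return None


def plant_retrogenes(genome: SeqRecord, models: Sequence[GeneModel], n: int,
                     identity: float, seed: int,
                     truth: Optional[SyntheticTruth] = None,
                     ) -> tuple[SeqRecord, SyntheticTruth]:
    """Overwrite intergenic background with mutated spliced-CDS retrocopies.

    Parents are drawn from multi-exon genes; the planted copy is the parent's
    concatenated CDS point-mutated to the requested identity.  Planting
    overwrites background (genome length and gene coordinates are unchanged).
    """
    if not 0 < identity <= 100:
        raise ValueError(f"identity must be in (0, 100]: {identity}")
    rng = np.random.default_rng(seed)
    truth = truth or SyntheticTruth()
    if n == 0:
        return genome, truth
    parents = [m for m in models if m.n_exons >= 2]
    if len(parents) < n:
        raise ValueError(f"need {n} multi-exon parents, have {len(parents)}")
    chosen = rng.choice(len(parents), size=n, replace=False)
    seq = genome.seq
    taken = [tuple(iv) for _, iv, _ in truth.planted_retrogenes]
    taken += [tuple(t["interval"]) for t in truth.planted_tes]
    arr = list(seq)
    for idx in chosen:
        parent = parents[idx]
        cds = parent.spliced_seq(seq)
        copy = _mutate_to_identity(rng, cds, identity, keep_frame_open=True)
        start = _intergenic_slots(len(seq), models, taken, len(copy), rng)
        if start is None:
            raise ValueError("no intergenic space left for retrocopy")
        arr[start : start + len(copy)] = list(copy)
        iv = (start, start + len(copy))
        taken.append(iv)
        realized = 100.0 * sum(a == b for a, b in zip(cds, copy)) / len(cds)
        truth.planted_retrogenes.append((parent.gene_id, iv, realized))
    return SeqRecord(id=genome.id, seq="".join(arr)), truth


def plant_tes(genome: SeqRecord, models: Sequence[GeneModel],
              te_library: Sequence[SeqRecord], n: int,
              identity_range: tuple[float, float], seed: int,
              min_fragment: int = 120,
              truth: Optional[SyntheticTruth] = None,
              ) -> tuple[SeqRecord, SyntheticTruth]:
    """Insert mutated full or partial TE copies at intergenic positions."""
    lo, hi = identity_range
    if not (0 < lo <= 100 and 0 < hi <= 100 and lo <= hi):
        raise ValueError(f"bad identity range {identity_range}")
    if not te_library:
        raise ValueError("empty TE library")
    rng = np.random.default_rng(seed)
    truth = truth or SyntheticTruth()
    if n == 0:
        return genome, truth
    seq = genome.seq
    taken = [tuple(iv) for _, iv, _ in truth.planted_retrogenes]
    taken += [tuple(t["interval"]) for t in truth.planted_tes]
    arr = list(seq)
    for _ in range(n):
        elem = te_library[int(rng.integers(len(te_library)))]
        if len(elem.seq) > min_fragment and rng.random() < 0.5:
            flen = int(rng.integers(min_fragment, len(elem.seq) + 1))
            off = int(rng.integers(0, len(elem.seq) - flen + 1))
            frag = elem.seq[off : off + flen]
        else:
            frag = elem.seq
        ident = float(rng.uniform(lo, hi))
        mutated = _mutate_to_identity(rng, frag, ident)
        if rng.random() < 0.5:
            mutated = revcomp(mutated)
            strand = "-"
        else:
            strand = "+"
        start = _intergenic_slots(len(seq), models, taken, len(mutated), rng)
        if start is None:
            raise ValueError("no intergenic space left for TE insertion")
        arr[start : start + len(mutated)] = list(mutated)
        iv = (start, start + len(mutated))
        taken.append(iv)
        fwd = mutated if strand == "+" else revcomp(mutated)
        realized = 100.0 * sum(a == b for a, b in zip(frag, fwd)) / len(frag)
        truth.planted_tes.append({
            "family": elem.id, "interval": iv, "identity": realized,
            "strand": strand})
    return SeqRecord(id=genome.id, seq="".join(arr)), truth


# ---------------------------------------------------------------------------
# reads

def simulate_reads(genome: SeqRecord, coverage: float, read_len: int = 100,
                   insert: int = 300, error_rate: float = 0.0,
                   n_frac: float = 0.0, dup_frac: float = 0.0,
                   seed: int = 0) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Paired-end reads at the given coverage from random fragments.

    Read 1 is the fragment 5' end, read 2 the reverse complement of the 3'
    end.  ``dup_frac`` emits an identical twin of that fraction of pairs
    (PCR-duplication); ``n_frac`` replaces bases with N; ``error_rate``
    substitutes bases uniformly.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not read_len < insert < len(genome.seq):
        raise ValueError("need read_len < insert < genome length")
    rng = np.random.default_rng(seed)
    glen = len(genome.seq)
    n_pairs = int(round(coverage * glen / (2 * read_len)))
    r1: list[SeqRecord] = []
    r2: list[SeqRecord] = []
    qual = [40] * read_len

    def corrupt(s: str) -> str:
        arr = list(s)
        if error_rate > 0:
            for i in np.flatnonzero(rng.random(len(arr)) < error_rate):
                arr[i] = "ACGT"[(("ACGT".index(arr[i]) if arr[i] in "ACGT"
                                  else 0) + int(rng.integers(1, 4))) % 4]
        if n_frac > 0:
            for i in np.flatnonzero(rng.random(len(arr)) < n_frac):
                arr[i] = "N"
        return "".join(arr)

    for i in range(n_pairs):
        start = int(rng.integers(0, glen - insert + 1))
        frag = genome.seq[start : start + insert]
        a = corrupt(frag[:read_len])
        b = corrupt(revcomp(frag[-read_len:]))
        r1.append(SeqRecord(id=f"pair{i}/1", seq=a, quality=list(qual)))
        r2.append(SeqRecord(id=f"pair{i}/2", seq=b, quality=list(qual)))
        if dup_frac > 0 and rng.random() < dup_frac:
            r1.append(SeqRecord(id=f"pair{i}d/1", seq=a, quality=list(qual)))
            r2.append(SeqRecord(id=f"pair{i}d/2", seq=b, quality=list(qual)))
    return r1, r2


# ---------------------------------------------------------------------------
# expression

def simulate_expression(n_genes: int, frac_male: float, frac_female: float,
                        fold_range: tuple[float, float] = (2.5, 30.0),
                        base_fpkm_mean: float = 1.2, seed: int = 0,
                        ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """FPKM table with an exact number of planted sex-biased genes.

    Biased genes satisfy the two-clause rule (fold >= 2 with the higher sex
    above 2 FPKM) by construction; unbiased genes have fold < 2 and so fail
    the rule regardless of level.
    """
    if frac_male + frac_female > 1:
        raise ValueError("biased fractions exceed 1")
    rng = np.random.default_rng(seed)
    n_male = int(round(n_genes * frac_male))
    n_female = int(round(n_genes * frac_female))
    labels = (["male"] * n_male + ["female"] * n_female
              + ["none"] * (n_genes - n_male - n_female))
    rows = []
    truth = SyntheticTruth()
    for i, lab in enumerate(labels):
        gid = f"gene{i:05d}"
        base = float(rng.lognormal(mean=base_fpkm_mean, sigma=1.0))
        if lab == "none":
            fold = float(rng.uniform(1.0, 1.9))
            hi, lo = base * fold, base
            if rng.random() < 0.5:
                hi, lo = lo, hi
            m, f = hi, lo
        else:
            fold = float(rng.uniform(*fold_range))
            hi = max(base, 2.5)           # higher sex clears the FPKM>2 clause
            lo = hi / fold
            m, f = (hi, lo) if lab == "male" else (lo, hi)
        rows.append((gid, m, f))
        truth.sexbias_labels[gid] = lab
    df = pd.DataFrame(rows, columns=["gene_id", "fpkm_male", "fpkm_female"])
    return df, truth


# ---------------------------------------------------------------------------
# gene-family count matrix

def simulate_family_matrix(n_families: int, species: Sequence[str],
                           events: Sequence[tuple[str, int]], seed: int = 0,
                           focal_species: str = "focal",
                           ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Family x species count matrix; focal counts = group median + planted Δ."""
    rng = np.random.default_rng(seed)
    ev = dict(events)
    truth = SyntheticTruth()
    data = {}
    fam_names = [f"fam{i}" for i in range(n_families)]
    for fam in fam_names:
        base = int(rng.integers(1, 8))
        counts = base + rng.integers(-1, 2, size=len(species))
        counts = np.maximum(counts, 0)
        med = float(np.median(counts))
        if med != int(med):
            # force an integer median so the planted Δ is exact
            order = np.argsort(counts)
            mid = order[len(counts) // 2]
            counts[mid] = counts[order[len(counts) // 2 - 1]]
            med = float(np.median(counts))
        delta = ev.get(fam, 0)
        if int(med) + delta < 0:
            # raise the whole group so the contracted focal count stays >= 0
            counts = counts + (-(int(med) + delta))
            med = float(np.median(counts))
        focal = int(med) + delta
        data[fam] = list(counts) + [focal]
        truth.family_events[fam] = float(delta)
    df = pd.DataFrame.from_dict(
        data, orient="index", columns=list(species) + [focal_species])
    df.index.name = "family"
    return df, truth


# ---------------------------------------------------------------------------
# codon pair evolution

def evolve_codon_pair(n_codons: int, dS_target: float, dN_target: float,
                      kappa: float = 2.0, seed: int = 0,
                      pair_id: str = "pair1",
                      ) -> tuple[SeqRecord, SeqRecord, SyntheticTruth]:
    """Two coding sequences diverged from a common ancestor.

    Mutation is Kimura-style with transition/transversion rate ratio
    ``kappa``; nonsynonymous changes are accepted with probability
    dN_target/dS_target (selection), stop-creating changes never.  The total
    mutation distance per site is dS_target, so the synonymous divergence per
    synonymous site is dS_target and the nonsynonymous divergence per
    nonsynonymous site is dN_target in expectation.
    """
    if dS_target > 1.0:
        raise ValueError("dS target above 1.0 risks saturation")
    if dS_target < 0 or dN_target < 0:
        raise ValueError("negative divergence target")
    if dN_target > 0 and dS_target == 0:
        raise ValueError("dN > 0 requires dS > 0 under this model")
    rng = np.random.default_rng(seed)
    anc = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS),
                                                 size=n_codons)]
    omega = (dN_target / dS_target) if dS_target > 0 else 0.0

    # per-site: one transition partner at rate a, two transversion partners
    # at rate b/2 each; a + b = 1 in distance units, a/b = kappa
    b = 1.0 / (1.0 + kappa)
    a = kappa * b

    _TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
    _TV = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

    def evolve(codons: list[str], dist: float) -> list[str]:
        if dist == 0:
            return list(codons)
        out = list(codons)
        # total proposal rate per codon is 3*(a+b)=3 distance units
        n_events = rng.poisson(3.0 * dist, size=len(out))
        for ci in np.flatnonzero(n_events):
            for _ in range(n_events[ci]):
                codon = out[ci]
                pos = int(rng.integers(3))
                old = codon[pos]
                if rng.random() < a:
                    new = _TS[old]
                else:
                    new = _TV[old][int(rng.integers(2))]
                cand = codon[:pos] + new + codon[pos + 1 :]
                if cand in STOP_CODONS:
                    continue
                if GENETIC_CODE[cand] != GENETIC_CODE[codon]:
                    if rng.random() >= omega:
                        continue
                out[ci] = cand
        return out

    seq_a = evolve(anc, dS_target / 2)
    seq_b = evolve(anc, dS_target / 2)
    truth = SyntheticTruth()
    truth.codon_truth[pair_id] = (dS_target, dN_target)
    return (SeqRecord(id=f"{pair_id}_a", seq="".join(seq_a)),
            SeqRecord(id=f"{pair_id}_b", seq="".join(seq_b)),
            truth)
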