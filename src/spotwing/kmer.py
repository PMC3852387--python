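"""K-mer-spectrum genome-size estimation and paired-read quality filters.

The genome size G is estimated as G = K_num / K_depth, where K_num is the
total number of k-mer occurrences in the reads (a read of length L holds
L - K + 1 k-mers) and K_depth is the modal k-mer multiplicity once the
low-frequency sequencing-error peak is excluded.  The default k is 17.

Read filtering drops a pair when either mate has too many N or low-quality
bases, matches adapter, when short-insert mates overlap, or when the pair is
an exact PCR duplicate of an earlier pair.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

from ._util import revcomp
from .io import SeqRecord

log = logging.getLogger("spotwing")

__all__ = [
    "KmerSpectrum",
    "ReadFilterConfig",
    "count_kmers",
    "find_peak_depth",
    "estimate_genome_size",
    "genome_size_mbp",
    "filter_reads",
]

FILTER_RULES = ("n_fraction", "low_quality", "adapter", "overlap", "duplicate")


@dataclasses.dataclass
class KmerSpectrum:
    """Histogram multiplicity -> number of distinct k-mers at that multiplicity."""

    K: int
    hist: dict[int, int]
    K_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")

    @property
    def K_num(self) -> int:
        return sum(m * c for m, c in self.hist.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.hist.values())


@dataclasses.dataclass
class ReadFilterConfig:
    """Per-library-class thresholds for the five pair-dropping rules.

    Defaults follow the short-insert library class (N fraction 10%,
    low-quality fraction 40% at Q<=7); the long-insert class uses 20%/30% and
    is exempt from the mate-overlap rule.
    """

    library_class: str = "short_insert"
    n_frac_max: Optional[float] = None
    lowq_frac_max: Optional[float] = None
    q_threshold: int = 7
    adapter: Optional[str] = None
    adapter_min_match: int = 10
    adapter_max_mismatch: int = 2
    overlap_min: int = 10
    overlap_exempt: bool = False   # 250-bp insert / PE150 exception
    drop_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.library_class not in {"short_insert", "long_insert"}:
            raise ValueError(f"unknown library class {self.library_class!r}")
        short = self.library_class == "short_insert"
        if self.n_frac_max is None:
            self.n_frac_max = 0.10 if short else 0.20
        if self.lowq_frac_max is None:
            self.lowq_frac_max = 0.40 if short else 0.30
        for frac in (self.n_frac_max, self.lowq_frac_max):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction out of [0,1]: {frac}")


def count_kmers(reads: Iterable[SeqRecord], K: int,
                canonical: bool = True) -> KmerSpectrum:
    """Multiplicity spectrum of all k-mers in the reads.

    Windows containing N are skipped; reads shorter than K contribute
    nothing.  ``canonical`` (the default) replaces each k-mer by the
    lexicographically smaller of itself and its reverse complement; because
    shotgun reads sample both strands, strand-specific counting would halve
    the modal multiplicity while leaving K_num unchanged and so double the
    G = K_num / K_depth estimate.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    counts: Counter[str] = Counter()
    for read in reads:
        seq = read.seq
        for i in range(len(seq) - K + 1):
            kmer = seq[i : i + K]
            if "N" in kmer:
                continue
            if canonical:
                rc = revcomp(kmer)
                if rc < kmer:
                    kmer = rc
            counts[kmer] += 1
    return KmerSpectrum(K=K, hist=dict(Counter(counts.values())))


def find_peak_depth(spectrum: KmerSpectrum) -> int:
    """Modal multiplicity after excluding the low-frequency error peak.

    The error peak sits at multiplicity 1 and decays; the main coverage peak
    is the argmax of the histogram over multiplicities strictly beyond the
    first local minimum.  A monotone-decreasing histogram (no valley) falls
    back to the global argmax.
    """
    if not spectrum.hist:
        raise ValueError("empty spectrum")
    mult = sorted(spectrum.hist)
    counts = [spectrum.hist[m] for m in mult]
    valley = None
    for i in range(1, len(counts)):
        if counts[i] > counts[i - 1]:
            valley = mult[i - 1]
            break
    if valley is None:
        best = max(mult, key=lambda m: (spectrum.hist[m], -m))
    else:
        after = [m for m in mult if m > valley]
        best = max(after, key=lambda m: (spectrum.hist[m], -m))
    spectrum.K_depth = best
    return best


def estimate_genome_size(spectrum: KmerSpectrum) -> float:
    """G = K_num / K_depth (bp, real-valued)."""
    if spectrum.K_depth is None:
        find_peak_depth(spectrum)
    if spectrum.K_depth == 0:
        raise ValueError("K_depth is zero")
    return spectrum.K_num / spectrum.K_depth


def genome_size_mbp(g_bp: float) -> int:
    """Report a genome size in integer millions of bp (floor)."""
    return int(g_bp // 1_000_000)


# ---------------------------------------------------------------------------
# read filtering

def _adapter_match(seq: str, adapter: str, min_match: int,
                   max_mismatch: int) -> bool:
    """Any >= min_match bp window of the adapter matching the read with
    <= max_mismatch mismatches."""
    if not adapter or len(adapter) < min_match:
        return False
    m = min_match
    for ai in range(len(adapter) - m + 1):
        sub = adapter[ai : ai + m]
        for si in range(len(seq) - m + 1):
            mism = 0
            window = seq[si : si + m]
            for x, y in zip(window, sub):
                if x != y:
                    mism += 1
                    if mism > max_mismatch:
                        break
            else:
                return True
    return False


def _mates_overlap(r1: SeqRecord, r2: SeqRecord, overlap_min: int) -> bool:
    """Exact suffix(read1) / prefix(revcomp(read2)) overlap >= overlap_min bp."""
    rc2 = revcomp(r2.seq)
    max_o = min(len(r1.seq), len(rc2))
    for o in range(max_o, overlap_min - 1, -1):
        if r1.seq[-o:] == rc2[:o]:
            return True
    return False


def _mate_fails_frac(read: SeqRecord, config: ReadFilterConfig,
                     rule: str) -> bool:
    n = len(read.seq)
    if rule == "n_fraction":
        return read.seq.count("N") / n > config.n_frac_max
    if read.quality is None:
        return False
    lowq = sum(q <= config.q_threshold for q in read.quality)
    return lowq / n > config.lowq_frac_max


def filter_reads(pairs: Sequence[tuple[SeqRecord, SeqRecord]],
                 config: ReadFilterConfig,
                 ) -> tuple[list[tuple[SeqRecord, SeqRecord]], dict[str, int]]:
    """Apply the five pair-dropping rules; drop counts partition the input.

    A dropped pair is attributed to the first failing rule in the fixed order
    N-fraction, low-quality fraction, adapter, mate overlap, duplicate.
    """
    kept: list[tuple[SeqRecord, SeqRecord]] = []
    drops = dict.fromkeys(FILTER_RULES, 0)
    seen: set[tuple[str, str]] = set()
    for r1, r2 in pairs:
        if (_mate_fails_frac(r1, config, "n_fraction")
                or _mate_fails_frac(r2, config, "n_fraction")):
            drops["n_fraction"] += 1
            continue
        if (_mate_fails_frac(r1, config, "low_quality")
                or _mate_fails_frac(r2, config, "low_quality")):
            drops["low_quality"] += 1
            continue
        if config.adapter and (
                _adapter_match(r1.seq, config.adapter, config.adapter_min_match,
                               config.adapter_max_mismatch)
                or _adapter_match(r2.seq, config.adapter,
                                  config.adapter_min_match,
                                  config.adapter_max_mismatch)):
            drops["adapter"] += 1
            continue
        if (config.library_class == "short_insert" and not config.overlap_exempt
                and _mates_overlap(r1, r2, config.overlap_min)):
            drops["overlap"] += 1
            continue
        key = (r1.seq, r2.seq)
        if config.drop_duplicates and key in seen:
            drops["duplicate"] += 1
            continue
        seen.add(key)
        kept.append((r1, r2))
    log.info("filter_reads: %d pairs in, %d kept, drops=%s",
             len(pairs), len(kept), drops)
    return kept, drops
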