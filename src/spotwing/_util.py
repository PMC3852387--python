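"""Small shared helpers: complementing, translation, ORFs, rounding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code, DNA codons -> one-letter amino acids ('*' = stop).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True when the substitution a->b is a transition (purine<->purine etc.)."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def translate(seq: str) -> str:
    """Translate an in-frame DNA sequence; trailing partial codon ignored."""
    return "".join(
        GENETIC_CODE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def longest_orf_aa(seq: str) -> int:
    """Length in amino acids of the longest ATG-initiated ORF over 6 frames.

    An ORF runs from an ATG to the first in-frame stop (the stop is not
    counted) or, failing a stop, to the end of the frame.
    """
    best = 0
    for strand_seq in (seq, revcomp(seq)):
        for frame in range(3):
            aa = translate(strand_seq[frame:])
            start = None
            for i, a in enumerate(aa):
                if a == "M" and start is None:
                    start = i
                elif a == "*" and start is not None:
                    best = max(best, i - start)
                    start = None
            if start is not None:
                best = max(best, len(aa) - start)
    return best


def pct_half_up(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places (reporting convention)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(numerator) / Decimal(denominator) * 100).quantize(q, ROUND_HALF_UP)
    )
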