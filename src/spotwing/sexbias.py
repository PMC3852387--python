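"""Sex-biased expression calling from male/female FPKM tables.

A gene is called sex-biased when its expression differs at least two-fold
between sexes and the higher sex exceeds 2 FPKM; an optional FDR column from
an external differential test can be required as well.  A zero in one sex is
an infinite fold change, so the gene is biased toward the expressed sex
whenever the level clause holds.  Cross-species comparison flags bias
switches: orthologs male-biased in one species and female-biased in the
other.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._util import pct_half_up

__all__ = [
    "ExpressionRecord",
    "BiasCall",
    "call_sex_bias",
    "bias_summary",
    "bias_switch",
    "records_from_frame",
]


@dataclasses.dataclass
class ExpressionRecord:
    gene_id: str
    fpkm_male: float
    fpkm_female: float
    qvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fpkm_male < 0 or self.fpkm_female < 0:
            raise ValueError(f"{self.gene_id}: negative FPKM")


@dataclasses.dataclass
class BiasCall:
    gene_id: str
    label: str    # male / female / none
    fold: float   # max/min, inf when min == 0


def records_from_frame(df: pd.DataFrame) -> list[ExpressionRecord]:
    """Build records from a table with gene_id / fpkm_male / fpkm_female."""
    has_q = "qvalue" in df.columns
    return [ExpressionRecord(
        gene_id=str(r.gene_id), fpkm_male=float(r.fpkm_male),
        fpkm_female=float(r.fpkm_female),
        qvalue=float(r.qvalue) if has_q else None)
        for r in df.itertuples(index=False)]


def call_sex_bias(records: Sequence[ExpressionRecord], fold_min: float = 2.0,
                  fpkm_min: float = 2.0,
                  qvalue_max: Optional[float] = None) -> list[BiasCall]:
    """Two-clause rule: fold >= fold_min and the higher sex above fpkm_min."""
    calls: list[BiasCall] = []
    for r in records:
        hi, lo = max(r.fpkm_male, r.fpkm_female), min(r.fpkm_male, r.fpkm_female)
        fold = math.inf if lo == 0 else (hi / lo if hi > 0 else 1.0)
        label = "none"
        if hi > fpkm_min and fold >= fold_min:
            label = "male" if r.fpkm_male > r.fpkm_female else "female"
        if label != "none" and qvalue_max is not None:
            if r.qvalue is None or r.qvalue > qvalue_max:
                label = "none"
        calls.append(BiasCall(gene_id=r.gene_id, label=label, fold=fold))
    return calls


def bias_summary(calls: Sequence[BiasCall], n_annotated: int,
                 n_expressed: int) -> dict:
    """Counts plus biased fractions of annotated and expressed genes.

    Percentages are reported to one decimal, rounding half up.
    """
    if n_annotated <= 0 or n_expressed <= 0:
        raise ValueError("denominators must be positive")
    n_male = sum(c.label == "male" for c in calls)
    n_female = sum(c.label == "female" for c in calls)
    n_biased = n_male + n_female
    if n_biased > n_expressed:
        raise ValueError("more biased genes than expressed genes")
    return {
        "n_male": n_male,
        "n_female": n_female,
        "n_biased": n_biased,
        "n_none": len(calls) - n_biased,
        "pct_of_annotated": pct_half_up(n_biased, n_annotated),
        "pct_of_expressed": pct_half_up(n_biased, n_expressed),
    }


def bias_switch(calls_a: Sequence[BiasCall], calls_b: Sequence[BiasCall],
                ortholog_map: Mapping[str, str]) -> dict:
    """Orthologs whose bias direction flips between two species.

    ``ortholog_map`` maps species-A gene ids to species-B gene ids and must
    be one-to-one; genes unbiased in either species are not switches.
    """
    targets = list(ortholog_map.values())
    if len(set(targets)) != len(targets):
        raise ValueError("ortholog map is not one-to-one")
    a = {c.gene_id: c.label for c in calls_a}
    b = {c.gene_id: c.label for c in calls_b}
    m2f = []
    f2m = []
    for ga, gb in ortholog_map.items():
        la, lb = a.get(ga, "none"), b.get(gb, "none")
        if la == "male" and lb == "female":
            m2f.append((ga, gb))
        elif la == "female" and lb == "male":
            f2m.append((ga, gb))
    return {
        "male_to_female": m2f,
        "female_to_male": f2m,
        "n_switches": len(m2f) + len(f2m),
    }
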