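"""Gene-family expansion/contraction statistics and EASE-score enrichment.

For each gene family the statistic is Δ = N_focal − Ñ, the focal species'
gene count minus the median count in a comparison species group; Δ ≥ 2 is an
expansion, Δ ≤ −2 a contraction.  Three comparison groups are conventional:
all other species, a basal paraphyletic group, and the focal species' own
subgroup; families called consistently in all three are the strongest
lineage-specific candidates.

Term enrichment on the expanded/contracted lists uses the EASE score, a
conservative variant of the one-sided Fisher exact test in which one gene is
removed from the list-hit cell before computing the tail probability.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FamilyDelta",
    "EnrichmentResult",
    "compute_deltas",
    "three_group_deltas",
    "consistent_families",
    "pick_representative",
    "ease_enrichment",
    "DELTA_THRESHOLD",
    "EASE_THRESHOLD",
]

DELTA_THRESHOLD = 2
EASE_THRESHOLD = 0.1


@dataclasses.dataclass
class FamilyDelta:
    family: str
    delta: float
    label: str          # expanded / contracted / neutral
    group: str


@dataclasses.dataclass
class EnrichmentResult:
    term: str
    list_hits: int
    list_size: int
    background_hits: int
    background_size: int
    ease_p: float
    fisher_p: float
    significant: bool
    bh_q: Optional[float] = None


def _label(delta: float, threshold: float = DELTA_THRESHOLD) -> str:
    if delta >= threshold:
        return "expanded"
    if delta <= -threshold:
        return "contracted"
    return "neutral"


def compute_deltas(matrix: pd.DataFrame, group: Sequence[str],
                   focal_species: str, group_name: str = "group",
                   threshold: float = DELTA_THRESHOLD) -> list[FamilyDelta]:
    """Δ = focal count − median(group counts) per family, with labels.

    ``matrix`` is families (rows) × species (columns), non-negative integers.
    The median of an even-sized group may be fractional; thresholds apply to
    the real-valued Δ.
    """
    if not group:
        raise ValueError("empty comparison group")
    missing = set(group) - set(matrix.columns)
    if missing:
        raise ValueError(f"group species not in matrix: {sorted(missing)}")
    if focal_species in group:
        raise ValueError("focal species cannot be in its comparison group")
    med = matrix[list(group)].median(axis=1)
    deltas = matrix[focal_species] - med
    return [FamilyDelta(family=f, delta=float(d), label=_label(d, threshold),
                        group=group_name)
            for f, d in deltas.items()]


def three_group_deltas(matrix: pd.DataFrame,
                       groups: Mapping[str, Sequence[str]],
                       focal_species: str,
                       threshold: float = DELTA_THRESHOLD,
                       ) -> dict[str, list[FamilyDelta]]:
    """compute_deltas per comparison group; groups must not overlap.

    The intersection of labels across groups is obtained with
    :func:`consistent_families`.
    """
    # the all-others group legitimately contains every species, so nested
    # groups are fine; only partially overlapping groups are rejected
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = set(groups[a]) & set(groups[b])
            if overlap and not (set(groups[a]) <= set(groups[b])
                                or set(groups[b]) <= set(groups[a])):
                raise ValueError(
                    f"groups {a!r} and {b!r} overlap: {sorted(overlap)}")
    return {name: compute_deltas(matrix, members, focal_species,
                                 group_name=name, threshold=threshold)
            for name, members in groups.items()}


def consistent_families(per_group: Mapping[str, Sequence[FamilyDelta]],
                        label: str) -> set[str]:
    """Families carrying ``label`` in every comparison group."""
    sets = [{d.family for d in deltas if d.label == label}
            for deltas in per_group.values()]
    return set.intersection(*sets) if sets else set()


def pick_representative(family_members: Sequence[str],
                        go_annotation: Mapping[str, Iterable[str]]) -> str:
    """Member with the most annotation terms; ties to the smallest gene id."""
    if not family_members:
        raise ValueError("empty family")
    return min(family_members,
               key=lambda g: (-len(set(go_annotation.get(g, ()))), g))


def ease_enrichment(hit_genes: Sequence[str], background_genes: Sequence[str],
                    term_map: Mapping[str, Iterable[str]],
                    threshold: float = EASE_THRESHOLD,
                    ) -> list[EnrichmentResult]:
    """Per-term one-sided Fisher and EASE p-values for a gene list.

    Genes without any annotation are excluded from both the list and the
    background.  fisher_p is the hypergeometric upper tail P(X >= a); ease_p
    is the same tail with the list-hit cell decremented by one (floor 0), so
    a single-gene hit can never be significant.
    """
    background = [g for g in dict.fromkeys(background_genes)
                  if term_map.get(g)]
    bg_set = set(background)
    hits = [g for g in dict.fromkeys(hit_genes) if term_map.get(g)]
    stray = [g for g in hits if g not in bg_set]
    if stray:
        raise ValueError(f"hit genes missing from background: {stray}")
    n = len(hits)
    N = len(background)
    terms: dict[str, set[str]] = {}
    for g in background:
        for t in term_map[g]:
            terms.setdefault(t, set()).add(g)
    results: list[EnrichmentResult] = []
    for term, genes_with in sorted(terms.items()):
        K = len(genes_with)
        a = sum(g in genes_with for g in hits)
        fisher_p = float(stats.hypergeom.sf(a - 1, N, K, n))
        ease_p = float(stats.hypergeom.sf(a - 2, N, K, n)) if a >= 1 else 1.0
        results.append(EnrichmentResult(
            term=term, list_hits=a, list_size=n, background_hits=K,
            background_size=N, ease_p=min(ease_p, 1.0),
            fisher_p=min(fisher_p, 1.0), significant=ease_p <= threshold))
    # Benjamini-Hochberg on the EASE p-values, informational only
    if results:
        ps = np.array([r.ease_p for r in results])
        order = np.argsort(ps)
        m = len(ps)
        q = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, ps[i] * m / (rank_idx + 1))
            q[i] = prev
        for r, qi in zip(results, q):
            r.bh_q = float(qi)
    return results
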