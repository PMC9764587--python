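"""Fisher's exact enrichment with explicit backgrounds.

Three uses from the source workflow: over-representation of risk genes
among a cell type's DEGs against the >10%-detected expressed-gene
background; one-sided composition tests of a cell subtype against an
exposure label (e.g. a macrophage subtype against smoking status); and a
functional-overlap score between two gene lists used to rank ligands.
Odds ratios are the sample a*d/(b*c) (conditional MLE not used); infinite
or zero ORs are flagged rather than continuity-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "composition_test",
    "functional_overlap_score",
]


@dataclass
class EnrichmentResult:
    a: int  # hit & category
    b: int  # hit & not category
    c: int  # not hit & category
    d: int  # neither
    odds_ratio: float  # inf flagged via or_degenerate
    or_degenerate: bool
    p_value: float
    alternative: str
    background_size: int

    @property
    def table(self):
        return np.array([[self.a, self.b], [self.c, self.d]])


def _fisher(a, b, c, d, alternative) -> EnrichmentResult:
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a * d == 0 and (b * c == 0) else 0.0)
        degenerate = True
        if a * d == 0:
            odds = np.nan  # 0/0: undefined
    else:
        odds = (a * d) / (b * c)
        degenerate = False
    return EnrichmentResult(
        a=int(a), b=int(b), c=int(c), d=int(d),
        odds_ratio=float(odds), or_degenerate=degenerate,
        p_value=float(p), alternative=alternative,
        background_size=int(a + b + c + d),
    )


def fisher_enrichment(
    hits, category, background, alternative: str = "greater",
    allow_hits_outside_background: bool = False,
) -> EnrichmentResult:
    """Fisher's exact test of ``hits`` against ``category`` over ``background``.

    ``category`` is intersected with the background before tabulation;
    hits outside the background raise unless explicitly permitted (the
    silent-intersection failure mode is forbidden by default).
    """
    hits, category, background = set(hits), set(category), set(background)
    if not background:
        raise ValueError("empty background")
    outside = hits - background
    if outside:
        if not allow_hits_outside_background:
            raise ValueError(
                f"{len(outside)} hits outside the background "
                "(pass allow_hits_outside_background=True to intersect)"
            )
        hits &= background
    category &= background
    a = len(hits & category)
    b = len(hits - category)
    c = len(category - hits)
    d = len(background) - a - b - c
    return _fisher(a, b, c, d, alternative)


def composition_test(
    membership: pd.Series, exposure: pd.Series, subtype: str,
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher test of a subtype's composition against an exposure.

    ``membership`` maps cell -> subtype; ``exposure`` maps cell -> exposed
    status. Pass a boolean series (True = exposed); a two-level string
    series is accepted, with the lexicographically larger level treated as
    exposed.
    """
    membership = pd.Series(membership)
    exposure = pd.Series(exposure)
    if not membership.index.equals(exposure.index):
        exposure = exposure.reindex(membership.index)
    if membership.isna().any() or exposure.isna().any():
        raise ValueError("every cell needs both a subtype and an exposure label")
    if exposure.dtype != bool:
        levels = sorted(pd.unique(exposure))
        if len(levels) != 2:
            raise ValueError("exposure must be binary")
        exposure = exposure == levels[1]
    if (membership == subtype).sum() == 0:
        raise ValueError(f"subtype {subtype!r} absent")
    in_sub = membership == subtype
    a = int((in_sub & exposure).sum())
    b = int((in_sub & ~exposure).sum())
    c = int((~in_sub & exposure).sum())
    d = int((~in_sub & ~exposure).sum())
    return _fisher(a, b, c, d, alternative)


def functional_overlap_score(gene_list_a, gene_list_b, universe) -> dict:
    """Overlap size, Jaccard index, and hypergeometric over-representation p
    of two gene lists within a universe. Used to rank candidate ligands by
    how much their correlated-gene lists overlap a DEG list."""
    a, b, universe = set(gene_list_a), set(gene_list_b), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not a <= universe or not b <= universe:
        raise ValueError("gene lists must be subsets of the universe")
    inter = a & b
    union = a | b
    k = len(inter)
    # P(overlap >= k) drawing |a| from the universe with |b| marked
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(b), len(a))) if a and b else 1.0
    return {
        "overlap": k,
        "jaccard": (k / len(union)) if union else 0.0,
        "p_value": min(p, 1.0),
        "n_a": len(a),
        "n_b": len(b),
        "universe_size": len(universe),
    }
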