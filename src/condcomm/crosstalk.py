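"""Cross-individual pseudobulk correlation for sender -> receiver crosstalk.

The procedure infers communication that ligand--receptor databases cannot
capture (e.g. metabolite-mediated): for a focal gene in a sender cell type
(say, a sphingolipid enzyme in macrophages) and every gene expressed in a
recipient cell type, compute the Spearman correlation of their
per-individual pseudobulk means across the cohort's individuals. A
recipient gene whose expression tracks the sender gene across individuals
is a candidate downstream target. Per recipient cell type the proportion
of its expressed genes with |rho| >= 0.8 (a correlation of exactly 0.8
counts) summarizes how strongly the recipient responds, and recipients
are ranked by the mean proportion over focal genes.

With only nine individuals, |rho| >= 0.8 sits in the far tail of the null
permutation distribution of Spearman's rho, which is what makes the
threshold selective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PseudobulkCube

__all__ = [
    "CrosstalkCorrelationMap",
    "sender_receiver_correlation",
    "correlated_proportion",
    "correlated_gene_lists",
]


def _spearman_matrix(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho between every column of A and every column of B over
    shared rows (individuals). Ties get average ranks; constant columns
    yield NaN."""
    ra = np.apply_along_axis(stats.rankdata, 0, A.to_numpy(dtype=float))
    rb = np.apply_along_axis(stats.rankdata, 0, B.to_numpy(dtype=float))
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    sa = np.sqrt((ra**2).sum(axis=0))
    sb = np.sqrt((rb**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra.T @ rb) / np.outer(sa, sb)
    rho[np.abs(sa) < 1e-12, :] = np.nan
    rho[:, np.abs(sb) < 1e-12] = np.nan
    return pd.DataFrame(rho, index=A.columns, columns=B.columns)


@dataclass
class CrosstalkCorrelationMap:
    """Per-recipient focal-gene x target-gene Spearman correlations."""

    sender_ct: str
    focal_genes: list
    rho: dict  # recipient_ct -> DataFrame (focal x target)
    n_individuals: dict  # recipient_ct -> int
    expressed_sets: dict  # recipient_ct -> set of genes (proportion denominator)
    threshold: float = 0.8
    self_excluded: bool = True
    dropped: dict = field(default_factory=dict)  # recipient -> reason

    def recipients(self):
        return list(self.rho)


def sender_receiver_correlation(
    cube: PseudobulkCube,
    focal_genes,
    sender_ct: str,
    recipient_cts,
    expressed_sets: dict,
    min_individuals: int = 5,
    threshold: float = 0.8,
) -> CrosstalkCorrelationMap:
    """Correlate focal-gene pseudobulk in the sender with every expressed
    gene's pseudobulk in each recipient, across individuals.

    ``expressed_sets`` maps cell type -> expressed gene set (>10% detection,
    see :func:`condcomm.preprocess.expressed_gene_set`); it restricts the
    targets and later supplies the proportion denominator. Individuals
    missing either cell type are dropped pairwise; fewer than
    ``min_individuals`` shared individuals is an error. Constant pseudobulk
    vectors yield NaN rho (flagged, not zero).
    """
    focal_genes = [g for g in focal_genes]
    missing = [g for g in focal_genes if g not in cube.genes]
    if missing:
        raise ValueError(f"focal genes not in the pseudobulk cube: {missing}")
    if sender_ct not in cube.cell_types:
        raise ValueError(f"sender cell type {sender_ct!r} not in the cube")
    s_idx = cube.cell_types.index(sender_ct)
    rho_by_recipient = {}
    n_by_recipient = {}
    dropped = {}
    sets_used = {}
    for rct in recipient_cts:
        if rct not in cube.cell_types:
            raise ValueError(f"recipient cell type {rct!r} not in the cube")
        targets = sorted(set(expressed_sets[rct]) & set(cube.genes))
        if not targets:
            dropped[rct] = "empty expressed set"
            continue
        r_idx = cube.cell_types.index(rct)
        shared = cube.present[:, s_idx] & cube.present[:, r_idx]
        n = int(shared.sum())
        if n < min_individuals:
            raise ValueError(
                f"only {n} individuals have both {sender_ct!r} and {rct!r} "
                f"(floor is {min_individuals})"
            )
        inds = [cube.individuals[i] for i in np.flatnonzero(shared)]
        A = cube.gene_matrix(sender_ct, focal_genes).loc[inds]
        B = cube.gene_matrix(rct, targets).loc[inds]
        rho_by_recipient[rct] = _spearman_matrix(A, B)
        n_by_recipient[rct] = n
        sets_used[rct] = set(targets)
    return CrosstalkCorrelationMap(
        sender_ct=sender_ct,
        focal_genes=focal_genes,
        rho=rho_by_recipient,
        n_individuals=n_by_recipient,
        expressed_sets=sets_used,
        threshold=threshold,
        dropped=dropped,
    )


def correlated_proportion(cmap: CrosstalkCorrelationMap, threshold: float = None):
    """Proportion of each recipient's expressed genes with |rho| >= threshold,
    per focal gene; recipients ordered by row-mean proportion descending.

    Returns ``(heatmap DataFrame [recipient x focal], ordered recipient list)``.
    """
    thr = cmap.threshold if threshold is None else threshold
    rows = {}
    for rct, rho in cmap.rho.items():
        denom = len(cmap.expressed_sets[rct])
        hits = (rho.abs() >= thr)
        # exclude the focal gene's self-correlation in the autocrine case
        if cmap.self_excluded and rct == cmap.sender_ct:
            for g in cmap.focal_genes:
                if g in rho.columns:
                    hits.loc[g, g] = False
        rows[rct] = hits.sum(axis=1) / denom
    heat = pd.DataFrame(rows).T  # recipient x focal
    heat = heat.loc[heat.mean(axis=1).sort_values(ascending=False, kind="mergesort").index]
    return heat, list(heat.index)


def correlated_gene_lists(
    cmap: CrosstalkCorrelationMap,
    threshold: float = None,
    side: str = "recipient",
) -> dict:
    """Per focal gene, the genes whose |rho| meets the threshold.

    ``side='recipient'`` returns ``{recipient_ct: {focal: [genes]}}``;
    ``side='sender'`` restricts to the sender's own map (cell-autonomous
    lists), excluding the focal gene itself. Lists are sorted, so the
    output is invariant to individual ordering.
    """
    thr = cmap.threshold if threshold is None else threshold
    if side == "sender":
        if cmap.sender_ct not in cmap.rho:
            raise ValueError(
                "sender-side lists need the sender among the recipients of the map"
            )
        rcts = [cmap.sender_ct]
    elif side == "recipient":
        rcts = [r for r in cmap.rho]
    else:
        raise ValueError(f"unknown side {side!r}")
    out = {}
    for rct in rcts:
        rho = cmap.rho[rct]
        lists = {}
        for g in cmap.focal_genes:
            sel = rho.loc[g].abs() >= thr
            genes = sorted(rho.columns[sel.fillna(False)])
            if side == "sender" and cmap.self_excluded and g in genes:
                genes.remove(g)
            lists[g] = genes
        out[rct] = lists
    return out if side == "recipient" else out[cmap.sender_ct]
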