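"""Cell-type prioritization by downsampling-equalized DEG counts.

Comparing raw DEG counts across cell types confounds perturbation strength
with statistical power: abundant types yield more DEGs simply because more
cells were sampled. The remedy implemented here downsamples every cell
type to the same number of cells (stratified by individual, so the cohort
design is preserved in every replicate), re-runs differential expression,
and ranks cell types by their median DEG count per condition over
replicates.

A complementary separability score — the cross-validated AUC of a
classifier separating perturbed from unperturbed cells within one cell
type over highly variable genes — is provided as an orthogonal
prioritization axis; in planted-effect simulations the two rankings agree
on the top cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PrioritizationResult",
    "downsample_prioritize",
    "separability_score",
    "condition_labels",
]

from .de import CONDITION_COLUMNS


def condition_labels(obs: pd.DataFrame, condition: str) -> np.ndarray:
    """Boolean perturbed/unperturbed labels for one condition."""
    if condition == "disease":
        return (obs["disease"] == "COPD").to_numpy()
    if condition == "aging":
        return (obs["age_group"] == "old").to_numpy()
    if condition == "smoking":
        return (obs["smoking"] == "AS").to_numpy()
    raise ValueError(f"unknown condition {condition!r}")


def _default_de_callable(sub: ad.AnnData, cell_type: str) -> dict:
    from .de import call_degs, fit_condition_de
    from .preprocess import expressed_gene_set

    genes = sorted(expressed_gene_set(sub, cell_type))
    if not genes:
        return {c: 0 for c in CONDITION_COLUMNS}
    table = fit_condition_de(sub, cell_type, method="pseudobulk_lm", genes=genes)
    called = call_degs(table)
    counts = called[called["is_deg"]].groupby("condition").size()
    return {c: int(counts.get(c, 0)) for c in CONDITION_COLUMNS}


def _stratified_sample(rng, strata_codes: np.ndarray, n_total: int) -> np.ndarray:
    """Sample ``n_total`` indices preserving strata proportions (largest
    remainder allocation), without replacement within strata."""
    codes, counts = np.unique(strata_codes, return_counts=True)
    quota = n_total * counts / counts.sum()
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    short = n_total - alloc.sum()
    if short > 0:
        order = np.argsort(-remainder)
        for k in order[:short]:
            alloc[k] += 1
    alloc = np.minimum(alloc, counts)
    # if capping left us short, top up from strata with spare cells
    deficit = n_total - alloc.sum()
    while deficit > 0:
        spare = np.flatnonzero(counts - alloc > 0)
        k = spare[np.argmax((counts - alloc)[spare])]
        alloc[k] += 1
        deficit -= 1
    picked = []
    for code, m in zip(codes, alloc):
        pool = np.flatnonzero(strata_codes == code)
        if m > 0:
            picked.append(rng.choice(pool, size=m, replace=False))
    return np.concatenate(picked) if picked else np.array([], dtype=int)


def _drop_cross_class_duplicates(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boolean keep-mask after pairing off identical rows with opposite labels."""
    keys = {}
    for i, row in enumerate(X):
        keys.setdefault(row.tobytes(), []).append(i)
    keep = np.ones(len(y), dtype=bool)
    for idx in keys.values():
        pos = [i for i in idx if y[i]]
        neg = [i for i in idx if not y[i]]
        k = min(len(pos), len(neg))
        for i in pos[:k] + neg[:k]:
            keep[i] = False
    return keep


@dataclass
class PrioritizationResult:
    """Replicate-level DEG counts, summaries, and per-condition ranks."""

    replicates: pd.DataFrame  # cell_type, condition, replicate, n_degs
    n_cells: int
    excluded: list = field(default_factory=list)

    @property
    def summary(self) -> pd.DataFrame:
        g = self.replicates.groupby(["cell_type", "condition"])["n_degs"]
        out = g.agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75)).reset_index()
        out["iqr"] = out["q3"] - out["q1"]
        return out

    @property
    def ranks(self) -> pd.DataFrame:
        s = self.summary.sort_values(["condition", "cell_type"])
        s["rank"] = (
            s.groupby("condition")["median"]
            .rank(ascending=False, method="first")
            .astype(int)
        )
        return s[["condition", "cell_type", "median", "rank"]].reset_index(drop=True)

    def top(self, condition: str) -> str:
        r = self.ranks
        r = r[r["condition"] == condition]
        return r.loc[r["rank"] == 1, "cell_type"].iloc[0]


def downsample_prioritize(
    adata: ad.AnnData,
    n_reps: int = 20,
    n_cells="auto",
    seed: int = 0,
    de_callable=None,
    min_cells_floor: int = 30,
    stratify_by: str = "individual",
    per_cell_normalize: bool = False,
) -> PrioritizationResult:
    """Rank cell types by downsampling-equalized DEG counts.

    For each replicate and cell type, ``n_cells`` cells are sampled
    (stratified by ``stratify_by``; ``None`` for unstratified), DE is run
    via ``de_callable(subset, cell_type) -> {condition: n_degs}`` and the
    counts recorded. ``n_cells='auto'`` uses the smallest included cell
    type's size; types below ``min_cells_floor`` are excluded with a
    warning. ``per_cell_normalize`` divides counts by ``n_cells`` instead
    (the alternative reading of count-per-cell normalization).
    """
    if de_callable is None:
        de_callable = _default_de_callable
    rng = np.random.default_rng(seed)
    sizes = adata.obs["cell_type"].value_counts()
    included = [ct for ct in sizes.index if sizes[ct] >= min_cells_floor]
    excluded = [ct for ct in sizes.index if sizes[ct] < min_cells_floor]
    if excluded:
        warnings.warn(
            f"cell types below the {min_cells_floor}-cell floor excluded: {excluded}"
        )
    if not included:
        raise ValueError("no cell type meets the downsampling floor")
    if n_cells == "auto":
        n_cells = int(min(sizes[ct] for ct in included))
    n_cells = int(n_cells)
    rows = []
    ct_masks = {ct: (adata.obs["cell_type"] == ct).to_numpy() for ct in included}
    for rep in range(n_reps):
        for ct in included:
            idx = np.flatnonzero(ct_masks[ct])
            if stratify_by is None:
                pick = rng.choice(idx, size=min(n_cells, idx.size), replace=False)
            else:
                strata = adata.obs[stratify_by].to_numpy()[idx]
                codes = pd.Categorical(strata).codes
                pick = idx[_stratified_sample(rng, codes, min(n_cells, idx.size))]
            sub = adata[pick]
            counts = de_callable(sub, ct)
            for cond, n in counts.items():
                val = n / n_cells if per_cell_normalize else n
                rows.append((ct, cond, rep, val))
    reps = pd.DataFrame(rows, columns=["cell_type", "condition", "replicate", "n_degs"])
    return PrioritizationResult(replicates=reps, n_cells=n_cells, excluded=excluded)


def separability_score(
    adata: ad.AnnData,
    cell_type: str,
    condition: str,
    n_subsamples: int = 3,
    cells_per_subsample=None,
    seed: int = 0,
    n_hvg: int = 500,
    n_folds: int = 3,
) -> float:
    """Mean cross-validated AUC separating perturbed from unperturbed cells.

    Per subsample, equal-size groups are drawn, features are the top
    ``n_hvg`` variable genes of the subsample, and a random-forest
    classifier is scored by stratified ``n_folds``-fold cross-validated
    AUC. Higher means more perturbed; 0.5 is indistinguishable.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    rng = np.random.default_rng(seed)
    mask = (adata.obs["cell_type"] == cell_type).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"cell type {cell_type!r} has no cells")
    sub = adata[mask]
    y_all = condition_labels(sub.obs, condition)
    n1, n0 = int(y_all.sum()), int((~y_all).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"condition {condition!r} has a single group in {cell_type!r}")
    m = min(n1, n0)
    if cells_per_subsample is not None:
        m = min(m, int(cells_per_subsample))
    if m < n_folds:
        raise ValueError(f"group size {m} smaller than fold count {n_folds}")
    X_full = sub.X
    if sparse.issparse(X_full):
        X_full = np.asarray(X_full.todense())
    # a cell identical to an opposite-class cell carries no class
    # information, but its twin leaks the wrong label through CV folds;
    # pair such duplicates off and drop them (never triggers on real data)
    keep = _drop_cross_class_duplicates(X_full, y_all)
    X_full, y_all = X_full[keep], y_all[keep]
    n1, n0 = int(y_all.sum()), int((~y_all).sum())
    if n1 < n_folds or n0 < n_folds:
        warnings.warn(
            "classes are indistinguishable up to duplicated cells; AUC is chance"
        )
        return 0.5
    m = min(m, n1, n0)
    aucs = []
    pos_idx = np.flatnonzero(y_all)
    neg_idx = np.flatnonzero(~y_all)
    for s in range(n_subsamples):
        pick = np.concatenate(
            [
                rng.choice(pos_idx, size=m, replace=False),
                rng.choice(neg_idx, size=m, replace=False),
            ]
        )
        X = X_full[pick]
        y = y_all[pick].astype(int)
        variances = X.var(axis=0)
        hv = np.argsort(-variances)[: min(n_hvg, X.shape[1])]
        X = X[:, hv]
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for train, test in skf.split(X, y):
            clf = RandomForestClassifier(
                n_estimators=100, random_state=int(rng.integers(2**31)), n_jobs=1
            )
            clf.fit(X[train], y[train])
            score = clf.predict_proba(X[test])[:, 1]
            if len(np.unique(y[test])) < 2:
                continue
            aucs.append(roc_auc_score(y[test], score))
    if not aucs:
        raise ValueError("no evaluable CV folds")
    return float(np.mean(aucs))
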