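"""Two-endpoint pseudotime, association statistics, and driver enrichment.

Pseudotime here is a deliberately simple monotone ordering between two
named clusters (e.g. classical -> intermediate monocytes): cells of the
two clusters are projected in PC space onto the axis joining the cluster
centroids and min-max scaled to [0, 1] with the start cluster anchored at
0. Per-gene association with pseudotime is the F statistic of a natural
cubic spline regression (4 knots by default) against the intercept-only
model. "Driver genes" are the top N by this statistic (N = 250 for the
monocyte lineage, 500 for AT2->AT1, 100 for club-cell lineages in the
source cohort's conventions; all configurable), and enrichment of a DEG
set among high-association genes is a one-sided two-sample
Kolmogorov-Smirnov test with the alternative that DEG statistics are
stochastically larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "compute_pseudotime",
    "natural_cubic_basis",
    "association_statistic",
    "DriverRanking",
    "rank_drivers",
    "driver_enrichment_ks",
    "DEFAULT_TOP_N",
]

# lineage-specific driver-set sizes used by the source cohort
DEFAULT_TOP_N = {"monocyte": 250, "AT2_AT1": 500, "club": 100}


def compute_pseudotime(
    adata: ad.AnnData,
    start_cluster: str,
    end_cluster: str,
    n_pcs: int = 10,
    cluster_key: str = "cell_type",
) -> pd.Series:
    """Centroid-axis pseudotime in [0, 1] for the two clusters' cells."""
    from sklearn.decomposition import PCA

    labels = adata.obs[cluster_key]
    mask = labels.isin([start_cluster, end_cluster]).to_numpy()
    for cl in (start_cluster, end_cluster):
        if (labels == cl).sum() < 10:
            raise ValueError(f"cluster {cl!r} needs >= 10 cells")
    sub = adata[mask]
    X = sub.X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(X - X.mean(axis=0))
    is_start = (sub.obs[cluster_key] == start_cluster).to_numpy()
    c_start = pcs[is_start].mean(axis=0)
    c_end = pcs[~is_start].mean(axis=0)
    axis = c_end - c_start
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("identical cluster centroids; pseudotime axis undefined")
    proj = pcs @ (axis / norm)
    t = (proj - proj.min()) / (proj.max() - proj.min())
    if t[is_start].mean() > t[~is_start].mean():
        t = 1.0 - t
    return pd.Series(t, index=sub.obs_names, name="pseudotime")


def natural_cubic_basis(t: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) with knots at
    quantiles of ``t``; returns ``n_knots - 1`` columns."""
    knots = np.quantile(t, np.linspace(0, 1, n_knots))
    knots = np.unique(knots)
    if knots.size < 3:
        # degenerate spread: fall back to a linear column
        return t[:, None].astype(float)
    K = knots.size

    def d(k):
        return (
            np.clip(t - knots[k], 0, None) ** 3 - np.clip(t - knots[-1], 0, None) ** 3
        ) / (knots[-1] - knots[k])

    cols = [t.astype(float)]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def association_statistic(
    expr, t, n_knots: int = 4
) -> pd.DataFrame:
    """F statistic (and p) of spline-on-pseudotime vs intercept-only, per gene.

    ``expr`` is cells x genes (DataFrame, array, or 1-D vector); ``t`` the
    matching pseudotime. Constant genes get statistic 0, p 1.
    """
    t = np.asarray(t, dtype=float)
    if t.size < 20:
        raise ValueError("need >= 20 cells for the association test")
    if isinstance(expr, pd.DataFrame):
        names = list(expr.columns)
        Y = expr.to_numpy(dtype=float)
    else:
        Y = np.asarray(expr, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        names = [f"g{j}" for j in range(Y.shape[1])]
    n = t.size
    B = natural_cubic_basis(t, n_knots=n_knots)
    X = np.column_stack([np.ones(n), B])
    q = X.shape[1] - 1
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    rss1 = ((Y - X @ beta) ** 2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    df2 = n - q - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss0 - rss1) / q) / (rss1 / df2)
    p = stats.f.sf(F, q, df2)
    const = rss0 <= 1e-300
    F = np.where(const, 0.0, np.maximum(F, 0.0))
    p = np.where(const, 1.0, p)
    # perfect fits: rss1 ~ 0 -> infinite F, p -> 0
    perfect = (rss1 <= 1e-300) & ~const
    F = np.where(perfect, np.inf, F)
    p = np.where(perfect, 0.0, p)
    return pd.DataFrame({"gene": names, "statistic": F, "p_value": p})


@dataclass
class DriverRanking:
    """Genes ranked by association statistic, with the top-N driver set."""

    table: pd.DataFrame  # gene, statistic, rank (1 = largest statistic)
    top_n: int

    @property
    def driver_set(self) -> set:
        return set(self.table.loc[self.table["rank"] <= self.top_n, "gene"])

    def statistic_series(self) -> pd.Series:
        return self.table.set_index("gene")["statistic"]


def rank_drivers(assoc: pd.DataFrame, top_n: int = 250) -> DriverRanking:
    """Build a :class:`DriverRanking` from :func:`association_statistic` output."""
    t = assoc.sort_values("statistic", ascending=False, kind="mergesort").reset_index(drop=True)
    t["rank"] = np.arange(1, len(t) + 1)
    return DriverRanking(table=t, top_n=min(top_n, len(t)))


def driver_enrichment_ks(
    ranking: DriverRanking,
    deg_set,
    alternative: str = "greater",
    mode: str = "statistic",
) -> dict:
    """One-sided K-S enrichment of a DEG set among trajectory drivers.

    ``mode='statistic'`` compares association statistics of DEG genes
    against the remaining tested genes; ``mode='rank'`` compares rank
    positions instead (smaller rank = stronger driver). With
    ``alternative='greater'`` the alternative is that DEG genes are
    stochastically stronger drivers. Returns D, p, and the overlap of the
    DEG set with the top-N driver set.
    """
    tested = ranking.table["gene"]
    in_deg = tested.isin(set(deg_set)).to_numpy()
    if in_deg.sum() == 0:
        raise ValueError("DEG set does not intersect the tested genes")
    if in_deg.all():
        raise ValueError("DEG set covers all tested genes; no complement to compare")
    if mode == "statistic":
        values = ranking.table["statistic"].to_numpy(dtype=float)
    elif mode == "rank":
        values = -ranking.table["rank"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    x, y = values[in_deg], values[~in_deg]
    # "greater" = DEG values stochastically larger = ECDF of x below that of y
    scipy_alt = {"greater": "less", "less": "greater", "two-sided": "two-sided"}[alternative]
    res = stats.ks_2samp(x, y, alternative=scipy_alt, method="auto")
    overlap = len(set(deg_set) & ranking.driver_set)
    return {
        "D": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_deg": int(in_deg.sum()),
        "n_other": int((~in_deg).sum()),
        "driver_overlap": overlap,
    }
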