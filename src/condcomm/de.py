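"""Per-cell-type differential expression with jointly modeled conditions.

The three condition contrasts — disease (COPD vs control), aging (old vs
young) and smoking (active vs never smoker) — enter one design matrix
(intercept + disease + age + smoking) so that each coefficient is adjusted
for the other two. This is the deconvolution contract: a gene shifted only
by disease should show a near-zero aging and smoking coefficient.

Two estimation methods are provided behind the same interface:

``pseudobulk_lm``
    Ordinary least squares across the nine individual-level pseudobulk
    means. With n individuals and p=4 parameters the t-based p-values are
    exactly calibrated under normal errors; pseudobulk means over tens of
    cells are close to normal.

``cell_hurdle``
    A two-part model per gene at single-cell resolution: a logistic
    regression of detection on the design, and a linear regression of the
    positive log-normalized values on the design. The two per-condition
    Wald z statistics are combined by Stouffer's method. Within-individual
    dependence is handled either by cluster-robust (by individual)
    covariance (default) or by individual fixed effects.

log2 fold changes are always the covariate-adjusted coefficient of a
linear model on all cells' log-normalized values, converted to log2.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "ConditionDEModel",
    "DEResults",
    "fit_condition_de",
    "call_degs",
    "ols_wald_table",
    "CONDITION_COLUMNS",
]

CONDITION_COLUMNS = ("disease", "aging", "smoking")


def _design_from_obs(obs: pd.DataFrame) -> pd.DataFrame:
    d = pd.DataFrame(index=obs.index)
    d["intercept"] = 1.0
    d["disease"] = (obs["disease"] == "COPD").astype(float)
    d["aging"] = (obs["age_group"] == "old").astype(float)
    d["smoking"] = (obs["smoking"] == "AS").astype(float)
    return d


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = []
        for col in X.columns:
            sub = X.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                bad.append(col)
        raise ValueError(
            "rank-deficient design: collinear columns "
            + ", ".join(bad or list(X.columns))
        )


def ols_wald_table(D: np.ndarray, Y: np.ndarray):
    """Vectorized OLS of every column of Y on design D.

    Returns ``(beta, two-sided t p-values, residual variances)`` with
    shapes (p, G), (p, G), (G,). With a single binary covariate this is
    exactly the equal-variance two-sample t-test per column.
    """
    n, p = D.shape
    if n <= p:
        raise ValueError("need more observations than design columns")
    beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    XtX_inv = np.linalg.inv(D.T @ D)
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), df)
    return beta, pvals, sigma2


class DEResults:
    """Per-gene, per-condition effect estimates from :class:`ConditionDEModel`.

    ``table`` has one row per (gene, condition) with columns
    ``log2fc`` and ``p_value``.
    """

    def __init__(self, table: pd.DataFrame, cell_type: str, method: str):
        self.table = table
        self.cell_type = cell_type
        self.method = method

    def condition(self, condition: str) -> pd.DataFrame:
        return self.table[self.table["condition"] == condition].set_index("gene")

    def summary(self, condition: str = "disease", top: int = 10) -> pd.DataFrame:
        t = self.condition(condition).sort_values("p_value")
        return t.head(top)[["log2fc", "p_value"]]


class ConditionDEModel:
    """Joint disease/aging/smoking DE model for one cell type.

    Parameters
    ----------
    adata
        Normalized AnnData (see :func:`condcomm.preprocess.normalize`).
    cell_type
        The cluster to model; other cells are ignored.
    genes
        Genes to test; defaults to the cell type's expressed gene set
        (detection > 10%).
    method
        ``"cell_hurdle"`` or ``"pseudobulk_lm"``.
    individual_adjust
        ``"robust"`` (cluster-robust by individual, cell_hurdle only) or
        ``"fixed"`` (individual fixed-effect block).
    """

    def __init__(
        self,
        adata: ad.AnnData,
        cell_type: str,
        genes=None,
        method: str = "cell_hurdle",
        individual_adjust: str = "robust",
    ):
        if method not in ("cell_hurdle", "pseudobulk_lm"):
            raise ValueError(f"unknown method {method!r}")
        if individual_adjust not in ("robust", "fixed"):
            raise ValueError(f"unknown individual_adjust {individual_adjust!r}")
        mask = (adata.obs["cell_type"] == cell_type).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"cell type {cell_type!r} has no cells")
        self.adata = adata[mask]
        self.cell_type = cell_type
        self.method = method
        self.individual_adjust = individual_adjust
        if genes is None:
            from .preprocess import expressed_gene_set

            genes = sorted(expressed_gene_set(adata, cell_type))
        self.genes = list(genes)
        obs = self.adata.obs
        for cond, col in (("disease", "disease"), ("aging", "age_group"), ("smoking", "smoking")):
            if obs[col].nunique() < 2:
                raise ValueError(f"condition {cond!r} has a single level in {cell_type!r}")
        self.design = _design_from_obs(obs)
        _check_full_rank(self.design)

    # ---- fitting -----------------------------------------------------

    def fit(self) -> DEResults:
        gi = [self.adata.var_names.get_loc(g) for g in self.genes]
        X = self.adata.X[:, gi]
        if sparse.issparse(X):
            X = np.asarray(X.todense())
        X = np.asarray(X, dtype=float)
        if self.method == "pseudobulk_lm":
            table = self._fit_pseudobulk(X)
        else:
            table = self._fit_hurdle(X)
        return DEResults(table, self.cell_type, self.method)

    def _fit_pseudobulk(self, X: np.ndarray) -> pd.DataFrame:
        obs = self.adata.obs
        individuals = list(pd.unique(obs["individual"]))
        Y = np.empty((len(individuals), X.shape[1]))
        D = np.empty((len(individuals), 4))
        for i, ind in enumerate(individuals):
            m = (obs["individual"] == ind).to_numpy()
            Y[i] = X[m].mean(axis=0)
            D[i] = self.design.to_numpy()[m][0]
        _check_full_rank(pd.DataFrame(D, columns=self.design.columns))
        beta, pvals, sigma2 = ols_wald_table(D, Y)
        # constant genes: zero effect, p = 1
        const = (Y.max(axis=0) - Y.min(axis=0)) == 0
        rows = []
        for ci, cond in enumerate(CONDITION_COLUMNS, start=1):
            lfc = beta[ci] / np.log(2)
            pv = pvals[ci].copy()
            pv[const] = 1.0
            lfc = np.where(const, 0.0, lfc)
            for g, l, p_ in zip(self.genes, lfc, pv):
                rows.append((g, self.cell_type, cond, float(l), float(np.clip(p_, 0, 1))))
        return pd.DataFrame(
            rows, columns=["gene", "cell_type", "condition", "log2fc", "p_value"]
        )

    def _fit_hurdle(self, X: np.ndarray) -> pd.DataFrame:
        import statsmodels.api as sm

        obs = self.adata.obs
        D = self.design.to_numpy()
        cols = list(self.design.columns)
        if self.individual_adjust == "fixed":
            dummies = pd.get_dummies(obs["individual"], drop_first=True, dtype=float)
            D_full = np.column_stack([D, dummies.to_numpy()])
            # drop individual dummies collinear with the condition columns
            keep = [True] * D.shape[1]
            cur = D
            for j in range(D.shape[1], D_full.shape[1]):
                cand = np.column_stack([cur, D_full[:, j]])
                if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(cur):
                    cur = cand
                    keep.append(True)
                else:
                    keep.append(False)
            D_fit = cur
            fit_kwargs = {}
        else:
            D_fit = D
            fit_kwargs = {
                "cov_type": "cluster",
                "cov_kwds": {"groups": obs["individual"].to_numpy()},
            }
        cidx = [cols.index(c) for c in CONDITION_COLUMNS]
        n_groups = obs["individual"].nunique()

        def part_z(tstats, df):
            """Signed normal quantiles from t-referenced two-sided p-values.

            With cluster-robust covariance the Wald statistic is referenced
            against t(G-1) (G = individuals), the standard small-G guard.
            """
            tstats = np.asarray(tstats, dtype=float)
            p = 2 * stats.t.sf(np.abs(tstats), df)
            p = np.clip(p, 1e-300, 1.0)
            return np.sign(tstats) * stats.norm.isf(p / 2)

        rows = []
        for j, gene in enumerate(self.genes):
            y = X[:, j]
            det = (y > 0).astype(float)
            # adjusted log2fc from the all-cells linear model
            ols_all = sm.OLS(y, D_fit).fit(**fit_kwargs)
            lfc = ols_all.params[cidx] / np.log(2)
            z_cont = np.full(3, np.nan)
            z_disc = np.full(3, np.nan)
            if y.std() == 0:
                for cond in CONDITION_COLUMNS:
                    rows.append((gene, self.cell_type, cond, 0.0, 1.0))
                continue
            pos = y > 0
            if pos.sum() > D_fit.shape[1] + 1 and y[pos].std() > 0:
                kw = dict(fit_kwargs)
                if "cov_kwds" in kw:
                    kw = {
                        "cov_type": "cluster",
                        "cov_kwds": {"groups": obs["individual"].to_numpy()[pos]},
                    }
                    if len(np.unique(kw["cov_kwds"]["groups"])) < 2:
                        kw = {}
                try:
                    cont = sm.OLS(y[pos], D_fit[pos]).fit(**kw)
                    df_c = (
                        n_groups - 1 if kw.get("cov_type") == "cluster" else cont.df_resid
                    )
                    z_cont = part_z(np.asarray(cont.tvalues)[cidx], df_c)
                except np.linalg.LinAlgError:
                    pass
            if 0 < det.sum() < len(det):
                logit_kwargs = (
                    {"cov_type": "cluster", "cov_kwds": {"groups": obs["individual"].to_numpy()}}
                    if self.individual_adjust == "robust"
                    else {}
                )
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        logit = sm.Logit(det, D_fit).fit(
                            disp=0, maxiter=200, method="bfgs", **logit_kwargs
                        )
                    z = np.asarray(logit.tvalues)[cidx]
                    if np.all(np.isfinite(z)):
                        df_d = (
                            n_groups - 1
                            if self.individual_adjust == "robust"
                            else max(len(det) - D_fit.shape[1], 1)
                        )
                        z_disc = part_z(z, df_d)
                except (np.linalg.LinAlgError, ValueError):
                    pass  # separation / singular information: detection part dropped
            for k, cond in enumerate(CONDITION_COLUMNS):
                zs = [z for z in (z_cont[k], z_disc[k]) if np.isfinite(z)]
                if not zs:
                    p = 1.0
                else:
                    z = np.sum(zs) / np.sqrt(len(zs))  # Stouffer combination
                    p = 2 * stats.norm.sf(abs(z))
                rows.append(
                    (gene, self.cell_type, cond, float(lfc[k]), float(np.clip(p, 0, 1)))
                )
        return pd.DataFrame(
            rows, columns=["gene", "cell_type", "condition", "log2fc", "p_value"]
        )


def fit_condition_de(
    adata: ad.AnnData,
    cell_type: str,
    method: str = "cell_hurdle",
    genes=None,
    individual_adjust: str = "robust",
) -> pd.DataFrame:
    """Convenience wrapper: fit :class:`ConditionDEModel` and return its table."""
    return (
        ConditionDEModel(
            adata, cell_type, genes=genes, method=method, individual_adjust=individual_adjust
        )
        .fit()
        .table
    )


def call_degs(
    stats_table: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_abs_log2fc: float = 0.25,
) -> pd.DataFrame:
    """Benjamini-Hochberg FDR within each (cell_type, condition), then call
    DEGs at ``fdr < fdr_threshold`` and ``|log2fc| >= min_abs_log2fc``.

    Returns the table with added ``fdr``, ``direction`` and ``is_deg``
    columns; rows not passing remain for transparency.
    """
    if stats_table.empty:
        return stats_table.assign(fdr=[], direction=[], is_deg=[])
    from statsmodels.stats.multitest import multipletests

    out = stats_table.copy()
    out["fdr"] = np.nan
    for _, idx in out.groupby(["cell_type", "condition"]).groups.items():
        p = out.loc[idx, "p_value"].to_numpy()
        out.loc[idx, "fdr"] = multipletests(p, method="fdr_bh")[1]
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["is_deg"] = (out["fdr"] < fdr_threshold) & (
        out["log2fc"].abs() >= min_abs_log2fc
    )
    return out
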