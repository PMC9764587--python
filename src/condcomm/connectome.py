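"""Ligand-receptor permutation scoring and condition delta-connectomes.

For an ordered cell-type pair (sender A, receiver B) and a
ligand--receptor pair (L, R), the interaction score is the mean of L's
average expression in A and R's average expression in B, computed only
when L is detected in more than ``expr_gate`` of A's cells and R in more
than ``expr_gate`` of B's cells. Significance comes from shuffling the
cluster labels: p = (1 + #{null >= observed}) / (1 + n_perm).

Condition contrasts run the test separately on case and control cells and
count significant pairs per ordered cell-type pair; the difference and
percent change form the delta-connectome, thresholded at a strict >10%
change for the network view. Enhanced pairs are classified by whether the
ligand, the receptor, both, or neither is an up-regulated DEG in its cell
type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "load_lr_database",
    "lr_score_test",
    "DeltaMatrix",
    "condition_delta",
    "delta_network",
    "classify_enhanced_pairs",
]


def load_lr_database(path) -> pd.DataFrame:
    """Read a two-column (ligand, receptor) TSV into an LR database table."""
    db = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in db.columns]
    db.columns = cols
    if "ligand" not in cols or "receptor" not in cols:
        raise ValueError("LR database needs 'ligand' and 'receptor' columns")
    db = db[["ligand", "receptor"]].dropna().astype(str)
    db["pair_id"] = db["ligand"] + "_" + db["receptor"]
    if db["pair_id"].duplicated().any():
        db = db.drop_duplicates("pair_id")
    return db.reset_index(drop=True)


def lr_score_test(
    adata: ad.AnnData,
    db: pd.DataFrame,
    cluster_key: str = "cell_type",
    n_perm: int = 1000,
    alpha: float = 0.05,
    expr_gate: float = 0.10,
    min_cells: int = 3,
    seed: int = 0,
    exact: bool = False,
) -> pd.DataFrame:
    """Permutation test of ligand-receptor scores for every ordered cluster pair.

    Returns one row per (sender, receiver, pair) with ``score``,
    ``p_value``, ``gated`` and ``significant``. Gated-out combinations
    (expression gate failed, or a cluster below ``min_cells``) carry NaN
    score/p and are never significant. With ``exact=True`` every distinct
    assignment of the label multiset is enumerated instead of sampled and
    p = #{null >= observed} / #assignments (the observed assignment is one
    of them, so p > 0); feasible only for a handful of cells.
    """
    if not exact and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-value resolution is coarse")
    labels = adata.obs[cluster_key].to_numpy()
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    genes = sorted(
        (set(db["ligand"]) | set(db["receptor"])) & set(adata.var_names)
    )
    db = db[db["ligand"].isin(genes) & db["receptor"].isin(genes)].reset_index(drop=True)
    gi = {g: k for k, g in enumerate(genes)}
    X = adata[:, genes].X
    if sparse.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    n_cells = X.shape[0]
    codes = pd.Categorical(labels, categories=clusters).codes
    n_cl = len(clusters)
    sizes = np.bincount(codes, minlength=n_cl)
    valid = sizes >= min_cells

    def cluster_means(c):
        M = np.zeros((n_cl, X.shape[1]))
        for k in range(n_cl):
            m = c == k
            if m.any():
                M[k] = X[m].mean(axis=0)
        return M

    obs_means = cluster_means(codes)
    det = np.zeros((n_cl, X.shape[1]))
    for k in range(n_cl):
        m = codes == k
        if m.any():
            det[k] = (X[m] > 0).mean(axis=0)

    if exact:
        from itertools import permutations

        if n_cells > 10:
            raise ValueError("exact enumeration is only feasible for <= 10 cells")
        perms = sorted({tuple(p) for p in permutations(codes.tolist())})
        null_means = np.stack([cluster_means(np.array(c)) for c in perms])
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        null_means = np.empty((n_perm, n_cl, X.shape[1]))
        perm_codes = codes.copy()
        for p in range(n_perm):
            rng.shuffle(perm_codes)
            null_means[p] = cluster_means(perm_codes)

    rows = []
    for _, pair in db.iterrows():
        li, ri = gi[pair["ligand"]], gi[pair["receptor"]]
        for a in range(n_cl):
            for b in range(n_cl):
                gate_ok = (
                    valid[a]
                    and valid[b]
                    and det[a, li] > expr_gate
                    and det[b, ri] > expr_gate
                )
                if not gate_ok:
                    rows.append(
                        (clusters[a], clusters[b], pair["pair_id"], np.nan, np.nan, True, False)
                    )
                    continue
                score = 0.5 * (obs_means[a, li] + obs_means[b, ri])
                null = 0.5 * (null_means[:, a, li] + null_means[:, b, ri])
                if exact:
                    # observed assignment is among the enumerated ones
                    pval = int((null >= score - 1e-12).sum()) / n_perm
                else:
                    pval = (1 + int((null >= score).sum())) / (1 + n_perm)
                rows.append(
                    (
                        clusters[a],
                        clusters[b],
                        pair["pair_id"],
                        score,
                        pval,
                        False,
                        pval < alpha,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["sender_ct", "receiver_ct", "pair_id", "score", "p_value", "gated", "significant"],
    )


@dataclass
class DeltaMatrix:
    """Counts of significant LR pairs per ordered cell-type pair in two
    condition groups, their differences, and per-cell-type totals."""

    pairs: pd.DataFrame  # sender_ct, receiver_ct, n_case, n_control, delta, pct_change
    totals: pd.Series  # per cell type: sum of deltas as sender + as receiver

    def matrix(self, column: str = "delta") -> pd.DataFrame:
        return self.pairs.pivot(index="sender_ct", columns="receiver_ct", values=column)


def condition_delta(case_table: pd.DataFrame, control_table: pd.DataFrame) -> DeltaMatrix:
    """Delta-connectome between two interaction tables (same db and gates).

    ``pct_change`` is NaN-flagged where the control count is zero.
    """
    cl_case = set(case_table["sender_ct"]) | set(case_table["receiver_ct"])
    cl_ctrl = set(control_table["sender_ct"]) | set(control_table["receiver_ct"])
    if cl_case != cl_ctrl:
        raise ValueError("mismatched cluster sets between case and control tables")

    def counts(t):
        sig = t[t["significant"]]
        return sig.groupby(["sender_ct", "receiver_ct"]).size()

    n_case = counts(case_table)
    n_ctrl = counts(control_table)
    clusters = sorted(cl_case)
    rows = []
    for a in clusters:
        for b in clusters:
            nc = int(n_case.get((a, b), 0))
            nk = int(n_ctrl.get((a, b), 0))
            delta = nc - nk
            pct = delta / nk if nk > 0 else np.nan
            rows.append((a, b, nc, nk, delta, pct))
    pairs = pd.DataFrame(
        rows, columns=["sender_ct", "receiver_ct", "n_case", "n_control", "delta", "pct_change"]
    )
    totals = pd.Series(0, index=clusters, dtype=int)
    for _, r in pairs.iterrows():
        totals[r["sender_ct"]] += r["delta"]
        totals[r["receiver_ct"]] += r["delta"]
    return DeltaMatrix(pairs=pairs, totals=totals)


def delta_network(d: DeltaMatrix, threshold: float = 0.10):
    """Edges with a strictly greater than ``threshold`` absolute percent
    change; a +10.0% change is excluded. Returns ``(edge DataFrame, DiGraph)``
    with per-node total-change attributes."""
    p = d.pairs.dropna(subset=["pct_change"])
    edges = p[p["pct_change"].abs() > threshold].copy()
    edges["sign"] = np.where(edges["pct_change"] > 0, "increase", "decrease")
    g = nx.DiGraph()
    for ct, tot in d.totals.items():
        g.add_node(ct, total_change=int(tot))
    for _, r in edges.iterrows():
        g.add_edge(
            r["sender_ct"], r["receiver_ct"], pct_change=float(r["pct_change"]), sign=r["sign"]
        )
    return edges.reset_index(drop=True), g


def classify_enhanced_pairs(
    enhanced: pd.DataFrame,
    degs: pd.DataFrame,
    condition: str = "disease",
) -> pd.DataFrame:
    """Classify enhanced LR pairs by DEG status of their endpoints.

    ``enhanced`` rows need ``sender_ct``, ``receiver_ct``, ``ligand``,
    ``receptor``. A pair is ``ligand-up`` when the ligand is an up-DEG in
    the sender and the receptor is not an up-DEG in the receiver;
    ``receptor-up`` symmetrically; ``both``/``neither`` accordingly. Genes
    absent from the DEG table count as non-DEG (logged via warning once).
    """
    d = degs[(degs["condition"] == condition) & degs["is_deg"] & (degs["direction"] == "up")]
    up = set(zip(d["cell_type"], d["gene"]))
    tested = set(zip(degs["cell_type"], degs["gene"]))
    missing = []
    classes = []
    for _, r in enhanced.iterrows():
        if (r["sender_ct"], r["ligand"]) not in tested:
            missing.append((r["sender_ct"], r["ligand"]))
        if (r["receiver_ct"], r["receptor"]) not in tested:
            missing.append((r["receiver_ct"], r["receptor"]))
        l_up = (r["sender_ct"], r["ligand"]) in up
        r_up = (r["receiver_ct"], r["receptor"]) in up
        if l_up and r_up:
            classes.append("both")
        elif l_up:
            classes.append("ligand-up")
        elif r_up:
            classes.append("receptor-up")
        else:
            classes.append("neither")
    if missing:
        warnings.warn(
            f"{len(missing)} ligand/receptor genes absent from the DEG table; treated as non-DEG"
        )
    out = enhanced.copy()
    out["class"] = classes
    return out
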