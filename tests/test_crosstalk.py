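import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from condcomm.crosstalk import (
    CrosstalkCorrelationMap,
    _spearman_matrix,
    correlated_gene_lists,
    correlated_proportion,
    sender_receiver_correlation,
)
from condcomm.preprocess import PseudobulkCube


def _cube(values_by_ct, individuals=None):
    """Build a PseudobulkCube from {cell_type: DataFrame(ind x gene)}."""
    cts = list(values_by_ct)
    genes = sorted({g for df in values_by_ct.values() for g in df.columns})
    inds = individuals or list(values_by_ct[cts[0]].index)
    values = np.full((len(inds), len(cts), len(genes)), np.nan)
    counts = np.zeros((len(inds), len(cts)), dtype=int)
    for j, ct in enumerate(cts):
        df = values_by_ct[ct]
        for i, ind in enumerate(inds):
            if ind in df.index:
                counts[i, j] = 1
                for g in df.columns:
                    values[i, j, genes.index(g)] = df.loc[ind, g]
    return PseudobulkCube(values, counts, inds, cts, genes)


def test_hand_spearman_value():
    """x=(1,2,3) vs y=(3,1,2) gives rho = -0.5 (sum d^2 = 6)."""
    A = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc"))
    B = pd.DataFrame({"t": [3.0, 1.0, 2.0]}, index=list("abc"))
    rho = _spearman_matrix(A, B)
    assert rho.loc["f", "t"] == pytest.approx(-0.5)
    # cross-check through the public operation
    cube = _cube({"S": A, "R": B})
    cmap = sender_receiver_correlation(
        cube, ["f"], "S", ["R"], expressed_sets={"R": {"t"}}, min_individuals=3
    )
    assert cmap.rho["R"].loc["f", "t"] == pytest.approx(-0.5)


def test_spearman_matches_scipy_with_ties():
    rng = np.random.default_rng(0)
    A = pd.DataFrame(rng.integers(0, 4, size=(9, 3)).astype(float))
    B = pd.DataFrame(rng.integers(0, 4, size=(9, 4)).astype(float))
    A.columns = [f"f{i}" for i in range(3)]
    B.columns = [f"t{i}" for i in range(4)]
    rho = _spearman_matrix(A, B)
    for f in A.columns:
        for t in B.columns:
            expected = stats.spearmanr(A[f], B[t]).statistic
            if np.isnan(expected):
                assert np.isnan(rho.loc[f, t])
            else:
                assert rho.loc[f, t] == pytest.approx(expected, abs=1e-12)


def test_shared_monotone_factor_gives_rho_one():
    u = pd.Series([0.3, -1.2, 0.8, 2.0, -0.5, 0.1, 1.1], index=[f"i{k}" for k in range(7)])
    A = pd.DataFrame({"f": np.exp(u)}, index=u.index)
    B = pd.DataFrame({"t": 2 * u + 5}, index=u.index)
    cube = _cube({"S": A, "R": B})
    cmap = sender_receiver_correlation(
        cube, ["f"], "S", ["R"], expressed_sets={"R": {"t"}}, min_individuals=5
    )
    assert cmap.rho["R"].loc["f", "t"] == pytest.approx(1.0)


def test_independent_genes_have_near_zero_mean_rho():
    rng = np.random.default_rng(1)
    n = 9
    A = pd.DataFrame({"f": rng.normal(size=n)}, index=[f"i{k}" for k in range(n)])
    B = pd.DataFrame(
        rng.normal(size=(n, 500)), index=A.index, columns=[f"t{j}" for j in range(500)]
    )
    cube = _cube({"S": A, "R": B})
    cmap = sender_receiver_correlation(
        cube, ["f"], "S", ["R"], expressed_sets={"R": set(B.columns)}, min_individuals=5
    )
    mean_rho = np.nanmean(cmap.rho["R"].to_numpy())
    assert abs(mean_rho) < 2 / np.sqrt(n)


def test_null_tail_matches_exact_permutation_distribution():
    """P(|rho| >= 0.8) for independent genes at n=7 equals the tail of
    Spearman's exact permutation distribution (full 7! enumeration)."""
    n = 7
    base = np.arange(1, n + 1)
    rhos = []
    for perm in itertools.permutations(range(1, n + 1)):
        rhos.append(stats.spearmanr(base, perm).statistic)
    exact_tail = np.mean(np.abs(rhos) >= 0.8)

    rng = np.random.default_rng(2)
    n_targets = 4000
    A = pd.DataFrame({"f": rng.normal(size=n)}, index=[f"i{k}" for k in range(n)])
    B = pd.DataFrame(
        rng.normal(size=(n, n_targets)),
        index=A.index,
        columns=[f"t{j}" for j in range(n_targets)],
    )
    cube = _cube({"S": A, "R": B})
    cmap = sender_receiver_correlation(
        cube, ["f"], "S", ["R"], expressed_sets={"R": set(B.columns)}, min_individuals=5
    )
    frac = (cmap.rho["R"].abs() >= 0.8).to_numpy().mean()
    se = np.sqrt(exact_tail * (1 - exact_tail) / n_targets)
    assert abs(frac - exact_tail) < 5 * se + 0.005


class TestCorrelatedProportion:
    def _map(self, rho_df, expressed, sender="S"):
        return CrosstalkCorrelationMap(
            sender_ct=sender,
            focal_genes=list(rho_df.index),
            rho={"R": rho_df},
            n_individuals={"R": 9},
            expressed_sets={"R": expressed},
        )

    def test_zero_rho_gives_zero_proportions(self):
        rho = pd.DataFrame(np.zeros((2, 4)), index=["f1", "f2"], columns=list("abcd"))
        heat, order = correlated_proportion(self._map(rho, set("abcd")))
        assert (heat.to_numpy() == 0).all()

    def test_exact_threshold_is_counted(self):
        rho = pd.DataFrame([[0.8, -0.8, 0.79]], index=["f"], columns=list("abc"))
        heat, _ = correlated_proportion(self._map(rho, set("abc")))
        assert heat.loc["R", "f"] == pytest.approx(2 / 3)

    def test_recipients_ordered_by_mean_proportion(self):
        rho_hi = pd.DataFrame([[0.9, 0.9]], index=["f"], columns=["a", "b"])
        rho_lo = pd.DataFrame([[0.9, 0.0]], index=["f"], columns=["a", "b"])
        cmap = CrosstalkCorrelationMap(
            sender_ct="S",
            focal_genes=["f"],
            rho={"low": rho_lo, "high": rho_hi},
            n_individuals={"low": 9, "high": 9},
            expressed_sets={"low": {"a", "b"}, "high": {"a", "b"}},
        )
        heat, order = correlated_proportion(cmap)
        assert order == ["high", "low"]


class TestCorrelatedGeneLists:
    def test_threshold_above_one_empties_lists(self):
        rho = pd.DataFrame([[1.0, 0.9]], index=["f"], columns=["a", "b"])
        cmap = CrosstalkCorrelationMap(
            "S", ["f"], {"R": rho}, {"R": 9}, {"R": {"a", "b"}}
        )
        lists = correlated_gene_lists(cmap, threshold=1.1)
        assert lists["R"]["f"] == []

    def test_sender_side_excludes_self(self):
        rho = pd.DataFrame(
            [[1.0, 0.95]], index=["f"], columns=["f", "other"]
        )
        cmap = CrosstalkCorrelationMap(
            "S", ["f"], {"S": rho}, {"S": 9}, {"S": {"f", "other"}}
        )
        lists = correlated_gene_lists(cmap, side="sender")
        assert lists["f"] == ["other"]

    def test_individual_order_invariance(self):
        rng = np.random.default_rng(3)
        inds = [f"i{k}" for k in range(9)]
        A = pd.DataFrame({"f": rng.normal(size=9)}, index=inds)
        B = pd.DataFrame(rng.normal(size=(9, 30)), index=inds,
                         columns=[f"t{j}" for j in range(30)])
        cube1 = _cube({"S": A, "R": B})
        perm = list(np.random.default_rng(4).permutation(inds))
        cube2 = _cube({"S": A.loc[perm], "R": B.loc[perm]}, individuals=perm)
        sets = {"R": set(B.columns)}
        l1 = correlated_gene_lists(
            sender_receiver_correlation(cube1, ["f"], "S", ["R"], sets), threshold=0.5
        )
        l2 = correlated_gene_lists(
            sender_receiver_correlation(cube2, ["f"], "S", ["R"], sets), threshold=0.5
        )
        assert l1 == l2


def test_min_individuals_floor_and_constant_flagging():
    inds = [f"i{k}" for k in range(4)]
    A = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=inds)
    B = pd.DataFrame({"t": [1.0, 1.0, 1.0, 1.0]}, index=inds)
    cube = _cube({"S": A, "R": B})
    with pytest.raises(ValueError, match="floor"):
        sender_receiver_correlation(cube, ["f"], "S", ["R"], {"R": {"t"}})
    cmap = sender_receiver_correlation(
        cube, ["f"], "S", ["R"], {"R": {"t"}}, min_individuals=4
    )
    assert np.isnan(cmap.rho["R"].loc["f", "t"])  # constant vector flagged


def test_planted_module_recipient_ranks_first(planted_norm, planted_cohort):
    from condcomm.preprocess import expressed_gene_set, individual_pseudobulk

    _, truth = planted_cohort
    module = truth.module_ledger[0]
    cube = individual_pseudobulk(planted_norm)
    cts = list(pd.unique(planted_norm.obs["cell_type"]))
    sets = {ct: expressed_gene_set(planted_norm, ct) for ct in cts}
    cmap = sender_receiver_correlation(
        cube, module["focal_genes"], module["sender_ct"],
        [ct for ct in cts if ct != module["sender_ct"]], expressed_sets=sets,
    )
    heat, order = correlated_proportion(cmap)
    assert order[0] == module["receiver_ct"]
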