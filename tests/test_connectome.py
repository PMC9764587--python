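import itertools

import numpy as np
import pandas as pd
import pytest

from condcomm.connectome import (
    DeltaMatrix,
    classify_enhanced_pairs,
    condition_delta,
    delta_network,
    load_lr_database,
    lr_score_test,
)
from tests.conftest import make_adata


def _db(pairs):
    db = pd.DataFrame(pairs, columns=["ligand", "receptor"])
    db["pair_id"] = db["ligand"] + "_" + db["receptor"]
    return db


def _interaction_table(rows):
    return pd.DataFrame(
        rows,
        columns=["sender_ct", "receiver_ct", "pair_id", "score", "p_value", "gated", "significant"],
    )


class TestLRScoreTest:
    def test_expression_gate(self):
        # ligand g0 detected in 1/20 (5%) of sender cells -> gated out
        counts = np.zeros((40, 2))
        counts[0, 0] = 5.0  # ligand in one A cell only
        counts[:, 1] = 1.0  # receptor everywhere
        adata = make_adata(counts, cell_types=["A"] * 20 + ["B"] * 20)
        res = lr_score_test(adata, _db([("g0", "g1")]), n_perm=100, seed=0)
        row = res.set_index(["sender_ct", "receiver_ct"]).loc[("A", "B")]
        assert bool(row["gated"]) and not bool(row["significant"])

    def test_exact_enumeration_matches_brute_force(self):
        """p from the exact mode equals an independent enumeration of all
        label permutations on a 6-cell instance."""
        rng = np.random.default_rng(1)
        counts = rng.poisson(3.0, size=(6, 2)).astype(float) + 1
        labels = ["A", "A", "A", "B", "B", "B"]
        adata = make_adata(counts, cell_types=labels)
        res = lr_score_test(
            adata, _db([("g0", "g1")]), exact=True, expr_gate=0.0, min_cells=3, seed=0
        )
        X = counts
        # independent oracle: all distinct assignments of the label multiset
        def score(assign, a, b):
            ma = [i for i, l in enumerate(assign) if l == a]
            mb = [i for i, l in enumerate(assign) if l == b]
            return 0.5 * (X[ma, 0].mean() + X[mb, 1].mean())

        perms = sorted(set(itertools.permutations(labels)))
        assert len(perms) == 20
        for a, b in itertools.product("AB", repeat=2):
            obs = score(labels, a, b)
            p_oracle = np.mean([score(p, a, b) >= obs - 1e-12 for p in perms])
            got = res.set_index(["sender_ct", "receiver_ct"]).loc[(a, b), "p_value"]
            assert got == pytest.approx(p_oracle, abs=1e-12)

    def test_type_i_rate_under_exchangeable_labels(self):
        """With iid cells split into arbitrary clusters the significant
        fraction at alpha=0.05 stays within 0.05 +/- 0.02 over 2,000 tests."""
        rng = np.random.default_rng(2)
        n_pairs = 125  # x 16 ordered cluster pairs = 2,000 tests
        counts = rng.poisson(2.0, size=(120, 2 * n_pairs)).astype(float)
        labels = np.repeat(list("ABCD"), 30)
        adata = make_adata(counts, cell_types=labels)
        pairs = [(f"g{2 * i}", f"g{2 * i + 1}") for i in range(n_pairs)]
        res = lr_score_test(adata, _db(pairs), n_perm=400, seed=3)
        tested = res[~res["gated"]]
        assert len(tested) == 2000
        frac = tested["significant"].mean()
        assert abs(frac - 0.05) <= 0.02

    def test_seed_reproducibility_and_cell_order_invariance(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(2.0, size=(60, 4)).astype(float)
        labels = ["A"] * 30 + ["B"] * 30
        adata = make_adata(counts, cell_types=labels)
        db = _db([("g0", "g1"), ("g2", "g3")])
        r1 = lr_score_test(adata, db, n_perm=200, seed=9)
        r2 = lr_score_test(adata, db, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(2.0, size=(80, 20)).astype(float)
        labels = np.repeat(["A", "B"], 40)
        adata = make_adata(counts, cell_types=labels)
        db = _db([(f"g{2 * i}", f"g{2 * i + 1}") for i in range(10)])
        lo = lr_score_test(adata, db, n_perm=300, alpha=0.05, seed=1)
        hi = lr_score_test(adata, db, n_perm=300, alpha=0.20, seed=1)
        assert hi["significant"].sum() >= lo["significant"].sum()


class TestConditionDelta:
    def test_case_equals_control_gives_zero(self):
        rows = [("A", "B", "p1", 1.0, 0.01, False, True)]
        d = condition_delta(_interaction_table(rows), _interaction_table(rows))
        assert (d.pairs["delta"] == 0).all()

    def test_percent_change_arithmetic(self):
        rows_case = [("A", "B", f"p{i}", 1.0, 0.01, False, True) for i in range(23)]
        rows_ctrl = [("A", "B", f"p{i}", 1.0, 0.01, False, True) for i in range(20)]
        d = condition_delta(_interaction_table(rows_case), _interaction_table(rows_ctrl))
        row = d.pairs.set_index(["sender_ct", "receiver_ct"]).loc[("A", "B")]
        assert row["delta"] == 3
        assert row["pct_change"] == pytest.approx(0.15)

    def test_zero_control_flagged_undefined(self):
        rows_case = [("A", "B", "p1", 1.0, 0.01, False, True)]
        rows_ctrl = [("A", "B", "p1", 1.0, 0.9, False, False)]
        d = condition_delta(_interaction_table(rows_case), _interaction_table(rows_ctrl))
        row = d.pairs.set_index(["sender_ct", "receiver_ct"]).loc[("A", "B")]
        assert np.isnan(row["pct_change"]) and row["delta"] == 1

    def test_mismatched_clusters_error(self):
        t1 = _interaction_table([("A", "B", "p1", 1.0, 0.01, False, True)])
        t2 = _interaction_table([("A", "C", "p1", 1.0, 0.01, False, True)])
        with pytest.raises(ValueError, match="mismatch"):
            condition_delta(t1, t2)

    def test_counts_are_order_dependent(self, planted_norm):
        """count(A->B) need not equal count(B->A): built directly from an
        asymmetric table."""
        rows = [
            ("A", "B", "p1", 1.0, 0.01, False, True),
            ("A", "B", "p2", 1.0, 0.01, False, True),
            ("B", "A", "p1", 1.0, 0.01, False, True),
        ]
        t = _interaction_table(rows)
        empty = _interaction_table([("A", "B", "p1", 1.0, 0.9, False, False)])
        d = condition_delta(t, empty)
        m = d.matrix("n_case")
        assert m.loc["A", "B"] == 2 and m.loc["B", "A"] == 1


class TestDeltaNetwork:
    def _delta(self, pct):
        pairs = pd.DataFrame(
            {
                "sender_ct": ["A"],
                "receiver_ct": ["B"],
                "n_case": [11],
                "n_control": [10],
                "delta": [1],
                "pct_change": [pct],
            }
        )
        return DeltaMatrix(pairs=pairs, totals=pd.Series({"A": 1, "B": 1}))

    def test_exact_threshold_excluded(self):
        edges, g = delta_network(self._delta(0.10))
        assert len(edges) == 0 and g.number_of_edges() == 0

    def test_above_threshold_included_with_sign(self):
        edges, g = delta_network(self._delta(0.15))
        assert len(edges) == 1 and edges.iloc[0]["sign"] == "increase"
        assert g.nodes["A"]["total_change"] == 1

    def test_all_zero_deltas_empty(self):
        edges, _ = delta_network(self._delta(0.0))
        assert edges.empty


def test_classify_enhanced_pairs():
    degs = pd.DataFrame(
        {
            "gene": ["L1", "R1", "L2", "R2", "L3", "R3"],
            "cell_type": ["S", "R", "S", "R", "S", "R"],
            "condition": "disease",
            "log2fc": [1, 1, 1, -1, -1, 1],
            "fdr": 0.01,
            "direction": ["up", "up", "up", "down", "down", "up"],
            "is_deg": [True, True, True, True, False, False],
        }
    )
    enhanced = pd.DataFrame(
        {
            "sender_ct": ["S"] * 4,
            "receiver_ct": ["R"] * 4,
            "ligand": ["L1", "L2", "L3", "LX"],
            "receptor": ["R2", "R1", "R3", "RX"],
        }
    )
    with pytest.warns(UserWarning, match="absent"):
        out = classify_enhanced_pairs(enhanced, degs)
    assert out["class"].tolist() == ["ligand-up", "both", "neither", "neither"]


def test_planted_lr_pair_gives_positive_delta(planted_norm):
    db = _db([("G00300", "G00301")])
    case = planted_norm[(planted_norm.obs["disease"] == "COPD").to_numpy()]
    ctrl = planted_norm[(planted_norm.obs["disease"] != "COPD").to_numpy()]
    tc = lr_score_test(case, db, n_perm=300, seed=1)
    tk = lr_score_test(ctrl, db, n_perm=300, seed=2)
    d = condition_delta(tc, tk)
    assert d.matrix("delta").loc["monocyte", "AT2"] >= 1


def test_load_lr_database(tmp_path):
    p = tmp_path / "db.tsv"
    p.write_text("ligand\treceptor\nL1\tR1\nL1\tR1\nL2\tR2\n")
    db = load_lr_database(p)
    assert len(db) == 2 and set(db.columns) == {"ligand", "receptor", "pair_id"}
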