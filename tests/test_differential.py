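"""Differential calls, set overlaps and the QC surfaces."""
import numpy as np
import pandas as pd
import pingouin
import pytest

import plexquant as pq
from plexquant.differential import CALL_DOWN, CALL_UNCHANGED, CALL_UNTESTABLE, CALL_UP
from plexquant.rollup import ProteinQuantTable


def _table(control: np.ndarray, glaucoma: np.ndarray, accs) -> ProteinQuantTable:
    nc, ng = control.shape[1], glaucoma.shape[1]
    cols = [f"C{i}" for i in range(nc)] + [f"G{i}" for i in range(ng)]
    data = pd.DataFrame(np.hstack([control, glaucoma]), index=accs, columns=cols)
    groups = pd.Series(["control"] * nc + ["glaucoma"] * ng, index=cols)
    return ProteinQuantTable("retina", data, groups)


class TestTestProtein:
    def test_identical_groups(self):
        v = np.array([1.0, 2, 3, 4, 5])
        fc, p = pq.test_protein(v, v)
        assert fc == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_clear_twofold_shift_matches_reference_ttest(self):
        """fc = 2 exactly and p agrees with an independent t-test
        implementation (pingouin) on the log2 values."""
        c = np.array([1.0, 1.1, 0.9, 1.0, 1.0])
        g = 2.0 * c
        fc, p = pq.test_protein(c, g)
        assert fc == pytest.approx(2.0)
        assert p < 1e-6
        ref = pingouin.ttest(np.log2(g), np.log2(c), correction=False)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_min_n_gate(self):
        fc, p = pq.test_protein(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]), min_n=3)
        assert np.isnan(fc) and np.isnan(p)

    def test_constant_but_different_groups(self):
        fc, p = pq.test_protein(np.array([1.0, 1, 1]), np.array([2.0, 2, 2]))
        assert fc == pytest.approx(2.0)
        assert p == 0.0

    def test_table_agrees_with_scalar_path(self):
        rng = np.random.default_rng(5)
        C = rng.lognormal(0, 0.3, (40, 10))
        G = rng.lognormal(0.2, 0.3, (40, 10))
        table = _table(C, G, [f"P{i}" for i in range(40)])
        res = pq.test_table(table)
        for i in (0, 7, 23):
            fc, p = pq.test_protein(C[i], G[i])
            assert res["fold_change"].iloc[i] == pytest.approx(fc)
            assert res["p_value"].iloc[i] == pytest.approx(p)


class TestClassify:
    def _frame(self, p, fc):
        return pd.DataFrame({"fold_change": [fc], "log2_fc": [np.log2(fc)], "p_value": [p]}, index=["X"])

    @pytest.mark.parametrize(
        "p,fc,expected",
        [
            (0.05, 1.3, CALL_UP),        # both boundaries inclusive
            (0.05, 0.77, CALL_DOWN),
            (0.001, 1.2, CALL_UNCHANGED),  # fold gate fails
            (0.06, 3.0, CALL_UNCHANGED),   # significance gate fails
            (np.nan, np.nan, CALL_UNTESTABLE),
        ],
    )
    def test_dual_threshold_boundaries(self, p, fc, expected):
        out = pq.classify_differential(self._frame(p, fc))
        assert out["call"].iloc[0] == expected

    def test_down_variant_076(self):
        out = pq.classify_differential(self._frame(0.01, 0.765), down_fc=0.76)
        assert out["call"].iloc[0] == CALL_UNCHANGED
        out = pq.classify_differential(self._frame(0.01, 0.765), down_fc=0.77)
        assert out["call"].iloc[0] == CALL_DOWN

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            pq.classify_differential(self._frame(0.5, 1.0), up_fc=1.3, down_fc=1.4)

    def test_group_swap_symmetry(self):
        """Swapping group labels maps up <-> down and keeps p-values."""
        rng = np.random.default_rng(11)
        C = rng.lognormal(0, 0.3, (60, 10))
        G = C * rng.choice([0.5, 1.0, 2.0], size=(60, 1))
        accs = [f"P{i}" for i in range(60)]
        fwd = pq.classify_differential(pq.test_table(_table(C, G, accs)))
        rev = pq.classify_differential(pq.test_table(_table(G, C, accs)))
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-9)
        swap = {CALL_UP: CALL_DOWN, CALL_DOWN: CALL_UP}
        for a, b in zip(fwd["call"], rev["call"]):
            assert b == swap.get(a, a)


class TestVenn:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"a", "b"}, {"b", "c"}, (1, 1, 1)),
            ({"x", "y", "z"}, {"p", "q", "r", "s"}, (3, 0, 4)),
            ({"a", "b"}, {"a", "b"}, (0, 2, 0)),
        ],
    )
    def test_counts(self, a, b, expected):
        ov = pq.venn_overlap(a, b)
        assert (ov.only_a, ov.shared, ov.only_b) == expected
        assert ov.only_a + ov.shared + ov.only_b == len(a | b)


class TestQCSurfaces:
    def _setup(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        C = rng.lognormal(0, 0.2, (n, 6))
        G = C * np.where(rng.random((n, 1)) < 0.3, 2.0, 1.0)
        G = G * rng.lognormal(0, 0.05, (n, 6))  # per-sample measurement noise
        accs = [f"P{i}" for i in range(n)]
        table = _table(C, G, accs)
        classified = pq.classify_differential(pq.test_table(table))
        return table, classified

    def test_volcano_arithmetic(self):
        """A protein with p = 0.01 and fc = 2 lands at (1.0, 2.0) in
        (log2 fc, -log10 p) coordinates."""
        table, classified = self._setup()
        classified.loc[classified.index[0], ["fold_change", "log2_fc", "p_value"]] = [2.0, 1.0, 0.01]
        qc = pq.qc_surfaces(table, classified)
        row = qc.volcano.loc[classified.index[0]]
        assert row["log2_fc"] == pytest.approx(1.0)
        assert row["neg_log10_p"] == pytest.approx(2.0)

    def test_duplicated_samples_merge_first(self):
        table, classified = self._setup(seed=3)
        data = table.data.copy()
        data["G0"] = data["G1"]  # duplicate one glaucoma sample
        dup = ProteinQuantTable(table.tissue, data, table.groups)
        qc = pq.qc_surfaces(dup, classified)
        first = qc.linkage[0]
        cols = list(qc.ratio_matrix.columns)
        merged = {cols[int(first[0])], cols[int(first[1])]}
        assert merged == {"G0", "G1"}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_rank_one_matrix_single_component(self):
        """A matrix that is rank one in log space (sample effect + protein
        effect) puts 100% of the variance on PC1."""
        from plexquant.differential import compute_pca

        rng = np.random.default_rng(7)
        col = rng.lognormal(0, 0.5, 30)
        weights = rng.uniform(0.5, 2.0, 8)
        data = pd.DataFrame(
            np.outer(col, weights), index=[f"P{i}" for i in range(30)],
            columns=[f"C{i}" for i in range(4)] + [f"G{i}" for i in range(4)],
        )
        table = ProteinQuantTable(
            "retina", data, pd.Series(["control"] * 4 + ["glaucoma"] * 4,
                                      index=data.columns),
        )
        _, evr = compute_pca(table)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_rejected(self):
        data = pd.DataFrame(
            np.ones((5, 6)), index=[f"P{i}" for i in range(5)],
            columns=[f"C{i}" for i in range(3)] + [f"G{i}" for i in range(3)],
        )
        table = ProteinQuantTable(
            "retina", data, pd.Series(["control"] * 3 + ["glaucoma"] * 3, index=data.columns)
        )
        classified = pd.DataFrame(
            {"fold_change": 2.0, "log2_fc": 1.0, "p_value": 0.01},
            index=data.index,
        )
        classified = pq.classify_differential(classified)
        with pytest.raises(ValueError):
            pq.qc_surfaces(table, classified)

    def test_sample_summaries_cover_all_samples(self):
        table, classified = self._setup(seed=9)
        qc = pq.qc_surfaces(table, classified)
        assert set(qc.sample_summaries.index) == set(table.data.columns)
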