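"""HRF, design matrices, regulation/voxelwise GLMs, group LMEs, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adaptivenf import analysis, preproc, taskdesign


class TestCanonicalHRF:
    def test_zero_at_origin(self):
        h = analysis.canonical_hrf(2.0)
        assert h[0] == 0.0

    def test_peak_near_five_seconds(self):
        """Numeric maximization of the double-gamma at fine sampling."""
        h = analysis.canonical_hrf(0.01)
        assert np.argmax(h) * 0.01 == pytest.approx(5.0, abs=0.1)

    def test_peak_normalized(self):
        assert analysis.canonical_hrf(2.0).max() == pytest.approx(1.0)

    def test_undershoot_exists(self):
        h = analysis.canonical_hrf(0.5)
        assert h.min() < 0


class TestBuildDesign:
    def test_two_task_regressors_without_opacity(self, training_design):
        dm = analysis.build_design(training_design)
        assert dm.names == ("intercept", "attend_word", "attend_face")

    def test_four_task_regressors_with_opacity(self, feedback_design):
        opacity = np.full(feedback_design.n_trs, 0.6)
        opacity[feedback_design.tr_labels == 0] = np.nan
        opacity = np.nan_to_num(opacity, nan=0.5)
        dm = analysis.build_design(feedback_design, opacity=opacity)
        assert len(dm.task_names) == 4
        assert "attend_word_x_opacity" in dm.names

    def test_constant_opacity_modulator_zero(self, feedback_design):
        dm = analysis.build_design(
            feedback_design, opacity=np.full(feedback_design.n_trs, 0.7)
        )
        mod = dm.values[:, list(dm.names).index("attend_face_x_opacity")]
        np.testing.assert_allclose(mod, 0, atol=1e-12)

    def test_convolution_linearity(self, training_design):
        """The design of a run equals the sum of single-block designs."""
        full = analysis.build_design(training_design)
        col = list(full.names).index("attend_face")
        acc = np.zeros(training_design.n_trs)
        for k, b in enumerate(training_design.blocks):
            if b.instruction != taskdesign.ATTEND_FACE:
                continue
            boxcar = (training_design.block_index_per_tr() == k).astype(float)
            acc += analysis.hrf_convolve(boxcar, training_design.tr_seconds)
        np.testing.assert_allclose(full.values[:, col], acc, atol=1e-10)


def ols_normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestRegulationBetas:
    def test_exact_fit_recovers_unit_beta(self, training_design):
        dm = analysis.build_design(training_design)
        hd = dm.values[:, list(dm.names).index("attend_face")]
        res = analysis.regulation_betas(hd, dm)
        assert res.betas["attend_face"] == pytest.approx(1.0, abs=1e-9)
        assert res.betas["attend_word"] == pytest.approx(0.0, abs=1e-9)

    def test_negated_hd_negates_betas(self, training_design):
        rng = np.random.default_rng(0)
        dm = analysis.build_design(training_design)
        hd = dm.values @ np.array([0.1, 0.5, -0.7]) + rng.normal(0, 0.1, training_design.n_trs)
        a = analysis.regulation_betas(hd, dm)
        b = analysis.regulation_betas(-hd, dm)
        np.testing.assert_allclose(a.betas.values, -b.betas.values, atol=1e-10)

    def test_white_noise_betas_near_zero(self, training_design):
        """Null HD traces: task betas within 3 SEs of zero almost always."""
        rng = np.random.default_rng(1)
        dm = analysis.build_design(training_design)
        within = 0
        n_rep = 120
        for _ in range(n_rep):
            res = analysis.regulation_betas(rng.normal(size=training_design.n_trs), dm)
            z = res.betas["attend_face"] / res.stderr["attend_face"]
            within += abs(z) < 3
        assert within / n_rep > 0.95

    def test_matches_normal_equations_oracle(self, training_design):
        rng = np.random.default_rng(2)
        dm = analysis.build_design(training_design)
        for _ in range(20):
            hd = rng.normal(size=training_design.n_trs)
            res = analysis.regulation_betas(hd, dm)
            expected = ols_normal_equations(dm.values, hd)
            np.testing.assert_allclose(res.betas.values, expected, atol=1e-8)

    def test_rank_deficient_design_names_columns(self, training_design):
        dm = analysis.build_design(training_design)
        bad = analysis.DesignMatrix(
            values=np.column_stack([dm.values, dm.values[:, 1]]),
            names=(*dm.names, "attend_word_copy"),
            tr_seconds=dm.tr_seconds,
            keep=dm.keep,
        )
        with pytest.raises(ValueError, match="collinear"):
            analysis.regulation_betas(np.ones(training_design.n_trs), bad)


class TestVoxelwiseGLM:
    def test_planted_coefficient_recovered(self, feedback_design):
        rng = np.random.default_rng(3)
        opacity = 0.5 + 0.2 * np.sin(np.arange(feedback_design.n_trs))
        dm = analysis.build_design(feedback_design, opacity=opacity)
        mod = dm.values[:, list(dm.names).index("attend_word_x_opacity")]
        y = np.column_stack(
            [2.0 * mod + rng.normal(0, 1e-8, len(mod)), rng.normal(size=len(mod))]
        )
        out = analysis.voxelwise_glm(y, dm)
        row = out[out.regressor == "attend_word_x_opacity"].iloc[0]
        assert row["beta"][0] == pytest.approx(2.0, abs=1e-6)

    def test_null_voxel_t_within_three_se(self, training_design):
        rng = np.random.default_rng(4)
        dm = analysis.build_design(training_design)
        y = rng.normal(size=(training_design.n_trs, 200))
        out = analysis.voxelwise_glm(y, dm)
        t = out[out.regressor == "attend_face"].iloc[0]["t"]
        assert np.mean(np.abs(t) < 3) > 0.95

    def test_censored_rows_ignored(self, training_design):
        rng = np.random.default_rng(5)
        n = training_design.n_trs
        keep = np.ones(n, dtype=bool)
        keep[10:20] = False
        cm = preproc.CensorMask(
            keep=keep,
            reasons=np.where(keep, preproc.CensorReason.KEPT, preproc.CensorReason.FD_SPIKE),
        )
        dm = analysis.build_design(training_design, censor=cm)
        y = rng.normal(size=(n, 5))
        a = analysis.voxelwise_glm(y, dm)
        y2 = y.copy()
        y2[10:20] += 50.0
        b = analysis.voxelwise_glm(y2, dm)
        np.testing.assert_allclose(
            a[a.regressor == "attend_face"].iloc[0]["beta"],
            b[b.regressor == "attend_face"].iloc[0]["beta"],
            atol=1e-10,
        )


def _behavior_table(rng, group_effect=0.0, n_per_group=12):
    rows = []
    for g, code in (("p", 1), ("c", -1)):
        for i in range(n_per_group):
            subj = f"{g}{i}"
            intercept = rng.normal(0, 0.5)
            for attention in (1, -1):
                for valence in (1, -1):
                    y = (
                        intercept
                        + group_effect * code
                        + 0.2 * attention
                        + rng.normal(0, 0.3)
                    )
                    rows.append(
                        {
                            "subject": subj,
                            "group": code,
                            "attention": attention,
                            "valence": valence,
                            "age": rng.uniform(20, 50),
                            "education": rng.uniform(10, 20),
                            "sensitivity": y,
                        }
                    )
    return pd.DataFrame(rows)


class TestGroupLME:
    FORMULA = "sensitivity ~ attention * valence * group + age + education"

    def test_null_group_effect_type_i(self):
        """Under a zero group effect the group t stays within +-3 nearly always."""
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            tab = _behavior_table(rng, group_effect=0.0)
            res = analysis.fit_group_lme(tab, self.FORMULA, re_formula="~attention")
            t = res.fixed_effects.set_index("name").loc["group", "t"]
            hits += abs(t) < 3
        assert hits / n_rep >= 0.9

    def test_planted_group_effect_sign(self):
        rng = np.random.default_rng(7)
        signs = 0
        n_rep = 30
        for _ in range(n_rep):
            tab = _behavior_table(rng, group_effect=-0.4)
            res = analysis.fit_group_lme(tab, self.FORMULA, re_formula="~attention")
            est = res.fixed_effects.set_index("name").loc["group", "estimate"]
            signs += est < 0
        assert signs > n_rep / 2

    def test_constant_covariates_match_covariate_free_model(self):
        rng = np.random.default_rng(8)
        tab = _behavior_table(rng, group_effect=0.3)
        tab["age"] = 30.0
        tab["education"] = 12.0
        with_cov = analysis.fit_group_lme(tab, self.FORMULA, re_formula="~1")
        without = analysis.fit_group_lme(
            tab, "sensitivity ~ attention * valence * group", re_formula="~1"
        )
        a = with_cov.fixed_effects.set_index("name").loc["group", "estimate"]
        b = without.fixed_effects.set_index("name").loc["group", "estimate"]
        assert a == pytest.approx(b, abs=1e-6)


def flood_fill_clusters(binary, min_size):
    """Brute-force face-connectivity components by iterative flood fill."""
    visited = np.zeros_like(binary, dtype=bool)
    sizes = []
    dims = binary.shape
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        comp = 0
        while stack:
            x, y, z = stack.pop()
            comp += 1
            for dx, dy, dz in (
                (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
            ):
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < dims[i] for i in range(3)) and binary[p] and not visited[p]:
                    visited[p] = True
                    stack.append(p)
        sizes.append(comp)
    return sorted(s for s in sizes if s >= min_size)


def plant_blob(shape, start, n, value, out):
    """Grow a face-connected blob of exactly n voxels from start."""
    placed = [start]
    out[start] = value
    frontier = [start]
    while len(placed) < n:
        x, y, z = frontier.pop(0)
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1), (-1, 0, 0), (0, -1, 0), (0, 0, -1)):
            p = (x + d[0], y + d[1], z + d[2])
            if (
                all(0 <= p[i] < shape[i] for i in range(3))
                and out[p] == 0
                and len(placed) < n
            ):
                out[p] = value
                placed.append(p)
                frontier.append(p)
    return out


class TestClusterThreshold:
    DF = 17

    def tmap(self, shape=(12, 12, 12)):
        return np.zeros(shape)

    def test_extent_rule_keeps_only_large_blob(self):
        t = self.tmap()
        plant_blob(t.shape, (2, 2, 2), 14, 10.0, t)
        plant_blob(t.shape, (9, 9, 9), 5, 10.0, t)
        table = analysis.cluster_threshold(t, df=self.DF, extent=13)
        assert len(table) == 1
        assert table.clusters.iloc[0]["size"] == 14

    def test_thirteen_voxel_blob_survives(self):
        t = self.tmap()
        plant_blob(t.shape, (3, 3, 3), 13, 8.0, t)
        assert len(analysis.cluster_threshold(t, df=self.DF, extent=13)) == 1

    def test_twelve_voxel_blob_does_not_survive(self):
        t = self.tmap()
        plant_blob(t.shape, (3, 3, 3), 12, 8.0, t)
        assert len(analysis.cluster_threshold(t, df=self.DF, extent=13)) == 0

    def test_corner_touching_blobs_are_separate(self):
        t = self.tmap()
        t[2:4, 2:4, 2] = 9.0  # 4-voxel plate
        t[4, 4, 3] = 9.0  # touches (3,3,2) only diagonally
        plant_blob(t.shape, (4, 4, 3), 4, 9.0, t)
        table = analysis.cluster_threshold(t, df=self.DF, extent=2)
        assert len(table) == 2

    def test_signs_reported_separately(self):
        t = self.tmap()
        plant_blob(t.shape, (2, 2, 2), 15, 9.0, t)
        plant_blob(t.shape, (8, 8, 8), 15, -9.0, t)
        table = analysis.cluster_threshold(t, df=self.DF, extent=13)
        assert sorted(table.clusters["sign"]) == [-1, 1]

    def test_threshold_uses_two_sided_p(self):
        t_crit = stats.t.isf(0.0005, self.DF)
        t = self.tmap()
        plant_blob(t.shape, (2, 2, 2), 20, t_crit - 0.01, t)
        assert len(analysis.cluster_threshold(t, df=self.DF, extent=13)) == 0

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            t = (rng.random((10, 10, 10)) < 0.25) * 10.0
            table = analysis.cluster_threshold(t, df=self.DF, extent=3)
            got = sorted(table.clusters["size"])
            expected = flood_fill_clusters(t > 0, min_size=3)
            assert got == expected
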