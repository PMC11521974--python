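"""Cohort statistics: normality screen, two-way ANOVA, post-hoc, regression."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from otokit import group_stats as gs
from otokit import synthetic as syn
from otokit.types import DegenerateInputError, ParameterError


def balanced_table(cells, n, sd, seed, measurement="m"):
    """cells: {(age, sex): mean}."""
    rng = np.random.default_rng(seed)
    rows = []
    for (age, sex), mu in cells.items():
        for v in mu + rng.normal(0, sd, n):
            rows.append(
                {"mouse_id": "x", "ear": "left", "age_group": age, "sex": sex,
                 "measurement": measurement, "value": float(v)}
            )
    return pd.DataFrame(rows)


def anova_oracle(df):
    """Classical balanced two-way sums-of-squares decomposition."""
    grand = df["value"].mean()
    n = len(df)
    cell = df.groupby(["age_group", "sex"])["value"]
    a_means = df.groupby("age_group")["value"].mean()
    b_means = df.groupby("sex")["value"].mean()
    cell_means = cell.mean()
    n_cell = cell.size().iloc[0]
    n_a = df.groupby("age_group").size().iloc[0]
    n_b = df.groupby("sex").size().iloc[0]
    ss_a = (n_a * (a_means - grand) ** 2).sum()
    ss_b = (n_b * (b_means - grand) ** 2).sum()
    ss_cells = (n_cell * (cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = 0.0
    for _, g in df.groupby(["age_group", "sex"])["value"]:
        ss_e += ((g - g.mean()) ** 2).sum()
    df_e = n - 4
    out = {}
    for name, ss, d in (("age", ss_a, 1), ("sex", ss_b, 1), ("interaction", ss_ab, 1)):
        f = (ss / d) / (ss_e / df_e)
        out[name] = (f, float(stats.f.sf(f, d, df_e)))
    return out


class TestNormality:
    def test_normal_sample_usually_passes(self):
        passes = 0
        for seed in range(100):
            vals = np.random.default_rng(seed).normal(0, 1, 200)
            passes += gs.normality_screen(vals).passed
        assert passes >= 90

    def test_two_point_mass_fails(self):
        vals = np.r_[np.zeros(100), np.ones(100)]
        assert not gs.normality_screen(vals).passed

    def test_too_small_sample_rejected(self):
        with pytest.raises(ParameterError):
            gs.normality_screen(np.array([1.0, 2.0]))


class TestTwoWayAnova:
    def test_matches_brute_force_decomposition_on_balanced_design(self):
        cells = {("young", "female"): 10.0, ("young", "male"): 12.0,
                 ("old", "female"): 9.0, ("old", "male"): 14.0}
        df = balanced_table(cells, n=3, sd=2.0, seed=1)
        res = gs.two_way_anova(df, "m")
        oracle = anova_oracle(df)
        for effect in ("age", "sex", "interaction"):
            assert res.f[effect] == pytest.approx(oracle[effect][0], rel=1e-9)
            assert res.p[effect] == pytest.approx(oracle[effect][1], rel=1e-9)
        assert res.df_resid == len(df) - 4

    def test_unbalanced_design_supported(self):
        cells = {("young", "female"): 10.0, ("young", "male"): 10.0,
                 ("old", "female"): 10.0, ("old", "male"): 10.0}
        df = balanced_table(cells, n=5, sd=1.0, seed=2)
        df = df.iloc[:-1]  # one ear lost
        res = gs.two_way_anova(df, "m")
        assert res.n == 19
        assert all(0 <= p <= 1 for p in res.p.values())

    def test_null_design_with_tiny_jitter_gives_large_p(self):
        cells = {k: 5.0 for k in gs.CELLS}
        df = balanced_table(cells, n=5, sd=1e-9, seed=3)
        res = gs.two_way_anova(df, "m")
        assert all(p > 0.2 for p in res.p.values())

    def test_missing_factor_level_rejected(self):
        cells = {("young", "female"): 1.0, ("young", "male"): 2.0}
        df = balanced_table(cells, n=4, sd=1.0, seed=4)
        with pytest.raises(DegenerateInputError, match="old"):
            gs.two_way_anova(df, "m")

    def test_age_effect_power(self):
        hits = 0
        for seed in range(50):
            eff = syn.MeasurementEffects(baseline=10.0, age_effect=4.0, residual_sd=2.0)
            coh = syn.gen_cohort(syn.CohortEffects(10, {"m": eff}, seed=seed))
            hits += gs.two_way_anova(coh, "m").p["age"] < 0.05
        assert hits >= 45


class TestPosthoc:
    def test_identical_cells_cap_adjusted_p_at_one(self):
        cells = {k: 5.0 for k in gs.CELLS}
        df = balanced_table(cells, n=6, sd=1.0, seed=5)
        table = gs.bonferroni_posthoc(df, "m")
        assert len(table) == 6
        assert (table["p_adj"] <= 1.0).all()
        assert (table["p_adj"] >= table["p_raw"]).all()

    def test_adjustment_is_family_size_multiplication(self):
        assert min(1.0, 6 * 0.004) == pytest.approx(0.024)
        cells = {("young", "female"): 0.0, ("young", "male"): 0.5,
                 ("old", "female"): 1.0, ("old", "male"): 1.5}
        df = balanced_table(cells, n=8, sd=1.0, seed=6)
        table = gs.bonferroni_posthoc(df, "m")
        np.testing.assert_allclose(table["p_adj"], np.minimum(1.0, 6 * table["p_raw"]))

    def test_reported_contrast_family(self):
        cells = {k: 1.0 for k in gs.CELLS}
        df = balanced_table(cells, n=4, sd=1.0, seed=7)
        table = gs.bonferroni_posthoc(df, "m", family=4)
        assert len(table) == 4
        assert table["reported_contrast"].all()

    def test_shifted_cell_detected(self):
        hits, others = 0, 0
        for seed in range(20):
            cells = {("young", "female"): 0.0, ("young", "male"): 0.0,
                     ("old", "female"): 0.0, ("old", "male"): 5.0}
            df = balanced_table(cells, n=10, sd=1.0, seed=seed)
            t = gs.bonferroni_posthoc(df, "m")
            involves = t["cell_a"].eq("old male") | t["cell_b"].eq("old male")
            hits += (t.loc[involves, "p_adj"] < 0.05).all()
            others += (t.loc[~involves, "p_adj"] > 0.05).all()
        assert hits >= 18
        assert others >= 18


class TestAreaRegression:
    def test_exact_proportionality(self):
        x = np.linspace(10, 100, 10)
        res = gs.area_regression(pd.DataFrame({"tissue_area_um2": x, "ct_area_um2": 2 * x}))
        assert res["slope"] == pytest.approx(2.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_independent_response_rarely_significant(self):
        sig = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"tissue_area_um2": rng.normal(50, 10, 50), "ct_area_um2": rng.normal(50, 10, 50)}
            )
            sig += gs.area_regression(df)["p"] < 0.05
        assert sig <= 12  # ~5% type-I at alpha=0.05

    def test_phantom_slices_correlate_with_truth(self, default_phantom):
        from otokit import ct_morphometry as ct

        vol, rois, truth = default_phantom
        thr = ct.compute_threshold(vol, rois)
        seg = ct.segment_otolith(vol, rois.otolith_roi, thr.threshold)
        ct_areas = ct.slice_areas(seg, vol.meta, axis="z")["area_um2"]
        true_areas = ct.slice_areas(truth.otolith_mask, vol.meta, axis="z")["area_um2"]
        keep = true_areas > 0
        res = gs.area_regression(
            pd.DataFrame({"tissue_area_um2": true_areas[keep], "ct_area_um2": ct_areas[keep]})
        )
        assert res["slope"] > 0
        assert res["p"] < 1e-6

    def test_constant_explanatory_rejected(self):
        df = pd.DataFrame({"tissue_area_um2": [1.0] * 5, "ct_area_um2": range(5)})
        with pytest.raises(DegenerateInputError):
            gs.area_regression(df)


class TestAnalyzeMeasurement:
    def test_posthoc_triggered_by_interaction(self):
        eff = syn.MeasurementEffects(
            baseline=10.0, age_effect=0.0, sex_effect=0.0,
            interaction_effect=6.0, residual_sd=1.0,
        )
        coh = syn.gen_cohort(syn.CohortEffects(10, {"m": eff}, seed=0))
        res = gs.analyze_measurement(coh, "m", posthoc="auto")
        assert res["anova"].interaction_significant
        assert res["posthoc"] is not None

    def test_posthoc_skipped_without_interaction(self):
        eff = syn.MeasurementEffects(baseline=10.0, age_effect=5.0, residual_sd=1.0)
        coh = syn.gen_cohort(syn.CohortEffects(10, {"m": eff}, seed=1))
        res = gs.analyze_measurement(coh, "m", posthoc="auto")
        assert res["posthoc"] is None
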