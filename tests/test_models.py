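"""Screening, backward elimination, mixed models and Tukey contrasts."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from calftherm.models import (
    DlwgModel,
    ModelSpec,
    backward_select,
    fit_lmm,
    tukey_posthoc,
    univariable_screen,
)
from calftherm.simulate import CohortGenConfig, simulate_g2e_dataset


def _screen_p(rng, n, beta):
    x = rng.normal(0.0, 1.0, n)
    y = 0.1 + beta * x + rng.normal(0.0, 1.0, n)
    df = pd.DataFrame({"dlwg": y, "x": x})
    table = DlwgModel.from_dataframe(df, candidate_terms=["x"]).screen()
    return float(table["pvalue"].iloc[0])


class TestScreening:
    def test_type_one_rate_near_alpha_for_null_covariate(self):
        """A covariate independent of DLWG survives the 0.20 screen in
        about 20% of replicates (n = 271)."""
        rng = np.random.default_rng(20_24)
        hits = sum(_screen_p(rng, 271, 0.0) < 0.20 for _ in range(500))
        assert 0.17 <= hits / 500 <= 0.23

    def test_strong_effect_always_survives(self):
        rng = np.random.default_rng(7)
        hits = sum(_screen_p(rng, 271, 0.5) < 0.20 for _ in range(100))
        assert hits == 100

    def test_constant_column_skipped_with_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"dlwg": rng.normal(0, 1, 50),
                           "flat": np.ones(50),
                           "x": rng.normal(0, 1, 50)})
        spec = ModelSpec(candidate_terms=("flat", "x"))
        with pytest.warns(UserWarning, match="constant"):
            surviving, table = univariable_screen(df, spec)
        assert "flat" not in surviving
        assert table.set_index("term").loc["flat", "note"] == "constant; skipped"
        assert np.isfinite(table.set_index("term").loc["x", "pvalue"])


class TestBackwardSelection:
    def test_null_covariate_yields_intercept_only_most_of_the_time(self):
        rng = np.random.default_rng(555)
        kept = 0
        for _ in range(300):
            df = pd.DataFrame({"dlwg": rng.normal(0, 0.3, 100),
                               "x": rng.normal(0, 1, 100)})
            res = backward_select(df, ["x"], ModelSpec(candidate_terms=("x",)))
            kept += bool(res.retained)
        # retained only when p < 0.05 by chance: ~5% of replicates
        assert 0.02 <= kept / 300 <= 0.09

    def test_active_terms_recovered(self):
        from calftherm.simulate import simulate_b2g_dataset

        recovered = 0
        for seed in range(1, 11):
            df = simulate_b2g_dataset(seed)
            rng = np.random.default_rng(seed)
            df["noise"] = rng.normal(0, 1, len(df))
            res = DlwgModel.from_dataframe(
                df, candidate_terms=["prop_cat", "birth_weight", "exit_age",
                                     "noise"]).fit()
            if set(res.retained) >= {"prop_cat", "birth_weight", "exit_age"}:
                recovered += 1
        assert recovered >= 7  # majority of seeds

    def test_retained_terms_all_significant_and_trace_bounded(self):
        rng = np.random.default_rng(99)
        n = 200
        df = pd.DataFrame({
            "x1": rng.normal(0, 1, n), "x2": rng.normal(0, 1, n),
            "x3": rng.normal(0, 1, n)})
        df["dlwg"] = 0.4 * df["x1"] + rng.normal(0, 1, n)
        spec = ModelSpec(candidate_terms=("x1", "x2", "x3"))
        res = DlwgModel(df, spec).backward_select(["x1", "x2", "x3"])
        assert all(p < 0.05 for p in res.term_pvalues.values())
        assert len(res.trace) <= 3

    def test_collinear_duplicate_dropped_deterministically(self):
        rng = np.random.default_rng(17)
        n = 120
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "x_copy": 2.0 * x,
                           "dlwg": 0.5 * x + rng.normal(0, 0.5, n)})
        spec = ModelSpec(candidate_terms=("x", "x_copy"))
        with pytest.warns(UserWarning, match="collinear"):
            res = DlwgModel(df, spec).backward_select(["x", "x_copy"])
        assert res.retained == ["x"]  # the later duplicate loses
        assert any(s["step"] == "collinearity" and s["dropped"] == "x_copy"
                   for s in res.trace)

    def test_empty_surviving_set_gives_intercept_only_model(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"dlwg": rng.normal(0.2, 0.1, 60)})
        res = backward_select(df, [], ModelSpec(candidate_terms=()))
        assert res.retained == []
        assert res.params["Intercept"] == pytest.approx(df["dlwg"].mean())


def _mixed_null(rng, n=160, n_groups=16, group_sd=0.05, beta=0.0):
    g = np.repeat(np.arange(n_groups), n // n_groups)
    x = rng.normal(0.0, 1.0, n)
    y = 0.5 + beta * x + rng.normal(0, group_sd, n_groups)[g] \
        + rng.normal(0, 0.15, n)
    return pd.DataFrame({"dlwg": y, "x": x, "group_id": g})


class TestMixedModels:
    def test_zero_variance_limit_matches_ols(self):
        cfg = CohortGenConfig(n_calves=221, re_sd_group=0.0, re_sd_pen=0.0,
                              re_sd_feeder=0.0)
        df = simulate_g2e_dataset(5, config=cfg)
        terms = ["prop_cat", "entry_age", "avg_cmr"]
        lmm = fit_lmm(df, terms, ["group_id", "pen_id", "feeder_system"],
                      term_tests=False)
        ols = DlwgModel.from_dataframe(df, candidate_terms=terms).fit(
            screen=False, select=False)
        np.testing.assert_allclose(lmm.params.values, ols.params.values,
                                   atol=1e-6)

    def test_variance_components_recovered(self):
        truth = 0.15**2
        cfg = CohortGenConfig(n_calves=221, re_sd_group=0.15, re_sd_pen=0.15,
                              re_sd_feeder=0.0)
        estimates = []
        for seed in range(1, 16):
            df = simulate_g2e_dataset(seed, config=cfg)
            res = fit_lmm(df, ["prop_cat", "entry_age", "avg_cmr"],
                          ["group_id", "pen_id"], term_tests=False)
            estimates.append(res.vcomp["group_id"])
        mean_est = float(np.mean(estimates))
        assert truth * 0.5 <= mean_est <= truth * 1.8

    def test_lrt_type_one_rate_near_nominal(self):
        """LRT p-value of a null covariate is ~U(0,1): empirical rejection
        at 0.05 close to 5%."""
        rng = np.random.default_rng(31)
        hits = 0
        reps = 200
        for _ in range(reps):
            df = _mixed_null(rng)
            model = DlwgModel.from_dataframe(df, candidate_terms=["x"],
                                             random_terms=["group_id"])
            hits += model.term_pvalue(["x"], "x") < 0.05
        assert 0.015 <= hits / reps <= 0.095

    def test_single_level_random_term_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        df = _mixed_null(rng)
        df["solo"] = "only"
        with pytest.warns(UserWarning, match="solo"):
            model = DlwgModel.from_dataframe(df, candidate_terms=["x"],
                                             random_terms=["group_id", "solo"])
        assert model.spec.random_terms == ("group_id",)

    def test_estimates_stable_across_optimisers(self):
        df = simulate_g2e_dataset(11, config=CohortGenConfig(
            n_calves=221, re_sd_group=0.15, re_sd_pen=0.15,
            re_sd_feeder=0.15))
        model = DlwgModel.from_dataframe(
            df, candidate_terms=["prop_cat", "entry_age", "avg_cmr"],
            random_terms=["group_id", "pen_id", "feeder_system"])
        terms = ["prop_cat", "entry_age", "avg_cmr"]
        r1 = model._fit(terms, method="powell")
        r2 = model._fit(terms, method="nm")
        assert np.max(np.abs(r1.fe_params.values - r2.fe_params.values)) < 1e-4

    def test_agrees_with_lme4_reference(self, tmp_path):
        """Independent cross-check of the mixed-model fit against lme4."""
        df = simulate_g2e_dataset(3)
        csv = tmp_path / "g2e.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "fixef.csv"
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$prop_cat <- factor(d$prop_cat,
            levels=c("<=0.01","0.02-0.06","0.07-0.27",">=0.28"))
        m <- lmer(dlwg ~ prop_cat + entry_age + avg_cmr +
                  (1|group_id) + (1|pen_id) + (1|feeder_system),
                  data=d, REML=TRUE)
        write.csv(data.frame(coef=fixef(m)), "{out}")
        """
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out)["coef"].to_numpy()
        res = fit_lmm(df, ["prop_cat", "entry_age", "avg_cmr"],
                      ["group_id", "pen_id", "feeder_system"],
                      term_tests=False)
        np.testing.assert_allclose(res.params.values, ref, atol=2e-4,
                                   rtol=1e-2)


class TestTukey:
    def _oneway(self, means, n_per=40, seed=0, sd=0.5):
        rng = np.random.default_rng(seed)
        levels = [f"L{i}" for i in range(len(means))]
        rows = []
        for lv, mu in zip(levels, means):
            for _ in range(n_per):
                rows.append({"grp": lv, "dlwg": mu + rng.normal(0, sd)})
        df = pd.DataFrame(rows)
        df["grp"] = pd.Categorical(df["grp"], categories=levels)
        return df

    def test_null_contrasts_not_significant(self):
        df = self._oneway([0.3, 0.3, 0.3, 0.3], seed=12)
        res = DlwgModel.from_dataframe(df, candidate_terms=["grp"]).fit(
            screen=False, select=False)
        contrasts = tukey_posthoc(res, "grp")
        assert len(contrasts) == 6
        assert (contrasts["p_adjusted"] > 0.05).all()

    def test_matches_statsmodels_oneway_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = self._oneway([0.0, 0.25, 0.1], seed=4)
        res = DlwgModel.from_dataframe(df, candidate_terms=["grp"]).fit(
            screen=False, select=False)
        mine = res.tukey("grp")
        ref = pairwise_tukeyhsd(df["dlwg"].to_numpy(), df["grp"].to_numpy())
        np.testing.assert_allclose(mine["estimate"], ref.meandiffs, atol=1e-10)
        np.testing.assert_allclose(mine["p_adjusted"], ref.pvalues, atol=1e-3)

    def test_two_level_factor_adjusted_equals_unadjusted(self):
        df = self._oneway([0.0, 0.2], seed=9)
        res = DlwgModel.from_dataframe(df, candidate_terms=["grp"]).fit(
            screen=False, select=False)
        contrasts = res.tukey("grp")
        assert len(contrasts) == 1
        t_p = float(res.level_pvalues["C(grp)[T.L1]"])
        assert contrasts["p_adjusted"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_factor_not_in_model_is_an_error(self):
        df = self._oneway([0.0, 0.2])
        df["other"] = "x"
        res = DlwgModel.from_dataframe(df, candidate_terms=["grp"]).fit(
            screen=False, select=False)
        with pytest.raises(ValueError):
            res.tukey("other")

    def test_exposure_category_contrast_pattern(self):
        """Under the hutch-phase generating effects the extreme-exposure
        contrast (>=0.97 vs <=0.32) is the most significant pair on
        average."""
        from calftherm.simulate import simulate_b2g_dataset

        ps = {pair: [] for pair in [("<=0.32", ">=0.97"),
                                    ("<=0.32", "0.33-0.58")]}
        for seed in range(1, 9):
            df = simulate_b2g_dataset(seed)
            res = DlwgModel.from_dataframe(
                df, candidate_terms=["prop_cat", "birth_weight",
                                     "exit_age"]).fit(screen=False,
                                                      select=False)
            tk = res.tukey("prop_cat").set_index(["level_1", "level_2"])
            for pair in ps:
                ps[pair].append(float(tk.loc[pair, "p_adjusted"]))
        assert np.median(ps[("<=0.32", ">=0.97")]) < \
            np.median(ps[("<=0.32", "0.33-0.58")])
        assert np.median(ps[("<=0.32", ">=0.97")]) < 0.05


class TestSummary:
    def test_summary_table_shape_and_content(self):
        from calftherm.simulate import simulate_b2g_dataset

        df = simulate_b2g_dataset(1)
        res = DlwgModel.from_dataframe(
            df, candidate_terms=["prop_cat", "birth_weight", "exit_age"]).fit(
            screen=False, select=False)
        frame = res.to_frame()
        assert list(frame.columns) == ["variable", "level", "estimate", "se",
                                       "p_reference", "p_effect"]
        assert (frame["variable"] == "prop_cat").sum() == 4  # ref + 3 levels
        text = res.summary()
        assert "Intercept" in text and "prop_cat" in text
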