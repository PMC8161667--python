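"""Windowed mixed models, oblimin components, composites, correlations."""

import numpy as np
import pandas as pd
import pytest

from erptrains.features import factor_variable_names
from erptrains.simulate import generate_factor_structure_data
from erptrains.stats import (
    ModelSpec,
    bonferroni_alpha,
    correlate_outcomes,
    fit_window_lmm,
    pairwise_followup,
    partial_correlate,
    pca_oblimin,
    score_composites,
)

SITES = ("left", "central", "right")
WINDOWS = [f"{a}-{a+50}" for a in range(100, 500, 50)]


def build_window_table(cell_fn, n_per_cell=4, noise_sd=0.0, subject_sd=0.0, seed=0):
    """Long WindowTable for one contrast/region with planted cell means.

    ``cell_fn(age, group, site, window_index)`` gives the mean amplitude.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group in ("TD", "NF1"):
        for i in range(n_per_cell):
            subject = f"s{sid}"
            sid += 1
            b = rng.normal(0.0, subject_sd)
            for age in (5, 10):
                for site in SITES:
                    for wi, window in enumerate(WINDOWS):
                        rows.append(
                            (subject, group, age, "frontal", site, "S1-S2", window,
                             cell_fn(age, group, site, wi) + b
                             + rng.normal(0.0, noise_sd))
                        )
    return pd.DataFrame(
        rows, columns=["subject", "group", "age", "region", "site", "contrast",
                       "window", "amplitude"],
    )


class TestWindowLMM:
    def test_noiseless_marginal_means_recovered_exactly(self):
        cell = lambda age, group, site, wi: (
            (2.0 if group == "TD" else -1.0)
            + (0.5 if age == 10 else 0.0) * (1 if group == "TD" else 3)
            + 0.1 * wi + (0.2 if site == "left" else 0.0)
        )
        table = build_window_table(cell)
        fit = fit_window_lmm(table, ModelSpec(contrast="S1-S2", region="frontal"))
        assert fit.degenerate
        for age in (5, 10):
            for group in ("TD", "NF1"):
                expected = np.mean(
                    [cell(age, group, s, w) for s in SITES for w in range(8)]
                )
                assert fit.cell_mean(age, group) == pytest.approx(expected, abs=1e-8)

    def test_interaction_power_at_planted_effect(self):
        """TD changes 2 uV between ages, NF1 is flat; sigma=1, n=30/cell:
        the Age x Group interaction is detected in >= 90% of replicates."""
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            cell = lambda age, group, site, wi: (
                2.0 if (group == "TD" and age == 10) else 0.0
            )
            table = build_window_table(
                cell, n_per_cell=30, noise_sd=1.0, subject_sd=0.5, seed=rep
            )
            fit = fit_window_lmm(table, ModelSpec(contrast="S1-S2", region="frontal"))
            inter = fit.effects[fit.effects["term"] == "C(age):C(group)"]
            if float(inter["p"].iloc[0]) < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_single_group_errors(self):
        table = build_window_table(lambda *a: 0.0)
        table = table[table["group"] == "TD"]
        with pytest.raises(ValueError, match="group"):
            fit_window_lmm(table, ModelSpec(contrast="S1-S2", region="frontal"))

    def test_missing_contrast_errors(self):
        table = build_window_table(lambda *a: 0.0)
        with pytest.raises(ValueError, match="no rows"):
            fit_window_lmm(table, ModelSpec(contrast="S2-S3", region="frontal"))


class TestFollowups:
    def test_bonferroni_alpha_family_of_four_prints_013(self):
        assert bonferroni_alpha(0.05, 4) == 0.013

    def test_family_one_is_unadjusted(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)

    def test_adjusted_p_is_raw_times_family(self):
        table = build_window_table(
            lambda age, group, site, wi: (1.0 if group == "TD" else 0.0),
            n_per_cell=10, noise_sd=1.0, subject_sd=0.3, seed=3,
        )
        fit = fit_window_lmm(table, ModelSpec(contrast="S1-S2", region="frontal"))
        fu, adj_alpha = pairwise_followup(fit)
        assert adj_alpha == 0.013
        assert len(fu) == 4  # 2 within-group age + 2 within-age group contrasts
        np.testing.assert_allclose(
            fu["p_bonferroni"], np.minimum(1.0, fu["p"] * 4), atol=1e-12
        )


class TestPcaOblimin:
    def test_exactly_unit_eigenvalues_retain_nothing(self):
        # orthonormal centred columns -> sample correlation exactly identity
        rng = np.random.default_rng(0)
        M = rng.normal(size=(40, 8))
        M -= M.mean(axis=0)
        Q, _ = np.linalg.qr(M)
        df = pd.DataFrame(Q[:, :8], columns=factor_variable_names())
        df.insert(0, "subject", [f"s{i}" for i in range(40)])
        df.insert(1, "group", "TD")
        df.insert(2, "age", 5)
        sol = pca_oblimin(df, factor_variable_names())
        np.testing.assert_allclose(sol.eigenvalues, 1.0, atol=1e-8)
        assert sol.component_names == []
        assert sol.loadings.shape[1] == 0

    def test_planted_structure_recovered(self):
        from erptrains.simulate import DEFAULT_LOADING_PATTERN
        df = generate_factor_structure_data(300, seed=5)
        sol = pca_oblimin(df, factor_variable_names())
        assert len(sol.component_names) == 2
        assert sol.component_names[0] == "deviant_response"
        planted = np.array([DEFAULT_LOADING_PATTERN[v] for v in factor_variable_names()])
        rec = sol.loadings.to_numpy()
        for j in range(2):
            congruence = np.abs(planted[:, j] @ rec[:, j]) / (
                np.linalg.norm(planted[:, j]) * np.linalg.norm(rec[:, j])
            )
            assert congruence > 0.9
        # deviant variables load positively on their component
        assert sol.loadings.loc["S2-DevPitch_frontal", "deviant_response"] != 0
        dev_rows = [v for v in factor_variable_names() if "Dev" in v]
        assert sol.loadings.loc[dev_rows, "deviant_response"].sum() > 0

    def test_rotation_preserves_communalities(self):
        df = generate_factor_structure_data(120, seed=6)
        vars_ = factor_variable_names()
        sol = pca_oblimin(df, vars_)
        X = df[vars_].to_numpy(dtype=float)
        eigvals, eigvecs = np.linalg.eigh(np.corrcoef(X, rowvar=False))
        order = np.argsort(eigvals)[::-1]
        k = len(sol.component_names)
        A = eigvecs[:, order[:k]] * np.sqrt(eigvals[order[:k]])
        np.testing.assert_allclose(
            sol.communalities.to_numpy(), (A**2).sum(axis=1), atol=1e-8
        )

    def test_same_component_count_per_age_as_pooled(self):
        # age-invariant structure: pooled and per-age analyses agree
        df5 = generate_factor_structure_data(80, seed=7)
        df10 = generate_factor_structure_data(80, seed=8)
        df5["age"], df10["age"] = 5, 10
        pooled = pca_oblimin(pd.concat([df5, df10]), factor_variable_names())
        k5 = len(pca_oblimin(df5, factor_variable_names()).component_names)
        k10 = len(pca_oblimin(df10, factor_variable_names()).component_names)
        assert k5 == k10 == len(pooled.component_names)

    def test_rank_deficient_matrix_errors(self):
        df = generate_factor_structure_data(60, seed=9)
        df["S1_posterior"] = -df["S1_frontal"]
        with pytest.raises(ValueError, match="rank"):
            pca_oblimin(df, factor_variable_names())


def outcome_frame(**overrides):
    base = pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(6)],
            "group": ["TD", "TD", "TD", "TD", "NF1", "NF1"],
            "msel_receptive_raw": [28.0, 30.0, 32.0, 30.0, 26.0, 24.0],
            "msel_expressive_raw": [25.0, 26.0, 27.0, 26.0, 22.0, 23.0],
            "cdi_words_understood": [100.0, 120.0, 140.0, 120.0, 90.0, 80.0],
            "cdi_words_understands_says": [30.0, 40.0, 50.0, 40.0, 25.0, 20.0],
            "ibqr_activity": [3.5, 4.0, 4.5, 4.0, 4.2, 4.8],
            "ibqr_missing_frac": [0.0, 0.0, 0.0, 0.0, 0.0, 0.3],
        }
    )
    for k, v in overrides.items():
        base[k] = v
    return base


class TestComposites:
    def test_td_mean_subject_scores_zero(self):
        out = score_composites(outcome_frame())
        td = out[out["group"] == "TD"]
        assert td["language_comprehension"].mean() == pytest.approx(0.0, abs=1e-9)
        # subject exactly at the TD mean on both scores
        at_mean = out.iloc[1]
        assert at_mean["language_comprehension"] == pytest.approx(0.0, abs=1e-9)

    def test_one_sd_above_both_gives_one(self):
        df = outcome_frame()
        mu_r, sd_r = df.loc[:3, "msel_receptive_raw"].agg(["mean", "std"])
        mu_c, sd_c = df.loc[:3, "cdi_words_understood"].agg(["mean", "std"])
        df.loc[5, "msel_receptive_raw"] = mu_r + sd_r
        df.loc[5, "cdi_words_understood"] = mu_c + sd_c
        out = score_composites(df)
        assert out.loc[5, "language_comprehension"] == pytest.approx(1.0)

    def test_missing_constituent_blanks_composite(self):
        df = outcome_frame()
        df.loc[0, "cdi_words_understood"] = np.nan
        out = score_composites(df)
        assert np.isnan(out.loc[0, "language_comprehension"])
        assert np.isfinite(out.loc[0, "language_production"])

    def test_ibqr_blanked_over_20pct_missing(self):
        out = score_composites(outcome_frame())
        assert np.isnan(out.loc[5, "ibqr_activity"])
        assert np.isfinite(out.loc[0, "ibqr_activity"])

    def test_zero_td_sd_errors(self):
        df = outcome_frame(msel_receptive_raw=[30.0] * 6)
        with pytest.raises(ValueError, match="SD"):
            score_composites(df)

    def test_affine_equivariance(self):
        df = outcome_frame()
        out1 = score_composites(df)
        df2 = df.copy()
        df2["msel_receptive_raw"] = df2["msel_receptive_raw"] * 3.0 + 11.0
        df2["cdi_words_understood"] = df2["cdi_words_understood"] * 0.5 - 2.0
        out2 = score_composites(df2)
        np.testing.assert_allclose(
            out1["language_comprehension"], out2["language_comprehension"], atol=1e-12
        )


class TestCorrelations:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["y"] = 2 * df["x"] + 1
        res = correlate_outcomes(df, [("x", "y")])
        assert res["r"].iloc[0] == pytest.approx(1.0)
        assert res["df"].iloc[0] == 2

    def test_textbook_pairs(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 5.0]})
        res = correlate_outcomes(df, [("x", "y")])
        assert res["r"].iloc[0] == pytest.approx(0.9819805, abs=1e-6)

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        r1 = correlate_outcomes(df, [("x", "y")])["r"].iloc[0]
        df["x"] = df["x"] * 7.0 - 3.0
        r2 = correlate_outcomes(df, [("x", "y")])["r"].iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_insufficient_pairs_unavailable(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan], "y": [1.0, np.nan, 3.0]})
        res = correlate_outcomes(df, [("x", "y")])
        assert not res["available"].iloc[0]
        assert np.isnan(res["r"].iloc[0])


class TestPartialCorrelation:
    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=50)
        x = 0.5 * z + rng.normal(size=50)
        y = -0.3 * z + 0.4 * x + rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        r, ddf, p = partial_correlate(df, "x", "y", "z")
        # independent oracle: correlation of the OLS residuals of x~z and y~z
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)
        assert ddf == 47

    def test_independent_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({
            "x": rng.normal(size=2000), "z": rng.normal(size=2000)
        })
        df["y"] = 0.5 * df["x"] + rng.normal(size=2000)
        plain = correlate_outcomes(df, [("x", "y")])["r"].iloc[0]
        r, _, _ = partial_correlate(df, "x", "y", "z")
        assert r == pytest.approx(plain, abs=0.05)

    def test_degenerate_control_errors(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "y": [2.0, 1.0, 4.0, 3.0, 5.0]})
        df["z"] = df["y"]
        with pytest.raises(ValueError, match="collinear"):
            partial_correlate(df, "x", "y", "z")

    def test_too_few_triples_errors(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0], "z": [0.0, 1.0]})
        with pytest.raises(ValueError, match="at least 5"):
            partial_correlate(df, "x", "y", "z")
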