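"""Temperature split, allometry, ordinal stage model, AICc, variation
partitioning, and ML GLS with AR(1) residuals."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import rostrumorph as rm
from rostrumorph.envmodels import (
    CollinearityError,
    aicc,
    allometry_confint,
    compare_slopes,
    fit_allometry,
    gls_ar1_fit,
    gls_select,
    lithology_dummies,
    ordinal_stage_model,
    predictor_collinearity_check,
    split_by_temperature,
    variation_partitioning,
)
from rostrumorph.io import Lithology, Stage


def _records_with_d18o(values):
    from dataclasses import replace

    base = rm.SpecimenRecord(
        specimen_id="s", taxon="t", stage=Stage.ADULT, bed="b01",
        subzone="Solare", lithology=Lithology.MARL,
    )
    return [
        replace(base, specimen_id=f"s{i}", proxies={"d18O": v, "d13C": 0.0, "d11B": 38.0})
        for i, v in enumerate(values)
    ]


class TestTemperatureSplit:
    def test_all_warm(self):
        warm, cold = split_by_temperature(_records_with_d18o([-2.0, -1.5, -3.0]))
        assert len(warm) == 3 and len(cold) == 0

    def test_boundary_value_is_cold(self):
        warm, cold = split_by_temperature(_records_with_d18o([-0.9]))
        assert len(cold) == 1 and len(warm) == 0

    def test_conservation(self, rng):
        vals = rng.uniform(-2, 0, 50)
        warm, cold = split_by_temperature(_records_with_d18o(vals))
        assert len(warm) + len(cold) == 50

    def test_missing_proxy_lists_specimens(self):
        recs = _records_with_d18o([-1.0])
        recs[0].proxies = None
        with pytest.raises(ValueError, match="s0"):
            split_by_temperature(recs)


class TestAllometry:
    def test_noiseless_slope_recovery(self):
        x = np.linspace(20, 60, 30)
        fit = fit_allometry(x, 0.5 - 0.003 * x)
        assert fit.slope == pytest.approx(-0.003, abs=1e-12)
        assert fit.adj_r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        fit = fit_allometry([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert fit.adj_r_squared <= 0.0

    def test_degenerate_predictor(self):
        with pytest.raises(ValueError):
            fit_allometry([2, 2, 2], [1, 2, 3])


class TestCompareSlopes:
    def test_duplicated_regime_f_near_zero(self, rng):
        x = rng.uniform(20, 60, 40)
        y = 1 - 0.003 * x + rng.normal(0, 0.02, 40)
        f, p = compare_slopes(x, y, x, y)
        assert f < 1e-12
        assert p > 0.99

    def test_planted_slope_difference_detected(self, rng):
        x1 = rng.uniform(20, 60, 200)
        x2 = rng.uniform(20, 60, 200)
        y1 = 1 - 0.004 * x1 + rng.normal(0, 0.005, 200)
        y2 = 1 - 0.002 * x2 + rng.normal(0, 0.005, 200)
        _, p = compare_slopes(x1, y1, x2, y2)
        assert p < 0.001

    def test_small_regime_errors(self):
        with pytest.raises(ValueError):
            compare_slopes([1, 2], [1, 2], [1, 2, 3], [1, 2, 3])


class TestAICc:
    def test_formula_oracle(self):
        assert aicc(-3.0, 2, 10) == pytest.approx(10 + 12 / 7)

    def test_large_n_limit(self):
        aic = -2 * (-3.0) + 2 * 2
        assert aicc(-3.0, 2, 10_000) == pytest.approx(aic, abs=0.01)

    def test_undefined_at_small_n(self):
        with pytest.raises(ValueError):
            aicc(-3.0, 2, 3)


class TestOrdinalStageModel:
    def test_planted_monotone_effect_selects_stage_model(self, rng):
        stages = [Stage.JUVENILE, Stage.NEANIC, Stage.ADULT] * 20
        codes = np.array([0, 1, 2] * 20)
        y = 0.5 * codes + rng.normal(0, 0.3, 60)
        sel = ordinal_stage_model(y, stages)
        assert sel.best_model == "stage"
        assert sel.metadata["stage_p"] < 0.001
        # linear contrast dominates the quadratic one
        est = sel.coefficients.set_index("term")["estimate"]
        assert abs(est["stage^1"]) > abs(est["stage^2"])

    def test_stage_independent_prefers_null(self, rng):
        stages = [Stage.JUVENILE, Stage.NEANIC, Stage.ADULT] * 20
        y = rng.normal(0, 1, 60)
        sel = ordinal_stage_model(y, stages)
        assert sel.best_model == "null"

    def test_aicc_bookkeeping(self, rng):
        stages = [Stage.JUVENILE, Stage.NEANIC] * 10
        y = rng.normal(0, 1, 20)
        sel = ordinal_stage_model(y, stages)
        assert np.isfinite(sel.table["AICc"]).all()
        assert sel.table["delta_AICc"].iloc[0] == 0.0
        # two-level stage model: intercept + linear contrast + variance = 3
        assert set(sel.table["k"]) == {3, 2}

    def test_single_stage_errors(self):
        with pytest.raises(ValueError):
            ordinal_stage_model([1, 2, 3, 4, 5], [Stage.ADULT] * 5)


class TestVariationPartitioning:
    def test_orthogonal_predictors_unique_fractions(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x1 -= x1.mean()
        x2 -= x2.mean()
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # exactly orthogonal
        y = 2 * x1 + 1 * x2 + rng.normal(0, 1, n)
        part = variation_partitioning(y, {"a": x1, "b": x2})
        from rostrumorph.envmodels import _adjust_r2, _rda_r2

        solo_a = _adjust_r2(_rda_r2(y[:, None], x1[:, None]), n, 1)
        solo_b = _adjust_r2(_rda_r2(y[:, None], x2[:, None]), n, 1)
        assert part.fractions["unique_a"] == pytest.approx(solo_a, abs=0.02)
        assert part.fractions["unique_b"] == pytest.approx(solo_b, abs=0.02)
        assert abs(part.fractions["shared"]) < 0.02

    def test_null_response(self, rng):
        y = rng.normal(size=(100, 3))
        part = variation_partitioning(
            y, {"a": rng.normal(size=100), "b": rng.normal(size=100)}
        )
        assert abs(part.fractions["unique_a"]) < 0.05
        assert part.fractions["residual"] > 0.9

    def test_fractions_sum_to_one(self, rng):
        y = rng.normal(size=(60, 4))
        part = variation_partitioning(
            y,
            {
                "a": rng.normal(size=60),
                "b": rng.normal(size=60),
                "lith": lithology_dummies(
                    [Lithology.MARL, Lithology.LIMESTONE, Lithology.MARLY_LIMESTONE] * 20
                ),
            },
        )
        assert part.total() == pytest.approx(1.0, abs=1e-9)

    def test_constant_predictor_dropped(self, rng):
        y = rng.normal(size=50)
        with pytest.warns(UserWarning, match="constant"):
            part = variation_partitioning(
                y, {"a": np.ones(50), "b": rng.normal(size=50)}
            )
        assert part.dropped == ["a"]


class TestCollinearityCheck:
    def test_identical_columns_fail(self, rng):
        x = rng.normal(size=30)
        frame = predictor_collinearity_check(pd.DataFrame({"a": x, "b": x}))
        assert frame["fail"].all()
        assert frame["r"].iloc[0] == pytest.approx(1.0)

    def test_negation_fails(self, rng):
        x = rng.normal(size=30)
        frame = predictor_collinearity_check(pd.DataFrame({"a": x, "b": -x}))
        assert frame["fail"].all()
        assert frame["r"].iloc[0] == pytest.approx(-1.0)

    def test_independent_columns_pass(self, rng):
        frame = predictor_collinearity_check(
            pd.DataFrame({"a": rng.normal(size=500), "b": rng.normal(size=500)})
        )
        assert not frame["fail"].any()

    def test_constant_column_errors(self, rng):
        with pytest.raises(ValueError):
            predictor_collinearity_check(
                pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10)})
            )


def _ar1_noise(rng, n, phi, sd=1.0):
    e = np.empty(n)
    e[0] = rng.normal(0, sd)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + rng.normal(0, sd * np.sqrt(1 - phi**2))
    return e


class TestGLS:
    def test_phi_zero_reproduces_ols(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [2.0, -1.0] + rng.normal(0, 1, n)
        fit = gls_ar1_fit(y, X, ["i", "x"], phi=0.0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.coefficients["estimate"], ols, atol=1e-8)

    def test_phi_recovery(self, rng):
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 0.5] + _ar1_noise(rng, n, 0.5)
        fit = gls_ar1_fit(y, X, ["i", "x"])
        assert fit.phi == pytest.approx(0.5, abs=0.15)

    def test_selects_true_predictor(self, rng):
        n = 120
        env = pd.DataFrame(
            {
                "d18O": rng.normal(size=n),
                "d13C": rng.normal(size=n),
                "d11B": rng.normal(size=n),
            }
        )
        liths = [Lithology.MARL, Lithology.LIMESTONE] * (n // 2)
        y = 1.5 * env["d18O"].to_numpy() + rng.normal(0, 1, n)
        sel = gls_select(y, env, liths, np.arange(n))
        assert sel.best_model == "d18O"
        coef = sel.coefficients.set_index("term")
        assert coef.at["d18O", "p"] < 0.001

    def test_pure_noise_prefers_null(self, rng):
        n = 150
        env = pd.DataFrame(
            {
                "d18O": rng.normal(size=n),
                "d13C": rng.normal(size=n),
                "d11B": rng.normal(size=n),
            }
        )
        liths = [Lithology.MARL, Lithology.LIMESTONE, Lithology.MARLY_LIMESTONE] * (n // 3)
        sel = gls_select(rng.normal(size=n), env, liths, np.arange(n))
        assert sel.table["predictor_subset"].iloc[0] in {"null", "d18O", "d13C", "d11B"}

    def test_collinear_predictors_rejected(self, rng):
        n = 60
        x = rng.normal(size=n)
        env = pd.DataFrame({"d18O": x, "d13C": x + 1e-9 * rng.normal(size=n), "d11B": rng.normal(size=n)})
        with pytest.raises(CollinearityError, match="d18O"):
            gls_select(rng.normal(size=n), env, [Lithology.MARL] * n, np.arange(n))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_nlme_gls_oracle(self, rng, tmp_path):
        """Independent oracle: nlme::gls(method='ML', corAR1) on a small
        fixture agrees on coefficients and the AR(1) estimate."""
        n = 80
        x = rng.normal(size=n)
        y = 1.0 + 0.8 * x + _ar1_noise(rng, n, 0.4)
        data = pd.DataFrame({"y": y, "x": x})
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            """
            suppressMessages(library(nlme))
            d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
            m <- gls(y ~ x, data=d, correlation=corAR1(form=~1), method="ML")
            phi <- coef(m$modelStruct$corStruct, unconstrained=FALSE)
            cat(jsonlite::toJSON(list(beta=as.numeric(coef(m)), phi=as.numeric(phi),
                logLik=as.numeric(logLik(m))), digits=12))
            """
        )
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        X = np.column_stack([np.ones(n), x])
        fit = gls_ar1_fit(y, X, ["intercept", "x"])
        assert np.allclose(fit.coefficients["estimate"], ref["beta"], atol=2e-3)
        assert fit.phi == pytest.approx(ref["phi"][0], abs=0.02)
        assert fit.log_likelihood == pytest.approx(ref["logLik"][0], abs=0.02)


def test_allometry_confint_covers_noiseless_truth():
    x = np.linspace(10, 50, 25)
    y = 0.3 - 0.003 * x
    lo, hi = allometry_confint(x, y + np.random.default_rng(0).normal(0, 1e-4, 25))
    assert lo <= -0.003 <= hi
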