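import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ipre import risk_model
from ipre.datasets import ExpressionMatrix
from ipre.risk_model import (
    PRESET_IPRE_2014,
    RiskModel,
    choose_cutoff,
    classify,
    encode_clinical,
    fit_logistic_backward,
    impute_receptor,
    load_preset,
    risk_score,
)


def clinical_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["grade", "size_cm", "er", "pr", "her2"],
        index=[f"s{i}" for i in range(len(rows))],
    )


class TestEncodeClinical:
    def test_reference_coding(self):
        clin = clinical_frame([("III", 2.5, "positive", "positive", "negative")])
        enc = encode_clinical(clin, pd.Series({"s0": 0.6}))
        assert enc.loc["s0"].tolist() == [1.0, 0.55, 1.0, 1.0, -1.0, 0.6]

    @pytest.mark.parametrize(
        "size,code",
        [(1.9, 0.0), (2.0, 0.55), (3.5, 0.55), (3.99, 0.55), (4.0, 1.0), (5.5, 1.0)],
    )
    def test_size_bins_are_contiguous(self, size, code):
        clin = clinical_frame([("I", size, "negative", "negative", "negative")])
        assert encode_clinical(clin, pd.Series({"s0": 0.0})).loc["s0", "x2_size"] == code

    def test_grade_one_and_two_collapse_to_zero(self):
        clin = clinical_frame([
            ("I", 1.0, "negative", "negative", "negative"),
            ("II", 1.0, "negative", "negative", "negative"),
        ])
        enc = encode_clinical(clin, pd.Series(0.0, index=clin.index))
        assert (enc["x1_grade"] == 0.0).all()

    def test_missing_grade_encodes_nan(self):
        clin = clinical_frame([(np.nan, 1.0, "negative", "negative", "negative")])
        enc = encode_clinical(clin, pd.Series({"s0": 0.2}))
        assert np.isnan(enc.loc["s0", "x1_grade"])

    def test_mscore_outside_unit_interval_rejected(self):
        clin = clinical_frame([("I", 1.0, "negative", "negative", "negative")])
        with pytest.raises(ValueError, match="mScore"):
            encode_clinical(clin, pd.Series({"s0": 1.2}))


class TestImputeReceptor:
    def _expr(self, esr1, pgr):
        return ExpressionMatrix(
            pd.DataFrame({"s0": [esr1, pgr]}, index=["ESR1", "PGR"]),
            normalized=True,
        )

    def _clin(self, er, pr):
        df = clinical_frame([("I", 1.0, er, pr, "negative")])
        return df

    def test_missing_er_imputed_from_esr1(self):
        out = impute_receptor(self._expr(0.8, 0.1), self._clin(np.nan, np.nan))
        assert out.loc["s0", "er"] == "positive"
        assert out.loc["s0", "pr"] == "negative"

    def test_recorded_status_never_overridden(self):
        out = impute_receptor(self._expr(0.9, 0.9), self._clin("negative", "positive"))
        assert out.loc["s0", "er"] == "negative"

    def test_boundary_half_is_positive(self):
        out = impute_receptor(self._expr(0.5, 0.5), self._clin(np.nan, np.nan))
        assert out.loc["s0", "er"] == "positive"

    def test_gene_absent_leaves_status_missing(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s0": [0.5]}, index=["OTHER"]), normalized=True
        )
        out = impute_receptor(expr, self._clin(np.nan, "positive"))
        assert pd.isna(out.loc["s0", "er"])


def simulate_covariates(rng, n):
    return pd.DataFrame(
        {
            "x1_grade": rng.integers(0, 2, n).astype(float),
            "x2_size": rng.choice([0.0, 0.55, 1.0], n),
            "x3_er": rng.choice([-1.0, 1.0], n),
            "x4_pr": rng.choice([-1.0, 1.0], n),
            "x5_her2": rng.choice([-1.0, 1.0], n),
            "x6_mscore": rng.random(n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestFitLogisticBackward:
    def test_pure_noise_covariate_eliminated(self):
        rng = np.random.default_rng(101)
        X = simulate_covariates(rng, 2000)
        lin = -0.2 + 0.9 * X["x2_size"] - 0.7 * X["x3_er"] - 0.6 * X["x4_pr"] \
            + 0.5 * X["x5_her2"] - 1.5 * X["x6_mscore"]  # x1 carries no signal
        y = np.where(rng.random(2000) < expit(lin), "poor", "good")
        model = fit_logistic_backward(X, y)
        assert "x1_grade" not in model.retained
        assert any(v == "x1_grade" for v, _ in model.trace)
        assert all(p <= 0.05 for p in model.p_values.values())

    def test_known_model_recovered_within_three_se(self):
        rng = np.random.default_rng(202)
        n = 5000
        X = simulate_covariates(rng, n)
        truth = {"x1_grade": 0.6, "x2_size": 0.9, "x3_er": -0.7,
                 "x4_pr": -0.5, "x5_her2": 0.4, "x6_mscore": -1.2}
        lin = -0.3 + sum(b * X[k] for k, b in truth.items())
        y = np.where(rng.random(n) < expit(lin), "poor", "good")
        model = fit_logistic_backward(X, y)
        for name, beta in truth.items():
            assert name in model.retained
            assert abs(model.coefficients[name] - beta) < 3 * model.std_errors[name]

    def test_independent_labels_yield_intercept_only_model(self):
        rng = np.random.default_rng(302)
        X = simulate_covariates(rng, 400)
        y = rng.choice(["poor", "good"], 400)
        model = fit_logistic_backward(X, y)
        assert model.retained == ()
        assert len(model.trace) == 6

    def test_elimination_terminates_within_candidate_count(self):
        rng = np.random.default_rng(404)
        X = simulate_covariates(rng, 300)
        y = rng.choice(["poor", "good"], 300)
        model = fit_logistic_backward(X, y)
        assert len(model.trace) <= X.shape[1]

    def test_perfect_separation_raises_with_guidance(self):
        x = pd.DataFrame({"x6_mscore": np.linspace(0, 1, 40)})
        y = np.where(x["x6_mscore"] >= 0.5, "poor", "good")
        with pytest.raises(PerfectSeparationError):
            fit_logistic_backward(x, y)

    def test_collinear_pair_named(self):
        rng = np.random.default_rng(505)
        x6 = rng.random(100)
        X = pd.DataFrame({"x6_mscore": x6, "x2_size": 2 * x6 - 1})
        y = rng.choice(["poor", "good"], 100)
        with pytest.raises(ValueError, match="x6_mscore.*x2_size|x2_size.*x6_mscore"):
            fit_logistic_backward(X, y)

    def test_missing_covariate_values_rejected(self):
        rng = np.random.default_rng(606)
        X = simulate_covariates(rng, 50)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_logistic_backward(X, rng.choice(["poor", "good"], 50))


class TestRiskScorePreset:
    def test_direct_substitution_examples(self):
        rs1 = risk_score(PRESET_IPRE_2014,
                         {"x2_size": 0, "x3_er": 1, "x4_pr": 1, "x6_mscore": 1})
        assert rs1 == pytest.approx(-2.53567, abs=1e-12)
        rs2 = risk_score(PRESET_IPRE_2014,
                         {"x2_size": 1, "x3_er": -1, "x4_pr": -1, "x6_mscore": 0})
        assert rs2 == pytest.approx(-0.93032, abs=1e-12)

    def test_all_zero_covariates_give_intercept(self):
        rs = risk_score(PRESET_IPRE_2014,
                        {"x2_size": 0, "x3_er": 0, "x4_pr": 0, "x6_mscore": 0})
        assert rs == PRESET_IPRE_2014.intercept

    def test_missing_retained_covariate_rejected(self):
        with pytest.raises(ValueError, match="x6_mscore"):
            risk_score(PRESET_IPRE_2014, {"x2_size": 0, "x3_er": 1, "x4_pr": 1})

    def test_lower_mscore_strictly_increases_risk(self):
        base = {"x2_size": 0.55, "x3_er": 1, "x4_pr": -1}
        scores = [risk_score(PRESET_IPRE_2014, {**base, "x6_mscore": m})
                  for m in np.linspace(1, 0, 7)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_dataframe_input_returns_series(self):
        cov = pd.DataFrame(
            {"x2_size": [0.0, 1.0], "x3_er": [1.0, -1.0],
             "x4_pr": [1.0, -1.0], "x6_mscore": [1.0, 0.0]},
            index=["a", "b"],
        )
        rs = risk_score(PRESET_IPRE_2014, cov)
        assert rs["a"] == pytest.approx(-2.53567)
        assert rs["b"] == pytest.approx(-0.93032)


class TestClassify:
    @pytest.mark.parametrize(
        "rs,expected",
        [(-2.53567, "good"), (-1.480, "poor"), (-0.93032, "poor"),
         (-1.4801, "good")],
    )
    def test_cutoff_rule(self, rs, expected):
        assert classify(rs) == expected

    def test_vectorized(self):
        out = classify(pd.Series([-2.0, -1.0], index=["a", "b"]))
        assert list(out) == ["good", "poor"]


class TestChooseCutoff:
    @staticmethod
    def exhaustive_best_f(scores, labels):
        """Oracle: best F over every midpoint and beyond-extremes threshold."""
        scores = np.asarray(scores, dtype=float)
        uniq = np.unique(scores)
        candidates = np.concatenate(
            [[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, uniq, [uniq[-1] + 1]]
        )
        best = 0.0
        for eps in candidates:
            pred = np.where(scores >= eps, "poor", "good")
            tp = int(((pred == "poor") & (labels == "poor")).sum())
            fp = int(((pred == "poor") & (labels == "good")).sum())
            fn = int(((pred == "good") & (labels == "poor")).sum())
            denom = 2 * tp + fp + fn
            best = max(best, 2 * tp / denom if denom else 0.0)
        return best

    def test_perfectly_separable_scores(self):
        scores = [-0.5, -0.2, 0.1, 0.4]
        labels = np.array(["good", "good", "poor", "poor"])
        eps = choose_cutoff(scores, labels)
        pred = np.where(np.asarray(scores) >= eps, "poor", "good")
        assert (pred == labels).all()

    def test_identical_scores_fall_back_to_all_poor(self):
        labels = np.array(["poor", "good", "good"])
        eps = choose_cutoff([0.2, 0.2, 0.2], labels)
        assert eps == 0.2  # everything predicted poor: F = 2/(2+2) = 0.5

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(4, 51))
            scores = rng.normal(size=n)
            labels = rng.choice(["poor", "good"], n)
            if len(set(labels)) < 2:
                labels[0], labels[1] = "poor", "good"
            eps = choose_cutoff(scores, labels)
            pred = np.where(scores >= eps, "poor", "good")
            tp = int(((pred == "poor") & (labels == "poor")).sum())
            fp = int(((pred == "poor") & (labels == "good")).sum())
            fn = int(((pred == "good") & (labels == "poor")).sum())
            achieved = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
            assert achieved == pytest.approx(
                self.exhaustive_best_f(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            choose_cutoff([0.1, 0.2], np.array(["poor", "poor"]))


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        X = simulate_covariates(rng, 800)
        lin = 0.5 - 2.0 * X["x6_mscore"]
        y = np.where(rng.random(800) < expit(lin), "poor", "good")
        model = fit_logistic_backward(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = RiskModel.from_json(path)
        assert back.coefficients == model.coefficients
        assert back.cutoff == model.cutoff
        assert back.trace == model.trace

    def test_preset_lookup(self):
        preset = load_preset("ipre-2014")
        assert preset.cutoff == -1.480
        assert set(preset.coefficients) == {"x2_size", "x3_er", "x4_pr", "x6_mscore"}
        with pytest.raises(KeyError):
            load_preset("nope")

    def test_preset_json_is_valid(self):
        payload = json.loads(PRESET_IPRE_2014.to_json())
        assert payload["intercept"] == pytest.approx(-0.99475)
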