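"""QSRR regression layer: OLS fits, subset selection and reporting."""

import re
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromlogd import (
    CollinearityError,
    InsufficientDataError,
    fit_mlr,
    model_report,
    select_model,
)
from conftest import UNIVARIATE_PUBLISHED


def random_design(rng, n=20, terms=("n_e", "A", "B")):
    data = {"logkw": rng.uniform(-0.5, 4.0, n)}
    data.update({t: rng.uniform(0, 1, n) for t in terms})
    return pd.DataFrame(data)


class TestFitMlr:
    def test_two_points_exact_interpolation(self):
        X = pd.DataFrame({"logkw": [1.0, 2.0]})
        model = fit_mlr([0.5, 1.7], X)
        assert model.r2 == pytest.approx(1.0)
        assert model.coef["logkw"] == pytest.approx(1.2)
        assert model.coef["intercept"] == pytest.approx(-0.7)

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(5)
        X = random_design(rng, n=15)
        y = rng.normal(size=15)
        model = fit_mlr(y, X)
        design = np.column_stack([X.to_numpy(), np.ones(15)])
        beta = np.linalg.pinv(design) @ y
        for value, name in zip(beta, [*X.columns, "intercept"]):
            assert model.coef[name] == pytest.approx(value, abs=1e-10)

    def test_published_univariate_rows(self, univariate_design):
        """The four published calibration lines, at their printed resolution."""
        for ph, (y, X) in univariate_design.items():
            slope, se_s, intercept, se_i, r2_adj = UNIVARIATE_PUBLISHED[ph]
            model = fit_mlr(y, X, ph=ph)
            assert model.coef["logkw"] == pytest.approx(slope, abs=0.01)
            assert model.coef["intercept"] == pytest.approx(intercept, abs=0.01)
            assert model.se["logkw"] == pytest.approx(se_s, abs=0.01)
            assert model.se["intercept"] == pytest.approx(se_i, abs=0.01)
            assert model.r2_adj == pytest.approx(r2_adj, abs=0.001)

    def test_benzylamine_removal_improves_linearity(self, univariate_design):
        """The one strongly dissociated amine degrades the pH 7.0 line."""
        y, X = univariate_design[7.0]
        full = fit_mlr(y, X, ph=7.0)
        keep = [i for i, cid in enumerate(X.index) if cid != "9"]
        reduced = fit_mlr(y[keep], X.iloc[keep], ph=7.0)
        assert reduced.r2 > full.r2
        assert reduced.r2_adj > full.r2_adj

    def test_collinear_design_names_terms(self):
        rng = np.random.default_rng(2)
        X = random_design(rng, n=12, terms=("n_e",))
        X["A"] = 2.0 * X["n_e"]
        with pytest.raises(CollinearityError) as err:
            fit_mlr(rng.normal(size=12), X)
        assert {"n_e", "A"} & set(err.value.terms)

    def test_insufficient_rows(self):
        X = pd.DataFrame({"logkw": [1.0, 2.0], "n_e": [0.1, 0.9]})
        with pytest.raises(InsufficientDataError):
            fit_mlr([0.0, 1.0], X, subset=("n_e",))

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        X = random_design(rng, n=18)
        y = 1.1 * X["logkw"].to_numpy() + rng.normal(0, 0.1, 18)
        order = rng.permutation(18)
        a = fit_mlr(y, X)
        b = fit_mlr(y[order], X.iloc[order])
        for name in a.coef:
            assert a.coef[name] == pytest.approx(b.coef[name], abs=1e-10)


class TestSelectModel:
    def test_recovers_informative_descriptor(self):
        """n_e drives logD; pure-noise A and B must not be selected."""
        rng = np.random.default_rng(12)
        X = random_design(rng, n=23)
        y = 1.0 * X["logkw"] - 0.8 * X["n_e"] + rng.normal(0, 0.05, 23)
        best, ranking = select_model(y, X)
        assert best.subset == ("n_e",)
        assert len(ranking) == 8
        assert ranking["selected"].sum() == 1

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(4)
        X = random_design(rng, n=12, terms=("n_e",))
        y = X["logkw"] - 0.5 * X["n_e"] + rng.normal(0, 0.02, 12)
        best, ranking = select_model(y, X, candidates=("n_e",))
        assert best.subset == ("n_e",)
        assert set(ranking["subset"]) == {"(none)", "n_e"}

    def test_noise_free_exact_recovery(self):
        truth = {"logkw": 0.93, "n_e": -0.29, "A": 0.21, "B": -0.49,
                 "intercept": 0.21}
        rng = np.random.default_rng(8)
        X = random_design(rng, n=23)
        y = truth["intercept"] + sum(
            truth[t] * X[t] for t in ("logkw", "n_e", "A", "B")
        )
        # without a parsimony tolerance the noise-free full model is the
        # unique exact fit, and every generating coefficient is recovered
        best, _ = select_model(y, X, r2_tol=0.0)
        assert best.subset == ("n_e", "A", "B")
        for name, value in truth.items():
            assert best.coef[name] == pytest.approx(value, abs=1e-8)

    @given(seed=st.integers(0, 2**16))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_r2_monotone_under_nesting(self, seed):
        rng = np.random.default_rng(seed)
        X = random_design(rng, n=23)
        y = X["logkw"] - 0.4 * X["n_e"] + rng.normal(0, 0.1, 23)
        r2 = {}
        for size in range(4):
            for subset in combinations(("n_e", "A", "B"), size):
                r2[frozenset(subset)] = fit_mlr(y, X, subset=subset).r2
        for s, value in r2.items():
            for t, larger in r2.items():
                if s < t:
                    assert larger >= value - 1e-12


class TestModelReport:
    def test_rendered_equation(self, univariate_design):
        y, X = univariate_design[8.0]
        text = model_report(fit_mlr(y, X, ph=8.0))
        assert text == "logD = (1.02 ± 0.07) logkw - (0.21 ± 0.12)"

    def test_round_trip_recovers_estimates(self):
        rng = np.random.default_rng(6)
        X = random_design(rng, n=23)
        y = X["logkw"] - 0.8 * X["n_e"] + 0.3 * X["A"] + rng.normal(0, 0.1, 23)
        model = fit_mlr(y, X, subset=("n_e", "A"))
        text = model_report(model)
        matches = re.findall(r"([+-]?)\s*\((\d+\.\d{2}) ± (\d+\.\d{2})\)\s*(\S*)", text)
        parsed = {}
        for sign, est, se, name in matches:
            parsed[name or "intercept"] = float(f"{sign}{est}")
        for name in model.terms + ("intercept",):
            assert parsed[name] == pytest.approx(round(model.coef[name], 2), abs=5e-3)

    def test_degenerate_all_zero_model(self):
        X = pd.DataFrame({"logkw": [0.0, 1.0, 2.0, 3.0]})
        text = model_report(fit_mlr([0.0, 0.0, 0.0, 0.0], X))
        assert text.startswith("logD = (0.00 ±")
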