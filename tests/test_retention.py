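"""Retention layer: time correction, retention factors and LSS fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromlogd import (
    DegenerateAnchorError,
    InsufficientDataError,
    InvalidArgumentError,
    NonRetainedSoluteError,
    RetentionSeries,
    build_logkw_matrix,
    correct_time,
    fit_lss,
    retention_factor,
)


def make_series(logkw=2.0, s=3.0, t0=2.5, phis=(0.1, 0.2, 0.3, 0.4, 0.5),
                noise=None, rng=None, **kwargs):
    points = []
    for phi in phis:
        tr = t0 * (1.0 + 10.0 ** (logkw - s * phi))
        if noise:
            tr += rng.normal(0.0, noise)
        points.append((phi, tr))
    return RetentionSeries(compound_id=kwargs.pop("compound_id", "c"),
                           ph=kwargs.pop("ph", 7.0), t0=t0,
                           points=tuple(points), **kwargs)


class TestCorrectTime:
    def test_identity_when_observed_equals_reference(self):
        anchors = ((2.0, 2.0), (10.0, 10.0))
        assert correct_time(7.3, anchors) == 7.3

    def test_affine_map_through_two_anchor_points(self):
        # observed 2 -> reference 2, observed 12 -> reference 10
        anchors = ((2.0, 2.0), (10.0, 12.0))
        assert correct_time(7.0, anchors) == pytest.approx(6.0)

    @given(
        r1=st.floats(1, 5), r2=st.floats(6, 30),
        o1=st.floats(1, 5), o2=st.floats(6, 30),
        t=st.floats(0.5, 40),
    )
    @settings(derandomize=True, max_examples=100)
    def test_exact_at_anchors_and_invertible(self, r1, r2, o1, o2, t):
        anchors = ((r1, o1), (r2, o2))
        assert correct_time(o1, anchors) == pytest.approx(r1, abs=1e-9)
        assert correct_time(o2, anchors) == pytest.approx(r2, abs=1e-9)
        inverse = ((o1, r1), (o2, r2))
        assert correct_time(correct_time(t, anchors), inverse) == pytest.approx(
            t, abs=1e-12 * max(1.0, abs(t))
        )

    def test_degenerate_anchors(self):
        with pytest.raises(DegenerateAnchorError):
            correct_time(5.0, ((2.0, 3.0), (4.0, 3.0)))


class TestRetentionFactor:
    @pytest.mark.parametrize(
        "tr, t0, expected", [(5.0, 2.5, 1.0), (27.5, 2.5, 10.0), (4.1, 2.05, 1.0)]
    )
    def test_values(self, tr, t0, expected):
        assert retention_factor(tr, t0) == pytest.approx(expected)

    def test_non_retained(self):
        with pytest.raises(NonRetainedSoluteError):
            retention_factor(2.0, 2.5)
        with pytest.raises(InvalidArgumentError):
            retention_factor(2.0, -1.0)


class TestFitLSS:
    def test_exact_line(self):
        fit = fit_lss(make_series(logkw=2.0, s=3.0))
        assert fit.logkw == pytest.approx(2.0, abs=1e-10)
        assert fit.S == pytest.approx(3.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert not fit.low_r2

    def test_noise_free_residuals_negligible(self):
        fit = fit_lss(make_series(logkw=1.45, s=2.8))
        phis = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        resid = (1.45 - 2.8 * phis) - (fit.logkw - fit.S * phis)
        assert np.sum(resid**2) < 1e-20

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        series = make_series(logkw=1.3, s=2.2, noise=0.02, rng=rng)
        phi = np.array([p for p, _ in series.averaged_points()])
        logk = np.log10([(tr - series.t0) / series.t0
                         for _, tr in series.averaged_points()])
        design = np.column_stack([np.ones_like(phi), phi])
        intercept, slope = np.linalg.solve(design.T @ design, design.T @ logk)
        fit = fit_lss(series)
        assert fit.logkw == pytest.approx(intercept, abs=1e-10)
        assert fit.S == pytest.approx(-slope, abs=1e-10)

    def test_recovery_within_three_se(self):
        rng = np.random.default_rng(7)
        series = make_series(logkw=1.45, s=2.8, noise=0.005, rng=rng)
        fit = fit_lss(series)
        assert abs(fit.logkw - 1.45) <= 3 * fit.se_logkw

    @given(seed=st.integers(0, 2**16))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_order_and_replicate_invariance(self, seed):
        rng = np.random.default_rng(seed)
        base = make_series(logkw=1.2, s=2.5, noise=0.01, rng=rng)
        shuffled = RetentionSeries(
            compound_id=base.compound_id, ph=base.ph, t0=base.t0,
            points=tuple(reversed(base.points)),
        )
        doubled = RetentionSeries(
            compound_id=base.compound_id, ph=base.ph, t0=base.t0,
            points=base.points + base.points,
        )
        ref = fit_lss(base)
        for variant in (shuffled, doubled):
            fit = fit_lss(variant)
            assert fit.logkw == pytest.approx(ref.logkw, abs=1e-12)
            assert fit.S == pytest.approx(ref.S, abs=1e-12)

    def test_anchored_series_fit_on_corrected_times(self):
        """A run-time drift undone by the anchors yields the clean fit."""
        clean = make_series(logkw=1.8, s=3.2)
        a, b = 1.05, -0.4  # drift: observed = a * reference + b
        drifted_points = tuple((phi, a * tr + b) for phi, tr in clean.points)
        anchors = ((2.0, a * 2.0 + b), (20.0, a * 20.0 + b))
        drifted = RetentionSeries(
            compound_id="c", ph=7.0, t0=clean.t0,
            points=drifted_points, anchors=anchors,
        )
        ref, fit = fit_lss(clean), fit_lss(drifted)
        assert fit.logkw == pytest.approx(ref.logkw, abs=1e-10)
        assert fit.S == pytest.approx(ref.S, abs=1e-10)

    def test_too_few_phi_levels(self):
        with pytest.raises(InsufficientDataError):
            fit_lss(make_series(phis=(0.1, 0.2, 0.3)))

    def test_low_r2_flagged_not_rejected(self, caplog):
        rng = np.random.default_rng(3)
        series = make_series(logkw=0.2, s=1.0, noise=0.15, rng=rng)
        with caplog.at_level("WARNING"):
            fit = fit_lss(series)
        assert fit.low_r2
        assert any("R²" in rec.message for rec in caplog.records)

    def test_series_invariants(self):
        with pytest.raises(NonRetainedSoluteError):
            RetentionSeries("c", 7.0, 2.5, points=((0.1, 2.0),))
        with pytest.raises(InvalidArgumentError):
            RetentionSeries("c", 7.0, 2.5, points=((1.2, 9.0),))


class TestLogkwMatrix:
    def test_cells_match_individual_fits(self):
        series = [
            make_series(logkw=kw, s=s, compound_id=cid, ph=ph)
            for cid, kw, s in [("a", 0.8, 2.0), ("b", 1.5, 3.0), ("c", 2.4, 4.0)]
            for ph in (7.0, 9.0)
        ]
        table = build_logkw_matrix(series, (7.0, 9.0))
        for s in series:
            assert table.at[s.compound_id, s.ph] == pytest.approx(
                fit_lss(s).logkw, abs=1e-12
            )

    def test_empty_input(self):
        assert build_logkw_matrix([], (7.0, 8.0)).empty

    def test_missing_cells_are_nan(self):
        series = [make_series(compound_id="a", ph=7.0)]
        table = build_logkw_matrix(series, (7.0, 9.0))
        assert np.isnan(table.at["a", 9.0])

    def test_duplicate_series_rejected(self):
        series = [make_series(compound_id="a"), make_series(compound_id="a")]
        with pytest.raises(InvalidArgumentError):
            build_logkw_matrix(series, (7.0,))
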