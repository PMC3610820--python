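"""Detrending, damped-cosine fitting, period deviations and the phenotypic score."""

import numpy as np
import pandas as pd
import pytest

from circanet import (
    DampedCosineModel,
    LuminescenceSeries,
    ReporterSimSpec,
    detrend,
    fit_damped_cosine,
    period_deviation,
    phenotypic_score,
    score_vs_dynamic_degree,
    simulate_reporter,
)
from circanet.phenotype import PerturbationResult, ScoreRules


def series(y, dt=0.5, well="w"):
    y = np.asarray(y, dtype=float)
    return LuminescenceSeries(id=well, t=np.arange(len(y)) * dt, y=y)


class TestDetrend:
    def test_linear_ramp_removed(self):
        t = np.arange(0, 120.5, 0.5)
        s = LuminescenceSeries("w", t, 5.0 * t + 100.0)
        d = detrend(s)
        interior = slice(48, -48)  # away from shrinking-window edges
        np.testing.assert_allclose(d.y[interior], 0.0, atol=1e-6)

    def test_cosine_passes_through(self):
        t = np.arange(0, 120.5, 0.5)
        y = 100 * np.cos(2 * np.pi * t / 24)
        d = detrend(LuminescenceSeries("w", t, y))
        interior = slice(48, -48)
        np.testing.assert_allclose(d.y[interior], y[interior], atol=1.0)

    def test_idempotent_within_tolerance(self):
        t = np.arange(0, 144.5, 0.5)
        rng = np.random.default_rng(0)
        y = 100 * np.cos(2 * np.pi * t / 24) + 2 * t + rng.normal(0, 5, len(t))
        d1 = detrend(LuminescenceSeries("w", t, y))
        d2 = detrend(d1)
        interior = slice(48, -48)
        assert np.max(np.abs(d1.y[interior] - d2.y[interior])) < 2.0

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            detrend(series(np.ones(20)))  # 10 h < 24 h window


class TestDampedCosineFit:
    def test_noiseless_parameter_recovery(self):
        s = simulate_reporter(ReporterSimSpec(period_h=24.5, amplitude=800.0,
                                              damping_rate=0.01, noise_sd=0.0))
        res = fit_damped_cosine(s)
        assert res.rhythmic
        assert res.period == pytest.approx(24.5, abs=0.05)
        assert res.fit_correlation > 0.999

    def test_white_noise_classified_arrhythmic(self):
        rng = np.random.default_rng(1)
        s = series(rng.normal(0, 50, 289))
        res = fit_damped_cosine(s)
        assert not res.rhythmic
        assert res.fit_correlation < 0.8

    def test_amplitude_positive_phase_canonical(self):
        s = simulate_reporter(ReporterSimSpec(period_h=22.0, amplitude=300.0,
                                              damping_rate=0.02, noise_sd=10.0, seed=2))
        res = fit_damped_cosine(s)
        assert res.amplitude > 0
        assert 0.0 <= res.phase < res.period

    def test_r_invariant_to_positive_scaling(self):
        s = simulate_reporter(ReporterSimSpec(period_h=25.0, amplitude=100.0,
                                              damping_rate=0.015, noise_sd=8.0, seed=3))
        r1 = fit_damped_cosine(s).fit_correlation
        r2 = fit_damped_cosine(LuminescenceSeries(s.id, s.t, 7.5 * s.y)).fit_correlation
        assert r1 == pytest.approx(r2, abs=1e-3)

    def test_trend_removed_before_fit(self):
        s = simulate_reporter(ReporterSimSpec(period_h=24.0, amplitude=400.0,
                                              damping_rate=0.01, trend=(-10.0, 3000.0),
                                              noise_sd=0.0))
        res = fit_damped_cosine(s)
        assert res.rhythmic
        assert res.period == pytest.approx(24.0, abs=0.1)

    def test_model_results_summary(self):
        s = simulate_reporter(ReporterSimSpec(period_h=24.0, amplitude=100.0, noise_sd=5.0, seed=4))
        res = DampedCosineModel(s).fit()
        text = res.summary()
        assert "period tau" in text and "fit corr r" in text
        assert len(res.fittedvalues()) == len(s.t)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            DampedCosineModel(series(np.ones(50)))  # 25 h < 48 h

    def test_parameter_recovery_ensemble(self):
        """Median period error < 0.1 h over simulated traces at SNR 10."""
        rng = np.random.default_rng(5)
        errors = []
        for i in range(30):
            tau = rng.uniform(22, 26)
            s = simulate_reporter(ReporterSimSpec(period_h=tau, amplitude=500.0,
                                                  damping_rate=0.01, noise_sd=50.0,
                                                  seed=100 + i))
            res = fit_damped_cosine(s)
            assert res.rhythmic
            errors.append(abs(res.period - tau))
        assert np.median(errors) < 0.1


def _fit(period, rhythmic=True):
    class F:  # minimal stand-in carrying the two fields period_deviation reads
        pass

    f = F()
    f.period = period
    f.rhythmic = rhythmic
    return f


class TestPeriodDeviation:
    def test_sample_equal_to_control_mean(self):
        d = period_deviation(_fit(24.1), [_fit(24.0), _fit(24.2)])
        assert d.delta == pytest.approx(0.0)
        assert not d.arrhythmic

    def test_arithmetic(self):
        d = period_deviation(_fit(25.1), [_fit(24.0), _fit(24.2)])
        assert d.delta == pytest.approx(1.0)

    def test_arrhythmic_sample_flag_propagates(self):
        d = period_deviation(_fit(float("nan"), rhythmic=False),
                             [_fit(24.0), _fit(24.2)])
        assert d.arrhythmic
        assert np.isnan(d.delta)

    def test_replicate_sem(self):
        d = period_deviation([_fit(25.0), _fit(25.4)], [_fit(24.0), _fit(24.0)])
        assert d.delta == pytest.approx(1.2)
        assert d.sem == pytest.approx(0.2)

    def test_needs_two_rhythmic_controls(self):
        with pytest.raises(ValueError):
            period_deviation(_fit(25.0), [_fit(24.0), _fit(float("nan"), rhythmic=False)])


def rec(direction="KD", deltas=(0.0,), **flags):
    return PerturbationResult(gene="g", direction=direction,
                              construct_deltas=tuple(deltas), **flags)


class TestPhenotypicScore:
    @pytest.mark.parametrize("kd,oe,expected", [
        ((0.1,), (0.2,), 0),      # below all thresholds
        ((1.0,), (0.1,), 1),      # one mild period shift
        ((2.5,), (0.0,), 2),      # strong shift in one direction
        ((-3.0,), (2.0,), 4),     # strong both directions (sign ignored)
    ])
    def test_rule_arithmetic_two_directions(self, kd, oe, expected):
        assert phenotypic_score([rec("KD", kd), rec("OE", oe)]) == expected

    def test_arrhythmic_plus_strong_shift(self):
        records = [rec("KD", (float("nan"),), arrhythmic=True), rec("OE", (2.5,))]
        assert phenotypic_score(records) == 5

    def test_single_direction(self):
        assert phenotypic_score([rec("KD", (1.0,))]) == 1

    def test_amplitude_flag_lifts_score_to_one(self):
        assert phenotypic_score([rec("KD", (0.1,), low_amplitude=True)]) == 1
        assert phenotypic_score([rec("KD", (0.1,), high_damping=True)]) == 1

    def test_inconsistent_constructs_take_weaker_score(self):
        # constructs disagree by > 0.5 h: the milder construct's score wins
        assert phenotypic_score([rec("KD", (0.1, 2.5))]) == 0

    def test_monotone_in_deviation_and_flags(self):
        deltas = [0.0, 0.4, 0.6, 1.9, 2.1, 5.0]
        scores = [phenotypic_score([rec("KD", (d,))]) for d in deltas]
        assert all(a <= b for a, b in zip(scores[:-1], scores[1:]))
        for d in deltas:
            plain = phenotypic_score([rec("KD", (d,))])
            flagged = phenotypic_score([rec("KD", (d,), low_amplitude=True)])
            assert flagged >= plain

    def test_no_records_raises(self):
        with pytest.raises(ValueError):
            phenotypic_score([])

    def test_custom_rules(self):
        rules = ScoreRules(mild=1.0, strong=4.0)
        assert phenotypic_score([rec("KD", (0.8,))], rules) == 0
        assert phenotypic_score([rec("KD", (2.0,))], rules) == 1


class TestScoreVsDynamicDegree:
    @staticmethod
    def _data(association: bool, seed: int):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(60)]
        degrees = pd.Series(rng.integers(0, 12, 60), index=genes)
        if association:
            scores = pd.Series(
                (degrees >= 5).astype(int) * 2 + rng.integers(0, 2, 60), index=genes
            )
        else:
            scores = pd.Series(rng.integers(0, 4, 60), index=genes)
        return scores, degrees

    def test_null_usually_not_significant(self):
        pvals = []
        for seed in range(5):
            scores, degrees = self._data(False, seed)
            r = score_vs_dynamic_degree(scores, degrees)
            pvals.extend([r.t_p, r.mannwhitney_p])
        assert np.median(pvals) > 0.05

    def test_planted_association_significant(self):
        scores, degrees = self._data(True, 1)
        r = score_vs_dynamic_degree(scores, degrees, cut=5)
        assert r.t_p < 0.01 and r.mannwhitney_p < 0.01
        assert r.mean_high > r.mean_low

    def test_cut_above_max_degree_errors(self):
        scores, degrees = self._data(False, 2)
        with pytest.raises(ValueError):
            score_vs_dynamic_degree(scores, degrees, cut=int(degrees.max()) + 1)
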