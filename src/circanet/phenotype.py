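"""Circadian phenotyping of bioluminescence reporter time series.

Oscillation traces (luciferase counts sampled every 30 min for several
days) are detrended with a centered 24-h running mean and fitted with an
exponentially damped cosine

    y(t) = A * exp(-lambda * t) * cos(2*pi*(t - phi)/tau)

by multi-start nonlinear least squares over a period grid.  The Pearson
correlation r between the fitted curve and the detrended data is the
rhythmicity criterion: traces with r below a cutoff (default 0.8) are
classified arrhythmic.  Period deviations from a panel of control fits,
together with amplitude/damping/magnitude flags and arrhythmicity, are
combined into an ordinal *phenotypic score* per gene across knockdown and
overexpression perturbations, which is then tested against the number of
predicted dynamic interactions.

The fit is exposed statsmodels-style: ``DampedCosineModel(t, y).fit()``
returns a :class:`DampedCosineResults` with parameters, diagnostics and a
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LuminescenceSeries",
    "DampedCosineModel",
    "DampedCosineResults",
    "detrend",
    "fit_damped_cosine",
    "period_deviation",
    "PeriodDeviation",
    "PerturbationResult",
    "ScoreRules",
    "phenotypic_score",
    "score_vs_dynamic_degree",
]

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_PERIOD_WINDOW = (18.0, 32.0)


@dataclass(frozen=True)
class LuminescenceSeries:
    """One well's bioluminescence trace (uniform sampling)."""

    id: str
    t: np.ndarray  # hours since synchronization
    y: np.ndarray  # counts

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D and equally long")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def detrend(series: LuminescenceSeries, window_h: float = 24.0) -> LuminescenceSeries:
    """Subtract a centered running mean of width ``window_h``.

    The window shrinks at the edges (pandas centered rolling mean with
    ``min_periods=1``), so slow drifts and polynomial trends are removed
    while a full-period oscillation passes through nearly unchanged.
    """
    if series.duration <= window_h:
        raise ValueError("series shorter than the detrending window")
    dt = float(np.median(np.diff(series.t)))
    half = max(int(round(window_h / dt / 2)), 1)
    # trapezoidal weights: the two endpoints of the centered window count half,
    # so a full-period cosine averages to exactly zero and a linear ramp to its
    # center value; edges renormalize over the available (shrunken) window
    kernel = np.ones(2 * half + 1)
    kernel[0] = kernel[-1] = 0.5
    trend = np.convolve(series.y, kernel, mode="same") / np.convolve(
        np.ones_like(series.y), kernel, mode="same"
    )
    return LuminescenceSeries(id=series.id, t=series.t, y=series.y - trend)


def _damped_cosine(t, amplitude, damping, period, phase):
    return amplitude * np.exp(-damping * t) * np.cos(2 * np.pi * (t - phase) / period)


class DampedCosineModel:
    """Damped-cosine oscillation model for one (already raw) trace.

    Parameters
    ----------
    series : LuminescenceSeries
    detrend_window_h : float or None
        Width of the running-mean detrending window; ``None`` skips
        detrending (for pre-detrended data).
    """

    def __init__(self, series: LuminescenceSeries, detrend_window_h: float | None = 24.0):
        if series.duration < 48.0:
            raise ValueError("need at least 48 h of data for a circadian fit")
        self.series = series
        if detrend_window_h:
            self.detrended = detrend(series, detrend_window_h)
            # fit only where the centered window was complete: a running mean
            # applied to a damped cosine rescales it exactly in the interior
            # but distorts the shrunken-window edges
            dt = float(np.median(np.diff(series.t)))
            half = max(int(round(detrend_window_h / dt / 2)), 1)
            self._fit_slice = slice(half, len(series.t) - half)
        else:
            self.detrended = series
            self._fit_slice = slice(None)

    def fit(
        self,
        period_window: tuple[float, float] = DEFAULT_PERIOD_WINDOW,
        r_threshold: float = DEFAULT_R_THRESHOLD,
        n_starts: int = 8,
    ) -> "DampedCosineResults":
        """Multi-start least-squares fit over a period grid.

        For each start period the remaining parameters are initialized from
        the data (amplitude from the detrended spread, phase from the
        best-overlap cosine shift) and refined with bounded least squares;
        the lowest-SSE solution wins.  Amplitude is canonicalized positive
        with phase in [0, period).
        """
        t, y = self.detrended.t[self._fit_slice], self.detrended.y[self._fit_slice]
        lo, hi = period_window
        if self.series.duration < 2 * lo:
            raise ValueError("need at least two cycles within the period window")
        amp0 = float(np.sqrt(2.0) * np.std(y))
        if amp0 == 0:
            return self._failure(r_threshold, "constant trace")
        best = None
        for tau0 in np.linspace(lo, hi, n_starts):
            shifts = np.arange(0.0, tau0, 0.25)
            overlap = y @ np.cos(2 * np.pi * (t[:, None] - shifts[None, :]) / tau0)
            phi0 = float(shifts[int(np.argmax(overlap))])
            p0 = [amp0, 0.01, tau0, phi0]
            try:
                popt, _ = optimize.curve_fit(
                    _damped_cosine,
                    t,
                    y,
                    p0=p0,
                    bounds=([1e-9, -0.1, lo, -hi], [np.inf, 1.0, hi, 2 * hi]),
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            sse = float(np.sum((y - _damped_cosine(t, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
        if best is None:
            return self._failure(r_threshold, "no start converged")
        amplitude, damping, period, phase = best[1]
        phase = float(phase % period)
        fitted = _damped_cosine(t, amplitude, damping, period, phase)
        r = float(stats.pearsonr(fitted, y)[0]) if np.std(fitted) > 0 else 0.0
        return DampedCosineResults(
            model=self,
            period=float(period),
            amplitude=float(amplitude),
            damping=float(damping),
            phase=phase,
            fit_correlation=r,
            rhythmic=bool(r >= r_threshold),
            r_threshold=r_threshold,
            converged=True,
            message="ok",
        )

    def _failure(self, r_threshold: float, message: str) -> "DampedCosineResults":
        return DampedCosineResults(
            model=self,
            period=float("nan"),
            amplitude=float("nan"),
            damping=float("nan"),
            phase=float("nan"),
            fit_correlation=float("nan"),
            rhythmic=False,
            r_threshold=r_threshold,
            converged=False,
            message=message,
        )


@dataclass
class DampedCosineResults:
    """Fitted damped-cosine parameters and rhythmicity classification."""

    model: DampedCosineModel
    period: float  # tau, hours
    amplitude: float  # counts
    damping: float  # lambda, per hour
    phase: float  # phi, hours in [0, period)
    fit_correlation: float  # Pearson r of fit vs detrended data
    rhythmic: bool
    r_threshold: float
    converged: bool
    message: str

    def fittedvalues(self) -> np.ndarray:
        d = self.model.detrended
        if not self.converged:
            return np.full_like(d.y, np.nan)
        return _damped_cosine(d.t, self.amplitude, self.damping, self.period, self.phase)

    def summary(self) -> str:
        cls = "rhythmic" if self.rhythmic else "arrhythmic"
        lines = [
            f"Damped cosine fit: {self.model.series.id}",
            "=" * 40,
            f"period tau     {self.period:>10.3f} h",
            f"amplitude      {self.amplitude:>10.1f} counts",
            f"damping lambda {self.damping:>10.4f} /h",
            f"phase phi      {self.phase:>10.2f} h",
            f"fit corr r     {self.fit_correlation:>10.4f}",
            f"class          {cls:>10s} (r >= {self.r_threshold:g})",
        ]
        if not self.converged:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


def fit_damped_cosine(
    series: LuminescenceSeries,
    period_window: tuple[float, float] = DEFAULT_PERIOD_WINDOW,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    detrend_window_h: float | None = 24.0,
) -> DampedCosineResults:
    """Convenience wrapper: detrend then fit (see :class:`DampedCosineModel`)."""
    return DampedCosineModel(series, detrend_window_h).fit(period_window, r_threshold)


@dataclass(frozen=True)
class PeriodDeviation:
    """Period difference of a sample vs the control-panel mean."""

    delta: float  # hours; NaN when arrhythmic
    sem: float  # over sample replicates; NaN when < 2 replicates
    arrhythmic: bool
    control_mean: float
    n_controls: int


def period_deviation(
    fits: DampedCosineResults | list[DampedCosineResults],
    control_fits: list[DampedCosineResults],
) -> PeriodDeviation:
    """Period deviation (sample minus control mean), sem over replicates.

    Controls must contain at least two rhythmic fits.  If every sample
    replicate is arrhythmic the deviation is undefined and the arrhythmic
    flag is set.
    """
    if not isinstance(fits, (list, tuple)):
        fits = [fits]
    ctrl = [f.period for f in control_fits if f.rhythmic]
    if len(ctrl) < 2:
        raise ValueError("need at least two rhythmic control fits")
    cmean = float(np.mean(ctrl))
    periods = [f.period for f in fits if f.rhythmic]
    if not periods:
        return PeriodDeviation(float("nan"), float("nan"), True, cmean, len(ctrl))
    delta = float(np.mean(periods) - cmean)
    sem = float(stats.sem(periods)) if len(periods) >= 2 else float("nan")
    return PeriodDeviation(delta, sem, False, cmean, len(ctrl))


@dataclass(frozen=True)
class PerturbationResult:
    """Phenotype of one perturbation direction (KD or OE) of one gene.

    ``construct_deltas`` holds the per-construct period deviations in hours
    (NaN for an arrhythmic construct).
    """

    gene: str
    direction: str  # "KD" | "OE"
    construct_deltas: tuple[float, ...]
    arrhythmic: bool = False
    low_amplitude: bool = False
    high_damping: bool = False
    low_magnitude: bool = False


@dataclass(frozen=True)
class ScoreRules:
    """Thresholds of the ordinal phenotypic score (hours).

    Per direction: 0 if |delta| < ``mild`` and no flags; 1 if
    ``mild`` <= |delta| < ``strong`` or any amplitude/damping/magnitude
    flag; 2 if |delta| >= ``strong``; 3 if arrhythmic.  The gene score sums
    the two directions.  When two constructs disagree by more than
    ``consistency`` hours, the direction takes the weaker (smaller) of the
    per-construct scores.
    """

    mild: float = 0.5
    strong: float = 2.0
    consistency: float = 0.5


def _delta_score(delta: float, flagged: bool, rules: ScoreRules) -> int:
    if np.isnan(delta):
        return 3
    if abs(delta) >= rules.strong:
        return 2
    if abs(delta) >= rules.mild or flagged:
        return 1
    return 0


def _direction_score(rec: PerturbationResult, rules: ScoreRules) -> int:
    if rec.arrhythmic:
        return 3
    flagged = rec.low_amplitude or rec.high_damping or rec.low_magnitude
    deltas = [d for d in rec.construct_deltas]
    if not deltas:
        raise ValueError(f"{rec.gene} {rec.direction}: no period deviations recorded")
    per_construct = [_delta_score(d, flagged, rules) for d in deltas]
    finite = [d for d in deltas if not np.isnan(d)]
    if len(finite) >= 2 and (max(finite) - min(finite)) > rules.consistency:
        return min(per_construct)  # inconsistent replicates: weaker construct wins
    return _delta_score(float(np.nanmean(deltas)) if finite else float("nan"), flagged, rules)


def phenotypic_score(
    records: list[PerturbationResult],
    rules: ScoreRules = ScoreRules(),
) -> int:
    """Ordinal circadian-defect score for one gene.

    Sums the per-direction scores over the knockdown and overexpression
    records supplied (at least one direction required).  Deterministic
    given the records and rules.
    """
    if not records:
        raise ValueError("no perturbation records")
    by_dir: dict[str, PerturbationResult] = {}
    for rec in records:
        if rec.direction not in ("KD", "OE"):
            raise ValueError(f"unknown perturbation direction {rec.direction!r}")
        if rec.direction in by_dir:
            raise ValueError(f"duplicate records for direction {rec.direction}")
        by_dir[rec.direction] = rec
    return sum(_direction_score(rec, rules) for rec in by_dir.values())


@dataclass(frozen=True)
class ScoreDegreeComparison:
    """Phenotypic score compared between high- and low-dynamic-degree genes."""

    t_statistic: float
    t_p: float
    mannwhitney_u: float
    mannwhitney_p: float
    mean_high: float
    mean_low: float
    n_high: int
    n_low: int
    cut: int


def score_vs_dynamic_degree(
    scores: pd.Series,
    dynamic_degrees: pd.Series,
    cut: int = 5,
) -> ScoreDegreeComparison:
    """Test whether genes with many dynamic interactions score higher.

    Two-sided Welch t-test and Mann-Whitney U comparing phenotypic scores
    between genes with dynamic degree >= ``cut`` and the rest (both on the
    genes present in both series).
    """
    common = scores.index.intersection(dynamic_degrees.index)
    s = scores.loc[common].astype(float)
    d = dynamic_degrees.loc[common].astype(float)
    high = s[d >= cut]
    low = s[d < cut]
    if len(high) == 0 or len(low) == 0:
        raise ValueError(
            f"empty group at cut {cut}: n_high={len(high)}, n_low={len(low)}"
        )
    t_stat, t_p = stats.ttest_ind(high, low, equal_var=False)
    u_stat, u_p = stats.mannwhitneyu(high, low, alternative="two-sided")
    return ScoreDegreeComparison(
        t_statistic=float(t_stat),
        t_p=float(t_p),
        mannwhitney_u=float(u_stat),
        mannwhitney_p=float(u_p),
        mean_high=float(high.mean()),
        mean_low=float(low.mean()),
        n_high=len(high),
        n_low=len(low),
        cut=cut,
    )
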