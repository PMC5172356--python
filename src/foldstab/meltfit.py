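"""Fluorescence denaturation analysis.

The transition midpoint of a protein unfolding curve is extracted in three
steps: each emission spectrum is condensed to its barycentric mean (the
intensity-weighted mean emission wavelength, which red-shifts as buried
tryptophans become solvent-exposed), the per-condition means form a melting
curve, and the curve is fitted to the Boltzmann sigmoid

    λ(x) = λ_N + (λ_D − λ_N) / (1 + exp((x_half − x)/rate))

where x is temperature (K) or denaturant concentration (mol/L), λ_N and λ_D
the native/denatured plateau wavelengths, x_half the midpoint and ``rate``
the slope parameter.  Replicate midpoints are summarized as mean ± SEM and
compared between constructs with a two-tailed Student's t test (pooled
variance by default; Welch behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .dataio import EmissionSpectrum, ValidationError

__all__ = [
    "MeltCurve",
    "MeltFitResult",
    "MeltSummary",
    "ComparisonResult",
    "barycentric_mean",
    "build_melt_curve",
    "fit_sigmoid",
    "aggregate_replicates",
    "compare_transitions",
]

P_FLOOR = 1e-300   # reported when the pooled variance is exactly zero but means differ


@dataclass
class MeltCurve:
    """Barycentric means across conditions for one replicate."""

    condition_values: np.ndarray
    barycentric_means: np.ndarray
    replicate_id: str = "rep1"
    condition_kind: str = "thermal"

    def __post_init__(self):
        self.condition_values = np.asarray(self.condition_values, dtype=float)
        self.barycentric_means = np.asarray(self.barycentric_means, dtype=float)
        if self.condition_values.size != self.barycentric_means.size:
            raise ValidationError("condition and barycentric arrays differ in length")
        if not np.all(np.diff(self.condition_values) > 0):
            raise ValidationError("conditions must be strictly increasing within a replicate")


@dataclass
class MeltFitResult:
    lambda_n: float
    lambda_d: float
    t_half: float
    rate: float
    se_lambda_n: float
    se_lambda_d: float
    se_t_half: float
    se_rate: float
    converged: bool
    residual_rms: float
    replicate_id: str = "rep1"
    condition_kind: str = "thermal"


@dataclass
class MeltSummary:
    mean: float
    sem: float
    n: int


@dataclass
class ComparisonResult:
    delta: float            # mean_b - mean_a
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


def barycentric_mean(spectrum: EmissionSpectrum) -> float:
    """Intensity-weighted mean emission wavelength, Σλ·F(λ) / ΣF(λ), in nm."""
    total = float(np.sum(spectrum.intensities))
    if total <= 0:
        raise ValidationError("total intensity must be positive for a barycentric mean")
    return float(np.sum(spectrum.wavelengths * spectrum.intensities) / total)


def build_melt_curve(spectra: Iterable[EmissionSpectrum]) -> list[MeltCurve]:
    """One melting curve per replicate, sorted by condition.

    Duplicate (replicate, condition) pairs are rejected; each replicate needs
    at least 3 distinct conditions.
    """
    by_rep: dict[str, list[EmissionSpectrum]] = {}
    for s in spectra:
        by_rep.setdefault(s.replicate_id, []).append(s)
    curves = []
    for rep in sorted(by_rep):
        group = sorted(by_rep[rep], key=lambda s: s.condition_value)
        conds = np.array([s.condition_value for s in group])
        if np.unique(conds).size != conds.size:
            raise ValidationError(
                f"replicate {rep}: duplicate condition values in melt series")
        if conds.size < 3:
            raise ValidationError(
                f"replicate {rep}: at least 3 distinct conditions are required")
        kinds = {s.condition_kind for s in group}
        if len(kinds) != 1:
            raise ValidationError(f"replicate {rep}: mixed condition kinds")
        curves.append(MeltCurve(
            condition_values=conds,
            barycentric_means=np.array([barycentric_mean(s) for s in group]),
            replicate_id=rep,
            condition_kind=kinds.pop(),
        ))
    return curves


def _sigmoid(x, lam_n, lam_d, x_half, rate):
    return lam_n + (lam_d - lam_n) / (1.0 + np.exp((x_half - x) / rate))


def _initial_guess(x: np.ndarray, y: np.ndarray, condition_kind: str):
    k = max(1, x.size // 10)
    lam_n = float(np.mean(y[:k]))
    lam_d = float(np.mean(y[-k:]))
    slopes = np.gradient(y, x)
    x_half = float(x[np.argmax(np.abs(slopes))])
    rate = 2.0 if condition_kind == "thermal" else float((x[-1] - x[0]) / 15.0)
    return [lam_n, lam_d, x_half, max(rate, 1e-3)]


def fit_sigmoid(curve: MeltCurve, init: Sequence[float] | None = None) -> MeltFitResult:
    """Least-squares Boltzmann-sigmoid fit of one melting curve.

    Standard errors come from the local curvature (scaled covariance of the
    fit).  The result is flagged non-converged — never raised — when the
    optimizer fails, the midpoint lands outside the data range, the errors
    are non-finite, or the fitted amplitude is indistinguishable from the
    residual noise (no transition in range).
    """
    x = curve.condition_values
    y = curve.barycentric_means
    if x.size < 5:
        raise ValidationError("at least 5 points are required to fit a sigmoid")
    p0 = list(init) if init is not None else _initial_guess(x, y, curve.condition_kind)

    def _fail(rms=np.nan):
        return MeltFitResult(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                             np.nan, np.nan, False, rms,
                             curve.replicate_id, curve.condition_kind)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(_sigmoid, x, y, p0=p0, maxfev=10000)
    except (RuntimeError, ValueError):
        return _fail()
    lam_n, lam_d, x_half, rate = popt
    resid = y - _sigmoid(x, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    se = np.sqrt(np.diag(pcov))
    amplitude = abs(lam_d - lam_n)
    if not np.all(np.isfinite(se)):
        return _fail(rms)
    if not (x.min() <= x_half <= x.max()):
        return _fail(rms)
    if amplitude < max(4.0 * rms, 1e-9 * max(1.0, abs(lam_n))):
        return _fail(rms)   # flat within noise: no resolvable transition
    return MeltFitResult(
        lambda_n=float(lam_n), lambda_d=float(lam_d), t_half=float(x_half),
        rate=float(rate), se_lambda_n=float(se[0]), se_lambda_d=float(se[1]),
        se_t_half=float(se[2]), se_rate=float(se[3]), converged=True,
        residual_rms=rms, replicate_id=curve.replicate_id,
        condition_kind=curve.condition_kind)


def aggregate_replicates(fits: Sequence[MeltFitResult]) -> MeltSummary:
    """Mean, SEM (sample SD/√n) and n over converged replicate midpoints."""
    converged = [f for f in fits if f.converged]
    if len(converged) < len(fits):
        warnings.warn(f"{len(fits) - len(converged)} non-converged fit(s) excluded "
                      "from aggregation", stacklevel=2)
    if len(converged) < 2:
        raise ValidationError("at least 2 converged fits are required to aggregate")
    vals = np.array([f.t_half for f in converged])
    return MeltSummary(mean=float(np.mean(vals)),
                       sem=float(np.std(vals, ddof=1) / np.sqrt(vals.size)),
                       n=int(vals.size))


def compare_transitions(group_a: Sequence[float], group_b: Sequence[float],
                        welch: bool = False) -> ComparisonResult:
    """Two-tailed two-sample t test on replicate midpoints.

    Pooled-variance (classical Student) by default; Welch with ``welch=True``.
    Δ is reported as mean(b) − mean(a).  Zero variance in both groups gives
    p = 1 when the means are equal and a floored p with a warning otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 replicates")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    sem_a = float(np.sqrt(var_a / a.size))
    sem_b = float(np.sqrt(var_b / b.size))
    delta = mean_b - mean_a

    if var_a == 0.0 and var_b == 0.0:
        if mean_a == mean_b:
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("zero variance in both groups with unequal means; "
                          "p reported at the underflow floor", stacklevel=2)
            t_stat, p = float(np.sign(delta)) * np.inf, P_FLOOR
        return ComparisonResult(delta, mean_a, sem_a, mean_b, sem_b,
                                t_stat, p, a.size, b.size)

    if welch:
        se2 = var_a / a.size + var_b / b.size
        t_stat = delta / np.sqrt(se2)
        df = se2**2 / ((var_a / a.size) ** 2 / (a.size - 1)
                       + (var_b / b.size) ** 2 / (b.size - 1))
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * var_a + (b.size - 1) * var_b) / df
        t_stat = delta / np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    p = max(p, P_FLOOR)
    return ComparisonResult(delta, mean_a, sem_a, mean_b, sem_b,
                            float(t_stat), p, a.size, b.size)
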