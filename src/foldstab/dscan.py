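"""DSC thermogram analysis: baseline correction, transition peaks,
reversibility from reheating scans.

The transition temperature is the temperature of the peak maximum of the
baseline-corrected excess heat capacity — no thermodynamic model is fitted,
so the readout remains meaningful for irreversible transitions where a
two-state equilibrium analysis would not be.  Folding reversibility is
quantified per transition as the ratio of the reheat peak area to the
first-heat peak area after matching peaks by temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .dataio import DSCTrace, ValidationError

__all__ = [
    "TransitionPeak",
    "ReversibilityReport",
    "correct_baseline",
    "find_transition_peaks",
    "reversibility_index",
]

# fraction of peak height defining the integration support
SUPPORT_FRACTION = 0.05


@dataclass
class TransitionPeak:
    t_m: float          # K, grid temperature of the maximum
    height: float       # kJ K^-1 mol^-1 above baseline
    area: float         # kJ mol^-1, trapezoidal integral over the support
    prominence: float
    index: int          # grid index of the maximum


@dataclass
class ReversibilityReport:
    """Matched (first-heat, reheat) peak pairs with per-pair area ratios.

    ``pairs`` holds (first_peak, reheat_peak_or_None, index); an unmatched
    first-heat peak is reported with index 0.
    """

    pairs: list
    indices: np.ndarray


def correct_baseline(trace: DSCTrace, pre_window: tuple | None = None,
                     post_window: tuple | None = None) -> DSCTrace:
    """Subtract a linear baseline through the means of two transition-free windows.

    Windows are (T_low, T_high) in K; defaults are the first and last 10% of
    the temperature grid.  A warning is issued if a detected peak's support
    reaches into either window (the baseline is then biased).
    """
    temps = trace.temperatures
    cp = trace.heat_capacity
    span = temps[-1] - temps[0]
    if pre_window is None:
        pre_window = (temps[0], temps[0] + 0.1 * span)
    if post_window is None:
        post_window = (temps[-1] - 0.1 * span, temps[-1])
    for name, win in (("pre", pre_window), ("post", post_window)):
        if win[0] > win[1]:
            raise ValidationError(f"{name}_window bounds are reversed")
        if win[1] < temps[0] or win[0] > temps[-1]:
            raise ValidationError(f"{name}_window lies outside the trace range")
    pre_mask = (temps >= pre_window[0]) & (temps <= pre_window[1])
    post_mask = (temps >= post_window[0]) & (temps <= post_window[1])
    if pre_mask.sum() < 2 or post_mask.sum() < 2:
        raise ValidationError("each baseline window must contain at least 2 points")

    x1, y1 = temps[pre_mask].mean(), cp[pre_mask].mean()
    x2, y2 = temps[post_mask].mean(), cp[post_mask].mean()
    slope = (y2 - y1) / (x2 - x1)
    corrected = cp - (y1 + slope * (temps - x1))

    # floor below which residual structure is floating-point noise, not signal
    noise_floor = 1e-8 * max(1.0, float(np.max(np.abs(cp))))
    peaks = find_transition_peaks(
        DSCTrace(temps, corrected, trace.scan_label, trace.scan_rate),
        min_prominence=0.2 * max(corrected.max(), 0.0) if corrected.max() > 0 else np.inf)
    for pk in peaks:
        if pk.height <= noise_floor:
            continue
        lo, hi = _support(temps, corrected, pk.index)
        if temps[lo] <= pre_window[1] or temps[hi] >= post_window[0]:
            warnings.warn("baseline window overlaps a transition peak support; "
                          "choose transition-free windows", stacklevel=2)
            break
    return DSCTrace(temps.copy(), corrected, trace.scan_label, trace.scan_rate)


def _support(temps: np.ndarray, cp: np.ndarray, peak_idx: int) -> tuple[int, int]:
    """Contiguous index range around a peak where Cp > SUPPORT_FRACTION * height."""
    thresh = SUPPORT_FRACTION * cp[peak_idx]
    lo = peak_idx
    while lo > 0 and cp[lo - 1] > thresh:
        lo -= 1
    hi = peak_idx
    while hi < cp.size - 1 and cp[hi + 1] > thresh:
        hi += 1
    return lo, hi


def find_transition_peaks(trace: DSCTrace, min_prominence: float) -> list[TransitionPeak]:
    """Local maxima of a baseline-corrected trace exceeding ``min_prominence``.

    The transition temperature is the grid temperature of each maximum (no
    interpolation); the area is the trapezoidal integral over the contiguous
    region where the corrected Cp exceeds 5% of the peak height.  An empty
    list (not an error) is returned when nothing clears the threshold.
    """
    temps = trace.temperatures
    cp = trace.heat_capacity
    idx, props = find_peaks(cp, prominence=min_prominence)
    out = []
    for i, prom in zip(idx, props["prominences"]):
        lo, hi = _support(temps, cp, i)
        area = float(np.trapezoid(cp[lo:hi + 1], temps[lo:hi + 1]))
        out.append(TransitionPeak(
            t_m=float(temps[i]), height=float(cp[i]), area=area,
            prominence=float(prom), index=int(i)))
    out.sort(key=lambda p: p.t_m)
    return out


def reversibility_index(first: DSCTrace, reheat: DSCTrace,
                        matching_tolerance: float = 3.0,
                        min_prominence: float | None = None) -> ReversibilityReport:
    """Per-transition reversibility from a (first heat, reheat) scan pair.

    Peaks are detected in both baseline-corrected traces (default prominence:
    5% of each trace's own dynamic range) and matched by nearest transition
    temperature within ``matching_tolerance`` K.  The index is the matched
    reheat area divided by the first-heat area; an unmatched first-heat peak
    gets index 0 (transition lost on reheat).
    """
    def _prom(trace):
        if min_prominence is not None:
            return min_prominence
        rng = float(trace.heat_capacity.max() - trace.heat_capacity.min())
        return 0.05 * rng if rng > 0 else np.inf

    first_peaks = find_transition_peaks(first, _prom(first))
    if not first_peaks:
        raise ValidationError("no transition peaks detected in the first heat")
    reheat_peaks = find_transition_peaks(reheat, _prom(reheat))

    pairs = []
    indices = []
    available = list(reheat_peaks)
    for fp in first_peaks:
        best = None
        if available:
            cand = min(available, key=lambda rp: abs(rp.t_m - fp.t_m))
            if abs(cand.t_m - fp.t_m) <= matching_tolerance:
                best = cand
                available.remove(cand)
        if best is None:
            if reheat_peaks:
                warnings.warn(f"first-heat peak at {fp.t_m:.1f} K has no reheat "
                              f"match within {matching_tolerance} K", stacklevel=2)
            pairs.append((fp, None, 0.0))
            indices.append(0.0)
        else:
            idx = best.area / fp.area if fp.area > 0 else np.inf
            pairs.append((fp, best, float(idx)))
            indices.append(float(idx))
    return ReversibilityReport(pairs=pairs, indices=np.asarray(indices))
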