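"""Optical densitometry: dye concentration from transmitted light and PDR.

The clearance test injects indocyanine green (ICG) intravenously and tracks
its blood concentration through a finger by transmitted light.  The
Beer-Lambert law relates transmitted intensity (measured as voltage on the
photodiode load resistor) to concentration,

    c = (1 / (eps * z)) * log10(u0 / u),

where ``eps`` is the decadic extinction coefficient (L mg^-1 cm^-1), ``z``
the optical path (cm) and ``u0`` the dye-free reference voltage.  After the
recirculation transient ends at time ``t1`` the concentration decays as

    c(t) = c1 * exp(-0.01 * PDR * (t - t1)),

with PDR (plasma disappearance rate) in %/min and t in minutes.  Taking the
double-log transform

    f(t) = -ln[ A(t) / A(t1) ] * 100%          (A = absorbance)

turns the decay into a straight line of slope PDR, estimated here by
ordinary least squares.

The module also provides the closed-form standard deviation of the
concentration estimate as a function of concentration, obtained by
propagating a voltage noise floor ``delta_u`` through the log transform:

    dc = ln(10) * delta_u / (eps * z * u0) * sqrt(1 + exp(2 ln(10) eps c z)).

The exponential growth of this error with concentration is what bounds the
usable dye concentration range from above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, signal, stats

from .errors import (
    InsufficientEliminationDataError,
    NoInjectionError,
    RecirculationEndNotFoundError,
)

logger = logging.getLogger(__name__)

LN10 = np.log(10.0)

__all__ = [
    "DensitometryCalibration",
    "IntensityTrace",
    "ClearanceSegmentation",
    "SegmentationParams",
    "LinearizedElimination",
    "PDRResult",
    "concentration_from_voltage",
    "voltage_from_concentration",
    "concentration_sigma",
    "segment_trace",
    "linearize_elimination",
    "estimate_pdr",
    "analyze_clearance",
    "nonlinear_pdr_crosscheck",
]


@dataclass(frozen=True)
class DensitometryCalibration:
    """Optical and electronic constants of the densitometry channel.

    Parameters
    ----------
    epsilon:
        Decadic extinction coefficient of the dye, L mg^-1 cm^-1.
    path_z:
        Optical path length through the tissue, cm.
    sensitivity_s:
        Photodiode sensitivity, A/W.  Enters only through the identity
        relative-intensity-deviation == relative-voltage-deviation, so its
        value never changes a concentration; it is kept for completeness.
    load_r:
        Load resistance, Ohm (same remark as ``sensitivity_s``).
    u0:
        Reference (zero-dye) voltage, V.
    delta_u:
        Standard deviation of the voltage measurement, V.
    """

    epsilon: float
    path_z: float
    u0: float = 1.0
    delta_u: float = 0.0
    sensitivity_s: float = 1.0
    load_r: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.path_z <= 0:
            raise ValueError(f"path_z must be > 0, got {self.path_z}")
        if self.u0 <= 0:
            raise ValueError(f"u0 must be > 0, got {self.u0}")
        if self.delta_u < 0:
            raise ValueError(f"delta_u must be >= 0, got {self.delta_u}")
        if self.sensitivity_s <= 0:
            raise ValueError(f"sensitivity_s must be > 0, got {self.sensitivity_s}")
        if self.load_r <= 0:
            raise ValueError(f"load_r must be > 0, got {self.load_r}")


@dataclass
class IntensityTrace:
    """Timestamped photodetector voltages of the densitometry channel.

    ``times`` are in minutes and strictly increasing; ``voltages`` are in
    volts and strictly positive (logarithms of voltage ratios are taken
    downstream).
    """

    times: np.ndarray
    voltages: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.voltages.shape:
            raise ValueError("times and voltages must be 1-D arrays of equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValueError(f"times must be strictly increasing (violation at sample {i + 1})")
            # downstream segmentation assumes an (approximately) constant period
            if np.ptp(dt) > 1e-6 * np.median(dt):
                logger.warning("irregular sample timestamps; a constant period is assumed downstream")
        bad = np.flatnonzero(self.voltages <= 0)
        if bad.size:
            raise ValueError(f"voltages must be > 0 (sample {bad[0]} is {self.voltages[bad[0]]!r})")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def sample_period(self) -> float:
        """Median sample period, minutes."""
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class ClearanceSegmentation:
    """Detected phases of a clearance trace.

    ``baseline_window`` and ``elimination_window`` are half-open index
    ranges ``(start, stop)`` into the trace.  ``u0`` is the reference
    voltage defined as the baseline-window mean.
    """

    baseline_window: tuple[int, int]
    t0: float
    peak_time: float
    t1: float
    elimination_window: tuple[int, int]
    u0: float

    def __post_init__(self) -> None:
        if not (self.t0 < self.peak_time < self.t1):
            raise ValueError(
                f"expected t0 < peak_time < t1, got {self.t0}, {self.peak_time}, {self.t1}"
            )
        if self.elimination_window[1] - self.elimination_window[0] < 10:
            raise ValueError("elimination window must contain at least 10 samples")
        if self.u0 <= 0:
            raise ValueError("baseline reference voltage must be positive")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds of :func:`segment_trace`.

    ``k_threshold`` scales the baseline absorbance noise to form the
    injection-detection threshold; ``sustain`` is the number of consecutive
    above-threshold samples required (guards against single-sample noise
    spikes).  ``guard`` samples immediately before the detected injection
    are excluded from the baseline.  ``t1_sigma_mult`` scales the local
    log-absorbance noise when testing how far the terminal exponential can
    be extended backwards; ``t1_tol_floor`` is the absolute floor of that
    tolerance (keeps the test meaningful on noiseless input).
    """

    k_threshold: float = 5.0
    sustain: int = 5
    guard: int = 5
    baseline_init: int = 20
    smooth_window: int = 5
    anchor_frac: float = 0.5
    t1_sigma_mult: float = 5.0
    t1_tol_floor: float = 1e-9


def _as_array(u: Any) -> np.ndarray:
    return np.asarray(u, dtype=float)


def concentration_from_voltage(u, cal: DensitometryCalibration, u0: float | None = None):
    """Dye concentration (mg/L) from detected voltage (V).

    Inverts the Beer-Lambert transduction ``u = u0 * 10^(-eps*c*z)``.
    Accepts scalars or arrays.  Values below the reference voltage map to
    negative concentrations (noise below baseline); they are returned as-is
    so callers can flag or exclude them.
    """
    ref = cal.u0 if u0 is None else u0
    arr = _as_array(u)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(
            f"non-positive voltage at sample {bad[0]} (value {arr.flat[bad[0]]!r}); "
            "cannot take the logarithm"
        )
    c = np.log10(ref / arr) / (cal.epsilon * cal.path_z)
    return float(c) if np.isscalar(u) or np.ndim(u) == 0 else c


def voltage_from_concentration(c, cal: DensitometryCalibration, u0: float | None = None):
    """Detected voltage (V) for a dye concentration (mg/L): u0 * 10^(-eps*c*z)."""
    ref = cal.u0 if u0 is None else u0
    arr = _as_array(c)
    if np.any(arr < 0):
        raise ValueError("negative concentration has no transduced voltage")
    u = ref * np.power(10.0, -cal.epsilon * arr * cal.path_z)
    return float(u) if np.isscalar(c) or np.ndim(c) == 0 else u


def concentration_sigma(c, cal: DensitometryCalibration):
    """Standard deviation of the concentration estimate at concentration ``c``.

    Propagates the voltage noise ``delta_u`` through both the reference and
    the sample measurement:

        dc = ln(10)*delta_u/(eps*z*u0) * sqrt(1 + exp(2*ln(10)*eps*c*z))

    At ``c = 0`` both voltage terms contribute equally, giving the sqrt(2)
    floor; the error then grows exponentially with concentration because the
    transmitted voltage decays exponentially while its noise does not.
    """
    arr = _as_array(c)
    if np.any(arr < 0):
        raise ValueError("concentration must be >= 0")
    ez = cal.epsilon * cal.path_z
    dc = (LN10 * cal.delta_u / (ez * cal.u0)) * np.sqrt(1.0 + np.exp(2.0 * LN10 * ez * arr))
    return float(dc) if np.isscalar(c) or np.ndim(c) == 0 else dc


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    # reflect-pad so the peak location is not biased at the edges
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


def segment_trace(
    trace: IntensityTrace, params: SegmentationParams | None = None
) -> ClearanceSegmentation:
    """Detect baseline, injection arrival, recirculation peak and its end.

    The reference voltage u0 is the mean over the pre-injection window.
    Injection arrival t0 is the first sample whose absorbance exceeds
    ``k_threshold`` baseline noise SDs and stays above for ``sustain``
    samples.  The recirculation end t1 is found by fitting a line to the
    log-absorbance of the trailing ``anchor_frac`` of the post-peak record
    (the terminal exponential is exactly linear there) and extending it
    backwards towards the peak: t1 is the earliest sample from which every
    later sample still lies on that line within tolerance.  This exploits
    the slope kink between the recirculation flank and the elimination
    exponential.

    Raises
    ------
    NoInjectionError
        If no sustained departure from baseline exists.
    RecirculationEndNotFoundError
        If the record ends at/near the peak or shows no post-peak decay.
    """
    p = params or SegmentationParams()
    n = len(trace)
    if n < 60:
        raise ValueError(f"trace too short to segment ({n} samples, need >= 60)")
    u = trace.voltages
    t = trace.times

    n_init = min(p.baseline_init, n // 4)
    u0_init = float(np.mean(u[:n_init]))
    a_init = np.log10(u0_init / u)
    sd0 = float(np.std(a_init[:n_init]))
    thr = max(p.k_threshold * sd0, 1e-9)

    above = a_init > thr
    t0_idx = None
    run = 0
    for i in range(n_init, n):
        run = run + 1 if above[i] else 0
        if run >= p.sustain:
            t0_idx = i - p.sustain + 1
            break
    if t0_idx is None:
        raise NoInjectionError(
            f"no injection detected: absorbance never exceeded {thr:.3g} "
            f"for {p.sustain} consecutive samples"
        )

    b_stop = max(t0_idx - p.guard, 2)
    u0 = float(np.mean(u[:b_stop]))
    a = np.log10(u0 / u)
    logger.info("injection detected at t0 = %.4g min (sample %d), u0 = %.6g V", t[t0_idx], t0_idx, u0)

    a_smooth = _moving_average(a, p.smooth_window)
    post = a_smooth[t0_idx:]
    peaks, _ = signal.find_peaks(post, prominence=0.25 * float(np.max(post)))
    peak_idx = t0_idx + (int(peaks[0]) if peaks.size else int(np.argmax(post)))
    if peak_idx >= n - max(p.sustain, 10):
        raise RecirculationEndNotFoundError(
            "recirculation end not found: trace ends at or near the concentration peak"
        )
    logger.info("recirculation peak at %.4g min (sample %d)", t[peak_idx], peak_idx)

    # terminal-anchor fit on log-absorbance
    tail_start = peak_idx + int(np.ceil((n - peak_idx) * (1.0 - p.anchor_frac)))
    tail_start = min(tail_start, n - 10)
    a_tail = a[tail_start:]
    valid = a_tail > 0
    if valid.sum() < 10:
        raise RecirculationEndNotFoundError(
            "recirculation end not found: too few positive-absorbance samples after the peak"
        )
    y = np.log(a_tail[valid])
    x = t[tail_start:][valid]
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise RecirculationEndNotFoundError(
            "recirculation end not found: no post-peak decay (non-negative terminal slope)"
        )
    resid = y - (slope * x + intercept)
    half = max(len(resid) // 2, 5)
    sd_local = 1.4826 * float(np.median(np.abs(resid[:half] - np.median(resid[:half]))))
    tol = max(p.t1_sigma_mult * sd_local, p.t1_tol_floor)

    t1_idx = tail_start
    for i in range(tail_start - 1, peak_idx, -1):
        if a[i] <= 0:
            break
        if abs(np.log(a[i]) - (slope * t[i] + intercept)) > tol:
            break
        t1_idx = i
    logger.info("recirculation end at t1 = %.4g min (sample %d)", t[t1_idx], t1_idx)

    if n - t1_idx < 10:
        raise RecirculationEndNotFoundError(
            "recirculation end not found: fewer than 10 samples remain after t1"
        )
    return ClearanceSegmentation(
        baseline_window=(0, b_stop),
        t0=float(t[t0_idx]),
        peak_time=float(t[peak_idx]),
        t1=float(t[t1_idx]),
        elimination_window=(t1_idx, n),
        u0=u0,
    )


@dataclass(frozen=True)
class LinearizedElimination:
    """The double-log transform f(t) of the elimination phase.

    ``f`` is in percent and satisfies f(t1) = 0 by construction; its slope
    against ``times - t1`` is the PDR.  ``n_excluded`` counts samples whose
    absorbance was not positive (voltage at or above the baseline) and that
    were therefore dropped rather than clipped.
    """

    times: np.ndarray
    f: np.ndarray
    t1: float
    n_excluded: int


def linearize_elimination(
    trace: IntensityTrace,
    seg: ClearanceSegmentation,
    cal: DensitometryCalibration,
) -> LinearizedElimination:
    """Compute f(t) = -ln[A(t)/A(t1)] * 100% over the elimination window.

    Samples with non-positive absorbance (noise at or below baseline) are
    excluded and counted; clipping them instead would bias the slope.
    """
    i0, i1 = seg.elimination_window
    u = trace.voltages[i0:i1]
    t = trace.times[i0:i1]
    absb = np.log10(seg.u0 / u)
    a1 = absb[0]
    if a1 <= 0:
        raise InsufficientEliminationDataError(
            "absorbance at t1 is not positive; cannot anchor the log-linearization"
        )
    keep = absb > 0
    n_excl = int((~keep).sum())
    if n_excl:
        logger.info("excluded %d non-positive-absorbance samples from the elimination window", n_excl)
    if keep.sum() < 10:
        raise InsufficientEliminationDataError(
            f"insufficient elimination data: {int(keep.sum())} usable samples after "
            f"excluding {n_excl} (need >= 10)"
        )
    f = -np.log(absb[keep] / a1) * 100.0
    return LinearizedElimination(times=t[keep], f=f, t1=seg.t1, n_excluded=n_excl)


@dataclass(frozen=True)
class PDRResult:
    """Plasma disappearance rate with ordinary-least-squares diagnostics."""

    pdr: float
    c1: float | None
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.pdr):
            raise ValueError("PDR estimate is not finite")
        if not (-1e-9 <= self.r_squared <= 1.0 + 1e-9):
            raise ValueError(f"r_squared out of range: {self.r_squared}")


def estimate_pdr(lin: LinearizedElimination, c1: float | None = None) -> PDRResult:
    """PDR as the OLS slope of f(t) against (t - t1), in %/min."""
    if len(lin.f) < 10:
        raise InsufficientEliminationDataError("fewer than 10 points for the PDR fit")
    x = lin.times - lin.t1
    if np.ptp(x) <= 0 or np.var(x) == 0:
        raise ValueError("degenerate time axis: zero variance in elimination times")
    res = stats.linregress(x, lin.f)
    fitted = res.intercept + res.slope * x
    resid = lin.f - fitted
    dof = max(len(x) - 2, 1)
    rsq = 0.0 if np.allclose(np.var(lin.f), 0) else float(res.rvalue**2)
    if np.allclose(resid, 0, atol=1e-9 * max(1.0, float(np.max(np.abs(lin.f))))):
        rsq = 1.0
    out = PDRResult(
        pdr=float(res.slope),
        c1=c1,
        intercept=float(res.intercept),
        r_squared=rsq,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=len(x),
        n_excluded=lin.n_excluded,
    )
    logger.info("PDR = %.4g %%/min (r^2 = %.6g, n = %d)", out.pdr, out.r_squared, out.n_points)
    return out


def analyze_clearance(
    trace: IntensityTrace,
    cal: DensitometryCalibration,
    params: SegmentationParams | None = None,
) -> tuple[PDRResult, ClearanceSegmentation]:
    """Full densitometry pipeline: segment, linearize, fit, recover c1.

    c1 is the concentration at the detected t1, converted from the t1-sample
    voltage against the baseline-window reference.
    """
    seg = segment_trace(trace, params)
    lin = linearize_elimination(trace, seg, cal)
    u_t1 = float(trace.voltages[seg.elimination_window[0]])
    c1 = concentration_from_voltage(u_t1, cal, u0=seg.u0)
    return estimate_pdr(lin, c1=c1), seg


def nonlinear_pdr_crosscheck(
    trace: IntensityTrace,
    seg: ClearanceSegmentation,
    cal: DensitometryCalibration,
) -> float:
    """Diagnostic: PDR from a direct exponential fit of the concentration decay.

    Provided as an independent check of the log-linearized OLS estimate; the
    OLS estimate is the reported one.
    """
    i0, i1 = seg.elimination_window
    t = trace.times[i0:i1] - seg.t1
    c = concentration_from_voltage(trace.voltages[i0:i1], cal, u0=seg.u0)
    c1_guess = max(float(c[0]), 1e-12)

    def model(tt, c1, pdr):
        return c1 * np.exp(-0.01 * pdr * tt)

    popt, _ = optimize.curve_fit(model, t, c, p0=(c1_guess, 10.0), maxfev=10000)
    return float(popt[1])
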