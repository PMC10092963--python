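"""Synthetic sensor signals with known ground truth for both channels.

No public dataset of raw clearance or speckle records exists, and the
estimators cannot be validated on hardware here, so every stage is tested
by parameter recovery on simulated signals:

* ``simulate_clearance`` builds a densitometry voltage trace from a known
  (PDR, c1, t0, t1): zero dye before injection, a smooth log-normal
  recirculation bump peaking between t0 and t1, then the exponential
  elimination decay, transduced to voltage through the Beer-Lambert law and
  corrupted with additive white Gaussian voltage noise.

* ``simulate_speckle`` builds stationary Gaussian intensity records whose
  normalized autocorrelation is exactly the Gaussian decay
  exp(-(tau/tau_c)^2) with tau_c = 1/(K*v), using circulant spectral
  synthesis (white complex spectrum shaped by the square root of the target
  power spectral density), plus additive white noise at a stated
  fluctuation-to-noise power ratio.

* ``simulate_flow_sweep`` is the in-silico analogue of the microsphere
  capillary calibration: a grid of true velocities, ten replicates each,
  pushed through the full DLS pipeline and compared with truth.

All generators are pure functions of their scenario (seed included):
identical scenarios produce bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import dls
from .densitometry import (
    DensitometryCalibration,
    IntensityTrace,
    voltage_from_concentration,
)
from .dls import OpticalGeometry, SpeckleTrace
from .errors import HepaflowError, UnderResolvedSamplingError

logger = logging.getLogger(__name__)

__all__ = [
    "ClearanceScenario",
    "ClearanceTruth",
    "SpeckleScenario",
    "SpeckleTruth",
    "SweepPoint",
    "SweepReport",
    "DEFAULT_CALIBRATION",
    "simulate_clearance",
    "simulate_speckle",
    "simulate_flow_sweep",
]

#: ICG-like calibration used by default in simulations: extinction
#: 0.2 L/(mg cm) and a 1 cm transilluminated path give absorbance ~0.6 at a
#: typical post-distribution concentration of 3 mg/L, i.e. a quarter of the
#: reference voltage -- comfortably inside the measurable range.
DEFAULT_CALIBRATION = DensitometryCalibration(
    epsilon=0.2, path_z=1.0, u0=1.0, delta_u=1e-3
)

#: Minimum number of samples the expected correlation time must span.
MIN_SAMPLES_PER_TAU = 20


@dataclass(frozen=True)
class ClearanceScenario:
    """Ground-truth parameters of a simulated clearance test.

    Defaults describe a routine test: injection arriving at the finger
    1 min in, recirculation settled by 2.5 min, a peak 1.5x the mixed
    concentration, a 15 min record at 60 samples/min, and a relative
    voltage noise of 1e-3.
    """

    pdr_true: float = 20.0
    c1_true: float = 3.0
    t0: float = 1.0
    t1: float = 2.5
    peak_height_ratio: float = 1.5
    duration: float = 15.0
    sampling_rate: float = 60.0
    noise_rel: float = 1e-3
    seed: int = 0
    peak_position: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.t0 < self.t1 < self.duration):
            raise ValueError("need 0 < t0 < t1 < duration")
        if self.pdr_true <= 0:
            raise ValueError("pdr_true must be positive")
        if self.peak_height_ratio < 1:
            raise ValueError("peak_height_ratio must be >= 1")
        if not (0 < self.peak_position < 1):
            raise ValueError("peak_position must lie strictly between t0 and t1")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")


@dataclass(frozen=True)
class ClearanceTruth:
    """Ground truth accompanying a simulated clearance trace."""

    pdr_true: float
    c1_true: float
    t0: float
    t1: float
    peak_time: float
    u0: float
    concentration: np.ndarray


def _recirculation_bump(t: np.ndarray, s: ClearanceScenario) -> np.ndarray:
    """Unit-peak log-normal bump on (t0, inf), equal to 1/ratio at t1.

    The log-normal flank vanishes smoothly at t0 and its width is solved so
    the bump passes through c1 exactly at t1, where the exponential decay
    takes over.  Shown only schematically in real data; any smooth
    single-peak shape with these constraints would do.
    """
    span = s.t1 - s.t0
    mode = s.peak_position * span
    x = np.maximum(t - s.t0, 0.0)
    if s.peak_height_ratio == 1.0:
        return np.where(x > 0, 1.0, 0.0)
    w = abs(math.log(span / mode)) / math.sqrt(2.0 * math.log(s.peak_height_ratio))
    out = np.zeros_like(t)
    pos = x > 0
    out[pos] = np.exp(-(np.log(x[pos] / mode) ** 2) / (2.0 * w * w))
    return out


def simulate_clearance(
    s: ClearanceScenario,
    cal: DensitometryCalibration = DEFAULT_CALIBRATION,
) -> tuple[IntensityTrace, ClearanceTruth]:
    """Simulate a densitometry voltage trace with known (PDR, c1, t0, t1).

    Concentration is zero before t0, a log-normal recirculation bump of
    height ``peak_height_ratio * c1`` between t0 and t1 (with c(t1) = c1),
    and ``c1*exp(-0.01*PDR*(t - t1))`` after t1.  Voltage is the
    Beer-Lambert transduction plus white Gaussian noise of SD
    ``noise_rel * u0``.
    """
    n = int(round(s.duration * s.sampling_rate)) + 1
    t = np.arange(n) / s.sampling_rate
    c = np.where(
        t >= s.t1,
        s.c1_true * np.exp(-0.01 * s.pdr_true * (t - s.t1)),
        s.peak_height_ratio * s.c1_true * _recirculation_bump(t, s),
    )
    u_clean = voltage_from_concentration(c, cal)
    rng = np.random.default_rng(s.seed)
    u = u_clean + rng.normal(0.0, s.noise_rel * cal.u0, n) if s.noise_rel > 0 else u_clean
    # the trace type requires positive voltages; at realistic noise levels
    # the floor is never reached
    u = np.maximum(u, 1e-12 * cal.u0)
    trace = IntensityTrace(times=t, voltages=u, meta={"seed": s.seed, "synthetic": True})
    truth = ClearanceTruth(
        pdr_true=s.pdr_true,
        c1_true=s.c1_true,
        t0=s.t0,
        t1=s.t1,
        peak_time=s.t0 + s.peak_position * (s.t1 - s.t0),
        u0=cal.u0,
        concentration=c,
    )
    return trace, truth


@dataclass(frozen=True)
class SpeckleScenario:
    """Ground-truth parameters of a simulated speckle acquisition.

    Defaults follow the measurement protocol: 10 replicate records of
    0.2 s, a fluctuation-to-noise power ratio of 10, and the effective
    backscatter geometry (K ~= 4*pi/lambda) under which the correlation
    time spans ~17 us at 3 mm/s to ~1 ms at 0.05 mm/s.  The 2 MHz sampling
    default keeps the fastest correlation time above 20 samples.
    """

    velocity_true: float = 1.0
    geometry: OpticalGeometry = field(
        default_factory=OpticalGeometry.effective_backscatter
    )
    sampling_rate: float = 2.0e6
    duration: float = 0.2
    snr: float = 10.0
    n_replicates: int = 10
    seed: int = 0
    mean_intensity: float = 10.0

    def __post_init__(self) -> None:
        if self.velocity_true <= 0:
            raise ValueError("velocity_true must be positive")
        if self.duration * self.sampling_rate < 1024:
            raise ValueError("record must contain at least 1024 samples")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.snr <= 0:
            raise ValueError("snr must be positive (use math.inf for noiseless)")

    @property
    def tau_c(self) -> float:
        """Implied correlation time 1/(K*v), s."""
        return 1.0 / (self.geometry.coefficient_k * self.velocity_true)


@dataclass(frozen=True)
class SpeckleTruth:
    """Ground truth accompanying simulated speckle replicates."""

    velocity_true: float
    tau_c: float
    coefficient_k: float


def _gaussian_process(n: int, dt: float, tau_c: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance stationary Gaussian series with ACF exp(-(tau/tau_c)^2).

    Circulant spectral synthesis: the target autocovariance is laid out on a
    circular grid of power-of-two length >= 2n, its eigenvalues obtained by
    FFT, and a white complex-Gaussian spectrum shaped by their square root
    is transformed back.  The real part is an exact sample of the target
    process (the Gaussian ACF decays far inside the embedding, so the
    circulant eigenvalues are non-negative up to rounding).
    """
    m = 1 << int(np.ceil(np.log2(2 * n)))
    k = np.arange(m)
    circ_lag = np.minimum(k, m - k) * dt
    r = np.exp(-((circ_lag / tau_c) ** 2))
    lam = np.fft.fft(r).real
    lam = np.maximum(lam, 0.0)
    xi = rng.normal(size=m, scale=math.sqrt(0.5)) + 1j * rng.normal(size=m, scale=math.sqrt(0.5))
    spectrum = np.sqrt(lam / m) * xi
    x = math.sqrt(2.0) * np.fft.fft(spectrum).real
    return x[:n]


def simulate_speckle(s: SpeckleScenario) -> tuple[list[SpeckleTrace], SpeckleTruth]:
    """Simulate independent replicate speckle records at a known velocity.

    Each replicate is a stationary Gaussian process with normalized ACF
    exp(-(tau/tau_c)^2), tau_c = 1/(K*v), riding on a constant mean
    intensity, plus additive white Gaussian noise whose power is
    fluctuation power / snr.
    """
    tau_c = s.tau_c
    min_rate = MIN_SAMPLES_PER_TAU / tau_c
    if tau_c * s.sampling_rate < MIN_SAMPLES_PER_TAU:
        raise UnderResolvedSamplingError(
            f"correlation time {tau_c:.3g} s spans fewer than {MIN_SAMPLES_PER_TAU} samples "
            f"at {s.sampling_rate:.3g} Hz; sample at >= {min_rate:.3g} Hz"
        )
    n = int(round(s.duration * s.sampling_rate))
    dt = 1.0 / s.sampling_rate
    noise_sd = 0.0 if math.isinf(s.snr) else math.sqrt(1.0 / s.snr)
    seeds = np.random.SeedSequence(s.seed).spawn(s.n_replicates)
    traces: list[SpeckleTrace] = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        x = _gaussian_process(n, dt, tau_c, rng)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, n)
        traces.append(
            SpeckleTrace(
                samples=s.mean_intensity + x,
                sampling_rate=s.sampling_rate,
                meta={"replicate": i, "seed": s.seed, "synthetic": True},
            )
        )
    truth = SpeckleTruth(
        velocity_true=s.velocity_true,
        tau_c=tau_c,
        coefficient_k=s.geometry.coefficient_k,
    )
    return traces, truth


@dataclass(frozen=True)
class SweepPoint:
    """Recovery result at one true velocity of a flow sweep."""

    velocity_true: float
    mean_velocity: float | None
    sd_velocity: float | None
    relative_error: float | None
    n_replicates_used: int
    error: str | None = None


@dataclass(frozen=True)
class SweepReport:
    """In-silico flow-sweep calibration report (mirrors the capillary protocol)."""

    points: tuple[SweepPoint, ...]

    @property
    def relative_errors(self) -> np.ndarray:
        return np.array(
            [p.relative_error for p in self.points if p.relative_error is not None]
        )

    @property
    def max_relative_error(self) -> float:
        return float(np.max(self.relative_errors))

    @property
    def mean_relative_error(self) -> float:
        return float(np.mean(self.relative_errors))


def simulate_flow_sweep(
    velocities: list[float] | np.ndarray,
    base: SpeckleScenario = SpeckleScenario(),
) -> SweepReport:
    """Run the DLS pipeline over a grid of true velocities.

    The in-silico analogue of pumping a microsphere suspension through a
    capillary at a ladder of set flow rates: for each velocity,
    ``base.n_replicates`` records are synthesized and the full
    ACF -> tau_c -> velocity chain applied; the report carries per-velocity
    mean, SD and relative error against truth.  Pipeline failures at one
    velocity are recorded without aborting the sweep.  Per-velocity seeds
    are derived deterministically from ``base.seed``.
    """
    velocities = np.asarray(velocities, dtype=float)
    if np.any(velocities <= 0):
        raise ValueError("all sweep velocities must be positive")
    child_seeds = np.random.SeedSequence(base.seed).spawn(len(velocities))
    points: list[SweepPoint] = []
    for v, ss in zip(velocities, child_seeds):
        scen = replace(base, velocity_true=float(v), seed=int(ss.generate_state(1)[0] % (2**31)))
        try:
            traces, _ = simulate_speckle(scen)
            est = dls.aggregate_replicates(traces, scen.geometry)
        except HepaflowError as exc:
            logger.warning("sweep point v=%.4g mm/s failed: %s", v, exc)
            points.append(
                SweepPoint(
                    velocity_true=float(v),
                    mean_velocity=None,
                    sd_velocity=None,
                    relative_error=None,
                    n_replicates_used=0,
                    error=str(exc),
                )
            )
            continue
        rel = abs(est.mean_velocity - v) / v
        points.append(
            SweepPoint(
                velocity_true=float(v),
                mean_velocity=est.mean_velocity,
                sd_velocity=est.sd_velocity,
                relative_error=float(rel),
                n_replicates_used=est.n_replicates,
            )
        )
    return SweepReport(points=tuple(points))
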