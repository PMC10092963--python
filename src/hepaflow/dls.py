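"""Dynamic light scattering: flow velocity from speckle-intensity records.

Coherent light scattered by moving red blood cells produces a speckle
intensity that decorrelates on a time scale inversely proportional to the
scatterer velocity.  The pipeline is:

1. normalized intensity autocorrelation G(tau) via the Wiener-Khinchin
   theorem (FFT of the mean-subtracted signal's periodogram, zero-padded to
   avoid circular wrap-around),
2. correlation time tau_c read off at the 1/e level of G (first downward
   crossing, linearly interpolated),
3. velocity v = 1 / (K * tau_c), with the geometry coefficient
   K = [omega^2 + sigma^2 * dx^2]^(-1/2), dx = lambda*l/(pi*omega).

Ten replicate records are acquired per measurement and the per-replicate
velocities averaged, because capillary flow shows spontaneous second-scale
accelerations that a single short record would alias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CorrelationTimeNotReachedError, DegenerateTraceError, HepaflowError

logger = logging.getLogger(__name__)

__all__ = [
    "OpticalGeometry",
    "SpeckleTrace",
    "AutocorrelationResult",
    "VelocityEstimate",
    "autocorrelation_fft",
    "correlation_time",
    "coefficient_k",
    "velocity_from_tau",
    "estimate_velocity",
    "aggregate_replicates",
]

#: Default laser wavelength of the sensor head, nm.
DEFAULT_WAVELENGTH_NM = 650.0


@dataclass(frozen=True)
class OpticalGeometry:
    """Parameters of the scattering scheme and its derived coefficient.

    ``wavelength_nm`` is the laser wavelength (nm), ``distance_l_cm`` the
    scattering-volume-to-detector distance (cm), ``beam_waist_mm`` the beam
    radius omega at the sample (mm) and ``sigma`` the dimensionless
    wavefront parameter (sigma = l/rho + 1 for a wavefront curvature radius
    rho; a plane wave has sigma = 1).

    The speckle scale ``delta_x = lambda*l/(pi*omega)`` (mm) and the
    decorrelation coefficient ``K = [omega^2 + sigma^2*delta_x^2]^(-1/2)``
    (mm^-1) are always derived from these primitives, never stored.
    """

    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    distance_l_cm: float = 7.5
    beam_waist_mm: float = 0.5
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.distance_l_cm <= 0:
            raise ValueError("detector distance must be positive")
        if self.beam_waist_mm <= 0:
            raise ValueError("beam waist must be positive")
        if self.sigma < 1:
            raise ValueError("sigma is l/rho + 1 >= 1")

    @classmethod
    def from_rho(
        cls,
        wavelength_nm: float,
        distance_l_cm: float,
        beam_waist_mm: float,
        rho_cm: float,
    ) -> "OpticalGeometry":
        """Build a geometry from the wavefront curvature radius rho (cm)."""
        if rho_cm <= 0:
            raise ValueError("wavefront curvature radius must be positive")
        return cls(wavelength_nm, distance_l_cm, beam_waist_mm, distance_l_cm / rho_cm + 1.0)

    @classmethod
    def effective_backscatter(cls, wavelength_nm: float = DEFAULT_WAVELENGTH_NM) -> "OpticalGeometry":
        """Effective geometry with decorrelation at the wavevector scale.

        With macroscopic bench values (mm beam waist, cm detector distance)
        the coefficient K is of order 1 mm^-1, which at mm/s velocities
        would imply correlation times of seconds.  Observed speckle
        decorrelation in backscattering happens at the wavevector scale
        1/q = lambda/(4*pi) instead (microsecond correlation times at mm/s),
        so simulations default to an effective beam waist of lambda/(4*pi)
        with a negligible far-field speckle term, giving
        K ~= 4*pi/lambda ~= 1.93e4 mm^-1 at 650 nm.
        """
        lam_mm = wavelength_nm * 1e-6
        omega = lam_mm / (4.0 * math.pi)
        # distance chosen so the sigma*delta_x term is << omega
        return cls(wavelength_nm, distance_l_cm=1e-7, beam_waist_mm=omega, sigma=1.0)

    @property
    def delta_x_mm(self) -> float:
        """Speckle scale lambda*l/(pi*omega), mm."""
        lam_mm = self.wavelength_nm * 1e-6
        l_mm = self.distance_l_cm * 10.0
        return lam_mm * l_mm / (math.pi * self.beam_waist_mm)

    @property
    def coefficient_k(self) -> float:
        """Decorrelation coefficient K = [omega^2 + sigma^2*dx^2]^(-1/2), mm^-1."""
        return 1.0 / math.hypot(self.beam_waist_mm, self.sigma * self.delta_x_mm)


def coefficient_k(geom: OpticalGeometry) -> float:
    """Functional alias for :attr:`OpticalGeometry.coefficient_k` (mm^-1)."""
    return geom.coefficient_k


@dataclass
class SpeckleTrace:
    """A single speckle-intensity record (arbitrary units, photocurrent-proportional)."""

    samples: np.ndarray
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.sampling_rate


@dataclass
class AutocorrelationResult:
    """Normalized intensity autocorrelation G(tau) with G(0) = 1."""

    lags: np.ndarray
    g_normalized: np.ndarray
    tau_c: float | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g_normalized = np.asarray(self.g_normalized, dtype=float)
        if self.lags.shape != self.g_normalized.shape:
            raise ValueError("lags and g_normalized must have the same shape")
        if abs(self.g_normalized[0] - 1.0) > 1e-9:
            raise ValueError("g_normalized must start at 1")
        if self.tau_c is not None and not (self.lags[0] <= self.tau_c <= self.lags[-1]):
            raise ValueError("tau_c must lie within the lag span")


def autocorrelation_fft(trace: SpeckleTrace, max_lag_frac: float = 0.1) -> AutocorrelationResult:
    """Normalized autocorrelation via the Wiener-Khinchin theorem.

    The mean is subtracted, the signal zero-padded to at least twice its
    length (so the circular correlation of the padded signal equals the
    linear one), the periodogram inverse-transformed and the result divided
    by N (the biased estimator, which is positive semidefinite) and by the
    lag-0 value.  Lags up to ``max_lag_frac`` of the record are retained;
    longer lags are too poorly averaged to be useful.
    """
    x = trace.samples
    n = len(x)
    if n < 1024:
        raise ValueError(f"need at least 1024 samples, got {n}")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        raise DegenerateTraceError("degenerate trace: zero variance, no correlation structure")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / n
    m = max(int(n * max_lag_frac), 2)
    g = acov[:m] / acov[0]
    lags = np.arange(m) / trace.sampling_rate
    return AutocorrelationResult(lags=lags, g_normalized=g)


def correlation_time(acf: AutocorrelationResult) -> float:
    """Correlation time: first downward crossing of the 1/e level of G.

    Located by linear interpolation between the two bracketing lags; any
    noise-induced later re-crossings are ignored.
    """
    g = acf.g_normalized
    level = 1.0 / math.e
    below = np.flatnonzero(g < level)
    if below.size == 0:
        raise CorrelationTimeNotReachedError(
            "record too short for correlation time: G(tau) never fell below 1/e "
            f"within the retained {acf.lags[-1]:.3g} s lag span"
        )
    k = int(below[0])
    if k == 0:
        raise CorrelationTimeNotReachedError(
            "correlation time unresolved: G fell below 1/e before the first lag"
        )
    g_hi, g_lo = g[k - 1], g[k]
    frac = (g_hi - level) / (g_hi - g_lo)
    tau_c = float(acf.lags[k - 1] + frac * (acf.lags[k] - acf.lags[k - 1]))
    return tau_c


def velocity_from_tau(tau_c: float, geom: OpticalGeometry) -> float:
    """Scatterer velocity v = 1/(K * tau_c), mm/s."""
    if tau_c <= 0:
        raise ValueError("correlation time must be positive")
    return 1.0 / (geom.coefficient_k * tau_c)


def estimate_velocity(trace: SpeckleTrace, geom: OpticalGeometry) -> tuple[float, float]:
    """Full single-record chain: ACF -> tau_c -> velocity.  Returns (v, tau_c)."""
    acf = autocorrelation_fft(trace)
    tau_c = correlation_time(acf)
    return velocity_from_tau(tau_c, geom), tau_c


@dataclass(frozen=True)
class VelocityEstimate:
    """Replicate-aggregated flow-velocity estimate (mm/s)."""

    velocities: tuple[float, ...]
    mean_velocity: float
    sd_velocity: float
    n_replicates: int
    tau_c_values: tuple[float, ...] = ()
    n_failed: int = 0
    failures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_replicates != len(self.velocities):
            raise ValueError("n_replicates inconsistent with the velocity list")
        if any(v <= 0 for v in self.velocities):
            raise ValueError("all velocities must be positive")


def aggregate_replicates(
    traces: list[SpeckleTrace], geom: OpticalGeometry
) -> VelocityEstimate:
    """Velocity from a set of replicate records: per-record chain, then mean/SD.

    Records for which the correlation time cannot be extracted are dropped
    and counted; if every record fails, the per-record causes are collected
    into a single error.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 replicate records")
    rates = {t.sampling_rate for t in traces}
    if len(rates) > 1:
        raise ValueError(f"replicates must share one sampling rate, got {sorted(rates)}")
    velocities: list[float] = []
    taus: list[float] = []
    failures: list[str] = []
    for i, tr in enumerate(traces):
        try:
            v, tau = estimate_velocity(tr, geom)
        except HepaflowError as exc:
            failures.append(f"replicate {i}: {exc}")
            logger.warning("dropping replicate %d: %s", i, exc)
            continue
        velocities.append(v)
        taus.append(tau)
    if not velocities:
        raise CorrelationTimeNotReachedError(
            "all replicates failed velocity extraction:\n" + "\n".join(failures)
        )
    arr = np.array(velocities)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return VelocityEstimate(
        velocities=tuple(velocities),
        mean_velocity=float(arr.mean()),
        sd_velocity=sd,
        n_replicates=len(velocities),
        tau_c_values=tuple(taus),
        n_failed=len(failures),
        failures=tuple(failures),
    )
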