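"""Per-point flow statistics and spectral diagnostics for probe velocity records.

Operates on uniformly sampled three-component (u, v, w) wind records at a
single point.  Provides the acceptance-cone filter used by multi-hole
pressure probes, mean/turbulence statistics, Welch power spectra, log-log
spectral-slope fits, and the longitudinal integral length scale via the
frozen-turbulence hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ValidationError

__all__ = [
    "VelocityTimeSeries",
    "FlowSampleStats",
    "SpectrumEstimate",
    "cone_filter",
    "point_statistics",
    "power_spectrum",
    "spectral_slope",
    "integral_length_scale",
]


@dataclass(frozen=True)
class VelocityTimeSeries:
    """Wind velocity record at a point: time (s) and u/v/w components (m/s).

    ``t`` must be strictly increasing and all values finite.  A uniform time
    base is required by the spectral operations; cone-filtered series may be
    non-uniform (samples removed) and are accepted here but rejected by
    ``power_spectrum`` and ``integral_length_scale``.
    """

    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    sample_rate: float

    def __post_init__(self):
        for name in ("t", "u", "v", "w"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.t)
        if not (len(self.u) == len(self.v) == len(self.w) == n):
            raise ValidationError("t, u, v, w must have equal lengths")
        if n == 0:
            raise ValidationError("empty velocity series")
        for name in ("t", "u", "v", "w"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite values in '{name}'")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("t must be strictly increasing")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def is_uniform(self) -> bool:
        if len(self.t) < 2:
            return True
        dt = np.diff(self.t)
        return bool(np.allclose(dt, 1.0 / self.sample_rate, rtol=0, atol=1e-6))

    def require_uniform(self) -> None:
        if not self.is_uniform:
            raise ValidationError("operation requires a uniformly sampled series")


@dataclass(frozen=True)
class FlowSampleStats:
    """Mean-flow and turbulence statistics of one point sample."""

    mean_u: float
    mean_v: float
    mean_w: float
    mean_speed: float
    pitch_angle: float  # degrees above horizontal
    turbulence_intensity: float  # std(u)/mean(u), fraction
    n_samples: int
    n_rejected: int = 0

    def __post_init__(self):
        if self.n_rejected > self.n_samples + self.n_rejected:
            raise ValidationError("n_rejected exceeds total sample count")
        if self.turbulence_intensity < 0:
            raise ValidationError("turbulence_intensity must be >= 0")
        if not -90.0 <= self.pitch_angle <= 90.0:
            raise ValidationError("pitch_angle must lie in [-90, 90] degrees")


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided power spectral density estimate with estimator metadata."""

    frequency: np.ndarray  # Hz, positive ascending
    density: np.ndarray  # (m/s)^2 / Hz
    segment_length: int
    overlap: float = 0.5
    window: str = "hann"

    def __post_init__(self):
        object.__setattr__(self, "frequency", np.asarray(self.frequency, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if len(self.frequency) != len(self.density):
            raise ValidationError("frequency and density lengths differ")
        if np.any(self.frequency <= 0) or np.any(np.diff(self.frequency) <= 0):
            raise ValidationError("frequencies must be positive and ascending")
        if np.any(self.density < 0):
            raise ValidationError("spectral densities must be >= 0")


def cone_filter(series: VelocityTimeSeries, half_angle: float = 45.0):
    """Reject samples whose velocity vector deviates from the probe axis (+x)
    by more than ``half_angle`` degrees.

    Returns ``(filtered_series, n_rejected)``.  Samples exactly on the cone
    boundary are retained.  Zero-magnitude samples have no defined direction
    and are retained.
    """
    if half_angle <= 0:
        raise ValidationError("half_angle must be positive")
    mag = np.sqrt(series.u**2 + series.v**2 + series.w**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosdev = np.where(mag > 0, series.u / np.where(mag > 0, mag, 1.0), 1.0)
    deviation = np.degrees(np.arccos(np.clip(cosdev, -1.0, 1.0)))
    keep = deviation <= half_angle
    n_rejected = int(np.sum(~keep))
    if n_rejected == 0:
        return series, 0
    if not np.any(keep):
        raise ValidationError("cone filter rejected every sample")
    out = VelocityTimeSeries(
        t=series.t[keep],
        u=series.u[keep],
        v=series.v[keep],
        w=series.w[keep],
        sample_rate=series.sample_rate,
    )
    return out, n_rejected


def point_statistics(series: VelocityTimeSeries, n_rejected: int = 0) -> FlowSampleStats:
    """Mean components, resultant speed, pitch angle and longitudinal TI.

    Pitch angle is computed from the *mean* components,
    ``atan2(mean_w, mean_u)``, not as the mean of instantaneous angles.
    Turbulence intensity is the longitudinal definition ``std(u)/mean(u)``.
    """
    mean_u = float(np.mean(series.u))
    mean_v = float(np.mean(series.v))
    mean_w = float(np.mean(series.w))
    if mean_u <= 0:
        raise ValidationError("mean(u) must be positive to define turbulence intensity")
    ti = float(np.std(series.u) / mean_u)
    return FlowSampleStats(
        mean_u=mean_u,
        mean_v=mean_v,
        mean_w=mean_w,
        mean_speed=float(np.sqrt(mean_u**2 + mean_v**2 + mean_w**2)),
        pitch_angle=float(np.degrees(np.arctan2(mean_w, mean_u))),
        turbulence_intensity=ti,
        n_samples=len(series),
        n_rejected=int(n_rejected),
    )


def _component(series: VelocityTimeSeries, component: str) -> np.ndarray:
    if component not in ("u", "v", "w"):
        raise ValidationError(f"unknown component '{component}'")
    return getattr(series, component)


def power_spectrum(
    series: VelocityTimeSeries,
    component: str = "u",
    segment_seconds: float = 8.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectrumEstimate:
    """One-sided averaged modified-periodogram (Welch) PSD estimate.

    Defaults: Hann window, 50 % overlap, 8 s segments (long enough that the
    sub-resolution low-frequency tail of atmospheric-like spectra stays
    below a few percent of the variance).  The series mean is
    removed per segment, so the integral of the density over frequency
    approximates the component's fluctuation variance (Parseval).
    """
    series.require_uniform()
    x = _component(series, component)
    nperseg = int(round(segment_seconds * series.sample_rate))
    if nperseg < 2:
        raise ValidationError("segment length must contain at least 2 samples")
    if len(x) < 2 * nperseg:
        raise ValidationError(
            f"series too short: need >= {2 * nperseg} samples, got {len(x)}"
        )
    freq, psd = signal.welch(
        x,
        fs=series.sample_rate,
        window=window,
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
    )
    # drop the zero-frequency bin; densities are defined for f > 0
    return SpectrumEstimate(
        frequency=freq[1:],
        density=psd[1:],
        segment_length=nperseg,
        overlap=overlap,
        window=window,
    )


def spectral_slope(spectrum: SpectrumEstimate, band: tuple[float, float]) -> float:
    """Least-squares slope of log10(density) vs log10(frequency) over a band."""
    f_lo, f_hi = band
    if not f_lo < f_hi:
        raise ValidationError("band must satisfy f_lo < f_hi")
    if f_lo < spectrum.frequency[0] or f_hi > spectrum.frequency[-1]:
        raise ValidationError("band lies outside the spectrum support")
    mask = (spectrum.frequency >= f_lo) & (spectrum.frequency <= f_hi)
    if int(np.sum(mask)) < 5:
        raise ValidationError("fewer than 5 frequency bins in fitting band")
    dens = spectrum.density[mask]
    if np.any(dens <= 0):
        raise ValidationError("zero spectral density inside fitting band")
    slope, _ = np.polyfit(np.log10(spectrum.frequency[mask]), np.log10(dens), 1)
    return float(slope)


def integral_length_scale(series: VelocityTimeSeries) -> float:
    """Longitudinal integral length scale via Taylor's frozen-turbulence hypothesis.

    ``L = mean(u) * integral of the u-fluctuation autocorrelation up to its
    first zero crossing``.  The crossing point is located by linear
    interpolation between the last positive and first negative lag.
    """
    series.require_uniform()
    mean_u = float(np.mean(series.u))
    if mean_u <= 0:
        raise ValidationError("mean(u) must be positive")
    fluct = series.u - mean_u
    var = float(np.mean(fluct**2))
    if var == 0:
        raise ValidationError("zero variance: integral length scale undefined")
    n = len(fluct)
    # biased autocovariance via FFT (O(n log n))
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(fluct, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / n
    rho = acov / acov[0]
    dt = 1.0 / series.sample_rate
    below = np.nonzero(rho < 0)[0]
    if len(below) == 0:
        timescale = float(np.trapezoid(rho, dx=dt))
    else:
        k = int(below[0])  # first negative lag; rho[k-1] >= 0
        timescale = float(np.trapezoid(rho[:k], dx=dt))
        # add the sliver between lag k-1 and the interpolated zero crossing
        frac = rho[k - 1] / (rho[k - 1] - rho[k])
        timescale += 0.5 * rho[k - 1] * frac * dt
    return mean_u * timescale
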