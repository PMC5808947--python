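"""Static-mode branch: breathing waveform extraction and rate estimation.

The breathing chest modulates the echo phase by well under one Doppler bin,
so the spectrogram trace itself stays in the zero-Doppler bin.  The
micro-Doppler statistic Psi(n) recovers the sub-bin motion as the
centre-weighted asymmetry of each frame's Doppler profile: bins above zero
Doppler get positive weight, bins below get negative weight, and the weight
magnitude grows linearly with distance from the centre.  Psi(n) is positive
while the chest moves toward the antenna (inhale) and negative during
exhale, i.e. it tracks chest-wall *velocity*; integrating it reconstructs a
displacement waveform comparable with a chest-belt reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_coeffs, savgol_filter
from scipy.stats import pearsonr

from .errors import DataError, ParameterError
from .radar import DopplerSpectrogram

__all__ = [
    "MicroDopplerSeries",
    "SGFilterSpec",
    "BreathingEstimate",
    "micro_doppler_weights",
    "extract_micro_doppler",
    "sg_smooth",
    "to_displacement",
    "estimate_rate",
    "evaluate_against_reference",
    "analyze_breathing",
]


@dataclass
class MicroDopplerSeries:
    """Per-frame asymmetry statistic Psi(n) -- the raw breathing waveform."""

    psi: np.ndarray
    frame_times_s: np.ndarray
    weights: np.ndarray | None = None
    smoothed: bool = False
    kind: str = "velocity"  # velocity (raw Psi) or displacement (integrated)

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if len(self.psi) != len(self.frame_times_s):
            raise ParameterError("psi and frame_times_s lengths differ")

    @property
    def frame_rate_hz(self) -> float:
        if len(self.frame_times_s) > 1:
            return 1.0 / float(np.median(np.diff(self.frame_times_s)))
        return 1.0

    @property
    def duration_s(self) -> float:
        if len(self.frame_times_s) < 2:
            return 0.0
        return float(self.frame_times_s[-1] - self.frame_times_s[0])


@dataclass(frozen=True)
class SGFilterSpec:
    """Savitzky-Golay smoother: moving least-squares polynomial fit.

    ``window_s`` is converted to an odd sample count 2M+1 at the series'
    frame rate; the fitted polynomial order is ``poly_order``.
    """

    window_s: float = 2.0
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ParameterError("window_s must be positive")
        if self.poly_order < 0:
            raise ParameterError("poly_order must be >= 0")

    def window_samples(self, frame_rate_hz: float) -> int:
        w = int(round(self.window_s * frame_rate_hz))
        if w % 2 == 0:
            w += 1
        # The window must over-determine the polynomial fit.
        return max(w, self.poly_order + 1 + ((self.poly_order + 1) % 2 == 0))

    def coefficients(self, frame_rate_hz: float) -> np.ndarray:
        """Convolution coefficients h; they sum to 1 (constants are preserved)."""
        w = self.window_samples(frame_rate_hz)
        if self.poly_order >= w:
            raise ParameterError("poly_order must be smaller than the window length")
        return savgol_coeffs(w, self.poly_order)


@dataclass
class BreathingEstimate:
    """FFT breathing-rate estimate plus the waveform it came from."""

    rate_bpm: float
    waveform: MicroDopplerSeries
    search_band_bpm: tuple[float, float]
    valid: bool
    r_value: float | None = None
    mse: float | None = None
    psi_raw: MicroDopplerSeries | None = None
    belt_resampled: np.ndarray | None = None

    def __post_init__(self) -> None:
        lo, hi = self.search_band_bpm
        if self.valid and not (lo <= self.rate_bpm <= hi):
            raise ParameterError("a valid rate must lie within the search band")


# ---------------------------------------------------------------------------
# Micro-Doppler extraction


def micro_doppler_weights(num_bins: int) -> np.ndarray:
    """Centre-weighted antisymmetric bin weights.

    For an odd number of Doppler bins (ascending axis) the weight of bin i is
    ``i - centre``: zero at zero Doppler, +1, +2, ... above, -1, -2, ...
    below.  This is the ceil(j/2 - i) ramp of the asymmetry statistic
    re-centred so that a Doppler profile symmetric about zero scores exactly
    zero.
    """
    if num_bins < 1:
        raise ParameterError("num_bins must be >= 1")
    center = (num_bins - 1) / 2.0
    return np.arange(num_bins) - center


def extract_micro_doppler(spec: DopplerSpectrogram) -> MicroDopplerSeries:
    """Psi(n) = sum_i D[i, n] * w_i -- linear in the spectrogram."""
    if spec.num_frames == 0:
        raise DataError("empty spectrogram")
    w = micro_doppler_weights(len(spec.doppler_axis_hz))
    psi = w @ spec.values
    return MicroDopplerSeries(psi=psi, frame_times_s=spec.frame_times_s.copy(), weights=w)


def sg_smooth(series: MicroDopplerSeries, spec: SGFilterSpec | None = None) -> MicroDopplerSeries:
    """Savitzky-Golay smoothing of Psi(n).

    Polynomials of degree <= poly_order are reproduced exactly; the first and
    last half-windows are handled by evaluating the polynomial fitted to the
    edge window (``mode='interp'``).
    """
    spec = spec or SGFilterSpec()
    w = spec.window_samples(series.frame_rate_hz)
    if w >= len(series.psi):
        raise ParameterError(
            f"SG window of {w} samples does not fit a series of {len(series.psi)}"
        )
    if spec.poly_order >= w:
        raise ParameterError("poly_order must be smaller than the window length")
    sm = savgol_filter(series.psi, w, spec.poly_order, mode="interp")
    return MicroDopplerSeries(
        psi=sm,
        frame_times_s=series.frame_times_s.copy(),
        weights=series.weights,
        smoothed=True,
        kind=series.kind,
    )


def to_displacement(series: MicroDopplerSeries, highpass_s: float = 10.0) -> MicroDopplerSeries:
    """Integrate the velocity-like Psi(n) into a displacement-like waveform.

    Cumulative trapezoid integration followed by removal of the slow trend
    (centred moving mean over ``highpass_s``) that integration of noise and
    any bias would otherwise accumulate.
    """
    if len(series.psi) < 2:
        raise DataError("need at least two samples to integrate")
    disp = cumulative_trapezoid(series.psi, series.frame_times_s, initial=0.0)
    n = max(int(round(highpass_s * series.frame_rate_hz)), 1)
    if n > 1:
        disp = disp - uniform_filter1d(disp, size=n, mode="nearest")
    disp = disp - disp.mean()
    return MicroDopplerSeries(
        psi=disp,
        frame_times_s=series.frame_times_s.copy(),
        weights=series.weights,
        smoothed=series.smoothed,
        kind="displacement",
    )


# ---------------------------------------------------------------------------
# Rate estimation


def estimate_rate(
    series: MicroDopplerSeries,
    band_bpm: tuple[float, float] = (6.0, 30.0),
) -> BreathingEstimate:
    """Breathing rate as the argmax of the zero-padded magnitude spectrum.

    The series is mean-removed, Hann-windowed and zero-padded (16x) before
    the FFT; the peak is searched inside ``band_bpm``.  The estimate is
    flagged invalid when the series is constant or the in-band spectrum is
    flat (peak below twice the in-band median).
    """
    lo, hi = band_bpm
    if not 0 < lo < hi:
        raise ParameterError("band_bpm must satisfy 0 < lo < hi")
    n = len(series.psi)
    if n < 4:
        raise ParameterError("series too short for rate estimation")
    if series.duration_s < 2.0 * 60.0 / lo:
        raise ParameterError(
            f"series of {series.duration_s:g} s is shorter than two periods at {lo:g} bpm"
        )
    fs = series.frame_rate_hz
    x = series.psi - series.psi.mean()
    if np.std(x) == 0:
        return BreathingEstimate(
            rate_bpm=float("nan"), waveform=series, search_band_bpm=band_bpm, valid=False
        )
    win = np.hanning(n)
    nfft = next_fast_len(16 * n)
    mag = np.abs(rfft(x * win, nfft))
    freqs = rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= lo / 60.0) & (freqs <= hi / 60.0)
    if not np.any(band):
        raise ParameterError("search band contains no spectral bins")
    mag_band = mag[band]
    k = int(np.argmax(mag_band))
    peak = mag_band[k]
    rate = float(freqs[band][k] * 60.0)
    valid = bool(peak > 0 and peak > 2.0 * np.median(mag_band))
    return BreathingEstimate(
        rate_bpm=rate if valid else float("nan"),
        waveform=series,
        search_band_bpm=band_bpm,
        valid=valid,
    )


# ---------------------------------------------------------------------------
# Reference-belt evaluation


def evaluate_against_reference(
    wave: MicroDopplerSeries,
    belt: np.ndarray,
    belt_rate_hz: float,
    belt_start_s: float = 0.0,
) -> tuple[float, float]:
    """Pearson R and MSE between the radar waveform and a chest-belt trace.

    The radar waveform is resampled down to the belt rate over the
    overlapping time support and the belt is normalized to the radar
    waveform's scale before computing the two statistics.
    """
    belt = np.asarray(belt, dtype=float)
    if belt_rate_hz <= 0:
        raise ParameterError("belt_rate_hz must be positive")
    if len(belt) < 2 or len(wave.psi) < 2:
        raise DataError("need at least two samples in both waveforms")
    belt_t = belt_start_s + np.arange(len(belt)) / belt_rate_hz
    t_lo = max(wave.frame_times_s[0], belt_t[0])
    t_hi = min(wave.frame_times_s[-1], belt_t[-1])
    if t_hi <= t_lo:
        raise DataError("radar waveform and belt reference do not overlap in time")
    sel = (belt_t >= t_lo) & (belt_t <= t_hi)
    if np.count_nonzero(sel) < 3:
        raise DataError("fewer than three overlapping belt samples")
    radar = np.interp(belt_t[sel], wave.frame_times_s, wave.psi)
    b = belt[sel]
    sigma_b = np.std(b)
    if sigma_b == 0:
        b_norm = np.full_like(b, radar.mean())
        r = 0.0
    else:
        b_norm = (b - b.mean()) / sigma_b * np.std(radar) + radar.mean()
        if np.std(radar) == 0:
            r = 0.0
        else:
            r = float(pearsonr(radar, b_norm).statistic)
    mse = float(np.mean((radar - b_norm) ** 2))
    return r, mse


def analyze_breathing(
    spec: DopplerSpectrogram,
    sg: SGFilterSpec | None = None,
    band_bpm: tuple[float, float] = (6.0, 30.0),
    belt: np.ndarray | None = None,
    belt_rate_hz: float = 2.0,
    belt_start_s: float = 0.0,
) -> BreathingEstimate:
    """Full static-mode chain: Psi -> SG smoothing -> rate (+ belt R/MSE).

    The rate is estimated from the smoothed Psi(n); the belt comparison uses
    the integrated (displacement-like) waveform, matching the displacement
    the belt sensor reports.
    """
    raw = extract_micro_doppler(spec)
    smooth = sg_smooth(raw, sg)
    est = estimate_rate(smooth, band_bpm=band_bpm)
    est.psi_raw = raw
    if belt is not None:
        disp = to_displacement(smooth)
        r, mse = evaluate_against_reference(disp, belt, belt_rate_hz, belt_start_s)
        est.r_value, est.mse = r, mse
        belt_t = belt_start_s + np.arange(len(belt)) / belt_rate_hz
        est.belt_resampled = np.interp(
            smooth.frame_times_s, belt_t, np.asarray(belt, dtype=float)
        )
        est.waveform = disp
    return est
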