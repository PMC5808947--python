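"""Synthetic RF scenes for passive bistatic radar sensing.

Generates paired reference/surveillance complex-baseband recordings of a
room illuminated by a 915 MHz DSSS wireless-energy transmitter, containing a
static multipath background plus either a breathing chest or a whole-body
activity.  Every scene carries its ground truth (breathing rate, activity
label, Doppler profile) so the downstream radar, breathing and classification
stages can be validated without hardware.

Conventions
-----------
* A propagation path's Doppler is stored *fractionally* (``f_d ~ 2v/c``,
  dimensionless); the instantaneous shift in Hz is ``f_c * f_d(t)``.  This
  makes the narrowband echo model ``A * x(t - tau) * exp(j * phi(t))`` with
  ``phi(t) = 2*pi*f_c * integral(f_d)`` dimensionally consistent, and reduces
  to a fixed shift ``f_c*f_d`` when the path velocity is constant.
* All generators are pure functions of their (spec, seed) arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.constants import c as C_LIGHT
from scipy.integrate import cumulative_trapezoid
from scipy.signal import upfirdn

from .errors import ParameterError

__all__ = [
    "SourceSpec",
    "PathSpec",
    "ChestMotionModel",
    "ActivityTrajectory",
    "BasebandRecording",
    "ACTIVITY_LABELS",
    "desk_source_spec",
    "generate_dsss_source",
    "add_noise",
    "simulate_scene",
    "chest_motion_path",
    "activity_path",
    "activity_trajectory",
    "breathing_scene",
    "activity_scene",
    "mixed_scene",
    "CorpusEntry",
    "generate_experiment_corpus",
    "root_raised_cosine",
]

#: The six monitored activities of daily living.
ACTIVITY_LABELS = ("walking", "running", "jumping", "standing", "sitting", "turning")

# ---------------------------------------------------------------------------
# Desk-scale scene defaults (see docs/methods.md).  The physics (carrier,
# displacement, velocities) is full scale; only the signal bandwidth / sample
# rate are scaled down, which is transparent to the Doppler processing.
DESK_SAMPLE_RATE_HZ = 50e3
DESK_BANDWIDTH_HZ = 12.5e3
DESK_CHIP_RATE_HZ = 10e3
#: Chest echo amplitude relative to the direct path at 40 cm (~ -17 dB).
CHEST_ECHO_AMP_40CM = 0.14
#: Whole-body echo amplitude relative to the direct path (~ -10 dB).
BODY_ECHO_AMP = 0.3
#: Amplitude of the secondary static clutter path.
CLUTTER_AMP = 0.15
#: Chest-belt reference sampling rate used in simulation.
BELT_RATE_HZ = 2.0


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SourceSpec:
    """DSSS illuminator: random-phase data bits spread by a +-1 chip sequence
    and shaped with a root-raised-cosine pulse."""

    carrier_freq_hz: float = 915e6
    bandwidth_hz: float = 20e6
    chip_rate_hz: float = 16e6
    num_bits: int = 64
    tx_power_dbm: float = 30.0
    rolloff: float = 0.25

    def __post_init__(self) -> None:
        if self.bandwidth_hz <= 0:
            raise ParameterError("bandwidth_hz must be positive")
        if self.chip_rate_hz <= 0 or self.chip_rate_hz > self.bandwidth_hz:
            raise ParameterError("chip_rate_hz must lie in (0, bandwidth_hz]")
        if self.num_bits < 1:
            raise ParameterError("num_bits must be >= 1")


def desk_source_spec(carrier_freq_hz: float = 915e6) -> SourceSpec:
    """Scaled-down source used by the bundled scenes (12.5 kHz occupied band)."""
    return SourceSpec(
        carrier_freq_hz=carrier_freq_hz,
        bandwidth_hz=DESK_BANDWIDTH_HZ,
        chip_rate_hz=DESK_CHIP_RATE_HZ,
    )


DopplerProfile = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class PathSpec:
    """One propagation path: delay, linear attenuation and fractional Doppler.

    ``doppler_profile`` may be a constant (fractional Doppler, ``2v/c``) or a
    vectorized callable of time returning fractional Doppler.  ``phase_rad``
    is the static carrier phase of the path, so several unresolved paths in
    one delay cell combine into a complex channel gain.
    """

    delay_s: float
    attenuation: float
    doppler_profile: float | DopplerProfile = 0.0
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.delay_s < 0:
            raise ParameterError("delay_s must be >= 0")
        if self.attenuation < 0:
            raise ParameterError("attenuation must be >= 0")

    def fractional_doppler(self, t: np.ndarray) -> np.ndarray:
        if callable(self.doppler_profile):
            return np.asarray(self.doppler_profile(t), dtype=float)
        return np.full_like(t, float(self.doppler_profile))


@dataclass(frozen=True)
class ChestMotionModel:
    """Breathing chest wall: sub-centimetre periodic displacement.

    ``orientation_gain`` in (0, 1] scales the radial component of the chest
    motion (1 = subject facing the surveillance antenna).
    """

    rate_bpm: float = 15.0
    displacement_amp_m: float = 0.005
    waveform: str = "sinusoid"
    orientation_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_bpm <= 0:
            raise ParameterError("rate_bpm must be positive")
        if self.displacement_amp_m <= 0:
            raise ParameterError("displacement_amp_m must be positive")
        if not 0.0 < self.orientation_gain <= 1.0:
            raise ParameterError("orientation_gain must be in (0, 1]")
        if self.waveform not in ("sinusoid", "asymmetric"):
            raise ParameterError(f"unknown chest waveform {self.waveform!r}")

    def displacement(self, t: np.ndarray) -> np.ndarray:
        """Chest displacement in metres at times ``t`` (seconds)."""
        theta = 2.0 * math.pi * (self.rate_bpm / 60.0) * np.asarray(t, dtype=float)
        if self.waveform == "sinusoid":
            return self.displacement_amp_m * np.sin(theta)
        # Asymmetric inhale/exhale: phase-warped sinusoid (faster inhale).
        return self.displacement_amp_m * np.sin(theta + 0.35 * np.sin(theta))

    def velocity(self, t: np.ndarray) -> np.ndarray:
        """Analytic chest-wall velocity (m/s)."""
        t = np.asarray(t, dtype=float)
        omega = 2.0 * math.pi * self.rate_bpm / 60.0
        theta = omega * t
        if self.waveform == "sinusoid":
            return self.displacement_amp_m * omega * np.cos(theta)
        return (
            self.displacement_amp_m
            * omega
            * np.cos(theta + 0.35 * np.sin(theta))
            * (1.0 + 0.35 * np.cos(theta))
        )


@dataclass(frozen=True)
class ActivityTrajectory:
    """Radial velocity profile of a whole-body activity."""

    label: str
    radial_velocity_profile: Callable[[np.ndarray], np.ndarray]
    duration_s: float

    def __post_init__(self) -> None:
        if self.label not in ACTIVITY_LABELS:
            raise ParameterError(
                f"unknown activity label {self.label!r}; expected one of {ACTIVITY_LABELS}"
            )
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")

    def velocity(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(self.radial_velocity_profile(np.asarray(t, dtype=float)), dtype=float)


@dataclass
class BasebandRecording:
    """Complex IQ samples of one channel with timing/carrier metadata.

    Both channels of one scene share the sample rate and start time (the
    hardware MIMO clock share is modelled as perfect synchronization).
    """

    channel: str
    samples: np.ndarray
    sample_rate_hz: float
    carrier_freq_hz: float
    duration_s: float
    seed: int | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel not in ("reference", "surveillance"):
            raise ParameterError(f"channel must be reference|surveillance, got {self.channel!r}")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be positive")
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        expected = int(round(self.sample_rate_hz * self.duration_s))
        if len(self.samples) != expected:
            raise ParameterError(
                f"samples length {len(self.samples)} != round(rate*duration) = {expected}"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz

    def power(self) -> float:
        return float(np.mean(np.abs(self.samples) ** 2))


# ---------------------------------------------------------------------------
# Source generation


def root_raised_cosine(sps: int, span_symbols: int = 10, rolloff: float = 0.25) -> np.ndarray:
    """Root-raised-cosine taps at ``sps`` samples/symbol (unit-energy)."""
    if sps < 1:
        raise ParameterError("sps must be >= 1")
    if not 0.0 < rolloff < 1.0:
        raise ParameterError("rolloff must be in (0, 1)")
    n = np.arange(-span_symbols * sps, span_symbols * sps + 1)
    t = n / float(sps)  # in symbol periods
    beta = rolloff
    taps = np.empty_like(t)
    for k, ti in enumerate(t):
        if abs(ti) < 1e-12:
            taps[k] = 1.0 - beta + 4.0 * beta / math.pi
        elif abs(abs(ti) - 1.0 / (4.0 * beta)) < 1e-9:
            taps[k] = (beta / math.sqrt(2.0)) * (
                (1.0 + 2.0 / math.pi) * math.sin(math.pi / (4.0 * beta))
                + (1.0 - 2.0 / math.pi) * math.cos(math.pi / (4.0 * beta))
            )
        else:
            num = math.sin(math.pi * ti * (1.0 - beta)) + 4.0 * beta * ti * math.cos(
                math.pi * ti * (1.0 + beta)
            )
            den = math.pi * ti * (1.0 - (4.0 * beta * ti) ** 2)
            taps[k] = num / den
    return taps / math.sqrt(np.sum(taps**2))


def generate_dsss_source(
    spec: SourceSpec,
    duration_s: float,
    sample_rate_hz: float = 1e6,
    seed: int | None = None,
) -> BasebandRecording:
    """Generate the reference-channel DSSS baseband signal.

    Random ``+-1`` chips spread ``spec.num_bits`` random-phase data bits; the
    chip train is shaped with a root-raised-cosine pulse.  Identical seeds
    give bitwise-identical sample streams.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if sample_rate_hz < spec.bandwidth_hz:
        raise ParameterError(
            f"sample_rate_hz ({sample_rate_hz:g}) must be >= bandwidth_hz ({spec.bandwidth_hz:g})"
        )
    sps_f = sample_rate_hz / spec.chip_rate_hz
    sps = int(round(sps_f))
    if abs(sps_f - sps) > 1e-6:
        raise ParameterError(
            "sample_rate_hz must be an integer multiple of chip_rate_hz "
            f"(got ratio {sps_f:g})"
        )
    rng = np.random.default_rng(seed)
    n_total = int(round(sample_rate_hz * duration_s))
    n_chips = int(math.ceil(n_total / sps)) + 1
    chips = rng.choice(np.array([-1.0, 1.0]), size=n_chips)
    bit_phase = rng.uniform(0.0, 2.0 * math.pi, size=spec.num_bits)
    bit_of_chip = np.minimum(
        (np.arange(n_chips) * spec.num_bits) // n_chips, spec.num_bits - 1
    )
    symbols = chips * np.exp(1j * bit_phase[bit_of_chip])

    taps = root_raised_cosine(sps, span_symbols=8, rolloff=spec.rolloff)
    shaped = upfirdn(taps, symbols, up=sps)
    delay = (len(taps) - 1) // 2  # group delay of the symmetric filter
    shaped = shaped[delay : delay + n_total]
    if len(shaped) < n_total:  # pragma: no cover - generous n_chips margin
        shaped = np.pad(shaped, (0, n_total - len(shaped)))

    amp = math.sqrt(10.0 ** ((spec.tx_power_dbm - 30.0) / 10.0))
    rms = math.sqrt(float(np.mean(np.abs(shaped) ** 2)))
    shaped = shaped * (amp / rms)
    return BasebandRecording(
        channel="reference",
        samples=shaped.astype(np.complex128),
        sample_rate_hz=sample_rate_hz,
        carrier_freq_hz=spec.carrier_freq_hz,
        duration_s=n_total / sample_rate_hz,
        seed=None if seed is None else int(seed),
        truth={"source": "dsss", "bandwidth_hz": spec.bandwidth_hz, "chip_rate_hz": spec.chip_rate_hz},
    )


def add_noise(rec: BasebandRecording, noise_power: float, seed: int | None = None) -> BasebandRecording:
    """Return a copy of ``rec`` with complex AWGN of the given power added."""
    if noise_power < 0:
        raise ParameterError("noise_power must be >= 0")
    if noise_power == 0:
        return replace(rec, samples=rec.samples.copy())
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(noise_power / 2.0)
    w = rng.normal(0.0, sigma, len(rec.samples)) + 1j * rng.normal(0.0, sigma, len(rec.samples))
    return replace(rec, samples=rec.samples + w)


# ---------------------------------------------------------------------------
# Channel simulation


def simulate_scene(
    src: BasebandRecording,
    static_paths: Sequence[PathSpec] = (),
    dynamic_path: PathSpec | Sequence[PathSpec] | None = None,
    noise_power: float = 0.0,
    seed: int | None = None,
    truth: dict | None = None,
) -> BasebandRecording:
    """Propagate the reference signal through a multipath channel.

    The surveillance channel is ``sum_l A_l * x(t - tau_l) * exp(j*phi_l(t))``
    plus AWGN, where the phase of each path is accumulated from its
    instantaneous fractional Doppler profile:
    ``phi_l(t) = 2*pi*f_c * integral_0^t f_dl(t') dt'``.
    """
    if src.channel != "reference":
        raise ParameterError("simulate_scene expects a reference-channel recording")
    fs = src.sample_rate_hz
    n = len(src.samples)
    t = src.times
    out = np.zeros(n, dtype=np.complex128)
    if dynamic_path is None:
        dynamic = []
    elif isinstance(dynamic_path, PathSpec):
        dynamic = [dynamic_path]
    else:
        dynamic = list(dynamic_path)
    paths = list(static_paths) + dynamic
    for path in paths:
        d = int(round(path.delay_s * fs))
        if path.delay_s >= src.duration_s:
            raise ParameterError(
                f"path delay {path.delay_s:g} s exceeds recording duration {src.duration_s:g} s"
            )
        delayed = np.zeros(n, dtype=np.complex128)
        delayed[d:] = src.samples[: n - d]
        gain = path.attenuation * np.exp(1j * path.phase_rad)
        fd = path.fractional_doppler(t)
        if np.any(fd):
            phase = 2.0 * math.pi * src.carrier_freq_hz * cumulative_trapezoid(
                fd, dx=1.0 / fs, initial=0.0
            )
            out += gain * delayed * np.exp(1j * phase)
        else:
            out += gain * delayed
    if noise_power > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(noise_power / 2.0)
        out += rng.normal(0.0, sigma, n) + 1j * rng.normal(0.0, sigma, n)
    merged_truth = dict(src.truth)
    merged_truth.update(truth or {})
    return BasebandRecording(
        channel="surveillance",
        samples=out,
        sample_rate_hz=fs,
        carrier_freq_hz=src.carrier_freq_hz,
        duration_s=src.duration_s,
        seed=None if seed is None else int(seed),
        truth=merged_truth,
    )


# ---------------------------------------------------------------------------
# Motion models -> paths


def chest_motion_path(chest: ChestMotionModel, range_m: float, f_c: float) -> PathSpec:
    """Echo path of a breathing chest at the given range.

    The fractional Doppler is the two-way path-length rate over c:
    ``f_d(t) = 2 * orientation_gain * d'(t) / c``; the peak shift in Hz for a
    sinusoid displacement is ``2*gain*A*omega*f_c/c``.  The echo amplitude
    follows an inverse-square law anchored at -17 dB (vs the direct path) at
    40 cm.
    """
    if range_m <= 0:
        raise ParameterError("range_m must be positive")

    def profile(t: np.ndarray) -> np.ndarray:
        return 2.0 * chest.orientation_gain * chest.velocity(t) / C_LIGHT

    attenuation = CHEST_ECHO_AMP_40CM * (0.4 / range_m) ** 2
    return PathSpec(delay_s=2.0 * range_m / C_LIGHT, attenuation=attenuation, doppler_profile=profile)


def activity_path(traj: ActivityTrajectory, f_c: float, attenuation: float = BODY_ECHO_AMP) -> PathSpec:
    """Echo path of a moving body; fractional Doppler ``2 v(t) / c``."""

    def profile(t: np.ndarray) -> np.ndarray:
        return 2.0 * traj.velocity(t) / C_LIGHT

    return PathSpec(delay_s=2.0 * 3.0 / C_LIGHT, attenuation=attenuation, doppler_profile=profile)


def _hann_pulse(t: np.ndarray, center: float, width: float, peak: float) -> np.ndarray:
    x = (t - center) / width
    out = np.zeros_like(t)
    mask = np.abs(x) < 0.5
    out[mask] = peak * 0.5 * (1.0 + np.cos(2.0 * math.pi * x[mask]))
    return out


def activity_trajectory(
    label: str,
    duration_s: float = 4.0,
    speed_scale: float = 1.0,
    gait_freq_scale: float = 1.0,
    start_offset_s: float = 0.0,
) -> ActivityTrajectory:
    """Build one of the six default radial-velocity templates.

    walking/running: trapezoidal bulk velocity with sinusoidal gait
    modulation, sustained for most of the recording; jumping: two biphasic
    (up/down) bouts with the widest Doppler excursion; standing/sitting:
    single short (<1 s) monotone torso transient of opposite sign; turning: a
    short low-amplitude biphasic twist.
    """
    if label not in ACTIVITY_LABELS:
        raise ParameterError(f"unknown activity label {label!r}")
    s = float(speed_scale)
    g = float(gait_freq_scale)
    mid = duration_s / 2.0 + start_offset_s

    if label in ("walking", "running"):
        base = (1.2 if label == "walking" else 2.4) * s
        gait_f = (1.8 if label == "walking" else 3.0) * g
        gait_a = 0.25 * base
        ramp = 0.4
        t0, t1 = 0.3 + start_offset_s, duration_s - 0.3 + start_offset_s

        def profile(t: np.ndarray, base=base, gait_f=gait_f, gait_a=gait_a, t0=t0, t1=t1, ramp=ramp):
            env = np.clip((t - t0) / ramp, 0.0, 1.0) * np.clip((t1 - t) / ramp, 0.0, 1.0)
            return env * (base + gait_a * np.sin(2.0 * math.pi * gait_f * (t - t0)))

    elif label == "jumping":
        peak = 3.5 * s
        bout = 0.9

        def profile(t: np.ndarray, peak=peak, bout=bout, mid=mid):
            out = np.zeros_like(t)
            for center in (mid - 0.7, mid + 0.7):
                x = t - (center - bout / 2.0)
                mask = (x >= 0) & (x < bout)
                out[mask] += peak * np.sin(2.0 * math.pi * x[mask] / bout)
            return out

    elif label == "standing":

        def profile(t: np.ndarray, mid=mid, s=s):
            return _hann_pulse(t, mid, 0.7, 0.9 * s)

    elif label == "sitting":

        def profile(t: np.ndarray, mid=mid, s=s):
            return _hann_pulse(t, mid, 0.7, -0.9 * s)

    else:  # turning

        def profile(t: np.ndarray, mid=mid, s=s):
            x = (t - mid) / 0.8
            out = np.zeros_like(t)
            mask = np.abs(x) < 0.5
            out[mask] = 0.45 * s * np.sin(2.0 * math.pi * x[mask]) * (
                0.5 * (1.0 + np.cos(2.0 * math.pi * x[mask]))
            )
            return out

    return ActivityTrajectory(label=label, radial_velocity_profile=profile, duration_s=duration_s)


# ---------------------------------------------------------------------------
# Ready-made scenes

#: Delay of the shared room range cell, in samples at the scene rate: at
#: desk-scale sample rates every room path is unresolved in delay, so the
#: direct signal, the static background and the subject's echo all occupy
#: this one cell.
_DIRECT_DELAY_SAMPLES = 1


def _scene_channels(
    spec: SourceSpec,
    duration_s: float,
    sample_rate_hz: float,
    dynamic_path: PathSpec,
    surv_snr_db: float,
    ref_snr_db: float,
    seed_seq: np.random.SeedSequence,
    truth: dict,
) -> tuple[BasebandRecording, BasebandRecording]:
    s_src, s_ref, s_surv = seed_seq.spawn(3)
    src = generate_dsss_source(
        spec, duration_s, sample_rate_hz, seed=int(s_src.generate_state(1)[0] % 2**31)
    )
    fs = sample_rate_hz
    # At desk-scale sample rates one delay bin spans kilometres, so every
    # static room path is unresolved in delay: the direct signal and the
    # stationary multipath background share one range cell and combine into
    # a complex channel gain (mirroring the coarse c/2B range resolution of
    # the narrowband illuminator).
    direct = PathSpec(delay_s=_DIRECT_DELAY_SAMPLES / fs, attenuation=1.0)
    clutter = PathSpec(
        delay_s=_DIRECT_DELAY_SAMPLES / fs, attenuation=CLUTTER_AMP, phase_rad=2.0
    )
    direct_power = src.power()  # direct path has unit attenuation
    noise = direct_power / 10.0 ** (surv_snr_db / 10.0)
    surv = simulate_scene(
        src,
        static_paths=[direct, clutter],
        dynamic_path=dynamic_path,
        noise_power=noise,
        seed=int(s_surv.generate_state(1)[0] % 2**31),
        truth=truth,
    )
    ref_noise = direct_power / 10.0 ** (ref_snr_db / 10.0)
    ref = add_noise(src, ref_noise, seed=int(s_ref.generate_state(1)[0] % 2**31))
    ref.truth.update(truth)
    return ref, surv


def breathing_scene(
    rate_bpm: float = 15.0,
    distance_m: float = 0.4,
    duration_s: float = 30.0,
    sample_rate_hz: float = DESK_SAMPLE_RATE_HZ,
    orientation_gain: float = 1.0,
    waveform: str = "sinusoid",
    surv_snr_db: float = 40.0,
    ref_snr_db: float = 50.0,
    belt_noise_std: float = 0.0,
    seed: int | None = None,
) -> tuple[BasebandRecording, BasebandRecording]:
    """Reference/surveillance pair for a stationary breathing subject.

    Ground truth (rate, chest model parameters and a chest-belt displacement
    waveform sampled at 2 Hz) is stored in both recordings' ``truth`` dicts.
    """
    ss = np.random.SeedSequence(seed)
    chest = ChestMotionModel(
        rate_bpm=rate_bpm, waveform=waveform, orientation_gain=orientation_gain
    )
    path = chest_motion_path(chest, distance_m, 915e6)
    # The chest shares the direct path's range cell at desk scale.
    path = replace(path, delay_s=_DIRECT_DELAY_SAMPLES / sample_rate_hz)
    belt_t = np.arange(0.0, duration_s, 1.0 / BELT_RATE_HZ)
    belt = chest.displacement(belt_t)
    belt_ss = ss.spawn(1)[0]  # spawned unconditionally to keep seeding stable
    if belt_noise_std > 0:
        belt_rng = np.random.default_rng(belt_ss)
        belt = belt + belt_rng.normal(0.0, belt_noise_std * np.std(belt), len(belt))
    truth = {
        "kind": "breathing",
        "rate_bpm": rate_bpm,
        "distance_m": distance_m,
        "orientation_gain": orientation_gain,
        "waveform": waveform,
        "belt_rate_hz": BELT_RATE_HZ,
        "belt": belt.tolist(),
    }
    spec = desk_source_spec()
    return _scene_channels(
        spec, duration_s, sample_rate_hz, path, surv_snr_db, ref_snr_db, ss, truth
    )


def activity_scene(
    label: str = "walking",
    duration_s: float = 4.0,
    sample_rate_hz: float = DESK_SAMPLE_RATE_HZ,
    speed_scale: float = 1.0,
    gait_freq_scale: float = 1.0,
    start_offset_s: float = 0.0,
    echo_amp: float = BODY_ECHO_AMP,
    surv_snr_db: float = 40.0,
    ref_snr_db: float = 50.0,
    seed: int | None = None,
    subject: int | None = None,
    repetition: int | None = None,
) -> tuple[BasebandRecording, BasebandRecording]:
    """Reference/surveillance pair for one whole-body activity recording."""
    ss = np.random.SeedSequence(seed)
    traj = activity_trajectory(
        label,
        duration_s=duration_s,
        speed_scale=speed_scale,
        gait_freq_scale=gait_freq_scale,
        start_offset_s=start_offset_s,
    )
    path = activity_path(traj, 915e6, attenuation=echo_amp)
    # The body shares the static background's (unresolved) range cell.
    path = replace(path, delay_s=_DIRECT_DELAY_SAMPLES / sample_rate_hz)
    truth = {
        "kind": "activity",
        "label": label,
        "subject": subject,
        "repetition": repetition,
        "speed_scale": speed_scale,
    }
    spec = desk_source_spec()
    return _scene_channels(
        spec, duration_s, sample_rate_hz, path, surv_snr_db, ref_snr_db, ss, truth
    )


def mixed_scene(
    duration_s: float = 60.0,
    switch_s: float = 30.0,
    rate_bpm: float = 15.0,
    sample_rate_hz: float = DESK_SAMPLE_RATE_HZ,
    surv_snr_db: float = 40.0,
    ref_snr_db: float = 50.0,
    seed: int | None = None,
) -> tuple[BasebandRecording, BasebandRecording]:
    """A subject sitting still (breathing) until ``switch_s``, then walking.

    Exercises the auto mode switch: the ground-truth state boundary is
    stored under ``truth['switch_s']``.
    """
    if not 0 < switch_s < duration_s:
        raise ParameterError("switch_s must fall inside the recording")
    ss = np.random.SeedSequence(seed)
    fs = sample_rate_hz
    chest = ChestMotionModel(rate_bpm=rate_bpm)
    chest_path = replace(
        chest_motion_path(chest, 0.4, 915e6), delay_s=_DIRECT_DELAY_SAMPLES / fs
    )
    walk = activity_trajectory("walking", duration_s=duration_s)

    def walk_profile(t: np.ndarray) -> np.ndarray:
        env = np.clip((t - (switch_s + 0.3)) / 0.4, 0.0, 1.0) * np.clip(
            (duration_s - 0.3 - t) / 0.4, 0.0, 1.0
        )
        return 2.0 * env * walk.velocity(t - switch_s + 0.3) / C_LIGHT

    walk_path = PathSpec(
        delay_s=_DIRECT_DELAY_SAMPLES / fs, attenuation=BODY_ECHO_AMP,
        doppler_profile=walk_profile,
    )
    truth = {
        "kind": "mixed",
        "rate_bpm": rate_bpm,
        "switch_s": switch_s,
        "belt_rate_hz": BELT_RATE_HZ,
    }
    belt_t = np.arange(0.0, switch_s, 1.0 / BELT_RATE_HZ)
    truth["belt"] = chest.displacement(belt_t).tolist()
    spec = desk_source_spec()
    s_src, s_ref, s_surv = ss.spawn(3)
    src = generate_dsss_source(
        spec, duration_s, fs, seed=int(s_src.generate_state(1)[0] % 2**31)
    )
    direct = PathSpec(delay_s=_DIRECT_DELAY_SAMPLES / fs, attenuation=1.0)
    clutter = PathSpec(
        delay_s=_DIRECT_DELAY_SAMPLES / fs, attenuation=CLUTTER_AMP, phase_rad=2.0
    )
    noise = src.power() / 10.0 ** (surv_snr_db / 10.0)
    surv = simulate_scene(
        src,
        static_paths=[direct, clutter],
        dynamic_path=[chest_path, walk_path],
        noise_power=noise,
        seed=int(s_surv.generate_state(1)[0] % 2**31),
        truth=truth,
    )
    ref = add_noise(src, src.power() / 10.0 ** (ref_snr_db / 10.0),
                    seed=int(s_ref.generate_state(1)[0] % 2**31))
    ref.truth.update(truth)
    return ref, surv


# ---------------------------------------------------------------------------
# Experiment corpus


@dataclass(frozen=True)
class CorpusEntry:
    """Lazily-realized labelled scene pair from the activity corpus."""

    label: str
    subject: int
    repetition: int
    seed: int
    speed_scale: float
    gait_freq_scale: float
    start_offset_s: float

    def realize(self) -> tuple[BasebandRecording, BasebandRecording]:
        return activity_scene(
            label=self.label,
            speed_scale=self.speed_scale,
            gait_freq_scale=self.gait_freq_scale,
            start_offset_s=self.start_offset_s,
            seed=self.seed,
            subject=self.subject,
            repetition=self.repetition,
        )


def generate_experiment_corpus(
    design: dict | None = None, seed: int | None = None
) -> list[CorpusEntry]:
    """Labelled corpus of activities x repetitions x subjects scene pairs.

    Defaults follow the measurement design: 6 activities x 10 repetitions x
    3 subjects = 180 recordings.  Each subject carries a systematic random
    speed/gait offset (inter-subject variation) on top of per-repetition
    jitter; the corpus manifest is a pure function of (design, seed).
    """
    design = dict(design or {})
    n_act = int(design.get("activities", 6))
    n_rep = int(design.get("repetitions", 10))
    n_sub = int(design.get("subjects", 3))
    if n_act < 1 or n_rep < 1 or n_sub < 1:
        raise ParameterError("corpus design counts must be positive")
    if n_act > len(ACTIVITY_LABELS):
        raise ParameterError(f"at most {len(ACTIVITY_LABELS)} activities available")
    labels = ACTIVITY_LABELS[:n_act]
    ss = np.random.SeedSequence(seed)
    subject_streams = ss.spawn(n_sub)
    entries: list[CorpusEntry] = []
    for sub_idx, sub_ss in enumerate(subject_streams):
        rng = np.random.default_rng(sub_ss)
        subj_speed = float(np.exp(rng.normal(0.0, 0.10)))
        subj_gait = float(np.exp(rng.normal(0.0, 0.08)))
        for label in labels:
            for rep in range(n_rep):
                rep_speed = subj_speed * float(np.exp(rng.normal(0.0, 0.05)))
                rep_gait = subj_gait * float(np.exp(rng.normal(0.0, 0.04)))
                offset = float(rng.uniform(-0.2, 0.2))
                scene_seed = int(rng.integers(0, 2**31))
                entries.append(
                    CorpusEntry(
                        label=label,
                        subject=sub_idx,
                        repetition=rep,
                        seed=scene_seed,
                        speed_scale=rep_speed,
                        gait_freq_scale=rep_gait,
                        start_offset_s=offset,
                    )
                )
    return entries
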