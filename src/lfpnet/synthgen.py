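"""Synthetic wake LFP recordings and evoked sweeps with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes — a 1/f background, band-limited oscillations, theta-phase-modulated
gamma amplitude of controlled depth, lagged inter-channel mixing, powerline
contamination, motion-gated wake/quiet alternation, and parametric evoked
waveforms (stimulus artifact + fEPSP + population spike) across a sigmoidal
stimulus-response relation with an HFS potentiation time course.  Ground
truth is explicit so recovery tests can compare estimates against known
parameters.  Everything is deterministic given the seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .evoked import STANDARD_INTENSITIES_MV, Sweep
from .preprocess import LFP_CHANNELS, Recording

__all__ = [
    "BandComponent",
    "PacSpec",
    "PairMixing",
    "LfpGroundTruth",
    "SigmoidIO",
    "EvokedGroundTruth",
    "AgedEffects",
    "GroupDataset",
    "generate_recording",
    "generate_pac_signal",
    "generate_sweep",
    "generate_group_dataset",
]

RATE = 512.0
NYQUIST = RATE / 2.0


@dataclass(frozen=True)
class BandComponent:
    """A band-limited oscillation: Gaussian noise band-passed around a centre.

    ``bandwidth_hz = 0`` yields a pure sinusoid with random phase.
    ``amplitude`` is the component's RMS in microvolts.
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float


@dataclass(frozen=True)
class PacSpec:
    """Theta-gamma construction: a slow oscillation whose phase modulates the
    envelope of a fast carrier as ``amp_fast * (1 + depth * cos(phase))``."""

    f_phase: float = 7.0
    f_amp: float = 57.5
    depth: float = 0.6
    amp_slow: float = 30.0
    amp_fast: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"modulation depth {self.depth} outside [0, 1]")


@dataclass(frozen=True)
class PairMixing:
    """Linear lagged mixing: ``target += gain * source`` delayed by ``lag`` samples."""

    source: str = "OBL"
    target: str = "OBR"
    gain: float = 0.8
    lag_samples: int = 4

    def __post_init__(self) -> None:
        if self.lag_samples < 0:
            raise ValueError("mixing lag must be >= 0 samples")


@dataclass(frozen=True)
class LfpGroundTruth:
    """Ground-truth parameters of one synthetic animal's recording."""

    background_exponent: float = 1.0
    background_amplitude: float = 20.0
    band_components: tuple[BandComponent, ...] = (BandComponent(2.0, 1.5, 25.0),)
    pac: PacSpec | None = PacSpec()
    pair_mixing: PairMixing | None = PairMixing()
    line_freq: float = 50.0
    line_amplitude: float = 10.0
    motion_profile: tuple[float, float] = (30.0, 30.0)
    seed: int = 0

    def all_center_freqs(self) -> list[float]:
        freqs = [c.center_hz for c in self.band_components]
        if self.pac is not None:
            freqs += [self.pac.f_phase, self.pac.f_amp]
        return freqs


def _one_over_f_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectrum ~ 1/f^beta (spectral shaping)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / RATE)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    rms = x.std()
    return x / rms if rms > 0 else x


def _narrowband(n: int, comp: BandComponent, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS narrowband process at the component's centre frequency."""
    t = np.arange(n) / RATE
    if comp.bandwidth_hz <= 0:
        phase0 = rng.uniform(0, 2 * np.pi)
        return math.sqrt(2.0) * np.cos(2 * np.pi * comp.center_hz * t + phase0)
    lo = max(comp.center_hz - comp.bandwidth_hz / 2.0, 0.1)
    hi = min(comp.center_hz + comp.bandwidth_hz / 2.0, NYQUIST * 0.999)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=RATE, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    rms = x.std()
    return x / rms if rms > 0 else x


def generate_pac_signal(
    f_phase: float,
    f_amp: float,
    depth: float,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = RATE,
    amp_slow: float = 1.0,
    amp_fast: float = 1.0,
    rng: np.random.Generator | None = None,
    return_parts: bool = False,
):
    """Single-channel signal with exact phase-amplitude coupling.

    The fast carrier's envelope is ``amp_fast * (1 + depth * cos(phase))``
    where ``phase`` is the instantaneous phase of the slow component, so the
    construction has a closed form against which estimators can be checked.

    With ``return_parts=True`` also returns the slow part, the fast part and
    the slow phase series (ground truth for oracle tests).
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError(f"modulation depth {depth} outside [0, 1]")
    if not 0 < f_phase < f_amp < fs / 2:
        raise ValueError("need 0 < f_phase < f_amp < Nyquist")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phi0 = rng.uniform(0, 2 * np.pi)
    psi0 = rng.uniform(0, 2 * np.pi)
    phase = 2 * np.pi * f_phase * t + phi0
    slow = amp_slow * np.cos(phase)
    envelope = amp_fast * (1.0 + depth * np.cos(phase))
    fast = envelope * np.cos(2 * np.pi * f_amp * t + psi0)
    x = slow + fast
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    if return_parts:
        return x, slow, fast, phase
    return x


def _motion_envelope(
    n: int, profile: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Two-state active/quiet box-car, 1-s smoothed, with mild positive noise."""
    active_s, quiet_s = profile
    period = int(round((active_s + quiet_s) * RATE))
    active_n = int(round(active_s * RATE))
    base = np.zeros(n)
    if period <= 0:
        base[:] = 1.0
    else:
        pos = np.arange(n) % period
        base[pos < active_n] = 1.0
    kernel = np.ones(int(RATE)) / RATE
    smooth = signal.fftconvolve(base, kernel, mode="same")
    env = smooth * (1.0 + 0.05 * rng.standard_normal(n)) + 0.01 * np.abs(
        rng.standard_normal(n)
    )
    return np.clip(env, 0.0, None)


def generate_recording(
    truth: LfpGroundTruth,
    duration_s: float,
    channel_labels: Sequence[str] = LFP_CHANNELS,
) -> Recording:
    """Generate a multichannel wake recording at 512 Hz from ground truth.

    Every channel receives an independent realisation of the same spectral
    content (background + band components + the PAC theta/gamma pair + line
    contamination); the mixing spec then injects a lagged, scaled copy of the
    source channel into the target channel.  The motion envelope alternates
    active/quiet per the motion profile.
    """
    if duration_s < 10:
        raise ValueError("duration must be at least 10 s")
    for f in truth.all_center_freqs():
        if f >= NYQUIST:
            raise ValueError(
                f"component frequency {f} Hz is at or above Nyquist ({NYQUIST} Hz)"
            )
    n = int(round(duration_s * RATE))
    t = np.arange(n) / RATE
    ss = np.random.SeedSequence(truth.seed)
    children = ss.spawn(len(channel_labels) + 1)
    data = np.empty((len(channel_labels), n))
    for ci, label in enumerate(channel_labels):
        rng = np.random.default_rng(children[ci])
        x = truth.background_amplitude * _one_over_f_noise(
            n, truth.background_exponent, rng
        ) if truth.background_amplitude > 0 else np.zeros(n)
        for comp in truth.band_components:
            x = x + comp.amplitude * _narrowband(n, comp, rng)
        if truth.pac is not None:
            p = truth.pac
            x = x + generate_pac_signal(
                p.f_phase, p.f_amp, p.depth, duration_s,
                amp_slow=p.amp_slow, amp_fast=p.amp_fast, rng=rng,
            )
        if truth.line_amplitude > 0:
            x = x + truth.line_amplitude * np.sin(2 * np.pi * truth.line_freq * t)
        data[ci] = x
    channel_map = {label: i for i, label in enumerate(channel_labels)}
    if truth.pair_mixing is not None:
        mix = truth.pair_mixing
        if mix.source in channel_map and mix.target in channel_map:
            src = data[channel_map[mix.source]]
            lag = mix.lag_samples
            if lag == 0:
                data[channel_map[mix.target]] += mix.gain * src
            else:
                data[channel_map[mix.target], lag:] += mix.gain * src[:-lag]
    motion = _motion_envelope(n, truth.motion_profile, np.random.default_rng(children[-1]))
    return Recording(data, RATE, channel_map, motion)


# ---------------------------------------------------------------------------
# evoked sweeps
# ---------------------------------------------------------------------------

SWEEP_RATE_HZ = 3000.0
SWEEP_WINDOW_MS = (-5.0, 45.0)


@dataclass(frozen=True)
class SigmoidIO:
    """Logistic stimulus-response relation, fraction of maximal response."""

    half_max_mv: float = 4000.0
    steepness_mv: float = 800.0

    def fraction(self, intensity_mv: float) -> float:
        return 1.0 / (1.0 + math.exp(-(intensity_mv - self.half_max_mv) / self.steepness_mv))


@dataclass(frozen=True)
class EvokedGroundTruth:
    """Parameters of the synthetic evoked waveform.

    Amplitudes are the asymptotic (sigmoid-ceiling) values; the response at a
    given stimulation intensity is scaled by ``sigmoid_io.fraction`` and by
    the potentiation ``timepoint_factor``.  The default geometry places the
    half-maximum response inside the study's inclusion windows (latency
    6-10 ms, amplitude 1500-2500 uV, slope 400-900 uV/ms).
    """

    artifact_duration_ms: float = 1.0
    epsp_onset_ms: float = 2.0
    epsp_peak_ms: float = 6.0
    epsp_flat_width_ms: float = 2.0
    epsp_amplitude_uv: float = 4000.0
    spike_amplitude_uv: float = 700.0
    spike_center_ms: float = 7.0
    spike_width_ms: float = 0.3
    spike_positivity_ratio: float = 0.5
    spike_positivity_width_ms: float = 0.6
    recovery_tau_ms: float = 12.0
    sigmoid_io: SigmoidIO = SigmoidIO()
    noise_sd_uv: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.epsp_peak_ms > self.epsp_onset_ms > self.artifact_duration_ms:
            raise ValueError("need peak latency > onset latency > artifact duration")
        if not (
            self.epsp_peak_ms
            < self.spike_center_ms
            < self.epsp_peak_ms + self.epsp_flat_width_ms
        ):
            raise ValueError("spike centre must lie within the fEPSP flat bottom")
        for name in ("epsp_amplitude_uv", "spike_amplitude_uv", "noise_sd_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def epsp_slope_uv_per_ms(self) -> float:
        """Slope magnitude of the ceiling-level fEPSP ramp."""
        return self.epsp_amplitude_uv / (self.epsp_peak_ms - self.epsp_onset_ms)


def generate_sweep(
    truth: EvokedGroundTruth,
    intensity_mv: float,
    timepoint_factor: float = 1.0,
    seed: int = 0,
    timepoint_min: float | None = None,
    rng: np.random.Generator | None = None,
) -> Sweep:
    """One evoked sweep: artifact transient + fEPSP + spike complex + noise.

    The fEPSP descends linearly from onset to its negative peak, holds a flat
    bottom, then recovers exponentially; the population spike complex is a
    narrow negative Gaussian notch riding inside a wider positive bump,
    producing the two positivities flanking the spike trough that the tangent
    (chord) PSA measurement requires.  Response magnitude scales as
    ``sigmoid_io.fraction(intensity) * timepoint_factor``.
    """
    if intensity_mv <= 0:
        raise ValueError("stimulation intensity must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    dt = 1000.0 / SWEEP_RATE_HZ
    t = np.arange(SWEEP_WINDOW_MS[0], SWEEP_WINDOW_MS[1] + dt / 2, dt)
    scale = truth.sigmoid_io.fraction(intensity_mv) * timepoint_factor
    amp = truth.epsp_amplitude_uv * scale
    spike = truth.spike_amplitude_uv * scale
    v = np.zeros_like(t)

    # stimulus artifact: fast-decaying positive transient inside the blanking
    art = (t >= 0) & (t < truth.artifact_duration_ms)
    v[art] += 5000.0 * np.exp(-t[art] / (truth.artifact_duration_ms / 3.0))

    on, pk = truth.epsp_onset_ms, truth.epsp_peak_ms
    flat_end = pk + truth.epsp_flat_width_ms
    ramp = (t >= on) & (t < pk)
    v[ramp] -= amp * (t[ramp] - on) / (pk - on)
    v[(t >= pk) & (t <= flat_end)] -= amp
    rec = t > flat_end
    v[rec] -= amp * np.exp(-(t[rec] - flat_end) / truth.recovery_tau_ms)

    if spike > 0:
        d = t - truth.spike_center_ms
        v += (
            truth.spike_positivity_ratio
            * spike
            * np.exp(-(d**2) / (2 * truth.spike_positivity_width_ms**2))
        )
        v -= spike * np.exp(-(d**2) / (2 * truth.spike_width_ms**2))
    if truth.noise_sd_uv > 0:
        v = v + truth.noise_sd_uv * rng.standard_normal(t.size)
    return Sweep(t, v, stim_intensity_mv=float(intensity_mv), timepoint_min=timepoint_min)


# ---------------------------------------------------------------------------
# group datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgedEffects:
    """Multiplicative aged-group effects on ground-truth parameters.

    Defaults encode the direction and rough magnitude of the aging
    phenotype the pipeline is meant to detect: halved gamma amplitude,
    increased delta, strongly reduced theta-gamma coupling depth, reduced
    inter-bulb mixing (coherence) and reduced post-HFS potentiation.
    """

    gamma_amplitude: float = 0.5
    delta_amplitude: float = 1.5
    pac_depth: float = 0.4
    mixing_gain: float = 0.5
    potentiation: float = 0.62

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"aged-effect multiplier {name} must be >= 0")


@dataclass
class GroupDataset:
    """A synthetic cohort: recordings plus evoked-sweep series per animal."""

    recordings: dict[str, Recording]
    groups: dict[str, str]
    lfp_truths: dict[str, LfpGroundTruth]
    evoked_truths: dict[str, EvokedGroundTruth]
    io_sweeps: dict[str, dict[float, list[Sweep]]]
    ltp_sweeps: dict[str, list[Sweep]]

    @property
    def animal_ids(self) -> list[str]:
        return list(self.groups)


#: Post-HFS potentiation factor for a young animal at time t (min after HFS):
#: an immediate doubling decaying with a 120-min time constant.
def _young_potentiation(t_min: float, magnitude: float = 1.0) -> float:
    return 1.0 + magnitude * math.exp(-t_min / 120.0)


#: 12 baseline timepoints (-30 .. -2.5 min) and 36 post-HFS timepoints
#: (2.5 .. 90 min) on the 2.5-min acquisition grid; HFS at t = 0.
LTP_TIMEPOINTS_MIN = tuple(np.arange(-30.0, -2.5 + 1e-9, 2.5)) + tuple(
    np.arange(2.5, 90.0 + 1e-9, 2.5)
)
SWEEPS_PER_TIMEPOINT = 5
SWEEPS_PER_INTENSITY = 3


def generate_group_dataset(
    n_young: int = 8,
    n_aged: int = 8,
    aged_effects: AgedEffects | None = None,
    duration_s: float = 120.0,
    seed: int = 0,
    base_lfp: LfpGroundTruth | None = None,
    base_evoked: EvokedGroundTruth | None = None,
    animal_jitter: float = 0.15,
    include_evoked: bool = True,
) -> GroupDataset:
    """Generate a young/aged cohort with per-animal seeds and variability.

    Aged animals receive the multiplicative :class:`AgedEffects`; every
    animal additionally gets a lognormal jitter (sd ``animal_jitter`` on the
    log scale) on its component amplitudes and coupling depth so that
    between-animal variance exists for the group statistics.  All per-animal
    seeds derive reproducibly from the master seed.
    """
    if n_young < 2 or n_aged < 2:
        raise ValueError("need at least two animals per group")
    eff = aged_effects if aged_effects is not None else AgedEffects()
    base = base_lfp if base_lfp is not None else LfpGroundTruth()
    ebase = base_evoked if base_evoked is not None else EvokedGroundTruth()

    ss = np.random.SeedSequence(seed)
    n_total = n_young + n_aged
    children = ss.spawn(n_total)
    recordings, groups, lfp_truths, evoked_truths = {}, {}, {}, {}
    io_sweeps, ltp_sweeps = {}, {}

    for ai in range(n_total):
        group = "young" if ai < n_young else "aged"
        animal = f"{group}_{ai if ai < n_young else ai - n_young:02d}"
        rng = np.random.default_rng(children[ai])
        animal_seed = int(rng.integers(0, 2**31 - 1))

        jit = lambda: float(np.exp(animal_jitter * rng.standard_normal()))
        delta_mult = (eff.delta_amplitude if group == "aged" else 1.0) * jit()
        gamma_mult = (eff.gamma_amplitude if group == "aged" else 1.0) * jit()
        depth_mult = (eff.pac_depth if group == "aged" else 1.0) * jit()
        gain_mult = (eff.mixing_gain if group == "aged" else 1.0) * jit()

        comps = tuple(
            replace(c, amplitude=c.amplitude * (delta_mult if c.center_hz < 4 else jit()))
            for c in base.band_components
        )
        pac = None
        if base.pac is not None:
            pac = replace(
                base.pac,
                amp_fast=base.pac.amp_fast * gamma_mult,
                amp_slow=base.pac.amp_slow * jit(),
                depth=min(base.pac.depth * depth_mult, 1.0),
            )
        mixing = None
        if base.pair_mixing is not None:
            mixing = replace(base.pair_mixing, gain=base.pair_mixing.gain * gain_mult)
        truth = replace(
            base, band_components=comps, pac=pac, pair_mixing=mixing, seed=animal_seed
        )
        recordings[animal] = generate_recording(truth, duration_s)
        groups[animal] = group
        lfp_truths[animal] = truth

        if not include_evoked:
            continue
        etruth = replace(
            ebase,
            epsp_amplitude_uv=ebase.epsp_amplitude_uv
            * float(np.exp(0.05 * rng.standard_normal())),
            spike_amplitude_uv=ebase.spike_amplitude_uv
            * float(np.exp(0.05 * rng.standard_normal())),
            seed=animal_seed,
        )
        evoked_truths[animal] = etruth
        srng = np.random.default_rng(animal_seed)
        io = {}
        for inten in STANDARD_INTENSITIES_MV:
            io[inten] = [
                generate_sweep(etruth, inten, rng=srng)
                for _ in range(SWEEPS_PER_INTENSITY)
            ]
        io_sweeps[animal] = io

        test_stim = etruth.sigmoid_io.half_max_mv
        pot_mag = float(np.exp(0.1 * rng.standard_normal()))
        series = []
        for tp in LTP_TIMEPOINTS_MIN:
            if tp < 0:
                factor = 1.0
            else:
                factor = _young_potentiation(tp, pot_mag)
                if group == "aged":
                    factor *= eff.potentiation
            for _ in range(SWEEPS_PER_TIMEPOINT):
                series.append(
                    generate_sweep(
                        etruth, test_stim, timepoint_factor=factor,
                        timepoint_min=float(tp), rng=srng,
                    )
                )
        ltp_sweeps[animal] = series

    return GroupDataset(
        recordings, groups, lfp_truths, evoked_truths, io_sweeps, ltp_sweeps
    )
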