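"""Synthetic auditory steady-state response (ASSR) sessions with known coupling.

Every downstream stage of the pipeline (preprocessing, time-frequency,
phase-amplitude coupling, cluster statistics, waveform-shape checks) is
exercised against data from this module, which emulates a source-level
auditory-cortex time course during a click-train oddball paradigm:

* an entrained sinusoid at the stimulation frequency (40/30/20 Hz), active
  during the click train and phase-locked across trials (configurable jitter
  degrades inter-trial coherence continuously);
* a low-frequency (4-12 Hz) background oscillation with random phase per
  trial, optionally non-sinusoidal (asymmetric rise/decay);
* a gamma-band carrier whose instantaneous amplitude follows
  ``1 + m * waveform(phi_low)`` inside a configurable coupling window, so the
  true (fP, fA, m) of the phase-amplitude coupling is known exactly;
* additive 1/f background noise, independent across trials.

All randomness flows through one :class:`numpy.random.Generator` per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ParadigmSpec",
    "CouplingSpec",
    "NoiseSpec",
    "TrialEnsemble",
    "ClickTrain",
    "generate_click_train",
    "generate_session_plan",
    "synthesize_trial",
    "synthesize_session",
    "generate_cohort",
    "asymmetric_cos",
    "one_over_f_noise",
]

STANDARD = "standard"
ODDBALL = "oddball"


@dataclass(frozen=True)
class ParadigmSpec:
    """Click-train oddball paradigm geometry.

    Defaults follow the study design this package targets: 1-s trains of
    1-ms tones at 40, 30 or 20 Hz; 100 trials per condition in 10 blocks of
    10, of which 15 are oddballs (deviant carrier tone) excluded from
    analysis; epochs of -1.5 to +1.5 s around train onset at 1000 Hz.
    """

    stim_freq_hz: float = 40.0
    train_duration_s: float = 1.0
    tone_duration_ms: float = 1.0
    n_trials_total: int = 100
    n_oddball: int = 15
    n_blocks: int = 10
    sampling_rate_hz: float = 1000.0
    epoch_window_s: tuple[float, float] = (-1.5, 1.5)

    def __post_init__(self) -> None:
        if self.stim_freq_hz <= 0 or self.train_duration_s <= 0:
            raise ValueError("stim_freq_hz and train_duration_s must be positive")
        n_clicks = self.stim_freq_hz * self.train_duration_s
        if abs(n_clicks - round(n_clicks)) > 1e-9:
            raise ValueError(
                f"stim_freq_hz * train_duration_s = {n_clicks} is not a whole "
                "number of clicks"
            )
        if not 0 <= self.n_oddball < self.n_trials_total:
            raise ValueError("need 0 <= n_oddball < n_trials_total")
        if self.n_trials_total % self.n_blocks != 0:
            raise ValueError("n_trials_total must be divisible by n_blocks")
        if self.epoch_window_s[0] >= self.epoch_window_s[1]:
            raise ValueError("epoch_window_s must be an increasing pair")

    @property
    def n_clicks(self) -> int:
        return int(round(self.stim_freq_hz * self.train_duration_s))

    def times(self) -> np.ndarray:
        """Epoch time axis in seconds, 0 = stimulus onset."""
        t0, t1 = self.epoch_window_s
        n = int(round((t1 - t0) * self.sampling_rate_hz)) + 1
        return t0 + np.arange(n) / self.sampling_rate_hz


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth phase-amplitude coupling injected into synthetic trials.

    ``modulation_depth`` m scales the gamma envelope as ``1 + m*cos(phi)``:
    m=0 means no coupling, m=1 lets the envelope touch zero.
    ``phase_amp_ratio`` is the amplitude of the low-frequency oscillation
    relative to the (unit) gamma carrier. ``waveform_asymmetry`` in (-1, 1)
    skews the low-frequency cycle: the rise (trough-to-peak) occupies a
    fraction (1 - a)/2 of the cycle, so a > 0 compresses the rise and the
    rise-decay ratio becomes (1 - a)/(1 + a).
    """

    phase_freq_hz: float = 6.0
    amp_freq_hz: float = 40.0
    modulation_depth: float = 0.0
    phase_amp_ratio: float = 2.0
    coupling_window_s: tuple[float, float] = (0.2, 1.0)
    waveform_asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in [0, 1]")
        if not 4.0 <= self.phase_freq_hz <= 12.0:
            raise ValueError("phase_freq_hz must be in [4, 12] Hz")
        if not 13.0 <= self.amp_freq_hz <= 60.0:
            raise ValueError("amp_freq_hz must be in [13, 60] Hz")
        if not -1.0 < self.waveform_asymmetry < 1.0:
            raise ValueError("waveform_asymmetry must be in (-1, 1)")
        if self.coupling_window_s[0] >= self.coupling_window_s[1]:
            raise ValueError("coupling_window_s must be an increasing pair")


@dataclass(frozen=True)
class NoiseSpec:
    """Background and entrained-response parameters of a synthetic trial."""

    one_over_f_exponent: float = 1.0
    noise_sd: float = 1.0
    assr_amplitude: float = 1.0
    assr_onset_s: float = 0.0
    assr_offset_s: float = 1.0
    #: 0 = perfectly phase-locked ASSR (ITC ~ 1); 1 = fully random onset phase.
    assr_phase_jitter: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.assr_amplitude < 0:
            raise ValueError("noise_sd and assr_amplitude must be >= 0")
        if not 0.0 <= self.assr_phase_jitter <= 1.0:
            raise ValueError("assr_phase_jitter must be in [0, 1]")


@dataclass
class TrialEnsemble:
    """Epoched trials of one condition: a trials x time real matrix.

    ``times_s`` is uniform at 1/``sampling_rate_hz`` with 0 at stimulus
    onset. ``trial_kinds`` tags each row "standard" or "oddball".
    """

    data: np.ndarray
    times_s: np.ndarray
    sampling_rate_hz: float
    condition_label: str = ""
    trial_kinds: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be trials x time")
        if self.data.shape[1] != self.times_s.size:
            raise ValueError("data and times_s length mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        dt = np.diff(self.times_s)
        if dt.size and not np.allclose(dt, 1.0 / self.sampling_rate_hz, rtol=1e-6):
            raise ValueError("times_s must be uniform at 1/sampling_rate_hz")
        if self.trial_kinds is not None:
            self.trial_kinds = np.asarray(self.trial_kinds)
            if self.trial_kinds.shape[0] != self.data.shape[0]:
                raise ValueError("trial_kinds length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def window_indices(self, window_s: tuple[float, float]) -> np.ndarray:
        """Sample indices with start <= t < end (half-open window)."""
        start, end = window_s
        return np.nonzero((self.times_s >= start) & (self.times_s < end))[0]

    def copy_with(self, data: np.ndarray, trial_kinds=None) -> "TrialEnsemble":
        return TrialEnsemble(
            data=data,
            times_s=self.times_s.copy(),
            sampling_rate_hz=self.sampling_rate_hz,
            condition_label=self.condition_label,
            trial_kinds=trial_kinds,
            ground_truth=dict(self.ground_truth),
        )


@dataclass(frozen=True)
class ClickTrain:
    """Onset times and sample-level 0/1 pulse sequence of one click train."""

    onsets_s: np.ndarray
    pulses: np.ndarray
    carrier_hz: float
    sampling_rate_hz: float


def generate_click_train(spec: ParadigmSpec, oddball: bool = False) -> ClickTrain:
    """Click onsets over [0, train_duration) at 1/stim_freq intervals.

    The oddball flag only switches the carrier tone identity (2000 Hz vs
    1000 Hz); pulse timing is identical for standard and oddball trains.
    """
    onsets = np.arange(spec.n_clicks) / spec.stim_freq_hz
    n_samp = int(round(spec.train_duration_s * spec.sampling_rate_hz))
    pulses = np.zeros(n_samp, dtype=np.int8)
    width = max(1, int(round(spec.tone_duration_ms / 1000.0 * spec.sampling_rate_hz)))
    for on in onsets:
        i0 = int(round(on * spec.sampling_rate_hz))
        pulses[i0 : min(i0 + width, n_samp)] = 1
    return ClickTrain(
        onsets_s=onsets,
        pulses=pulses,
        carrier_hz=2000.0 if oddball else 1000.0,
        sampling_rate_hz=spec.sampling_rate_hz,
    )


def generate_session_plan(
    spec: ParadigmSpec, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Ordered trial list with uniformly random oddball placement.

    Returns a frame with columns ``trial_index``, ``block``, ``kind``;
    oddball slots are a uniform random subset of all trial slots (no
    block-wise constraint), matching an unconstrained random assignment
    across the session.
    """
    rng = np.random.default_rng(seed)
    kinds = np.array([STANDARD] * spec.n_trials_total, dtype=object)
    odd_slots = rng.choice(spec.n_trials_total, size=spec.n_oddball, replace=False)
    kinds[odd_slots] = ODDBALL
    per_block = spec.n_trials_total // spec.n_blocks
    return pd.DataFrame(
        {
            "trial_index": np.arange(spec.n_trials_total),
            "block": np.arange(spec.n_trials_total) // per_block,
            "kind": kinds,
        }
    )


def asymmetric_cos(phase: np.ndarray, asymmetry: float = 0.0) -> np.ndarray:
    """Cosine with a piecewise-linearly warped cycle.

    The decay (peak-to-trough) occupies a fraction (1 + a)/2 of each cycle
    and the rise (trough-to-peak) the remaining (1 - a)/2, preserving the
    fundamental period. a = 0 reduces exactly to ``cos(phase)``.
    """
    if not -1.0 < asymmetry < 1.0:
        raise ValueError("asymmetry must be in (-1, 1)")
    if asymmetry == 0.0:
        return np.cos(phase)
    u = np.mod(np.asarray(phase) / (2 * np.pi), 1.0)
    delta = (1.0 + asymmetry) / 2.0  # decay fraction
    w = np.where(
        u < delta,
        np.pi * u / delta,
        np.pi + np.pi * (u - delta) / (1.0 - delta),
    )
    return np.cos(w)


def one_over_f_noise(
    n_samples: int,
    sampling_rate_hz: float,
    exponent: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent.

    White Gaussian noise is shaped in the frequency domain by f^(-exponent/2)
    (DC removed) and rescaled to standard deviation ``sd``.
    """
    if sd == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samples)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _epoch_components(
    spec: ParadigmSpec,
    coupling: CouplingSpec,
    noise: NoiseSpec,
    rng: np.random.Generator,
    times: np.ndarray,
) -> np.ndarray:
    """One epoch: entrained ASSR + low-frequency oscillation + coupled gamma
    + 1/f noise."""
    t0, t1 = spec.epoch_window_s
    c0, c1 = coupling.coupling_window_s
    if c0 < t0 or c1 > t1:
        raise ValueError("coupling_window_s must lie within the epoch window")

    x = np.zeros_like(times)

    # (i) entrained steady-state response, phase-locked up to jitter
    if noise.assr_amplitude > 0:
        ph = noise.assr_phase_jitter * rng.uniform(-np.pi, np.pi)
        active = (times >= noise.assr_onset_s) & (times < noise.assr_offset_s)
        x[active] += noise.assr_amplitude * np.sin(
            2 * np.pi * spec.stim_freq_hz * times[active] + ph
        )

    # (ii) low-frequency oscillation, random phase per trial
    phi0 = rng.uniform(0, 2 * np.pi)
    phase_low = 2 * np.pi * coupling.phase_freq_hz * times + phi0
    low_wave = asymmetric_cos(phase_low, coupling.waveform_asymmetry)
    x += coupling.phase_amp_ratio * low_wave

    # (iii) gamma carrier; amplitude 1 + m*waveform(phi_low) inside the
    # coupling window, tapered over 50 ms so the envelope step is smooth
    psi0 = rng.uniform(0, 2 * np.pi)
    env = np.ones_like(times)
    if coupling.modulation_depth > 0:
        ramp = np.clip((times - c0) / 0.05, 0, 1) * np.clip((c1 - times) / 0.05, 0, 1)
        env += coupling.modulation_depth * low_wave * ramp
    x += env * np.cos(2 * np.pi * coupling.amp_freq_hz * times + psi0)

    # (iv) 1/f background
    x += one_over_f_noise(
        times.size, spec.sampling_rate_hz, noise.one_over_f_exponent, noise.noise_sd, rng
    )
    return x


def synthesize_trial(
    spec: ParadigmSpec,
    coupling: CouplingSpec,
    noise: NoiseSpec,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Generate a single epoch time series; reproducible from ``seed``."""
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    return _epoch_components(spec, coupling, noise, rng, spec.times())


def synthesize_session(
    spec: ParadigmSpec,
    coupling: CouplingSpec,
    noise: NoiseSpec,
    seed: int | np.random.Generator | None = None,
    condition_label: str | None = None,
) -> TrialEnsemble:
    """Full session: a trial ensemble following the session plan.

    Oddball trials share the generative model of standard trials (the
    carrier-tone identity is inaudible at source level); they exist so the
    standard-trial selection step has something to exclude.
    """
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    plan = generate_session_plan(spec, rng)
    times = spec.times()
    data = np.empty((spec.n_trials_total, times.size))
    for i in range(spec.n_trials_total):
        data[i] = _epoch_components(spec, coupling, noise, rng, times)
    label = condition_label or f"{spec.stim_freq_hz:g}Hz"
    return TrialEnsemble(
        data=data,
        times_s=times,
        sampling_rate_hz=spec.sampling_rate_hz,
        condition_label=label,
        trial_kinds=plan["kind"].to_numpy(),
        ground_truth={"coupling": coupling, "noise": noise, "paradigm": spec},
    )


def generate_cohort(
    n_subjects: int,
    spec: ParadigmSpec,
    coupling: CouplingSpec,
    noise: NoiseSpec,
    seed: int | None = None,
    null_cohort: bool = False,
) -> list[TrialEnsemble]:
    """Independent per-subject sessions, deterministic from ``seed``.

    In ``null_cohort`` mode the stimulation window carries no structure
    beyond baseline: coupling depth is forced to 0 and the entrained
    response is switched off, so the stimulus and baseline analysis windows
    are draws from one stationary process (exchangeable null).
    """
    if n_subjects < 2:
        raise ValueError("need n_subjects >= 2")
    if null_cohort:
        coupling = replace(coupling, modulation_depth=0.0)
        noise = replace(noise, assr_amplitude=0.0)
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(0, 2**31 - 1, size=n_subjects)
    return [
        synthesize_session(spec, coupling, noise, seed=int(s)) for s in subject_seeds
    ]
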