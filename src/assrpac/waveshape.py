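"""Rise-decay ratio: a waveform-shape control against spurious coupling.

Non-sinusoidal low-frequency oscillations (sawtooth-like cycles with fast
rises or decays) produce phase-locked harmonic energy that can masquerade
as phase-amplitude coupling. The rise-decay ratio — mean trough-to-peak
duration over mean peak-to-trough duration of the fP-band waveform — is 1
for a symmetric (sinusoidal) wave; if the ratio differs between the
stimulation and baseline windows, apparent coupling differences may be
waveform artifacts.

Extrema are located on a shape-preserving narrowband reconstruction: the
sum of the real parts of the Morlet coefficients at fP and its first few
harmonics (default 4). The fundamental alone would regress every waveform
to a sinusoid (ratio 1 by construction); retaining harmonics keeps the
cycle asymmetry while rejecting broadband noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .synth import TrialEnsemble
from .timefreq import morlet_kernel

__all__ = [
    "RiseDecayResult",
    "narrowband_reconstruction",
    "rise_decay_ratio",
    "compare_rise_decay",
]


@dataclass
class RiseDecayResult:
    ratios: np.ndarray  # per retained trial
    window: str
    phase_freq_hz: float
    n_cycles_used: np.ndarray  # alternation count per retained trial

    @property
    def mean_ratio(self) -> float:
        return float(self.ratios.mean())


def narrowband_reconstruction(
    data: np.ndarray,
    phase_freq_hz: float,
    sampling_rate_hz: float,
    n_cycles: float = 10.0,
    n_harmonics: int = 4,
) -> np.ndarray:
    """Real-valued fP-band signal from Morlet coefficients at fP and
    harmonics below Nyquist."""
    data = np.atleast_2d(np.asarray(data, float))
    n_times = data.shape[-1]
    out = np.zeros_like(data)
    for h in range(1, n_harmonics + 1):
        f = h * phase_freq_hz
        if f >= sampling_rate_hz / 2:
            break
        k = morlet_kernel(f, n_cycles, sampling_rate_hz)
        half = k.size // 2
        for t in range(data.shape[0]):
            c = np.convolve(data[t], k, mode="full")[half : half + n_times]
            out[t] += c.real
    return out


def _alternating_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and types (+1 peak / -1 trough) of strictly alternating
    extrema; of same-type neighbours the more extreme one is kept."""
    peaks, _ = sps.find_peaks(x)
    troughs, _ = sps.find_peaks(-x)
    idx = np.concatenate([peaks, troughs])
    typ = np.concatenate([np.ones(peaks.size), -np.ones(troughs.size)])
    order = np.argsort(idx)
    idx, typ = idx[order], typ[order]
    keep_idx: list[int] = []
    keep_typ: list[float] = []
    for i, t in zip(idx, typ):
        if keep_typ and keep_typ[-1] == t:
            prev = keep_idx[-1]
            better = x[i] > x[prev] if t > 0 else x[i] < x[prev]
            if better:
                keep_idx[-1] = int(i)
        else:
            keep_idx.append(int(i))
            keep_typ.append(float(t))
    return np.array(keep_idx), np.array(keep_typ)


def rise_decay_ratio(
    ensemble_or_data: TrialEnsemble | np.ndarray,
    phase_freq_hz: float,
    window_s: tuple[float, float],
    sampling_rate_hz: float | None = None,
    times_s: np.ndarray | None = None,
    n_cycles: float = 10.0,
    n_harmonics: int = 4,
    window_tag: str = "",
) -> RiseDecayResult:
    """Per-trial rise-decay ratio of the fP-band waveform in a window.

    The window must span at least 2 cycles at fP; a trial with fewer than
    two rise or decay intervals raises.
    """
    if isinstance(ensemble_or_data, TrialEnsemble):
        data = ensemble_or_data.data
        sfreq = ensemble_or_data.sampling_rate_hz
        times = ensemble_or_data.times_s
    else:
        data = np.atleast_2d(np.asarray(ensemble_or_data, float))
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required for raw arrays")
        sfreq = sampling_rate_hz
        times = (
            times_s if times_s is not None else np.arange(data.shape[-1]) / sfreq
        )
    if (window_s[1] - window_s[0]) * phase_freq_hz < 2:
        raise ValueError("window must contain at least 2 cycles at phase_freq_hz")
    narrow = narrowband_reconstruction(data, phase_freq_hz, sfreq, n_cycles, n_harmonics)
    sel = (times >= window_s[0]) & (times < window_s[1])
    ratios = []
    n_cyc = []
    for trial in narrow[:, sel]:
        idx, typ = _alternating_extrema(trial)
        rises, decays = [], []
        for a, b, ta in zip(idx[:-1], idx[1:], typ[:-1]):
            if ta < 0:  # trough -> peak
                rises.append(b - a)
            else:  # peak -> trough
                decays.append(b - a)
        if len(rises) < 1 or len(decays) < 1 or len(idx) < 4:
            raise ValueError(
                "fewer than 2 trough/peak alternations in window; "
                "widen the window or lower n_harmonics"
            )
        ratios.append(np.mean(rises) / np.mean(decays))
        n_cyc.append(min(len(rises), len(decays)))
    return RiseDecayResult(
        ratios=np.array(ratios),
        window=window_tag,
        phase_freq_hz=phase_freq_hz,
        n_cycles_used=np.array(n_cyc),
    )


def compare_rise_decay(
    stim_ratios: np.ndarray,
    base_ratios: np.ndarray,
    n_comparisons: int = 1,
) -> tuple[float, float]:
    """Paired t-test of per-subject mean ratios, Bonferroni-corrected.

    Returns (t, corrected p); p is multiplied by ``n_comparisons`` and
    capped at 1. Identical conditions give t = 0, p = 1.
    """
    stim_ratios = np.asarray(stim_ratios, float)
    base_ratios = np.asarray(base_ratios, float)
    if stim_ratios.shape != base_ratios.shape:
        raise ValueError("paired inputs must have equal length")
    if stim_ratios.size < 3:
        raise ValueError("need at least 3 subjects")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    d = stim_ratios - base_ratios
    if np.all(d == 0):
        return 0.0, 1.0
    t, p = stats.ttest_rel(stim_ratios, base_ratios)
    return float(t), float(min(1.0, p * n_comparisons))
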