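"""Across-trials mean-vector-length (MVL) phase-amplitude coupling with
surrogate z-scoring.

For a phase frequency fP and amplitude frequency fA, the coupling statistic
at one time sample tau is the modulus of the across-trials mean of
amplitude-weighted unit phase vectors,

    MVL(tau) = | (1/n) * sum_t  a[t, tau] * exp(i * phi[t, tau]) |,

with a the min-max-normalized fA amplitude, phi the fP phase and n the
number of trials; the reported raw PAC is the mean of MVL(tau) over the
analysis window. This event-related (across-trials) form is sensitive to
coupling that is consistent over trials at each latency, unlike the
within-trial time-averaged variant.

Null calibration uses segment-swap surrogates: each trial's raw time series
is cut at a random interior point and the two segments are swapped, the
phase is re-measured on the shuffled signal, and MVL is recomputed against
the *unshuffled* amplitudes. z = (observed - mean(surrogates)) /
sd(surrogates) with 250 surrogates by default.

Numerical note: within this module the wavelet filtering is circular over
the epoch by default. A two-segment swap is exactly a circular time shift,
and circular convolution commutes with circular shifts, so all surrogate
phase series are index-shifted views of one transform — the 250-surrogate
ensemble costs no additional convolutions. Observed and surrogate values go
through the identical transform. The wrap-around contamination lives within
``trunc_sigmas * sigma(f)`` of the epoch edges, outside the interior
analysis windows for all but the lowest phase frequencies (where the
decomposition's ``valid_mask`` flags it); ``transform="linear"`` selects
literal zero-padded re-transforms of every shuffled signal instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft

from .synth import TrialEnsemble
from .timefreq import WaveletParams, morlet_kernel, morlet_sigma, morlet_transform

__all__ = [
    "PacParams",
    "Comodulogram",
    "ComodulogramEngine",
    "minmax_normalize",
    "mvl_pac",
    "surrogate_pac",
    "z_score_pac",
    "comodulogram",
    "comodulogram_pair",
]


@dataclass(frozen=True)
class PacParams:
    """Grids, windows and surrogate settings for comodulogram estimation."""

    phase_freqs_hz: np.ndarray = field(default_factory=lambda: np.arange(4.0, 13.0))
    amp_freqs_hz: np.ndarray = field(default_factory=lambda: np.arange(13.0, 61.0))
    n_cycles: float = 10.0
    n_surrogates: int = 250
    stim_window_s: tuple[float, float] = (0.2, 1.0)
    baseline_window_s: tuple[float, float] = (-1.3, -0.5)
    normalization_window_s: tuple[float, float] = (-1.3, 1.3)
    n_segments: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "phase_freqs_hz", np.atleast_1d(np.asarray(self.phase_freqs_hz, float))
        )
        object.__setattr__(
            self, "amp_freqs_hz", np.atleast_1d(np.asarray(self.amp_freqs_hz, float))
        )
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    def window(self, tag: str) -> tuple[float, float]:
        if tag == "stimulus":
            return self.stim_window_s
        if tag == "baseline":
            return self.baseline_window_s
        raise ValueError(f"unknown window tag {tag!r}")


@dataclass
class Comodulogram:
    """fP x fA grid of coupling values with per-cell surrogate summaries."""

    values: np.ndarray  # fP x fA, of `kind`
    raw_mvl: np.ndarray  # fP x fA observed MVL
    surrogate_mean: np.ndarray | None
    surrogate_sd: np.ndarray | None
    phase_freqs_hz: np.ndarray
    amp_freqs_hz: np.ndarray
    kind: str  # "surrogate_z" or "raw_mvl"
    window: str  # "stimulus" | "baseline" | "difference"
    window_s: tuple[float, float] | None
    n_surrogates: int
    seed: int | None

    def argmax_cell(self) -> tuple[float, float]:
        """(fP, fA) of the grid maximum of ``values``."""
        i, j = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.phase_freqs_hz[i]), float(self.amp_freqs_hz[j])


def minmax_normalize(
    series: np.ndarray, norm_mask: np.ndarray
) -> np.ndarray:
    """Min-max transform along the last axis, min/max taken over
    ``norm_mask`` samples.

    Output lies in [0, 1] inside the normalization window; a constant
    series (max == min) maps to all zeros with a warning.
    """
    series = np.asarray(series)
    if not np.issubdtype(series.dtype, np.floating):
        series = series.astype(float)
    window_vals = series[..., norm_mask]
    lo = window_vals.min(axis=-1, keepdims=True)
    hi = window_vals.max(axis=-1, keepdims=True)
    span = hi - lo
    degenerate = span <= 0
    if np.any(degenerate):
        warnings.warn(
            "constant amplitude series in normalization window; mapped to zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, span)
    out = (series - lo) / safe
    return np.where(degenerate, 0.0, out)


def mvl_pac(
    phase: np.ndarray, amp: np.ndarray, window_mask: np.ndarray | None = None
) -> float:
    """Raw across-trials MVL: per-sample modulus of the complex trial mean,
    averaged over the window samples."""
    phase = np.asarray(phase, float)
    amp = np.asarray(amp, float)
    if phase.shape != amp.shape:
        raise ValueError("phase and amp must have the same trials x time shape")
    if phase.shape[0] < 2:
        raise ValueError("MVL requires at least 2 trials")
    z = amp * np.exp(1j * phase)
    per_sample = np.abs(z.mean(axis=0))
    if window_mask is not None:
        per_sample = per_sample[..., window_mask]
    return float(per_sample.mean())


def z_score_pac(observed: float, surrogates: np.ndarray) -> float:
    """z of the observed MVL within the surrogate distribution (sample sd,
    ddof=1)."""
    surrogates = np.asarray(surrogates, float)
    sd = surrogates.std(ddof=1)
    if not sd > 0:
        raise ValueError("degenerate surrogate distribution (sd = 0)")
    return float((observed - surrogates.mean()) / sd)


def _draw_cuts(
    rng: np.random.Generator,
    n_surrogates: int,
    n_trials: int,
    n_times: int,
    margin: int,
) -> np.ndarray:
    lo, hi = margin, n_times - margin
    if hi <= lo:
        lo, hi = 1, n_times - 1  # degenerate margins on very short signals
    return rng.integers(lo, hi, size=(n_surrogates, n_trials))


def _segment_shuffle(
    signal: np.ndarray, cuts: np.ndarray, rng: np.random.Generator, n_segments: int
) -> np.ndarray:
    """Shuffle each trial by cutting and permuting segments.

    With 2 segments (default) the single cut-and-swap equals a circular
    shift by the cut point.
    """
    out = np.empty_like(signal)
    n = signal.shape[-1]
    for t in range(signal.shape[0]):
        if n_segments == 2:
            c = int(cuts[t])
            out[t] = np.concatenate([signal[t, c:], signal[t, :c]])
        else:
            pts = np.sort(rng.choice(np.arange(1, n), size=n_segments - 1, replace=False))
            segs = np.split(signal[t], pts)
            order = rng.permutation(n_segments)
            out[t] = np.concatenate([segs[k] for k in order])
    return out


def surrogate_pac(
    signal: np.ndarray,
    norm_amp: np.ndarray,
    phase_freq_hz: float,
    sampling_rate_hz: float,
    window_mask: np.ndarray,
    n_surrogates: int = 250,
    n_cycles: float = 10.0,
    seed: int | np.random.Generator | None = None,
    n_segments: int = 2,
) -> np.ndarray:
    """Surrogate MVL distribution by literal re-transform.

    Per surrogate, each trial's raw ``signal`` is segment-shuffled, the fP
    wavelet transform is re-run on the shuffled signal (zero-padded linear
    convolution), and MVL is recomputed against the unshuffled ``norm_amp``.
    This is the reference (slow) path; :func:`comodulogram` uses the
    shift-equivalent circular path.
    """
    if window_mask.sum() < 3:
        raise ValueError("analysis window must contain at least 3 samples")
    rng = np.random.default_rng(seed)
    n_trials, n_times = signal.shape
    margin = int(np.ceil(morlet_sigma(phase_freq_hz, n_cycles) * sampling_rate_hz))
    margin = min(margin, (n_times - 2) // 2)
    cuts = _draw_cuts(rng, n_surrogates, n_trials, n_times, margin)
    kernel = morlet_kernel(phase_freq_hz, n_cycles, sampling_rate_hz)
    half = kernel.size // 2
    out = np.empty(n_surrogates)
    for s in range(n_surrogates):
        shuffled = _segment_shuffle(signal, cuts[s], rng, n_segments)
        coeff = np.array(
            [np.convolve(row, kernel, mode="full")[half : half + n_times] for row in shuffled]
        )
        out[s] = mvl_pac(np.angle(coeff), norm_amp, window_mask)
    return out


def _circular_tfr(data: np.ndarray, kernels: list[np.ndarray]) -> np.ndarray:
    """Circular convolution of each trial with each kernel over the epoch
    length; kernels longer than the epoch wrap (periodic summation)."""
    n_trials, n_times = data.shape
    X = fft(data, axis=-1)
    out = np.empty((n_trials, len(kernels), n_times), dtype=complex)
    for j, k in enumerate(kernels):
        half = k.size // 2
        k_circ = np.zeros(n_times, dtype=complex)
        np.add.at(k_circ, (np.arange(k.size) - half) % n_times, k)
        out[:, j, :] = ifft(X * fft(k_circ), axis=-1)
    return out


class ComodulogramEngine:
    """Shared transforms for comodulograms of one ensemble.

    Computes the fP phase streams and min-max-normalized fA amplitudes once;
    :meth:`compute` then evaluates the z-scored grid on any window. Using one
    engine for the stimulus and baseline windows halves the transform cost
    and guarantees both windows see identical machinery.
    """

    def __init__(
        self,
        ensemble: TrialEnsemble,
        params: PacParams | None = None,
        transform: str = "circular",
    ):
        self.params = params or PacParams()
        self.ensemble = ensemble
        self.transform = transform
        p = self.params
        sfreq = ensemble.sampling_rate_hz
        kernels_p = [
            morlet_kernel(f, p.n_cycles, sfreq) for f in p.phase_freqs_hz
        ]
        kernels_a = [morlet_kernel(f, p.n_cycles, sfreq) for f in p.amp_freqs_hz]
        if transform == "circular":
            coeff_p = _circular_tfr(ensemble.data, kernels_p)
            coeff_a = _circular_tfr(ensemble.data, kernels_a)
        elif transform == "linear":
            wp = WaveletParams(freqs_hz=p.phase_freqs_hz, n_cycles=p.n_cycles)
            wa = WaveletParams(freqs_hz=p.amp_freqs_hz, n_cycles=p.n_cycles)
            coeff_p = morlet_transform(ensemble, wp).coeffs
            coeff_a = morlet_transform(ensemble, wa).coeffs
        else:
            raise ValueError("transform must be 'circular' or 'linear'")

        norm_mask = _mask(ensemble.times_s, p.normalization_window_s)
        if not norm_mask.any():
            raise ValueError("normalization window contains no samples")
        amp = np.abs(coeff_a).transpose(1, 0, 2).astype(np.float32)  # (nfA, trials, T)
        self.norm_amp = minmax_normalize(amp, norm_mask)  # (nfA, trials, T) f32
        with np.errstate(invalid="ignore", divide="ignore"):
            mod = np.abs(coeff_p)
            self.unit_phase = np.where(mod > 0, coeff_p / mod, 0.0).transpose(1, 0, 2)
        # (nfP, trials, T) unit phase vectors
        self._unit32 = self.unit_phase.astype(np.complex64)
        self._doubled_cache: dict[int, np.ndarray] = {}
        self.n_trials, self.n_times = ensemble.data.shape

    def _doubled(self, i: int) -> np.ndarray:
        """Phase unit vectors at fP index i, tiled twice along time so any
        circularly shifted window is a contiguous slice."""
        if i not in self._doubled_cache:
            u = self._unit32[i]
            self._doubled_cache[i] = np.concatenate([u, u], axis=-1)
        return self._doubled_cache[i]

    def compute(self, window: str = "stimulus", seed: int | None = None) -> Comodulogram:
        p = self.params
        window_s = p.window(window)
        win = np.nonzero(_mask(self.ensemble.times_s, window_s))[0]
        if win.size < 3:
            raise ValueError("analysis window must contain at least 3 samples")
        if self.n_trials < 2:
            raise ValueError("MVL requires at least 2 trials")
        seed = p.seed if seed is None else seed
        rng = np.random.default_rng(seed)

        nfP = p.phase_freqs_hz.size
        nfA = p.amp_freqs_hz.size
        n = self.n_trials

        # observed grid (float64 accumulation over float32 inputs)
        A_w = np.ascontiguousarray(
            self.norm_amp[:, :, win].transpose(2, 0, 1), dtype=float
        )  # (nwin, nfA, trials)
        raw = np.empty((nfP, nfA))
        for i in range(nfP):
            U = self.unit_phase[i][:, win].T[:, :, None]  # (nwin, trials, 1)
            Cr = A_w @ U.real
            Ci = A_w @ U.imag
            raw[i] = (np.sqrt(Cr**2 + Ci**2)[..., 0] / n).mean(axis=0)

        # surrogates: two-segment swap == circular shift; the shifted phase
        # window is a contiguous slice of the doubled phase array, so no
        # convolution is repeated
        margin = int(
            np.ceil(
                morlet_sigma(p.phase_freqs_hz.min(), p.n_cycles)
                * self.ensemble.sampling_rate_hz
            )
        )
        margin = min(margin, (self.n_times - 2) // 2)
        if p.n_segments != 2 or self.transform == "linear":
            return self._compute_literal(window, window_s, win, raw, rng)
        cuts = _draw_cuts(rng, p.n_surrogates, n, self.n_times, margin)
        if np.any(np.diff(win) != 1):
            raise AssertionError("analysis window must be a contiguous sample range")
        w0, nwin = int(win[0]), win.size

        A_w32 = A_w.astype(np.float32)
        sur = np.empty((nfP, nfA, p.n_surrogates), dtype=np.float32)
        chunk = 64
        trial_ix = np.arange(n)[None, :]
        for s0 in range(0, p.n_surrogates, chunk):
            c = cuts[s0 : s0 + chunk]  # (S, trials)
            start = (w0 + c) % self.n_times  # (S, trials) slice starts
            for i in range(nfP):
                # (trials, 2T - nwin + 1, nwin) sliding view, then block-copy
                # the (S, trials) selected windows
                view = np.lib.stride_tricks.sliding_window_view(
                    self._doubled(i), nwin, axis=-1
                )
                U = view[trial_ix, start]  # (S, trials, nwin) complex64
                Uw = np.ascontiguousarray(U.transpose(2, 1, 0))  # (nwin, trials, S)
                Cr = A_w32 @ Uw.real
                Ci = A_w32 @ Uw.imag
                sur[i, :, s0 : s0 + c.shape[0]] = (
                    np.sqrt(Cr**2 + Ci**2) / n
                ).mean(axis=0)

        sur64 = sur.astype(float)
        smean = sur64.mean(axis=2)
        ssd = sur64.std(axis=2, ddof=1)
        if np.any(ssd <= 0):
            raise ValueError("degenerate surrogate distribution (sd = 0)")
        z = (raw - smean) / ssd
        return Comodulogram(
            values=z,
            raw_mvl=raw,
            surrogate_mean=smean,
            surrogate_sd=ssd,
            phase_freqs_hz=p.phase_freqs_hz.copy(),
            amp_freqs_hz=p.amp_freqs_hz.copy(),
            kind="surrogate_z",
            window=window,
            window_s=window_s,
            n_surrogates=p.n_surrogates,
            seed=seed,
        )

    def _compute_literal(self, window, window_s, win, raw, rng):
        """Reference path: re-transform every shuffled signal."""
        p = self.params
        win_mask = np.zeros(self.n_times, dtype=bool)
        win_mask[win] = True
        nfP, nfA = p.phase_freqs_hz.size, p.amp_freqs_hz.size
        sur = np.empty((nfP, nfA, p.n_surrogates))
        seed_seq = rng.integers(0, 2**31 - 1, size=nfP)
        for i, fp in enumerate(p.phase_freqs_hz):
            for j in range(nfA):
                sur[i, j] = surrogate_pac(
                    self.ensemble.data,
                    self.norm_amp[j],
                    fp,
                    self.ensemble.sampling_rate_hz,
                    win_mask,
                    n_surrogates=p.n_surrogates,
                    n_cycles=p.n_cycles,
                    seed=int(seed_seq[i]),
                    n_segments=p.n_segments,
                )
        smean = sur.mean(axis=2)
        ssd = sur.std(axis=2, ddof=1)
        if np.any(ssd <= 0):
            raise ValueError("degenerate surrogate distribution (sd = 0)")
        return Comodulogram(
            values=(raw - smean) / ssd,
            raw_mvl=raw,
            surrogate_mean=smean,
            surrogate_sd=ssd,
            phase_freqs_hz=p.phase_freqs_hz.copy(),
            amp_freqs_hz=p.amp_freqs_hz.copy(),
            kind="surrogate_z",
            window=window,
            window_s=window_s,
            n_surrogates=p.n_surrogates,
            seed=None,
        )


def _mask(times: np.ndarray, window_s: tuple[float, float]) -> np.ndarray:
    return (times >= window_s[0]) & (times < window_s[1])


def comodulogram(
    ensemble: TrialEnsemble,
    params: PacParams | None = None,
    window: str = "stimulus",
    seed: int | None = None,
    transform: str = "circular",
) -> Comodulogram:
    """z-scored PAC comodulogram of one ensemble on one analysis window."""
    return ComodulogramEngine(ensemble, params, transform=transform).compute(
        window, seed=seed
    )


def comodulogram_pair(
    ensemble: TrialEnsemble,
    params: PacParams | None = None,
    seed: int | None = None,
    transform: str = "circular",
) -> tuple[Comodulogram, Comodulogram]:
    """Stimulus- and baseline-window comodulograms sharing one transform."""
    eng = ComodulogramEngine(ensemble, params, transform=transform)
    return eng.compute("stimulus", seed=seed), eng.compute("baseline", seed=seed)
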