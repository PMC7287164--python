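# Methods

## Pipeline overview

The package analyses epoched, source-level time series from an auditory
steady-state response (ASSR) paradigm: click trains at 40/30/20 Hz inside
an oddball task (100 trials per condition, 85 standards analyzed, epochs
−1.5…+1.5 s at 1000 Hz). Stages: epoch conditioning → Morlet
time-frequency (amplitude, inter-trial phase coherence) → across-trials
mean-vector-length phase-amplitude coupling (PAC) with surrogate
z-scoring → stimulus-vs-baseline cluster permutation inference →
rise-decay waveform-shape control → tidy per-subject/cohort tables.
A synthetic session generator with exact ground truth drives all testing.

## Synthetic sessions

Each trial is a sum of four components:

1. **Entrained response**: a sinusoid at the stimulation frequency,
   active over the train (default 0–1 s), phase-locked across trials;
   `assr_phase_jitter` ∈ [0, 1] interpolates from perfect locking
   (ITC ≈ 1) to fully random onset phase. Default amplitude 1 (the gamma
   carrier defines the unit).
2. **Low-frequency oscillation** at fP (default 6 Hz), amplitude
   `phase_amp_ratio` (default 2) relative to the gamma carrier, with a
   random phase per trial — the paradigm does not reset ongoing slow
   rhythms, matching the across-trials PAC logic where amplitude and
   phase vary by trial. `waveform_asymmetry` a ∈ (−1, 1) warps each cycle
   piecewise-linearly (rise occupies (1−a)/2 of the cycle) while
   preserving the fundamental period, giving the rise-decay module a
   controlled positive case; the ideal ratio is (1−a)/(1+a).
3. **Gamma carrier** at fA (default 40 Hz), unit amplitude, with envelope
   `1 + m·waveform(φ_low)` inside the coupling window (default
   0.2–1.0 s, 50-ms cosine ramps at the edges to avoid a broadband step);
   m ∈ [0, 1] is the ground-truth modulation depth (m = 1 lets the
   envelope touch zero). Coupling locks to the *warped* phase when the
   waveform is asymmetric.
4. **1/f noise**: white Gaussian noise spectrally shaped to
   PSD ∝ 1/f^α (default α = 1), rescaled to `noise_sd` (default 1),
   independent across trials.

Defaults were chosen once as plausible source-level proportions (slow
rhythms larger than gamma; broadband background comparable to the gamma
carrier) and drive all validation experiments. All randomness flows
through a single seeded `numpy.random.Generator` per call; cohort
generation derives independent per-subject seeds (< 2³¹) from one root
seed.

**What the generator does not emulate**: sensor-level physics (forward
models, channel noise covariance), head motion, ECG/EOG artifacts,
heterogeneous oscillator bandwidths, non-stationary background spectra.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative law, not robustness to every property of recorded
MEG.

## Epoch conditioning

Windows are half-open `[start, end)` seconds; canonical values: amplitude
baseline −1.3…−0.5 s, PAC stimulus 0.2…1.0 s, PAC baseline −1.3…−0.5 s,
normalization −1.3…+1.3 s. Baseline subtraction removes each trial's
baseline mean from the whole epoch by default (a `scope="post"` switch
restricts it to t ≥ 0); the whole-epoch choice changes no amplitude
contrast and keeps baseline-window statistics centred. Peak-to-peak
rejection drops a trial iff max−min ≥ threshold (the boundary rejects);
the conventional MEG thresholds (100e−12 fT magnetometers, 4000e−13
fT/cm gradiometers) apply only to channel-level data through the FIF
adapter — synthetic/source data use user-set thresholds in their own
units. Upstream artifact suppression (tSSS, ICA, filtering, source
estimation) is out of scope; the FIF adapter assumes cleaned input.

## Time-frequency decomposition

Morlet kernels `w(t) = exp(2πift)·exp(−t²/2σ²)`, `σ = n/(2πf)`, n = 10
cycles everywhere (frequency resolution prioritized). Numerical choices:

* Kernels truncated at ±5σ (Gaussian tail < 1e−5) and scaled by
  `2/Σg` (g the sampled envelope), so a unit sinusoid at f has amplitude
  1.000 at its own frequency — amplitude maps read in signal units.
* Linear (zero-padded) FFT convolution, 'same' alignment; verified
  against naive time-domain convolution to 1e−10.
* `valid_mask` flags samples within 2σ(f) of an epoch edge instead of
  trimming. At fP = 4 Hz (σ ≈ 0.40 s) parts of the standard analysis
  windows are flagged; computation proceeds and the flag is surfaced —
  low-fP cells should be read with that caveat.
* Amplitude grids 1–60 Hz in 1-Hz steps; baseline correction subtracts
  the per-frequency baseline mean from the trial-averaged map (per-trial
  correction available); ITC is the modulus of the across-trials mean
  unit phase vector.

## Phase-amplitude coupling

At each (fP, fA) cell: fA amplitudes are min-max normalized per trial ×
frequency over the normalization window (a constant series maps to zeros
with a warning); the across-trials MVL
`MVL(τ) = |n⁻¹ Σ_t a_{t,τ} e^{iφ_{t,τ}}|` is averaged over the window's
samples. The observed value is z-scored (sample sd, ddof 1) against 250
surrogates; each surrogate cuts every trial's raw time series at one
uniformly random interior point (margins of one σ at the lowest fP
excluded, so near-identity swaps cannot occur), swaps the two segments,
re-measures fP phase on the shuffled signal, and recomputes MVL against
the unshuffled amplitudes. Phase streams only are randomized; amplitudes
stay fixed.

**Numerical choice — circular transforms in the PAC module.** A
two-segment swap is exactly a circular shift, and circular convolution
commutes with circular shifts, so with the wavelet filtering defined
circularly over the epoch every surrogate phase stream is an
index-shifted view of one transform: the full 250-surrogate ensemble
costs no repeated convolutions. Observed and surrogate values pass
through identical machinery. Wrap-around contamination is confined within
5σ(f) of the epoch edges — outside the interior analysis windows except
at the lowest phase frequencies, where `valid_mask` flags it anyway. The
literal zero-padded re-transform path is retained
(`transform="linear"`, and the public `surrogate_pac`); the two agree to
machine precision in the wrap-free interior and serve as mutual oracles
in the tests. Surrogate mass computations run in single precision (the
z-score is insensitive at the 1e−7 level); observed grids accumulate in
double precision.

More than two segments (`n_segments > 2`, random segment permutation) is
supported through the literal path.

## Cluster inference

Paired design: per subject one stimulus- and one baseline-window
comodulogram from the same trials. Per-cell paired t (df = n−1);
one-tailed cluster-forming threshold at p = 0.01; connected components
under 4-neighbour adjacency (8-neighbour by flag); cluster mass = Σt.
The null is the distribution of the maximum cluster mass over independent
per-subject sign flips of the paired differences (the exact paired
exchangeability null; sums of squares are flip-invariant, so only means
are recomputed per permutation). Corrected
p = (1 + #{max ≥ mass})/(1 + N) with N = 5000 by default; a cluster is
significant at p < 0.05. The two printed operating points coexist as:
cluster-*forming* (inclusion) threshold 0.01, cluster-level significance
0.05; both configurable. Exhaustive 2ⁿ enumeration replaces Monte-Carlo
sampling on request for n ≤ 16 subjects and anchors the oracle tests;
cohorts with fewer than 100 distinct sign patterns trigger a resolution
warning.

## Rise-decay control

The fP-band waveform is reconstructed as the sum of the real parts of
Morlet coefficients at fP and its harmonics up to the 4th (below
Nyquist). Reconstruction from the fundamental alone would be sinusoidal
for *any* waveform — the control would read 1 by construction — while
harmonics beyond the 4th mostly admit noise (at noise sd 0.5 the
8-harmonic estimate of a ratio-0.43 waveform regresses to ≈ 0.95; the
4-harmonic estimate stays ≈ 0.53). Local extrema with enforced
peak/trough alternation (keeping the more extreme of same-type
neighbours) yield per-trial mean rise (trough→peak) and decay
(peak→trough) durations; the ratio is 1 for symmetric waveforms and
(1−a)/(1+a) ideally for warp a — measured ≈ 0.50 at a = 0.4 (ideal 0.43;
harmonic truncation biases mildly toward 1). Condition comparison:
paired t on per-subject mean ratios, Bonferroni-corrected across the fP
rows tested (significant-cluster rows by default, full grid otherwise).

## Validation experiments and problem sizes

`assrpac.validation` defines the standard self-checks; Monte-Carlo sizes
are scaled-down defaults chosen as desk-sized experiments:

* **Null calibration**: 50 no-coupling sessions (85 trials, 500 Hz
  sampling, 200 surrogates); pooled comodulogram z ≈ N(0, 1) (measured
  mean ≈ −0.02, sd ≈ 0.98). Within one grid, cells are correlated, so
  per-run grid means scatter more than 1/√cells — calibration holds
  pooled, not per run.
* **Parameter recovery**: coupled (6, 40, m) sessions; z at the true cell
  is strictly monotone in m (≈ −0.6 / 0.7 / 2.8 / 4.2 at
  m = 0/0.3/0.6/0.9) and far exceeds the off-ridge grid.
* **Familywise error**: 200 null cohorts × 12 subjects, 250 Hz, 20
  trials, 5×12 grid, 50 surrogates, 1000 permutations, significance at
  the 1% familywise level; observed false-positive rate ≈ 0.5–1%.
  Validity follows from exchangeability alone, so the reduction does not
  weaken the check.

Validation ensembles switch the entrained component off
(`assr_amplitude = 0`). This is deliberate: a phase-locked evoked
transient leaks consistent low-frequency phase across trials near
stimulus onset/offset and biases event-related MVL upward everywhere
(measured grid-mean z ≈ +1.5 at default ASSR amplitude) — the evoked
confound of across-trials PAC. Estimator calibration is therefore defined
against the stationary process; on data with strong evoked responses the
stimulus-window PAC should be interpreted with this caveat (the
stimulus-vs-baseline cluster contrast subtracts much, but not all, of
it).

## Known limitations

* **fA localization is bandwidth-limited.** With n = 10 cycles the
  amplitude filter at 40 Hz has σ_f = 4 Hz, below a 6-Hz modulation
  rate: the sidebands of an envelope-modulated carrier fall partly
  outside the filter at the true cell, while filters centred 4–6 Hz
  higher pass carrier + one sideband and see a *larger relative*
  modulation depth. Since min-max normalization and surrogate z-scoring
  are scale-free, the comodulogram forms a broad plateau over
  fA ≈ truth ± fP whose maximum typically sits 3–6 Hz above the true
  carrier; single-cell argmax recovery in fA is accordingly unreliable
  (the fP axis localizes to ±1 Hz once realistic background noise
  decoheres neighbouring phase rows). Cluster-level inference is the
  intended readout: significant clusters bracket the truth but span a
  broad fA band, as in the worked example.
* Event-related MVL inherits the evoked-transient bias described above.
* The surrogate scheme preserves waveform shape and autocorrelation but
  not slow nonstationarity within an epoch; strongly drifting signals
  could inflate surrogate variance.
* Group-level inferential statistics beyond the cluster test (ANCOVA and
  relatives on cluster summaries) are intentionally not implemented; the
  report tables are designed to feed standard statistics environments.
  Spearman confound correlations are reported uncorrected with the
  conventional adjusted alpha (0.025) noted in the manifest.
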