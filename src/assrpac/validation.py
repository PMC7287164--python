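"""Estimator-validation experiments: null calibration, parameter recovery,
and familywise error rate of the cluster test under an exchangeable null.

These routines define the package's standard self-checks on synthetic
ground truth. They deliberately use the generator's entrainment-free mode
(``assr_amplitude = 0``): a phase-locked evoked response leaks transient
low-frequency phase alignment across trials and biases the event-related
MVL everywhere (a known confound of across-trials coupling measures, see
the methods note), so estimator calibration is defined against the
stationary process. Monte-Carlo problem sizes (sampling rate, trial count,
grids, surrogate count) are scaled-down defaults chosen to keep the
experiments desk-sized; the statistics they probe do not depend on the
reduction.
"""

from __future__ import annotations

import numpy as np

from .cluster_stats import ClusterTestParams, cluster_permutation_test
from .pac import Comodulogram, ComodulogramEngine, PacParams
from .preprocess import select_analysis_trials
from .synth import CouplingSpec, NoiseSpec, ParadigmSpec, generate_cohort, synthesize_session

__all__ = [
    "validation_paradigm",
    "validation_ensemble",
    "null_calibration_z",
    "recovery_comodulogram",
    "fwer_null_experiment",
]


def validation_paradigm(sampling_rate_hz: float = 500.0) -> ParadigmSpec:
    """Study paradigm at a reduced sampling rate for Monte-Carlo work."""
    return ParadigmSpec(sampling_rate_hz=sampling_rate_hz)


def validation_ensemble(
    seed: int,
    modulation_depth: float,
    sampling_rate_hz: float = 500.0,
    noise_sd: float = 1.0,
):
    """One analyzed session (85 standard trials), entrainment-free."""
    spec = validation_paradigm(sampling_rate_hz)
    coupling = CouplingSpec(modulation_depth=modulation_depth)
    noise = NoiseSpec(noise_sd=noise_sd, assr_amplitude=0.0)
    return select_analysis_trials(synthesize_session(spec, coupling, noise, seed=seed))


def null_calibration_z(seed: int, n_surrogates: int = 250) -> np.ndarray:
    """Stimulus-window z-grid of one no-coupling ensemble."""
    ens = validation_ensemble(seed, modulation_depth=0.0)
    params = PacParams(n_surrogates=n_surrogates, seed=seed)
    return ComodulogramEngine(ens, params).compute("stimulus").values


def recovery_comodulogram(
    seed: int, modulation_depth: float = 0.8, n_surrogates: int = 250
) -> Comodulogram:
    """Stimulus-window comodulogram of a coupled (6 Hz, 40 Hz) ensemble."""
    ens = validation_ensemble(seed, modulation_depth=modulation_depth)
    params = PacParams(n_surrogates=n_surrogates, seed=seed)
    return ComodulogramEngine(ens, params).compute("stimulus")


def fwer_null_experiment(
    n_cohorts: int = 200,
    n_subjects: int = 12,
    seed: int = 0,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.01,
    n_trials: int = 20,
    n_surrogates: int = 50,
    sampling_rate_hz: float = 250.0,
) -> dict:
    """Familywise false-positive rate of the full pipeline under an
    exchangeable null.

    Each cohort: ``n_subjects`` stationary no-coupling sessions; per subject
    a stimulus- and a baseline-window comodulogram on a coarsened 5 x 12
    grid; then the one-tailed cluster permutation test (cluster-forming
    p = 0.01) declaring significance at ``cluster_alpha``. Returns the
    fraction of cohorts with any significant cluster.
    """
    spec = ParadigmSpec(
        sampling_rate_hz=sampling_rate_hz,
        n_trials_total=n_trials,
        n_oddball=0,
        n_blocks=4,
    )
    pac = PacParams(
        phase_freqs_hz=np.arange(4.0, 13.0, 2.0),
        amp_freqs_hz=np.arange(15.0, 61.0, 4.0),
        n_surrogates=n_surrogates,
    )
    root = np.random.default_rng(seed)
    false_positives = 0
    for k in range(n_cohorts):
        cohort_seed = int(root.integers(0, 2**31 - 1))
        cohort = generate_cohort(
            n_subjects, spec, CouplingSpec(), NoiseSpec(), seed=cohort_seed,
            null_cohort=True,
        )
        stim, base = [], []
        for sid, ens in enumerate(cohort):
            eng = ComodulogramEngine(ens, pac)
            stim.append(eng.compute("stimulus", seed=cohort_seed + sid).values)
            base.append(eng.compute("baseline", seed=cohort_seed + sid).values)
        res = cluster_permutation_test(
            stim,
            base,
            ClusterTestParams(
                n_permutations=n_permutations,
                cluster_forming_p=0.01,
                cluster_alpha=cluster_alpha,
                seed=cohort_seed,
            ),
        )
        if res.significant_clusters:
            false_positives += 1
    return {
        "false_positive_rate": false_positives / n_cohorts,
        "n_cohorts": n_cohorts,
        "n_false_positive": false_positives,
        "nominal_alpha": cluster_alpha,
    }
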