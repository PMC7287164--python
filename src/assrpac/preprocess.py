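"""Epoch-level conditioning: baseline subtraction, peak-to-peak rejection,
analysis-trial selection, and the canonical analysis windows.

Windows are half-open ``[start, end)`` in seconds; a sample belongs to a
window iff ``start <= t < end``. This avoids double-counting boundary
samples between adjacent windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import STANDARD, TrialEnsemble

__all__ = [
    "WindowSet",
    "RejectionRule",
    "RejectionReport",
    "baseline_subtract",
    "reject_epochs",
    "select_analysis_trials",
]

Window = tuple[float, float]


@dataclass(frozen=True)
class WindowSet:
    """Canonical analysis windows (seconds, relative to stimulus onset)."""

    epoch_s: Window = (-1.5, 1.5)
    amp_baseline_s: Window = (-1.3, -0.5)
    pac_baseline_s: Window = (-1.3, -0.5)
    pac_stim_s: Window = (0.2, 1.0)
    normalization_s: Window = (-1.3, 1.3)

    def __post_init__(self) -> None:
        lo, hi = self.epoch_s
        for name in ("amp_baseline_s", "pac_baseline_s", "pac_stim_s", "normalization_s"):
            a, b = getattr(self, name)
            if not (a < b):
                raise ValueError(f"{name} must have start < end")
            if a < lo or b > hi:
                raise ValueError(f"{name} must lie within epoch_s")


@dataclass(frozen=True)
class RejectionRule:
    """Peak-to-peak rejection threshold in the data's own amplitude units.

    For recorded MEG channels the conventional thresholds are 100e-12
    (magnetometers, fT) and 4000e-13 (gradiometers, fT/cm); source-level or
    synthetic data use whatever units the ensemble carries.
    """

    ptp_threshold: float
    channel_kind: str = "source"

    def __post_init__(self) -> None:
        if self.ptp_threshold <= 0:
            raise ValueError("ptp_threshold must be > 0")


@dataclass
class RejectionReport:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def dropped_indices(self) -> np.ndarray:
        if self.table.empty:
            return np.array([], dtype=int)
        return self.table.loc[self.table["dropped"], "trial_index"].to_numpy()

    @property
    def n_dropped(self) -> int:
        return int(self.table["dropped"].sum()) if not self.table.empty else 0


def baseline_subtract(
    ensemble: TrialEnsemble,
    window: Window = WindowSet().amp_baseline_s,
    scope: str = "epoch",
) -> TrialEnsemble:
    """Subtract each trial's mean over the baseline window.

    ``scope='epoch'`` (default) removes the baseline mean from the whole
    trial so baseline-window statistics are centred everywhere downstream;
    ``scope='post'`` subtracts only from post-stimulus samples (t >= 0),
    leaving the pre-stimulus segment untouched.
    """
    idx = ensemble.window_indices(window)
    if idx.size == 0:
        raise ValueError(f"baseline window {window} contains no samples")
    means = ensemble.data[:, idx].mean(axis=1, keepdims=True)
    if scope == "epoch":
        data = ensemble.data - means
    elif scope == "post":
        data = ensemble.data.copy()
        post = ensemble.times_s >= 0
        data[:, post] -= means
    else:
        raise ValueError("scope must be 'epoch' or 'post'")
    return ensemble.copy_with(data, trial_kinds=ensemble.trial_kinds)


def reject_epochs(
    ensemble: TrialEnsemble, rule: RejectionRule
) -> tuple[TrialEnsemble, RejectionReport]:
    """Drop trials whose peak-to-peak amplitude reaches the threshold.

    A trial is rejected iff ``max - min >= ptp_threshold`` (the threshold
    itself rejects). Raises if nothing survives, with the report attached to
    the exception.
    """
    ptp = ensemble.data.max(axis=1) - ensemble.data.min(axis=1)
    dropped = ptp >= rule.ptp_threshold
    report = RejectionReport(
        pd.DataFrame(
            {
                "trial_index": np.arange(ensemble.n_trials),
                "ptp": ptp,
                "threshold": rule.ptp_threshold,
                "dropped": dropped,
            }
        )
    )
    if dropped.all():
        err = ValueError("all trials rejected by peak-to-peak threshold")
        err.report = report  # type: ignore[attr-defined]
        raise err
    keep = ~dropped
    kinds = ensemble.trial_kinds[keep] if ensemble.trial_kinds is not None else None
    return ensemble.copy_with(ensemble.data[keep], trial_kinds=kinds), report


def select_analysis_trials(ensemble: TrialEnsemble) -> TrialEnsemble:
    """Keep standard trials only (oddballs are excluded from analysis),
    preserving order."""
    if ensemble.trial_kinds is None:
        raise ValueError("ensemble has no trial_kinds; cannot select standards")
    keep = np.asarray(ensemble.trial_kinds) == STANDARD
    if not keep.any():
        raise ValueError("no standard trials present")
    return ensemble.copy_with(
        ensemble.data[keep], trial_kinds=ensemble.trial_kinds[keep]
    )
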