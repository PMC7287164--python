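"""Readers and writers: HDF5 trial ensembles, CSV tables, comodulogram
CSV + JSON sidecars, delimited-text import, and a thin FIF epochs adapter.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import CouplingSpec, NoiseSpec, ParadigmSpec, TrialEnsemble

__all__ = [
    "save_ensemble_h5",
    "load_ensemble_h5",
    "save_comodulogram_csv",
    "load_comodulogram_csv",
    "ensemble_from_delimited",
    "ensemble_from_fif_epochs",
]


def save_ensemble_h5(ensemble: TrialEnsemble, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ensemble.data)
        f.create_dataset("times", data=ensemble.times_s)
        if ensemble.trial_kinds is not None:
            f.create_dataset(
                "labels", data=np.asarray(ensemble.trial_kinds, dtype="S16")
            )
        f.attrs["sampling_rate_hz"] = ensemble.sampling_rate_hz
        f.attrs["condition_label"] = ensemble.condition_label
        for key in ("coupling", "noise", "paradigm"):
            spec = ensemble.ground_truth.get(key)
            if spec is not None:
                f.attrs[f"{key}_json"] = json.dumps(asdict(spec), default=float)


def load_ensemble_h5(path: str | Path) -> TrialEnsemble:
    with h5py.File(path, "r") as f:
        kinds = None
        if "labels" in f:
            kinds = np.array([s.decode() for s in f["labels"][()]])
        gt = {}
        for key, cls in (
            ("coupling", CouplingSpec),
            ("noise", NoiseSpec),
            ("paradigm", ParadigmSpec),
        ):
            attr = f.attrs.get(f"{key}_json")
            if attr is not None:
                d = json.loads(attr)
                for k, v in d.items():
                    if isinstance(v, list):
                        d[k] = tuple(v)
                gt[key] = cls(**d)
        return TrialEnsemble(
            data=f["data"][()],
            times_s=f["times"][()],
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            condition_label=str(f.attrs.get("condition_label", "")),
            trial_kinds=kinds,
            ground_truth=gt,
        )


def save_comodulogram_csv(comod, path: str | Path) -> None:
    """fP rows x fA columns CSV plus a JSON sidecar with run metadata."""
    path = Path(path)
    df = pd.DataFrame(
        comod.values,
        index=pd.Index(comod.phase_freqs_hz, name="fP_hz"),
        columns=pd.Index(comod.amp_freqs_hz, name="fA_hz"),
    )
    df.to_csv(path)
    sidecar = {
        "kind": comod.kind,
        "window": comod.window,
        "window_s": list(comod.window_s) if comod.window_s else None,
        "n_surrogates": comod.n_surrogates,
        "seed": comod.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_comodulogram_csv(path: str | Path):
    """Load the grid (values only) with its frequency axes."""
    df = pd.read_csv(path, index_col=0)
    return (
        df.to_numpy(),
        df.index.to_numpy(dtype=float),
        df.columns.to_numpy(dtype=float),
    )


def ensemble_from_delimited(
    path: str | Path,
    sampling_rate_hz: float,
    t_start_s: float = 0.0,
    delimiter: str = ",",
    condition_label: str = "",
) -> TrialEnsemble:
    """Trials x time numeric text file -> ensemble (rows are trials)."""
    data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    times = t_start_s + np.arange(data.shape[1]) / sampling_rate_hz
    return TrialEnsemble(
        data=data,
        times_s=times,
        sampling_rate_hz=sampling_rate_hz,
        condition_label=condition_label,
    )


def ensemble_from_fif_epochs(
    path: str | Path, picks=None, condition_label: str = ""
) -> TrialEnsemble:
    """Epoched FIF file -> ensemble of the mean across picked channels.

    Requires the optional ``mne`` dependency. The input is assumed to be
    already cleaned (artifact suppression, filtering and source estimation
    are upstream, external stages).
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "the FIF adapter requires mne (pip install assrpac[fif])"
        ) from err
    epochs = mne.read_epochs(str(path), preload=True, verbose="error")
    data = epochs.get_data(picks=picks).mean(axis=1)
    return TrialEnsemble(
        data=data,
        times_s=epochs.times,
        sampling_rate_hz=float(epochs.info["sfreq"]),
        condition_label=condition_label,
    )
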