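"""Diagnostic figures: time-frequency images and comodulogram panels.

Requires the optional matplotlib dependency; figures are returned, not
shown, so callers control the backend.
"""

from __future__ import annotations

import numpy as np


def _mpl():
    try:
        import matplotlib.pyplot as plt
    except ImportError as err:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install assrpac[plot])") from err
    return plt


def plot_time_frequency(
    value_map: np.ndarray,
    freqs_hz: np.ndarray,
    times_s: np.ndarray,
    title: str = "",
    cmap: str = "RdBu_r",
    symmetric: bool = True,
):
    """Image of a freqs x time map (amplitude or ITC) on the epoch axes."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    vmax = np.abs(value_map).max() or 1.0
    kw = dict(vmin=-vmax, vmax=vmax) if symmetric else {}
    mesh = ax.pcolormesh(times_s, freqs_hz, value_map, cmap=cmap, shading="auto", **kw)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title)
    fig.colorbar(mesh, ax=ax)
    return fig


def plot_comodulogram(comod, title: str = "", cmap: str = "viridis"):
    """fP x fA panel of a comodulogram's values (z by default)."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 3.2))
    mesh = ax.pcolormesh(
        comod.amp_freqs_hz, comod.phase_freqs_hz, comod.values, cmap=cmap, shading="auto"
    )
    ax.set_xlabel("amplitude frequency fA (Hz)")
    ax.set_ylabel("phase frequency fP (Hz)")
    ax.set_title(title or f"{comod.window} window ({comod.kind})")
    fig.colorbar(mesh, ax=ax, label="z" if comod.kind == "surrogate_z" else "MVL")
    return fig
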