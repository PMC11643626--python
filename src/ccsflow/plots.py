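"""Figure output: radial speed curves, polar direction histograms, quiver
overlays and kymographs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .flowquant import DirectionHistogram, RadialProfile
from .piv import FlowField

__all__ = ["plot_radial_profile", "plot_direction_histogram",
           "plot_flow_field", "plot_kymograph"]


def plot_radial_profile(profile: RadialProfile, path: str | Path,
                        absolute: bool = True) -> None:
    """Radial speed vs distance from the cell centre.  By default plots
    |Vr| ("radial speed"); the stored Vr is signed (negative = inward)."""
    fig, ax = plt.subplots(figsize=(4, 3))
    v = np.abs(profile.vr_um_s) if absolute else profile.vr_um_s
    ax.plot(profile.r_mid_um, v, "o-")
    ax.set_xlabel("radial distance (µm)")
    ax.set_ylabel("radial speed (µm/s)" if absolute
                  else "radial velocity $V_r$ (µm/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_direction_histogram(hist: DirectionHistogram, path: str | Path) -> None:
    """Polar histogram of flow direction relative to the radial direction."""
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    centers = np.radians(hist.bin_centers_deg)
    widths = np.radians(np.diff(hist.bin_edges_deg))
    ax.bar(centers, hist.density, width=widths, bottom=0.0, alpha=0.7,
           edgecolor="k", linewidth=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_flow_field(field: FlowField, path: str | Path,
                    background: np.ndarray | None = None) -> None:
    """Quiver plot of the (time-averaged) flow field, optionally over an
    intensity image."""
    fig, ax = plt.subplots(figsize=(5, 5))
    if background is not None:
        ax.imshow(background, cmap="gray", origin="upper")
    ok = field.valid
    ax.quiver(field.x[ok], field.y[ok], field.vx[ok], -field.vy[ok],
              color="yellow" if background is not None else "tab:blue",
              angles="xy")
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_kymograph(kymo: np.ndarray, path: str | Path,
                   pixel_size: float = 1.0, frame_interval: float = 1.0) -> None:
    """Space-time image: x axis distance, y axis time."""
    fig, ax = plt.subplots(figsize=(4, 4))
    extent = (0, kymo.shape[1] * pixel_size, kymo.shape[0] * frame_interval, 0)
    ax.imshow(kymo, aspect="auto", cmap="gray", extent=extent)
    ax.set_xlabel("distance (µm)" if pixel_size != 1.0 else "distance (px)")
    ax.set_ylabel("time (s)" if frame_interval != 1.0 else "time (frames)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
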