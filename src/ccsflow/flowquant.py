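"""Radial flow profiles and flow-direction histograms.

Given a time-averaged flow field V(x, y) and the cell centre (xc, yc), the
field is moved to centred polar coordinates (r, theta) and quantified as:

* the radial speed profile Vr(r): the radial component
  Vr = Vx cos(theta) + Vy sin(theta) averaged over annuli of width dr
  (default 60 px), signed so that inward flow is negative;
* the tangential profile Vtheta(r), computed the same way for the polar
  component;
* the normalized direction histogram P(theta_dir) of
  theta_dir = theta_v - theta, the angle of each velocity vector relative
  to the local outward radial direction.  Pure outward radial flow gives
  theta_dir = 0, pure inward flow 180 degrees, and pure circular flow
  +/-90 degrees depending on the sense of rotation.

Centripetal transport of clathrin-coated structures shows up as a sharp
peak of P(theta_dir) at 180 degrees together with Vr(r) < 0; stalled
structures give a broad P(theta_dir) and negligible |Vr|.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .piv import FlowField

__all__ = [
    "RadialProfile",
    "DirectionHistogram",
    "estimate_cell_center",
    "radial_profile",
    "direction_histogram",
    "pooled_direction_histogram",
    "direction_angles",
]

DEFAULT_DR_PX = 60  # annulus width; 60 px spans ~0.5-1.2 um at typical zoom
DEFAULT_N_BINS = 24


@dataclasses.dataclass
class RadialProfile:
    """Annulus-averaged radial and tangential speed.

    ``r_inner_um`` are increasing inner radii; annuli with no vectors carry
    NaN, never zero.  ``vr_um_s`` is signed (negative = inward).
    """

    r_inner_um: np.ndarray
    dr_um: float
    vr_um_s: np.ndarray
    vtheta_um_s: np.ndarray
    count: np.ndarray
    #: mean radius of the vectors that contributed to each annulus (NaN for
    #: empty annuli); the faithful abscissa for profile plots and fits
    r_mean_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r_inner_um) <= 0):
            raise ValueError("radii must be increasing")
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")

    @property
    def r_mid_um(self) -> np.ndarray:
        return self.r_inner_um + self.dr_um / 2.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_inner_um": self.r_inner_um,
                "r_mid_um": self.r_mid_um,
                "r_mean_um": (np.full_like(self.r_inner_um, np.nan)
                              if self.r_mean_um is None else self.r_mean_um),
                "vr_um_s": self.vr_um_s,
                "vtheta_um_s": self.vtheta_um_s,
                "n_vectors": self.count,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclasses.dataclass
class DirectionHistogram:
    """Normalized histogram of flow direction relative to the radial
    direction, over a full 360-degree circle."""

    bin_edges_deg: np.ndarray  # length n_bins + 1, increasing, spans 360
    density: np.ndarray  # per-degree density; integrates to 1
    n_vectors: int

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges_deg)
        if np.any(widths <= 0) or not np.isclose(widths.sum(), 360.0):
            raise ValueError("bin edges must increase and span 360 degrees")
        if np.any(self.density < 0):
            raise ValueError("densities must be non-negative")
        if self.n_vectors > 0 and not np.isclose(
            float(np.sum(self.density * widths)), 1.0
        ):
            raise ValueError("histogram must integrate to 1")

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])

    @property
    def modal_bin_center_deg(self) -> float:
        """Centre of the most populated bin, wrapped to [0, 360)."""
        return float(self.bin_centers_deg[np.argmax(self.density)] % 360.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_deg": self.bin_edges_deg[:-1],
                "bin_right_deg": self.bin_edges_deg[1:],
                "density_per_deg": self.density,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def estimate_cell_center(
    movie_or_mask, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Cell centre (xc, yc) in px as the intensity-weighted centroid.

    Accepts a ``Movie`` (centroid of its time-maximum projection, restricted
    to its mask when present), a 2D intensity image, or a boolean mask
    (unweighted centroid).
    """
    obj = movie_or_mask
    if hasattr(obj, "frames"):
        image = obj.frames.max(axis=0)
        if mask is None:
            mask = obj.mask
    else:
        image = np.asarray(obj)
    if image.ndim != 2:
        raise ValueError("need a 2D image or mask")
    weights = image.astype(float)
    if mask is not None:
        weights = weights * mask
    total = weights.sum()
    if total <= 0:
        raise ValueError("empty mask / all-zero projection: no centre")
    yy, xx = np.mgrid[0:image.shape[0], 0:image.shape[1]]
    return (float((weights * xx).sum() / total), float((weights * yy).sum() / total))


def _polar_components(field: FlowField, center: tuple[float, float]):
    xc, yc = center
    dx = field.x - xc
    dy = field.y - yc
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    vr = field.vx * np.cos(theta) + field.vy * np.sin(theta)
    vt = -field.vx * np.sin(theta) + field.vy * np.cos(theta)
    return r, theta, vr, vt


def radial_profile(
    field: FlowField,
    center: tuple[float, float],
    dr_px: float = DEFAULT_DR_PX,
) -> RadialProfile:
    """Annulus-average the radial and tangential velocity components.

    Each valid vector is assigned to the annulus [r, r + dr] containing its
    distance to the centre; components are averaged per annulus and
    converted to um/s.  Inward flow is negative (the radial unit vector
    points outward).
    """
    xc, yc = center
    if not (field.x.min() <= xc <= field.x.max() and
            field.y.min() <= yc <= field.y.max()):
        raise ValueError("center outside grid extent")
    r, _, vr, vt = _polar_components(field, center)
    # the radial direction is undefined at the centre itself
    ok = field.valid & np.isfinite(vr) & (r > 0)
    if not ok.any():
        raise ValueError("no valid vectors")
    n_ann = int(np.ceil(r[ok].max() / dr_px))
    scale = field.px_per_frame_to_um_per_s
    r_inner = np.arange(n_ann) * dr_px
    vr_mean = np.full(n_ann, np.nan)
    vt_mean = np.full(n_ann, np.nan)
    r_mean = np.full(n_ann, np.nan)
    count = np.zeros(n_ann, dtype=int)
    which = np.minimum((r[ok] / dr_px).astype(int), n_ann - 1)
    for b in range(n_ann):
        sel = which == b
        count[b] = sel.sum()
        if count[b]:
            vr_mean[b] = vr[ok][sel].mean() * scale
            vt_mean[b] = vt[ok][sel].mean() * scale
            r_mean[b] = r[ok][sel].mean() * field.pixel_size
    return RadialProfile(
        r_inner_um=r_inner * field.pixel_size,
        dr_um=dr_px * field.pixel_size,
        vr_um_s=vr_mean,
        vtheta_um_s=vt_mean,
        count=count,
        r_mean_um=r_mean,
    )


def direction_angles(
    field: FlowField, center: tuple[float, float]
) -> np.ndarray:
    """theta_dir = theta_v - theta in degrees for every valid nonzero
    vector, wrapped to [0, 360)."""
    r, theta, _, _ = _polar_components(field, center)
    theta_v = np.arctan2(field.vy, field.vx)
    mag = np.hypot(field.vx, field.vy)
    # zero vectors and the centre point have no defined direction
    ok = field.valid & (mag > 0) & (r > 0) & np.isfinite(theta_v)
    tdir = np.degrees(theta_v[ok] - theta[ok]) % 360.0
    return tdir


def _bin_angles(tdir: np.ndarray, n_bins: int,
                edge_origin: float | None) -> DirectionHistogram:
    width = 360.0 / n_bins
    origin = -width / 2.0 if edge_origin is None else float(edge_origin)
    edges = origin + width * np.arange(n_bins + 1)
    shifted = (tdir - origin) % 360.0 + origin
    counts, _ = np.histogram(shifted, bins=edges)
    density = counts / (counts.sum() * width)
    return DirectionHistogram(
        bin_edges_deg=edges, density=density, n_vectors=int(counts.sum())
    )


def direction_histogram(
    field: FlowField,
    center: tuple[float, float],
    n_bins: int = DEFAULT_N_BINS,
    edge_origin: float | None = None,
) -> DirectionHistogram:
    """Normalized histogram P(theta_dir) of flow direction relative to the
    outward radial direction.

    Bins tile the full circle.  By default the first edge sits at minus
    half a bin width, so the canonical directions 0/90/180/270 degrees fall
    at bin centres rather than on edges (a pure radial or circular flow
    would otherwise land exactly on an edge and the modal bin would be
    decided by rounding).  Pass ``edge_origin=0`` for plain [0, 360) edges.
    Vectors are unweighted; zero-magnitude vectors are excluded (their
    direction is undefined).
    """
    xc, yc = center
    if not (field.x.min() <= xc <= field.x.max() and
            field.y.min() <= yc <= field.y.max()):
        raise ValueError("center outside grid extent")
    tdir = direction_angles(field, center)
    if tdir.size == 0:
        raise ValueError("no valid nonzero vectors")
    return _bin_angles(tdir, n_bins, edge_origin)


def pooled_direction_histogram(
    fields: list[FlowField],
    center: tuple[float, float],
    n_bins: int = DEFAULT_N_BINS,
    edge_origin: float | None = None,
) -> DirectionHistogram:
    """P(theta_dir) pooled over the per-frame-pair fields of a movie.

    Each valid nonzero vector of every pair contributes one angle.  For a
    directed flow this coincides with the single-field histogram (every
    pair points the same way); for a stalled cell it is the statistically
    meaningful version — time-averaging first would hand the histogram a
    small number of near-zero vectors whose directions are spatially
    correlated noise, producing spurious peaks.
    """
    angles = [direction_angles(f, center) for f in fields]
    tdir = np.concatenate(angles) if angles else np.empty(0)
    if tdir.size == 0:
        raise ValueError("no valid nonzero vectors in any field")
    return _bin_angles(tdir, n_bins, edge_origin)
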