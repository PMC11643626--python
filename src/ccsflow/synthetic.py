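"""Seeded synthetic data with known ground truth for every pipeline stage.

Real inputs to this package are live-cell movies of punctate fluorescence,
AFM force curves and FRAP traces.  This module generates all three from
known ground truth so that every downstream estimator can be validated
end-to-end:

* movies of diffraction-limited puncta advected by an analytic flow model
  (centripetal, circular, stalled, uniform, or zero flow) on top of a
  static fluorescent background pool, with Poisson shot noise;
* analytic flow fields evaluated noiselessly on a grid (oracles for the
  polar quantification);
* Sneddon-model force curves with a flat pre-contact baseline and Gaussian
  force noise;
* FRAP traces with configurable bleach depth, mobile fraction and
  single-exponential recovery, including acquisition photobleaching of the
  reference channel.

All randomness comes from one ``numpy.random.default_rng(seed)`` per call:
the same seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .afm import ForceCurve, sneddon_contact_radius, sneddon_force
from .correction import Movie
from .frap import FRAPTrace
from .piv import FlowField

__all__ = [
    "FlowModel",
    "SyntheticGroundTruth",
    "linear_ramp",
    "generate_ccs_movie",
    "generate_analytic_flow",
    "generate_force_curve",
    "generate_frap_trace",
]

FLOW_KINDS = ("centripetal", "circular_cw", "circular_ccw", "stalled",
              "uniform_translation", "zero")

# default imaging conditions: 5 min at 5 s intervals, confocal at high zoom
DEFAULT_N_FRAMES = 60
DEFAULT_SHAPE = (512, 512)
DEFAULT_PIXEL_SIZE = 0.021  # um/px
DEFAULT_FRAME_INTERVAL = 5.0  # s


def linear_ramp(v_max: float, cell_radius: float) -> Callable[[float], float]:
    """Speed profile rising linearly from 0 at the centre to ``v_max`` at
    the cell radius (the maximum radial speed is attained near the
    membrane), clamped at v_max beyond it."""
    def profile(r):
        return v_max * np.clip(np.asarray(r, dtype=float) / cell_radius, 0.0, 1.0)
    return profile


@dataclasses.dataclass
class FlowModel:
    """Analytic advection model for puncta.

    ``speed`` may be a constant (px/frame) or a function of radial distance
    r (px); ``jitter_sd`` adds isotropic Gaussian positional jitter per
    frame on top of the deterministic update.
    """

    kind: str
    center: tuple[float, float]
    speed: float | Callable[[float], float] = 0.0
    jitter_sd: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)  # for uniform_translation

    def __post_init__(self) -> None:
        if self.kind not in FLOW_KINDS:
            raise ValueError(f"unknown flow model kind: {self.kind!r}")
        if not callable(self.speed) and self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    def _speed_at(self, r: np.ndarray) -> np.ndarray:
        if callable(self.speed):
            return np.asarray(self.speed(r), dtype=float)
        return np.full_like(np.asarray(r, dtype=float), float(self.speed))

    def velocity(self, x, y):
        """Deterministic velocity (vx, vy) in px/frame at positions (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dx = x - self.center[0]
        dy = y - self.center[1]
        r = np.hypot(dx, dy)
        safe_r = np.where(r > 0, r, 1.0)
        ux, uy = dx / safe_r, dy / safe_r  # outward radial unit vector
        if self.kind == "centripetal":
            s = self._speed_at(r)
            return -s * ux, -s * uy
        if self.kind in ("circular_ccw", "circular_cw"):
            s = self._speed_at(r)
            sign = 1.0 if self.kind == "circular_ccw" else -1.0
            return -sign * s * uy, sign * s * ux
        if self.kind == "uniform_translation":
            tx, ty = self.translation
            return np.full_like(x, tx), np.full_like(y, ty)
        # stalled / zero: no deterministic motion
        return np.zeros_like(x), np.zeros_like(y)


@dataclasses.dataclass
class SyntheticGroundTruth:
    """Everything needed to score an estimator against the generator.

    ``tracks`` has shape (n_particles, n_frames, 2) holding (x, y) px; the
    recorded positions obey the flow-model update exactly (jitter included,
    pixel noise not).
    """

    seed: int
    model: FlowModel | None = None
    tracks: np.ndarray | None = None
    is_static: np.ndarray | None = None
    afm: dict | None = None
    frap: dict | None = None

    def tracks_to_csv(self, path: str | Path) -> None:
        if self.tracks is None:
            raise ValueError("no particle tracks recorded")
        n_p, n_f, _ = self.tracks.shape
        rows = []
        for p in range(n_p):
            for f in range(n_f):
                rows.append(
                    (p, f, self.tracks[p, f, 0], self.tracks[p, f, 1],
                     bool(self.is_static[p]))
                )
        pd.DataFrame(
            rows, columns=["particle_id", "frame", "x_px", "y_px", "is_static"]
        ).to_csv(path, index=False)

    def mobile_speeds(self) -> np.ndarray:
        """Per-step ground-truth speeds (px/frame) of the mobile particles."""
        mob = self.tracks[~self.is_static]
        steps = np.diff(mob, axis=1)
        return np.hypot(steps[..., 0], steps[..., 1]).ravel()


def _render_frame(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitude: float,
    psf_sigma: float,
    background: float,
) -> np.ndarray:
    """Sum of isotropic 2D Gaussian puncta plus a flat background."""
    frame = np.full(shape, background, dtype=float)
    h, w = shape
    ext = int(np.ceil(4 * psf_sigma))
    for x0, y0 in positions:
        xi, yi = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(0, xi - ext), min(w, xi + ext + 1)
        y_lo, y_hi = max(0, yi - ext), min(h, yi + ext + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        frame[y_lo:y_hi, x_lo:x_hi] += amplitude * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * psf_sigma**2)
        )
    return frame


def generate_ccs_movie(
    model: FlowModel,
    n_particles: int = 100,
    static_fraction: float = 0.3,
    psf_sigma: float = 1.5,
    noise: str = "poisson",
    noise_sd: float = 0.0,
    n_frames: int = DEFAULT_N_FRAMES,
    shape: tuple[int, int] = DEFAULT_SHAPE,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    seed: int = 0,
    amplitude: float = 200.0,
    background: float = 10.0,
    cell_radius: float | None = None,
    bleach_rate: float = 0.0,
) -> tuple[Movie, SyntheticGroundTruth]:
    """Render a seeded movie of advected puncta over a static pool.

    ``static_fraction`` of the particles never move (the static clathrin
    background pool); the rest follow ``model.velocity`` plus per-frame
    Gaussian jitter.  Particles start uniformly inside a disk of
    ``cell_radius`` (default 45% of the smaller image side) around the
    model centre; draws landing outside the image are rejected and
    resampled.  ``noise`` is one of ``none``, ``poisson`` (shot noise on
    the photon-scaled intensities) or ``gaussian`` (read noise of
    ``noise_sd``).  Optional whole-field exponential photobleaching at
    ``bleach_rate`` per frame (off by default).
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    if n_frames < 2:
        raise ValueError("need at least two frames")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    if not 0.0 <= static_fraction <= 1.0:
        raise ValueError("static_fraction must be in [0, 1]")
    if noise not in ("none", "poisson", "gaussian"):
        raise ValueError("noise must be 'none', 'poisson' or 'gaussian'")
    h, w = shape
    xc, yc = model.center
    if not (0 <= xc < w and 0 <= yc < h):
        raise ValueError("model centre must lie inside the image")
    if cell_radius is None:
        cell_radius = 0.45 * min(shape)
    rng = np.random.default_rng(seed)

    # initial positions: uniform in the cell disk, resampled if outside image
    pos = np.empty((n_particles, 2))
    filled = 0
    while filled < n_particles:
        n_draw = n_particles - filled
        rr = cell_radius * np.sqrt(rng.uniform(size=n_draw))
        th = rng.uniform(0, 2 * np.pi, size=n_draw)
        cand = np.column_stack([xc + rr * np.cos(th), yc + rr * np.sin(th)])
        ok = (
            (cand[:, 0] >= 0) & (cand[:, 0] < w)
            & (cand[:, 1] >= 0) & (cand[:, 1] < h)
        )
        n_ok = int(ok.sum())
        pos[filled:filled + n_ok] = cand[ok]
        filled += n_ok

    n_static = int(round(static_fraction * n_particles))
    is_static = np.zeros(n_particles, dtype=bool)
    is_static[:n_static] = True

    tracks = np.empty((n_particles, n_frames, 2))
    tracks[:, 0] = pos
    for t in range(1, n_frames):
        prev = tracks[:, t - 1]
        vx, vy = model.velocity(prev[:, 0], prev[:, 1])
        step = np.column_stack([vx, vy])
        if model.jitter_sd > 0:
            step = step + rng.normal(0.0, model.jitter_sd, size=step.shape)
        step[is_static] = 0.0
        tracks[:, t] = prev + step

    frames = np.empty((n_frames, h, w))
    for t in range(n_frames):
        clean = _render_frame(shape, tracks[:, t], amplitude, psf_sigma,
                              background)
        if bleach_rate > 0:
            clean = clean * np.exp(-bleach_rate * t)
        if noise == "poisson":
            frames[t] = rng.poisson(clean).astype(float)
        elif noise == "gaussian":
            frames[t] = np.clip(clean + rng.normal(0, noise_sd, clean.shape),
                                0, None)
        else:
            frames[t] = clean

    movie = Movie(frames=frames, pixel_size=pixel_size,
                  frame_interval=frame_interval)
    truth = SyntheticGroundTruth(seed=seed, model=model, tracks=tracks,
                                 is_static=is_static)
    return movie, truth


def generate_analytic_flow(
    model: FlowModel,
    grid: tuple[int, int] = (33, 33),
    spacing: float = 10.0,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> FlowField:
    """Evaluate a flow model noiselessly on a regular grid centred on the
    model centre; all vectors valid.  Oracle for the polar quantification."""
    nx, ny = grid
    if nx < 2 or ny < 2:
        raise ValueError("grid must be at least 2x2")
    xc, yc = model.center
    xs = xc + spacing * (np.arange(nx) - (nx - 1) / 2.0)
    ys = yc + spacing * (np.arange(ny) - (ny - 1) / 2.0)
    gx, gy = np.meshgrid(xs, ys)
    vx, vy = model.velocity(gx, gy)
    return FlowField(
        x=gx, y=gy, vx=vx, vy=vy, valid=np.ones(gx.shape, dtype=bool),
        pixel_size=pixel_size, frame_interval=frame_interval,
    )


def generate_force_curve(
    E: float = 1000.0,
    R: float = 2.5e-6,
    nu: float = 0.5,
    k: float = 0.2,
    max_depth: float = 500e-9,
    n_points: int = 600,
    noise_sd: float = 0.0,
    contact_offset: float = 200e-9,
    seed: int = 0,
) -> tuple[ForceCurve, SyntheticGroundTruth]:
    """Simulate an approach curve of a beaded cantilever on an elastic cell.

    The piezo first travels ``contact_offset`` with zero deflection (flat
    baseline), then indents to ``max_depth`` following the Sneddon pair;
    Gaussian force noise of ``noise_sd`` (N) enters through the deflection
    channel, so F = k d_cant and delta = d_pz - d_cant stay consistent.
    """
    if not 0 < max_depth < R:
        raise ValueError("max_depth must satisfy 0 < max_depth < R "
                         "(delta(a) diverges as a -> R)")
    if E <= 0 or k <= 0:
        raise ValueError("E and k must be positive")
    if not 0 <= nu < 0.5 + 1e-9:
        raise ValueError("Poisson ratio out of range")
    rng = np.random.default_rng(seed)
    deltas = np.linspace(0.0, max_depth, max(10, n_points // 2))
    a = sneddon_contact_radius(deltas, R)
    F_true = np.asarray(sneddon_force(a, E, nu, R))
    d_cant_true = F_true / k
    span_post = max_depth + d_cant_true[-1]
    n_pre = max(5, int(round(len(deltas) * contact_offset / max(span_post, 1e-12))))
    d_pz = np.concatenate([
        np.linspace(0.0, contact_offset, n_pre, endpoint=False),
        contact_offset + deltas + d_cant_true,
    ])
    F = np.concatenate([np.zeros(n_pre), F_true])
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, size=F.shape)
    d_cant = F / k
    curve = ForceCurve(d_pz=d_pz, d_cant=d_cant, k=k, R=R)
    truth = SyntheticGroundTruth(
        seed=seed,
        afm={"E_Pa": E, "R_m": R, "nu": nu, "contact_offset_m": contact_offset,
             "contact_index": n_pre, "max_depth_m": max_depth},
    )
    return curve, truth


def generate_frap_trace(
    mobile_fraction: float = 0.6,
    tau: float = 10.0,
    bleach_depth: float = 0.7,
    pre_frames: int = 15,
    post_frames: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    frame_interval: float = 5.66,
    acquisition_bleach_rate: float = 0.0,
    background_level: float = 50.0,
    roi_scale: float = 1000.0,
    ref_scale: float = 5000.0,
) -> tuple[FRAPTrace, SyntheticGroundTruth]:
    """Simulate raw FRAP channels with known recovery parameters.

    The underlying normalized ROI signal is a pre-bleach plateau at 1, a
    drop to ``1 - bleach_depth`` at the bleach, and a single-exponential
    recovery toward floor + mobile_fraction * (1 - floor) with time
    constant ``tau`` (s).  The ROI and reference channels share an optional
    acquisition-photobleaching decay (per-frame rate), and Gaussian noise
    of ``noise_sd`` (in normalized-intensity units) is added per channel.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile fraction must be in [0, 1]")
    if not 0 < bleach_depth <= 1:
        raise ValueError("bleach depth must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = pre_frames + post_frames
    t = np.arange(n, dtype=float) * frame_interval
    floor = 1.0 - bleach_depth
    signal = np.ones(n)
    t_post = t[pre_frames:] - t[pre_frames]
    signal[pre_frames:] = floor + mobile_fraction * (1.0 - floor) * (
        1.0 - np.exp(-t_post / tau)
    )
    decay = np.exp(-acquisition_bleach_rate * np.arange(n, dtype=float))
    roi = background_level + roi_scale * decay * (
        signal + rng.normal(0.0, noise_sd, size=n)
    )
    ref = background_level + ref_scale * decay * (
        1.0 + rng.normal(0.0, noise_sd, size=n)
    )
    bg = np.full(n, background_level)
    trace = FRAPTrace(t_s=t, roi=roi, reference=ref, background=bg,
                      bleach_index=pre_frames, pre_frames=pre_frames)
    truth = SyntheticGroundTruth(
        seed=seed,
        frap={"mobile_fraction": mobile_fraction, "tau_s": tau,
              "bleach_depth": bleach_depth, "floor": floor},
    )
    return trace, truth
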