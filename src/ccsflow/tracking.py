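"""Single-particle tracking of punctate structures, and kymographs.

The PIV modules measure the collective flow field; this module is the
single-particle counterpart.  Diffraction-limited puncta are detected per
frame with a Laplacian-of-Gaussian blob detector at a single user scale,
refined to sub-pixel position by an intensity centroid on a small patch,
and linked frame-to-frame by greedy mutual-nearest-neighbour assignment
within a maximum displacement, with optional gap closing.

Per-trajectory statistics follow the standard definitions: the mean
instantaneous velocity is the average over consecutive frame intervals of
(step length in um) / (frame interval in s); the radial displacement
series r(t) - r(0) is signed so that negative values indicate net movement
toward the cell centre.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

__all__ = [
    "Trajectory",
    "detect_spots",
    "link_detections",
    "detect_and_link",
    "mean_instantaneous_velocity",
    "radial_displacement_series",
    "kymograph",
    "trajectories_to_csv",
]

MIN_VELOCITY_TRACK_LENGTH = 3  # shorter tracks excluded from speed statistics


@dataclasses.dataclass
class Trajectory:
    """One particle's time-ordered positions with calibration."""

    particle_id: int
    frames: np.ndarray  # strictly increasing frame indices
    x_px: np.ndarray
    y_px: np.ndarray
    pixel_size: float = 1.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if not (len(self.frames) == len(self.x_px) == len(self.y_px)):
            raise ValueError("frames/x/y must have equal length")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def detect_spots(
    frame: np.ndarray,
    spot_sigma: float = 1.5,
    detect_threshold: float = 0.2,
    refine_halfwidth: int = 2,
) -> np.ndarray:
    """Detect bright puncta in one frame; returns (n, 2) array of (x, y) px.

    Scale-matched Laplacian-of-Gaussian response with local maxima above
    ``detect_threshold`` times the response maximum, followed by an
    intensity-centroid refinement on a (2*halfwidth+1)^2 patch of the
    background-subtracted response.
    """
    frame = np.asarray(frame, dtype=float)
    resp = -ndimage.gaussian_laplace(frame, spot_sigma) * spot_sigma**2
    if resp.max() <= 0:
        return np.empty((0, 2))
    peaks = peak_local_max(
        resp, min_distance=max(1, int(round(2 * spot_sigma))),
        threshold_abs=detect_threshold * resp.max(),
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.empty((0, 2))
    out = []
    h, w = frame.shape
    hw = refine_halfwidth
    for py, px in peaks:
        y0, y1 = max(0, py - hw), min(h, py + hw + 1)
        x0, x1 = max(0, px - hw), min(w, px + hw + 1)
        patch = resp[y0:y1, x0:x1]
        patch = np.clip(patch - patch.min(), 0, None)
        tot = patch.sum()
        if tot <= 0:
            out.append((float(px), float(py)))
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out.append(((patch * xx).sum() / tot, (patch * yy).sum() / tot))
    return np.asarray(out)


def _greedy_mutual_links(prev_pts: np.ndarray, cur_pts: np.ndarray,
                         max_disp: float) -> list[tuple[int, int]]:
    """One-to-one links sorted by displacement; ties broken by smaller
    displacement then lower source index."""
    if len(prev_pts) == 0 or len(cur_pts) == 0:
        return []
    d = np.linalg.norm(prev_pts[:, None, :] - cur_pts[None, :, :], axis=-1)
    cand = np.argwhere(d <= max_disp)
    order = np.lexsort((cand[:, 0], d[cand[:, 0], cand[:, 1]]))
    used_prev: set[int] = set()
    used_cur: set[int] = set()
    links = []
    for i, j in cand[order]:
        if i in used_prev or j in used_cur:
            continue
        used_prev.add(int(i))
        used_cur.add(int(j))
        links.append((int(i), int(j)))
    return links


def link_detections(
    detections: list[np.ndarray],
    max_disp: float,
    memory: int = 0,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> list[Trajectory]:
    """Link per-frame (x, y) detections into trajectories.

    Greedy nearest-neighbour assignment within ``max_disp`` px per frame
    step; a track missing from up to ``memory`` consecutive frames can be
    picked up again within ``max_disp * (gap + 1)``.
    """
    next_id = 0
    # active tracks: id -> dict(frames, xs, ys, last_frame)
    active: dict[int, dict] = {}
    finished: list[dict] = []
    for t, pts in enumerate(detections):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        unmatched = set(range(len(pts)))
        # try to extend tracks, most recent first (gap = 0, then 1, ...)
        for gap in range(memory + 1):
            cand_ids = [tid for tid, tr in active.items()
                        if tr["frames"][-1] == t - 1 - gap]
            if not cand_ids or not unmatched:
                continue
            prev_pts = np.array([[active[tid]["xs"][-1], active[tid]["ys"][-1]]
                                 for tid in cand_ids])
            cur_idx = sorted(unmatched)
            links = _greedy_mutual_links(
                prev_pts, pts[cur_idx], max_disp * (gap + 1)
            )
            for i, j in links:
                tid = cand_ids[i]
                cj = cur_idx[j]
                active[tid]["frames"].append(t)
                active[tid]["xs"].append(pts[cj, 0])
                active[tid]["ys"].append(pts[cj, 1])
                unmatched.discard(cj)
        # retire tracks that fell out of the memory window
        for tid in [tid for tid, tr in active.items()
                    if tr["frames"][-1] < t - memory]:
            finished.append(active.pop(tid))
        # new tracks for unmatched detections
        for j in sorted(unmatched):
            active[next_id] = {"frames": [t], "xs": [pts[j, 0]], "ys": [pts[j, 1]]}
            next_id += 1
    finished.extend(active.values())
    finished.sort(key=lambda tr: (tr["frames"][0], tr["xs"][0]))
    return [
        Trajectory(
            particle_id=i, frames=np.array(tr["frames"]),
            x_px=np.array(tr["xs"]), y_px=np.array(tr["ys"]),
            pixel_size=pixel_size, frame_interval=frame_interval,
        )
        for i, tr in enumerate(finished)
    ]


def detect_and_link(
    movie,
    spot_sigma: float = 1.5,
    detect_threshold: float = 0.2,
    max_disp: float = 5.0,
    memory: int = 0,
) -> list[Trajectory]:
    """Detect puncta in every frame of a movie and link them into tracks."""
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to track")
    detections = [
        detect_spots(frame, spot_sigma=spot_sigma, detect_threshold=detect_threshold)
        for frame in movie.frames
    ]
    if all(len(d) == 0 for d in detections):
        raise ValueError("no detections in any frame")
    return link_detections(
        detections, max_disp=max_disp, memory=memory,
        pixel_size=movie.pixel_size, frame_interval=movie.frame_interval,
    )


def mean_instantaneous_velocity(traj: Trajectory) -> float:
    """Mean over consecutive intervals of step length / frame interval, um/s."""
    if len(traj) < 2:
        raise ValueError("trajectory too short for a velocity")
    steps_px = np.hypot(np.diff(traj.x_px), np.diff(traj.y_px))
    dt = np.diff(traj.frames) * traj.frame_interval
    return float(np.mean(steps_px * traj.pixel_size / dt))


def radial_displacement_series(
    traj: Trajectory, center: tuple[float, float]
) -> np.ndarray:
    """Signed radial displacement r(t) - r(0) in um; negative = inward."""
    xc, yc = center
    r = np.hypot(traj.x_px - xc, traj.y_px - yc) * traj.pixel_size
    return r - r[0]


def kymograph(
    movie, line: tuple[tuple[float, float], tuple[float, float]], width: int = 3
) -> np.ndarray:
    """Space-time image along a line: rows are time, columns distance.

    Intensity is sampled at 1 px spacing along the line and mean-aggregated
    across ``width`` perpendicular pixels.  Diagonal streaks indicate
    motion; vertical lines indicate stalled structures.
    """
    (x0, y0), (x1, y1) = line
    h, w = movie.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError("line endpoints must lie inside the image")
    length = np.hypot(x1 - x0, y1 - y0)
    if length == 0:
        raise ValueError("zero-length line")
    n = int(np.ceil(length)) + 1
    s = np.linspace(0.0, 1.0, n)
    xs = x0 + s * (x1 - x0)
    ys = y0 + s * (y1 - y0)
    # unit normal to the line, for perpendicular averaging
    nx, ny = -(y1 - y0) / length, (x1 - x0) / length
    offsets = np.arange(width) - (width - 1) / 2.0
    out = np.empty((movie.n_frames, n))
    for k in range(movie.n_frames):
        rows = []
        for off in offsets:
            rows.append(
                ndimage.map_coordinates(
                    movie.frames[k], [ys + off * ny, xs + off * nx],
                    order=1, mode="nearest",
                )
            )
        out[k] = np.mean(rows, axis=0)
    return out


def trajectories_to_csv(trajectories: list[Trajectory], path: str | Path) -> None:
    rows = []
    for tr in trajectories:
        for f, x, y in zip(tr.frames, tr.x_px, tr.y_px):
            rows.append((tr.particle_id, f, x, y))
    pd.DataFrame(rows, columns=["particle", "frame", "x_px", "y_px"]).to_csv(
        path, index=False
    )
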