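"""End-to-end flow pipeline: correction -> PIV -> polar quantification.

Chains drift correction, static-background intensity correction, per-pair
multipass PIV with post-processing, steady-state time averaging, cell
centre estimation, and the radial-profile / direction-histogram
quantification.  Every run can write its intermediates plus a manifest
(config, seed, package versions) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy import ndimage as _ndi
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image

from . import __version__
from .correction import Movie, estimate_and_apply_drift, intensity_correct
from .flowquant import (DEFAULT_DR_PX, DEFAULT_N_BINS, DirectionHistogram,
                        RadialProfile, estimate_cell_center,
                        pooled_direction_histogram, radial_profile)
from .piv import DEFAULT_PASSES, FlowField, movie_flow, time_average

__all__ = ["PipelineConfig", "FlowPipelineResult", "run_flow_pipeline",
           "auto_cell_mask"]

log = logging.getLogger("ccsflow")


@dataclasses.dataclass
class PipelineConfig:
    """Serializable settings for one flow-pipeline run."""

    movie_path: str | None = None
    pixel_size: float | None = None  # um/px override
    frame_interval: float | None = None  # s override
    mask_path: str | None = None
    auto_mask: bool = True
    drift_reference: int = 0
    passes: tuple[int, ...] = DEFAULT_PASSES
    overlap: float = 0.5
    sd_threshold: float = 4.0
    median_threshold: float = 4.0
    deform: bool = False
    dr_px: float = DEFAULT_DR_PX
    n_bins: int = DEFAULT_N_BINS
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.dr_px <= 0 or self.n_bins < 2:
            raise ValueError("dr_px must be positive and n_bins >= 2")
        if self.sd_threshold <= 0 or self.median_threshold <= 0:
            raise ValueError("filter thresholds must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["passes"] = list(self.passes)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        data["passes"] = tuple(data.get("passes", DEFAULT_PASSES))
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


@dataclasses.dataclass
class FlowPipelineResult:
    profile: RadialProfile
    histogram: DirectionHistogram
    mean_field: FlowField
    per_pair_fields: list[FlowField]
    center_px: tuple[float, float]
    drift_px: np.ndarray
    manifest: dict


def auto_cell_mask(movie: Movie, min_size: int = 9) -> np.ndarray:
    """Cell mask from the time-maximum projection: Otsu threshold, removal
    of connected components below ``min_size`` px (noise specks; a
    diffraction-limited punctum covers ~25 px), convex hull (the cell is
    assumed roughly convex; the projection of the puncta fills its
    footprint)."""
    proj = movie.frames.max(axis=0)
    binary = proj > threshold_otsu(proj)
    labels, n = _ndi.label(binary)
    if n:
        areas = np.bincount(labels.ravel())
        areas[0] = 0
        binary = np.isin(labels, np.flatnonzero(areas >= min_size))
    if not binary.any():
        raise ValueError("auto mask failed: nothing above threshold")
    return convex_hull_image(binary)


def _manifest(config: PipelineConfig) -> dict:
    return {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "ccsflow": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }


def run_flow_pipeline(
    config: PipelineConfig, movie: Movie | None = None
) -> FlowPipelineResult:
    """Execute the full flow pipeline.

    ``movie`` may be passed in memory; otherwise ``config.movie_path`` is
    read.  Stage failures re-raise with the stage name; intermediates
    already written to ``config.out_dir`` are preserved.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(_manifest(config), indent=2))

    stage = "load"
    try:
        if movie is None:
            if config.movie_path is None:
                raise ValueError("no movie given (in memory or by path)")
            movie = Movie.from_tiff(config.movie_path, config.pixel_size,
                                    config.frame_interval)
        if config.pixel_size:
            movie.pixel_size = config.pixel_size
        if config.frame_interval:
            movie.frame_interval = config.frame_interval

        stage = "mask"
        if config.mask_path:
            mask = tifffile.imread(config.mask_path).astype(bool)
        elif config.auto_mask:
            mask = auto_cell_mask(movie)
        else:
            mask = None
        log.info("mask: %s px inside", int(mask.sum()) if mask is not None else "all")

        stage = "drift_correction"
        registered, drift = estimate_and_apply_drift(movie, config.drift_reference)
        if out:
            drift.to_csv(out / "drift.csv")

        stage = "intensity_correction"
        corrected, mean_frame = intensity_correct(registered)
        if out:
            tifffile.imwrite(out / "mean_frame.tif",
                             mean_frame.astype(np.float32))
            corrected.to_tiff(out / "corrected.tif")

        stage = "piv"
        fields = movie_flow(
            corrected.frames, passes=config.passes, overlap=config.overlap,
            mask=mask, sd_threshold=config.sd_threshold,
            median_threshold=config.median_threshold, deform=config.deform,
            pixel_size=movie.pixel_size, frame_interval=movie.frame_interval,
        )
        log.info("piv: %d frame pairs", len(fields))

        stage = "time_average"
        mean_field = time_average(fields)
        if out:
            mean_field.to_csv(out / "mean_field.csv")

        stage = "center"
        center = estimate_cell_center(movie, mask=mask)
        log.info("cell centre at (%.1f, %.1f) px", *center)

        stage = "quantify"
        profile = radial_profile(mean_field, center, dr_px=config.dr_px)
        # direction statistics pooled over frame pairs: the time-averaged
        # field of a stalled cell holds only a handful of near-zero vectors
        # whose noise directions are spatially correlated
        histogram = pooled_direction_histogram(fields, center,
                                               n_bins=config.n_bins)
        if out:
            profile.to_csv(out / "radial_profile.csv")
            histogram.to_csv(out / "direction_histogram.csv")
            from . import plots

            plots.plot_radial_profile(profile, out / "radial_profile.png")
            plots.plot_direction_histogram(histogram,
                                           out / "direction_histogram.png")
            plots.plot_flow_field(mean_field, out / "flow_field.png",
                                  background=mean_frame)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"flow pipeline failed at stage '{stage}': {exc}") from exc

    return FlowPipelineResult(
        profile=profile, histogram=histogram, mean_field=mean_field,
        per_pair_fields=fields, center_px=center, drift_px=drift.shifts,
        manifest=_manifest(config),
    )
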