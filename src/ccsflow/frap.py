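"""FRAP normalization and recovery-curve fitting.

Fluorescence recovery after photobleaching reports the exchange rate and
mobile fraction of a tagged protein.  Raw traces need correction for
background and for acquisition photobleaching of the whole cell; the
standard "double" normalization divides the background-subtracted ROI
signal by the background-subtracted whole-cell (reference) signal and then
rescales so the pre-bleach mean equals 1:

    I_norm(t) = [ (roi - bg) / (ref - bg) ] / mean_prebleach[ ... ]

Recovery is summarized by a single-exponential fit
I(t) = I0 + A (1 - exp(-t / tau)) on the post-bleach frames; the mobile
fraction is (plateau - floor) / (1 - floor) and the half time tau ln 2.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["FRAPTrace", "RecoveryFit", "double_normalize", "single_normalize",
           "fit_recovery", "analyze_trace"]


@dataclasses.dataclass
class FRAPTrace:
    """Raw FRAP channels: bleached ROI, whole-cell reference, background."""

    t_s: np.ndarray
    roi: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_index: int
    pre_frames: int | None = None

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float)
                  for a in (self.t_s, self.roi, self.reference, self.background)]
        self.t_s, self.roi, self.reference, self.background = arrays
        if len({a.shape for a in arrays}) != 1:
            raise ValueError("all series must have the same length")
        if not 0 < self.bleach_index < len(self.t_s):
            raise ValueError("bleach index must be inside the trace")
        if self.pre_frames is None:
            self.pre_frames = self.bleach_index

    @classmethod
    def from_csv(cls, path: str | Path, bleach_index: int) -> "FRAPTrace":
        df = pd.read_csv(path)
        return cls(
            t_s=df["t_s"].to_numpy(), roi=df["roi"].to_numpy(),
            reference=df["reference"].to_numpy(),
            background=df["background"].to_numpy(),
            bleach_index=bleach_index,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"t_s": self.t_s, "roi": self.roi, "reference": self.reference,
             "background": self.background}
        ).to_csv(path, index=False)


@dataclasses.dataclass
class RecoveryFit:
    mobile_fraction: float
    t_half_s: float
    tau_s: float
    plateau: float
    floor: float
    converged: bool = True
    clamped: bool = False  # raw mobile-fraction estimate fell outside [0, 1]


def _normalize(trace: FRAPTrace, use_reference: bool) -> np.ndarray:
    roi = trace.roi - trace.background
    if use_reference:
        ref = trace.reference - trace.background
        if np.any(ref <= 0):
            raise ValueError("reference intensity must exceed background")
        ratio = roi / ref
    else:
        ratio = roi
    pre = ratio[: trace.bleach_index]
    if len(pre) < 2:
        raise ValueError("need at least 2 pre-bleach frames")
    return ratio / pre.mean()


def double_normalize(trace: FRAPTrace) -> np.ndarray:
    """Background-subtracted ROI over background-subtracted reference,
    scaled so the pre-bleach mean is 1 (corrects acquisition bleaching)."""
    return _normalize(trace, use_reference=True)


def single_normalize(trace: FRAPTrace) -> np.ndarray:
    """Background-subtracted ROI scaled to unit pre-bleach mean (no
    reference correction)."""
    return _normalize(trace, use_reference=False)


def fit_recovery(
    normalized: np.ndarray,
    bleach_index: int,
    t_s: np.ndarray | None = None,
) -> RecoveryFit:
    """Single-exponential recovery fit on the post-bleach frames.

    Fits I(t) = I0 + A (1 - exp(-t/tau)) with t measured from the first
    post-bleach frame.  The mobile fraction (plateau - floor)/(1 - floor)
    is clamped to [0, 1] with out-of-range raw values flagged; on
    non-convergence a flagged result with NaN estimates is returned.
    """
    normalized = np.asarray(normalized, dtype=float)
    post = normalized[bleach_index:]
    if len(post) < 10:
        raise ValueError("need at least 10 post-bleach frames")
    if t_s is None:
        t = np.arange(len(post), dtype=float)
    else:
        t = np.asarray(t_s, dtype=float)[bleach_index:]
        t = t - t[0]

    def model(t, i0, amp, tau):
        return i0 + amp * (1.0 - np.exp(-t / tau))

    span = max(post.max() - post[0], 1e-12)
    p0 = (post[0], span, max(t[-1] / 3.0, 1e-6))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, post, p0=p0, maxfev=10000,
                bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            )
    except (RuntimeError, ValueError):
        return RecoveryFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                           converged=False)
    i0, amp, tau = popt
    plateau = i0 + amp
    denom = 1.0 - i0
    raw_mf = amp / denom if denom > 1e-9 else np.inf
    clamped = not 0.0 <= raw_mf <= 1.0
    mf = float(np.clip(raw_mf, 0.0, 1.0))
    return RecoveryFit(
        mobile_fraction=mf, t_half_s=float(tau * np.log(2.0)), tau_s=float(tau),
        plateau=float(plateau), floor=float(i0), clamped=clamped,
    )


def analyze_trace(trace: FRAPTrace, variant: str = "double") -> RecoveryFit:
    """Normalize (double by default, or single) and fit the recovery."""
    if variant == "double":
        norm = double_normalize(trace)
    elif variant == "single":
        norm = single_normalize(trace)
    else:
        raise ValueError("variant must be 'double' or 'single'")
    return fit_recovery(norm, trace.bleach_index, t_s=trace.t_s)
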