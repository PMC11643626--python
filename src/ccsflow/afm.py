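"""AFM nanoindentation: Sneddon spherical-indenter fits for Young's modulus.

A bead of radius R glued to a soft cantilever (spring constant k) is pushed
into a cell.  The recorded channels are the base-piezo displacement d_pz
and the cantilever deflection d_cant (both in metres after sensitivity
conversion).  Force and cell deformation follow from

    F = k * d_cant,        delta = d_pz - d_cant.

For a rigid sphere on a linear-elastic half-space, force and deformation
are parameterized by the contact-circle radius a (Sneddon):

    F(a)     = E / (1 - nu^2) * [ (a^2 + R^2)/2 * ln((R + a)/(R - a)) - a R ]
    delta(a) = a/2 * ln((R + a)/(R - a))

E is the Young's modulus and nu the sample's Poisson ratio.  For shallow
indentation (delta << R) this reduces to the Hertz sphere result
F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2).  Since F is linear in E, fitting
E at fixed (R, nu) is a closed-form least-squares problem once the contact
point is known; the contact point itself is found by searching for the
split of the approach curve that best explains a flat baseline before and
a Sneddon curve after.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ForceCurve",
    "IndentationFit",
    "force_deformation",
    "sneddon_force",
    "sneddon_depth",
    "sneddon_contact_radius",
    "sneddon_model",
    "hertz_sphere_force",
    "detect_contact_point",
    "fit_youngs_modulus",
    "analyze_curve",
    "summarize_cell",
]

DEFAULT_R = 2.5e-6  # m; 5 um diameter glass bead
DEFAULT_NU = 0.5  # incompressible cell
DEFAULT_MAX_DEPTH = 500e-9  # m; cells deformed by ~500 nm


@dataclasses.dataclass
class ForceCurve:
    """Raw approach (or retract) channels of one indentation.

    ``d_pz`` and ``d_cant`` are in metres; volts are converted on load via
    the detector sensitivity (nm/V).
    """

    d_pz: np.ndarray
    d_cant: np.ndarray
    k: float  # N/m
    R: float = DEFAULT_R
    segment: str = "approach"

    def __post_init__(self) -> None:
        self.d_pz = np.asarray(self.d_pz, dtype=float)
        self.d_cant = np.asarray(self.d_cant, dtype=float)
        if self.d_pz.shape != self.d_cant.shape:
            raise ValueError("channel arrays must have equal length")
        if self.k <= 0 or self.R <= 0:
            raise ValueError("spring constant and bead radius must be positive")

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        k: float,
        R: float = DEFAULT_R,
        sensitivity_nm_per_V: float | None = None,
    ) -> "ForceCurve":
        """Read a TSV/CSV force curve.

        Accepts columns ``piezo_m``/``deflection_m`` or
        ``piezo_V``/``deflection_V`` (the latter need
        ``sensitivity_nm_per_V``); an optional ``segment`` column selects
        the approach part.
        """
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep)
        if "segment" in df.columns:
            df = df[df["segment"] == "approach"]
        if "piezo_m" in df.columns:
            d_pz = df["piezo_m"].to_numpy()
            d_cant = df["deflection_m"].to_numpy()
        elif "piezo_V" in df.columns:
            if sensitivity_nm_per_V is None:
                raise ValueError("volt channels need a detector sensitivity")
            s = sensitivity_nm_per_V * 1e-9
            d_pz = df["piezo_V"].to_numpy() * s
            d_cant = df["deflection_V"].to_numpy() * s
        else:
            raise ValueError("no piezo_m/piezo_V column found")
        return cls(d_pz=d_pz, d_cant=d_cant, k=k, R=R)

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(
            {"piezo_m": self.d_pz, "deflection_m": self.d_cant,
             "segment": self.segment}
        ).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class IndentationFit:
    """Result of a Sneddon fit to one approach curve."""

    E_Pa: float
    nu: float
    R_m: float
    contact_index: int
    contact_offset_m: float
    max_depth_m: float
    rms_N: float
    n_points: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and self.E_Pa <= 0:
            raise ValueError("fitted modulus must be positive")
        if not 0 <= self.nu <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")


def force_deformation(curve: ForceCurve) -> tuple[np.ndarray, np.ndarray]:
    """Convert channels to force and deformation: F = k d_cant,
    delta = d_pz - d_cant (raw; contact alignment is a separate step)."""
    return curve.k * curve.d_cant, curve.d_pz - curve.d_cant


def sneddon_force(a, E: float, nu: float, R: float):
    """Sneddon force F(a) for contact radius a (0 <= a < R)."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a >= R):
        raise ValueError("contact radius must satisfy 0 <= a < R")
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.where(a > 0, np.log((R + a) / (R - a)), 0.0)
    F = E / (1.0 - nu**2) * ((a**2 + R**2) / 2.0 * log_term - a * R)
    return F if F.ndim else float(F)


def sneddon_depth(a, R: float):
    """Sneddon deformation delta(a) = a/2 ln((R+a)/(R-a))."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a >= R):
        raise ValueError("contact radius must satisfy 0 <= a < R")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(a > 0, a / 2.0 * np.log((R + a) / (R - a)), 0.0)
    return d if d.ndim else float(d)


def sneddon_contact_radius(delta, R: float, rtol: float = 1e-10):
    """Invert delta(a) by bracketed root finding on [0, R)."""
    deltas = np.atleast_1d(np.asarray(delta, dtype=float))
    if np.any(deltas < 0):
        raise ValueError("deformation must be non-negative")
    out = np.empty_like(deltas)
    hi = R * (1.0 - 1e-12)
    for i, d in enumerate(deltas):
        if d == 0:
            out[i] = 0.0
            continue
        if d >= sneddon_depth(hi, R):
            raise ValueError("deformation too large for this bead radius")
        out[i] = brentq(lambda a: sneddon_depth(a, R) - d, 0.0, hi,
                        rtol=rtol, xtol=1e-18)
    return out if np.ndim(delta) else float(out[0])


def sneddon_model(a, E: float, nu: float, R: float):
    """Evaluate the Sneddon pair (F(a), delta(a))."""
    return sneddon_force(a, E, nu, R), sneddon_depth(a, R)


def hertz_sphere_force(delta, E: float, nu: float, R: float):
    """Shallow-indentation Hertz sphere closed form
    (4/3) E/(1-nu^2) sqrt(R) delta^(3/2); reference for the delta << R
    limit of the Sneddon pair."""
    delta = np.asarray(delta, dtype=float)
    F = 4.0 / 3.0 * E / (1.0 - nu**2) * np.sqrt(R) * delta**1.5
    return F if F.ndim else float(F)


class _SneddonShape:
    """Unit-modulus force g(delta) via a dense (a -> delta, F) lookup table.

    F is linear in E, so fitting only needs g evaluated at the measured
    deformations; tabulating the monotone pair once per curve avoids a root
    solve per sample.  4096 nodes keep the interpolation error orders of
    magnitude below typical force noise.
    """

    def __init__(self, nu: float, R: float, delta_max: float, n: int = 4096):
        a_cap = R * (1.0 - 1e-9)
        if delta_max >= sneddon_depth(a_cap, R):
            a_hi = a_cap
        else:
            a_hi = brentq(lambda a: sneddon_depth(a, R) - delta_max,
                          0.0, a_cap, rtol=1e-12)
        a_grid = np.linspace(0.0, a_hi, n)
        self._delta = np.asarray(sneddon_depth(a_grid, R))
        self._g = np.asarray(sneddon_force(a_grid, 1.0, nu, R))

    def __call__(self, delta: np.ndarray) -> np.ndarray:
        return np.interp(delta, self._delta, self._g)


def _sneddon_shape(delta: np.ndarray, nu: float, R: float) -> np.ndarray:
    """Force at unit modulus for given deformations (exact inversion)."""
    a = sneddon_contact_radius(delta, R)
    return np.asarray(sneddon_force(a, 1.0, nu, R))


def _fit_E_closed_form(F: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Least-squares modulus and residual RMS; exact because F = E * g(delta)."""
    denom = float(np.dot(g, g))
    if denom == 0:
        return np.nan, np.nan
    E = float(np.dot(F, g)) / denom
    rms = float(np.sqrt(np.mean((F - E * g) ** 2)))
    return E, rms


def detect_contact_point(
    F: np.ndarray,
    d_pz: np.ndarray,
    d_cant: np.ndarray,
    k: float,
    R: float = DEFAULT_R,
    nu: float = DEFAULT_NU,
    min_baseline: int = 10,
    min_contact: int = 10,
    coarse: int = 50,
) -> tuple[int, float]:
    """Find the contact point of an approach curve.

    The approach segment (ordered by increasing piezo displacement) is
    split at every candidate index: before it, force is modelled as a flat
    baseline (after linear detrend of the pre-contact region); after it, as
    a Sneddon indentation.  The split minimizing the combined squared
    residual is searched coarsely and refined locally.  Returns the contact
    index and the piezo offset (m) of the contact point.

    Raises if no super-baseline region exists (the bead never contacts).
    """
    F = np.asarray(F, dtype=float)
    n = len(F)
    if n < min_baseline + min_contact:
        raise ValueError("curve too short for contact detection")
    base_guess = F[: max(min_baseline, n // 5)]
    noise = base_guess.std()
    if F.max() - base_guess.mean() < max(5 * noise, 1e-30):
        raise ValueError("no contact detected: curve never rises above baseline")

    span = float(np.max(d_pz) - np.min(d_pz))
    shape = _SneddonShape(nu, R, min(span, R * (1 - 1e-9)))

    def objective(i: int) -> float:
        pre = F[:i]
        t = np.arange(i, dtype=float)
        # linear detrend of the baseline
        coef = np.polyfit(t, pre, 1) if i > 2 else (0.0, pre.mean())
        pre_res = pre - np.polyval(coef, t)
        baseline = np.polyval(coef, i - 1)
        Fc = F[i:] - baseline
        delta = (d_pz[i:] - d_pz[i]) - (d_cant[i:] - d_cant[i])
        good = delta >= 0
        if good.sum() < min_contact:
            return np.inf
        dmax = delta[good].max()
        if dmax >= R:
            return np.inf
        g = shape(delta[good])
        E, _ = _fit_E_closed_form(Fc[good], g)
        if not np.isfinite(E) or E <= 0:
            return np.inf
        post_res = Fc[good] - E * g
        return float(np.sum(pre_res**2) + np.sum(post_res**2))

    lo, hi = min_baseline, n - min_contact
    step = max(1, (hi - lo) // coarse)
    coarse_idx = list(range(lo, hi, step))
    scores = [objective(i) for i in coarse_idx]
    best = coarse_idx[int(np.argmin(scores))]
    fine_lo = max(lo, best - step)
    fine_hi = min(hi, best + step + 1)
    fine_idx = list(range(fine_lo, fine_hi))
    fine_scores = [objective(i) for i in fine_idx]
    contact = fine_idx[int(np.argmin(fine_scores))]
    return contact, float(d_pz[contact] - d_pz[0])


def fit_youngs_modulus(
    F: np.ndarray,
    delta: np.ndarray,
    R: float = DEFAULT_R,
    nu: float = DEFAULT_NU,
    max_depth: float = DEFAULT_MAX_DEPTH,
    contact_index: int = 0,
    contact_offset: float = 0.0,
) -> IndentationFit:
    """Least-squares Young's modulus on contact-aligned (F, delta) data.

    Only samples with deformation in [0, max_depth] enter the fit (default
    500 nm); R and nu are held fixed.  At least 10 in-range samples are
    required.
    """
    if max_depth >= R:
        raise ValueError("max_depth must be smaller than the bead radius")
    F = np.asarray(F, dtype=float)
    delta = np.asarray(delta, dtype=float)
    sel = (delta >= 0) & (delta <= max_depth)
    if sel.sum() < 10:
        raise ValueError("fewer than 10 samples within the fit range")
    g = _sneddon_shape(delta[sel], nu, R)
    E, rms = _fit_E_closed_form(F[sel], g)
    if not np.isfinite(E) or E <= 0:
        return IndentationFit(
            E_Pa=np.nan, nu=nu, R_m=R, contact_index=contact_index,
            contact_offset_m=contact_offset, max_depth_m=max_depth,
            rms_N=np.nan, n_points=int(sel.sum()), converged=False,
        )
    return IndentationFit(
        E_Pa=E, nu=nu, R_m=R, contact_index=contact_index,
        contact_offset_m=contact_offset, max_depth_m=max_depth,
        rms_N=rms, n_points=int(sel.sum()),
    )


def analyze_curve(
    curve: ForceCurve,
    nu: float = DEFAULT_NU,
    max_depth: float = DEFAULT_MAX_DEPTH,
) -> IndentationFit:
    """Full pipeline for one approach curve: force/deformation conversion,
    contact detection with baseline detrend, and the Sneddon modulus fit."""
    F, _ = force_deformation(curve)
    i, offset = detect_contact_point(F, curve.d_pz, curve.d_cant, curve.k,
                                     R=curve.R, nu=nu)
    pre = F[:i]
    t = np.arange(i, dtype=float)
    coef = np.polyfit(t, pre, 1) if i > 2 else (0.0, float(pre.mean()))
    Fc = F[i:] - np.polyval(coef, i - 1)
    delta = (curve.d_pz[i:] - curve.d_pz[i]) - (curve.d_cant[i:] - curve.d_cant[i])
    fit = fit_youngs_modulus(Fc, delta, R=curve.R, nu=nu, max_depth=max_depth,
                             contact_index=i, contact_offset=offset)
    return fit


def summarize_cell(fits: list[IndentationFit]) -> float:
    """Per-cell modulus: median over the grid of converged curve fits
    (robust against the occasional bad curve in a 6x6 map)."""
    vals = [f.E_Pa for f in fits if f.converged and np.isfinite(f.E_Pa)]
    if not vals:
        raise ValueError("no converged fits to summarize")
    return float(np.median(vals))
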