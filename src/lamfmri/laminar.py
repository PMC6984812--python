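"""Cortical-depth grids, depth sampling, laminar profiles and shape fits.

A *laminar profile* is the vector of a measure (BOLD parameter estimate,
decoding accuracy) sampled at six relative cortical depths between the
white-matter (WM) and pial/CSF boundaries.  Depth index 0 is the deepest
surface (WM boundary side), index 5 the most superficial (CSF side),
matching the convention of plotting WM left and CSF right.

The profile's overall shape is summarised by a two-regressor GLM:

* ``C`` (constant): the profile mean across depths;
* ``L`` (linear): the per-depth-step slope of a mean-centred linear
  regressor, positive when the profile increases toward the surface.

With 6 depths the centred linear regressor is x = (-2.5, -1.5, ..., +2.5),
which is exactly orthogonal to the constant, so C and L are estimable
independently (closed-form OLS: C = mean(y), L = sum(x*y)/sum(x**2)).
The scale of L (units per depth step) is a package convention — only the
shape, not the scale, is fixed by the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import ATTENTION_STATES, CONDITIONS, STIM_MODALITIES

__all__ = [
    "N_DEPTHS",
    "ShapeParams",
    "ContrastSpec",
    "CONTRASTS",
    "equivolume_depth_fractions",
    "sample_along_normal",
    "roi_depth_profile",
    "compute_contrast",
    "blockwise_contrast",
    "fit_laminar_glm",
    "centered_depth_regressor",
]

#: Number of intracortical depth surfaces.
N_DEPTHS = 6


# --------------------------------------------------------------------------
# Equivolume depth construction (per-vertex 1D closed form)
# --------------------------------------------------------------------------

def equivolume_depth_fractions(thickness, inner_area, outer_area, n: int = N_DEPTHS):
    """Equivolume depth fractions between the WM and pial surfaces.

    The cortical ribbon at a vertex is modelled as a frustum-like column
    whose cross-sectional area interpolates linearly between ``inner_area``
    (WM boundary) and ``outer_area`` (pial boundary) as a function of the
    depth fraction rho in [0, 1] (rho = 0 at WM).  The k-th depth is placed
    at the rho for which the volume between the WM surface and rho equals
    the fraction alpha_k = (k - 1/2)/n of the total column volume, i.e. each
    surface sits at the centre of one of n equal-volume compartments.  In
    curved cortex (inner != outer area) this shifts depths toward the
    boundary with the larger area, which is the curvature compensation the
    equivolume construction exists for; for flat cortex (equal areas) the
    fractions reduce to the equidistant grid.

    Parameters
    ----------
    thickness : array_like
        Local cortical thickness; only its positivity is checked here (the
        fractions are relative; multiply by ``thickness`` for physical
        depths).
    inner_area, outer_area : array_like
        Cross-sectional area proxies at the WM and pial boundaries
        (strictly positive), broadcastable against each other.
    n : int
        Number of depth surfaces.

    Returns
    -------
    ndarray, shape (..., n)
        Depth fractions in (0, 1), strictly increasing, deep -> superficial.
    """
    thickness = np.asarray(thickness, dtype=float)
    a_in = np.asarray(inner_area, dtype=float)
    a_out = np.asarray(outer_area, dtype=float)
    if np.any(a_in <= 0) or np.any(a_out <= 0):
        raise ValueError("areas must be strictly positive")
    if np.any(thickness <= 0):
        raise ValueError("thickness must be strictly positive")
    a_in, a_out = np.broadcast_arrays(a_in, a_out)
    alpha = (np.arange(1, n + 1) - 0.5) / n            # (n,)
    a_in6 = a_in[..., None]
    d_a = (a_out - a_in)[..., None]
    total = (a_in + a_out)[..., None] / 2.0            # integral of area over [0,1]
    # Solve (dA/2) rho^2 + A_in rho - alpha * total = 0 for rho in (0,1).
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_curved = (-a_in6 + np.sqrt(a_in6**2 + 2.0 * d_a * alpha * total)) / d_a
    rho = np.where(np.isclose(d_a, 0.0), alpha, rho_curved)
    return rho


# --------------------------------------------------------------------------
# Sampling scalar volumes along surface normals
# --------------------------------------------------------------------------

def sample_along_normal(volume, surface_point, normal, depths):
    """Sample a scalar volume along the normal of a surface point.

    Points are ``surface_point + depth * normal`` in voxel coordinates, one
    per entry of ``depths``; values are trilinearly interpolated.  Points
    outside the volume yield NaN (the vertex is then excluded downstream —
    missing depths are never imputed).

    Parameters
    ----------
    volume : ndarray, 3D
    surface_point, normal : array_like, shape (3,)
    depths : array_like, shape (k,)
        Signed distances along ``normal`` in voxel units.

    Returns
    -------
    ndarray, shape (k,)
    """
    volume = np.asarray(volume, dtype=float)
    p = np.asarray(surface_point, dtype=float)
    nvec = np.asarray(normal, dtype=float)
    d = np.asarray(depths, dtype=float)
    pts = p[None, :] + d[:, None] * nvec[None, :]       # (k, 3)
    inside = np.all((pts >= 0) & (pts <= np.array(volume.shape) - 1), axis=1)
    out = np.full(len(d), np.nan)
    if np.any(inside):
        out[inside] = ndimage.map_coordinates(volume, pts[inside].T, order=1,
                                              mode="nearest")
    return out


# --------------------------------------------------------------------------
# ROI profiles and contrasts
# --------------------------------------------------------------------------

def roi_depth_profile(betas, roi_mask=None):
    """Median-over-vertices laminar profile(s) of an ROI.

    The median (not the mean) summarises each depth because per-vertex
    parameter estimates are heavily skewed, especially superficially.
    Vertices with any missing depth are excluded entirely.

    Parameters
    ----------
    betas : ndarray, shape (n_vertices, n_depths) or (n_vertices, n_depths, n_images)
    roi_mask : boolean ndarray (n_vertices,), optional

    Returns
    -------
    ndarray, shape (n_depths,) or (n_depths, n_images)
    """
    betas = np.asarray(betas, dtype=float)
    if roi_mask is not None:
        betas = betas[np.asarray(roi_mask, dtype=bool)]
    complete = np.all(np.isfinite(betas.reshape(betas.shape[0], -1)), axis=1)
    betas = betas[complete]
    if betas.shape[0] == 0:
        raise ValueError("ROI empty after missing-value exclusion")
    return np.median(betas, axis=0)


@dataclass(frozen=True)
class ContrastSpec:
    """Signed weights over the six condition labels, applied blockwise."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")

    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights.get(c, 0.0) for c in CONDITIONS])


def _attention_weights(sign: float) -> dict[str, float]:
    w = {}
    for s in STIM_MODALITIES:
        w[f"{s}_AttA"] = sign / 3.0
        w[f"{s}_AttV"] = -sign / 3.0
    return w


#: The six contrasts of interest.  Unisensory responses vs fixation average
#: the two attention conditions (/2); the crossmodal modulations are the AV
#: minus unisensory differences averaged over attention (/2); the attentional
#: modulations average the attention difference over the three stimulus
#: modalities (/3).
CONTRASTS: dict[str, ContrastSpec] = {
    "V-Fix": ContrastSpec("V-Fix", {"V_AttA": 0.5, "V_AttV": 0.5}),
    "A-Fix": ContrastSpec("A-Fix", {"A_AttA": 0.5, "A_AttV": 0.5}),
    "AV-A": ContrastSpec("AV-A", {"AV_AttA": 0.5, "AV_AttV": 0.5,
                                  "A_AttA": -0.5, "A_AttV": -0.5}),
    "AV-V": ContrastSpec("AV-V", {"AV_AttA": 0.5, "AV_AttV": 0.5,
                                  "V_AttA": -0.5, "V_AttV": -0.5}),
    "AttA-AttV": ContrastSpec("AttA-AttV", _attention_weights(+1.0)),
    "AttV-AttA": ContrastSpec("AttV-AttA", _attention_weights(-1.0)),
}


def compute_contrast(values: Mapping[str, np.ndarray], spec: ContrastSpec):
    """Apply a contrast formula to per-condition values.

    ``values`` maps condition labels to equally-shaped arrays (scalar, a
    laminar profile, or per-vertex arrays) for one block/run cell; the
    result is the weighted sum of the printed formula.
    """
    missing = [c for c, w in spec.weights.items() if w != 0 and c not in values]
    if missing:
        raise KeyError(f"contrast {spec.name}: missing condition(s) {missing}")
    out = None
    for cond, w in spec.weights.items():
        if w == 0:
            continue
        term = w * np.asarray(values[cond], dtype=float)
        out = term if out is None else out + term
    return out


def blockwise_contrast(betas, labels: pd.DataFrame, spec: ContrastSpec):
    """Blockwise contrast estimates over the 72-image axis.

    Applies the contrast within each (block occurrence i, run j) cell, i.e.
    combining the conditions' i-th block of run j, yielding 12 estimates
    under the default design.

    Parameters
    ----------
    betas : ndarray, (..., n_images)
        Last axis indexed by ``labels`` rows.
    labels : DataFrame with columns condition, block, run (and day).
    spec : ContrastSpec

    Returns
    -------
    contrasts : ndarray, (..., n_cells)
    cells : DataFrame with columns block, run, day for each output column.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape[-1] != len(labels):
        raise ValueError("betas last axis must match the label table")
    labels = labels.reset_index(drop=True)
    cells = (labels[["block", "run"]].drop_duplicates()
             .sort_values(["run", "block"]).reset_index(drop=True))
    out = np.zeros(betas.shape[:-1] + (len(cells),))
    for k, (block, run) in enumerate(zip(cells["block"], cells["run"])):
        pos = np.flatnonzero((labels["block"] == block) & (labels["run"] == run))
        vals = {labels.at[int(i), "condition"]: betas[..., int(i)] for i in pos}
        out[..., k] = compute_contrast(vals, spec)
    cells = cells.copy()
    cells["day"] = np.where(cells["run"] <= 2, 1, 2)
    return out, cells


# --------------------------------------------------------------------------
# Laminar shape GLM
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapeParams:
    """Constant (C) and linear (L) shape parameters of laminar profiles."""

    C: np.ndarray | float
    L: np.ndarray | float


def centered_depth_regressor(n: int = N_DEPTHS) -> np.ndarray:
    """Mean-centred linear depth regressor, unit step per depth."""
    return np.arange(n, dtype=float) - (n - 1) / 2.0


def fit_laminar_glm(profile) -> ShapeParams:
    """Fit the constant + centred-linear shape GLM to laminar profile(s).

    Works on a single 6-vector or on any array whose last axis is depth
    (mass-univariate per-vertex path included).  The two regressors are
    exactly orthogonal, so ``C`` is the profile mean and ``L`` the OLS
    slope per depth step (positive = increase toward the surface).
    """
    y = np.asarray(profile, dtype=float)
    if y.shape[-1] != N_DEPTHS:
        raise ValueError(f"last axis must have {N_DEPTHS} depths")
    if not np.all(np.isfinite(y)):
        raise ValueError("profile contains non-finite values")
    x = centered_depth_regressor(y.shape[-1])
    c = y.mean(axis=-1)
    slope = (y * x).sum(axis=-1) / (x**2).sum()
    return ShapeParams(C=c, L=slope)
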