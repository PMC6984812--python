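"""First-level mixed block-event GLM with AR(1) generalized least squares.

One design matrix per run: 18 canonical-HRF block regressors (3 blocks x 6
conditions) with temporal derivatives, four target-event regressors
(target modality x attended modality), one extra-response regressor, a
discrete-cosine drift basis (128 s cutoff) plus constant, and optional
opaque nuisance columns (e.g. realignment parameters).

Estimation is a two-pass "global approximate AR(1)" scheme: ordinary least
squares, a pooled (median-across-voxels) lag-1 autocorrelation of the
residuals, prewhitening of both sides, and OLS on the whitened system.
Only the canonical-HRF betas of the activation blocks are retained
downstream: 18 per run x 4 runs = 72 beta images per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import compute_regressor

from .design import RunDesign, TargetSchedule

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "build_design_matrix",
    "fit_glm_ar1",
    "dct_drift_basis",
    "dct_drift_order",
]


# --------------------------------------------------------------------------
# Drift basis
# --------------------------------------------------------------------------

def dct_drift_order(duration_s: float, cutoff_s: float = 128.0) -> int:
    """Number of DCT drift columns (excluding the constant).

    The standard rule keeps the cosines with period >= cutoff:
    order = floor(2 * duration / cutoff).
    """
    return int(np.floor(2.0 * duration_s / cutoff_s))


def dct_drift_basis(n_volumes: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """DCT-II drift regressors (n_volumes x order), unit-norm columns."""
    order = dct_drift_order(n_volumes * tr, cutoff_s)
    n = np.arange(n_volumes)
    basis = np.column_stack([
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_volumes))
        for k in range(1, order + 1)
    ]) if order else np.empty((n_volumes, 0))
    return basis


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Named first-level design matrix for one run."""

    matrix: pd.DataFrame                 # (n_volumes, p)
    frame_times: np.ndarray
    block_hrf_columns: list[str]         # the 18 activation-block HRF columns
    derivative_columns: list[str]
    event_columns: list[str]             # targets + extra-response
    drift_columns: list[str]             # DCT columns (constant excluded)
    nuisance_columns: list[str]
    degenerate_columns: list[str]        # all-zero columns (kept, flagged)

    @property
    def n_volumes(self) -> int:
        return len(self.matrix)

    def estimable(self) -> pd.DataFrame:
        """Matrix without degenerate columns."""
        keep = [c for c in self.matrix.columns if c not in self.degenerate_columns]
        return self.matrix[keep]


def _convolve(onsets, durations, frame_times, with_derivative: bool) -> np.ndarray:
    """Canonical (SPM-style double-gamma) HRF regressor, optionally + derivative."""
    cond = (np.asarray(onsets, float), np.asarray(durations, float),
            np.ones(len(onsets)))
    model = "spm + derivative" if with_derivative else "spm"
    reg, _ = compute_regressor(cond, model, frame_times, oversampling=16)
    return reg


def build_design_matrix(design: RunDesign, run: int,
                        schedule: TargetSchedule | None = None,
                        extra_response_onsets=None,
                        tr: float = 3.0, n_volumes: int = 302,
                        drift_cutoff_s: float = 128.0,
                        nuisance: pd.DataFrame | None = None) -> DesignMatrix:
    """Build the mixed block-event design matrix for one run.

    Blocks and events are convolved with the canonical double-gamma HRF and
    its temporal derivative (blocks as 33 s boxcars, targets and extra
    responses as zero-duration events).  Events at or beyond the scan end
    are truncated with a warning.  Deterministic.
    """
    frame_times = np.arange(n_volumes) * tr
    scan_end = n_volumes * tr
    cols: dict[str, np.ndarray] = {}
    block_cols, deriv_cols, event_cols, degenerate = [], [], [], []

    for b in sorted(design.run_blocks(run), key=lambda b: b.onset_s):
        name = f"{b.condition}_b{b.occurrence}"
        if b.onset_s >= scan_end:
            warnings.warn(f"block {name} beyond scan end; dropped")
            continue
        reg = _convolve([b.onset_s], [b.duration_s], frame_times, True)
        cols[name] = reg[:, 0]
        cols[name + "_deriv"] = reg[:, 1]
        block_cols.append(name)
        deriv_cols.append(name + "_deriv")

    # Target events split by target modality x attended modality.
    target_groups: dict[str, list[float]] = {
        f"Target{m}_Att{a}": [] for m in ("A", "V") for a in ("A", "V")}
    if schedule is not None:
        block_by = {(b.run, b.index_in_run): b for b in design.blocks}
        for t in schedule.targets:
            if t.run != run:
                continue
            att = block_by[(t.run, t.block_index_in_run)].attended
            target_groups[f"Target{t.modality}_Att{att}"].append(t.onset_s)
    for name, onsets in target_groups.items():
        onsets = [o for o in onsets if o < scan_end] if onsets else []
        if onsets:
            cols[name] = _convolve(onsets, [0.0] * len(onsets),
                                   frame_times, False)[:, 0]
        else:
            cols[name] = np.zeros(n_volumes)
            degenerate.append(name)
        event_cols.append(name)

    extra = [o for o in (extra_response_onsets or []) if o < scan_end]
    if len(extra) < len(list(extra_response_onsets or [])):
        warnings.warn("extra-response events beyond scan end; truncated")
    if extra:
        cols["extra_response"] = _convolve(extra, [0.0] * len(extra),
                                           frame_times, False)[:, 0]
    else:
        cols["extra_response"] = np.zeros(n_volumes)
        degenerate.append("extra_response")
    event_cols.append("extra_response")

    drift = dct_drift_basis(n_volumes, tr, drift_cutoff_s)
    drift_cols = [f"drift_{k:02d}" for k in range(1, drift.shape[1] + 1)]
    for name, col in zip(drift_cols, drift.T):
        cols[name] = col

    nuisance_cols: list[str] = []
    if nuisance is not None:
        if len(nuisance) != n_volumes:
            raise ValueError("nuisance rows must match n_volumes")
        for name in nuisance.columns:
            cname = f"nuis_{name}"
            cols[cname] = nuisance[name].to_numpy(dtype=float)
            nuisance_cols.append(cname)

    cols["constant"] = np.ones(n_volumes)
    matrix = pd.DataFrame(cols, index=frame_times)
    return DesignMatrix(matrix=matrix, frame_times=frame_times,
                        block_hrf_columns=block_cols,
                        derivative_columns=deriv_cols,
                        event_columns=event_cols,
                        drift_columns=drift_cols,
                        nuisance_columns=nuisance_cols,
                        degenerate_columns=degenerate)


# --------------------------------------------------------------------------
# AR(1) GLS fit
# --------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Whitened-model estimates for one run."""

    betas: pd.DataFrame          # (n_columns, n_voxels)
    rho: float                   # pooled lag-1 autocorrelation
    sigma2: np.ndarray           # residual variance per voxel (whitened model)
    columns: list[str]

    def block_betas(self, block_hrf_columns: list[str]) -> np.ndarray:
        """Activation-block HRF betas, (n_blocks, n_voxels)."""
        return self.betas.loc[block_hrf_columns].to_numpy()


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Columns involved in exact/near rank deficiency (QR diagnostic)."""
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < tol)]


def fit_glm_ar1(series, dm: DesignMatrix) -> GLMFit:
    """Two-pass AR(1) generalized-least-squares fit.

    1. OLS on the raw system.
    2. Pooled lag-1 autocorrelation of the residuals (median across voxels
       of sum(r_t * r_{t-1}) / sum(r_t^2)).
    3. Prewhitening of both sides (first row scaled by sqrt(1 - rho^2),
       then y*_t = y_t - rho * y_{t-1}), OLS on the whitened system.

    Degenerate (all-zero) columns are excluded from estimation and return
    beta 0.  Rank-deficient designs raise, naming the collinear columns.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    x_df = dm.estimable()
    x = x_df.to_numpy()
    names = list(x_df.columns)
    if y.shape[0] != x.shape[0]:
        raise ValueError("series rows must match the design matrix")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient; collinear columns: "
                         f"{_collinear_columns(x, names)}")

    beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta_ols
    num = np.sum(resid[1:] * resid[:-1], axis=0)
    den = np.sum(resid**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_vox = np.where(den > 0, num / den, 0.0)
    rho = float(np.median(rho_vox))
    rho = float(np.clip(rho, -0.999, 0.999))

    def whiten(a: np.ndarray) -> np.ndarray:
        w = np.empty_like(a)
        w[0] = np.sqrt(1.0 - rho**2) * a[0]
        w[1:] = a[1:] - rho * a[:-1]
        return w

    xw, yw = whiten(x), whiten(y)
    beta_w, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    resid_w = yw - xw @ beta_w
    dof = max(x.shape[0] - x.shape[1], 1)
    sigma2 = np.sum(resid_w**2, axis=0) / dof

    betas = pd.DataFrame(0.0, index=list(dm.matrix.columns),
                         columns=range(y.shape[1]))
    betas.loc[names] = beta_w
    return GLMFit(betas=betas, rho=rho, sigma2=sigma2,
                  columns=list(dm.matrix.columns))


def collect_block_betas(fits: list[GLMFit], dms: list[DesignMatrix],
                        design: RunDesign) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack retained activation-block HRF betas across runs.

    Returns a (n_voxels, 72) array ordered to match
    :func:`lamfmri.synth.make_beta_labels` (run, condition, block occurrence)
    together with that label table.
    """
    from .synth import make_beta_labels

    labels = make_beta_labels(design)
    cols = []
    for fit, dm, run in zip(fits, dms, range(1, design.params.n_runs + 1)):
        sub = labels[labels["run"] == run]
        names = [f"{row.condition}_b{row.block}" for row in sub.itertuples()]
        cols.append(fit.betas.loc[names].to_numpy())
    return np.vstack(cols).T, labels
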