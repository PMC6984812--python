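"""Ground-truthed synthetic cortical patches, vertex betas and time series.

The generator emulates, at desk scale, the structure of a depth-resolved
audiovisual attention experiment in four bilateral ROIs (A1, PT, V1, V2/3):

* a monotone depth gain producing the superficial bias of gradient-echo
  BOLD (signal rises roughly linearly toward the CSF boundary);
* sensory activation for the ROI's preferred modality with a patchy
  vertex pattern;
* crossmodal deactivation for the non-preferred unisensory stimulus with a
  planted laminar shape (C*, L*) and spatially patchy vertex variation;
* a crossmodal-modulation field added in audiovisual blocks, sign-varying
  and patchy, whose vertex-wise correlation with the deactivation field is
  rho* in expectation (so unisensory deactivation topography predicts
  audiovisual modulation topography);
* a multiplicative, pattern-preserving attentional gain, weighted toward
  the surface, applied when the preferred modality is attended;
* block-level Gaussian noise plus run/day offsets and Gaussian subject
  random effects on (C*, L*).

Patchy fields are smoothed Gaussian random fields on a flat 2D grid; all
in-scope statistics operate on per-vertex scalars, so no mesh topology is
needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage, signal

from . import glm as _glm
from .design import CONDITIONS, RunDesign, build_run_design
from .laminar import N_DEPTHS, centered_depth_regressor, equivolume_depth_fractions

__all__ = [
    "ROIPatch",
    "CorticalPatch",
    "ROITruth",
    "GroundTruth",
    "VertexBetaDataset",
    "make_cortical_patch",
    "simulate_vertex_betas",
    "simulate_voxel_timeseries",
    "smooth_random_field",
    "default_ground_truth",
    "DEFAULT_ROI_SIZES",
]

AUDITORY_ROIS = ("A1", "PT")
VISUAL_ROIS = ("V1", "V23")

#: Desk-scale vertex counts per bilateral ROI.
DEFAULT_ROI_SIZES: dict[str, int] = {"A1": 300, "PT": 200, "V1": 300, "V23": 200}


# --------------------------------------------------------------------------
# Cortical patch
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIPatch:
    name: str
    coords: np.ndarray          # (n_vertices, 2) grid coordinates
    curvature: np.ndarray       # (n_vertices,)
    inner_area: np.ndarray      # (n_vertices,) area proxy at WM boundary
    outer_area: np.ndarray      # (n_vertices,) area proxy at pial boundary
    eccentricity: np.ndarray | None  # (n_vertices,) visual ROIs only
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.coords)
        if n < 1:
            raise ValueError(f"ROI {self.name}: empty patch")
        if not np.all(np.isfinite(self.curvature)):
            raise ValueError(f"ROI {self.name}: curvature must be finite")
        if np.any(self.inner_area <= 0) or np.any(self.outer_area <= 0):
            raise ValueError(f"ROI {self.name}: areas must be strictly positive")

    @property
    def n_vertices(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class CorticalPatch:
    rois: Mapping[str, ROIPatch]
    seed: int

    @property
    def n_vertices(self) -> int:
        return sum(r.n_vertices for r in self.rois.values())

    def vertex_roi_labels(self) -> np.ndarray:
        return np.concatenate([[name] * roi.n_vertices
                               for name, roi in self.rois.items()])

    def roi_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, roi in self.rois.items():
            out[name] = slice(start, start + roi.n_vertices)
            start += roi.n_vertices
        return out


def smooth_random_field(grid_shape: tuple[int, int], corr_length: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Standardised Gaussian random field; ``corr_length=0`` is white noise."""
    z = rng.standard_normal(grid_shape)
    if corr_length > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_length, mode="wrap")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _grid_shape(n: int) -> tuple[int, int]:
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    return ny, nx


def make_cortical_patch(roi_sizes: Mapping[str, int] | None = None,
                        corr_length: float = 3.0,
                        curvature_sd: float = 1.0,
                        area_curvature_coupling: float = 0.3,
                        rng_seed: int = 0) -> CorticalPatch:
    """Generate a flat 2D cortical patch per ROI.

    Curvature is a smooth random field (correlation length in grid units);
    inner/outer area proxies are coupled to curvature (gyral crowns have
    larger outer than inner areas and vice versa), and the visual ROIs get
    an eccentricity coordinate increasing from the grid centre outward.
    Deterministic given ``rng_seed``.
    """
    roi_sizes = dict(roi_sizes or DEFAULT_ROI_SIZES)
    for name, size in roi_sizes.items():
        if size < 1:
            raise ValueError(f"ROI {name}: size must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rois: dict[str, ROIPatch] = {}
    for name in sorted(roi_sizes):
        size = roi_sizes[name]
        shape = _grid_shape(size)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        curv = curvature_sd * smooth_random_field(shape, corr_length, rng)
        inner = np.exp(-area_curvature_coupling * curv)
        outer = np.exp(+area_curvature_coupling * curv)
        ecc = None
        if name in VISUAL_ROIS:
            cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
            r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            ecc = (r / max(r.max(), 1e-12)).ravel()[:size]
        rois[name] = ROIPatch(
            name=name,
            coords=np.column_stack([yy.ravel()[:size], xx.ravel()[:size]]).astype(float),
            curvature=curv.ravel()[:size],
            inner_area=inner.ravel()[:size],
            outer_area=outer.ravel()[:size],
            eccentricity=ecc,
            grid_shape=shape,
        )
    return CorticalPatch(rois=rois, seed=int(rng_seed))


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ROITruth:
    """Planted effect structure for one ROI."""

    preferred: str                   # "A" or "V"
    base_activation: float = 2.0     # mean response to the preferred stimulus
    activation_patchy_sd: float = 0.5
    deact_C: float = -1.0            # planted constant of the crossmodal deactivation
    deact_L: float = 0.0             # planted linear term (per depth step)
    deact_C_sd: float = 0.5          # patchy vertex variation of the constant
    deact_L_sd: float = 0.2          # patchy vertex variation of the linear term
    mod_sd: float = 0.5              # sd of the crossmodal-modulation field (constant)
    mod_L_sd: float = 0.2            # sd of its depth-linear component (per step)
    rho_mod_deact: float = 0.8       # corr(modulation fields, deactivation fields)
    attention_gain: float = 0.3      # gamma, multiplicative when preferred attended
    depth_gain_slope: float = 1.0    # g(d) = 1 + slope * depth_fraction
    field_corr_length: float = 3.0   # patchiness scale (grid units)

    def __post_init__(self) -> None:
        if self.preferred not in ("A", "V"):
            raise ValueError("preferred must be 'A' or 'V'")
        if self.attention_gain < 0:
            raise ValueError("attention gain must be >= 0")
        if abs(self.rho_mod_deact) > 1:
            raise ValueError("|rho_mod_deact| must be <= 1")
        if 1.0 + self.depth_gain_slope <= 0:
            raise ValueError("depth gain must stay strictly positive")

    def depth_gain(self, depth_fraction) -> np.ndarray:
        """Superficial-bias gain, strictly positive, rising toward CSF."""
        return 1.0 + self.depth_gain_slope * np.asarray(depth_fraction, dtype=float)


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects per ROI plus the noise model."""

    rois: Mapping[str, ROITruth]
    beta_noise_sd: float = 0.5       # i.i.d. noise per (vertex, depth, beta)
    run_offset_sd: float = 0.1
    day_offset_sd: float = 0.1
    subject_deact_C_sd: float = 0.2  # random effects across subjects
    subject_deact_L_sd: float = 0.1

    def __post_init__(self) -> None:
        if min(self.beta_noise_sd, self.run_offset_sd, self.day_offset_sd,
               self.subject_deact_C_sd, self.subject_deact_L_sd) < 0:
            raise ValueError("noise parameters must be >= 0")


def default_ground_truth(**overrides) -> GroundTruth:
    """Study-condition ground truth for the four ROIs.

    Auditory ROIs carry a constant crossmodal deactivation (C* = -1,
    L* = 0) and a patchy audiovisual modulation field correlated with it;
    visual ROIs carry a deactivation growing in magnitude toward the
    surface (C* = -1, L* = -0.3) and no mean audiovisual modulation.
    """
    rois = {
        "A1": ROITruth(preferred="A"),
        "PT": ROITruth(preferred="A"),
        "V1": ROITruth(preferred="V", deact_L=-0.3, mod_sd=0.0, mod_L_sd=0.0,
                        rho_mod_deact=0.0),
        "V23": ROITruth(preferred="V", deact_L=-0.3, mod_sd=0.0, mod_L_sd=0.0,
                        rho_mod_deact=0.0),
    }
    rois.update(overrides.pop("rois", {}))
    return GroundTruth(rois=rois, **overrides)


# --------------------------------------------------------------------------
# Vertex-beta dataset
# --------------------------------------------------------------------------

def make_beta_labels(design: RunDesign) -> pd.DataFrame:
    """Canonical 72-row label table: condition x block occurrence x run."""
    rows = []
    for run in range(1, design.params.n_runs + 1):
        for cond in CONDITIONS:
            for block in range(1, design.params.blocks_per_condition_per_run + 1):
                stim, att = cond.split("_")
                rows.append({"condition": cond, "stim": stim, "att": att,
                             "block": block, "run": run,
                             "day": 1 if run <= design.params.runs_per_day else 2})
    return pd.DataFrame(rows)


@dataclass
class VertexBetaDataset:
    """Per-subject vertex x depth x beta array with labels and ROI maps."""

    subject_id: str
    betas: np.ndarray               # (n_vertices, N_DEPTHS, n_images)
    labels: pd.DataFrame            # one row per image
    roi_labels: np.ndarray          # (n_vertices,) ROI name per vertex
    depth_fractions: np.ndarray     # (n_vertices, N_DEPTHS), deep -> superficial

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nv, nd, ni = self.betas.shape
        if nd != N_DEPTHS:
            raise ValueError(f"expected {N_DEPTHS} depths, got {nd}")
        if ni != len(self.labels):
            raise ValueError("label table does not match the beta axis")
        required = {"condition", "block", "run", "day"}
        if not required <= set(self.labels.columns):
            raise ValueError(f"label table must have columns {sorted(required)}")
        expected = (len(CONDITIONS)
                    * self.labels["block"].nunique()
                    * self.labels["run"].nunique())
        if ni != expected or ni != len(self.labels.drop_duplicates(
                ["condition", "block", "run"])):
            raise ValueError("betas must be uniquely labelled condition x block x run")
        bad_day = self.labels["day"] != np.where(self.labels["run"] <= 2, 1, 2)
        if bad_day.any():
            raise ValueError("runs 1-2 must map to day 1 and runs 3-4 to day 2")
        if len(self.roi_labels) != nv or self.depth_fractions.shape != (nv, nd):
            raise ValueError("per-vertex arrays do not match the beta array")
        if not (np.all(np.diff(self.depth_fractions, axis=1) > 0)
                and np.all(self.depth_fractions > 0)
                and np.all(self.depth_fractions < 1)):
            raise ValueError("depth fractions must be strictly increasing in (0,1)")

    @property
    def n_vertices(self) -> int:
        return self.betas.shape[0]

    def roi_mask(self, roi: str) -> np.ndarray:
        return self.roi_labels == roi

    def roi_betas(self, roi: str) -> np.ndarray:
        return self.betas[self.roi_mask(roi)]

    # -- serialisation ----------------------------------------------------

    def save(self, path) -> None:
        """Write to an HDF5 container plus embedded label table."""
        with h5py.File(path, "w") as f:
            f.attrs["subject_id"] = self.subject_id
            f.create_dataset("betas", data=self.betas)
            f.create_dataset("depth_fractions", data=self.depth_fractions)
            f.create_dataset("roi_labels",
                             data=np.asarray(self.roi_labels, dtype="S"))
            f.create_dataset("labels_json",
                             data=self.labels.to_json(orient="split"))

    @classmethod
    def load(cls, path) -> "VertexBetaDataset":
        with h5py.File(path, "r") as f:
            from io import StringIO
            labels = pd.read_json(StringIO(f["labels_json"][()].decode()),
                                  orient="split")
            return cls(
                subject_id=str(f.attrs["subject_id"]),
                betas=f["betas"][()],
                labels=labels,
                roi_labels=f["roi_labels"][()].astype(str),
                depth_fractions=f["depth_fractions"][()],
            )


# --------------------------------------------------------------------------
# Beta simulation
# --------------------------------------------------------------------------

def _correlated_vector(z_anchor: np.ndarray, z_indep: np.ndarray,
                       rho: float) -> np.ndarray:
    """Mix two standardised fields so corr(out, anchor) = rho in expectation."""
    return rho * z_anchor + np.sqrt(max(0.0, 1.0 - rho**2)) * z_indep


def simulate_vertex_betas(patch: CorticalPatch, truth: GroundTruth,
                          design: RunDesign, n_subjects: int,
                          rng_seed: int = 0) -> list[VertexBetaDataset]:
    """Simulate per-subject vertex x depth x beta datasets.

    For every vertex v, depth d (fraction f) and condition (stim, att) the
    noiseless signal in an ROI with preferred modality P is::

        s(v,d) = [activation(v) if P in stim]
               + [deact(v,d)    if stim is the unpreferred unisensory stimulus]
               + [mod(v)        if stim is audiovisual]
        signal = g(f) * s(v,d) * (1 + gamma * f)   if att == P  else  g(f) * s(v,d)

    with deact(v,d) = (C* + dC(v)) + (L* + dL(v)) * x(d) for the centred
    depth regressor x, patchy fields dC, dL, and the modulation field
    mod(v) = mod_sd * (rho* z_dC + sqrt(1-rho*^2) z_ind) built from the
    standardised deactivation field z_dC so that corr(mod, deact) = rho* in
    expectation.  The attentional gain multiplies the whole pattern
    (pattern-preserving); the modulation field adds to it (pattern-altering).
    Noise adds run and day offsets and i.i.d. Gaussian noise per beta, and
    subjects perturb (C*, L*) with Gaussian random effects.
    """
    if set(patch.rois) != set(truth.rois):
        raise ValueError("patch and ground-truth ROI sets differ: "
                         f"{sorted(patch.rois)} vs {sorted(truth.rois)}")
    labels = make_beta_labels(design)
    n_images = len(labels)
    root = np.random.SeedSequence(rng_seed)
    subject_seeds = root.spawn(n_subjects)

    datasets = []
    for s_idx in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[s_idx])
        all_betas, all_roi, all_depth = [], [], []
        for name, roi in patch.rois.items():
            rt = truth.rois[name]
            nv = roi.n_vertices
            shape = roi.grid_shape
            size = nv

            depth_fr = equivolume_depth_fractions(
                np.ones(nv), roi.inner_area, roi.outer_area, N_DEPTHS)
            x = centered_depth_regressor(N_DEPTHS)

            act_field = rt.base_activation + rt.activation_patchy_sd * \
                smooth_random_field(shape, rt.field_corr_length, rng).ravel()[:size]
            z_dc = smooth_random_field(shape, rt.field_corr_length, rng).ravel()[:size]
            z_dl = smooth_random_field(shape, rt.field_corr_length, rng).ravel()[:size]
            z_ind = smooth_random_field(shape, rt.field_corr_length, rng).ravel()[:size]
            z_ind2 = smooth_random_field(shape, rt.field_corr_length, rng).ravel()[:size]
            z_mod = _correlated_vector(z_dc, z_ind, rt.rho_mod_deact)
            z_mod_l = _correlated_vector(z_dl, z_ind2, rt.rho_mod_deact)

            c_star = rt.deact_C + rng.normal(0.0, truth.subject_deact_C_sd)
            l_star = rt.deact_L + rng.normal(0.0, truth.subject_deact_L_sd)
            deact = ((c_star + rt.deact_C_sd * z_dc)[:, None]
                     + (l_star + rt.deact_L_sd * z_dl)[:, None] * x[None, :])
            mod = (rt.mod_sd * z_mod[:, None]
                   + rt.mod_L_sd * z_mod_l[:, None] * x[None, :])

            gain = rt.depth_gain(depth_fr)                     # (nv, 6)
            att_w = 1.0 + rt.attention_gain * depth_fr         # (nv, 6)

            unpreferred = "V" if rt.preferred == "A" else "A"
            cond_signal = {}
            for cond in CONDITIONS:
                stim, att = cond.split("_")
                s = np.zeros((nv, N_DEPTHS))
                if rt.preferred in stim:          # "A" in "A"/"AV" etc.
                    s += act_field[:, None]
                if stim == unpreferred:
                    s += deact
                if stim == "AV":
                    s += mod
                s = s * gain
                if att.endswith(rt.preferred):
                    s = s * att_w
                cond_signal[cond] = s

            run_off = rng.normal(0.0, truth.run_offset_sd,
                                 size=design.params.n_runs)
            day_off = rng.normal(0.0, truth.day_offset_sd, size=2)
            betas = np.empty((nv, N_DEPTHS, n_images))
            for i, row in enumerate(labels.itertuples(index=False)):
                base = cond_signal[row.condition]
                betas[:, :, i] = (base + run_off[row.run - 1] + day_off[row.day - 1]
                                  + rng.normal(0.0, truth.beta_noise_sd,
                                               size=(nv, N_DEPTHS)))
            all_betas.append(betas)
            all_roi.append(np.full(nv, name, dtype=object))
            all_depth.append(depth_fr)

        datasets.append(VertexBetaDataset(
            subject_id=f"sub-{s_idx + 1:02d}",
            betas=np.concatenate(all_betas, axis=0),
            labels=labels.copy(),
            roi_labels=np.concatenate(all_roi).astype(str),
            depth_fractions=np.concatenate(all_depth, axis=0),
        ))
    return datasets


def ground_truth_to_json(truth: GroundTruth, path) -> None:
    payload = {"rois": {k: asdict(v) for k, v in truth.rois.items()},
               **{k: v for k, v in asdict(truth).items() if k != "rois"}}
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


# --------------------------------------------------------------------------
# Voxel time-series simulation (input to the first-level GLM)
# --------------------------------------------------------------------------

def simulate_voxel_timeseries(design: RunDesign, true_betas,
                              run: int = 1,
                              drift_amplitude: float = 0.0,
                              ar1_rho: float = 0.0,
                              noise_sd: float = 0.0,
                              tr: float = 3.0,
                              n_volumes: int = 302,
                              rng_seed: int = 0) -> tuple[np.ndarray, "_glm.DesignMatrix"]:
    """Simulate voxel time series from planted block betas.

    ``series = X_blocks @ true_betas + drift + AR(1) noise`` for one run,
    where ``X_blocks`` are the canonical-HRF block regressors of the run's
    design matrix (302 volumes at TR 3 s by default).  The optional drift
    is a slow cosine at the 128 s cutoff period scaled by
    ``drift_amplitude``; the AR(1) noise is stationary with lag-1
    correlation ``ar1_rho`` and innovation scaled so the marginal sd is
    ``noise_sd``.  Deterministic given ``rng_seed``.

    Parameters
    ----------
    true_betas : ndarray, (18,) or (18, n_voxels)
        One beta per block-HRF regressor of the run.

    Returns
    -------
    series : ndarray, (n_volumes,) or (n_volumes, n_voxels)
    dm : DesignMatrix used for the prediction.
    """
    if not -1.0 < ar1_rho < 1.0:
        raise ValueError("ar1_rho must be in (-1, 1)")
    dm = _glm.build_design_matrix(design, run=run, tr=tr, n_volumes=n_volumes)
    xb = dm.matrix[dm.block_hrf_columns].to_numpy()
    beta = np.asarray(true_betas, dtype=float)
    series = xb @ beta
    t = np.arange(n_volumes) * tr
    drift = drift_amplitude * np.cos(2 * np.pi * t / 128.0)
    series = series + (drift if series.ndim == 1 else drift[:, None])
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        shape = (n_volumes,) if series.ndim == 1 else series.shape
        innov_sd = noise_sd * np.sqrt(1.0 - ar1_rho**2)
        e = rng.normal(0.0, innov_sd, size=shape)
        noise = signal.lfilter([1.0], [1.0, -ar1_rho], e, axis=0)
        # stationary start: seed the filter with a draw at the marginal sd
        x0 = rng.normal(0.0, noise_sd, size=shape[1:] if series.ndim > 1 else ())
        carry = x0
        powers = ar1_rho ** np.arange(1, n_volumes + 1)
        noise = noise + np.multiply.outer(powers, carry).reshape(shape)
        series = series + noise
    return series, dm
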