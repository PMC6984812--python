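"""Per-depth pattern decoding, accuracy-shape fits and pattern similarity.

Decoding: a linear support-vector classifier (C = 1) discriminates two
classes of blockwise vertex patterns independently at each cortical depth,
in leave-one-run-out cross-validation.  Features are mean-centred within
the training set and, separately, within the test set; no statistic of the
held-out run ever reaches training.  Pooled comparisons (e.g. audiovisual
vs auditory blocks irrespective of attention) stack the blockwise samples
of both attention conditions.

Accuracy profiles across the six depths are summarised with the same
constant + centred-linear shape GLM as the BOLD profiles, after
subtracting chance (0.5), so the constant tests above-chance decoding and
the linear term a depth trend.

Pattern similarity: Spearman rank correlations over vertices between
condition-mean patterns, Fisher-z transformed, averaged within two
families (e.g. attention pairs vs stimulus pairs) and contrasted per
subject; group inference by the exact sign-permutation test (all 2^n sign
assignments of the subject values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .laminar import N_DEPTHS, ShapeParams, fit_laminar_glm
from .synth import VertexBetaDataset

__all__ = [
    "PatternDataset",
    "DecodingProfile",
    "SimilarityResult",
    "make_pattern_dataset",
    "decode_per_depth",
    "fit_accuracy_shape",
    "condition_mean_patterns",
    "pattern_similarity",
    "exact_sign_permutation",
    "fisher_z",
    "ATTENTION_PAIRS",
    "STIMULUS_PAIRS",
]

#: Largest Spearman rho magnitude before Fisher transform (atanh clipping).
RHO_CLIP = 1.0 - 1e-12


# --------------------------------------------------------------------------
# Pattern extraction
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternDataset:
    """Blockwise vertex patterns per depth for a two-class comparison."""

    patterns: np.ndarray        # (n_samples, N_DEPTHS, n_features)
    y: np.ndarray               # (n_samples,) class indices 0/1
    runs: np.ndarray            # (n_samples,) run of each sample
    class_names: tuple[str, str]
    comparison: str

    def __post_init__(self) -> None:
        if self.patterns.shape[0] != len(self.y) or len(self.y) != len(self.runs):
            raise ValueError("samples, labels and runs must align")
        for run in np.unique(self.runs):
            present = set(self.y[self.runs == run])
            if present != {0, 1}:
                raise ValueError(f"run {run} lacks samples of both classes")

    @property
    def n_runs(self) -> int:
        return len(np.unique(self.runs))


def make_pattern_dataset(dataset: VertexBetaDataset, roi: str,
                         comparison: tuple[str, str],
                         by: str = "stim") -> PatternDataset:
    """Extract a two-class blockwise pattern dataset from an ROI.

    ``comparison`` names the two levels of the ``by`` label column
    (``"stim"``: e.g. ("AV", "A") pooled over attention; ``"att"``:
    ("AttA", "AttV") pooled over stimulus modality).  Class 0 is the first
    element.  Vertices missing any depth are dropped.
    """
    if by not in ("stim", "att"):
        raise ValueError("by must be 'stim' or 'att'")
    betas = dataset.roi_betas(roi)                     # (nv, 6, 72)
    keep = np.all(np.isfinite(betas.reshape(betas.shape[0], -1)), axis=1)
    betas = betas[keep]
    labels = dataset.labels.reset_index(drop=True)
    cls_of = {name: i for i, name in enumerate(comparison)}
    rows = labels[labels[by].isin(comparison)]
    pat = betas[:, :, rows.index.to_numpy()]           # (nv, 6, n_samples)
    return PatternDataset(
        patterns=np.transpose(pat, (2, 1, 0)),
        y=rows[by].map(cls_of).to_numpy(),
        runs=rows["run"].to_numpy(),
        class_names=tuple(comparison),
        comparison=f"{comparison[0]} vs {comparison[1]} (by {by})",
    )


# --------------------------------------------------------------------------
# Decoding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecodingProfile:
    """Cross-validated accuracy at each depth plus per-fold detail."""

    accuracies: np.ndarray          # (N_DEPTHS,)
    fold_accuracies: pd.DataFrame   # columns: depth, run, accuracy
    comparison: str

    def __post_init__(self) -> None:
        if np.any(self.accuracies < 0) or np.any(self.accuracies > 1):
            raise ValueError("accuracies must lie in [0, 1]")


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def _fit_fold(x_train: np.ndarray, y_train: np.ndarray, c: float) -> SVC:
    clf = SVC(kernel="linear", C=c)
    clf.fit(_center(x_train), y_train)
    return clf


def _predict(clf: SVC, x_test: np.ndarray) -> np.ndarray:
    # Deterministic tie-break: a decision value of exactly 0 goes to the
    # class with the lower label index.
    scores = clf.decision_function(_center(x_test))
    return (scores > 0).astype(int)


def decode_per_depth(data: PatternDataset, c: float = 1.0) -> DecodingProfile:
    """Leave-one-run-out linear SVC accuracy at each depth."""
    runs = np.unique(data.runs)
    if len(runs) < 2:
        raise ValueError("need at least two runs for leave-one-run-out CV")
    records = []
    acc = np.zeros(N_DEPTHS)
    for d in range(N_DEPTHS):
        fold_acc = []
        for run in runs:
            test = data.runs == run
            clf = _fit_fold(data.patterns[~test, d, :], data.y[~test], c)
            pred = _predict(clf, data.patterns[test, d, :])
            fold_acc.append(float(np.mean(pred == data.y[test])))
            records.append({"depth": d, "run": int(run), "accuracy": fold_acc[-1]})
        acc[d] = np.mean(fold_acc)
    return DecodingProfile(accuracies=acc,
                           fold_accuracies=pd.DataFrame(records),
                           comparison=data.comparison)


def fit_accuracy_shape(profile: DecodingProfile) -> ShapeParams:
    """Shape GLM of the accuracy profile after subtracting chance (0.5)."""
    return fit_laminar_glm(profile.accuracies - 0.5)


# --------------------------------------------------------------------------
# Pattern similarity
# --------------------------------------------------------------------------

def fisher_z(rho) -> np.ndarray:
    """Fisher z-transform with |rho| clipped just below 1 (finite output)."""
    return np.arctanh(np.clip(rho, -RHO_CLIP, RHO_CLIP))


def condition_mean_patterns(dataset: VertexBetaDataset, roi: str,
                            depth: int | None = None) -> dict[str, np.ndarray]:
    """Per-condition mean vertex pattern (averaged over blocks and runs).

    Depths are averaged unless a single depth index is requested.
    """
    betas = dataset.roi_betas(roi)
    keep = np.all(np.isfinite(betas.reshape(betas.shape[0], -1)), axis=1)
    betas = betas[keep]
    labels = dataset.labels.reset_index(drop=True)
    out = {}
    for cond, sub in labels.groupby("condition"):
        block_mean = betas[:, :, sub.index.to_numpy()].mean(axis=2)  # (nv, 6)
        out[cond] = block_mean[:, depth] if depth is not None else block_mean.mean(axis=1)
    return out


@dataclass(frozen=True)
class SimilarityResult:
    """Family-averaged Fisher-z similarities for one subject."""

    rho: dict[str, float]           # per pair "cond1|cond2"
    z_family_a: float               # mean Fisher z of family A pairs
    z_family_b: float
    contrast: float                 # z_family_a - z_family_b


def pattern_similarity(dataset: VertexBetaDataset, roi: str,
                       family_a: Sequence[tuple[str, str]],
                       family_b: Sequence[tuple[str, str]],
                       depth: int | None = None) -> SimilarityResult:
    """Spearman pattern similarity contrast between two pair families.

    For each condition pair, Spearman rho over common vertices between the
    condition-mean patterns; Fisher-z; averaged within family; the result
    is family A minus family B (e.g. attention pairs minus stimulus pairs:
    positive when attention preserves the pattern more than adding the
    other modality does).
    """
    means = condition_mean_patterns(dataset, roi, depth=depth)
    rho: dict[str, float] = {}

    def pair_rhos(pairs):
        zs = []
        for a, b in pairs:
            pa, pb = means[a], means[b]
            if np.std(pa) == 0 or np.std(pb) == 0:
                raise ValueError(f"constant pattern in pair ({a}, {b}); "
                                 "Spearman rho undefined")
            r = stats.spearmanr(pa, pb).statistic
            rho[f"{a}|{b}"] = float(r)
            zs.append(fisher_z(r))
        return float(np.mean(zs))

    za = pair_rhos(family_a)
    zb = pair_rhos(family_b)
    return SimilarityResult(rho=rho, z_family_a=za, z_family_b=zb,
                            contrast=za - zb)


#: Default similarity families in auditory cortex: attention pairs (same
#: stimulus, different attended modality) vs stimulus pairs (A vs AV under
#: the same attention).
ATTENTION_PAIRS = (("A_AttV", "A_AttA"), ("AV_AttV", "AV_AttA"))
STIMULUS_PAIRS = (("A_AttA", "AV_AttA"), ("A_AttV", "AV_AttV"))


# --------------------------------------------------------------------------
# Exact sign-permutation test
# --------------------------------------------------------------------------

MAX_EXHAUSTIVE_N = 20


def exact_sign_permutation(values, two_sided: bool = True) -> float:
    """Exact sign-flip permutation p-value for a zero-mean null.

    Enumerates all 2^n sign assignments of the per-subject values and
    returns the proportion of assignments whose |mean| (two-sided) or mean
    (one-sided, greater) reaches the observed one.  Exact — no sampling;
    p-values are multiples of 2^-n and never zero.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0 or not np.all(np.isfinite(v)):
        raise ValueError("values must be non-empty and finite")
    if n > MAX_EXHAUSTIVE_N:
        raise ValueError(f"n={n} too large for exhaustive enumeration "
                         f"(max {MAX_EXHAUSTIVE_N}); use a Monte-Carlo test")
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1) * 2 - 1
    perm_means = signs @ v / n
    obs = v.mean()
    tol = 1e-12 * max(1.0, float(np.max(np.abs(v))))
    if two_sided:
        count = np.sum(np.abs(perm_means) >= abs(obs) - tol)
    else:
        count = np.sum(perm_means >= obs - tol)
    return float(count) / 2**n
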