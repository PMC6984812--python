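"""Group-level step-down inference on laminar shape parameters.

For each contrast family the shape parameters (constant C, linear L) of
two ROIs (primary and non-primary) from n subjects enter a 2 (shape) x
2 (ROI) linear mixed model with a random intercept per subject, tested in
a step-down sequence:

1. a two-dimensional F-test that (C, L), each averaged across the two
   ROIs, are jointly zero;
2. if significant, per-shape tests of the ROI-averaged parameter;
3. if significant, per-ROI t-tests (one-sided where an a-priori direction
   exists, e.g. negative constants for crossmodal deactivation).

Each later stage runs only if the previous one was significant at alpha.

Because the design is balanced with one observation per subject-cell, the
mixed-model tests reduce exactly to statistics of per-subject averages
(the subject random effect is carried into them): stage 1 is Hotelling's
T^2 on the per-subject (C, L) ROI-averages, giving an exact
F(2, n-2) null distribution; stages 2 and 3 are one-sample t-tests with
n-1 degrees of freedom.  These reductions keep the family-wise error of
the whole procedure exactly controlled at small n, which plug-in Wald
F-tests with residual degrees of freedom do not.  `fit_shape_lmm` exposes
the underlying statsmodels MixedLM fit (cell means, variance components)
for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTable",
    "FittedShapeLMM",
    "StageResult",
    "StepDownResult",
    "make_group_table",
    "fit_shape_lmm",
    "stepdown_test",
    "one_sample_t",
]

SHAPES = ("C", "L")
ROI_LEVELS = ("primary", "nonprimary")


@dataclass(frozen=True)
class GroupTable:
    """Balanced (subject x ROI x shape) long table for one contrast."""

    data: pd.DataFrame      # columns: subject, roi, shape, value
    contrast: str = ""

    def __post_init__(self) -> None:
        req = {"subject", "roi", "shape", "value"}
        if not req <= set(self.data.columns):
            raise ValueError(f"group table needs columns {sorted(req)}")
        if set(self.data["roi"].unique()) != set(ROI_LEVELS):
            raise ValueError(f"table must contain exactly the ROIs {ROI_LEVELS}")
        if set(self.data["shape"].unique()) != set(SHAPES):
            raise ValueError(f"table must contain exactly the shapes {SHAPES}")
        counts = self.data.groupby(["subject", "roi", "shape"]).size()
        if counts.nunique() != 1:
            raise ValueError("unbalanced table: every subject must contribute "
                             "equally to every ROI x shape cell")
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")

    @property
    def n_subjects(self) -> int:
        return self.data["subject"].nunique()

    def subject_cell_means(self) -> pd.DataFrame:
        """One value per subject x ROI x shape (averaging replicates)."""
        return (self.data.groupby(["subject", "roi", "shape"])["value"]
                .mean().reset_index())

    def subject_matrix(self, shape: str) -> pd.DataFrame:
        """Subjects x ROI wide matrix for one shape parameter."""
        cm = self.subject_cell_means()
        return (cm[cm["shape"] == shape]
                .pivot(index="subject", columns="roi", values="value"))


def make_group_table(values: pd.DataFrame, contrast: str = "",
                     roi_map: dict[str, str] | None = None) -> GroupTable:
    """Build a GroupTable from a tidy (subject, roi, C, L) frame.

    ``roi_map`` renames concrete ROI names (e.g. A1 -> primary,
    PT -> nonprimary).
    """
    df = values.copy()
    if roi_map:
        df["roi"] = df["roi"].map(roi_map)
    long = df.melt(id_vars=["subject", "roi"], value_vars=["C", "L"],
                   var_name="shape", value_name="value")
    return GroupTable(data=long, contrast=contrast)


# --------------------------------------------------------------------------
# Mixed model fit (reporting / oracle cross-check)
# --------------------------------------------------------------------------

@dataclass
class FittedShapeLMM:
    """statsmodels MixedLM fit of value ~ 0 + shape:roi with subject intercept."""

    cell_means: pd.Series        # indexed by (shape, roi)
    subject_var: float
    resid_var: float
    result: object               # MixedLMResults
    table: GroupTable


def fit_shape_lmm(table: GroupTable) -> FittedShapeLMM:
    """Fit the 2x2 random-intercept model (REML).

    Fixed effects are the four shape x ROI cell means; in the balanced
    design they equal the sample cell means.
    """
    import statsmodels.formula.api as smf

    df = table.data.copy()
    df["cell"] = df["shape"] + ":" + df["roi"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ 0 + C(cell)", df, groups=df["subject"])
        result = model.fit(reml=True)
    means = {}
    for (shape, roi) in [(s, r) for s in SHAPES for r in ROI_LEVELS]:
        means[(shape, roi)] = float(result.params[f"C(cell)[{shape}:{roi}]"])
    return FittedShapeLMM(
        cell_means=pd.Series(means),
        subject_var=float(result.cov_re.iloc[0, 0]),
        resid_var=float(result.scale),
        result=result,
        table=table,
    )


# --------------------------------------------------------------------------
# Step-down procedure
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StageResult:
    stage: int
    label: str                  # e.g. "C+L", "C", "C:primary"
    statistic: float
    df: tuple[float, ...]       # (df1, df2) for F, (df,) for t
    p: float
    kind: str                   # "F" or "t"
    sided: str = "two-sided"    # "two-sided", "less", "greater"


@dataclass
class StepDownResult:
    contrast: str
    alpha: float
    stage1: StageResult
    stage2: dict[str, StageResult] = field(default_factory=dict)
    stage3: dict[str, StageResult] = field(default_factory=dict)
    stages_run: list[int] = field(default_factory=list)

    def significant(self, stage: int, label: str | None = None) -> bool:
        if stage == 1:
            return self.stage1.p < self.alpha
        pool = self.stage2 if stage == 2 else self.stage3
        if label is not None:
            return label in pool and pool[label].p < self.alpha
        return any(r.p < self.alpha for r in pool.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [self.stage1, *self.stage2.values(), *self.stage3.values()]
        return pd.DataFrame(
            [{"contrast": self.contrast, "stage": r.stage, "label": r.label,
              "kind": r.kind, "statistic": r.statistic,
              "df1": r.df[0], "df2": r.df[1] if len(r.df) > 1 else np.nan,
              "p": r.p, "sided": r.sided} for r in rows])


def one_sample_t(values: np.ndarray, sided: str = "two-sided") -> StageResult:
    """One-sample t-test of mean zero, as a StageResult shell."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    t, p = stats.ttest_1samp(values, 0.0, alternative=sided)
    return StageResult(stage=3, label="", statistic=float(t), df=(n - 1,),
                       p=float(p), kind="t", sided=sided)


def _hotelling_f(d: np.ndarray) -> tuple[float, tuple[float, float], float]:
    """Hotelling T^2 of mean-zero for n x 2 data, as an exact F."""
    n, k = d.shape
    if n <= k:
        raise ValueError("need more subjects than tested dimensions")
    mean = d.mean(axis=0)
    cov = np.cov(d, rowvar=False, ddof=1)
    t2 = n * mean @ np.linalg.solve(cov, mean)
    f = (n - k) / (k * (n - 1)) * t2
    df = (float(k), float(n - k))
    p = float(stats.f.sf(f, *df))
    return float(f), df, p


def stepdown_test(table: GroupTable, sided: dict[str, str] | None = None,
                  alpha: float = 0.05) -> StepDownResult:
    """Run the gated step-down procedure on a group table.

    Parameters
    ----------
    table : GroupTable
    sided : dict, optional
        A-priori directions per shape parameter, e.g. ``{"C": "less"}`` for
        predicted negative deactivation constants; applies to stages 2 and
        3.  Shapes not listed are tested two-sided (F at stage 2).
    alpha : float
        Gate for running each subsequent stage.
    """
    sided = sided or {}
    n = table.n_subjects
    roi_avg = {s: table.subject_matrix(s).mean(axis=1).to_numpy() for s in SHAPES}

    f, df, p = _hotelling_f(np.column_stack([roi_avg[s] for s in SHAPES]))
    stage1 = StageResult(stage=1, label="+".join(SHAPES), statistic=f,
                         df=df, p=p, kind="F")
    out = StepDownResult(contrast=table.contrast, alpha=alpha, stage1=stage1,
                         stages_run=[1])
    if p >= alpha:
        return out

    out.stages_run.append(2)
    for shape in SHAPES:
        vals = roi_avg[shape]
        direction = sided.get(shape)
        if direction in ("less", "greater"):
            r = one_sample_t(vals, sided=direction)
            out.stage2[shape] = StageResult(stage=2, label=shape,
                                            statistic=r.statistic, df=r.df,
                                            p=r.p, kind="t", sided=direction)
        else:
            t, p2 = stats.ttest_1samp(vals, 0.0)
            out.stage2[shape] = StageResult(stage=2, label=shape,
                                            statistic=float(t**2),
                                            df=(1.0, float(n - 1)),
                                            p=float(p2), kind="F")

    ran3 = False
    for shape in SHAPES:
        if out.stage2[shape].p >= alpha:
            continue
        ran3 = True
        mat = table.subject_matrix(shape)
        for roi in ROI_LEVELS:
            r = one_sample_t(mat[roi].to_numpy(),
                             sided=sided.get(shape, "two-sided"))
            out.stage3[f"{shape}:{roi}"] = StageResult(
                stage=3, label=f"{shape}:{roi}", statistic=r.statistic,
                df=r.df, p=r.p, kind="t", sided=r.sided)
    if ran3:
        out.stages_run.append(3)
    return out
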