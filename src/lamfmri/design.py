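"""Stimulus construction, block/run scheduling and behavioural scoring.

This module builds the parametric trajectories of the audiovisual looming
stimuli, the block timeline of the 3 (stimulus modality: A, V, AV) x
2 (attended modality) intersensory-attention experiment, the weak-target
schedule used to enforce modality-specific attention, and the scoring of
button presses against target response windows.

Conventions
-----------
* Times are seconds internally; milliseconds appear only in the stimulus
  specs, where the design constants are conventionally printed in ms.
* A "condition" is a (stimulus modality, attended modality) pair, labelled
  e.g. ``"AV_AttA"``.  There are six conditions.
* A run contains 18 activation blocks (3 per condition), each 33 s of 50
  looming stimuli at a fixed 660 ms onset asynchrony, preceded by 16 s
  fixation (with an attention cue 3 s before block onset) and followed,
  after the last block, by 20 s of fixation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STIM_MODALITIES",
    "ATTENTION_STATES",
    "CONDITIONS",
    "LoomingVisualSpec",
    "LoomingSoundSpec",
    "AnnulusTrajectory",
    "ToneTrajectory",
    "ExperimentParams",
    "Block",
    "RunDesign",
    "Target",
    "TargetSchedule",
    "ResponseLog",
    "BehavioralScore",
    "visual_annulus_trajectories",
    "auditory_looming_trajectories",
    "build_run_design",
    "schedule_targets",
    "score_responses",
    "events_table",
]

STIM_MODALITIES = ("A", "V", "AV")
ATTENTION_STATES = ("AttA", "AttV")
#: The six conditions of the factorial design, in canonical order.
CONDITIONS = tuple(f"{s}_{a}" for s in STIM_MODALITIES for a in ATTENTION_STATES)

#: Pure-tone bases of the looming sound (Hz).
LOOMING_TONE_BASES_HZ = (
    55.0, 110.0, 150.0, 220.0, 330.0, 380.0, 440.0,
    660.0, 880.0, 990.0, 1110.0, 1500.0, 2500.0, 3000.0,
)


class DesignError(ValueError):
    """Invalid design parameters or timeline."""


# --------------------------------------------------------------------------
# Stimulus specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LoomingVisualSpec:
    """Radially expanding annulus sequence (visual looming).

    Each annulus starts in the centre with radius ``start_radius_deg`` and
    expands at ``speed_deg_per_s`` until it reaches ``max_radius_deg``
    (at which point it is removed); a new annulus starts every
    ``onset_interval_ms`` during the ``duration_ms`` sequence.
    """

    start_radius_deg: float = 0.25
    speed_deg_per_s: float = 15.52
    max_radius_deg: float = 3.88
    onset_interval_ms: float = 125.0
    duration_ms: float = 500.0

    def __post_init__(self) -> None:
        for name in ("start_radius_deg", "speed_deg_per_s", "max_radius_deg",
                     "onset_interval_ms", "duration_ms"):
            if not getattr(self, name) > 0:
                raise DesignError(f"{name} must be strictly positive")
        if not self.start_radius_deg < self.max_radius_deg:
            raise DesignError("start_radius_deg must be < max_radius_deg")
        if self.onset_interval_ms > self.duration_ms:
            raise DesignError("onset_interval_ms must be <= duration_ms")


@dataclass(frozen=True)
class LoomingSoundSpec:
    """Looming sound: pure-tone mixture rising in amplitude and frequency.

    The amplitude of each tone at time ``t`` (s) is
    ``A(t) = A0 * exp(k * t) - 1`` with growth rate ``k =
    amp_exponent_per_s``; the frequency of each tone ramps linearly from its
    base ``f`` to ``f * (1 + freq_ramp_fraction)`` over the duration.
    """

    base_frequencies_hz: Sequence[float] = LOOMING_TONE_BASES_HZ
    amp_exponent_per_s: float = 0.68
    freq_ramp_fraction: float = 2.0 / 3.0
    base_amplitude: float = 1.0
    duration_ms: float = 500.0

    def __post_init__(self) -> None:
        freqs = tuple(self.base_frequencies_hz)
        if not freqs or any(f <= 0 for f in freqs):
            raise DesignError("base frequencies must be strictly positive")
        if list(freqs) != sorted(freqs):
            raise DesignError("base frequencies must be sorted ascending")
        if self.freq_ramp_fraction < 0:
            raise DesignError("freq_ramp_fraction must be >= 0")
        if self.duration_ms <= 0:
            raise DesignError("duration_ms must be strictly positive")
        object.__setattr__(self, "base_frequencies_hz", freqs)


@dataclass(frozen=True)
class AnnulusTrajectory:
    """One annulus: radius(t) on t in [0, lifetime_s], then removed."""

    onset_ms: float
    start_radius_deg: float
    speed_deg_per_s: float
    max_radius_deg: float

    @property
    def lifetime_s(self) -> float:
        """Time for the radius to grow from start to max."""
        return (self.max_radius_deg - self.start_radius_deg) / self.speed_deg_per_s

    def radius(self, t_s):
        """Radius (deg) at time ``t_s`` since annulus onset; NaN once removed."""
        t = np.asarray(t_s, dtype=float)
        r = self.start_radius_deg + self.speed_deg_per_s * t
        out = np.where((t >= 0) & (t <= self.lifetime_s), r, np.nan)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ToneTrajectory:
    """One pure-tone component of the looming sound."""

    base_hz: float
    amplitude: Callable[[float], float]
    frequency: Callable[[float], float]


def visual_annulus_trajectories(spec: LoomingVisualSpec | None = None) -> list[AnnulusTrajectory]:
    """Annulus trajectories of one visual looming stimulus.

    One trajectory per onset in {0, onset_interval, 2*onset_interval, ...}
    strictly below the sequence duration; each expands linearly and is
    removed upon reaching the maximum radius.
    """
    spec = spec or LoomingVisualSpec()
    n = math.ceil(spec.duration_ms / spec.onset_interval_ms)
    return [
        AnnulusTrajectory(
            onset_ms=k * spec.onset_interval_ms,
            start_radius_deg=spec.start_radius_deg,
            speed_deg_per_s=spec.speed_deg_per_s,
            max_radius_deg=spec.max_radius_deg,
        )
        for k in range(n)
    ]


def auditory_looming_trajectories(spec: LoomingSoundSpec | None = None) -> list[ToneTrajectory]:
    """Amplitude and frequency trajectories of each pure-tone component."""
    spec = spec or LoomingSoundSpec()
    dur_s = spec.duration_ms / 1000.0
    k = spec.amp_exponent_per_s
    a0 = spec.base_amplitude

    def _make(f_base: float) -> ToneTrajectory:
        def amplitude(t_s: float) -> float:
            return a0 * math.exp(k * t_s) - 1.0

        def frequency(t_s: float) -> float:
            return f_base * (1.0 + spec.freq_ramp_fraction * (t_s / dur_s))

        return ToneTrajectory(base_hz=f_base, amplitude=amplitude, frequency=frequency)

    return [_make(f) for f in spec.base_frequencies_hz]


# --------------------------------------------------------------------------
# Run / experiment timeline
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentParams:
    """Timing constants of the block design (defaults are the study's)."""

    block_duration_s: float = 33.0
    fixation_s: float = 16.0
    cue_lead_s: float = 3.0
    final_fixation_s: float = 20.0
    soa_ms: float = 660.0
    blocks_per_condition_per_run: int = 3
    n_runs: int = 4
    runs_per_day: int = 2

    def __post_init__(self) -> None:
        if min(self.block_duration_s, self.fixation_s, self.final_fixation_s,
               self.soa_ms) <= 0:
            raise DesignError("durations must be strictly positive")
        if self.cue_lead_s < 0 or self.cue_lead_s > self.fixation_s:
            raise DesignError("cue_lead_s must lie within the fixation period")
        if self.blocks_per_condition_per_run < 1 or self.n_runs < 1:
            raise DesignError("counts must be >= 1")
        if self.n_runs % self.runs_per_day:
            raise DesignError("n_runs must be divisible by runs_per_day")

    @property
    def stimuli_per_block(self) -> int:
        return int(math.floor(self.block_duration_s / (self.soa_ms / 1000.0)))

    @property
    def blocks_per_run(self) -> int:
        return self.blocks_per_condition_per_run * len(CONDITIONS)

    @property
    def run_duration_s(self) -> float:
        return (self.blocks_per_run * (self.fixation_s + self.block_duration_s)
                + self.final_fixation_s)


@dataclass(frozen=True)
class Block:
    """One activation block within a run."""

    condition: str          # e.g. "AV_AttA"
    run: int                # 1-based
    index_in_run: int       # 0-based position within the run
    occurrence: int         # 1..3, occurrence of this condition in this run
    onset_s: float          # within-run onset
    duration_s: float

    @property
    def stim_modality(self) -> str:
        return self.condition.split("_")[0]

    @property
    def attended(self) -> str:
        # "AttA" -> "A"
        return self.condition.split("_")[1][-1]

    @property
    def day(self) -> int:
        return 1 if self.run <= 2 else 2


@dataclass(frozen=True)
class RunDesign:
    """Full multi-run block timeline for one participant."""

    params: ExperimentParams
    blocks: tuple[Block, ...]
    seed: int

    def __post_init__(self) -> None:
        per_run: dict[int, list[Block]] = {}
        for b in self.blocks:
            per_run.setdefault(b.run, []).append(b)
        for run, blocks in per_run.items():
            counts: dict[str, int] = {}
            prev_end = -np.inf
            for b in sorted(blocks, key=lambda b: b.onset_s):
                counts[b.condition] = counts.get(b.condition, 0) + 1
                if b.onset_s <= prev_end:
                    raise DesignError(f"overlapping blocks in run {run}")
                prev_end = b.onset_s + b.duration_s
            expected = self.params.blocks_per_condition_per_run
            if any(c != expected for c in counts.values()) or len(counts) != len(CONDITIONS):
                raise DesignError(
                    f"run {run}: each condition must appear exactly {expected} times")

    @property
    def n_runs(self) -> int:
        return self.params.n_runs

    def run_blocks(self, run: int) -> list[Block]:
        return [b for b in self.blocks if b.run == run]

    def stimulus_onsets(self, block: Block) -> np.ndarray:
        """Within-run onsets (s) of the looming stimuli of ``block``."""
        soa = self.params.soa_ms / 1000.0
        n = self.params.stimuli_per_block
        return block.onset_s + soa * np.arange(n)


def build_run_design(params: ExperimentParams | None = None,
                     rng_seed: int = 0) -> RunDesign:
    """Build the pseudorandomised multi-run block timeline.

    The block order within each run is a seeded random permutation
    constrained to ``blocks_per_condition_per_run`` occurrences of each of
    the six conditions; runs are laid out as [fixation, block] * 18 plus a
    final fixation.  Deterministic given ``rng_seed``.
    """
    params = params or ExperimentParams()
    rng = np.random.default_rng(rng_seed)
    blocks: list[Block] = []
    for run in range(1, params.n_runs + 1):
        order = np.repeat(np.arange(len(CONDITIONS)),
                          params.blocks_per_condition_per_run)
        order = rng.permutation(order)
        seen: dict[str, int] = {}
        for i, cond_idx in enumerate(order):
            cond = CONDITIONS[cond_idx]
            seen[cond] = seen.get(cond, 0) + 1
            onset = params.fixation_s + i * (params.fixation_s + params.block_duration_s)
            blocks.append(Block(condition=cond, run=run, index_in_run=i,
                                occurrence=seen[cond], onset_s=onset,
                                duration_s=params.block_duration_s))
    return RunDesign(params=params, blocks=tuple(blocks), seed=int(rng_seed))


# --------------------------------------------------------------------------
# Target schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Target:
    modality: str           # "A" or "V"
    onset_s: float          # within-run onset
    run: int
    block_index_in_run: int
    condition: str


@dataclass(frozen=True)
class TargetSchedule:
    """Per-block weak-target onsets across the whole experiment."""

    targets: tuple[Target, ...]
    seed: int

    def per_condition_totals(self) -> pd.DataFrame:
        df = self.to_frame()
        if df.empty:
            return df
        return df.groupby(["condition", "modality"]).size().unstack(fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.modality, t.onset_s, t.run, t.block_index_in_run, t.condition)
             for t in self.targets],
            columns=["modality", "onset_s", "run", "block", "condition"],
        )


MIN_TARGET_SEPARATION_S = 1.0


def schedule_targets(design: RunDesign, rng_seed: int = 0) -> TargetSchedule:
    """Schedule the weak auditory and visual targets.

    Per condition, two thirds of its blocks (across all runs) receive one
    target of each modality and one third receive two of each, yielding 16
    targets per modality per condition under the default design.  Onsets are
    drawn uniformly from the final half of the block (targets were biased
    toward the end of the block to hold attention), with at least 1 s
    between any two targets of a block.  Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    by_condition: dict[str, list[Block]] = {}
    for b in design.blocks:
        by_condition.setdefault(b.condition, []).append(b)

    targets: list[Target] = []
    for cond in sorted(by_condition):
        blocks = sorted(by_condition[cond], key=lambda b: (b.run, b.index_in_run))
        n = len(blocks)
        if n % 3:
            raise DesignError(
                f"condition {cond}: block count {n} not divisible by 3, "
                "cannot apply the two-thirds single-target rule")
        n_double = n // 3
        double_idx = set(rng.choice(n, size=n_double, replace=False).tolist())
        for i, block in enumerate(blocks):
            count = 2 if i in double_idx else 1
            onsets = _draw_block_target_onsets(block, 2 * count, rng)
            assign = rng.permutation([m for m in ("A", "V") for _ in range(count)])
            for onset, modality in zip(onsets, assign):
                targets.append(Target(modality=str(modality), onset_s=float(onset),
                                      run=block.run,
                                      block_index_in_run=block.index_in_run,
                                      condition=cond))
    targets.sort(key=lambda t: (t.run, t.onset_s))
    return TargetSchedule(targets=tuple(targets), seed=int(rng_seed))


def _draw_block_target_onsets(block: Block, n: int, rng: np.random.Generator,
                              max_tries: int = 1000) -> np.ndarray:
    """Uniform onsets in the final half of the block, >= 1 s apart."""
    lo = block.onset_s + block.duration_s / 2.0
    hi = block.onset_s + block.duration_s
    if hi - lo < (n - 1) * MIN_TARGET_SEPARATION_S:
        raise DesignError(
            f"block at {block.onset_s:.1f}s too short for {n} targets "
            f"with {MIN_TARGET_SEPARATION_S} s separation")
    for _ in range(max_tries):
        onsets = np.sort(rng.uniform(lo, hi, size=n))
        if n < 2 or np.min(np.diff(onsets)) >= MIN_TARGET_SEPARATION_S:
            return onsets
    raise DesignError("target onset rejection sampling failed")  # pragma: no cover


# --------------------------------------------------------------------------
# Behavioural scoring
# --------------------------------------------------------------------------

RESPONSE_WINDOW_S = 2.5


@dataclass(frozen=True)
class ResponseLog:
    """Button presses: (run, time within run in s), sorted within run."""

    presses: tuple[tuple[int, float], ...]

    def run_presses(self, run: int) -> np.ndarray:
        return np.array(sorted(t for r, t in self.presses if r == run))


@dataclass(frozen=True)
class BehavioralScore:
    """% targets responded per (target x attended x block modality) cell."""

    table: pd.DataFrame     # columns: target_modality, attended, block_modality,
                            #          n_targets, n_responded, pct_responded
    n_hits: int             # presses that fell inside some target window
    n_extra: int            # presses outside every window

    @property
    def n_presses(self) -> int:
        return self.n_hits + self.n_extra


def score_responses(schedule: TargetSchedule, log: ResponseLog,
                    design: RunDesign) -> BehavioralScore:
    """Score button presses against target response windows.

    A press counts as a response to target k iff it falls inside
    ``[onset_k, min(onset_k + 2.5 s, onset_{k+1}))`` where ``onset_{k+1}``
    is the next target of either modality in the same run; presses outside
    every window (including before the first target) are extra-responses.
    Every press lands in exactly one category.
    """
    block_by = {(b.run, b.index_in_run): b for b in design.blocks}
    n_hits = 0
    n_extra = 0
    responded: dict[int, bool] = {}
    targets = sorted(enumerate(schedule.targets),
                     key=lambda kv: (kv[1].run, kv[1].onset_s))
    by_run: dict[int, list[tuple[int, Target]]] = {}
    for k, t in targets:
        by_run.setdefault(t.run, []).append((k, t))

    runs = sorted({r for r, _ in log.presses} | set(by_run))
    for run in runs:
        run_targets = by_run.get(run, [])
        onsets = np.array([t.onset_s for _, t in run_targets])
        ends = np.minimum(
            onsets + RESPONSE_WINDOW_S,
            np.append(onsets[1:], np.inf)) if len(onsets) else np.array([])
        for press in log.run_presses(run):
            idx = np.searchsorted(onsets, press, side="right") - 1
            if idx >= 0 and press < ends[idx]:
                n_hits += 1
                responded[run_targets[idx][0]] = True
            else:
                n_extra += 1

    rows = []
    for k, t in targets:
        block = block_by[(t.run, t.block_index_in_run)]
        rows.append({
            "target_modality": t.modality,
            "attended": block.attended,
            "block_modality": block.stim_modality,
            "responded": bool(responded.get(k, False)),
        })
    if rows:
        df = pd.DataFrame(rows)
        out = (df.groupby(["target_modality", "attended", "block_modality"])
               .agg(n_targets=("responded", "size"),
                    n_responded=("responded", "sum"))
               .reset_index())
        out["pct_responded"] = 100.0 * out["n_responded"] / out["n_targets"]
    else:
        out = pd.DataFrame(columns=["target_modality", "attended", "block_modality",
                                    "n_targets", "n_responded", "pct_responded"])
    return BehavioralScore(table=out, n_hits=n_hits, n_extra=n_extra)


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def events_table(design: RunDesign, run: int,
                 schedule: TargetSchedule | None = None) -> pd.DataFrame:
    """Events of one run as a BIDS-style (onset, duration, trial_type) table."""
    rows = []
    for b in design.run_blocks(run):
        rows.append({"onset": b.onset_s - design.params.cue_lead_s,
                     "duration": design.params.cue_lead_s,
                     "trial_type": f"cue_{b.attended}"})
        rows.append({"onset": b.onset_s, "duration": b.duration_s,
                     "trial_type": b.condition})
    if schedule is not None:
        for t in schedule.targets:
            if t.run == run:
                rows.append({"onset": t.onset_s, "duration": 0.0,
                             "trial_type": f"Target{t.modality}"})
    return (pd.DataFrame(rows)
            .sort_values("onset", kind="stable")
            .reset_index(drop=True))
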