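"""Analysis pipeline for trial logs, plus a synthetic-participant generator.

The behavioural analysis compares per-condition exploration counts (and final
efficiencies) with Welch's unequal-variance t-test, Bonferroni-adjusted alpha
and Cohen's d, exactly as one would for first-generation participants of the
asocial / unrepaid / repaid conditions of the virtual-arrowhead task.

Because no per-trial human logs are distributed, ``synth_participants``
fabricates cohorts that flow through the identical pipeline:

* parametric mode draws each participant's exploration count tau from a
  per-condition Normal(mean, sd) (rounded, clipped to [0, T-1]) and then
  synthesises a consistent trajectory by running the win-stay/lose-shift
  agent with that many explorations;
* agentic mode makes agents quasi-rational: tau is drawn from a softmax
  (quantal response) over the per-trial pay-off curve of the agent's
  condition, so behaviour is driven by the landscape itself plus a
  behavioural temperature.

The single interchange format is a trial-log CSV (one row per participant
trial) shared with the simulator, so synthetic and real data take the same
code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .agent import EXPLOIT, EXPLORE, DEFAULT_STEP
from .landscape import (
    ArrowheadDesign,
    FitnessLandscape,
    default_config,
    expected_score,
)
from .simulate import (
    LearningCurve,
    Trajectory,
    TrialRecord,
    estimate_learning_curve,
    optimal_tau,
    run_actions,
)

__all__ = [
    "CONDITIONS",
    "ParticipantRecord",
    "GroupComparison",
    "GroupSpec",
    "SynthConfig",
    "DEFAULT_GROUPS",
    "exploration_count",
    "final_efficiency",
    "compare_groups",
    "payment",
    "actions_for_count",
    "synth_participants",
    "records_to_frame",
    "frame_to_records",
    "write_logs",
    "read_logs",
    "analyze",
    "overshoot_fractions",
]

CONDITIONS = ("asocial", "unrepaid", "repaid")

CSV_COLUMNS = [
    "participant_id",
    "condition",
    "generation",
    "trial",
    "action",
    "length",
    "width",
    "thickness",
    "expected_score",
    "observed_score",
    "cumulative_score",
]


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's condition, generation and full 50-trial trajectory."""

    participant_id: str
    condition: str
    generation: int
    trajectory: Trajectory

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.generation not in (1, 2):
            raise ValueError(f"generation must be 1 or 2, got {self.generation}")
        if self.condition == "asocial" and self.generation != 1:
            raise ValueError("the asocial condition has no second generation")

    @property
    def W(self) -> int:
        return self.trajectory.W


def exploration_count(record: ParticipantRecord) -> int:
    """Number of exploration trials (tau) in the participant's log."""
    return record.trajectory.n_explorations


def final_efficiency(record: ParticipantRecord) -> float:
    """Noise-free expected score of the design held at the last trial."""
    return record.trajectory.final_efficiency


@dataclass(frozen=True)
class GroupComparison:
    """Welch two-sample comparison with Bonferroni-adjusted alpha."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    d: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def compare_groups(
    a: Sequence[float], b: Sequence[float], n_comparisons: int = 1
) -> GroupComparison:
    """Welch's unequal-variance t-test of group a vs b, two-sided.

    Degrees of freedom follow Welch-Satterthwaite; Cohen's d uses the
    classical pooled-SD form; ``alpha = 0.05 / n_comparisons`` (Bonferroni).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise ValueError("both groups have zero variance; the t statistic is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    n_a, n_b = len(a), len(b)
    s_pooled = math.sqrt(((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2))
    d = (a.mean() - b.mean()) / s_pooled
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.sqrt(va)),
        sd_b=float(np.sqrt(vb)),
        n_a=n_a,
        n_b=n_b,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        d=float(d),
        alpha=0.05 / int(n_comparisons),
    )


def payment(W: int) -> int:
    """Participant payment in JPY: 2W/50 rounded up to the nearest 10, plus 700.

    ``W`` is the cumulative calorie score; 700 JPY is the show-up fee.
    """
    W = int(W)
    if W < 0:
        raise ValueError(f"cumulative score must be non-negative, got {W}")
    # 2W/50 = W/25; round up to a multiple of 10 in exact integer arithmetic
    return 10 * ((W + 249) // 250) + 700


def actions_for_count(tau: int, T: int = 50) -> list[str]:
    """An action sequence with exactly ``tau`` explorations and trial 1 exploiting.

    For tau within the alternating family (2*tau <= T-1) this is exactly the
    alternating schedule.  Larger counts -- which human participants do
    produce -- keep the alternating backbone on even trials and fill odd
    trials from trial 3 upward, up to the maximum tau = T-1.
    """
    if not 0 <= tau <= T - 1:
        raise ValueError(f"tau = {tau} outside [0, T-1] with T = {T}")
    actions = [EXPLOIT] * T
    even = list(range(2, T + 1, 2))
    odd = list(range(3, T + 1, 2))
    for trial in (even + odd)[:tau]:
        actions[trial - 1] = EXPLORE
    return actions


@dataclass(frozen=True)
class GroupSpec:
    """Cohort size and exploration-count distribution for one condition."""

    n: int
    tau_mean: float
    tau_sd: float


#: Default parametric cohorts: the per-condition exploration-count summary
#: statistics of the first-generation behavioural data the generator emulates.
DEFAULT_GROUPS: dict[str, GroupSpec] = {
    "asocial": GroupSpec(n=20, tau_mean=20.10, tau_sd=3.51),
    "unrepaid": GroupSpec(n=20, tau_mean=19.45, tau_sd=6.42),
    "repaid": GroupSpec(n=20, tau_mean=24.60, tau_sd=5.56),
}


@dataclass(frozen=True)
class SynthConfig:
    """Settings for the synthetic-participant generator.

    parametric mode uses ``groups``' Normal(tau_mean, tau_sd) per condition;
    agentic mode ignores the means/sds and draws tau from a softmax over the
    per-trial pay-off curve with inverse temperature ``beta`` (per calorie),
    estimated from ``n_curve_agents`` agents.
    """

    mode: str = "parametric"
    groups: dict[str, GroupSpec] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    T: int = 50
    L: int = DEFAULT_STEP
    landscape: Optional[FitnessLandscape] = None
    initial_design: Optional[ArrowheadDesign] = None
    beta: float = 0.25
    n_curve_agents: int = 2000

    def __post_init__(self) -> None:
        if self.mode not in ("parametric", "agentic"):
            raise ValueError(f"mode must be 'parametric' or 'agentic', got {self.mode!r}")
        for cond, spec in self.groups.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in groups")
            if spec.n < 1:
                raise ValueError(f"group {cond} must have n >= 1")
            if spec.tau_sd < 0:
                raise ValueError(f"group {cond} has negative tau_sd")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def resolved_landscape(self) -> tuple[FitnessLandscape, ArrowheadDesign]:
        if self.landscape is not None and self.initial_design is not None:
            return self.landscape, self.initial_design
        landscape, init = default_config()
        return (self.landscape or landscape, self.initial_design or init)


def _draw_taus(
    config: SynthConfig, condition: str, rng: np.random.Generator
) -> np.ndarray:
    spec = config.groups[condition]
    hi = config.T - 1
    if config.mode == "parametric":
        raw = rng.normal(spec.tau_mean, spec.tau_sd, size=spec.n)
        return np.clip(np.rint(raw), 0, hi).astype(int)
    landscape, init = config.resolved_landscape()
    curve = estimate_learning_curve(
        config.n_curve_agents, landscape, init, rng, T=config.T, L=config.L
    )
    sol = optimal_tau(curve, config.T, "repaid" if condition == "repaid" else "unrepaid")
    logits = config.beta * (sol.per_trial_payoff - sol.per_trial_payoff.max())
    probs = np.exp(logits)
    probs /= probs.sum()
    return rng.choice(len(probs), size=spec.n, p=probs).astype(int)


def synth_participants(
    config: SynthConfig, rng: Union[np.random.Generator, int, None]
) -> list[ParticipantRecord]:
    """Generate a reproducible synthetic cohort of first-generation participants.

    Every record's trajectory is produced by actually running the win-stay/
    lose-shift agent for the drawn number of explorations, so
    ``exploration_count`` round-trips and all downstream statistics are
    internally consistent.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    landscape, init = config.resolved_landscape()
    records: list[ParticipantRecord] = []
    for condition in CONDITIONS:
        if condition not in config.groups:
            continue
        taus = _draw_taus(config, condition, rng)
        for k, tau in enumerate(taus):
            traj = run_actions(
                actions_for_count(int(tau), config.T), landscape, init, rng, L=config.L
            )
            records.append(
                ParticipantRecord(
                    participant_id=f"{condition}-{k + 1:03d}",
                    condition=condition,
                    generation=1,
                    trajectory=traj,
                )
            )
    return records


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Flatten participant records to the trial-log interchange table."""
    rows = []
    for rec in records:
        cumulative = 0
        for tr in rec.trajectory.records:
            if tr.observed_score is not None:
                cumulative += tr.observed_score
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "condition": rec.condition,
                    "generation": rec.generation,
                    "trial": tr.trial,
                    "action": tr.action,
                    "length": tr.design.length,
                    "width": tr.design.width,
                    "thickness": tr.design.thickness,
                    "expected_score": tr.expected_score,
                    "observed_score": tr.observed_score,
                    "cumulative_score": cumulative,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ParticipantRecord]:
    """Rebuild participant records from a trial-log table."""
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    records = []
    for (pid, cond, gen), chunk in frame.groupby(
        ["participant_id", "condition", "generation"], sort=False
    ):
        chunk = chunk.sort_values("trial")
        trial_records = []
        for row in chunk.itertuples(index=False):
            observed = None if pd.isna(row.observed_score) else int(row.observed_score)
            trial_records.append(
                TrialRecord(
                    trial=int(row.trial),
                    action=str(row.action),
                    design=ArrowheadDesign(int(row.length), int(row.width), int(row.thickness)),
                    expected_score=float(row.expected_score),
                    observed_score=observed,
                )
            )
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                condition=str(cond),
                generation=int(gen),
                trajectory=Trajectory(records=tuple(trial_records)),
            )
        )
    return records


def write_logs(records: Sequence[ParticipantRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_logs(path: Union[str, Path]) -> list[ParticipantRecord]:
    return frame_to_records(pd.read_csv(path))


def analyze(
    records: Sequence[ParticipantRecord],
    comparisons: Sequence[tuple[str, str]] = (("repaid", "asocial"), ("unrepaid", "asocial")),
    generation: int = 1,
    n_comparisons: Optional[int] = None,
) -> dict:
    """Full trial-log analysis: per-condition summaries and Welch comparisons.

    Exploration counts and final efficiencies are compared for the requested
    ``generation``; alpha is Bonferroni-adjusted by the number of
    exploration-count comparisons unless ``n_comparisons`` is given.
    """
    n_comparisons = n_comparisons or len(comparisons)
    selected = [r for r in records if r.generation == generation]
    taus = {c: [exploration_count(r) for r in selected if r.condition == c] for c in CONDITIONS}
    effs = {c: [final_efficiency(r) for r in selected if r.condition == c] for c in CONDITIONS}

    report: dict = {"generation": generation, "groups": {}, "comparisons": {}}
    for cond in CONDITIONS:
        if not taus[cond]:
            continue
        report["groups"][cond] = {
            "n": len(taus[cond]),
            "tau_mean": float(np.mean(taus[cond])),
            "tau_sd": float(np.std(taus[cond], ddof=1)) if len(taus[cond]) > 1 else 0.0,
            "final_efficiency_mean": float(np.mean(effs[cond])),
        }
    for a, b in comparisons:
        key = f"{a}_vs_{b}"
        entry: dict = {}
        entry["exploration"] = vars(compare_groups(taus[a], taus[b], n_comparisons))
        try:
            entry["final_efficiency"] = vars(compare_groups(effs[a], effs[b], n_comparisons))
        except ValueError:
            entry["final_efficiency"] = None
        report["comparisons"][key] = entry
    return report


def overshoot_fractions(
    records: Sequence[ParticipantRecord],
    landscape: FitnessLandscape,
    generation: int = 1,
) -> dict[str, dict[str, float]]:
    """Per-condition fraction of participants whose search crossed an optimum.

    A participant overshoots an attribute when its trajectory visits values on
    both sides of that attribute's optimal coordinate (exploratory summary).
    """
    out: dict[str, dict[str, float]] = {}
    by_cond: dict[str, list[ParticipantRecord]] = {}
    for rec in records:
        if rec.generation == generation:
            by_cond.setdefault(rec.condition, []).append(rec)
    for cond, recs in by_cond.items():
        out[cond] = {}
        for attr, opt in zip(("length", "width", "thickness"), landscape.optimum):
            crossed = 0
            for rec in recs:
                values = [tr.design.value(attr) for tr in rec.trajectory.records]
                if min(values) < opt and max(values) > opt:
                    crossed += 1
            out[cond][attr] = crossed / len(recs)
    return out
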