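"""Generations, transmission chains, ensemble learning curves and optimal tau.

A first-generation agent that alternates exploitation and exploration for its
first ``2*tau`` trials climbs the fitness landscape; let ``g(tau)`` be the
ensemble-mean efficiency (noise-free expected score) of the design held after
``tau`` explorations.  The expected total pay-off of the alternating strategy
is then

    W_u(tau) = sum_{k=0}^{tau-1} g(k) + (T - 2*tau) * g(tau)     (unrepaid/asocial)
    W_r(tau) = sum_{k=0}^{tau-1} g(k) + (2*T - 2*tau) * g(tau)   (repaid)

-- the first term covers the alternating phase (each exploration is preceded
by a hunt at the then-current efficiency), the second the exclusive
exploitation phase, doubled in the repaid condition because the successor's
pay-off is repaid to the predecessor.  The optimal exploration count ``tau*``
is the argmax over 0 <= 2*tau <= T-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .agent import (
    EXPLOIT,
    EXPLORE,
    DEFAULT_STEP,
    AgentState,
    AllocationSchedule,
    explore_step,
    exploit_step,
    schedule_actions,
)
from .landscape import ArrowheadDesign, FitnessLandscape, expected_score

__all__ = [
    "TrialRecord",
    "Trajectory",
    "LearningCurve",
    "TauSolution",
    "run_actions",
    "run_generation",
    "run_chain",
    "estimate_learning_curve",
    "payoff_from_curve",
    "optimal_tau",
    "strategy_count",
]

_CONDITION_HORIZON = {"unrepaid": 1, "asocial": 1, "repaid": 2}


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one agent: design held, its efficiency, and the hunt outcome.

    ``observed_score`` is None on exploration trials (no hunt happens).
    """

    trial: int
    action: str
    design: ArrowheadDesign
    expected_score: float
    observed_score: Optional[int]


@dataclass(frozen=True)
class Trajectory:
    """A complete T-trial run of one agent."""

    records: tuple[TrialRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty trajectory")
        if self.records[0].action != EXPLOIT:
            raise ValueError("the first trial must be exploitation")

    @property
    def T(self) -> int:
        return len(self.records)

    @property
    def W(self) -> int:
        """Cumulative observed score over exploitation trials, in calories."""
        return sum(r.observed_score for r in self.records if r.action == EXPLOIT)

    @property
    def n_explorations(self) -> int:
        return sum(1 for r in self.records if r.action == EXPLORE)

    @property
    def final_design(self) -> ArrowheadDesign:
        return self.records[-1].design

    @property
    def final_efficiency(self) -> float:
        return self.records[-1].expected_score


def run_actions(
    actions: Sequence[str],
    landscape: FitnessLandscape,
    initial_design: ArrowheadDesign,
    rng: np.random.Generator,
    L: int = DEFAULT_STEP,
    state: Optional[AgentState] = None,
) -> Trajectory:
    """Run a win-stay/lose-shift agent along an explicit action sequence.

    ``actions[0]`` must be 'exploit'.  A fresh agent memory with random
    initial directions is created unless ``state`` is given.
    """
    if state is None:
        state = AgentState.with_random_directions(rng)
    design = initial_design
    records = []
    for trial, action in enumerate(actions, start=1):
        if action == EXPLORE:
            design, state = explore_step(state, design, rng, L=L)
            records.append(
                TrialRecord(trial, EXPLORE, design, expected_score(landscape, design), None)
            )
        elif action == EXPLOIT:
            score, state = exploit_step(state, design, landscape, rng)
            records.append(
                TrialRecord(trial, EXPLOIT, design, expected_score(landscape, design), score)
            )
        else:
            raise ValueError(f"unknown action {action!r} at trial {trial}")
    return Trajectory(records=tuple(records))


def run_generation(
    schedule: AllocationSchedule,
    landscape: FitnessLandscape,
    initial_design: ArrowheadDesign,
    rng: np.random.Generator,
    L: int = DEFAULT_STEP,
) -> Trajectory:
    """One agent, one generation, alternating schedule."""
    return run_actions(schedule_actions(schedule), landscape, initial_design, rng, L=L)


def run_chain(
    tau_first: int,
    tau_second: int,
    landscape: FitnessLandscape,
    initial_design: ArrowheadDesign,
    rng: np.random.Generator,
    T: int = 50,
    L: int = DEFAULT_STEP,
) -> tuple[Trajectory, Trajectory]:
    """A two-generation transmission chain.

    The first generation's final design becomes the second generation's
    initial design, exactly; the second generation starts with fresh memory
    (new random directions, no remembered score).
    """
    first = run_generation(AllocationSchedule(tau_first, T), landscape, initial_design, rng, L=L)
    second = run_generation(
        AllocationSchedule(tau_second, T), landscape, first.final_design, rng, L=L
    )
    return first, second


@dataclass(frozen=True)
class LearningCurve:
    """Ensemble-mean efficiency g(tau) after tau explorations, tau = 0..tau_max."""

    g: np.ndarray
    se: np.ndarray
    n_agents: int

    @property
    def tau_max(self) -> int:
        return len(self.g) - 1


def estimate_learning_curve(
    n_agents: int,
    landscape: FitnessLandscape,
    initial_design: ArrowheadDesign,
    rng: Union[np.random.Generator, int, None],
    T: int = 50,
    L: int = DEFAULT_STEP,
) -> LearningCurve:
    """Monte-Carlo estimate of g(tau) from ``n_agents`` independent agents.

    Each agent follows the maximal alternating schedule (tau_max explorations),
    and the noise-free efficiency of its design is recorded after every
    exploration; one pass therefore yields every g(tau) simultaneously.
    g(0) is the efficiency of the common initial design, exactly (SE 0).

    The master seed spawns one substream per agent, so enlarging the ensemble
    extends rather than reshuffles it.
    """
    if n_agents < 1:
        raise ValueError(f"n_agents must be >= 1, got {n_agents}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tau_max = (T - 1) // 2
    eff = np.empty((n_agents, tau_max + 1))
    eff[:, 0] = expected_score(landscape, initial_design)
    for i, child in enumerate(rng.spawn(n_agents)):
        state = AgentState.with_random_directions(child)
        design = initial_design
        _, state = exploit_step(state, design, landscape, child)  # forced trial 1
        for tau in range(1, tau_max + 1):
            design, state = explore_step(state, design, child, L=L)
            eff[i, tau] = expected_score(landscape, design)
            _, state = exploit_step(state, design, landscape, child)
    g = eff.mean(axis=0)
    g[0] = eff[0, 0]  # exact: every agent starts from the same design
    se = eff.std(axis=0, ddof=1) / np.sqrt(n_agents) if n_agents > 1 else np.zeros_like(g)
    se[0] = 0.0
    return LearningCurve(g=g, se=se, n_agents=n_agents)


def _curve_values(g: Union[LearningCurve, Sequence[float], np.ndarray]) -> np.ndarray:
    values = g.g if isinstance(g, LearningCurve) else np.asarray(g, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("learning curve must be a non-empty 1-D sequence")
    return values


def payoff_from_curve(
    g: Union[LearningCurve, Sequence[float], np.ndarray],
    tau_p: int,
    T: int,
    condition: str,
) -> float:
    """Expected total pay-off of the alternating strategy with ``tau_p`` explorations.

    Unrepaid/asocial uses horizon T, repaid uses 2T in the exclusive-
    exploitation term (the successor's repaid earnings).
    """
    values = _curve_values(g)
    try:
        horizon = _CONDITION_HORIZON[str(condition).lower()] * T
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None
    if not 0 <= 2 * tau_p <= T - 1:
        raise ValueError(f"tau_p = {tau_p} violates 0 <= 2*tau_p <= T-1 with T = {T}")
    if tau_p >= len(values):
        raise ValueError(f"tau_p = {tau_p} beyond the estimated curve (tau_max = {len(values) - 1})")
    return float(values[:tau_p].sum() + (horizon - 2 * tau_p) * values[tau_p])


@dataclass(frozen=True)
class TauSolution:
    """Optimal exploration count and the full per-trial pay-off curve W(tau)/T."""

    condition: str
    tau_star: int
    per_trial_payoff: np.ndarray  # indexed by tau = 0..tau_max


def optimal_tau(
    g: Union[LearningCurve, Sequence[float], np.ndarray],
    T: int,
    condition: str,
) -> TauSolution:
    """Argmax of the expected pay-off over tau in {0, ..., floor((T-1)/2)}.

    Ties are broken toward the smaller tau (less exploration at equal pay-off).
    """
    values = _curve_values(g)
    tau_hi = min(len(values) - 1, (T - 1) // 2)
    payoffs = np.array(
        [payoff_from_curve(values, tau, T, condition) for tau in range(tau_hi + 1)]
    )
    tau_star = int(np.argmax(payoffs))  # first maximum = smallest tau
    return TauSolution(
        condition=str(condition).lower(),
        tau_star=tau_star,
        per_trial_payoff=payoffs / T,
    )


def strategy_count(T: int = 50) -> int:
    """Number of unrestricted explore/exploit sequences with trial 1 forced to exploit.

    Each of the remaining T-1 trials is a free binary choice: 2**(T-1).
    For T=50 this is 2**49 = 562,949,953,421,312 -- the size of the space the
    alternating family deliberately avoids searching.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    return 2 ** (T - 1)
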