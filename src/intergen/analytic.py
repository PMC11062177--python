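"""Optimal time allocation between exploration and exploitation in a two-player chain.

The continuous model: each of two sequential players has a time budget ``T``.
A player who has invested a total time ``t`` in exploring a technology exploits
it at efficiency ``f(t)`` (pay-off per unit time), where the learning curve
``f`` is non-negative, strictly increasing and log-concave.  The first player
(predecessor) explores until a switching time ``tp`` and exploits for the
remaining ``T - tp``; the accumulated technology is transmitted faithfully, so
the second player (successor) starts from efficiency ``f(tp)`` and, after
exploring for ``ts``, earns

    W_s = (T - ts) * f(tp + ts).

The predecessor's pay-off depends on the condition:

    unrepaid:  W_p = (T - tp) * f(tp)
    repaid:    W_p = (T - tp) * f(tp) + W_s

In the repaid condition there is no conflict of interest over ``ts``, so the
problem is equivalent to the unrepaid problem with budget ``2T``.  An interior
optimum satisfies the marginal-benefit/marginal-cost balance

    f'(t) / f(t) = 1 / (H - t),        H = T (unrepaid) or 2T (repaid),

and log-concavity makes the crossing unique.  When the ``2T``-horizon optimum
exceeds ``T`` (possible only for convex ``f``), the predecessor explores for
the whole budget (``tp* = T``) and the successor picks up the remainder
(``ts* = t* - T``); otherwise ``ts* = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LearningCurveSpec",
    "AllocationSolution",
    "PayoffRecord",
    "CurveValidationError",
    "curve_from_string",
    "evaluate_payoffs",
    "solve_allocation",
    "grid_oracle",
    "validate_curve",
]

_CONDITIONS = {"unrepaid": "unrepaid", "asocial": "unrepaid", "repaid": "repaid"}

#: f-values below this are treated as zeros and skipped by the log-concavity check.
_LOG_FLOOR = 1e-30


class CurveValidationError(ValueError):
    """A learning curve failed its validity checks (f >= 0, f' > 0, log-concavity).

    ``violations`` lists human-readable descriptions of the offending grid points.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        preview = "; ".join(self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"invalid learning curve: {preview}{more}")


def _normalize_condition(condition: str) -> str:
    try:
        return _CONDITIONS[str(condition).lower()]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected 'unrepaid', 'repaid' or 'asocial'"
        ) from None


@dataclass(frozen=True)
class LearningCurveSpec:
    """A learning curve ``f(t)`` with per-player time horizon ``T``.

    ``f`` maps cumulative exploration time to exploitation efficiency.  If the
    analytic derivative ``f_prime`` is not supplied it is approximated by
    central finite differences with step ``1e-6 * (1 + |t|)``.
    """

    f: Callable[[float], float]
    T: float
    f_prime: Optional[Callable[[float], float]] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"horizon T must be positive, got {self.T}")

    def derivative(self, t: float) -> float:
        if self.f_prime is not None:
            return float(self.f_prime(t))
        h = 1e-6 * (1.0 + abs(t))
        return (float(self.f(t + h)) - float(self.f(t - h))) / (2.0 * h)


@dataclass(frozen=True)
class PayoffRecord:
    """Pay-offs of both players at a given (tp, ts) allocation."""

    W_p: float
    W_s: float


@dataclass(frozen=True)
class AllocationSolution:
    """Optimal switching times and pay-offs for one condition.

    ``ts_star`` is defined as 0 in the unrepaid condition (the successor's own
    optimisation is not part of the predecessor's problem there) and can be
    positive in the repaid condition only when ``tp_star == T``.
    """

    condition: str
    tp_star: float
    ts_star: float
    W_p: float
    W_s: Optional[float] = None


def validate_curve(
    spec: LearningCurveSpec,
    n_grid: int = 1001,
    tol: float = 1e-8,
    strict: bool = True,
) -> list[str]:
    """Check f >= 0, f' > 0 and log-concavity of f on a grid over [0, 2T].

    Returns the list of violation descriptions; raises
    :class:`CurveValidationError` instead when ``strict`` (the default).
    Points with ``f < 1e-30`` are skipped by the log-concavity check (the model
    allows isolated zeros such as f(0) = 0 for power curves).
    """
    ts = np.linspace(0.0, 2.0 * spec.T, n_grid)
    fv = np.array([float(spec.f(t)) for t in ts])
    violations: list[str] = []

    neg = np.nonzero(fv < -tol)[0]
    for i in neg[:20]:
        violations.append(f"f({ts[i]:.6g}) = {fv[i]:.6g} < 0")

    # strict monotonicity via the derivative on interior points
    for t in ts[1:-1:10]:
        d = spec.derivative(float(t))
        if not d > 0.0:
            violations.append(f"f'({t:.6g}) = {d:.6g} <= 0")
            if len(violations) > 40:
                break

    ok = fv > _LOG_FLOOR
    logf = np.where(ok, np.log(np.where(ok, fv, 1.0)), np.nan)
    second = logf[:-2] - 2.0 * logf[1:-1] + logf[2:]
    interior_ok = ok[:-2] & ok[1:-1] & ok[2:]
    bad = np.nonzero(interior_ok & (second > tol))[0]
    for i in bad[:20]:
        violations.append(
            f"log f not concave at t = {ts[i + 1]:.6g} (second difference {second[i]:.3g})"
        )

    if violations and strict:
        raise CurveValidationError(violations)
    return violations


def evaluate_payoffs(
    spec: LearningCurveSpec, tp: float, ts: float, condition: str
) -> PayoffRecord:
    """Pay-offs of both players for switching times ``tp`` (predecessor) and ``ts``.

    ``W_s = (T - ts) f(tp + ts)``; the predecessor earns ``(T - tp) f(tp)``
    plus, in the repaid condition, the successor's pay-off as a bonus.
    """
    condition = _normalize_condition(condition)
    T = spec.T
    if not 0.0 <= tp <= T:
        raise ValueError(f"tp = {tp} outside [0, T] = [0, {T}]")
    if not 0.0 <= ts <= T:
        raise ValueError(f"ts = {ts} outside [0, T] = [0, {T}]")
    W_s = (T - ts) * float(spec.f(tp + ts))
    W_p = (T - tp) * float(spec.f(tp))
    if condition == "repaid":
        W_p += W_s
    return PayoffRecord(W_p=W_p, W_s=W_s)


def _switch_time(spec: LearningCurveSpec, horizon: float, n_scan: int = 4097) -> float:
    """Unique maximiser of (horizon - t) * f(t) on [0, horizon].

    Solves ``(H - t) f'(t) - f(t) = 0``.  This form avoids dividing by
    ``f`` (which may vanish at t = 0, e.g. f = t^b).  Under log-concavity the
    expression changes sign at most once, from + to -, so the root is bracketed
    by scanning a dense grid and refined with a bracketed solver.
    """

    def h(t: float) -> float:
        return (horizon - t) * spec.derivative(t) - float(spec.f(t))

    grid = np.linspace(0.0, horizon, n_scan)
    vals = np.array([h(float(t)) for t in grid])
    pos = np.nonzero(vals > 0.0)[0]
    if pos.size == 0:
        # marginal benefit never exceeds marginal cost: explore nothing
        return 0.0
    i = pos[-1]
    if i == n_scan - 1:  # pragma: no cover - impossible for f > 0 at the horizon
        return horizon
    lo, hi = float(grid[i]), float(grid[i + 1])
    return float(brentq(h, lo, hi, xtol=1e-12 * horizon))


def solve_allocation(
    spec: LearningCurveSpec, condition: str, validate: bool = True
) -> AllocationSolution:
    """Optimal switching times for the predecessor (and successor, if repaid).

    Unrepaid: the unique root of the marginal balance on horizon ``T``.
    Repaid: solve on horizon ``2T``; if the optimum ``t*`` fits within the
    predecessor's budget, ``(tp*, ts*) = (t*, 0)``; otherwise the predecessor
    explores its full budget and the successor continues, ``(T, t* - T)``.
    """
    condition = _normalize_condition(condition)
    if validate:
        validate_curve(spec)
    T = spec.T
    if condition == "unrepaid":
        tp = _switch_time(spec, T)
        ts = 0.0
        pay = evaluate_payoffs(spec, tp, ts, condition)
        return AllocationSolution(condition, tp, ts, W_p=pay.W_p, W_s=None)
    t2 = _switch_time(spec, 2.0 * T)
    if t2 <= T:
        tp, ts = t2, 0.0
    else:
        tp, ts = T, t2 - T
    pay = evaluate_payoffs(spec, tp, ts, condition)
    return AllocationSolution(condition, tp, ts, W_p=pay.W_p, W_s=pay.W_s)


def _vectorized(f: Callable[[float], float]) -> Callable[[np.ndarray], np.ndarray]:
    """Use f on arrays directly when it supports them, else fall back to a loop."""
    probe = np.array([0.25, 0.5])
    try:
        out = np.asarray(f(probe), dtype=float)
        if out.shape == probe.shape:
            return lambda arr: np.asarray(f(arr), dtype=float)
    except Exception:
        pass
    return np.vectorize(f, otypes=[float])


def grid_oracle(
    spec: LearningCurveSpec, condition: str, step: float, validate: bool = False
) -> AllocationSolution:
    """Brute-force maximiser of the pay-off on a (tp, ts) grid.

    Exhaustive and independent of the root-finding path; intended as a test
    oracle.  The repaid search is over the full two-dimensional grid (chunked
    to bound memory), without using the horizon-2T reduction.
    """
    condition = _normalize_condition(condition)
    if not step > 0:
        raise ValueError(f"step must be positive, got {step}")
    if validate:
        validate_curve(spec)
    T = spec.T
    tp_grid = np.arange(0.0, T + 0.5 * step, step)
    tp_grid[-1] = min(tp_grid[-1], T)
    f_tp = np.array([float(spec.f(t)) for t in tp_grid])
    W_own = (T - tp_grid) * f_tp

    if condition == "unrepaid":
        i = int(np.argmax(W_own))
        tp = float(tp_grid[i])
        pay = evaluate_payoffs(spec, tp, 0.0, condition)
        return AllocationSolution(condition, tp, 0.0, W_p=pay.W_p, W_s=None)

    ts_grid = tp_grid
    weight_s = T - ts_grid
    best_w, best_i, best_j = -math.inf, 0, 0
    fvec = _vectorized(spec.f)
    chunk = max(1, int(4e6 // max(len(ts_grid), 1)))
    for start in range(0, len(tp_grid), chunk):
        stop = min(start + chunk, len(tp_grid))
        total = fvec(tp_grid[start:stop, None] + ts_grid[None, :]) * weight_s[None, :]
        total += W_own[start:stop, None]
        flat = int(np.argmax(total))
        i, j = divmod(flat, len(ts_grid))
        if total[i, j] > best_w:
            best_w, best_i, best_j = float(total[i, j]), start + i, j
    tp, ts = float(tp_grid[best_i]), float(ts_grid[best_j])
    pay = evaluate_payoffs(spec, tp, ts, condition)
    return AllocationSolution(condition, tp, ts, W_p=pay.W_p, W_s=pay.W_s)


def curve_from_string(text: str, T: float) -> LearningCurveSpec:
    """Build a :class:`LearningCurveSpec` from a preset name or an expression in ``t``.

    Presets: ``linear:a,b`` -> a + b t; ``power:b`` -> t**b; ``exp:a`` -> exp(a t).
    Anything else is parsed as a sympy expression in the variable ``t`` (e.g.
    ``"1 + 2*t"`` or ``"sqrt(t) + 1"``), with the derivative taken symbolically.
    """
    text = text.strip()
    if ":" in text and text.split(":", 1)[0] in {"linear", "power", "exp"}:
        kind, args = text.split(":", 1)
        vals = [float(x) for x in args.split(",")]
        if kind == "linear":
            a, b = vals
            return LearningCurveSpec(
                f=lambda t: a + b * t, f_prime=lambda t: b, T=T, name=text
            )
        if kind == "power":
            (b,) = vals
            return LearningCurveSpec(
                f=lambda t: t**b,
                f_prime=lambda t: b * t ** (b - 1.0) if t > 0 else (b if b == 1.0 else 0.0),
                T=T,
                name=text,
            )
        (a,) = vals
        return LearningCurveSpec(
            f=lambda t: math.exp(a * t), f_prime=lambda t: a * math.exp(a * t), T=T, name=text
        )

    import sympy

    t = sympy.Symbol("t", nonnegative=True)
    expr = sympy.sympify(text, locals={"t": t})
    dexpr = sympy.diff(expr, t)
    f = sympy.lambdify(t, expr, "math")
    fp = sympy.lambdify(t, dexpr, "math")
    return LearningCurveSpec(f=f, f_prime=fp, T=T, name=text)
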