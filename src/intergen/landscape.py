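"""Virtual-arrowhead fitness landscape: expected scores and noisy hunting returns.

An arrowhead design is an integer triple (length, width, thickness), each
attribute in [1, 100].  The environment assigns each design an expected score
(the design's *efficiency*, in calories) from a unimodal quadratic surface

    efficiency(x) = max(0, peak - sum_i w_i * (x_i - optimum_i)**2)

capped so that scores lie in [0, 1000].  A hunt displays the efficiency plus
Gaussian noise (sd 5 calories by default), rounded to an integer and clamped
to [0, 1000]; agents and participants only ever observe these noisy scores.

The exact surface coefficients used in the original behavioural task are not
public, so the packaged default (``config/default_landscape.yaml``) is
calibrated by ``scripts/calibrate_landscape.py`` to reproduce the reference
optima of the simulation study (optimal exploration counts 12 unrepaid /
22 repaid under T=50 trials, step size L=5, noise sd 5).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np
import yaml

__all__ = [
    "ATTRIBUTES",
    "ArrowheadDesign",
    "FitnessLandscape",
    "expected_score",
    "hunt",
    "load_config",
    "default_config",
]

ATTRIBUTES = ("length", "width", "thickness")

ATTR_MIN, ATTR_MAX = 1, 100
SCORE_MIN, SCORE_MAX = 0, 1000


@dataclass(frozen=True)
class ArrowheadDesign:
    """An integer arrowhead design; every attribute lies in [1, 100]."""

    length: int
    width: int
    thickness: int

    def __post_init__(self) -> None:
        for name in ATTRIBUTES:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"{name} must be an integer, got {v!r}")
            if not ATTR_MIN <= v <= ATTR_MAX:
                raise ValueError(f"{name} = {v} outside [{ATTR_MIN}, {ATTR_MAX}]")
            object.__setattr__(self, name, int(v))

    def astuple(self) -> tuple[int, int, int]:
        return (self.length, self.width, self.thickness)

    def value(self, attribute: str) -> int:
        return getattr(self, attribute)

    def with_value(self, attribute: str, value: int) -> "ArrowheadDesign":
        if attribute not in ATTRIBUTES:
            raise ValueError(f"unknown attribute {attribute!r}")
        return replace(self, **{attribute: int(value)})

    def __iter__(self) -> Iterator[int]:
        return iter(self.astuple())


@dataclass(frozen=True)
class FitnessLandscape:
    """Unimodal quadratic expected-score surface over arrowhead designs.

    ``optimum`` need not be integer-valued; ``weights`` are the per-attribute
    quadratic penalty coefficients (calories per unit^2); ``peak`` is the
    expected score at the optimum and ``noise_sd`` the hunting noise sd, both
    in calories.
    """

    optimum: tuple[float, float, float]
    weights: tuple[float, float, float]
    peak: float = 1000.0
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "optimum", tuple(float(v) for v in self.optimum))
        object.__setattr__(self, "weights", tuple(float(v) for v in self.weights))
        if len(self.optimum) != 3 or len(self.weights) != 3:
            raise ValueError("optimum and weights must have one entry per attribute")
        if any(w <= 0 for w in self.weights):
            raise ValueError(f"weights must be positive, got {self.weights}")
        if not 0.0 < self.peak <= SCORE_MAX:
            raise ValueError(f"peak must lie in (0, {SCORE_MAX}], got {self.peak}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")


def expected_score(landscape: FitnessLandscape, design: ArrowheadDesign) -> float:
    """Noise-free expected score ("efficiency") of a design, in calories.

    Deterministic; the quadratic penalty is floored at 0 so the result always
    lies in [0, 1000].
    """
    penalty = sum(
        w * (x - o) ** 2
        for w, x, o in zip(landscape.weights, design, landscape.optimum)
    )
    return max(0.0, landscape.peak - penalty)


def hunt(
    landscape: FitnessLandscape, design: ArrowheadDesign, rng: np.random.Generator
) -> int:
    """One noisy hunting return: round(efficiency + N(0, noise_sd^2)), clamped.

    This integer is the score displayed to the hunter; it is the only signal
    an agent gets about the landscape.
    """
    eps = rng.normal(0.0, landscape.noise_sd)
    score = round(expected_score(landscape, design) + eps)
    return int(min(SCORE_MAX, max(SCORE_MIN, score)))


def _triple(block: dict, what: str) -> tuple:
    try:
        return tuple(block[a] for a in ATTRIBUTES)
    except KeyError as e:
        raise ValueError(f"{what} block must define {ATTRIBUTES}; missing {e}") from None


def load_config(path: Union[str, Path]) -> tuple[FitnessLandscape, ArrowheadDesign]:
    """Read a landscape config (YAML) -> (landscape, common initial design).

    Expected keys: ``optimum.{length,width,thickness}``, ``weights.*``,
    ``peak``, ``noise_sd``, ``initial_design.*``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


def parse_config(raw: dict) -> tuple[FitnessLandscape, ArrowheadDesign]:
    landscape = FitnessLandscape(
        optimum=_triple(raw["optimum"], "optimum"),
        weights=_triple(raw["weights"], "weights"),
        peak=float(raw.get("peak", 1000.0)),
        noise_sd=float(raw.get("noise_sd", 5.0)),
    )
    init = ArrowheadDesign(*(int(v) for v in _triple(raw["initial_design"], "initial_design")))
    return landscape, init


def default_config() -> tuple[FitnessLandscape, ArrowheadDesign]:
    """The packaged calibrated landscape and the common fixed initial design."""
    ref = resources.files("intergen") / "config" / "default_landscape.yaml"
    raw = yaml.safe_load(ref.read_text())
    return parse_config(raw)
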