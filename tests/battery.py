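"""A battery of valid learning curves (increasing, non-negative, log-concave).

All callables accept numpy arrays so the brute-force grid oracle can evaluate
them vectorised.  Convexity flags mark the curves for which a positive
successor exploration time is admissible in the repaid condition.
"""

import numpy as np

from intergen.analytic import LearningCurveSpec


def curve_battery(T: float = 1.0) -> list[tuple[LearningCurveSpec, bool]]:
    """Return [(spec, is_convex)] with > 20 members covering all shape classes."""
    specs: list[tuple[LearningCurveSpec, bool]] = []

    for a, b in [(1, 2), (1, 0.5), (0.2, 1), (2, 1), (0.5, 3), (1, 1), (3, 0.7), (0.1, 2)]:
        specs.append(
            (
                LearningCurveSpec(
                    f=lambda t, a=a, b=b: a + b * t,
                    f_prime=lambda t, b=b: b + 0.0 * t,
                    T=T,
                    name=f"linear:{a},{b}",
                ),
                False,
            )
        )

    for a, b in [(0.5, 1.0), (1.0, 2.0), (0.3, 0.8)]:  # concave: a + b*sqrt(t+c)
        c = 0.02
        specs.append(
            (
                LearningCurveSpec(
                    f=lambda t, a=a, b=b, c=c: a + b * np.sqrt(t + c),
                    f_prime=lambda t, b=b, c=c: 0.5 * b / np.sqrt(t + c),
                    T=T,
                    name=f"sqrt:{a},{b}",
                ),
                False,
            )
        )

    for a, b in [(0.5, 1.0), (1.0, 0.7), (0.2, 2.0)]:  # concave: a + b*log(1+t)
        specs.append(
            (
                LearningCurveSpec(
                    f=lambda t, a=a, b=b: a + b * np.log1p(t),
                    f_prime=lambda t, b=b: b / (1.0 + t),
                    T=T,
                    name=f"log:{a},{b}",
                ),
                False,
            )
        )

    for a, b, c in [(0.3, 2.0, 1.5), (0.5, 1.0, 3.0)]:  # saturating exponential
        specs.append(
            (
                LearningCurveSpec(
                    f=lambda t, a=a, b=b, c=c: a + b * (1.0 - np.exp(-c * t)),
                    f_prime=lambda t, b=b, c=c: b * c * np.exp(-c * t),
                    T=T,
                    name=f"sat:{a},{b},{c}",
                ),
                False,
            )
        )

    for c, b in [(0.0, 2.0), (0.0, 3.0), (0.1, 2.0), (0.3, 1.5)]:  # convex power (t+c)^b
        specs.append(
            (
                LearningCurveSpec(
                    f=lambda t, c=c, b=b: (t + c) ** b,
                    f_prime=lambda t, c=c, b=b: b * (t + c) ** (b - 1.0),
                    T=T,
                    name=f"power:{c},{b}",
                ),
                True,
            )
        )

    for a in [0.5, 3.0]:  # convex exponential exp(a*t)
        specs.append(
            (
                LearningCurveSpec(
                    f=lambda t, a=a: np.exp(a * t),
                    f_prime=lambda t, a=a: a * np.exp(a * t),
                    T=T,
                    name=f"exp:{a}",
                ),
                True,
            )
        )

    assert len(specs) >= 20
    return specs
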