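"""CI-based pairwise sensitivity significance testing.

The standard error of a sensitivity estimate is recovered from its 95% CI
width as ``(upper - lower) / (2 * 1.96)``; the difference of two estimates
is compared with ``Z = delta / sqrt(SE1**2 + SE2**2)`` against a two-tailed
standard-normal p-value at alpha = 0.05. CIs are Wilson score intervals
(the construction method is a documented choice; it is well-behaved near
0 and 1). The test treats the two estimates as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SensitivityEstimate",
    "ComparisonResult",
    "se_from_ci",
    "binomial_ci",
    "estimate_sensitivity",
    "compare_sensitivities",
    "pairwise_panel",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class SensitivityEstimate:
    sensitivity: float
    ci_lower: float
    ci_upper: float
    n_positive: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower <= self.sensitivity <= self.ci_upper <= 1.0):
            raise ValueError(
                "need 0 <= ci_lower <= sensitivity <= ci_upper <= 1, got "
                f"({self.ci_lower}, {self.sensitivity}, {self.ci_upper})"
            )

    @property
    def se(self) -> float:
        return se_from_ci(self.ci_lower, self.ci_upper)


@dataclass(frozen=True)
class ComparisonResult:
    delta_sensitivity: float
    delta_se: float
    z: float
    p: float
    significant: bool


def se_from_ci(ci_lower: float, ci_upper: float) -> float:
    """``(upper - lower) / (2 * 1.96)``."""
    if ci_upper < ci_lower:
        raise ValueError("inverted confidence interval")
    return (ci_upper - ci_lower) / (2.0 * 1.96)


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = norm.ppf(0.5 + level / 2.0)
    phat = successes / n
    denom = 1.0 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    return (max(center - half, 0.0), min(center + half, 1.0))


def estimate_sensitivity(
    tp: int, fn: int, level: float = 0.95
) -> SensitivityEstimate:
    """Sensitivity with its Wilson CI from positive-class counts."""
    n_pos = tp + fn
    if n_pos == 0:
        raise ValueError("no positive samples")
    lo, hi = binomial_ci(tp, n_pos, level)
    sens = tp / n_pos
    # Wilson interval always contains the point estimate
    return SensitivityEstimate(sens, lo, hi, n_positive=n_pos)


def compare_sensitivities(
    est_a: SensitivityEstimate, est_b: SensitivityEstimate
) -> ComparisonResult:
    """Z-test of ``est_b.sensitivity - est_a.sensitivity``."""
    delta = est_b.sensitivity - est_a.sensitivity
    delta_se = float(np.sqrt(est_a.se**2 + est_b.se**2))
    if delta_se == 0.0:
        raise ZeroDivisionError("both standard errors are zero: Z undefined")
    z = delta / delta_se
    p = float(2.0 * (1.0 - norm.cdf(abs(z))))
    return ComparisonResult(
        delta_sensitivity=delta,
        delta_se=delta_se,
        z=float(z),
        p=p,
        significant=p < ALPHA,
    )


def pairwise_panel(estimates: dict[str, SensitivityEstimate]) -> pd.DataFrame:
    """All unordered pairwise comparisons as a table."""
    names = list(estimates)
    if len(names) < 2:
        raise ValueError("need at least 2 estimates")
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names")
    rows = []
    for a, b in combinations(names, 2):
        r = compare_sensitivities(estimates[a], estimates[b])
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "model_a": a,
                "model_b": b,
                "delta_sensitivity": r.delta_sensitivity,
                "delta_se": r.delta_se,
                "z": r.z,
                "p": r.p,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
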