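"""Estimators for marginal and joint acceptance probabilities.

The joint probability of an ant accepting the good nest in both linked
experiments is not observable directly (each colony runs once per
context), so it is constructed from the threshold structure: ants whose
thresholds are so high that they rejected the poor nest in both runs
have no alternative to the good site and contribute deterministically;
the remaining ants are treated as independent across the two runs:

    p_joint = h + (p_a - h) * (p_b - h),
    h = min(rejectors of poor in A, rejectors of poor in B) / n.

Errors: the marginal acceptance probability gets the textbook standard
error of a proportion; the constructed joint gets a bootstrap SE from
multinomial resampling of each experiment's per-ant outcome categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .emigration import SimulationResult

__all__ = [
    "JointEstimate",
    "proportion_se",
    "high_threshold_count",
    "joint_accept_good",
    "joint_from_probs",
    "bootstrap_joint_se",
]


@dataclass(frozen=True)
class JointEstimate:
    p_joint: float
    se: float | None
    n_high: int
    method: str = "high-threshold+independent"


def proportion_se(p: float, n: int) -> float:
    """Standard error of a proportion, sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    return float(np.sqrt(p * (1.0 - p) / n))


def high_threshold_count(
    result_a: SimulationResult, result_b: SimulationResult
) -> int:
    """Minimum number of ants that rejected the poor nest in both runs."""
    if result_a.n_ants != result_b.n_ants:
        raise ValueError(
            f"colony sizes differ ({result_a.n_ants} vs {result_b.n_ants})"
        )
    return min(result_a.n_reject_poor, result_b.n_reject_poor)


def joint_from_probs(h: float, p_a: float, p_b: float) -> float:
    """High-threshold + independence construction, clipped to Fréchet bounds.

    Values outside the bounds (possible because the construction is
    heuristic) are clipped with a warning rather than rejected, since the
    downstream contextuality arithmetic requires a valid joint.
    """
    if p_a - h < -1e-12 or p_b - h < -1e-12:
        raise ValueError(
            f"high-threshold fraction h={h} exceeds a marginal ({p_a}, {p_b})"
        )
    raw = h + (p_a - h) * (p_b - h)
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    if raw < lo - 1e-12 or raw > hi + 1e-12:
        warnings.warn(
            f"constructed joint {raw:.6f} outside Fréchet bounds "
            f"[{lo:.6f}, {hi:.6f}]; clipping",
            stacklevel=2,
        )
    return float(min(max(raw, lo), hi))


def joint_accept_good(
    result_a: SimulationResult, result_b: SimulationResult
) -> JointEstimate:
    """Constructed joint probability of accepting the good nest in both runs."""
    n_high = high_threshold_count(result_a, result_b)
    h = n_high / result_a.n_ants
    p = joint_from_probs(h, result_a.p_accept_good, result_b.p_accept_good)
    return JointEstimate(p_joint=p, se=None, n_high=n_high)


def bootstrap_joint_se(
    result_a: SimulationResult,
    result_b: SimulationResult,
    reps: int,
    rng: np.random.Generator,
) -> float:
    """Bootstrap SE of the constructed joint.

    Each experiment's per-ant outcomes reduce to five categories
    (committed good x rejected poor, committed poor, uncommitted x
    rejected poor), so resampling ants with replacement is a multinomial
    draw on the category counts, independently per experiment.
    """
    if reps < 1:
        raise ValueError("need at least one bootstrap resample")
    n = result_a.n_ants
    if n != result_b.n_ants:
        raise ValueError("colony sizes differ")

    def _resample(result: SimulationResult) -> tuple[np.ndarray, np.ndarray]:
        counts = rng.multinomial(n, result.category_counts() / n, size=reps)
        p_good = (counts[:, 0] + counts[:, 1]) / n
        rejectors = counts[:, 0] + counts[:, 3]
        return p_good, rejectors

    pa, ra = _resample(result_a)
    pb, rb = _resample(result_b)
    h = np.minimum(ra, rb) / n
    raw = h + (pa - h) * (pb - h)
    lo = np.maximum(0.0, pa + pb - 1.0)
    hi = np.minimum(pa, pb)
    joint = np.clip(raw, lo, hi)
    return float(joint.std(ddof=1)) if reps > 1 else 0.0
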