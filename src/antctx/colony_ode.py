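"""Infinite-population deterministic model of colony nest choice.

In the infinite-population limit the colony is described by fractions
rather than individuals.  A fraction ``z`` starts out scouting; scouts
commit to the superior site at rate ``alpha_s * H`` and to the inferior
site at rate ``alpha_s * (1 - H)``, where ``H`` is the probability that
an individual ant accepts the superior site.  Scouts leak back to the
home nest at rate ``alpha``; home ants re-enter the scouting pool at the
scouting rate.  The system is linear:

    dh/dt = alpha * s - alpha_s * h
    ds/dt = alpha_s * h - (alpha_s + alpha) * s
    dx_sup/dt = alpha_s * H * s
    dx_inf/dt = alpha_s * (1 - H) * s

Asymptotically all mass commits, split H : (1-H), so the colony selects
the majority-preferred site 100% of the time — the winner depends only
on ``H`` (ties resolve to the superior site), never on ``alpha_s``,
``alpha`` or ``z``, which only shape the time course.  The binary,
zero-noise outcome is the point of the model: even a 51% individual
preference becomes a certain collective choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import solve_ivp

from . import design
from .cyclic import CyclicSystem, LinkedPair

__all__ = [
    "OdeParams",
    "OdeOutcome",
    "outcome_sign",
    "run_colony_ode",
    "masuda_cyclic_outcomes",
]


@dataclass(frozen=True)
class OdeParams:
    """H: individual acceptance probability of the superior site;
    alpha_s: commitment (recruitment) rate; alpha: leakage rate back
    home; z: initial scout fraction."""

    H: float
    alpha_s: float = 0.46
    alpha: float = 0.1
    z: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.H <= 1.0:
            raise ValueError("H must be a probability")
        if self.alpha_s < 0 or self.alpha < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 < self.z <= 1.0:
            raise ValueError("z must lie in (0, 1]")


@dataclass(frozen=True)
class OdeOutcome:
    winner: int  # +1 superior, -1 inferior
    select_prob_superior: int  # exactly 0 or 1
    duration: float  # time for the winner to reach 90% of its asymptote

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)


def outcome_sign(H: float) -> int:
    """Collective winner in the infinite-population limit: +1 iff H >= 0.5."""
    if not 0.0 <= H <= 1.0:
        raise ValueError("H must be a probability")
    return 1 if H >= 0.5 else -1


def run_colony_ode(params: OdeParams) -> OdeOutcome:
    """Integrate the recruitment system and time the winner's build-up."""
    if params.alpha_s == 0:
        raise ValueError("alpha_s = 0: no ant ever commits")
    winner = outcome_sign(params.H)
    h_win = params.H if winner == 1 else 1.0 - params.H
    if h_win == 0.0:
        # degenerate H in {0,1} with the losing site: cannot happen, winner
        # side always has h_win >= 0.5
        raise AssertionError
    target = 0.9 * h_win  # winner's asymptotic committed fraction is h_win

    a_s, a = params.alpha_s, params.alpha

    def rhs(_t, y):
        h, s, x = y
        return [
            a * s - a_s * h,
            a_s * h - (a_s + a) * s,
            a_s * (params.H if winner == 1 else 1.0 - params.H) * s,
        ]

    def hit(_t, y):
        return y[2] - target

    hit.terminal = True
    hit.direction = 1
    t_max = 2000.0 / a_s  # generous horizon; crossing is guaranteed
    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        [1.0 - params.z, params.z, 0.0],
        events=hit,
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.t_events[0].size:
        raise RuntimeError("winner never reached 90% of its asymptote")
    return OdeOutcome(
        winner=winner,
        select_prob_superior=1 if winner == 1 else 0,
        duration=float(sol.t_events[0][0]),
    )


def masuda_cyclic_outcomes(
    H_list,
) -> tuple[list[int], CyclicSystem]:
    """Deterministic ±1 outcomes for the 8-experiment design, as a cyclic system.

    Joint probabilities of deterministic outcomes are products: the joint
    of anything with 0 is 0, and of two 1s is 1.
    """
    H_list = list(H_list)
    if len(H_list) != 8:
        raise ValueError("expected one H per experiment (8 values)")
    outcomes = [outcome_sign(h) for h in H_list]
    p = [(o + 1) // 2 for o in outcomes]  # acceptance probability 0 or 1
    d = design.build_design()
    pairs = []
    for k, (i, j) in enumerate(d.pairing):
        pairs.append(
            LinkedPair(
                content=d.content_label(k),
                contexts=d.context_labels(k),
                p_a=float(p[i]),
                p_b=float(p[j]),
                p_joint=float(p[i] * p[j]),
            )
        )
    return outcomes, CyclicSystem(tuple(pairs))
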