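"""Toy cyclic systems with known contextuality status.

These serve as oracle surfaces for the criterion statistics and the LP
test: a deterministic intransitive-preference cycle (the ice-cream
construction), the maximally contextual PR box, the quantum-boundary
Tsirel'son system, and classical mixtures of deterministic assignments
that are noncontextual by construction.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .cyclic import CyclicSystem, LinkedPair

__all__ = [
    "ice_cream_system",
    "pr_box_system",
    "tsirelson_system",
    "classical_mixture_system",
    "random_consistent_system",
    "FIXTURES",
]

_LABELS = ("c1", "c2", "c3", "c4")


def _rank4(contents, entries) -> CyclicSystem:
    pairs = []
    for k, (p_a, p_b, p_joint) in enumerate(entries):
        pairs.append(
            LinkedPair(
                content=contents[k],
                contexts=(_LABELS[k - 1], _LABELS[k]),
                p_a=p_a,
                p_b=p_b,
                p_joint=p_joint,
            )
        )
    return CyclicSystem(tuple(pairs))


def _from_expectations(E, m_first, m_second) -> CyclicSystem:
    entries = []
    for e, ma, mb in zip(E, m_first, m_second):
        p_a = (1.0 + ma) / 2.0
        p_b = (1.0 + mb) / 2.0
        p_joint = (1.0 + ma + mb + e) / 4.0
        entries.append((p_a, p_b, p_joint))
    contents = tuple(f"x{k + 1}" for k in range(len(E)))
    return _rank4(contents, entries)


def ice_cream_system() -> CyclicSystem:
    """Deterministic intransitive preference cycle over four flavors.

    Four pairwise choices — double-fudge chocolate over double chocolate,
    double chocolate over chocolate, chocolate over pistachio, yet
    pistachio over double-fudge chocolate — encoded as deterministic ±1
    variables that agree (E = +1) on the three transitive edges and
    disagree (E = -1) on the cycle-closing edge.  The CHSH expression
    attains its algebraic maximum of 4, but the system is deterministic
    and hence classically realizable: all of the apparent violation is
    absorbed by inconsistent connectedness (Delta = 2, dC_cbd = 0).
    """
    contents = ("double-fudge", "double-choc", "chocolate", "pistachio")
    entries = [(1.0, 1.0, 1.0), (1.0, 1.0, 1.0), (1.0, 1.0, 1.0), (1.0, 0.0, 0.0)]
    return _rank4(contents, entries)


def pr_box_system() -> CyclicSystem:
    """Maximal contextuality with consistent connectedness: E = (1,1,1,-1),
    all marginals zero.  s_odd = 4, Delta = 0, dC_cbd = 2."""
    return _from_expectations([1.0, 1.0, 1.0, -1.0], [0.0] * 4, [0.0] * 4)


def tsirelson_system() -> CyclicSystem:
    """The quantum boundary: E = ±sqrt(2)/2, marginals zero, s_odd = 2*sqrt(2)."""
    r = math.sqrt(2.0) / 2.0
    return _from_expectations([r, r, r, -r], [0.0] * 4, [0.0] * 4)


#: the 16 deterministic assignments of ±1 to the four connection values
_ASSIGNMENTS = np.array(list(itertools.product([1, -1], repeat=4)))


def classical_mixture_system(weights, rng=None) -> CyclicSystem:
    """Rank-4 system realized by a mixture of deterministic assignments.

    A deterministic assignment fixes one ±1 value per shared-context
    connection; pair k then observes the values of connections k-1 and k,
    so E_k is their product.  Any mixture is noncontextual by
    construction (and consistently connected in the chained sense).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (16,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be a distribution over the 16 assignments")
    # connection values per assignment; pair k sees (conn[k-1], conn[k])
    first = _ASSIGNMENTS[:, [3, 0, 1, 2]]
    second = _ASSIGNMENTS
    m_first = w @ first
    m_second = w @ second
    E = w @ (first * second)
    return _from_expectations(E, m_first, m_second)


def random_consistent_system(rng: np.random.Generator) -> CyclicSystem:
    """Random rank-4 system with all marginal expectations zero.

    Correlations are drawn uniformly from [-1, 1]; with zero marginals
    every such E is Fréchet-feasible.  Contextual iff s_odd > 2.
    """
    E = rng.uniform(-1.0, 1.0, size=4)
    return _from_expectations(E, [0.0] * 4, [0.0] * 4)


FIXTURES = {
    "ice-cream": ice_cream_system,
    "pr-box": pr_box_system,
    "tsirelson": tsirelson_system,
    "classical": lambda: classical_mixture_system(np.full(16, 1 / 16)),
}
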