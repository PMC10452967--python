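"""Core statistics of cyclic systems of binary random variables.

A cyclic system of rank *n* consists of *n* "contents" (here: the four
distant nest sites), each measured in two of *n* "contexts" (the nearby
alternative presented alongside), arranged so that contexts chain in a
single cycle.  Rank 4 is the CHSH scenario.  Each linked pair of
experiments that shares a content yields a product correlation ``E``; the
criterion statistics are

    s_odd(E)  = max over sign patterns with an odd number of minuses of
                the signed sum of the E's,
    dC_chsh   = s_odd - (n - 2),
    dC_cbd    = s_odd - (n - 2) - Delta,

where ``Delta`` measures inconsistent connectedness — how much the
marginal expectation of a content shifts between its two contexts.  A
strictly positive ``dC_cbd`` indicates true (Type II) contextuality;
``Delta > 0`` alone is Type I contextuality.

All variables are coded +1 for "migrated to the good (distant) site" and
-1 for the poor (nearby) site.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "LinkedPair",
    "CyclicSystem",
    "ContextualityReport",
    "LpVerdict",
    "correlation_from_joint",
    "s_odd",
    "delta_icc",
    "is_sign_transitive",
    "contextuality_report",
    "noncontextual_lp_oracle",
]

#: probabilities this far outside [0,1] or the Fréchet band are rejected
TOL = 1e-9


def _check_prob(p: float, name: str, where: str) -> None:
    if not (-TOL <= p <= 1 + TOL):
        raise ValueError(f"{where}: {name}={p} is not a probability")


def _check_frechet(p_a: float, p_b: float, p_joint: float, where: str) -> None:
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    if not (lo - TOL <= p_joint <= hi + TOL):
        raise ValueError(
            f"{where}: joint probability {p_joint} violates the Fréchet bounds "
            f"[{lo}, {hi}] implied by marginals ({p_a}, {p_b})"
        )


@dataclass(frozen=True)
class LinkedPair:
    """Two experiments sharing a content (the same good nest).

    ``p_a``/``p_b`` are the probabilities of accepting the good nest in
    the two experiments, ``p_joint`` the constructed probability of
    accepting it in both.  ``n_a``/``n_b`` are the ant counts behind the
    estimates (optional, carried for error propagation).
    """

    content: str
    contexts: tuple[str, str]
    p_a: float
    p_b: float
    p_joint: float
    n_a: int | None = None
    n_b: int | None = None

    def __post_init__(self) -> None:
        where = f"pair {self.content}{self.contexts}"
        _check_prob(self.p_a, "p_a", where)
        _check_prob(self.p_b, "p_b", where)
        _check_prob(self.p_joint, "p_joint", where)
        _check_frechet(self.p_a, self.p_b, self.p_joint, where)

    @property
    def correlation(self) -> float:
        return correlation_from_joint(self.p_a, self.p_b, self.p_joint)

    @property
    def marginal_expectations(self) -> tuple[float, float]:
        return 2.0 * self.p_a - 1.0, 2.0 * self.p_b - 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contexts"] = list(self.contexts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LinkedPair":
        d = dict(d)
        d["contexts"] = tuple(d["contexts"])
        return cls(**d)


@dataclass(frozen=True)
class CyclicSystem:
    """An ordered cycle of linked pairs; rank = number of pairs.

    Pair *k*'s second context must equal pair *k+1*'s first context
    (wrapping), so the contexts chain in a single cycle.
    """

    pairs: tuple[LinkedPair, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if len(self.pairs) < 3:
            raise ValueError("a cyclic system needs rank >= 3")
        n = len(self.pairs)
        for k, pair in enumerate(self.pairs):
            nxt = self.pairs[(k + 1) % n]
            if pair.contexts[1] != nxt.contexts[0]:
                raise ValueError(
                    f"context labels do not chain: pair {k} ends in "
                    f"{pair.contexts[1]!r} but pair {(k + 1) % n} starts with "
                    f"{nxt.contexts[0]!r}"
                )

    @property
    def rank(self) -> int:
        return len(self.pairs)

    @property
    def correlations(self) -> list[float]:
        return [p.correlation for p in self.pairs]

    def to_dict(self) -> dict:
        return {"rank": self.rank, "pairs": [p.to_dict() for p in self.pairs]}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "CyclicSystem":
        return cls(tuple(LinkedPair.from_dict(p) for p in d["pairs"]))

    @classmethod
    def from_json(cls, s: str) -> "CyclicSystem":
        return cls.from_dict(json.loads(s))


def correlation_from_joint(p_a: float, p_b: float, p_joint: float) -> float:
    """Product expectation E[XY] of two ±1 variables from (p_a, p_b, p_ab).

    With both variables coded +1 on acceptance, the 2x2 outcome table has
    cells (++, +-, -+, --) = (p_ab, p_a - p_ab, p_b - p_ab,
    1 - p_a - p_b + p_ab), giving E = 1 - 2 p_a - 2 p_b + 4 p_ab.
    """
    _check_prob(p_a, "p_a", "correlation_from_joint")
    _check_prob(p_b, "p_b", "correlation_from_joint")
    _check_prob(p_joint, "p_joint", "correlation_from_joint")
    _check_frechet(p_a, p_b, p_joint, "correlation_from_joint")
    return 1.0 - 2.0 * p_a - 2.0 * p_b + 4.0 * p_joint


def s_odd(E) -> float:
    """Max of the signed sum of correlations over odd-minus sign patterns.

    Closed form: the best pattern takes every |E_i|; if the number of
    negative entries is already odd that is attainable, otherwise one
    entry (the smallest in magnitude) must be sacrificed twice.
    """
    E = np.asarray(E, dtype=float)
    if E.size == 0:
        raise ValueError("s_odd of an empty correlation list")
    if np.any(np.abs(E) > 1 + TOL):
        raise ValueError("correlations must lie in [-1, 1]")
    total = np.sum(np.abs(E))
    n_neg = int(np.sum(E < 0))
    if n_neg % 2 == 1:
        return float(total)
    return float(total - 2.0 * np.min(np.abs(E)))


def delta_icc(m_pairs) -> float:
    """Inconsistent-connectedness measure: sum of |m_A - m_B| over pairs.

    Zero iff every content has identical marginal expectations in its two
    contexts (consistent connectedness).
    """
    total = 0.0
    for m_a, m_b in m_pairs:
        if abs(m_a) > 1 + TOL or abs(m_b) > 1 + TOL:
            raise ValueError("marginal expectations must lie in [-1, 1]")
        total += abs(m_a - m_b)
    return total


def is_sign_transitive(E) -> bool:
    """True iff all cycle correlations, including the closing one, share a sign.

    An exact zero breaks the shared-sign premise and counts as not
    sign-transitive.  Breach of sign transitivity is necessary (though not
    sufficient) for maximal violation of the rank-4 inequality.
    """
    E = list(E)
    if any(e == 0 for e in E):
        return False
    signs = {e > 0 for e in E}
    return len(signs) == 1


@dataclass(frozen=True)
class ContextualityReport:
    """All criterion statistics for one cyclic system."""

    rank: int
    E: tuple[float, ...]
    m: tuple[float, ...]  # 2n marginal expectations, pair-major order
    s_odd: float
    delta: float
    dC_chsh: float
    dC_cbd: float
    sign_transitive: bool
    type1: bool  # inconsistent connectedness (delta > 0)
    type2: bool  # true contextuality (dC_cbd > 0)
    delta_convention: str = "linked"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["E"] = list(self.E)
        d["m"] = list(self.m)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ContextualityReport":
        d = dict(d)
        d["E"] = tuple(d["E"])
        d["m"] = tuple(d["m"])
        return cls(**d)


def _delta_chained(system: CyclicSystem) -> float:
    """Orthodox Delta: marginal differences across shared-context connections."""
    n = system.rank
    total = 0.0
    for k in range(n):
        m_b = system.pairs[k].marginal_expectations[1]
        m_a_next = system.pairs[(k + 1) % n].marginal_expectations[0]
        total += abs(m_b - m_a_next)
    return total


def contextuality_report(
    system: CyclicSystem, delta_convention: str = "linked"
) -> ContextualityReport:
    """Compute E, s_odd, Delta and both ΔC statistics for a cyclic system.

    ``delta_convention`` selects how inconsistent connectedness is summed:

    - ``"linked"`` (default): over the same-content pairs that also supply
      the product correlations — the convention under which the worked
      example reproduces its published statistics;
    - ``"chained"``: over the shared-context connections between
      consecutive pairs, the orthodox cyclic-system convention (the one
      the LP oracle tests).
    """
    E = system.correlations
    m_pairs = [p.marginal_expectations for p in system.pairs]
    if delta_convention == "linked":
        delta = delta_icc(m_pairs)
    elif delta_convention == "chained":
        delta = _delta_chained(system)
    else:
        raise ValueError(f"unknown delta convention {delta_convention!r}")
    s = s_odd(E)
    n = system.rank
    dc_chsh = s - (n - 2)
    dc_cbd = dc_chsh - delta
    return ContextualityReport(
        rank=n,
        E=tuple(E),
        m=tuple(itertools.chain.from_iterable(m_pairs)),
        s_odd=s,
        delta=delta,
        dC_chsh=dc_chsh,
        dC_cbd=dc_cbd,
        sign_transitive=bool(is_sign_transitive(E)),
        type1=bool(delta > TOL),
        type2=bool(dc_cbd > TOL),
        delta_convention=delta_convention,
    )


@dataclass(frozen=True)
class LpVerdict:
    """Outcome of the linear-programming noncontextuality test.

    ``margin`` is (achieved total same-content agreement) minus (the
    maximum each connection could achieve in isolation given its two
    marginals); ``noncontextual`` iff the margin is ~0, i.e. a single
    global distribution attains every maximal coupling simultaneously.
    """

    noncontextual: bool
    margin: float
    max_agreement: float
    target_agreement: float


def noncontextual_lp_oracle(system: CyclicSystem, tol: float = 1e-7) -> LpVerdict:
    """Independent LP test of the cyclic-system noncontextuality criterion.

    Variables are the probabilities of the ``2**(2n)`` deterministic
    assignments to all 2n measured variables.  Constraints pin each pair's
    observed 2x2 distribution; the objective maximizes the summed
    probability of agreement across the n shared-context connections.
    The system is noncontextual iff the maximum equals the sum of the
    per-connection Fréchet ceilings ``1 - |p_i - p_j|/...`` (in
    expectation form, ``1 - |m_i - m_j| / 2`` rescaled), i.e. all maximal
    couplings coexist in one joint distribution.
    """
    n = system.rank
    if n > 6:
        raise ValueError("LP oracle supports rank <= 6 only")
    nvar = 2 * n
    atoms = np.array(list(itertools.product([1, -1], repeat=nvar)))
    natoms = atoms.shape[0]

    # variable layout: pair k owns columns (2k, 2k+1)
    rows, rhs = [], []
    for k, pair in enumerate(system.pairs):
        a_col, b_col = 2 * k, 2 * k + 1
        cells = {
            (1, 1): pair.p_joint,
            (1, -1): pair.p_a - pair.p_joint,
            (-1, 1): pair.p_b - pair.p_joint,
            (-1, -1): 1.0 - pair.p_a - pair.p_b + pair.p_joint,
        }
        for (va, vb), p in cells.items():
            if p < -TOL:
                raise ValueError(
                    f"pair {k} has an infeasible 2x2 cell probability {p}"
                )
            rows.append((atoms[:, a_col] == va) & (atoms[:, b_col] == vb))
            rhs.append(max(p, 0.0))
    A_eq = np.array(rows, dtype=float)
    b_eq = np.array(rhs)

    # connections: pair k's second variable vs pair k+1's first
    agree = np.zeros(natoms)
    target = 0.0
    for k in range(n):
        i, j = 2 * k + 1, (2 * k + 2) % nvar
        agree += atoms[:, i] == atoms[:, j]
        p_i = system.pairs[k].p_b
        p_j = system.pairs[(k + 1) % n].p_a
        target += 1.0 - abs(p_i - p_j)  # max coupling agreement for 2 bernoullis

    res = linprog(
        -agree,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=(0, 1),
        method="highs",
    )
    if not res.success:
        raise ValueError(f"LP infeasible: {res.message}")
    max_agreement = -res.fun
    margin = max_agreement - target
    return LpVerdict(
        noncontextual=margin >= -tol,
        margin=float(margin),
        max_agreement=float(max_agreement),
        target_agreement=float(target),
    )
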