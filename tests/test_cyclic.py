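"""Unit and property tests for the cyclic-system statistics."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antctx.cyclic import (
    CyclicSystem,
    LinkedPair,
    contextuality_report,
    correlation_from_joint,
    delta_icc,
    is_sign_transitive,
    noncontextual_lp_oracle,
    s_odd,
)


def s_odd_bruteforce(E):
    """Independent oracle: enumerate every odd-minus sign pattern."""
    n = len(E)
    best = -np.inf
    for signs in itertools.product([1, -1], repeat=n):
        if sum(s < 0 for s in signs) % 2 == 1:
            best = max(best, sum(s * e for s, e in zip(signs, E)))
    return best


def correlation_bruteforce(p_a, p_b, p_joint):
    """Independent oracle: expectation over the enumerated 2x2 table."""
    cells = {
        (1, 1): p_joint,
        (1, -1): p_a - p_joint,
        (-1, 1): p_b - p_joint,
        (-1, -1): 1 - p_a - p_b + p_joint,
    }
    return sum(a * b * p for (a, b), p in cells.items())


@pytest.mark.parametrize(
    "p_a, p_b, p_joint, expected",
    [
        (0.78, 0.68, 0.51, 0.12),
        (1.0, 1.0, 1.0, 1.0),
        (0.5, 0.5, 0.25, 0.0),
    ],
)
def test_correlation_from_joint_examples(p_a, p_b, p_joint, expected):
    assert correlation_from_joint(p_a, p_b, p_joint) == pytest.approx(expected)


@settings(derandomize=True, max_examples=200)
@given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
def test_correlation_matches_table_expectation(p_a, p_b, u):
    """E from the closed form equals the ±1 expectation over the 2x2 table."""
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    p_joint = lo + u * (hi - lo)
    assert correlation_from_joint(p_a, p_b, p_joint) == pytest.approx(
        correlation_bruteforce(p_a, p_b, p_joint), abs=1e-12
    )


def test_frechet_violation_rejected_with_pair_name():
    with pytest.raises(ValueError, match="Fréchet"):
        correlation_from_joint(0.2, 0.3, 0.9)
    with pytest.raises(ValueError, match="q9"):
        LinkedPair("q9", ("c1", "c2"), 0.9, 0.9, 0.1)


def test_out_of_bounds_probability_rejected():
    with pytest.raises(ValueError, match="probability"):
        correlation_from_joint(1.2, 0.5, 0.4)


@pytest.mark.parametrize(
    "E, expected",
    [
        ((-0.06, 0.12, 0.06, 0.08), 0.32),
        ((1, 1, 1, 1), 2),
        ((1, 1, 1, -1), 4),
    ],
)
def test_s_odd_examples(E, expected):
    assert s_odd(E) == pytest.approx(expected)


def test_s_odd_empty_rejected():
    with pytest.raises(ValueError):
        s_odd([])


@settings(derandomize=True, max_examples=300)
@given(st.lists(st.floats(-1, 1), min_size=3, max_size=6))
def test_s_odd_closed_form_equals_enumeration(E):
    assert s_odd(E) == pytest.approx(s_odd_bruteforce(E), abs=1e-12)


@pytest.mark.parametrize(
    "m_pairs, expected",
    [
        ([(0.00, 0.58), (0.56, 0.36), (0.38, 0.16), (0.18, -0.02)], 1.20),
        ([(0.3, 0.3)] * 4, 0.0),
        ([(1, -1), (0, 0), (0, 0), (0, 0)], 2.0),
    ],
)
def test_delta_icc_examples(m_pairs, expected):
    assert delta_icc(m_pairs) == pytest.approx(expected)


@pytest.mark.parametrize(
    "E, expected",
    [
        ((1, 1, 1, 1), True),
        ((1, 1, 1, -1), False),
        ((-0.5, -0.5, -0.5, -0.5), True),
        ((0.0, 1, 1, 1), False),  # exact zero breaks the shared-sign premise
    ],
)
def test_sign_transitivity(E, expected):
    assert is_sign_transitive(E) is expected


def _random_system(rng):
    labels = ["c1", "c2", "c3", "c4"]
    pairs = []
    for k in range(4):
        p_a, p_b = rng.uniform(0, 1, 2)
        lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
        p_joint = rng.uniform(lo, hi)
        pairs.append(
            LinkedPair(f"q{k+1}", (labels[k - 1], labels[k]), p_a, p_b, p_joint)
        )
    return CyclicSystem(tuple(pairs))


def test_report_identity_and_bounds(rng):
    """dC_cbd = dC_chsh - Delta identically; s_odd and E stay bounded."""
    for _ in range(200):
        rep = contextuality_report(_random_system(rng))
        assert rep.dC_cbd == pytest.approx(rep.dC_chsh - rep.delta, abs=1e-12)
        assert rep.dC_cbd <= rep.dC_chsh + 1e-12
        assert rep.s_odd <= rep.rank
        assert all(abs(e) <= 1 + 1e-12 for e in rep.E)


def test_boundary_system_all_plus_one():
    system = CyclicSystem(
        tuple(
            LinkedPair(f"q{k+1}", (f"c{(k - 1) % 4 + 1}", f"c{k + 1}"), 1.0, 1.0, 1.0)
            for k in range(4)
        )
    )
    rep = contextuality_report(system)
    assert rep.dC_chsh == pytest.approx(0.0)
    assert rep.dC_cbd == pytest.approx(0.0)
    assert rep.sign_transitive


def test_chained_delta_convention(reference_rows):
    """The orthodox shared-context Delta is 0.08 on the worked example."""
    from antctx.pipeline import system_from_marginals

    system = system_from_marginals(*reference_rows)
    rep = contextuality_report(system, delta_convention="chained")
    assert rep.delta == pytest.approx(0.08)
    with pytest.raises(ValueError):
        contextuality_report(system, delta_convention="nonsense")


def test_system_chain_validation():
    pairs = [
        LinkedPair("q1", ("c4", "c1"), 0.5, 0.5, 0.25),
        LinkedPair("q2", ("c2", "c3"), 0.5, 0.5, 0.25),  # breaks the chain
        LinkedPair("q3", ("c3", "c4"), 0.5, 0.5, 0.25),
    ]
    with pytest.raises(ValueError, match="chain"):
        CyclicSystem(tuple(pairs))


def test_serialization_round_trip(rng):
    system = _random_system(rng)
    assert CyclicSystem.from_json(system.to_json()) == system
    rep = contextuality_report(system)
    from antctx.cyclic import ContextualityReport

    assert ContextualityReport.from_dict(json.loads(rep.to_json())) == rep


def test_lp_oracle_deterministic_system_noncontextual():
    system = CyclicSystem(
        tuple(
            LinkedPair(f"q{k+1}", (f"c{(k - 1) % 4 + 1}", f"c{k + 1}"), 1.0, 1.0, 1.0)
            for k in range(4)
        )
    )
    verdict = noncontextual_lp_oracle(system)
    assert verdict.noncontextual
    assert verdict.margin == pytest.approx(0.0, abs=1e-7)


def test_lp_oracle_rank_limit(rng):
    labels = [f"c{k}" for k in range(7)]
    pairs = tuple(
        LinkedPair(f"q{k}", (labels[k - 1], labels[k]), 0.5, 0.5, 0.25)
        for k in range(7)
    )
    with pytest.raises(ValueError, match="rank"):
        noncontextual_lp_oracle(CyclicSystem(pairs))
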