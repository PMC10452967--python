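"""Tests for the forced-emigration Monte-Carlo simulator."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from antctx.emigration import (
    DEFAULT_DISCOVERY,
    AntState,
    ExperimentConfig,
    evaluate_site,
    run_experiment,
    sample_thresholds,
    step_ant,
    summarize,
)


def test_discovery_kernel_rows_are_distributions():
    assert np.allclose(DEFAULT_DISCOVERY.sum(axis=1), 1.0)


def test_sample_thresholds_moments(rng):
    thr = sample_thresholds(10_000, 5.0, 1.0, rng)
    assert abs(thr.mean() - 5.0) < 4.0 / np.sqrt(10_000)
    # normal tail: fraction demanding more than quality 6.5
    expected_tail = 1 - norm.cdf(1.5)
    assert abs((thr > 6.5).mean() - expected_tail) < 0.01


def test_sample_thresholds_validation(rng):
    with pytest.raises(ValueError):
        sample_thresholds(0, 5.0, 1.0, rng)
    with pytest.raises(ValueError):
        sample_thresholds(10, 5.0, 0.0, rng)


def test_evaluate_site(rng):
    # the uninhabitable home site is never accepted
    assert not any(evaluate_site(-1000.0, 5.0, 1.0, rng) for _ in range(200))
    # zero noise, quality above threshold
    assert evaluate_site(6.5, 5.0, 0.0, rng)
    # symmetric error at the threshold accepts about half the time
    rate = np.mean([evaluate_site(5.0, 5.0, 1.0, rng) for _ in range(4000)])
    assert abs(rate - 0.5) < 0.03


def _config(**kw):
    defaults = dict(quality_poor=3.1, quality_good=6.5, n_ants=200, seed=7)
    defaults.update(kw)
    return ExperimentConfig(**defaults)


def test_step_ant_rejects_committed(rng):
    ant = AntState(threshold=5.0, phase="committed to superior site")
    with pytest.raises(ValueError, match="committed"):
        step_ant(ant, _config(), rng)


def test_step_ant_commits_on_good_discovery(rng):
    # deterministic kernel: always move to the good site; zero noise
    kernel = np.zeros((3, 3))
    kernel[:, 2] = 1.0
    cfg = _config(discovery_prob=kernel, assessment_error_sd=0.0)
    ant = AntState(threshold=5.0)
    stepped = step_ant(ant, cfg, rng)
    assert stepped.phase == "committed to superior site"
    assert stepped.first_site_found == 2
    assert stepped.clock == pytest.approx(143.0)  # travelled old -> good


def test_step_ant_first_site_bookkeeping(rng):
    kernel = np.zeros((3, 3))
    kernel[:, 1] = 1.0  # always the poor site
    cfg = _config(discovery_prob=kernel, threshold_mean=50.0)  # never accepts
    ant = AntState(threshold=50.0)
    stepped = step_ant(ant, cfg, rng)
    assert stepped.first_site_found == 1
    assert not stepped.committed
    again = step_ant(stepped, cfg, rng)
    assert again.first_site_found == 1  # unchanged after the first discovery


def test_run_experiment_deterministic_and_conserving():
    cfg = _config(n_ants=500, seed=42)
    r1 = run_experiment(cfg)
    r2 = run_experiment(cfg)
    assert r1 == r2
    assert r1.n_commit_good + r1.n_commit_poor + r1.n_uncommitted == cfg.n_ants
    assert r1.n_switch_to_good <= r1.n_commit_good
    assert r1.completed == (r1.n_uncommitted == 0)


def test_run_experiment_symmetric_qualities_split_evenly():
    # equal qualities and a symmetric kernel/travel: no site is favoured
    kernel = np.array([[0.0, 0.5, 0.5], [0.5, 0.25, 0.25], [0.5, 0.25, 0.25]])
    travel = np.ones((3, 3))
    cfg = ExperimentConfig(
        quality_poor=5.0,
        quality_good=5.0,
        n_ants=4000,
        seed=11,
        discovery_prob=kernel,
        travel_time=travel,
    )
    res = run_experiment(cfg)
    assert res.p_accept_good == pytest.approx(0.5, abs=0.03)


def test_run_experiment_unacceptable_poor_site():
    # zero noise, degenerate thresholds at 5: poor (4.6) is never accepted
    cfg = _config(
        quality_poor=4.6,
        quality_good=6.5,
        n_ants=500,
        threshold_sd=1e-9,
        assessment_error_sd=0.0,
        seed=3,
    )
    res = run_experiment(cfg)
    assert res.p_accept_good == 1.0
    assert res.n_commit_poor == 0


def test_run_experiment_nonterminating_is_flagged():
    # no ant can ever accept anything: the time cap must flag, not hang
    cfg = _config(
        quality_poor=-500.0,
        quality_good=-500.0,
        n_ants=50,
        threshold_sd=1e-9,
        assessment_error_sd=0.0,
        max_time=500.0,
        seed=1,
    )
    res = run_experiment(cfg)
    assert not res.completed
    assert res.n_uncommitted == 50


def test_per_ant_event_log():
    cfg = _config(n_ants=100, seed=5)
    res, ants = run_experiment(cfg, keep_ants=True)
    assert len(ants) == 100
    assert set(ants.columns) == {"ant", "threshold", "first_site", "final_site", "clock_s"}
    assert (ants.final_site == "good").sum() == res.n_commit_good


def test_summarize_schema():
    results = [run_experiment(_config(n_ants=100, seed=s)) for s in (1, 2)]
    table = summarize(results)
    assert list(table.experiment) == [1, 2]
    assert table.p_accept_good.between(0, 1).all()
    with pytest.raises(ValueError):
        summarize([])


def test_config_validation():
    with pytest.raises(ValueError):
        _config(n_ants=0)
    with pytest.raises(ValueError):
        _config(discovery_prob=np.full((3, 3), 0.5))  # rows don't sum to 1
    with pytest.raises(ValueError):
        _config(travel_time=-np.ones((3, 3)))
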