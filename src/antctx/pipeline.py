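"""Orchestration of the full study.

Runs the eight forced-emigration experiments, constructs the four joint
probabilities, assembles the rank-4 cyclic system and computes the
contextuality report — alongside the zero-noise infinite-population
counterpart driven by the same individual acceptance probabilities.
Bootstrap resampling of all eight experiments propagates simulation
error into standard errors for the ΔC statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import design
from .colony_ode import masuda_cyclic_outcomes
from .cyclic import ContextualityReport, CyclicSystem, LinkedPair, contextuality_report
from .emigration import ExperimentConfig, SimulationResult, run_experiment, summarize
from .estimation import bootstrap_joint_se, joint_accept_good, proportion_se

__all__ = [
    "RunReport",
    "build_design",
    "run_study",
    "report_from_table",
    "bootstrap_dc_se",
    "system_from_marginals",
    "configs_from_file",
]

build_design = design.build_design


def configs_from_file(path) -> list[ExperimentConfig]:
    """Load experiment configurations from a YAML or JSON file.

    Expected layout: an ``experiments`` list of ``{poor: .., good: ..}``
    mappings plus optional top-level simulator constants (``n_ants``,
    ``seed``, ``threshold_mean``, ``threshold_sd``,
    ``assessment_error_sd``, ``max_time``).  Seeds increment per
    experiment so runs are independent but reproducible.
    """
    import pathlib

    import yaml

    doc = yaml.safe_load(pathlib.Path(path).read_text())
    common = {k: v for k, v in doc.items() if k != "experiments"}
    base_seed = common.pop("seed", 0)
    configs = []
    for k, exp in enumerate(doc["experiments"]):
        configs.append(
            ExperimentConfig(
                quality_poor=float(exp["poor"]),
                quality_good=float(exp["good"]),
                seed=base_seed + k,
                **common,
            )
        )
    return configs


def system_from_marginals(p_accept, p_joint, n=None) -> CyclicSystem:
    """Assemble the design's cyclic system from 8 marginals and 4 joints."""
    p_accept = list(p_accept)
    p_joint = list(p_joint)
    if len(p_accept) != 8 or len(p_joint) != 4:
        raise ValueError("expected 8 acceptance probabilities and 4 joints")
    d = design.build_design()
    pairs = []
    for k, (i, j) in enumerate(d.pairing):
        pairs.append(
            LinkedPair(
                content=d.content_label(k),
                contexts=d.context_labels(k),
                p_a=float(p_accept[i]),
                p_b=float(p_accept[j]),
                p_joint=float(p_joint[k]),
                n_a=n,
                n_b=n,
            )
        )
    return CyclicSystem(tuple(pairs))


def report_from_table(p_accept, p_joint, n=None) -> ContextualityReport:
    """Contextuality report straight from tabulated probabilities.

    This is the worked-example entry point: feeding in the published
    acceptance and joint probabilities reproduces the published ΔC
    values without rerunning any simulation.
    """
    return contextuality_report(system_from_marginals(p_accept, p_joint, n=n))


@dataclass
class RunReport:
    """Everything the study produces, traceable to seeds and parameters."""

    summary: pd.DataFrame
    joints: pd.DataFrame
    system_mc: CyclicSystem
    report_mc: ContextualityReport
    se_dc_chsh: float
    se_dc_cbd: float
    outcomes_ode: list[int]
    system_ode: CyclicSystem
    report_ode: ContextualityReport
    seed: int
    n_ants: int
    bootstrap_reps: int
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return {
            "summary": self.summary.to_dict(orient="records"),
            "joints": self.joints.to_dict(orient="records"),
            "system_mc": self.system_mc.to_dict(),
            "report_mc": self.report_mc.to_dict(),
            "se_dc_chsh": self.se_dc_chsh,
            "se_dc_cbd": self.se_dc_cbd,
            "outcomes_ode": self.outcomes_ode,
            "system_ode": self.system_ode.to_dict(),
            "report_ode": self.report_ode.to_dict(),
            "seed": self.seed,
            "n_ants": self.n_ants,
            "bootstrap_reps": self.bootstrap_reps,
            "timestamp": self.timestamp,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _s_odd_rows(E: np.ndarray) -> np.ndarray:
    """Row-wise s_odd for an array of correlation vectors."""
    a = np.abs(E)
    total = a.sum(axis=1)
    odd = (E < 0).sum(axis=1) % 2 == 1
    return np.where(odd, total, total - 2.0 * a.min(axis=1))


def bootstrap_dc_se(
    results: list[SimulationResult], reps: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Propagate per-experiment resampling error into SEs for both ΔC."""
    n = results[0].n_ants
    pg = np.empty((reps, 8))
    rej = np.empty((reps, 8))
    for i, r in enumerate(results):
        counts = rng.multinomial(n, r.category_counts() / n, size=reps)
        pg[:, i] = (counts[:, 0] + counts[:, 1]) / n
        rej[:, i] = counts[:, 0] + counts[:, 3]
    E = np.empty((reps, 4))
    delta = np.zeros(reps)
    for k, (i, j) in enumerate(design.PAIRING):
        h = np.minimum(rej[:, i], rej[:, j]) / n
        raw = h + (pg[:, i] - h) * (pg[:, j] - h)
        lo = np.maximum(0.0, pg[:, i] + pg[:, j] - 1.0)
        hi = np.minimum(pg[:, i], pg[:, j])
        joint = np.clip(raw, lo, hi)
        E[:, k] = 1.0 - 2.0 * pg[:, i] - 2.0 * pg[:, j] + 4.0 * joint
        delta += np.abs(2.0 * pg[:, i] - 2.0 * pg[:, j])
    dc_chsh = _s_odd_rows(E) - 2.0
    dc_cbd = dc_chsh - delta
    return float(dc_chsh.std(ddof=1)), float(dc_cbd.std(ddof=1))


def run_study(
    seed: int = 0,
    n_ants: int = 10_000,
    bootstrap_reps: int = 100_000,
    max_time: float = 315_600.0,
) -> RunReport:
    """Run the whole pipeline end to end.

    Eight emigration simulations (one per design cell, seeded from
    ``seed`` via a SeedSequence spawn), joint construction with bootstrap
    SEs, the contextuality report, and the zero-noise colony-level
    counterpart fed by the simulated acceptance probabilities.
    """
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(9)
    ]
    results = []
    for k, (q_poor, q_good) in enumerate(design.EXPERIMENTS):
        cfg = ExperimentConfig(
            quality_poor=q_poor,
            quality_good=q_good,
            n_ants=n_ants,
            seed=child_seeds[k],
            max_time=max_time,
        )
        results.append(run_experiment(cfg))

    summary = summarize(results)
    summary["se_p"] = [
        round(proportion_se(r.p_accept_good, r.n_ants), 5) for r in results
    ]

    boot_rng = np.random.default_rng(child_seeds[8])
    joint_rows = []
    p_joint = []
    for k, (i, j) in enumerate(design.PAIRING):
        est = joint_accept_good(results[i], results[j])
        se = bootstrap_joint_se(results[i], results[j], bootstrap_reps, boot_rng)
        p_joint.append(est.p_joint)
        joint_rows.append(
            {
                "pair": f"({i + 1},{j + 1})",
                "content": design.build_design().content_label(k),
                "p_joint": round(est.p_joint, 4),
                "se_bootstrap": round(se, 5),
                "n_high": est.n_high,
            }
        )
    joints = pd.DataFrame(joint_rows)

    p_accept = [r.p_accept_good for r in results]
    system_mc = system_from_marginals(p_accept, p_joint, n=n_ants)
    report_mc = contextuality_report(system_mc)
    se_chsh, se_cbd = bootstrap_dc_se(results, bootstrap_reps, boot_rng)

    outcomes, system_ode = masuda_cyclic_outcomes(p_accept)
    report_ode = contextuality_report(system_ode)

    return RunReport(
        summary=summary,
        joints=joints,
        system_mc=system_mc,
        report_mc=report_mc,
        se_dc_chsh=se_chsh,
        se_dc_cbd=se_cbd,
        outcomes_ode=outcomes,
        system_ode=system_ode,
        report_ode=report_ode,
        seed=seed,
        n_ants=n_ants,
        bootstrap_reps=bootstrap_reps,
    )
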