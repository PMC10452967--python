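"""Monte-Carlo agent-based simulator of forced nest emigration.

Each ant is an independent realization of a five-state Markov chain:
evaluating the (destroyed) home site, evaluating the inferior site,
evaluating the superior site, committed to the inferior site, committed
to the superior site.  The committed states are absorbing.  An ant
carries a fixed acceptance threshold drawn from a normal distribution
across the colony; every assessment of a site compares the site's true
quality plus a fresh normal assessment error against that threshold.
The home site's quality of -1000 guarantees it is never accepted.

Movement between sites is a per-epoch categorical draw from a Markov
transition kernel.  The published discovery table is column-stochastic
(each column sums to 1.00), i.e. columns index the current location;
``DEFAULT_DISCOVERY`` below stores it row-major (row = current location)
so each row is a probability distribution over the next site.  On every
epoch the ant assesses whichever non-home site it occupies — staying put
in the "evaluating" state means assessing the same site again, which is
how an initially hesitant ant can end up committing to a mediocre nest.

Travel between distinct sites adds the corresponding travel time to the
ant's clock; remaining at a site costs one second per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TRAVEL",
    "DEFAULT_DISCOVERY",
    "ExperimentConfig",
    "AntState",
    "SimulationResult",
    "sample_thresholds",
    "evaluate_site",
    "step_ant",
    "run_experiment",
    "summarize",
]

OLD, POOR, GOOD = 0, 1, 2
_SITE_NAMES = ("old", "poor", "good")

PHASES = (
    "evaluating home site",
    "evaluating inferior site",
    "evaluating superior site",
    "committed to inferior site",
    "committed to superior site",
)

#: mean travel time in seconds between sites (symmetric; diagonal = one
#: "stay" epoch), derived from a walking speed of 8.4 mm/s
DEFAULT_TRAVEL = np.array(
    [
        [1.0, 36.0, 143.0],
        [36.0, 1.0, 116.0],
        [143.0, 116.0, 1.0],
    ]
)

#: per-epoch transition kernel, row = current location, columns old/poor/good;
#: this is the transpose of the published column-stochastic discovery table
#: (Old: 0.91/0.15/0.03, A: 0.06/0.80/0.06, B: 0.03/0.05/0.91 column-major)
DEFAULT_DISCOVERY = np.array(
    [
        [0.91, 0.06, 0.03],
        [0.15, 0.80, 0.05],
        [0.03, 0.06, 0.91],
    ]
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of one forced-emigration experiment."""

    quality_poor: float
    quality_good: float
    quality_old: float = -1000.0
    n_ants: int = 10_000
    threshold_mean: float = 5.0
    threshold_sd: float = 1.0
    assessment_error_sd: float = 1.0
    travel_time: np.ndarray = field(default_factory=lambda: DEFAULT_TRAVEL.copy())
    discovery_prob: np.ndarray = field(
        default_factory=lambda: DEFAULT_DISCOVERY.copy()
    )
    seed: int = 0
    max_time: float = 315_600.0  # seconds; 10x the longest reference duration

    def __post_init__(self) -> None:
        if self.n_ants <= 0:
            raise ValueError("n_ants must be positive")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.assessment_error_sd < 0:
            raise ValueError("assessment_error_sd must be non-negative")
        t = np.asarray(self.travel_time, dtype=float)
        d = np.asarray(self.discovery_prob, dtype=float)
        if t.shape != (3, 3) or d.shape != (3, 3):
            raise ValueError("travel_time and discovery_prob must be 3x3")
        if np.any(t < 0):
            raise ValueError("travel times must be non-negative")
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("discovery probabilities must lie in [0, 1]")
        if not np.allclose(d.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(
                "each discovery row must be a distribution over next sites"
            )
        object.__setattr__(self, "travel_time", t)
        object.__setattr__(self, "discovery_prob", d)

    @property
    def qualities(self) -> np.ndarray:
        return np.array([self.quality_old, self.quality_poor, self.quality_good])


@dataclass
class AntState:
    """One ant's private state; committed phases are absorbing."""

    threshold: float
    location: int = OLD
    phase: str = PHASES[0]
    first_site_found: int | None = None
    clock: float = 0.0

    @property
    def committed(self) -> bool:
        return self.phase in PHASES[3:]


@dataclass(frozen=True)
class SimulationResult:
    """Colony-level outcome of one experiment.

    The four commitment/rejection counts partition the colony together
    with ``n_uncommitted`` (nonzero only if ``max_time`` was hit).  The
    category counts ``n_good_rejected_poor`` etc. retain enough per-ant
    information for multinomial bootstrap resampling.
    """

    n_ants: int
    n_commit_good: int
    n_commit_poor: int
    n_uncommitted: int
    n_reject_poor: int  # assessed the poor site >= once, never committed to it
    n_switch_to_good: int  # first found the poor site, committed to the good one
    n_good_rejected_poor: int
    n_uncommitted_rejected_poor: int
    duration_min: float
    seed: int
    completed: bool

    @property
    def p_accept_good(self) -> float:
        return self.n_commit_good / self.n_ants

    @property
    def switch_rate(self) -> float:
        """Fraction of the whole colony that found poor first but chose good."""
        return self.n_switch_to_good / self.n_ants

    def category_counts(self) -> np.ndarray:
        """Per-ant outcome categories for bootstrap resampling.

        Order: (good & rejected poor, good & never assessed poor, poor,
        uncommitted & rejected poor, uncommitted & never assessed poor).
        """
        return np.array(
            [
                self.n_good_rejected_poor,
                self.n_commit_good - self.n_good_rejected_poor,
                self.n_commit_poor,
                self.n_uncommitted_rejected_poor,
                self.n_uncommitted - self.n_uncommitted_rejected_poor,
            ]
        )


def sample_thresholds(n: int, mean: float, sd: float, rng: np.random.Generator):
    """Draw the colony's fixed acceptance thresholds."""
    if n <= 0:
        raise ValueError("need at least one ant")
    if sd <= 0:
        raise ValueError("threshold sd must be positive")
    return rng.normal(mean, sd, size=n)


def evaluate_site(
    true_quality: float, threshold: float, error_sd: float, rng: np.random.Generator
) -> bool:
    """One noisy assessment: accept iff quality + fresh error >= threshold."""
    if error_sd < 0:
        raise ValueError("error sd must be non-negative")
    return bool(true_quality + rng.normal(0.0, error_sd) >= threshold)


def step_ant(
    ant: AntState, config: ExperimentConfig, rng: np.random.Generator
) -> AntState:
    """Advance one ant by one decision epoch.

    Draws the next site from the discovery kernel, charges travel (or a
    one-second stay), assesses the occupied site if it is not the home
    site, and commits on acceptance.  Committed ants may not be stepped.
    """
    if ant.committed:
        raise ValueError("committed ants are absorbed and cannot be stepped")
    dest = int(rng.choice(3, p=config.discovery_prob[ant.location]))
    moved = dest != ant.location
    clock = ant.clock + (
        config.travel_time[ant.location, dest] if moved else 1.0
    )
    first = ant.first_site_found
    phase = PHASES[dest]
    if dest != OLD:
        if first is None:
            first = dest
        if evaluate_site(
            config.qualities[dest], ant.threshold, config.assessment_error_sd, rng
        ):
            phase = PHASES[3] if dest == POOR else PHASES[4]
    return replace(ant, location=dest, phase=phase, first_site_found=first, clock=clock)


def run_experiment(
    config: ExperimentConfig, keep_ants: bool = False
) -> SimulationResult | tuple[SimulationResult, pd.DataFrame]:
    """Run all ants to absorption (vectorized over the colony).

    Identical config and seed produce a bit-identical result.  Ants whose
    clock exceeds ``max_time`` before committing are reported in
    ``n_uncommitted`` and the result is flagged ``completed=False``.
    With ``keep_ants=True`` a per-ant event table (threshold, first site,
    final site, clock) is returned as well.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_ants
    thr = sample_thresholds(n, config.threshold_mean, config.threshold_sd, rng)
    qual = config.qualities
    cum = config.discovery_prob.cumsum(axis=1)

    loc = np.zeros(n, dtype=np.int8)
    clock = np.zeros(n)
    committed = np.full(n, -1, dtype=np.int8)  # -1 active, POOR or GOOD
    first = np.zeros(n, dtype=np.int8)  # 0 = none yet
    assessed_poor = np.zeros(n, dtype=bool)
    commit_time = np.zeros(n)
    active = np.arange(n)

    while active.size:
        here = loc[active]
        u = rng.random(active.size)
        dest = (u[:, None] > cum[here]).sum(axis=1).astype(np.int8)
        moved = dest != here
        clock[active] += np.where(
            moved, config.travel_time[here, dest], 1.0
        )
        loc[active] = dest

        at_site = dest != OLD
        if at_site.any():
            idx = active[at_site]
            d = dest[at_site]
            first[idx] = np.where(first[idx] == 0, d, first[idx])
            assessed_poor[idx] |= d == POOR
            noise = rng.normal(0.0, config.assessment_error_sd, idx.size)
            accept = qual[d] + noise >= thr[idx]
            cidx = idx[accept]
            committed[cidx] = d[accept]
            commit_time[cidx] = clock[cidx]

        still = (committed[active] == -1) & (clock[active] <= config.max_time)
        active = active[still]

    good = committed == GOOD
    poor = committed == POOR
    uncommitted = committed == -1
    reject_poor = assessed_poor & ~poor
    result = SimulationResult(
        n_ants=n,
        n_commit_good=int(good.sum()),
        n_commit_poor=int(poor.sum()),
        n_uncommitted=int(uncommitted.sum()),
        n_reject_poor=int(reject_poor.sum()),
        n_switch_to_good=int((good & (first == POOR)).sum()),
        n_good_rejected_poor=int((good & assessed_poor).sum()),
        n_uncommitted_rejected_poor=int((uncommitted & assessed_poor).sum()),
        duration_min=float(commit_time.max() / 60.0),
        seed=config.seed,
        completed=not uncommitted.any(),
    )
    if not keep_ants:
        return result
    ants = pd.DataFrame(
        {
            "ant": np.arange(n),
            "threshold": thr,
            "first_site": np.array(_SITE_NAMES)[first],
            "final_site": np.where(good, "good", np.where(poor, "poor", "none")),
            "clock_s": np.where(uncommitted, clock, commit_time),
        }
    )
    return result, ants


def summarize(results) -> pd.DataFrame:
    """One row per experiment, mirroring the reference summary table."""
    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    return pd.DataFrame(
        {
            "experiment": np.arange(1, len(results) + 1),
            "p_accept_good": [round(r.p_accept_good, 4) for r in results],
            "switch_rate": [round(r.switch_rate, 4) for r in results],
            "duration_min": [round(r.duration_min, 1) for r in results],
            "n_reject_poor": [r.n_reject_poor for r in results],
            "n_uncommitted": [r.n_uncommitted for r in results],
            "seed": [r.seed for r in results],
        }
    )
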