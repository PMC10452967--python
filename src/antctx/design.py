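"""The eight-experiment rank-4 cyclic design and its reference numbers.

Four distant ("good") nests q1-q4 are each presented against two of four
nearby ("poor") alternatives c1-c4.  Pairing experiments that share the
good nest gives four linked pairs whose contexts chain in a single
4-cycle: (c4,c1) -> (c1,c2) -> (c2,c3) -> (c3,c4).

The REFERENCE_* constants are the published outputs of the original
emigration runs under this design; they drive the worked example and the
zero-noise colony model, and serve as the comparison point for fresh
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "OBJECT_QUALITIES",
    "CONTEXT_QUALITIES",
    "EXPERIMENTS",
    "PAIRING",
    "REFERENCE_P_ACCEPT",
    "REFERENCE_SWITCH_RATE",
    "REFERENCE_DURATION_MIN",
    "REFERENCE_P_JOINT",
    "DesignMatrix",
    "build_design",
]

#: distant-nest (object) qualities
OBJECT_QUALITIES: dict[str, float] = {"q1": 5.0, "q2": 5.5, "q3": 6.0, "q4": 6.5}

#: nearby-nest (context) qualities
CONTEXT_QUALITIES: dict[str, float] = {"c1": 3.1, "c2": 3.6, "c3": 4.1, "c4": 4.6}

#: experiment k -> (poor quality, good quality), in design order
EXPERIMENTS: tuple[tuple[float, float], ...] = (
    (4.6, 6.5),
    (3.1, 6.5),
    (3.1, 5.0),
    (3.6, 5.0),
    (3.6, 5.5),
    (4.1, 5.5),
    (4.1, 6.0),
    (4.6, 6.0),
)

#: linked pairs (0-based experiment indices) sharing the good nest
PAIRING: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5), (6, 7))

#: published acceptance probability of the good site, experiments 1-8
REFERENCE_P_ACCEPT: tuple[float, ...] = (0.50, 0.79, 0.78, 0.68, 0.69, 0.58, 0.59, 0.49)

#: published rate of switching to the good nest (fraction of the colony)
REFERENCE_SWITCH_RATE: tuple[float, ...] = (0.18, 0.46, 0.50, 0.40, 0.38, 0.28, 0.27, 0.18)

#: published emigration durations in minutes
REFERENCE_DURATION_MIN: tuple[float, ...] = (131, 206, 497, 526, 247, 231, 168, 163)

#: published joint acceptance probabilities, one per linked pair
REFERENCE_P_JOINT: tuple[float, ...] = (0.38, 0.51, 0.40, 0.31)

_QUALITY_TO_OBJECT = {v: k for k, v in OBJECT_QUALITIES.items()}
_QUALITY_TO_CONTEXT = {v: k for k, v in CONTEXT_QUALITIES.items()}


@dataclass(frozen=True)
class DesignMatrix:
    """The full design: qualities, the 8 (poor, good) experiments and linkage."""

    objects: dict[str, float]
    contexts: dict[str, float]
    experiments: tuple[tuple[float, float], ...]
    pairing: tuple[tuple[int, int], ...]

    def content_label(self, pair_index: int) -> str:
        good = self.experiments[self.pairing[pair_index][0]][1]
        return _QUALITY_TO_OBJECT[good]

    def context_labels(self, pair_index: int) -> tuple[str, str]:
        i, j = self.pairing[pair_index]
        return (
            _QUALITY_TO_CONTEXT[self.experiments[i][0]],
            _QUALITY_TO_CONTEXT[self.experiments[j][0]],
        )


def build_design() -> DesignMatrix:
    """The rank-4 design exactly as run in the study this package reproduces."""
    d = DesignMatrix(
        objects=dict(OBJECT_QUALITIES),
        contexts=dict(CONTEXT_QUALITIES),
        experiments=EXPERIMENTS,
        pairing=PAIRING,
    )
    for k, (i, j) in enumerate(d.pairing):
        if d.experiments[i][1] != d.experiments[j][1]:
            raise AssertionError(f"pair {k} does not share a good nest")
    return d
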