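"""Quantitative scoring of immunohistochemistry / immunofluorescence observations.

Raw inputs are cell counts, percent-positive values and 0-3 staining
intensity grades; this module turns them into per-case marker trajectories,
baseline-normalized series and the proliferation/apoptosis growth index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TWO_SCORE_MARKERS",
    "PERCENT_ONLY_MARKERS",
    "ZERO_SCORE_FLOOR",
    "IHCObservation",
    "MarkerTrajectory",
    "GrowthIndexSeries",
    "ki67_score",
    "composite_score",
    "h2ax_index",
    "floor_score",
    "normalize_to_baseline",
    "growth_index",
]

#: Markers quantified with the two-score (percent x intensity) system.
TWO_SCORE_MARKERS = frozenset({"CASP3", "P53", "P21", "MDM2"})
#: Markers quantified as percent positive only.
PERCENT_ONLY_MARKERS = frozenset({"Ki67", "gH2AX", "ER", "PR"})

#: Composite scores of exactly 0 are replaced by this value before any
#: ratio or baseline normalization (half the minimal nonzero composite
#: unit: 1% positivity at intensity 1).  Keeps ratios total.
ZERO_SCORE_FLOOR = 0.5

VALID_ARMS = ("vehicle", "doxo")
VALID_INTENSITIES = (0, 1, 2, 3)


class ScoreError(ValueError):
    """Raised for undefined or out-of-range scoring inputs."""


@dataclass(frozen=True)
class IHCObservation:
    """One (case, marker, arm, timepoint) staining measurement."""

    case_id: str
    marker: str
    arm: str
    time_h: float
    percent_positive: float
    intensity: int | None = None

    def __post_init__(self) -> None:
        if self.arm not in VALID_ARMS:
            raise ScoreError(f"unknown arm {self.arm!r}; expected one of {VALID_ARMS}")
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ScoreError(
                f"percent_positive {self.percent_positive} outside [0, 100] "
                f"for case {self.case_id}, marker {self.marker}"
            )
        if self.marker in PERCENT_ONLY_MARKERS:
            if self.intensity is not None:
                raise ScoreError(f"marker {self.marker} is percent-only; intensity must be absent")
        elif self.intensity is not None and self.intensity not in VALID_INTENSITIES:
            raise ScoreError(f"intensity {self.intensity} outside {{0,1,2,3}}")

    @property
    def score(self) -> float:
        """Scalar score: percent for percent-only markers, composite otherwise."""
        if self.intensity is None:
            return self.percent_positive
        return composite_score(self.percent_positive, self.intensity)


def ki67_score(positive_cells: int, total_tumor_cells: int) -> float:
    """Percentage of positive cells over the entire tumor cell population."""
    if total_tumor_cells <= 0:
        raise ScoreError("score undefined: total tumor cell count must be > 0")
    if positive_cells < 0 or positive_cells > total_tumor_cells:
        raise ScoreError(
            f"positive count {positive_cells} outside [0, {total_tumor_cells}]"
        )
    return 100.0 * positive_cells / total_tumor_cells


def composite_score(percent_positive: float, intensity: int) -> float:
    """Two-score composite: percent positive x intensity grade, range 0-300.

    The percent/intensity pair is also reported separately downstream; all
    quantification in this package uses the product (H-score convention).
    """
    if not 0.0 <= percent_positive <= 100.0:
        raise ScoreError(f"percent_positive {percent_positive} outside [0, 100]")
    if intensity not in VALID_INTENSITIES:
        raise ScoreError(f"intensity {intensity} outside {{0,1,2,3}}")
    return float(percent_positive) * int(intensity)


def h2ax_index(positive_cells: int, cells_scored: int = 100) -> float:
    """Percentage of phospho-H2AX-positive cells among cells scored."""
    return ki67_score(positive_cells, cells_scored)


def floor_score(score: float, floor: float = ZERO_SCORE_FLOOR) -> float:
    """Apply the zero-score floor used before ratios and normalization."""
    if score < 0:
        raise ScoreError(f"negative score {score}")
    return max(float(score), floor)


@dataclass(frozen=True)
class MarkerTrajectory:
    """Time series of scores for one (case, marker, arm)."""

    case_id: str
    marker: str
    arm: str
    times_h: tuple[float, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.scores):
            raise ScoreError("times and scores length mismatch")
        if list(self.times_h) != sorted(self.times_h):
            order = np.argsort(self.times_h)
            object.__setattr__(self, "times_h", tuple(self.times_h[i] for i in order))
            object.__setattr__(self, "scores", tuple(self.scores[i] for i in order))
        if len(set(self.times_h)) != len(self.times_h):
            raise ScoreError(f"duplicate timepoints in trajectory {self.case_id}/{self.marker}/{self.arm}")

    def at(self, time_h: float) -> float:
        try:
            return self.scores[self.times_h.index(time_h)]
        except ValueError:
            raise ScoreError(
                f"timepoint {time_h} h missing from trajectory "
                f"{self.case_id}/{self.marker}/{self.arm} (has {self.times_h})"
            ) from None

    @classmethod
    def from_observations(cls, observations: Sequence[IHCObservation]) -> "MarkerTrajectory":
        keys = {(o.case_id, o.marker, o.arm) for o in observations}
        if len(keys) != 1:
            raise ScoreError(f"observations span multiple (case, marker, arm) keys: {sorted(keys)}")
        case_id, marker, arm = keys.pop()
        obs = sorted(observations, key=lambda o: o.time_h)
        return cls(
            case_id=case_id,
            marker=marker,
            arm=arm,
            times_h=tuple(o.time_h for o in obs),
            scores=tuple(o.score for o in obs),
        )


@dataclass(frozen=True)
class GrowthIndexSeries:
    """Baseline-normalized Ki-67 / cleaved-caspase-3 ratio per timepoint."""

    case_id: str
    arm: str
    times_h: tuple[float, ...]
    gi: tuple[float, ...]
    raw_ratio: tuple[float, ...] = field(default=())


def normalize_to_baseline(traj: MarkerTrajectory, floor: float = ZERO_SCORE_FLOOR) -> MarkerTrajectory:
    """Express every timepoint as percent of the T0 score (T0 -> 100).

    Scores are floored (see :data:`ZERO_SCORE_FLOOR`) before the ratio so
    a zero baseline never divides by zero.
    """
    if 0.0 not in traj.times_h:
        raise ScoreError(
            f"baseline T0 missing from trajectory {traj.case_id}/{traj.marker}/{traj.arm}"
        )
    floored = [floor_score(s, floor) for s in traj.scores]
    t0 = floored[traj.times_h.index(0.0)]
    return MarkerTrajectory(
        case_id=traj.case_id,
        marker=traj.marker,
        arm=traj.arm,
        times_h=traj.times_h,
        scores=tuple(100.0 * s / t0 for s in floored),
    )


def growth_index(
    ki67: MarkerTrajectory, casp3: MarkerTrajectory, floor: float = ZERO_SCORE_FLOOR
) -> GrowthIndexSeries:
    """Pointwise Ki-67 / caspase-3 ratio, baseline-normalized so GI(T0) = 1."""
    if (ki67.case_id, ki67.arm) != (casp3.case_id, casp3.arm):
        raise ScoreError(
            f"trajectory mismatch: {ki67.case_id}/{ki67.arm} vs {casp3.case_id}/{casp3.arm}"
        )
    missing = set(ki67.times_h) ^ set(casp3.times_h)
    if missing:
        raise ScoreError(f"timepoint mismatch between Ki-67 and caspase-3: {sorted(missing)}")
    if 0.0 not in ki67.times_h:
        raise ScoreError(f"baseline T0 missing for case {ki67.case_id}")
    times = ki67.times_h
    ratio = tuple(
        floor_score(ki67.at(t), floor) / floor_score(casp3.at(t), floor) for t in times
    )
    r0 = ratio[times.index(0.0)]
    return GrowthIndexSeries(
        case_id=ki67.case_id,
        arm=ki67.arm,
        times_h=times,
        gi=tuple(r / r0 for r in ratio),
        raw_ratio=ratio,
    )
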