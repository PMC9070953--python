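"""Barrier-crossing statistics.

A track "terminates at the barrier" when its final midpoint lies within the
untrackable dead zone plus a termination margin of the barrier midline along
the odor axis.  Such tracks are classified by where they started and which
way they were moving over a trailing time window:

* ``reversal`` - started inside the termination band too (discounted);
* ``forward``  - net odor-axis displacement over the trailing window is
  toward the odor;
* ``reverse``  - net displacement away from the odor;
* ``none``     - the track does not terminate at the barrier.

Cumulative net crossings are (forward - reverse) counts normalized by the
estimated animal count, evaluated at checkpoint times (default 15/30/45 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedIndexError, UnitError
from .geometry_io import MM, Arena, Track, TrackSet

DEFAULT_CHECKPOINTS = (900.0, 1800.0, 2700.0)

FORWARD = "forward"
REVERSE = "reverse"
REVERSAL = "reversal"
NONE = "none"


@dataclass(frozen=True)
class TerminationLabel:
    track_id: str
    label: str
    termination_time: float | None = None


@dataclass(frozen=True)
class PlateCounts:
    n_odor_side: int
    n_origin_side: int

    def __post_init__(self) -> None:
        if self.n_odor_side < 0 or self.n_origin_side < 0:
            raise ValueError("plate counts must be >= 0")


@dataclass(eq=False)
class CrossingSummary:
    animal_count: int
    checkpoints: tuple[float, ...]
    forward: np.ndarray  # cumulative counts per checkpoint
    reverse: np.ndarray
    net: np.ndarray
    fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "checkpoint_s": list(self.checkpoints),
                "forward": self.forward,
                "reverse": self.reverse,
                "net": self.net,
                "fraction": self.fractions,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def _signed_axis(track: Track, arena: Arena) -> np.ndarray:
    return (track.x - arena.barrier_x) * arena.odor_sign


def classify_terminations(
    track_set: TrackSet, arena: Arena | None = None
) -> list[TerminationLabel]:
    """Label every track as forward / reverse / reversal / none."""
    arena = arena or track_set.arena
    if arena.barrier_x is None:
        raise ConfigurationError("arena.barrier_x is required")
    if track_set.units not in (None, MM):
        raise UnitError("classify_terminations requires mm-calibrated tracks")
    band = arena.dead_zone_halfwidth + arena.termination_margin
    labels: list[TerminationLabel] = []
    for t in track_set:
        s = _signed_axis(t, arena)
        if abs(s[-1]) > band:
            labels.append(TerminationLabel(t.track_id, NONE, None))
            continue
        t_end = float(t.time[-1])
        if abs(s[0]) <= band:
            labels.append(TerminationLabel(t.track_id, REVERSAL, t_end))
            continue
        # net displacement over the trailing direction window
        ref = int(np.searchsorted(t.time, t_end - arena.direction_window, side="left"))
        ref = min(ref, t.n_points - 1)
        disp = float(s[-1] - s[ref])
        if disp > 0:
            label = FORWARD
        elif disp < 0:
            label = REVERSE
        else:
            # no net approach direction: cannot be credited as a crossing
            label = REVERSAL
        labels.append(TerminationLabel(t.track_id, label, t_end))
    return labels


def labels_to_frame(labels: Iterable[TerminationLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": l.track_id,
                "label": l.label,
                "termination_time_s": l.termination_time,
            }
            for l in labels
        ],
        columns=["track_id", "label", "termination_time_s"],
    )


def cumulative_crossings(
    labels: Sequence[TerminationLabel],
    animal_count: int,
    checkpoints: Sequence[float] = DEFAULT_CHECKPOINTS,
) -> CrossingSummary:
    """Cumulative forward/reverse/net counts and net fractions at checkpoints.

    ``fraction = (forward - reverse) / animal_count``; reversal and none
    labels contribute nothing.
    """
    if animal_count < 1:
        raise UndefinedIndexError(
            "animal_count must be >= 1 to normalize crossing fractions"
        )
    cps = tuple(float(c) for c in checkpoints)
    if list(cps) != sorted(cps):
        raise ConfigurationError("checkpoints must be sorted ascending")
    fwd_times = np.array(
        [l.termination_time for l in labels if l.label == FORWARD], dtype=float
    )
    rev_times = np.array(
        [l.termination_time for l in labels if l.label == REVERSE], dtype=float
    )
    forward = np.array([(fwd_times <= c).sum() for c in cps], dtype=int)
    reverse = np.array([(rev_times <= c).sum() for c in cps], dtype=int)
    net = forward - reverse
    return CrossingSummary(
        animal_count=int(animal_count),
        checkpoints=cps,
        forward=forward,
        reverse=reverse,
        net=net,
        fractions=net / float(animal_count),
    )


def chemotactic_index(counts: PlateCounts) -> float:
    """Animals on the odor side divided by all animals on the plate."""
    total = counts.n_odor_side + counts.n_origin_side
    if total <= 0:
        raise UndefinedIndexError("chemotactic index undefined for zero animals")
    return counts.n_odor_side / total
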