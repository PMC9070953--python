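"""Track exclusion filters.

A track is rejected if it meets any of four criteria, evaluated in this
order for the audit label:

1. any midpoint falls inside a user-supplied exclusion region (shadows or
   markings on the plate; boundary counts as inside);
2. it lasts less than ``min_duration`` seconds (from timestamps, so dropped
   frames do not shorten a track);
3. its bounding-box area is below ``min_bbox_area`` square pixels
   (alternatively, with ``bbox_metric="path_length"``, its total path length
   is below the same threshold in pixels);
4. its largest axis-aligned span is below ``min_span`` pixels.

Thresholds are in pixel units by default; a criteria set converted with
:meth:`FilterCriteria.scaled` can be applied to mm-calibrated tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError, UnitError
from .geometry_io import PIXEL, Track, TrackSet

#: Rectangle as (x0, y0, x1, y1); corners may be given in any order.
Rect = tuple[float, float, float, float]

CRITERION_NAMES = {
    1: "exclusion_region",
    2: "too_short",
    3: "too_small_area",
    4: "too_small_span",
}


@dataclass(frozen=True)
class FilterCriteria:
    min_duration: float = 10.0
    min_bbox_area: float = 30.0
    min_span: float = 10.0
    exclusion_regions: tuple[Rect, ...] = ()
    bbox_metric: str = "area"  # or "path_length"
    units: str = PIXEL

    def __post_init__(self) -> None:
        if min(self.min_duration, self.min_bbox_area, self.min_span) < 0:
            raise ConfigurationError("filter thresholds must be >= 0")
        if self.bbox_metric not in ("area", "path_length"):
            raise ConfigurationError(
                f"bbox_metric must be 'area' or 'path_length', got {self.bbox_metric!r}"
            )
        object.__setattr__(
            self,
            "exclusion_regions",
            tuple(tuple(float(v) for v in r) for r in self.exclusion_regions),
        )

    def scaled(self, pixel_scale: float) -> "FilterCriteria":
        """Return the equivalent criteria in mm for calibrated tracks."""
        if self.units != PIXEL:
            return self
        area = (
            self.min_bbox_area * pixel_scale * pixel_scale
            if self.bbox_metric == "area"
            else self.min_bbox_area * pixel_scale
        )
        return replace(
            self,
            min_bbox_area=area,
            min_span=self.min_span * pixel_scale,
            exclusion_regions=tuple(
                tuple(v * pixel_scale for v in r) for r in self.exclusion_regions
            ),
            units="mm",
        )


@dataclass(eq=False)
class FilterReport:
    kept: TrackSet
    rejected: list[tuple[str, int]]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"track_id": t.track_id, "rejected_by": 0, "criterion": "kept"}
            for t in self.kept
        ]
        rows += [
            {"track_id": tid, "rejected_by": c, "criterion": CRITERION_NAMES[c]}
            for tid, c in self.rejected
        ]
        return pd.DataFrame(rows, columns=["track_id", "rejected_by", "criterion"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")


def _in_region(track: Track, region: Rect) -> bool:
    x0, y0, x1, y1 = region
    xlo, xhi = min(x0, x1), max(x0, x1)
    ylo, yhi = min(y0, y1), max(y0, y1)
    inside = (track.x >= xlo) & (track.x <= xhi) & (track.y >= ylo) & (track.y <= yhi)
    return bool(inside.any())


def first_rejection(track: Track, criteria: FilterCriteria) -> int:
    """Return the number (1-4) of the first matching exclusion criterion, 0 if kept."""
    if any(_in_region(track, r) for r in criteria.exclusion_regions):
        return 1
    if track.duration < criteria.min_duration:
        return 2
    travelled = (
        track.bbox_area if criteria.bbox_metric == "area" else track.path_length
    )
    if travelled < criteria.min_bbox_area:
        return 3
    if max(track.x_span, track.y_span) < criteria.min_span:
        return 4
    return 0


def filter_tracks(
    track_set: TrackSet, criteria: FilterCriteria | None = None
) -> FilterReport:
    """Partition a TrackSet into kept tracks and an audit of rejections.

    Raises :class:`UnitError` when the track units do not match the units the
    thresholds are expressed in (use :meth:`FilterCriteria.scaled` first).
    """
    criteria = criteria or FilterCriteria()
    if track_set.units is not None and track_set.units != criteria.units:
        raise UnitError(
            f"tracks are in {track_set.units!r} but thresholds are in "
            f"{criteria.units!r}; convert with FilterCriteria.scaled()"
        )
    kept: list[Track] = []
    rejected: list[tuple[str, int]] = []
    for t in track_set:
        c = first_rejection(t, criteria)
        if c:
            rejected.append((t.track_id, c))
        else:
            kept.append(t)
    return FilterReport(
        kept=TrackSet(
            tracks=kept,
            arena=track_set.arena,
            condition_label=track_set.condition_label,
            source=track_set.source,
        ),
        rejected=rejected,
    )
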