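"""Synthetic worm-track generator with full ground truth.

Each animal is a persistent random walk: per step the heading receives
wrapped-normal angular noise whose standard deviation is derived from the
per-step heading correlation (sigma = sqrt(-2 ln rho)), plus a weak drift
toward the odor; the step length follows a distance-dependent speed law with
multiplicative lognormal noise.  On encountering the barrier's dead zone the
animal crosses with a configurable probability (the track is truncated at
the dead-zone edge and a crossing event recorded) or turns away and is held
on an away heading for a short refractory period.  Crossed animals may
re-emerge on the far side and cross back, emitted as a new track because the
tracker cannot follow animals through the marker zone.

This is deliberately NOT a biophysical worm model: it is the minimal
generative process giving the analysis pipeline exact, known ground truth.
Tracks whose natural end (assay end) would fall inside the termination band
are trimmed back to their last point outside the band, so that termination
classification matches the recorded crossing events exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import UnitError, ValidationError
from .geometry_io import MM, PIXEL, Arena, Track, TrackSet
from .track_filter import CRITERION_NAMES, FilterCriteria, Rect

#: Speed law: ((signed distance mm, mean speed um/s), ...) interpolation knots.
SpeedLaw = tuple[tuple[float, float], ...]

DEFECT_CLASSES = ("too_short", "too_small_area", "too_small_span", "in_exclusion_region")
DEFECT_CRITERION = {
    "in_exclusion_region": 1,
    "too_short": 2,
    "too_small_area": 3,
    "too_small_span": 4,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_animals: int = 25
    duration: float = 2700.0
    frame_rate: float = 3.0
    arena: Arena = field(default_factory=Arena)
    base_speed: float = 200.0  # um/s, used when speed_vs_distance is None
    speed_vs_distance: SpeedLaw | None = None
    heading_persistence: float = 0.97
    odor_bias: float = 0.04  # drift of heading toward the odor, rad per step
    crossing_propensity: float = 0.3
    reversal_propensity: float = 0.1
    start_zone: tuple[float, float] = (2.0, 7.0)  # x interval, mm
    noise_tracks: dict = field(default_factory=dict)
    exclusion_regions: tuple[Rect, ...] = ()  # pixel rects, for planted defects
    seed: int = 0
    label: str = ""
    # generative-process constants (documented, configurable)
    step_noise_sd: float = 0.2  # lognormal sigma of multiplicative step noise
    encounter_band: float = 0.15  # mm beyond the dead zone that triggers a roll
    refractory_time: float = 3.0  # s held on an away heading after a refusal
    emergence_offset: float = 0.5  # mm beyond the termination band for re-emergence
    spawn_delay: tuple[float, float] = (10.0, 30.0)  # s before re-emergence

    def validate(self) -> None:
        a = self.arena
        if self.n_animals < 0:
            raise ValidationError("n_animals must be >= 0")
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        if abs(self.frame_rate - a.frame_rate) > 1e-9:
            raise ValidationError(
                "frame_rate: config and arena frame rates disagree"
            )
        for name in ("crossing_propensity", "reversal_propensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.heading_persistence < 1.0):
            raise ValidationError("heading_persistence must lie in [0, 1)")
        if self.base_speed < 0:
            raise ValidationError("base_speed must be >= 0")
        if self.speed_vs_distance is not None:
            xs = [k[0] for k in self.speed_vs_distance]
            if xs != sorted(xs):
                raise ValidationError(
                    "speed_vs_distance knots must be sorted by distance"
                )
            if any(k[1] < 0 for k in self.speed_vs_distance):
                raise ValidationError("speed_vs_distance speeds must be >= 0")
        clearance = a.dead_zone_halfwidth + self.encounter_band + 1.0
        if min(a.barrier_x, a.fov_width - a.barrier_x) <= clearance:
            raise ValidationError(
                "arena: the barrier must sit at least the encounter band plus "
                "1 mm away from both x walls"
            )
        lo, hi = self.start_zone
        if not (0.0 <= lo < hi <= a.fov_width):
            raise ValidationError("start_zone must be an interval inside the arena")
        band = a.dead_zone_halfwidth + a.termination_margin + self.encounter_band
        if min(abs(lo - a.barrier_x), abs(hi - a.barrier_x)) <= band or (
            lo < a.barrier_x < hi
        ):
            raise ValidationError(
                "start_zone must lie entirely on one side of the barrier, "
                "outside the termination band"
            )
        bad = set(self.noise_tracks) - set(DEFECT_CLASSES)
        if bad:
            raise ValidationError(f"noise_tracks: unknown defect classes {sorted(bad)}")
        if any(v < 0 for v in self.noise_tracks.values()):
            raise ValidationError("noise_tracks counts must be >= 0")

    def speed_law_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self.speed_vs_distance is None:
            return np.array([0.0]), np.array([self.base_speed])
        knots = np.asarray(self.speed_vs_distance, dtype=float)
        return knots[:, 0], knots[:, 1]


@dataclass(frozen=True)
class CrossingEvent:
    track_id: str
    time: float
    direction: str  # "forward" or "reverse"


@dataclass(frozen=True)
class ReversalEvent:
    parent_id: str
    child_id: str
    spawn_time: float


@dataclass(eq=False)
class GroundTruth:
    crossing_events: list[CrossingEvent]
    reversal_events: list[ReversalEvent]
    defect_labels: dict[str, str]  # track_id -> defect class
    speed_law: SpeedLaw | None
    animal_count: int

    def counts(self) -> tuple[int, int]:
        fwd = sum(1 for e in self.crossing_events if e.direction == "forward")
        rev = sum(1 for e in self.crossing_events if e.direction == "reverse")
        return fwd, rev

    def to_dict(self) -> dict:
        return {
            "animal_count": self.animal_count,
            "speed_law": self.speed_law,
            "crossing_events": [
                {"track_id": e.track_id, "time_s": e.time, "direction": e.direction}
                for e in self.crossing_events
            ],
            "reversal_events": [
                {
                    "parent_id": e.parent_id,
                    "child_id": e.child_id,
                    "spawn_time_s": e.spawn_time,
                }
                for e in self.reversal_events
            ],
            "defect_labels": self.defect_labels,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _reflect(v: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    flipped = (v < lo) | (v > hi)
    v = np.where(v < lo, 2 * lo - v, v)
    v = np.where(v > hi, 2 * hi - v, v)
    return np.clip(v, lo, hi), flipped


# walker states
_UNBORN, _FREE, _REFRACT, _BEELINE, _DONE = 0, 1, 2, 3, 4


def simulate_experiment(
    config: SimulationConfig, seed: int | None = None
) -> tuple[TrackSet, GroundTruth]:
    """Generate one experiment's TrackSet (pixel units) plus its ground truth.

    Identical (config, seed) pairs give identical output.  The seed defaults
    to ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    a = config.arena
    sgn, bx = a.odor_sign, a.barrier_x
    dzh = a.dead_zone_halfwidth
    fr = config.frame_rate
    F = int(round(config.duration * fr))
    n = config.n_animals
    W = 2 * n  # each primary may spawn at most one re-emergence walker
    enc = dzh + config.encounter_band
    band_term = dzh + a.termination_margin
    refract_frames = max(1, math.ceil(config.refractory_time * fr))
    rho = config.heading_persistence
    sigma_theta = math.sqrt(-2.0 * math.log(rho)) if rho > 0 else math.pi
    phi_odor = 0.0 if sgn > 0 else math.pi
    law_x, law_y = config.speed_law_arrays()

    X = np.full((W, F + 1), np.nan)
    Y = np.full((W, F + 1), np.nan)
    x = np.zeros(W)
    y = np.zeros(W)
    phi = np.zeros(W)
    state = np.full(W, _UNBORN, dtype=np.int64)
    born = np.full(W, -1, dtype=np.int64)
    died = np.full(W, -1, dtype=np.int64)
    crossp = np.full(W, config.crossing_propensity)
    refract = np.zeros(W, dtype=np.int64)
    spawn_frame = np.full(W, -1, dtype=np.int64)
    spawn_x = np.zeros(W)
    spawn_y = np.zeros(W)
    events: dict[int, tuple[int, str]] = {}  # walker -> (last frame, direction)
    reversal_pairs: list[tuple[int, int]] = []

    if n > 0:
        x[:n] = rng.uniform(config.start_zone[0], config.start_zone[1], n)
        margin_y = min(1.0, a.fov_height / 4)
        y[:n] = rng.uniform(margin_y, a.fov_height - margin_y, n)
        phi[:n] = rng.uniform(-math.pi, math.pi, n)
        state[:n] = _FREE
        born[:n] = 0
        X[:n, 0] = x[:n]
        Y[:n, 0] = y[:n]

    def _terminate(w: int, t: int) -> None:
        state[w] = _DONE
        died[w] = t - 1
        s_here = (x[w] - bx) * sgn
        direction = "forward" if s_here < 0 else "reverse"
        events[w] = (t - 1, direction)
        if w < n and rng.random() < config.reversal_propensity:
            delay = int(round(rng.uniform(*config.spawn_delay) * fr))
            tf = t + delay
            if tf <= F - refract_frames:
                side = 1.0 if s_here < 0 else -1.0  # new side, odor-axis sign
                spawn_frame[n + w] = tf
                off = band_term + config.emergence_offset
                spawn_x[n + w] = bx + sgn * side * off
                spawn_y[n + w] = float(np.clip(y[w], 1.0, a.fov_height - 1.0))
                crossp[n + w] = 1.0
                reversal_pairs.append((w, n + w))

    for t in range(1, F + 1):
        fresh = np.flatnonzero(spawn_frame == t)
        for w in fresh:
            state[w] = _FREE
            born[w] = t
            x[w], y[w] = spawn_x[w], spawn_y[w]
            phi[w] = 0.0 if x[w] < bx else math.pi  # head back toward the barrier
            X[w, t] = x[w]
            Y[w, t] = y[w]
        live = (state == _FREE) | (state == _REFRACT) | (state == _BEELINE)
        live &= born < t  # just-activated walkers move from the next frame
        # draw full-width noise every frame so the stream is state-independent
        step_noise = rng.lognormal(
            -0.5 * config.step_noise_sd**2, config.step_noise_sd, W
        )
        ang_noise = rng.normal(0.0, sigma_theta, W)
        rolls = rng.random(W)
        if not live.any():
            any_alive = (
                (state == _FREE) | (state == _REFRACT) | (state == _BEELINE)
            ).any()
            if not any_alive and not (spawn_frame > t).any():
                break
            continue
        s = (x - bx) * sgn
        speed = np.interp(s, law_x, law_y)  # um/s
        step = speed / 1000.0 / fr * step_noise
        free = live & (state == _FREE)
        refr = live & (state == _REFRACT)
        bee = live & (state == _BEELINE)
        away = np.where(x >= bx, 0.0, math.pi)
        toward = np.where(x >= bx, math.pi, 0.0)
        phi = np.where(
            free, phi - config.odor_bias * np.sin(phi - phi_odor) + ang_noise, phi
        )
        phi = np.where(refr, away, phi)
        phi = np.where(bee, toward, phi)
        nx = x + step * np.cos(phi)
        ny = y + step * np.sin(phi)
        nx, flipx = _reflect(nx, 0.0, a.fov_width)
        ny, flipy = _reflect(ny, 0.0, a.fov_height)
        phi = np.where(flipx & live, math.pi - phi, phi)
        phi = np.where(flipy & live, -phi, phi)
        ndist = np.abs(nx - bx)

        # ongoing beelines: terminate when the next step would enter the dead zone
        for w in np.flatnonzero(bee):
            if ndist[w] < dzh:
                _terminate(w, t)
            else:
                x[w], y[w] = nx[w], ny[w]

        # free walkers encountering the barrier band roll the crossing dice
        encounter = free & (ndist <= enc)
        for w in np.flatnonzero(encounter):
            if rolls[w] < crossp[w]:
                state[w] = _BEELINE
                d = 1.0 if bx > x[w] else -1.0
                bx2 = x[w] + d * step[w]
                if abs(bx2 - bx) < dzh:
                    _terminate(w, t)
                else:
                    x[w] = bx2
                    phi[w] = 0.0 if d > 0 else math.pi
            else:
                state[w] = _REFRACT
                refract[w] = refract_frames
                phi[w] = 0.0 if x[w] >= bx else math.pi
                # position unchanged this frame

        # free walkers clear of the barrier just move
        clear = free & ~encounter
        x = np.where(clear, nx, x)
        y = np.where(clear, ny, y)

        # refractory walkers move away and are released once clear of the band
        for w in np.flatnonzero(refr):
            x[w], y[w] = nx[w], ny[w]
            refract[w] -= 1
            if refract[w] <= 0 and abs(x[w] - bx) > enc + 0.05:
                state[w] = _FREE

        rec = (state == _FREE) | (state == _REFRACT) | (state == _BEELINE)
        rec &= born <= t
        X[rec, t] = x[rec]
        Y[rec, t] = y[rec]

    alive = (state == _FREE) | (state == _REFRACT) | (state == _BEELINE)
    died[alive] = F

    scale = a.pixel_scale
    if scale is None:
        raise ValidationError("arena.pixel_scale is required to emit pixel tracks")
    tracks: list[Track] = []
    id_of: dict[int, str] = {}
    crossing_events: list[CrossingEvent] = []
    for w in range(W):
        if born[w] < 0 or died[w] < born[w]:
            continue
        fa = np.arange(born[w], died[w] + 1)
        xs = X[w, born[w] : died[w] + 1].copy()
        ys = Y[w, born[w] : died[w] + 1].copy()
        if w not in events:
            # trim a natural track end back outside the termination band
            last = xs.size - 1
            while last > 0 and abs(xs[last] - bx) <= band_term:
                last -= 1
            fa, xs, ys = fa[: last + 1], xs[: last + 1], ys[: last + 1]
        tid = f"worm-{w:03d}"
        id_of[w] = tid
        tracks.append(
            Track(
                track_id=tid,
                frame=fa,
                time=fa / fr,
                x=xs / scale,
                y=ys / scale,
                units=PIXEL,
            )
        )
        if w in events:
            ef, direction = events[w]
            crossing_events.append(CrossingEvent(tid, ef / fr, direction))

    track_set = TrackSet(
        tracks=tracks,
        arena=a,
        condition_label=config.label,
        source=f"simulate_experiment(seed={config.seed if seed is None else seed})",
    )
    truth = GroundTruth(
        crossing_events=crossing_events,
        reversal_events=[
            ReversalEvent(id_of[p], id_of[c], born[c] / fr)
            for p, c in reversal_pairs
            if c in id_of
        ],
        defect_labels={},
        speed_law=config.speed_vs_distance,
        animal_count=n,
    )
    if config.noise_tracks:
        track_set, labels = inject_noise_tracks(track_set, config)
        truth.defect_labels = labels
    return track_set, truth


# ---------------------------------------------------------------------------
# condition pair and planted-defect tracks

WF_SPEED_LAW: SpeedLaw = ((-24, 220), (-8, 210), (-3, 140), (0, 120), (24, 210))
FD_SPEED_LAW: SpeedLaw = (
    (-24, 140),
    (-12, 195),
    (-5, 200),
    (-2, 140),
    (0, 120),
    (24, 200),
)


def make_wf_fd_pair(
    base: SimulationConfig,
) -> tuple[SimulationConfig, SimulationConfig]:
    """Well-fed / food-deprived config pair sharing every other field.

    The food-deprived config crosses more readily, drifts harder toward the
    barrier (elevating near-barrier residence), and is slower far from the
    barrier; the well-fed config is fast far out and slows near the barrier.
    """
    base.validate()
    wf = replace(
        base,
        label="well-fed",
        crossing_propensity=0.01,
        odor_bias=0.001,
        base_speed=220.0,
        speed_vs_distance=WF_SPEED_LAW,
    )
    fd = replace(
        base,
        label="food-deprived",
        crossing_propensity=0.02,
        odor_bias=0.04,
        base_speed=140.0,
        speed_vs_distance=FD_SPEED_LAW,
    )
    return wf, fd


def _anchor_clear_of(
    regions: Sequence[Rect], fov_px: float, extent: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Pick a placement origin whose extent-sized box avoids all regions."""
    for _ in range(200):
        ax = rng.uniform(0.02 * fov_px, 0.3 * fov_px)
        ay = rng.uniform(0.6 * fov_px, 0.95 * fov_px - extent)
        ok = True
        for x0, y0, x1, y1 in regions:
            xlo, xhi = min(x0, x1) - extent, max(x0, x1) + extent
            ylo, yhi = min(y0, y1) - extent, max(y0, y1) + extent
            if xlo <= ax <= xhi and ylo <= ay <= yhi:
                ok = False
                break
        if ok:
            return ax, ay
    raise ValidationError("could not place a noise track clear of exclusion regions")


def inject_noise_tracks(
    track_set: TrackSet,
    config: SimulationConfig,
    criteria: FilterCriteria | None = None,
) -> tuple[TrackSet, dict[str, str]]:
    """Append degenerate tracks each violating exactly one exclusion criterion.

    Counts per defect class come from ``config.noise_tracks``; returns the
    augmented TrackSet and a map of planted track id -> defect class.
    """
    config.validate()
    if track_set.units not in (None, PIXEL):
        raise UnitError("noise tracks are planted in pixel units")
    criteria = criteria or FilterCriteria(
        exclusion_regions=tuple(config.exclusion_regions)
    )
    counts = {c: int(config.noise_tracks.get(c, 0)) for c in DEFECT_CLASSES}
    if sum(counts.values()) == 0:
        return track_set, {}
    a = config.arena
    scale = a.pixel_scale or 1.0
    fov_px = a.fov_width / scale
    fr = config.frame_rate
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))

    span_ok = max(criteria.min_span * 2, math.sqrt(criteria.min_bbox_area) * 2, 40.0)
    small_span = 0.9 * criteria.min_span
    if counts["too_small_span"] and small_span * small_span < criteria.min_bbox_area:
        raise ValidationError(
            "too_small_span tracks are impossible: any track with both spans "
            f"below min_span={criteria.min_span} has bounding-box area at most "
            f"{criteria.min_span ** 2:.3g} < min_bbox_area={criteria.min_bbox_area}; "
            "lower min_bbox_area or raise min_span"
        )
    if counts["in_exclusion_region"] and not criteria.exclusion_regions:
        raise ValidationError(
            "in_exclusion_region tracks need at least one exclusion region"
        )

    def _frames(duration_s: float) -> np.ndarray:
        return np.arange(int(round(duration_s * fr)) + 1)

    new_tracks = list(track_set.tracks)
    labels: dict[str, str] = {}
    long_dur = max(criteria.min_duration * 1.5, criteria.min_duration + 5.0)
    short_dur = max(criteria.min_duration - 1.5, criteria.min_duration * 0.85)
    for cls in DEFECT_CLASSES:
        for k in range(counts[cls]):
            if cls == "in_exclusion_region":
                x0, y0, x1, y1 = criteria.exclusion_regions[0]
                ax, ay = (x0 + x1) / 2, (y0 + y1) / 2
                f = _frames(long_dur)
                ramp = np.linspace(-span_ok / 2, span_ok / 2, f.size)
                xs, ys = ax + ramp, ay + ramp
            elif cls == "too_short":
                ax, ay = _anchor_clear_of(
                    criteria.exclusion_regions, fov_px, span_ok, rng
                )
                f = _frames(short_dur)
                ramp = np.linspace(0.0, span_ok, f.size)
                xs, ys = ax + ramp, ay + ramp
            elif cls == "too_small_area":
                ax, ay = _anchor_clear_of(
                    criteria.exclusion_regions, fov_px, span_ok, rng
                )
                f = _frames(long_dur)
                wide = max(criteria.min_span, criteria.min_bbox_area / 2.0) + 2.0
                thin = min(1.0, (criteria.min_bbox_area * 0.8) / max(wide, 1e-9))
                xs = ax + np.linspace(0.0, wide, f.size)
                ys = ay + np.linspace(0.0, thin, f.size)
            else:  # too_small_span
                ax, ay = _anchor_clear_of(
                    criteria.exclusion_regions, fov_px, span_ok, rng
                )
                f = _frames(long_dur)
                xs = ax + np.linspace(0.0, small_span, f.size)
                ys = ay + np.linspace(0.0, small_span, f.size)
            tid = f"noise-{cls}-{k:02d}"
            new_tracks.append(
                Track(
                    track_id=tid, frame=f, time=f / fr, x=xs, y=ys, units=PIXEL
                )
            )
            labels[tid] = cls
    return (
        TrackSet(
            tracks=new_tracks,
            arena=track_set.arena,
            condition_label=track_set.condition_label,
            source=track_set.source,
        ),
        labels,
    )
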