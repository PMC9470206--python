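"""Place-preference metrics: ROIs, exclusion rules, binning, normalization.

A two-choice place-preference assay quantifies attraction to a stimulus by
where the fish dwells and where it points.  Three dependent variables are
computed per region of interest (ROI) and period:

* ``time_pct`` — percent of tracked time spent inside the ROI band;
* ``orient_pct`` — among in-ROI frames, percent in which the fish's heading
  points toward the stimulus wall (within +-90 degrees, i.e. a strictly
  positive dot product with the inward normal);
* ``rproj`` — the per-frame heading unit vectors averaged over in-ROI
  frames, projected onto the inward normal of the stimulus wall.  Rproj lies
  in [-1, 1]: +1 means always facing the stimulus, -1 always facing away,
  0 no net directionality.

Test-period values are baseline-normalized (Δ = test − baseline, per fish,
per ROI, per metric).  A fish that never enters an ROI in a period yields
missing values that propagate into the Δs and are dropped pairwise in the
statistics, so per-comparison sample sizes may differ.

Geometry: the arena coordinate frame is the tracked square with the origin
at its lower-left corner, in cm, y up.  Trajectories store pixels; the
arena's ``px_per_cm`` maps between the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CoverageError, GeometryError
from .tracking import Trajectory

__all__ = [
    "ArenaGeometry",
    "RoiBand",
    "PeriodDesign",
    "QualifyCriteria",
    "QualifyResult",
    "PreferenceSummary",
    "define_rois",
    "qualify_fish",
    "time_in_roi_pct",
    "orientation_toward_pct",
    "rproj",
    "bin_series",
    "summarize",
    "occupancy_heatmap",
]

_WALLS = ("left", "right", "top", "bottom")
_OPPOSITE = {"left": "right", "right": "left", "top": "bottom", "bottom": "top"}
# inward normal: unit vector pointing from the arena interior toward the wall
_NORMALS = {"left": (-1.0, 0.0), "right": (1.0, 0.0), "top": (0.0, 1.0), "bottom": (0.0, -1.0)}


@dataclass(frozen=True)
class ArenaGeometry:
    """Tank/tracked-area dimensions, stimulus-wall assignment and ROI sizing.

    Defaults follow the assay: a 15 cm square tank whose inner 12 x 12 cm is
    tracked, ROI bands one adult body length deep (20% of the tank side),
    stimuli on two opposite walls.
    """

    tank_side: float = 15.0
    tracked_side: float = 12.0
    px_per_cm: float = 40.0
    stimulus_walls: Mapping[str, str] = field(
        default_factory=lambda: {"bottom": "upright BM", "top": "non-BM"}
    )
    roi_fraction: float = 0.2
    roi_reference: str = "tank"  # ROI depth = fraction x tank_side (or "tracked")

    def __post_init__(self) -> None:
        if not 0 < self.tracked_side <= self.tank_side:
            raise GeometryError("need 0 < tracked_side <= tank_side")
        if self.px_per_cm <= 0:
            raise GeometryError("px_per_cm must be positive")
        for wall in self.stimulus_walls:
            if wall not in _WALLS:
                raise GeometryError(f"unknown wall {wall!r}")
        if not self.stimulus_walls:
            raise GeometryError("need at least one stimulus wall")

    @property
    def roi_depth(self) -> float:
        ref = self.tank_side if self.roi_reference == "tank" else self.tracked_side
        return self.roi_fraction * ref


@dataclass(frozen=True)
class RoiBand:
    """One ROI band along a wall of the tracked area."""

    label: str
    wall: str
    depth: float
    rect: tuple[float, float, float, float]  # (x0, y0, x1, y1) in cm
    inward_normal: tuple[float, float]
    stimulus: str = ""
    is_control: bool = False


def _band_rect(wall: str, side: float, depth: float) -> tuple[float, float, float, float]:
    if wall == "bottom":
        return (0.0, 0.0, side, depth)
    if wall == "top":
        return (0.0, side - depth, side, side)
    if wall == "left":
        return (0.0, 0.0, depth, side)
    return (side - depth, 0.0, side, side)


def define_rois(arena: ArenaGeometry) -> list[RoiBand]:
    """ROI bands for each stimulus wall (plus a mirrored control for a single wall).

    Depth = ``roi_fraction`` x tank side (3 cm at the defaults), measured
    inward from the tracked-area edge nearest the wall, spanning the full
    wall length.  With a single stimulus wall (the single-display design) the
    opposite band is created by mirroring and flagged as control.
    """
    depth = arena.roi_depth
    if depth <= 0:
        raise GeometryError("roi_fraction must be positive")
    side = arena.tracked_side
    if depth > side:
        raise GeometryError("ROI depth exceeds the tracked area")
    walls = list(arena.stimulus_walls)
    for w in walls:
        if _OPPOSITE[w] in walls and 2 * depth > side:
            raise GeometryError("opposite ROI bands overlap: depth > half the arena")
    bands = [
        RoiBand(
            label=f"ROI {i + 1}",
            wall=w,
            depth=depth,
            rect=_band_rect(w, side, depth),
            inward_normal=_NORMALS[w],
            stimulus=arena.stimulus_walls[w],
        )
        for i, w in enumerate(walls)
    ]
    if len(bands) == 1:
        w = _OPPOSITE[walls[0]]
        if 2 * depth > side:
            raise GeometryError("opposite ROI bands overlap: depth > half the arena")
        bands.append(
            RoiBand(
                label="ROI 2",
                wall=w,
                depth=depth,
                rect=_band_rect(w, side, depth),
                inward_normal=_NORMALS[w],
                stimulus="(control)",
                is_control=True,
            )
        )
    return bands


# ---------------------------------------------------------------------------
# frame ranges and coordinate helpers


@dataclass(frozen=True)
class PeriodDesign:
    """Period layout: 1-min baseline, 4-min test split into 1-min bins.

    ``habituation_s`` is the unrecorded settling period before the baseline;
    it matters only to the simulator (recorded frame 0 is baseline onset).
    """

    baseline_s: float = 60.0
    test_s: float = 240.0
    bin_s: float = 60.0
    habituation_s: float = 300.0


def bin_series(traj: Trajectory, design: PeriodDesign = PeriodDesign()) -> dict[str, range]:
    """Frame ranges for baseline, whole test period and the 1-minute bins."""
    fps = traj.fps
    n_base = round(design.baseline_s * fps)
    n_test = round(design.test_s * fps)
    n_bin = round(design.bin_s * fps)
    if n_bin <= 0 or n_test % n_bin:
        raise CoverageError("test period must divide evenly into bins")
    needed = n_base + n_test
    if traj.n_frames < needed:
        raise CoverageError(f"trajectory has {traj.n_frames} frames, design needs {needed}")
    ranges = {"baseline": range(0, n_base), "test": range(n_base, n_base + n_test)}
    for b in range(n_test // n_bin):
        start = n_base + b * n_bin
        ranges[f"bin{b + 1}"] = range(start, start + n_bin)
    return ranges


def _centroid_cm(traj: Trajectory) -> np.ndarray:
    scale = traj.arena.px_per_cm if traj.arena is not None else 1.0
    return traj.centroid / scale


def _heading_units(traj: Trajectory) -> np.ndarray:
    d = traj.head - traj.centroid
    norm = np.hypot(d[:, 0], d[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        u = d / norm[:, None]
    return u


def _range_slice(traj: Trajectory, frames) -> slice:
    if frames is None:
        return slice(0, traj.n_frames)
    if isinstance(frames, range):
        if len(frames) == 0:
            raise ValueError("empty frame range")
        return slice(frames.start, frames.stop)
    start, stop = frames
    if stop <= start:
        raise ValueError("empty frame range")
    return slice(int(start), int(stop))


def _in_rect(xy: np.ndarray, rect: tuple[float, float, float, float]) -> np.ndarray:
    x0, y0, x1, y1 = rect
    return (xy[:, 0] >= x0) & (xy[:, 0] <= x1) & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)


# ---------------------------------------------------------------------------
# exclusion criteria


@dataclass(frozen=True)
class QualifyCriteria:
    """Thresholds for the baseline-behaviour exclusion rules.

    ``freeze_s``: immobility longer than this (strictly) excludes the fish.
    ``freeze_eps``: per-frame centroid displacement (cm) below which a step
    counts as immobile.  ``restricted_min_frac``: minimum fraction of 1-cm
    grid cells the fish must visit during baseline.  ``max_missing``: more
    than this many tracking-failure frames excludes the fish.
    """

    freeze_s: float = 4.0
    freeze_eps: float = 0.1
    restricted_min_frac: float = 0.25
    grid_cm: float = 1.0
    max_missing: int = 500


@dataclass(frozen=True)
class QualifyResult:
    excluded: bool
    reasons: tuple[str, ...]


def qualify_fish(
    traj: Trajectory,
    criteria: QualifyCriteria = QualifyCriteria(),
    baseline: range | None = None,
) -> QualifyResult:
    """Apply the exclusion rules: freezing, restricted swimming, missing frames.

    Freezing and restricted-area use the baseline period (default: the whole
    trajectory if no range is given); the missing-frame rule uses the whole
    recording.  A fish is excluded iff any rule fires; all firing rules are
    reported.
    """
    sl = _range_slice(traj, baseline)
    ok = traj.ok[sl]
    xy = _centroid_cm(traj)[sl]
    reasons: list[str] = []

    # frozen: longest run of consecutive sub-threshold steps between ok frames
    steps_ok = ok[1:] & ok[:-1]
    disp = np.hypot(*(xy[1:] - xy[:-1]).T)
    sub = steps_ok & (disp < criteria.freeze_eps)
    run = best = 0
    for s in sub:
        run = run + 1 if s else 0
        best = max(best, run)
    if best / traj.fps > criteria.freeze_s:
        reasons.append("frozen")

    # restricted: fraction of occupied grid cells during baseline
    side = traj.arena.tracked_side if traj.arena is not None else float(np.nanmax(xy))
    n_cells = max(1, int(round(side / criteria.grid_cm)))
    pts = xy[ok]
    if len(pts):
        ij = np.clip((pts / criteria.grid_cm).astype(int), 0, n_cells - 1)
        occupied = len(np.unique(ij[:, 0] * n_cells + ij[:, 1]))
    else:
        occupied = 0
    if occupied / (n_cells * n_cells) < criteria.restricted_min_frac:
        reasons.append("restricted")

    if traj.missing_count > criteria.max_missing:
        reasons.append("missing")

    return QualifyResult(excluded=bool(reasons), reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# the three dependent variables


def time_in_roi_pct(traj: Trajectory, roi: RoiBand, frames=None) -> float:
    """Percent of tracked (ok) frames in the range with the centroid inside the ROI."""
    sl = _range_slice(traj, frames)
    ok = traj.ok[sl]
    if not ok.any():
        return float("nan")
    xy = _centroid_cm(traj)[sl][ok]
    return float(100.0 * _in_rect(xy, roi.rect).sum() / len(xy))


def orientation_toward_pct(traj: Trajectory, roi: RoiBand, frames=None) -> float:
    """Among in-ROI frames, percent with heading toward the stimulus wall.

    "Toward" means the heading unit vector has a strictly positive dot
    product with the ROI's inward normal (a +-90 degree tolerance band; the
    exact endpoints, a measure-zero set, count as not-toward).  Missing (NaN)
    when the fish never enters the ROI in the range.
    """
    sl = _range_slice(traj, frames)
    ok = traj.ok[sl]
    xy = _centroid_cm(traj)[sl]
    u = _heading_units(traj)[sl]
    inside = ok & _in_rect(xy, roi.rect)
    if not inside.any():
        return float("nan")
    dots = u[inside] @ np.asarray(roi.inward_normal)
    return float(100.0 * (dots > 0).sum() / len(dots))


def rproj(traj: Trajectory, roi: RoiBand, frames=None) -> float:
    """Scalar projection of the mean in-ROI heading unit vector onto the inward normal.

    The mean resultant vector of the per-frame unit headings is projected
    onto the direction orthogonal to the stimulus screen; the result lies in
    [-1, 1].  Missing (NaN) when the fish never enters the ROI in the range.
    """
    sl = _range_slice(traj, frames)
    ok = traj.ok[sl]
    xy = _centroid_cm(traj)[sl]
    u = _heading_units(traj)[sl]
    inside = ok & _in_rect(xy, roi.rect)
    if not inside.any():
        return float("nan")
    m = u[inside].mean(axis=0)
    return float(m @ np.asarray(roi.inward_normal))


# ---------------------------------------------------------------------------
# per-fish summary


@dataclass
class PreferenceSummary:
    """Per-fish metric table: one row per ROI x period, raw and baseline-normalized.

    ``table`` columns: roi, period, time_pct, orient_pct, rproj, d_time_pct,
    d_orient_pct, d_rproj (the Δ columns are NaN for the baseline row and
    whenever either operand is missing).
    """

    table: pd.DataFrame
    fish_id: str | int | None = None
    group: str | None = None

    def value(self, roi: str, period: str, column: str) -> float:
        t = self.table
        row = t[(t["roi"] == roi) & (t["period"] == period)]
        return float(row[column].iloc[0])


def summarize(
    traj: Trajectory,
    rois: list[RoiBand],
    design: PeriodDesign = PeriodDesign(),
    fish_id: str | int | None = None,
    group: str | None = None,
) -> PreferenceSummary:
    """All three metrics per ROI for baseline, test and each 1-min bin, with Δs."""
    ranges = bin_series(traj, design)
    rows = []
    for roi in rois:
        base = {
            "time_pct": time_in_roi_pct(traj, roi, ranges["baseline"]),
            "orient_pct": orientation_toward_pct(traj, roi, ranges["baseline"]),
            "rproj": rproj(traj, roi, ranges["baseline"]),
        }
        for period, rng in ranges.items():
            vals = {
                "time_pct": time_in_roi_pct(traj, roi, rng),
                "orient_pct": orientation_toward_pct(traj, roi, rng),
                "rproj": rproj(traj, roi, rng),
            }
            row = {"roi": roi.label, "period": period, **vals}
            for k in vals:
                row[f"d_{k}"] = vals[k] - base[k] if period != "baseline" else float("nan")
            rows.append(row)
    return PreferenceSummary(table=pd.DataFrame(rows), fish_id=fish_id, group=group)


def occupancy_heatmap(
    traj: Trajectory,
    frames=None,
    grid: tuple[int, int] = (24, 24),
) -> np.ndarray:
    """Occupancy matrix over the tracked area, scaled to [0, 1].

    Cell value = (ok frames in cell) / (total ok frames in range), then
    divided by the maximum cell value so the peak is 1.  Rows index y bins
    (ascending, so row 0 is the bottom wall), columns x bins.  All-zero when
    the range has no ok frames.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValueError("grid must be at least 1x1")
    sl = _range_slice(traj, frames)
    ok = traj.ok[sl]
    side = traj.arena.tracked_side if traj.arena is not None else 12.0
    out = np.zeros((rows, cols))
    if not ok.any():
        return out
    xy = _centroid_cm(traj)[sl][ok]
    hist, _, _ = np.histogram2d(
        xy[:, 1], xy[:, 0], bins=(rows, cols), range=[[0, side], [0, side]]
    )
    hist /= len(xy)
    peak = hist.max()
    return hist / peak if peak > 0 else hist
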