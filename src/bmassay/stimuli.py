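"""Point-light stimulus sequences: file I/O and the three stimulus classes.

A point-light display (PLD) renders a swimming fish as a handful of dots
placed along its body.  The assay uses three stimulus classes built from a
recorded "upright" sequence:

* **upright BM** — the recorded biological motion itself (six dots at equal
  distance along the body, 60 fps, 1 min);
* **inverted BM** — the same sequence mirror-flipped vertically, which keeps
  the posture and inter-dot geometry but reverses the direction of every
  vertical velocity and acceleration (gravity-incompatible);
* **non-BM** — a rigid chain of dots with the *average* inter-dot spacing of
  the recording, translating along a straight line at the *average* speed of
  the recording (no biological kinetics at all).

Coordinates are kept in arbitrary display units (a.u.) with y increasing
upward.  Files recorded in image convention (y down) can be flipped on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import GeometryError, ParseError, StructureError

__all__ = [
    "PointLightSequence",
    "read_pointlight",
    "write_pointlight",
    "scale_sequence",
    "invert_sequence",
    "make_nonbm",
]


@dataclass(frozen=True)
class PointLightSequence:
    """Per-frame 2D dot coordinates of a point-light stimulus.

    Parameters
    ----------
    coords:
        Array of shape ``(n_frames, n_dots, 2)`` holding (x, y) positions in
        arbitrary display units, y up.
    fps:
        Frame rate in Hz (the deposited fish recordings use 60).
    meta:
        Free-form provenance text.
    """

    coords: np.ndarray
    fps: float = 60.0
    meta: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 3 or coords.shape[2] != 2:
            raise StructureError(
                f"coords must have shape (n_frames, n_dots, 2), got {coords.shape}"
            )
        if coords.shape[0] < 2:
            raise StructureError("a sequence needs at least 2 frames")
        if coords.shape[1] < 2:
            raise StructureError("a sequence needs at least 2 dots")
        if not np.isfinite(coords).all():
            raise StructureError("all coordinates must be finite")
        if not self.fps > 0:
            raise StructureError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dots(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray, meta: str | None = None) -> "PointLightSequence":
        return replace(self, coords=coords, meta=self.meta if meta is None else meta)


def _sniff_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # whitespace


def _split(line: str, sep: str | None) -> list[str]:
    parts = line.split(sep) if sep else line.split()
    return [p.strip() for p in parts if p.strip() != ""]


def read_pointlight(
    path: str | Path,
    fps: float = 60.0,
    dialect: str = "auto",
    y_down: bool = False,
) -> PointLightSequence:
    """Read a delimited-text point-light file.

    Two dialects are accepted (delimiter auto-detected among comma / tab /
    whitespace, header line optional, 0-based frame index):

    * long form — one row per dot: ``frame, dot, x, y``;
    * wide form — one row per frame: ``frame, x1, y1, ..., xN, yN``.

    Parameters
    ----------
    fps:
        Frame rate to attach (files carry no rate metadata; default 60).
    dialect:
        ``"auto"`` (decide from column count), ``"long"`` or ``"wide"``.
    y_down:
        Set when the file stores image-convention y (down-positive); the y
        axis is negated so internal computation is always y-up.
    """
    path = Path(path)
    raw = path.read_text()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(raw.splitlines()) if ln.strip()]
    if not lines:
        raise StructureError(f"{path}: empty point-light file")

    sep = _sniff_delimiter(lines[0][1])
    rows: list[tuple[int, list[float]]] = []
    for idx, (lineno, ln) in enumerate(lines):
        parts = _split(ln, sep)
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            if idx == 0:  # header line
                continue
            raise ParseError(f"{path}: malformed row at line {lineno}: {ln!r}") from None
        rows.append((lineno, vals))
    if not rows:
        raise StructureError(f"{path}: no data rows")

    widths = {len(v) for _, v in rows}
    if len(widths) != 1:
        raise StructureError(f"{path}: inconsistent column counts {sorted(widths)}")
    width = widths.pop()

    if dialect == "auto":
        dialect = "long" if width == 4 else "wide"
    if dialect == "long":
        if width != 4:
            raise StructureError(f"{path}: long form needs 4 columns, got {width}")
        frames: dict[int, list[tuple[int, float, float]]] = {}
        for lineno, (f, d, x, y) in ((ln, v) for ln, v in rows):
            frames.setdefault(int(f), []).append((int(d), x, y))
        counts = {len(v) for v in frames.values()}
        if len(counts) != 1:
            raise StructureError(f"{path}: ragged dot counts across frames: {sorted(counts)}")
        n_dots = counts.pop()
        coords = np.empty((len(frames), n_dots, 2))
        for fi, f in enumerate(sorted(frames)):
            for di, (d, x, y) in enumerate(sorted(frames[f])):
                coords[fi, di] = (x, y)
    else:
        if width < 5 or width % 2 == 0:
            raise StructureError(
                f"{path}: wide form needs an odd column count >= 5 (frame, x1, y1, ...), got {width}"
            )
        data = np.array([v for _, v in rows])
        order = np.argsort(data[:, 0], kind="stable")
        coords = data[order, 1:].reshape(len(rows), -1, 2)

    if coords.shape[0] < 2:
        raise StructureError(f"{path}: fewer than 2 frames")
    if y_down:
        coords = coords.copy()
        coords[:, :, 1] = -coords[:, :, 1]
    return PointLightSequence(coords, fps=fps, meta=f"read from {path.name}")


def write_pointlight(
    seq: PointLightSequence,
    path: str | Path,
    dialect: str = "wide",
    sep: str = ",",
) -> None:
    """Write a sequence as delimited text in the long or wide dialect."""
    path = Path(path)
    out: list[str] = []
    if dialect == "wide":
        header = ["frame"]
        for d in range(seq.n_dots):
            header += [f"x{d + 1}", f"y{d + 1}"]
        out.append(sep.join(header))
        for f in range(seq.n_frames):
            vals = [str(f)] + [f"{v:.17g}" for v in seq.coords[f].ravel()]
            out.append(sep.join(vals))
    elif dialect == "long":
        out.append(sep.join(["frame", "dot", "x", "y"]))
        for f in range(seq.n_frames):
            for d in range(seq.n_dots):
                x, y = seq.coords[f, d]
                out.append(sep.join([str(f), str(d), f"{x:.17g}", f"{y:.17g}"]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(out) + "\n")


def mean_extent(seq: PointLightSequence) -> float:
    """Across-frame mean head-to-tail distance (first dot to last dot)."""
    d = seq.coords[:, -1] - seq.coords[:, 0]
    return float(np.mean(np.hypot(d[:, 0], d[:, 1])))


def scale_sequence(
    seq: PointLightSequence, target_length: float, px_per_cm: float
) -> PointLightSequence:
    """Uniformly rescale so the mean head-to-tail extent equals a physical length.

    The projected stimulus in the assay spans about 2.5 cm (an adult zebrafish
    body length); ``target_length`` is that length in cm and ``px_per_cm``
    the display scale.  The rescale is isotropic about the whole-sequence
    centroid.
    """
    if target_length <= 0 or px_per_cm <= 0:
        raise ValueError("target_length and px_per_cm must be positive")
    ext = mean_extent(seq)
    if ext <= 1e-12:
        raise GeometryError("degenerate geometry: all dots coincident (zero extent)")
    factor = target_length * px_per_cm / ext
    center = seq.coords.reshape(-1, 2).mean(axis=0)
    coords = center + factor * (seq.coords - center)
    return seq.with_coords(coords, meta=seq.meta + f" | scaled x{factor:.6g}")


def invert_sequence(seq: PointLightSequence) -> PointLightSequence:
    """Mirror-flip the stimulus vertically (the inverted-BM transform).

    y is reflected about the midline of the global bounding box,
    ``y' = (y_min + y_max) - y``, which keeps the stimulus inside its original
    vertical footprint; x is untouched.  Applied twice this is the identity.
    """
    y = seq.coords[:, :, 1]
    c = float(y.min()) + float(y.max())
    coords = seq.coords.copy()
    coords[:, :, 1] = c - y
    return seq.with_coords(coords, meta=seq.meta + " | inverted")


def make_nonbm(
    seq: PointLightSequence,
    heading_deg: float = 0.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> PointLightSequence:
    """Synthesize the non-BM control stimulus from a recorded sequence.

    The control keeps the dot count but destroys body configuration and swim
    kinetics: the dots become a rigid collinear chain whose adjacent spacing
    equals the recording's mean inter-dot distance (pooled over frames and
    adjacent pairs), translating along ``heading_deg`` at the recording's mean
    centroid speed, with elastic reflection at the edges of ``bounds`` so the
    chain stays on screen.

    Parameters
    ----------
    bounds:
        Display rectangle ``(xmin, ymin, xmax, ymax)``; defaults to the
        bounding box of the input sequence.
    """
    coords = seq.coords
    if bounds is None:
        bounds = (
            float(coords[:, :, 0].min()),
            float(coords[:, :, 1].min()),
            float(coords[:, :, 0].max()),
            float(coords[:, :, 1].max()),
        )
    xmin, ymin, xmax, ymax = map(float, bounds)

    # mean adjacent inter-dot distance, pooled over frames and adjacent pairs
    adj = np.diff(coords, axis=1)
    d_bar = float(np.mean(np.hypot(adj[:, :, 0], adj[:, :, 1])))
    # mean per-frame centroid displacement (a.u./frame)
    cent = coords.mean(axis=1)
    dc = np.diff(cent, axis=0)
    step = float(np.mean(np.hypot(dc[:, 0], dc[:, 1])))

    n = seq.n_dots
    chain_len = (n - 1) * d_bar
    theta = math.radians(heading_deg)
    u = np.array([math.cos(theta), math.sin(theta)])
    half_span = np.abs(u) * chain_len / 2.0
    lo = np.array([xmin, ymin]) + half_span
    hi = np.array([xmax, ymax]) - half_span
    if np.any(hi < lo):
        raise GeometryError(
            f"bounds {bounds} too small for a chain of length {chain_len:.3g} along {heading_deg} deg"
        )

    vel = step * u
    p = np.clip(cent[0], lo, hi)
    offsets = (np.arange(n) - (n - 1) / 2.0) * d_bar
    out = np.empty_like(coords)
    for t in range(seq.n_frames):
        speed = math.hypot(vel[0], vel[1])
        direction = vel / speed if speed > 0 else u
        out[t] = p + offsets[:, None] * direction
        p = p + vel
        for ax in (0, 1):
            # elastic reflection on the inset rectangle (chain tips stay inside)
            while p[ax] > hi[ax] or p[ax] < lo[ax]:
                if p[ax] > hi[ax]:
                    p[ax] = 2 * hi[ax] - p[ax]
                else:
                    p[ax] = 2 * lo[ax] - p[ax]
                vel[ax] = -vel[ax]
    return PointLightSequence(out, fps=seq.fps, meta=seq.meta + " | non-BM")
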