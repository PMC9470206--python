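"""Vertical kinematics and the gravity signature of point-light sequences.

Swimming up against gravity and sinking with it leave an asymmetric imprint
on the vertical component of a fish's motion: the magnitudes of upward and
downward vertical acceleration (and velocity) differ systematically.  This
module computes per-dot vertical velocity/acceleration profiles by finite
differences and summarizes them as a *gravity signature*: the mean magnitude
of the positive-sign (upward) and negative-sign (downward) samples, pooled
over all dots and valid frames.

Central differences are the default (symmetric, second-order accurate):

    v[t] = (y[t+1] - y[t-1]) / 2 * fps          (a.u./s)
    a[t] = (y[t+1] - 2 y[t] + y[t-1]) * fps^2   (a.u./s^2)

defined on interior frames.  A forward scheme is available for sensitivity
checks, and an optional moving-average pre-smoother because tracking jitter
inflates accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructureError
from .stimuli import PointLightSequence

__all__ = [
    "KinematicsProfile",
    "GravitySignature",
    "vertical_kinematics",
    "gravity_signature",
    "signature_table",
]


@dataclass(frozen=True)
class KinematicsProfile:
    """Per-frame, per-dot vertical velocity and acceleration.

    ``v`` and ``a`` have shape ``(n_frames, n_dots)`` with NaN outside the
    frames where the finite-difference stencil is complete; ``valid_mask``
    flags those frames.  Masked entries never enter averages.
    """

    v: np.ndarray
    a: np.ndarray
    valid_mask: np.ndarray
    fps: float
    scheme: str = "central"


@dataclass(frozen=True)
class GravitySignature:
    """Sign-split means of vertical acceleration and velocity.

    All four means are reported as magnitudes (>= 0); a side with no samples
    is NaN with count 0.  Positive / negative samples correspond to upward /
    downward motion; zero-valued samples belong to neither side.
    """

    mean_up_acc: float
    mean_down_acc: float
    mean_up_vel: float
    mean_down_vel: float
    n_up_acc: int
    n_down_acc: int
    n_up_vel: int
    n_down_vel: int


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, y)


def vertical_kinematics(
    seq: PointLightSequence,
    scheme: str = "central",
    smooth_window: int | None = None,
) -> KinematicsProfile:
    """Finite-difference vertical velocity and acceleration of every dot."""
    n = seq.n_frames
    if n < 3:
        raise StructureError(f"need at least 3 frames for kinematics, got {n}")
    y = seq.coords[:, :, 1]
    if smooth_window and smooth_window > 1:
        y = _moving_average(y, smooth_window)
    fps = seq.fps
    v = np.full_like(y, np.nan)
    a = np.full_like(y, np.nan)
    mask = np.zeros(n, dtype=bool)
    if scheme == "central":
        v[1:-1] = (y[2:] - y[:-2]) / 2.0 * fps
        a[1:-1] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) * fps**2
        mask[1:-1] = True
    elif scheme == "forward":
        v[:-2] = (y[1:-1] - y[:-2]) * fps
        a[:-2] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) * fps**2
        mask[:-2] = True
    else:
        raise ValueError(f"unknown differencing scheme {scheme!r}")
    return KinematicsProfile(v=v, a=a, valid_mask=mask, fps=fps, scheme=scheme)


def _sign_split(x: np.ndarray) -> tuple[float, float, int, int]:
    x = x[np.isfinite(x)]
    up = x[x > 0]
    down = x[x < 0]
    mean_up = float(np.mean(up)) if up.size else float("nan")
    mean_down = float(-np.mean(down)) if down.size else float("nan")
    return mean_up, mean_down, int(up.size), int(down.size)


def gravity_signature(profile: KinematicsProfile) -> GravitySignature:
    """Pool samples over all dots and valid frames, split by sign."""
    a = profile.a[profile.valid_mask].ravel()
    v = profile.v[profile.valid_mask].ravel()
    up_a, down_a, n_up_a, n_down_a = _sign_split(a)
    up_v, down_v, n_up_v, n_down_v = _sign_split(v)
    return GravitySignature(
        mean_up_acc=up_a,
        mean_down_acc=down_a,
        mean_up_vel=up_v,
        mean_down_vel=down_v,
        n_up_acc=n_up_a,
        n_down_acc=n_down_a,
        n_up_vel=n_up_v,
        n_down_vel=n_down_v,
    )


def _fmt_pair(up: float, down: float) -> str:
    fu = "n/a" if np.isnan(up) else f"{up:.2f}"
    fd = "n/a" if np.isnan(down) else f"{down:.2f}"
    return f"(+){fu}/(-){fd}"


def signature_table(
    seqs: list[PointLightSequence],
    labels: list[str] | None = None,
    scheme: str = "central",
) -> pd.DataFrame:
    """One gravity-signature row per sequence, acceleration columns first.

    Returns numeric magnitude/count columns plus formatted "(+)up/(-)down"
    strings for report output.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if labels is None:
        labels = [f"seq{i + 1}" for i in range(len(seqs))]
    if len(labels) != len(seqs):
        raise ValueError(f"{len(labels)} labels for {len(seqs)} sequences")
    rows = []
    for label, seq in zip(labels, seqs):
        sig = gravity_signature(vertical_kinematics(seq, scheme=scheme))
        rows.append(
            {
                "label": label,
                "up_acc": sig.mean_up_acc,
                "down_acc": sig.mean_down_acc,
                "up_vel": sig.mean_up_vel,
                "down_vel": sig.mean_down_vel,
                "n_up_acc": sig.n_up_acc,
                "n_down_acc": sig.n_down_acc,
                "n_up_vel": sig.n_up_vel,
                "n_down_vel": sig.n_down_vel,
                "acceleration": _fmt_pair(sig.mean_up_acc, sig.mean_down_acc),
                "velocity": _fmt_pair(sig.mean_up_vel, sig.mean_down_vel),
            }
        )
    return pd.DataFrame(rows)
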