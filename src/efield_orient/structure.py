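"""Structural preservation metrics: Kabsch superposition, Cα RMSD,
the 0.5 nm preservation criterion, RMSD at the orientation time and the
post-ramp plateau RMSD.

RMSD is always computed after least-squares optimal rigid superposition
(Kabsch), unweighted over the supplied atoms (conventionally Cα only).
A structure counts as preserved while RMSD ≤ 0.5 nm (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import PRESERVATION_THRESHOLD_NM

__all__ = [
    "StructureTrajectory",
    "DegenerateGeometryError",
    "kabsch_align",
    "rmsd",
    "rmsd_series",
    "is_preserved",
    "rmsd_at",
    "plateau_rmsd",
]


class DegenerateGeometryError(ValueError):
    """Coordinates are collinear (or fewer than 3 atoms): the optimal
    superposition is not unique."""


@dataclass
class StructureTrajectory:
    """Time-stamped Cα coordinate frames plus a reference frame, nm.

    The reference defaults, by convention, to the first production frame
    ("an earlier time point"); pass the crystal structure to override.
    """

    times: np.ndarray
    frames: np.ndarray
    reference: np.ndarray
    labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must have equal length")
        n_atoms = self.frames.shape[1]
        if self.reference.shape != (n_atoms, 3):
            raise ValueError("reference atom count differs from frames")
        if n_atoms < 3:
            raise ValueError("need at least 3 atoms")
        if self.labels is not None and len(self.labels) != n_atoms:
            raise ValueError("labels length differs from atom count")


def _check_pair(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(moving, dtype=float)
    b = np.asarray(target, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (N, 3); got {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 atoms")
    return a, b


def _assert_not_collinear(centered: np.ndarray) -> None:
    # rank < 2 after centering means all points on a line
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-9:
        raise DegenerateGeometryError("coordinates are collinear; superposition not unique")


def kabsch_align(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid superposition of ``moving`` onto ``target``.

    Returns ``(R, t)`` — a proper rotation matrix (det +1) and a
    translation — minimizing Σ |R xᵢ + t − yᵢ|².  Apply as
    ``moving @ R.T + t``.
    """
    a, b = _check_pair(moving, target)
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    _assert_not_collinear(a - ca)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    R = rot.as_matrix()
    t = cb - R @ ca
    return R, t


def rmsd(moving: np.ndarray, target: np.ndarray) -> float:
    """Root mean-square deviation after optimal superposition, nm.

    Symmetric in its arguments and invariant under rigid motions of
    either coordinate set.
    """
    a, b = _check_pair(moving, target)
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    _assert_not_collinear(a - ca)
    rot, _ = Rotation.align_vectors(b - cb, a - ca)
    # residual evaluated explicitly: the SVD-based rssd loses ~8 digits to
    # cancellation for near-identical sets
    diff = (a - ca) @ rot.as_matrix().T - (b - cb)
    return float(np.sqrt((diff**2).sum() / len(a)))


def rmsd_series(traj: StructureTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Framewise RMSD of a trajectory against its reference.

    Returns ``(times, rmsd_nm)``.
    """
    values = np.array([rmsd(frame, traj.reference) for frame in traj.frames])
    return traj.times.copy(), values


def is_preserved(rmsd_value: float, threshold: float = PRESERVATION_THRESHOLD_NM) -> bool:
    """Preservation criterion: RMSD ≤ threshold (0.5 nm, boundary inclusive)."""
    if rmsd_value < 0:
        raise ValueError("RMSD cannot be negative")
    return bool(rmsd_value <= threshold)


def rmsd_at(times: np.ndarray, values: np.ndarray, t: float) -> float:
    """Linearly interpolated RMSD at time ``t`` (ns); ``t`` must lie
    within the sampled span."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise ValueError("times and values must be equal-length 1-d arrays")
    if t < times[0] or t > times[-1]:
        raise ValueError(f"t = {t} ns outside series span [{times[0]}, {times[-1]}] ns")
    return float(np.interp(t, times, values))


def plateau_rmsd(
    times: np.ndarray, values: np.ndarray, t0: float, delay: float = 5.0
) -> float:
    """Mean RMSD over [t0 + delay, end] — the structural state reached
    once the field has been at full strength for ``delay`` ns.

    Errors when the series does not extend to t0 + delay (the reason
    long-ramp runs must be extended past the usual duration).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    cut = t0 + delay
    if times[-1] < cut - 1e-12:
        raise ValueError(
            f"series ends at {times[-1]} ns, before t0 + delay = {cut} ns"
        )
    mask = times >= cut - 1e-12
    return float(values[mask].mean())
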