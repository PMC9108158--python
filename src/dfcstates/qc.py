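"""Head-motion quality control.

Framewise displacement (FD) summarises volume-to-volume head movement as a
single millimetre-scale scalar per volume: the sum of absolute translation
differentials plus the sum of absolute rotation differentials converted to arc
length on a reference sphere (50 mm by convention).  Subjects whose raw
realignment parameters exceed a maximum translation or rotation are excluded
outright; mean FD additionally serves as a nuisance covariate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionTrace",
    "framewise_displacement",
    "motion_exclusion",
    "discard_initial_volumes",
]

#: Radius (mm) of the sphere used to convert rotation differentials to arc
#: length (Power-style FD).
DEFAULT_SPHERE_RADIUS_MM = 50.0

#: Number of leading volumes removed before analysis to allow scanner
#: stabilisation and subject adaptation.
DEFAULT_N_DISCARD = 10


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters for one subject.

    Parameters
    ----------
    params
        Array of shape (T, 6): three translations in millimetres followed by
        three rotations in radians, one row per retained volume.
    sphere_radius
        Radius in millimetres used to convert rotations to displacement.
    """

    params: np.ndarray
    sphere_radius: float = DEFAULT_SPHERE_RADIUS_MM

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion trace must be (T, 6); got shape {self.params.shape}"
            )
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class FdResult:
    """Per-volume FD series plus its mean over volumes 2..T."""

    fd: np.ndarray
    mean_fd: float


def framewise_displacement(trace: MotionTrace) -> FdResult:
    """Compute the framewise-displacement series and its mean.

    FD at volume ``t >= 2`` is ``sum |d translation_i| + radius * sum
    |d rotation_j|``; FD at the first volume is defined as 0 and excluded
    from the mean (the differential is undefined there).
    """
    n = trace.params.shape[0]
    if n < 2:
        raise ValueError("framewise displacement needs at least 2 volumes")
    diffs = np.abs(np.diff(trace.params, axis=0))
    fd_tail = diffs[:, :3].sum(axis=1) + trace.sphere_radius * diffs[:, 3:].sum(axis=1)
    fd = np.concatenate([[0.0], fd_tail])
    return FdResult(fd=fd, mean_fd=float(fd_tail.mean()))


def motion_exclusion(
    trace: MotionTrace,
    max_trans_mm: float = 3.0,
    max_rot_deg: float = 3.0,
) -> bool:
    """Return True if the subject should be KEPT.

    A subject is excluded iff any absolute translation exceeds
    ``max_trans_mm`` millimetres or any absolute rotation exceeds
    ``max_rot_deg`` degrees (strict inequality: a value exactly at the
    threshold is kept).  Rotations are stored in radians and compared in
    degrees.
    """
    trans_ok = np.all(np.abs(trace.translations) <= max_trans_mm)
    # compare in radians so a trace at exactly the degree threshold is kept
    rot_ok = np.all(np.abs(trace.rotations) <= np.deg2rad(max_rot_deg))
    return bool(trans_ok and rot_ok)


def discard_initial_volumes(
    matrix: np.ndarray, n_discard: int = DEFAULT_N_DISCARD
) -> np.ndarray:
    """Drop the first ``n_discard`` rows (volumes) of a T x R series.

    Acquisition protocols include lead-in volumes during which the scanner
    signal has not reached steady state; those volumes are removed before any
    connectivity computation (e.g. 239 acquired -> 229 analysed).
    """
    matrix = np.asarray(matrix)
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= matrix.shape[0]:
        raise ValueError(
            f"cannot discard {n_discard} volumes from a series of length "
            f"{matrix.shape[0]}"
        )
    return matrix[n_discard:]
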