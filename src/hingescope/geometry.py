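"""Rigid-body superposition and fluctuation statistics.

Center of geometry, Kabsch optimal rotation (SVD with reflection
correction), paired RMSD, rotation-angle extraction, and per-residue
RMSF about the two-pass mean structure. All superpositions are
unweighted: the analyses here operate on C-alpha atoms only, where mass
weighting would be a no-op anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptySelectionError,
    InsufficientFramesError,
    PairingError,
    UnderDeterminedError,
    ValidationError,
)
from .structure_io import Trajectory

__all__ = [
    "RigidTransform",
    "FluctuationProfile",
    "center_of_geometry",
    "kabsch",
    "paired_rmsd",
    "rotation_angle",
    "rmsd_series",
    "rmsf",
    "axis_angle_rotation",
]

#: entry-validation tolerance for orthonormality of rotation inputs
ORTHONORMALITY_TOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation`` (Angstroms)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float)
        )
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValidationError("rotation is not orthonormal (tol 1e-8)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValidationError("rotation determinant is not +1 (tol 1e-8)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class FluctuationProfile:
    """Per-residue root-mean-square fluctuation, Angstroms."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.residue_numbers.shape != self.rmsf.shape:
            raise ValueError("residue_numbers and rmsf differ in length")
        if np.any(self.rmsf < 0):
            raise ValueError("negative RMSF")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"residue_number": self.residue_numbers, "rmsf_A": self.rmsf}
        )


def center_of_geometry(coords: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of an M x 3 coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be M x 3")
    if coords.shape[0] == 0:
        raise EmptySelectionError("center of geometry of an empty point set")
    return coords.mean(axis=0)


def kabsch(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform minimizing the RMSD of the transformed mobile
    points to the reference over all rotations+translations, and that
    minimal (fitted) RMSD. Reflections are excluded by flipping the sign
    of the smallest singular vector when the covariance determinant is
    negative. Point sets must be paired index-for-index, M >= 3.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise PairingError(
            f"point sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be M x 3")
    if mobile.shape[0] < 3:
        raise UnderDeterminedError("rigid superposition needs at least 3 points")

    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    P = mobile - mob_center
    Q = reference - ref_center

    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if S[1] <= max(S[0], 1.0) * 1e-12:  # rank < 2: collinear point sets
        import warnings

        warnings.warn(
            "degenerate (near-collinear) point set; superposition may be "
            "ill-conditioned",
            stacklevel=2,
        )
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_center - R @ mob_center

    fitted = P @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def paired_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root-mean-square point-to-point deviation; no fitting is performed."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape:
        raise PairingError(f"point sets differ in shape: {A.shape} vs {B.shape}")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def rotation_angle(rotation: np.ndarray) -> float:
    """Magnitude of a rotation in degrees, in [0, 180].

    arccos((trace - 1) / 2), with the argument clamped to [-1, 1] to
    absorb floating-point drift.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValidationError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=ORTHONORMALITY_TOL):
        raise ValidationError(
            f"input is not orthonormal (tol {ORTHONORMALITY_TOL})"
        )
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_theta)))


def axis_angle_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a rotation of ``angle_deg`` about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero axis")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    theta = np.radians(angle_deg)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def rmsd_series(
    trajectory: Trajectory,
    fit_selection: np.ndarray,
    reference: np.ndarray | None = None,
    analysis_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after superposition.

    Each frame is superposed onto ``reference`` (default: frame 0) using
    ``fit_selection``, then the unfitted paired RMSD is measured over
    ``analysis_selection`` (default: the fit selection). The
    conventional trajectory RMSD uses all C-alpha atoms for both.
    """
    fit_idx = np.asarray(list(fit_selection), dtype=int)
    ana_idx = (
        fit_idx
        if analysis_selection is None
        else np.asarray(list(analysis_selection), dtype=int)
    )
    if fit_idx.size == 0 or ana_idx.size == 0:
        raise EmptySelectionError("empty RMSD selection")
    ref = trajectory.frames[0] if reference is None else np.asarray(reference)
    out = np.empty(trajectory.n_frames)
    for t in range(trajectory.n_frames):
        transform, _ = kabsch(trajectory.frames[t][fit_idx], ref[fit_idx])
        moved = transform.apply(trajectory.frames[t][ana_idx])
        out[t] = paired_rmsd(moved, ref[ana_idx])
    return out


def rmsf(
    trajectory: Trajectory,
    analysis_selection: np.ndarray,
    alignment_selection: np.ndarray,
) -> FluctuationProfile:
    """Per-atom RMSF about the time-averaged structure.

    Two-pass convention: every frame is first superposed (on the
    alignment selection) onto frame 0, the aligned frames are averaged,
    and each frame is then re-superposed onto that mean before the
    fluctuations of the analysis selection are accumulated:
    ``RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2)``.
    """
    analysis_idx = np.asarray(list(analysis_selection), dtype=int)
    alignment_idx = np.asarray(list(alignment_selection), dtype=int)
    if trajectory.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    if analysis_idx.size == 0 or alignment_idx.size == 0:
        raise EmptySelectionError("empty RMSF selection")

    frames = trajectory.frames

    def _align_all(reference_sub: np.ndarray) -> np.ndarray:
        aligned = np.empty_like(frames)
        for t in range(frames.shape[0]):
            transform, _ = kabsch(frames[t][alignment_idx], reference_sub)
            aligned[t] = transform.apply(frames[t])
        return aligned

    aligned = _align_all(frames[0][alignment_idx])
    mean_structure = aligned.mean(axis=0)
    aligned = _align_all(mean_structure[alignment_idx])
    mean_structure = aligned.mean(axis=0)

    disp = aligned[:, analysis_idx, :] - mean_structure[analysis_idx]
    per_atom = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=0))
    residues = np.array(
        [trajectory.topology[i].residue_number for i in analysis_idx], dtype=int
    )
    return FluctuationProfile(residues, per_atom)
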