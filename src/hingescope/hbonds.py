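"""Geometric hydrogen-bond detection and per-frame counting.

A hydrogen bond is recorded between a donor (N or O with a covalently
attached hydrogen) in one selection and an acceptor (any N or O) in the
other when the donor-acceptor distance is at most ``max_da_distance``
(default 3.3 A) and the hydrogen-donor-acceptor angle — the angle at the
donor between the D->H and D->A vectors, small for a near-linear
D-H...A arrangement — is at most ``max_hda_angle`` (default 30 deg).
Both criteria are inclusive.

Hydrogens are assigned to donors by proximity (H within 1.25 A of the
heavy atom) rather than connectivity records, since PDB inputs may lack
CONECT entries. Structures without hydrogens raise
:class:`~hingescope.errors.NoHydrogensError` unless heavy-atom-only mode
(distance criterion alone) is explicitly enabled; records produced in
that mode carry no hydrogen index and an undefined angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import NoHydrogensError, SelectionOverlapError
from .structure_io import StructureFrame, Trajectory

__all__ = [
    "HBondCriteria",
    "HBond",
    "HBondSeries",
    "COVALENT_H_CUTOFF",
    "find_donors_acceptors",
    "detect_hbonds",
    "hbond_count_series",
]

#: maximum H-to-heavy-atom distance treated as a covalent bond, A
COVALENT_H_CUTOFF = 1.25

_POLAR_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric detection thresholds, both applied inclusively."""

    max_da_distance: float = 3.3
    max_hda_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0 or self.max_hda_angle <= 0:
            raise ValueError("criteria must be strictly positive")


@dataclass(frozen=True)
class HBond:
    donor_index: int
    hydrogen_index: int  # -1 in heavy-atom-only mode
    acceptor_index: int
    da_distance: float
    hda_angle: float  # nan in heavy-atom-only mode
    frame_index: int = 0


@dataclass
class HBondSeries:
    """Per-frame bond counts with population mean and standard deviation."""

    counts: np.ndarray
    mean: float
    sd: float

    @classmethod
    def from_counts(cls, counts) -> "HBondSeries":
        counts = np.asarray(counts, dtype=int)
        return cls(
            counts=counts,
            mean=float(np.mean(counts)),
            sd=float(np.std(counts, ddof=0)),
        )


def _element(frame: StructureFrame, i: int) -> str:
    return frame.atoms[i].element.upper()


def find_donors_acceptors(
    frame: StructureFrame,
    selection,
    require_hydrogens: bool = True,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Donor (heavy-atom, hydrogen) pairs and acceptor atoms in a selection.

    Donors are N/O atoms with at least one hydrogen within
    :data:`COVALENT_H_CUTOFF`; a donor with several hydrogens yields one
    pair per hydrogen. Acceptors are all N/O atoms in the selection.
    If the selection contains polar atoms but the structure carries no
    hydrogens at all, a :class:`NoHydrogensError` is raised (pass
    ``require_hydrogens=False`` for heavy-atom-only workflows).
    """
    idx = np.asarray(list(selection), dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    polar = [int(i) for i in idx if _element(frame, i) in _POLAR_ELEMENTS]
    acceptors = list(polar)
    if not polar:
        return [], []

    h_all = [
        i for i in range(frame.n_atoms) if frame.atoms[i].element.upper() == "H"
    ]
    if not h_all:
        if require_hydrogens:
            raise NoHydrogensError(
                "structure contains no hydrogen atoms; add protons or enable "
                "heavy-atom-only mode"
            )
        return [], acceptors

    h_tree = cKDTree(frame.coords[h_all])
    donor_pairs: list[tuple[int, int]] = []
    # hydrogens ride with their heavy atom even when the selection lists
    # only heavy atoms, so the scan covers the whole structure
    for d in polar:
        for j in sorted(h_tree.query_ball_point(frame.coords[d], COVALENT_H_CUTOFF)):
            donor_pairs.append((d, h_all[j]))
    return donor_pairs, acceptors


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def _directed_bonds(
    frame: StructureFrame,
    donor_pairs: list[tuple[int, int]],
    acceptors: list[int],
    criteria: HBondCriteria,
    frame_index: int,
    heavy_only: bool,
) -> list[HBond]:
    if not acceptors or (not donor_pairs and not heavy_only):
        return []
    acc_tree = cKDTree(frame.coords[acceptors])
    bonds = []
    if heavy_only:
        seen = set()
        donors = sorted({d for d, _ in donor_pairs}) if donor_pairs else []
        for d in donors:
            for j in acc_tree.query_ball_point(
                frame.coords[d], criteria.max_da_distance
            ):
                a = acceptors[j]
                if a == d or (d, a) in seen:
                    continue
                seen.add((d, a))
                dist = float(np.linalg.norm(frame.coords[a] - frame.coords[d]))
                bonds.append(HBond(d, -1, a, dist, float("nan"), frame_index))
        return bonds
    for d, h in donor_pairs:
        for j in acc_tree.query_ball_point(
            frame.coords[d], criteria.max_da_distance
        ):
            a = acceptors[j]
            if a == d or a == h:
                continue
            da = frame.coords[a] - frame.coords[d]
            dist = float(np.linalg.norm(da))
            angle = _angle_deg(frame.coords[h] - frame.coords[d], da)
            if dist <= criteria.max_da_distance and angle <= criteria.max_hda_angle:
                bonds.append(HBond(d, h, a, dist, angle, frame_index))
    return bonds


def detect_hbonds(
    frame: StructureFrame,
    selection_a,
    selection_b,
    criteria: HBondCriteria = HBondCriteria(),
    heavy_atoms_only: bool = False,
    frame_index: int = 0,
) -> list[HBond]:
    """All hydrogen bonds crossing two disjoint selections in one frame.

    Both directions are scanned (donor in A / acceptor in B and the
    reverse); each unique (donor, hydrogen, acceptor) triple is reported
    once. With ``heavy_atoms_only=True`` the angle criterion is skipped
    and every polar atom is treated as a potential donor — intended for
    crystal structures without protons; such records have
    ``hydrogen_index == -1``.
    """
    set_a = set(int(i) for i in selection_a)
    set_b = set(int(i) for i in selection_b)
    if set_a & set_b:
        raise SelectionOverlapError(
            f"selections share {len(set_a & set_b)} atom(s)"
        )
    require_h = not heavy_atoms_only
    if heavy_atoms_only:
        polar_a = [i for i in sorted(set_a) if _element(frame, i) in _POLAR_ELEMENTS]
        polar_b = [i for i in sorted(set_b) if _element(frame, i) in _POLAR_ELEMENTS]
        donors_a = [(d, -1) for d in polar_a]
        donors_b = [(d, -1) for d in polar_b]
        acc_a, acc_b = polar_a, polar_b
    else:
        donors_a, acc_a = find_donors_acceptors(
            frame, sorted(set_a), require_hydrogens=require_h
        )
        donors_b, acc_b = find_donors_acceptors(
            frame, sorted(set_b), require_hydrogens=require_h
        )
    bonds = _directed_bonds(
        frame, donors_a, acc_b, criteria, frame_index, heavy_atoms_only
    )
    bonds += _directed_bonds(
        frame, donors_b, acc_a, criteria, frame_index, heavy_atoms_only
    )
    unique = {}
    for b in bonds:
        if heavy_atoms_only:
            # without protons the donor/acceptor roles are indistinguishable
            key = (min(b.donor_index, b.acceptor_index), -1,
                   max(b.donor_index, b.acceptor_index))
        else:
            key = (b.donor_index, b.hydrogen_index, b.acceptor_index)
        unique[key] = b
    return sorted(
        unique.values(),
        key=lambda b: (b.donor_index, b.hydrogen_index, b.acceptor_index),
    )


def hbond_count_series(
    traj: Trajectory,
    selection_a,
    selection_b,
    criteria: HBondCriteria = HBondCriteria(),
    heavy_atoms_only: bool = False,
) -> HBondSeries:
    """Per-frame cross-selection bond counts with mean +/- sd.

    The standard deviation uses the population convention (denominator
    T), matching how a per-frame observable over a fixed production
    window is usually summarised.
    """
    counts = [
        len(
            detect_hbonds(
                traj.frame(t),
                selection_a,
                selection_b,
                criteria,
                heavy_atoms_only=heavy_atoms_only,
                frame_index=t,
            )
        )
        for t in range(traj.n_frames)
    ]
    return HBondSeries.from_counts(counts)
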