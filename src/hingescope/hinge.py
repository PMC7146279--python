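"""Hinge-bending analysis: lip distance, state classification, hinge angle.

The mouth of a two-domain enzyme is characterised per frame by

* the distance between the C-alpha centers of the two lips flanking the
  active-site cleft,
* a conformational state derived from that distance (closed < 15 A,
  open > 20 A, semi-open between — boundaries inclusive to semi-open),
* the hinge-bending angle: the rigid rotation of subdomain I relative
  to subdomain II, measured by a two-stage superposition anchored on
  subdomain II,

plus trajectory-level summaries: state occupancy and the number of
conversions between the closed and open endpoint states.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import EmptySelectionError, UnderDeterminedError
from .geometry import center_of_geometry, kabsch, rotation_angle
from .structure_io import RegionSet, StructureFrame, Trajectory, select_ca

__all__ = [
    "ConformationalState",
    "StateThresholds",
    "HingeResult",
    "lip_distance",
    "classify_state",
    "hinge_angle",
    "count_conversions",
    "analyze_trajectory",
]


class ConformationalState(str, Enum):
    CLOSED = "closed"
    SEMI_OPEN = "semi_open"
    OPEN = "open"


@dataclass(frozen=True)
class StateThresholds:
    """Lip-distance cutoffs (A) separating closed / semi-open / open."""

    closed_max: float = 15.0
    open_min: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.closed_max < self.open_min:
            raise ValueError("need 0 < closed_max < open_min")


@dataclass
class HingeResult:
    """Per-frame hinge observables plus occupancy/conversion summary."""

    times: np.ndarray
    lip_distance: np.ndarray
    state: list[ConformationalState]
    hinge_angle: np.ndarray
    occupancy: dict[ConformationalState, float]
    n_conversions: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ns": self.times,
                "distance_A": self.lip_distance,
                "state": [s.value for s in self.state],
                "angle_deg": self.hinge_angle,
            }
        )

    def summary(self) -> dict:
        return {
            "occupancy": {s.value: self.occupancy[s] for s in ConformationalState},
            "n_conversions": self.n_conversions,
            "distance_A": {
                "min": float(np.min(self.lip_distance)),
                "max": float(np.max(self.lip_distance)),
                "mean": float(np.mean(self.lip_distance)),
            },
            "angle_deg": {
                "min": float(np.min(self.hinge_angle)),
                "max": float(np.max(self.hinge_angle)),
                "mean": float(np.mean(self.hinge_angle)),
            },
        }


def lip_distance(frame: StructureFrame, regions: RegionSet) -> float:
    """Distance between the C-alpha geometric centers of the two lips, A."""
    sel1 = select_ca(frame, regions.lip1, regions.chain_id)
    sel2 = select_ca(frame, regions.lip2, regions.chain_id)
    c1 = center_of_geometry(frame.coords[sel1.indices])
    c2 = center_of_geometry(frame.coords[sel2.indices])
    return float(np.linalg.norm(c1 - c2))


def classify_state(
    distance: float, thresholds: StateThresholds = StateThresholds()
) -> ConformationalState:
    """Map a lip distance to a conformational state.

    Open and closed are defined by strict inequalities; a distance of
    exactly ``closed_max`` or ``open_min`` is semi-open.
    """
    if distance < 0:
        raise ValueError(f"negative distance {distance}")
    if distance < thresholds.closed_max:
        return ConformationalState.CLOSED
    if distance > thresholds.open_min:
        return ConformationalState.OPEN
    return ConformationalState.SEMI_OPEN


def _common_ca(
    frame: StructureFrame,
    reference: StructureFrame,
    ranges: Sequence[Sequence[int]],
    chain_id: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired C-alpha index arrays over residues present in both structures."""
    sel_f = select_ca(frame, ranges, chain_id)
    sel_r = select_ca(reference, ranges, chain_id)

    def keyed(structure, sel):
        return {
            (
                structure.atoms[i].residue_number,
                structure.atoms[i].insertion_code,
            ): i
            for i in sel.indices
        }

    map_f = keyed(frame, sel_f)
    map_r = keyed(reference, sel_r)
    common = sorted(set(map_f) & set(map_r))
    if len(common) < 3:
        raise UnderDeterminedError(
            f"only {len(common)} residues common to both structures in "
            f"ranges {list(ranges)}; need >= 3"
        )
    idx_f = np.array([map_f[k] for k in common], dtype=int)
    idx_r = np.array([map_r[k] for k in common], dtype=int)
    return idx_f, idx_r


def hinge_angle(
    frame: StructureFrame, reference: StructureFrame, regions: RegionSet
) -> float:
    """Interdomain rotation of subdomain I relative to subdomain II, degrees.

    Two-stage superposition: (1) the frame is aligned onto the reference
    on the subdomain II C-alphas common to both, removing overall rigid
    motion; (2) the aligned frame's subdomain I C-alphas are fitted onto
    the reference's, and the magnitude of that second rotation is the
    hinge-bending angle. Residues missing from either structure (crystal
    gaps) are dropped from both fits.
    """
    sd2_f, sd2_r = _common_ca(frame, reference, regions.subdomain2, regions.chain_id)
    sd1_f, sd1_r = _common_ca(frame, reference, regions.subdomain1, regions.chain_id)

    anchor, _ = kabsch(frame.coords[sd2_f], reference.coords[sd2_r])
    aligned = anchor.apply(frame.coords)
    relative, _ = kabsch(aligned[sd1_f], reference.coords[sd1_r])
    return rotation_angle(relative.rotation)


def count_conversions(states: Sequence[ConformationalState]) -> int:
    """Number of closed<->open endpoint crossings in a state sequence.

    A conversion is counted each time the sequence reaches ``open`` after
    most recently having been ``closed``, or vice versa. Semi-open frames
    are transparent: they neither count nor reset the most recent
    endpoint.
    """
    if len(states) == 0:
        raise ValueError("empty state sequence")
    conversions = 0
    last_endpoint: ConformationalState | None = None
    for state in states:
        if state is ConformationalState.SEMI_OPEN:
            continue
        if last_endpoint is not None and state is not last_endpoint:
            conversions += 1
        last_endpoint = state
    return conversions


def analyze_trajectory(
    traj: Trajectory,
    regions: RegionSet,
    thresholds: StateThresholds = StateThresholds(),
    reference: StructureFrame | None = None,
) -> HingeResult:
    """Per-frame lip distance, state and hinge angle, plus summaries.

    ``reference`` anchors the hinge-angle superpositions and defaults to
    the trajectory's first frame.
    """
    if reference is None:
        reference = traj.frame(0)

    lip1 = select_ca(traj, regions.lip1, regions.chain_id)
    lip2 = select_ca(traj, regions.lip2, regions.chain_id)
    centers1 = traj.frames[:, lip1.indices, :].mean(axis=1)
    centers2 = traj.frames[:, lip2.indices, :].mean(axis=1)
    distances = np.linalg.norm(centers1 - centers2, axis=1)

    states = [classify_state(d, thresholds) for d in distances]

    # selections are topology-level, so intersect once and reuse per frame
    probe = traj.frame(0)
    sd2_f, sd2_r = _common_ca(probe, reference, regions.subdomain2, regions.chain_id)
    sd1_f, sd1_r = _common_ca(probe, reference, regions.subdomain1, regions.chain_id)
    ref_sd2 = reference.coords[sd2_r]
    ref_sd1 = reference.coords[sd1_r]

    angles = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        anchor, _ = kabsch(traj.frames[t][sd2_f], ref_sd2)
        aligned_sd1 = anchor.apply(traj.frames[t][sd1_f])
        relative, _ = kabsch(aligned_sd1, ref_sd1)
        angles[t] = rotation_angle(relative.rotation)

    total = len(states)
    occupancy = {
        s: sum(1 for x in states if x is s) / total for s in ConformationalState
    }
    return HingeResult(
        times=np.asarray(traj.times, dtype=float),
        lip_distance=distances,
        state=states,
        hinge_angle=angles,
        occupancy=occupancy,
        n_conversions=count_conversions(states),
    )
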