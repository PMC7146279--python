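"""Synthetic two-rigid-domain hinge systems with known ground truth.

The toy enzyme is a C-alpha-only protein made of two compact residue
lattices flanking a narrow cleft, mimicking the jaw-like mouth of a
hinge-bending metallopeptidase at desk scale. Domain II stays fixed;
domain I rotates about a prescribed hinge axis by a per-frame angle
schedule, and isotropic Gaussian coordinate noise is added to every
atom after the rotation so that alignment-based analyses are stressed
realistically. Because the motion is constructed, every observable the
analysis modules estimate — hinge angle, lip distance, conformational
state, conversion count, planted hydrogen bonds — has an exact known
value to compare against.

Default geometry: 100 + 100 residues on 3.8 A lattices, lip layers
facing each other across a 9 A closed-state mouth, with a lever arm
placed so the mouth passes the 20 A open threshold near a 20-degree
hinge rotation — the same order of magnitude as the maximal hinge
movement seen in ACE-family enzymes. Default trajectory: 2,000 frames
at 0.2 ns spacing (a 400 ns span) with 0.1 A coordinate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterizationError
from .geometry import axis_angle_rotation
from .hinge import ConformationalState, StateThresholds, classify_state
from .structure_io import AtomRecord, RegionSet, StructureFrame, Trajectory

__all__ = [
    "ConstantSchedule",
    "SinusoidalSchedule",
    "RandomWalkSchedule",
    "SyntheticHingeParams",
    "ToyEnzyme",
    "GroundTruth",
    "HBondFixture",
    "build_toy_enzyme",
    "generate_hinge_trajectory",
    "generate_hbond_fixture",
]

_LATTICE_SPACING = 3.8  # A, typical consecutive C-alpha distance
_HALF_GAP = 4.5  # A, half-width of the closed-state cleft
_LEVER_OFFSET = 25.0  # A, distance from the hinge point to the block edge


@dataclass(frozen=True)
class ConstantSchedule:
    theta: float = 0.0

    def angles(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n_frames, float(self.theta))


@dataclass(frozen=True)
class SinusoidalSchedule:
    """theta(t) = amplitude * (1 - cos(2 pi t / period)) / 2, period in frames.

    Starts at 0 (the closed reference geometry), peaks at ``amplitude``.
    """

    amplitude: float = 25.0
    period: float = 400.0

    def angles(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        t = np.arange(n_frames, dtype=float)
        return self.amplitude * (1.0 - np.cos(2.0 * np.pi * t / self.period)) / 2.0


@dataclass(frozen=True)
class RandomWalkSchedule:
    """Gaussian random walk in angle with reflecting bounds.

    Reflection keeps the walk inside ``bounds`` without absorbing
    states, so dwell statistics resemble a trajectory that converts
    repeatedly between closed and open rather than escaping one way.
    """

    step_sd: float = 1.0
    bounds: tuple[float, float] = (0.0, 30.0)

    def angles(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounds
        if not lo < hi:
            raise ParameterizationError("random-walk bounds must satisfy lo < hi")
        steps = rng.normal(0.0, self.step_sd, size=n_frames)
        theta = np.empty(n_frames)
        x = lo
        width = hi - lo
        for t in range(n_frames):
            x = x + steps[t]
            # reflect into [lo, hi]
            y = (x - lo) % (2 * width)
            theta[t] = lo + (y if y <= width else 2 * width - y)
        return theta


Schedule = Union[ConstantSchedule, SinusoidalSchedule, RandomWalkSchedule]


@dataclass(frozen=True)
class SyntheticHingeParams:
    n_res_domain1: int = 100
    n_res_domain2: int = 100
    lip_fraction: float = 0.25
    hinge_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    hinge_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    angle_schedule: Schedule = field(default_factory=RandomWalkSchedule)
    noise_sd: float = 0.1
    n_frames: int = 2000
    timestep: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res_domain1 < 10 or self.n_res_domain2 < 10:
            raise ParameterizationError("each domain needs at least 10 residues")
        if not 0.0 < self.lip_fraction <= 1.0:
            raise ParameterizationError("lip_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterizationError("noise_sd must be non-negative")
        if self.n_frames < 1:
            raise ParameterizationError("n_frames must be >= 1")
        axis = np.asarray(self.hinge_axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise ParameterizationError("hinge_axis must have unit norm (tol 1e-9)")


@dataclass
class ToyEnzyme:
    """A built toy structure with everything needed to animate it."""

    frame: StructureFrame
    regions: RegionSet
    theta_open: float  # deg; rotation at which the lip distance reaches open_min
    domain1_indices: np.ndarray
    domain2_indices: np.ndarray
    hinge_axis: np.ndarray
    hinge_point: np.ndarray
    thresholds: StateThresholds


@dataclass
class GroundTruth:
    theta: np.ndarray  # programmed hinge angle per frame, deg
    lip_distance_ideal: np.ndarray  # noise-free lip-center distance, A
    state_ideal: list[ConformationalState]
    planted_hbonds: list[list] = field(default_factory=list)


def _block_coords(n: int) -> np.ndarray:
    """n lattice points on a compact near-cubic 3-D grid, spacing 3.8 A."""
    side = int(np.ceil(n ** (1.0 / 3.0)))
    nz = max(2, side)
    pts = []
    for iy in range(nz):
        for ix in range(nz):
            for iz in range(nz):
                pts.append((ix, iy, iz))
                if len(pts) == n:
                    return np.array(pts, dtype=float) * _LATTICE_SPACING
    return np.array(pts[:n], dtype=float) * _LATTICE_SPACING


def build_toy_enzyme(params: SyntheticHingeParams) -> ToyEnzyme:
    """Construct the two-domain C-alpha toy and its region definitions.

    Domain II sits below the cleft plane (y < 0) and domain I above it,
    both offset from the hinge point along +x so the hinge has a lever
    arm. The mutually closest ``lip_fraction`` of each domain's residues
    (ranked by distance to the other domain's centroid) are the lips,
    and residues are numbered so each lip is a contiguous leading range
    of its subdomain. The returned ``theta_open`` is the rotation of
    domain I about the hinge axis at which the noise-free lip distance
    reaches the open threshold; if no rotation up to 90 degrees opens
    the mouth the geometry is rejected.
    """
    thresholds = StateThresholds()
    n1, n2 = params.n_res_domain1, params.n_res_domain2

    block1 = _block_coords(n1)
    block2 = _block_coords(n2)
    # domain I above the cleft, domain II mirrored below
    block1 = block1 + np.array([_LEVER_OFFSET, _HALF_GAP, 0.0])
    block2 = block2 * np.array([1.0, -1.0, 1.0]) + np.array(
        [_LEVER_OFFSET, -_HALF_GAP, 0.0]
    )

    k1 = int(round(params.lip_fraction * n1))
    k2 = int(round(params.lip_fraction * n2))
    if k1 < 1 or k2 < 1:
        raise ParameterizationError(
            "lip_fraction too small: each lip needs at least one residue"
        )

    c2 = block2.mean(axis=0)
    c1 = block1.mean(axis=0)
    order1 = np.argsort(np.linalg.norm(block1 - c2, axis=1), kind="stable")
    order2 = np.argsort(np.linalg.norm(block2 - c1, axis=1), kind="stable")
    block1 = block1[order1]  # lip residues first
    block2 = block2[order2]

    coords = np.vstack([block1, block2])
    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name="CA",
            element="C",
            residue_name="ALA",
            residue_number=i + 1,
            insertion_code="",
            chain_id="A",
            altloc="",
            occupancy=1.0,
            position=tuple(coords[i]),
        )
        for i in range(n1 + n2)
    ]
    frame = StructureFrame(atoms, coords)
    regions = RegionSet(
        chain_id="A",
        lip1=[[1, k1]],
        lip2=[[n1 + 1, n1 + k2]],
        subdomain1=[[1, n1]],
        subdomain2=[[n1 + 1, n1 + n2]],
    )

    axis = np.asarray(params.hinge_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    point = np.asarray(params.hinge_point, dtype=float)
    lip1_center = block1[:k1].mean(axis=0)
    lip2_center = block2[:k2].mean(axis=0)

    def lip_gap(theta: float) -> float:
        R = axis_angle_rotation(axis, theta)
        rotated = R @ (lip1_center - point) + point
        return float(np.linalg.norm(rotated - lip2_center))

    if lip_gap(0.0) >= thresholds.closed_max:
        raise ParameterizationError(
            f"closed-state lip distance {lip_gap(0.0):.2f} A is not closed"
        )
    grid = np.linspace(0.0, 90.0, 901)
    gaps = np.array([lip_gap(t) for t in grid])
    if not np.any(gaps >= thresholds.open_min):
        raise ParameterizationError(
            "lip distance cannot reach the open threshold for any rotation "
            "up to 90 degrees; increase the lever arm or residue counts"
        )
    first = int(np.argmax(gaps >= thresholds.open_min))
    lo = grid[max(first - 1, 0)]
    theta_open = float(
        brentq(lambda t: lip_gap(t) - thresholds.open_min, lo, grid[first])
    )

    return ToyEnzyme(
        frame=frame,
        regions=regions,
        theta_open=theta_open,
        domain1_indices=np.arange(n1),
        domain2_indices=np.arange(n1, n1 + n2),
        hinge_axis=axis,
        hinge_point=point,
        thresholds=thresholds,
    )


def generate_hinge_trajectory(
    params: SyntheticHingeParams,
) -> tuple[Trajectory, GroundTruth, ToyEnzyme]:
    """Animate the toy enzyme along the angle schedule.

    Frame t applies a rotation of theta(t) about the hinge axis to
    domain I, then adds i.i.d. N(0, noise_sd^2) displacement per
    coordinate to every atom (domain II included). Ground truth holds
    the programmed angles, the noise-free lip-center distances (rotated
    in closed form) and the ideal states under the default thresholds.
    Fully reproducible from ``params.seed``.
    """
    toy = build_toy_enzyme(params)
    rng = np.random.default_rng(params.seed)
    theta = params.angle_schedule.angles(params.n_frames, rng)

    base = toy.frame.coords
    d1 = toy.domain1_indices
    point = toy.hinge_point
    n_frames = params.n_frames

    frames = np.broadcast_to(base, (n_frames, *base.shape)).copy()
    for t in range(n_frames):
        R = axis_angle_rotation(toy.hinge_axis, theta[t])
        frames[t, d1] = (base[d1] - point) @ R.T + point
    if params.noise_sd > 0:
        frames += rng.normal(0.0, params.noise_sd, size=frames.shape)

    k1 = toy.regions.lip1[0][1] - toy.regions.lip1[0][0] + 1
    k2 = toy.regions.lip2[0][1] - toy.regions.lip2[0][0] + 1
    n1 = len(d1)
    lip1_center = base[:k1].mean(axis=0)
    lip2_center = base[n1 : n1 + k2].mean(axis=0)
    ideal = np.empty(n_frames)
    for t in range(n_frames):
        R = axis_angle_rotation(toy.hinge_axis, theta[t])
        rotated = R @ (lip1_center - point) + point
        ideal[t] = np.linalg.norm(rotated - lip2_center)
    states = [classify_state(d, toy.thresholds) for d in ideal]

    times = np.arange(n_frames, dtype=float) * params.timestep
    traj = Trajectory(toy.frame.atoms, frames, times)
    truth = GroundTruth(
        theta=theta,
        lip_distance_ideal=ideal,
        state_ideal=states,
        planted_hbonds=[[] for _ in range(n_frames)],
    )
    return traj, truth, toy


# ---------------------------------------------------------------------------
# Hydrogen-bond fixtures


@dataclass
class HBondFixture:
    frame: StructureFrame
    selection_a: np.ndarray  # donor-side atoms (N and H)
    selection_b: np.ndarray  # acceptor-side atoms (O)
    planted: list[tuple[int, int, int]]  # (donor, hydrogen, acceptor) indices


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _tilted(direction: np.ndarray, angle_deg: float, rng) -> np.ndarray:
    """Unit vector at exactly ``angle_deg`` from ``direction``."""
    perp = np.cross(direction, _random_unit(rng))
    while np.linalg.norm(perp) < 1e-6:
        perp = np.cross(direction, _random_unit(rng))
    perp /= np.linalg.norm(perp)
    R = axis_angle_rotation(perp, angle_deg)
    return R @ direction


def generate_hbond_fixture(
    n_true: int,
    n_decoys: int,
    criteria=None,
    seed: int = 0,
) -> HBondFixture:
    """A frame with planted D-H...A triples and single-criterion decoys.

    True triples satisfy both criteria with margin (distance <= max-0.05
    A, angle <= max-2 deg); decoys violate exactly one criterion by at
    least the same margin, alternating which. Triples sit on a 20 A grid
    so no cross-triple bond can form. Donor-side atoms (N, H) are in
    selection A, acceptors (O) in selection B, so every planted bond
    crosses the selections. A pair of inert carbons per selection keeps
    selections non-empty in degenerate cases.
    """
    from .hbonds import HBondCriteria

    if criteria is None:
        criteria = HBondCriteria()
    if n_true < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    sel_a: list[int] = []
    sel_b: list[int] = []
    planted: list[tuple[int, int, int]] = []

    def add_atom(name, element, resnum, xyz, bucket):
        idx = len(atoms)
        atoms.append(
            AtomRecord(
                serial=idx + 1,
                atom_name=name,
                element=element,
                residue_name="HBX",
                residue_number=resnum,
                insertion_code="",
                chain_id="X",
                altloc="",
                occupancy=1.0,
                position=tuple(xyz),
                het=True,
            )
        )
        coords.append(np.asarray(xyz, dtype=float))
        bucket.append(idx)
        return idx

    dist_margin, angle_margin = 0.05, 2.0
    total = n_true + n_decoys
    for k in range(total):
        site = np.array([20.0 * k, 0.0, 0.0])
        is_true = k < n_true
        violate_distance = (k - n_true) % 2 == 0  # decoys alternate
        v = _random_unit(rng)

        if is_true or not violate_distance:
            r = rng.uniform(2.7, criteria.max_da_distance - dist_margin)
        else:
            r = rng.uniform(
                criteria.max_da_distance + dist_margin,
                criteria.max_da_distance + 0.5,
            )
        if is_true or violate_distance:
            alpha = rng.uniform(0.0, criteria.max_hda_angle - angle_margin)
        else:
            alpha = rng.uniform(criteria.max_hda_angle + angle_margin, 60.0)

        d_idx = add_atom("N", "N", k + 1, site, sel_a)
        h_idx = add_atom("H", "H", k + 1, site + 1.0 * _tilted(v, alpha, rng), sel_a)
        a_idx = add_atom("O", "O", 1000 + k, site + r * v, sel_b)
        if is_true:
            planted.append((d_idx, h_idx, a_idx))

    # inert carbons keep both selections non-empty
    add_atom("C1", "C", 5000, np.array([-40.0, 0.0, 0.0]), sel_a)
    add_atom("C2", "C", 5001, np.array([-60.0, 0.0, 0.0]), sel_b)

    frame = StructureFrame(atoms, np.array(coords))
    return HBondFixture(
        frame=frame,
        selection_a=np.array(sel_a, dtype=int),
        selection_b=np.array(sel_b, dtype=int),
        planted=planted,
    )
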