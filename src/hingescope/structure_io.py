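"""Structure and trajectory I/O plus residue-range selections.

Reads single structures and multi-model trajectories from PDB files
(parsing backed by gemmi), resolves alternate locations by occupancy,
and turns residue-range region definitions into atom-index selections.
All coordinates are in Angstroms; residue numbers follow author (PDB)
numbering, with ranges inclusive on both ends.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    PDBParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "StructureFrame",
    "Trajectory",
    "RegionSet",
    "Selection",
    "read_pdb",
    "read_trajectory",
    "write_pdb",
    "select_ca",
    "write_timeseries",
    "read_timeseries",
    "load_preset",
    "available_presets",
]

_PRESET_DIR = Path(__file__).parent / "presets"


@dataclass(frozen=True)
class AtomRecord:
    """One atom's metadata; the position is duplicated in the frame's coords."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    altloc: str
    occupancy: float
    position: tuple[float, float, float]
    het: bool = False


@dataclass
class StructureFrame:
    """A single conformation: atom metadata plus an N x 3 coordinate array."""

    atoms: list[AtomRecord]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_coords(self, coords: np.ndarray) -> "StructureFrame":
        """Same topology with replaced coordinates."""
        return StructureFrame(self.atoms, np.asarray(coords, dtype=float))


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    ``frames`` is a T x N x 3 array in Angstroms; ``times`` holds one
    strictly increasing time per frame, in nanoseconds.
    """

    topology: list[AtomRecord]
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be T x N x 3")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError("frame atom count does not match topology")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("times length does not match frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame(self, t: int) -> StructureFrame:
        return StructureFrame(self.topology, self.frames[t])

    def __iter__(self) -> Iterator[StructureFrame]:
        for t in range(self.n_frames):
            yield self.frame(t)


Range = Sequence[int]  # inclusive [start, end]


def _ranges_overlap(ranges: Sequence[Range]) -> bool:
    spans = sorted((int(a), int(b)) for a, b in ranges)
    return any(spans[i][1] >= spans[i + 1][0] for i in range(len(spans) - 1))


def _union_contains(outer: Sequence[Range], inner: Sequence[Range]) -> bool:
    covered = set()
    for a, b in outer:
        covered.update(range(int(a), int(b) + 1))
    for a, b in inner:
        if not set(range(int(a), int(b) + 1)) <= covered:
            return False
    return True


@dataclass
class RegionSet:
    """Named residue-range partitions on one chain.

    Lips are the residue sets flanking the active-site cleft whose
    C-alpha centers define the mouth-opening distance; subdomains are
    the two rigid bodies whose relative rotation is the hinge angle.
    Each region is a list of inclusive ``[start, end]`` residue ranges
    in author numbering; every lip range must lie inside its subdomain.
    """

    chain_id: str
    lip1: list[list[int]]
    lip2: list[list[int]]
    subdomain1: list[list[int]]
    subdomain2: list[list[int]]

    def __post_init__(self) -> None:
        for name in ("lip1", "lip2", "subdomain1", "subdomain2"):
            ranges = getattr(self, name)
            if _ranges_overlap(ranges):
                raise ValueError(f"overlapping ranges in region {name!r}")
        if not _union_contains(self.subdomain1, self.lip1):
            raise ValueError("lip1 not contained in subdomain1")
        if not _union_contains(self.subdomain2, self.lip2):
            raise ValueError("lip2 not contained in subdomain2")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RegionSet":
        with open(source) as fh:
            data = yaml.safe_load(fh)
        return cls(
            chain_id=str(data["chain_id"]),
            lip1=[list(map(int, r)) for r in data["lip1"]],
            lip2=[list(map(int, r)) for r in data["lip2"]],
            subdomain1=[list(map(int, r)) for r in data["subdomain1"]],
            subdomain2=[list(map(int, r)) for r in data["subdomain2"]],
        )

    def to_yaml(self, destination: str | Path) -> None:
        data = {
            "chain_id": self.chain_id,
            "lip1": [list(r) for r in self.lip1],
            "lip2": [list(r) for r in self.lip2],
            "subdomain1": [list(r) for r in self.subdomain1],
            "subdomain2": [list(r) for r in self.subdomain2],
        }
        with open(destination, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def available_presets() -> list[str]:
    return sorted(p.stem for p in _PRESET_DIR.glob("*.yaml"))


def load_preset(name: str) -> RegionSet:
    """Load a shipped region preset (e.g. ``sace_cdomain`` or ``ace2``)."""
    path = _PRESET_DIR / f"{name}.yaml"
    if not path.exists():
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        )
    return RegionSet.from_yaml(path)


# ---------------------------------------------------------------------------
# PDB reading


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one record per atom site: highest occupancy, ties by altloc id."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (
            atom.chain_id,
            atom.residue_number,
            atom.insertion_code,
            atom.residue_name,
            atom.atom_name,
        )
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            held = best[key]
            if (atom.occupancy, _altloc_rank(atom.altloc)) > (
                held.occupancy,
                _altloc_rank(held.altloc),
            ):
                best[key] = atom
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # earlier altloc letter wins a tie -> higher rank
    return -ord(altloc) if altloc else 0.0


_TWO_LETTER = {
    "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "CU", "NI", "CO", "SE",
}


def _infer_element(atom_name: str, het: bool) -> str:
    name = atom_name.strip()
    bare = name.lstrip("0123456789")
    if not bare:
        return ""
    if bare[0] in "HDT" and not het:
        return "H" if bare[0] != "T" else "H"
    if het and bare.upper() in _TWO_LETTER:
        return bare.capitalize()
    return bare[0].upper()


def _frame_from_model(model: gemmi.Model) -> StructureFrame:
    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in residue:
                element = atom.element.name
                if element in ("X", ""):
                    element = _infer_element(atom.name, het)
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        atom_name=atom.name,
                        element=element,
                        residue_name=residue.name,
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        altloc="" if atom.altloc in ("\0", " ", "") else atom.altloc,
                        occupancy=float(atom.occ),
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        het=het,
                    )
                )
    atoms = _resolve_altlocs(atoms)
    coords = np.array([a.position for a in atoms], dtype=float)
    if len(atoms) == 0:
        coords = coords.reshape(0, 3)
    return StructureFrame(atoms, coords)


def _check_pdb_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except (ValueError, IndexError):
                raise PDBParseError(
                    f"malformed coordinate fields in record {line[:6].strip()}",
                    line_number=i,
                ) from None


def read_pdb(
    source: str | Path | io.TextIOBase,
    model_policy: str = "first",
    timestep: float = 1.0,
) -> StructureFrame | Trajectory:
    """Read a PDB file or text stream.

    With ``model_policy='first'`` the first MODEL (or the single implicit
    model) becomes a :class:`StructureFrame`. With ``'all'`` every MODEL
    becomes one frame of a :class:`Trajectory` whose times default to
    ``frame index * timestep`` nanoseconds. Alternate locations are
    resolved to the highest-occupancy copy (ties to the earlier altloc
    letter); HETATM records are retained and carry ``het=True``.
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    _check_pdb_lines(text)
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    structure.setup_entities()
    frames = [_frame_from_model(model) for model in structure]
    frames = [f for f in frames if f.n_atoms > 0]
    if not frames:
        raise EmptyStructureError("no ATOM/HETATM records found")
    if model_policy == "first":
        return frames[0]
    n = frames[0].n_atoms
    if any(f.n_atoms != n for f in frames):
        raise PDBParseError("MODELs differ in atom count")
    coords = np.stack([f.coords for f in frames])
    times = np.arange(len(frames), dtype=float) * timestep
    return Trajectory(frames[0].atoms, coords, times)


def read_trajectory(
    topology: str | Path,
    coordinates: str | Path,
    timestep: float = 1.0,
) -> Trajectory:
    """Read a topology PDB plus a plain-text coordinate stream.

    The coordinate file is a whitespace table of x y z triples, frames
    concatenated in order; its row count must be a multiple of the
    topology's atom count. Times are ``frame index * timestep`` ns.
    """
    frame = read_pdb(topology, model_policy="first")
    raw = np.loadtxt(coordinates, dtype=float)
    raw = np.atleast_2d(raw)
    if raw.shape[1] != 3 or raw.shape[0] % frame.n_atoms != 0:
        raise PDBParseError(
            f"coordinate stream has {raw.shape} values; expected a multiple "
            f"of {frame.n_atoms} x-y-z rows"
        )
    coords = raw.reshape(-1, frame.n_atoms, 3)
    times = np.arange(coords.shape[0], dtype=float) * timestep
    return Trajectory(frame.atoms, coords, times)


def _to_gemmi(obj: StructureFrame | Trajectory) -> gemmi.Structure:
    structure = gemmi.Structure()
    if isinstance(obj, Trajectory):
        frame_sets = [(obj.topology, obj.frames[t]) for t in range(obj.n_frames)]
    else:
        frame_sets = [(obj.atoms, obj.coords)]
    # gemmi's add_model/add_chain/add_residue copy their argument, so build
    # through the returned references
    for m, (atoms, coords) in enumerate(frame_sets, start=1):
        model = structure.add_model(gemmi.Model(m))
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple, gemmi.Residue] = {}
        for atom_rec, xyz in zip(atoms, coords):
            if atom_rec.chain_id not in chains:
                chains[atom_rec.chain_id] = model.add_chain(
                    gemmi.Chain(atom_rec.chain_id)
                )
            rkey = (
                atom_rec.chain_id,
                atom_rec.residue_number,
                atom_rec.insertion_code,
                atom_rec.residue_name,
            )
            if rkey not in residues:
                residue = gemmi.Residue()
                residue.name = atom_rec.residue_name
                residue.seqid = gemmi.SeqId(
                    atom_rec.residue_number, atom_rec.insertion_code or " "
                )
                residue.het_flag = "H" if atom_rec.het else "A"
                residues[rkey] = chains[atom_rec.chain_id].add_residue(residue)
            atom = gemmi.Atom()
            atom.name = atom_rec.atom_name
            atom.serial = atom_rec.serial
            atom.element = gemmi.Element(atom_rec.element)
            atom.occ = atom_rec.occupancy
            atom.altloc = atom_rec.altloc or "\0"
            atom.pos = gemmi.Position(*map(float, xyz))
            residues[rkey].add_atom(atom)
    return structure


def write_pdb(obj: StructureFrame | Trajectory, destination: str | Path) -> None:
    """Write a structure (single model) or trajectory (one MODEL per frame)."""
    structure = _to_gemmi(obj)
    structure.write_pdb(str(destination))


# ---------------------------------------------------------------------------
# Selections


@dataclass
class Selection:
    """Atom indices matched by a region, plus residues that were absent."""

    indices: np.ndarray
    missing_residues: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __getitem__(self, item):
        return self.indices[item]


def select_ca(
    frame_or_topology: StructureFrame | Trajectory | list[AtomRecord],
    region: Sequence[Range],
    chain_id: str,
) -> Selection:
    """Indices of C-alpha atoms in the given residue ranges of one chain.

    Ordered by residue number then insertion code. HETATM records never
    match (calcium ions share the name CA but are het-flagged). Residues
    listed in the region but absent from the structure are reported in
    ``missing_residues`` and logged, not raised: crystal structures
    routinely lack loop residues.
    """
    if not region:
        raise EmptySelectionError("region definition is empty")
    if isinstance(frame_or_topology, StructureFrame):
        atoms = frame_or_topology.atoms
    elif isinstance(frame_or_topology, Trajectory):
        atoms = frame_or_topology.topology
    else:
        atoms = frame_or_topology

    wanted = set()
    for a, b in region:
        wanted.update(range(int(a), int(b) + 1))

    hits = []
    found_residues = set()
    for i, atom in enumerate(atoms):
        if (
            not atom.het
            and atom.atom_name == "CA"
            and atom.chain_id == chain_id
            and atom.residue_number in wanted
        ):
            hits.append((atom.residue_number, atom.insertion_code, i))
            found_residues.add(atom.residue_number)
    if not hits:
        raise EmptySelectionError(
            f"no C-alpha atoms match ranges {list(region)} on chain {chain_id!r}"
        )
    hits.sort()
    missing = sorted(wanted - found_residues)
    if missing:
        logger.warning(
            "%d residue(s) in region absent from structure: %s",
            len(missing),
            missing,
        )
        warnings.warn(
            f"{len(missing)} region residue(s) absent from structure",
            stacklevel=2,
        )
    return Selection(np.array([i for _, _, i in hits], dtype=int), missing)


# ---------------------------------------------------------------------------
# Time-series CSV


def write_timeseries(table, destination: str | Path) -> None:
    """Write per-frame records as CSV with a header row.

    Accepts a DataFrame or any record collection DataFrame() accepts.
    Values round-trip to 6 significant digits.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    df.to_csv(destination, index=False, float_format="%.6g")


def read_timeseries(source: str | Path) -> pd.DataFrame:
    return pd.read_csv(source)
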