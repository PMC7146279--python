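import numpy as np
import pytest

from hingescope import AtomRecord, StructureFrame


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_frame(spec):
    """Build a StructureFrame from (name, element, resname, resnum, chain, xyz)
    tuples, optionally with a trailing het flag."""
    atoms = []
    coords = []
    for i, entry in enumerate(spec):
        name, element, resname, resnum, chain, xyz = entry[:6]
        het = entry[6] if len(entry) > 6 else False
        atoms.append(
            AtomRecord(
                serial=i + 1,
                atom_name=name,
                element=element,
                residue_name=resname,
                residue_number=resnum,
                insertion_code="",
                chain_id=chain,
                altloc="",
                occupancy=1.0,
                position=tuple(xyz),
                het=het,
            )
        )
        coords.append(xyz)
    return StructureFrame(atoms, np.asarray(coords, dtype=float))


@pytest.fixture
def ca_ladder():
    """Ten-residue chain A with one CA per residue, 3.8 A apart on x."""
    return make_frame(
        [("CA", "C", "ALA", i, "A", (3.8 * i, 0.0, 0.0)) for i in range(1, 11)]
    )


@pytest.fixture
def random_rigid(rng):
    """Factory for random proper rigid motions (R, t)."""

    def factory():
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, 180)
        from hingescope import axis_angle_rotation

        return axis_angle_rotation(axis, angle), rng.uniform(-20, 20, size=3)

    return factory
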