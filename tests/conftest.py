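import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ifaceprof.interactions import Thresholds
from ifaceprof.structure_io import AtomRecord, ChemistryTable, Ensemble, Frame, RegionScheme
from ifaceprof.synthetic import RESIDUE_TEMPLATES, build_residue


@pytest.fixture(scope="session")
def table() -> ChemistryTable:
    return ChemistryTable.default()


@pytest.fixture(scope="session")
def scheme() -> RegionScheme:
    return RegionScheme()


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()


def make_frame(residue_specs, index=0) -> Frame:
    """Build a single frame from (res_name, chain, res_seq, origin[, rotation])."""
    records, coords = [], []
    for spec in residue_specs:
        res_name, chain, seq, origin = spec[:4]
        rot = spec[4] if len(spec) > 4 else None
        recs, xyz = build_residue(res_name, chain, seq, np.asarray(origin, float), rot)
        records.extend(recs)
        coords.append(xyz)
    coords = np.vstack(coords)
    records = [
        AtomRecord(
            serial=i + 1, name=r.name, element=r.element, alt_loc="",
            res_name=r.res_name, chain_id=r.chain_id, res_seq=r.res_seq,
            i_code="", position=coords[i], is_hetatm=r.is_hetatm,
        )
        for i, r in enumerate(records)
    ]
    return Frame(records, coords, index=index)


def make_bare_residue_frame(residues) -> Frame:
    """Frame from explicit atoms: (res_name, chain, seq, [(name, element, xyz), ...])."""
    records, coords = [], []
    serial = 1
    for res_name, chain, seq, atoms in residues:
        for name, element, xyz in atoms:
            records.append(
                AtomRecord(
                    serial=serial, name=name, element=element, alt_loc="",
                    res_name=res_name, chain_id=chain, res_seq=seq, i_code="",
                    position=np.asarray(xyz, float),
                )
            )
            coords.append(xyz)
            serial += 1
    return Frame(records, np.asarray(coords, float), index=0)


RANDOM_FRAME_PALETTE = tuple(RESIDUE_TEMPLATES)


def random_frame(rng: np.random.Generator, n_residues: int, box: float = 1.8) -> Frame:
    """Random frame: template residues thrown into a box with random rotation.

    Small box guarantees plenty of genuine contacts of every kind for
    detector-vs-oracle comparisons.
    """
    specs = []
    for i in range(n_residues):
        name = RANDOM_FRAME_PALETTE[rng.integers(len(RANDOM_FRAME_PALETTE))]
        origin = rng.uniform(0.0, box, size=3)
        rot = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()
        chain = "A" if i % 2 == 0 else "B"
        specs.append((name, chain, 100 + i, origin, rot))
    return make_frame(specs)


def frame_to_ensemble(frame: Frame) -> Ensemble:
    return Ensemble(frame.topology, frame.coords[None, :, :])
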