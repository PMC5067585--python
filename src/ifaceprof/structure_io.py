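"""Multi-model PDB I/O, ensemble containers and the residue chemistry table.

The central container is :class:`Ensemble`: a fixed topology (one
:class:`AtomRecord` per atom, identical across frames) plus an
``(n_frames, n_atoms, 3)`` coordinate array in nanometres.  All downstream
analyses (contact detection, clustering, covariance analysis) consume this
container.  Coordinates are converted from PDB angstroms on read and back on
write; every geometric threshold in the package is therefore expressed in nm.

Parsing and serialisation are delegated to :mod:`gemmi`; this module layers
the ensemble contracts on top: topology-consistency checks across MODEL
blocks, the alternate-location policy (keep blank or ``A``), element
inference and hydrogen-name normalisation (``1HH1`` → ``HH11``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("ifaceprof")

ANGSTROM_PER_NM = 10.0

#: Default atomic masses (unified amu), used for side-chain centres of mass.
DEFAULT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: Backbone heavy-atom names used for RMSD/clustering selections.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Hydrogens bonded to backbone atoms; every other hydrogen in a residue is
#: treated as part of the side chain (e.g. for side-chain centres of mass).
BACKBONE_HYDROGENS = frozenset({"H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"})


class StructureError(Exception):
    """Base class for structural I/O and consistency errors."""


class PDBParseError(StructureError):
    """A PDB file could not be parsed."""


class TopologyMismatchError(StructureError):
    """MODEL blocks of one file disagree in atom identity or count."""

    def __init__(self, model: int, detail: str):
        self.model = model
        super().__init__(f"topology mismatch in model {model}: {detail}")


class RegionError(StructureError):
    """Unknown region label or chain in a region scheme lookup."""


# ---------------------------------------------------------------------------
# Atom / frame / ensemble containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology (PDB v3.3 record model)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    position: np.ndarray  # (3,) nm; frame-0 coordinates for topology records
    occupancy_field: float = 1.0
    is_hetatm: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """Residue identity: (chain_id, res_seq, i_code)."""
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def identity(self) -> tuple[str, int, str, str]:
        """Topology identity compared across MODEL blocks."""
        return (self.chain_id, self.res_seq, self.res_name, self.name)


@dataclass(frozen=True)
class ResidueView:
    """Indices of one residue's atoms within a topology."""

    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    atom_indices: tuple[int, ...]
    atom_index_by_name: Mapping[str, int]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    def index_of(self, atom_name: str) -> int | None:
        return self.atom_index_by_name.get(atom_name)


class Frame:
    """One conformation: the shared topology plus an (n_atoms, 3) nm array."""

    def __init__(self, topology: Sequence[AtomRecord], coords: np.ndarray, index: int = 0):
        if coords.shape != (len(topology), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(topology)}, 3)")
        if index < 0:
            raise ValueError("frame index must be >= 0")
        self.topology = tuple(topology)
        self.coords = np.asarray(coords, dtype=float)
        self.index = index
        self._residues: tuple[ResidueView, ...] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def atoms(self) -> Iterator[AtomRecord]:
        """Iterate AtomRecords carrying this frame's coordinates."""
        for rec, xyz in zip(self.topology, self.coords):
            yield replace(rec, position=xyz)

    def residues(self) -> tuple[ResidueView, ...]:
        if self._residues is None:
            self._residues = group_residues(self.topology)
        return self._residues


def group_residues(topology: Sequence[AtomRecord]) -> tuple[ResidueView, ...]:
    """Group topology atoms into residues by (chain_id, res_seq, i_code)."""
    order: list[tuple[str, int, str]] = []
    groups: dict[tuple[str, int, str], list[int]] = {}
    names: dict[tuple[str, int, str], str] = {}
    for i, rec in enumerate(topology):
        key = rec.residue_key
        if key not in groups:
            groups[key] = []
            names[key] = rec.res_name
            order.append(key)
        groups[key].append(i)
    views = []
    for key in order:
        idx = tuple(groups[key])
        by_name = {topology[i].name: i for i in idx}
        views.append(ResidueView(key[0], key[1], key[2], names[key], idx, by_name))
    return tuple(views)


class Ensemble:
    """An ordered set of frames over one fixed topology.

    Invariants: at least one frame; every frame shares the identical
    (chain_id, res_seq, res_name, name) atom sequence.
    """

    def __init__(self, topology: Sequence[AtomRecord], coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (len(topology), 3):
            raise ValueError(
                f"coords shape {coords.shape} incompatible with {len(topology)} atoms"
            )
        if coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.topology = tuple(topology)
        self.coords = coords
        self._residues: tuple[ResidueView, ...] | None = None

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        f = Frame(self.topology, self.coords[i], index=i)
        f._residues = self.residues()  # share the cached grouping
        return f

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def residues(self) -> tuple[ResidueView, ...]:
        if self._residues is None:
            self._residues = group_residues(self.topology)
        return self._residues

    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.topology:
            seen.setdefault(rec.chain_id, None)
        return tuple(seen)

    def subset(self, atom_indices: Sequence[int]) -> "Ensemble":
        """A new ensemble restricted to the given topology indices."""
        idx = list(atom_indices)
        if not idx:
            raise ValueError("empty atom selection")
        topo = [self.topology[i] for i in idx]
        return Ensemble(topo, self.coords[:, idx, :])

    def window(self, start: int, stop: int) -> "Ensemble":
        """Frames ``start:stop`` (python slice semantics) as a new ensemble."""
        if not (0 <= start < stop <= self.n_frames):
            raise ValueError(
                f"frame window [{start}, {stop}) outside 0..{self.n_frames}"
            )
        return Ensemble(self.topology, self.coords[start:stop])

    def atom_indices(
        self,
        atom_names: Iterable[str] | None = None,
        chains: Iterable[str] | None = None,
    ) -> list[int]:
        names = set(atom_names) if atom_names is not None else None
        ch = set(chains) if chains is not None else None
        return [
            i
            for i, rec in enumerate(self.topology)
            if (names is None or rec.name in names)
            and (ch is None or rec.chain_id in ch)
        ]


# ---------------------------------------------------------------------------
# Region scheme
# ---------------------------------------------------------------------------

DEFAULT_REGION_RANGES: dict[str, tuple[int, int]] = {
    "SH2": (589, 687),
    "L": (688, 693),
    "PTM": (694, 706),
    "nTAD": (707, 714),
}

REQUIRED_REGIONS = ("SH2", "L", "PTM", "nTAD")


@dataclass(frozen=True)
class RegionScheme:
    """Named inclusive residue-number ranges, shared by both chains.

    Defaults follow STAT5A numbering: the SH2 domain (589–687), the short
    flexible linker L (688–693), the phosphotyrosine motif PTM (694–706,
    around pY694) and the N-terminal transactivation-domain segment nTAD
    (707–714).
    """

    ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_RANGES)
    )

    def __post_init__(self):
        for label in REQUIRED_REGIONS:
            if label not in self.ranges:
                raise RegionError(f"required region label {label!r} missing")
        items = sorted(self.ranges.items(), key=lambda kv: kv[1])
        for (la, (a0, a1)), (lb, (b0, b1)) in zip(items, items[1:]):
            if a1 < a0 or b1 < b0:
                raise RegionError("region range with hi < lo")
            if b0 <= a1:
                raise RegionError(f"regions {la!r} and {lb!r} overlap")

    def range(self, label: str) -> tuple[int, int]:
        try:
            return self.ranges[label]
        except KeyError:
            raise RegionError(f"unknown region label {label!r}") from None

    def region_of(self, res_seq: int) -> str | None:
        for label, (lo, hi) in self.ranges.items():
            if lo <= res_seq <= hi:
                return label
        return None


def select_region(
    ensemble: Ensemble, chain: str, region: str, scheme: RegionScheme
) -> Ensemble:
    """Atoms of ``chain`` whose residue number lies in the region's range.

    An empty intersection raises only for unknown chain/label; a region that
    happens to contain no residues of the structure yields an empty-selection
    error by the Ensemble contract, so the caller is told explicitly.
    """
    lo, hi = scheme.range(region)
    if chain not in ensemble.chains():
        raise RegionError(f"unknown chain {chain!r}; present: {ensemble.chains()}")
    idx = [
        i
        for i, rec in enumerate(ensemble.topology)
        if rec.chain_id == chain and lo <= rec.res_seq <= hi
    ]
    if not idx:
        # Empty view is not an error per contract: return a 0-atom shell.
        out = Ensemble.__new__(Ensemble)
        out.topology = ()
        out.coords = ensemble.coords[:, :0, :]
        out._residues = ()
        return out
    return ensemble.subset(idx)


# ---------------------------------------------------------------------------
# Chemistry table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemistryEntry:
    """Donor/acceptor/side-chain/charge/aromatic atom sets for one residue."""

    res_name: str
    donors: tuple[tuple[str, tuple[str, ...]], ...]  # (heavy, bonded hydrogens)
    acceptors: frozenset[str]
    sidechain: frozenset[str]  # heavy atoms; hydrogens attached by exclusion
    positive: frozenset[str]
    negative: frozenset[str]
    aromatic: frozenset[str]


@dataclass(frozen=True)
class UnknownResidue:
    """Typed marker for residue codes absent from the chemistry table."""

    res_name: str


class ChemistryTable:
    """Residue chemistry knowledge base loaded from an editable TSV.

    Wildcard (``*``) rows contribute backbone chemistry to every residue in
    the table; ``remove_donor`` rows mask a wildcard donor (proline N).
    """

    def __init__(
        self,
        entries: Mapping[str, ChemistryEntry],
        masses: Mapping[str, float] | None = None,
    ):
        self._entries = dict(entries)
        self.masses = dict(masses or DEFAULT_MASSES)

    def get(self, res_name: str) -> ChemistryEntry | None:
        return self._entries.get(res_name)

    def __contains__(self, res_name: str) -> bool:
        return res_name in self._entries

    def residue_codes(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def without(self, res_name: str) -> "ChemistryTable":
        """A copy with one residue code removed (treated as unknown)."""
        entries = {k: v for k, v in self._entries.items() if k != res_name}
        return ChemistryTable(entries, self.masses)

    def mass(self, element: str) -> float:
        return self.masses.get(element.upper(), 0.0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChemistryTable":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 4 tab-separated fields"
                    )
                rows.append(tuple(parts))
        return cls._from_rows(rows)

    @classmethod
    def default(cls) -> "ChemistryTable":
        """The packaged table (20 standard residues + phosphotyrosine PTR)."""
        ref = resources.files("ifaceprof.data").joinpath("chemistry.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @classmethod
    def _from_rows(cls, rows: Sequence[tuple[str, str, str, str]]) -> "ChemistryTable":
        wildcard_donors: list[tuple[str, tuple[str, ...]]] = []
        wildcard_acceptors: set[str] = set()
        per_res: dict[str, dict[str, object]] = {}

        def bucket(res: str) -> dict[str, object]:
            return per_res.setdefault(
                res,
                {
                    "donor": [],
                    "acceptor": set(),
                    "sidechain": set(),
                    "positive": set(),
                    "negative": set(),
                    "aromatic": set(),
                    "remove_donor": set(),
                },
            )

        for res, role, atom, hyd in rows:
            hydrogens = tuple(h for h in hyd.split("|") if h and h != "-")
            if res == "*":
                if role == "donor":
                    wildcard_donors.append((atom, hydrogens))
                elif role == "acceptor":
                    wildcard_acceptors.add(atom)
                else:
                    raise ValueError(f"wildcard rows support donor/acceptor, not {role!r}")
                continue
            b = bucket(res)
            if atom == "-":
                continue  # existence-only row (e.g. glycine side chain)
            if role == "donor":
                b["donor"].append((atom, hydrogens))  # type: ignore[union-attr]
            elif role == "remove_donor":
                b["remove_donor"].add(atom)  # type: ignore[union-attr]
            elif role in ("acceptor", "sidechain", "positive", "negative", "aromatic"):
                b[role].add(atom)  # type: ignore[union-attr]
            else:
                raise ValueError(f"unknown role {role!r} for residue {res!r}")

        entries = {}
        for res, b in per_res.items():
            donors = [
                d for d in wildcard_donors if d[0] not in b["remove_donor"]
            ] + list(b["donor"])  # type: ignore[arg-type]
            entries[res] = ChemistryEntry(
                res_name=res,
                donors=tuple(donors),
                acceptors=frozenset(wildcard_acceptors | b["acceptor"]),  # type: ignore[operator]
                sidechain=frozenset(b["sidechain"]),  # type: ignore[arg-type]
                positive=frozenset(b["positive"]),  # type: ignore[arg-type]
                negative=frozenset(b["negative"]),  # type: ignore[arg-type]
                aromatic=frozenset(b["aromatic"]),  # type: ignore[arg-type]
            )
        return cls(entries)


def residue_chemistry(
    res_name: str, table: ChemistryTable
) -> ChemistryEntry | UnknownResidue:
    """Look up a residue's chemistry; unknown codes yield a typed marker.

    Detection modules exclude unknown residues (with a logged warning) rather
    than failing, so a stray ligand or cap does not abort an analysis.
    """
    entry = table.get(res_name)
    if entry is None:
        logger.warning("residue code %r not in chemistry table; excluded", res_name)
        return UnknownResidue(res_name)
    return entry


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def normalize_hydrogen_name(name: str) -> str:
    """Map rotated hydrogen names (``1HH1``) to IUPAC order (``HH11``)."""
    if name and name[0].isdigit():
        return name[1:] + name[0]
    return name


def _keep_altloc(altloc: str) -> bool:
    return altloc in ("", "\0", " ", "A")


def read_pdb_models(path: str | Path) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    One frame per MODEL block; a file without MODEL records yields a single
    frame.  Coordinates are converted Å→nm.  PTR (phosphotyrosine) is accepted
    from either ATOM or HETATM records.  Only blank/'A' alternate locations
    are kept.  A topology mismatch across models raises
    :class:`TopologyMismatchError` naming the first divergent model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no MODEL/ATOM content")

    frames_atoms: list[list[AtomRecord]] = []
    frames_xyz: list[list[tuple[float, float, float]]] = []
    for model in st:
        atoms: list[AtomRecord] = []
        xyz: list[tuple[float, float, float]] = []
        for chain in model:
            for res in chain:
                for atom in res:
                    if not _keep_altloc(atom.altloc):
                        continue
                    name = normalize_hydrogen_name(atom.name.strip())
                    element = atom.element.name.strip().upper()
                    if not element or element == "X":
                        element = _infer_element(name)
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            name=name,
                            element=element,
                            alt_loc="" if atom.altloc in ("\0", " ") else atom.altloc,
                            res_name=res.name.strip(),
                            chain_id=chain.name,
                            res_seq=res.seqid.num,
                            i_code="" if res.seqid.icode in (" ", "\0") else res.seqid.icode,
                            position=np.zeros(3),
                            occupancy_field=atom.occ,
                            is_hetatm=(res.het_flag == "H"),
                        )
                    )
                    xyz.append(
                        (
                            atom.pos.x / ANGSTROM_PER_NM,
                            atom.pos.y / ANGSTROM_PER_NM,
                            atom.pos.z / ANGSTROM_PER_NM,
                        )
                    )
        frames_atoms.append(atoms)
        frames_xyz.append(xyz)

    if not frames_atoms or not frames_atoms[0]:
        raise PDBParseError(f"{path}: no ATOM/HETATM records")

    ref = [a.identity for a in frames_atoms[0]]
    for m, atoms in enumerate(frames_atoms[1:], start=2):
        ids = [a.identity for a in atoms]
        if ids != ref:
            if len(ids) != len(ref):
                detail = f"{len(ids)} atoms vs {len(ref)} in model 1"
            else:
                k = next(i for i, (x, y) in enumerate(zip(ids, ref)) if x != y)
                detail = f"atom {k}: {ids[k]} vs {ref[k]}"
            raise TopologyMismatchError(m, detail)

    coords = np.asarray(frames_xyz, dtype=float)
    topo = [
        replace(rec, position=coords[0, i]) for i, rec in enumerate(frames_atoms[0])
    ]
    ens = Ensemble(topo, coords)
    _warn_if_wrapped(ens)
    return ens


def _infer_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H":
        return "H"
    for two in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        if stripped[:2] == two:
            return two
    return stripped[0]


def _warn_if_wrapped(ensemble: Ensemble, max_extent_nm: float = 50.0) -> None:
    # Periodic imaging is out of scope; a huge extent usually means the
    # molecule crosses a box boundary in the source trajectory.
    span = ensemble.coords.max(axis=(0, 1)) - ensemble.coords.min(axis=(0, 1))
    if np.any(span > max_extent_nm):
        warnings.warn(
            f"ensemble extent {span} nm exceeds {max_extent_nm} nm; "
            "coordinates may be wrapped across periodic boundaries",
            stacklevel=2,
        )


def write_pdb_models(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a fixed-width multi-model PDB file (nm→Å)."""
    if ensemble is None or ensemble.n_atoms == 0:
        raise ValueError("cannot write an empty ensemble")
    st = gemmi.Structure()
    st.name = "ifaceprof"
    for f in range(ensemble.n_frames):
        model = gemmi.Model(f + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        res_map: dict[tuple[str, int, str], gemmi.Residue] = {}
        for i, rec in enumerate(ensemble.topology):
            if rec.chain_id not in chain_map:
                chain = gemmi.Chain(rec.chain_id)
                model.add_chain(chain)
                chain_map[rec.chain_id] = model[len(model) - 1]
            chain = chain_map[rec.chain_id]
            rkey = rec.residue_key
            if rkey not in res_map:
                res = gemmi.Residue()
                res.name = rec.res_name
                res.seqid = gemmi.SeqId(rec.res_seq, rec.i_code or " ")
                res.het_flag = "H" if rec.is_hetatm else "A"
                chain.add_residue(res)
                res_map[rkey] = chain[len(chain) - 1]
            res = res_map[rkey]
            atom = gemmi.Atom()
            atom.name = rec.name
            atom.serial = i + 1
            atom.element = gemmi.Element(rec.element.capitalize())
            atom.occ = rec.occupancy_field
            x, y, z = ensemble.coords[f, i] * ANGSTROM_PER_NM
            atom.pos = gemmi.Position(x, y, z)
            if rec.alt_loc:
                atom.altloc = rec.alt_loc
            res.add_atom(atom)
        st.add_model(model)
    st.write_pdb(str(path))
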