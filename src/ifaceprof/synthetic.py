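"""Synthetic two-chain ensembles with exact, designed ground truth.

Every pipeline stage is testable without external data: this module builds
multi-model ensembles in which the per-frame presence or absence of each
designed contact is known by construction.  Designed pairs are placed in
well-separated spatial cells (no cross-pair contacts are geometrically
possible) and their governing distance is drawn inside margin bands —
present frames at 65–85% of the threshold, absent frames at 130–190% — so
that positional jitter can never flip a designed state.  After building each
frame the generator re-evaluates the pair's criterion and redraws the jitter
if a margin was violated, making occupancy recovery exact rather than
statistical.

Residues are minimal idealized builds (fixed internal geometry, explicit
hydrogens where donors need them, including phosphotyrosine PTR); no
force-field realism is intended.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import (
    Thresholds,
    detect_aromatic,
    detect_hbonds,
    detect_hydrophobic,
    detect_salt_bridges,
)
from .structure_io import (
    AtomRecord,
    ChemistryTable,
    Ensemble,
    Frame,
    write_pdb_models,
)


class ConstructionError(ValueError):
    """A designed geometry cannot be realised (conflicting constraints)."""


# ---------------------------------------------------------------------------
# Minimal residue templates (nm, idealized; anchor-facing direction is +x)
# ---------------------------------------------------------------------------

# atom name -> (element, offset). Backbone sits at negative x; the
# "business" atom of each template is the one closest to +x.
RESIDUE_TEMPLATES: dict[str, dict[str, tuple[str, tuple[float, float, float]]]] = {
    "GLY": {
        "N": ("N", (-0.25, -0.10, 0.0)),
        "H": ("H", (-0.33, -0.14, 0.0)),
        "CA": ("C", (-0.15, 0.0, 0.0)),
        "C": ("C", (-0.22, 0.13, 0.0)),
        "O": ("O", (-0.31, 0.20, 0.0)),
    },
    "ALA": {
        "N": ("N", (-0.25, -0.10, 0.0)),
        "H": ("H", (-0.33, -0.14, 0.0)),
        "CA": ("C", (-0.15, 0.0, 0.0)),
        "C": ("C", (-0.22, 0.13, 0.0)),
        "O": ("O", (-0.31, 0.20, 0.0)),
        "CB": ("C", (0.0, 0.0, 0.0)),
        "HB1": ("H", (0.06, 0.08, 0.0)),
        "HB2": ("H", (0.06, -0.04, 0.07)),
        "HB3": ("H", (0.06, -0.04, -0.07)),
    },
    "SER": {
        "N": ("N", (-0.42, -0.05, 0.0)),
        "H": ("H", (-0.50, -0.10, 0.0)),
        "CA": ("C", (-0.32, 0.05, 0.0)),
        "C": ("C", (-0.35, 0.19, 0.02)),
        "O": ("O", (-0.44, 0.26, 0.02)),
        "CB": ("C", (-0.15, 0.0, 0.0)),
        "OG": ("O", (0.0, 0.0, 0.0)),
        "HG": ("H", (0.096, 0.0, 0.0)),
    },
    "THR": {
        "N": ("N", (-0.42, -0.05, 0.0)),
        "H": ("H", (-0.50, -0.10, 0.0)),
        "CA": ("C", (-0.32, 0.05, 0.0)),
        "C": ("C", (-0.35, 0.19, 0.02)),
        "O": ("O", (-0.44, 0.26, 0.02)),
        "CB": ("C", (-0.15, 0.0, 0.0)),
        "OG1": ("O", (0.0, 0.0, 0.0)),
        "HG1": ("H", (0.096, 0.0, 0.0)),
        "CG2": ("C", (-0.18, -0.14, 0.0)),
    },
    "GLN": {
        "N": ("N", (-0.55, -0.05, 0.0)),
        "H": ("H", (-0.63, -0.10, 0.0)),
        "CA": ("C", (-0.45, 0.05, 0.0)),
        "C": ("C", (-0.50, 0.19, 0.02)),
        "O": ("O", (-0.59, 0.26, 0.02)),
        "CB": ("C", (-0.31, 0.0, 0.0)),
        "CG": ("C", (-0.20, -0.06, 0.0)),
        "CD": ("C", (-0.10, 0.02, 0.0)),
        "OE1": ("O", (0.0, 0.0, 0.0)),
        "NE2": ("N", (-0.12, 0.15, 0.0)),
        "HE21": ("H", (-0.07, 0.23, 0.0)),
        "HE22": ("H", (-0.22, 0.16, 0.0)),
    },
    "LEU": {
        "N": ("N", (-0.40, -0.10, 0.0)),
        "H": ("H", (-0.48, -0.14, 0.0)),
        "CA": ("C", (-0.30, 0.0, 0.0)),
        "C": ("C", (-0.37, 0.13, 0.0)),
        "O": ("O", (-0.46, 0.20, 0.0)),
        "CB": ("C", (-0.15, 0.0, 0.0)),
        "CG": ("C", (-0.05, 0.08, 0.0)),
        "CD1": ("C", (0.06, 0.02, 0.08)),
        "CD2": ("C", (0.06, 0.02, -0.08)),
    },
    "ARG": {
        "N": ("N", (-0.72, -0.10, 0.0)),
        "H": ("H", (-0.80, -0.15, 0.0)),
        "CA": ("C", (-0.62, 0.0, 0.0)),
        "C": ("C", (-0.66, 0.14, 0.0)),
        "O": ("O", (-0.74, 0.22, 0.0)),
        "CB": ("C", (-0.48, -0.05, 0.0)),
        "CG": ("C", (-0.34, 0.0, 0.0)),
        "CD": ("C", (-0.20, -0.05, 0.0)),
        "NE": ("N", (-0.12, 0.05, 0.0)),
        "HE": ("H", (-0.14, 0.15, 0.0)),
        "CZ": ("C", (-0.06, -0.04, 0.0)),
        "NH1": ("N", (0.0, 0.0, 0.0)),
        # Amide hydrogens kept near-perpendicular to the interaction axis so a
        # designed salt bridge never doubles as a hydrogen bond (angle >= 30°).
        "HH11": ("H", (0.0, 0.10, 0.0)),
        "HH12": ("H", (0.0, -0.10, 0.02)),
        "NH2": ("N", (-0.08, -0.16, 0.0)),
        "HH21": ("H", (-0.02, -0.24, 0.0)),
        "HH22": ("H", (-0.17, -0.18, 0.0)),
    },
    "LYS": {
        "N": ("N", (-0.60, -0.10, 0.0)),
        "H": ("H", (-0.68, -0.15, 0.0)),
        "CA": ("C", (-0.50, 0.0, 0.0)),
        "C": ("C", (-0.56, 0.13, 0.0)),
        "O": ("O", (-0.64, 0.20, 0.0)),
        "CB": ("C", (-0.38, -0.02, 0.0)),
        "CG": ("C", (-0.27, 0.04, 0.0)),
        "CD": ("C", (-0.17, -0.03, 0.0)),
        "CE": ("C", (-0.08, 0.05, 0.0)),
        "NZ": ("N", (0.0, 0.0, 0.0)),
        "HZ1": ("H", (0.02, 0.10, 0.0)),
        "HZ2": ("H", (0.05, -0.08, 0.05)),
        "HZ3": ("H", (0.05, -0.08, -0.05)),
    },
    "GLU": {
        "N": ("N", (-0.52, -0.05, 0.0)),
        "H": ("H", (-0.60, -0.10, 0.0)),
        "CA": ("C", (-0.42, 0.05, 0.0)),
        "C": ("C", (-0.47, 0.19, 0.02)),
        "O": ("O", (-0.56, 0.26, 0.02)),
        "CB": ("C", (-0.28, 0.0, 0.0)),
        "CG": ("C", (-0.17, -0.06, 0.0)),
        "CD": ("C", (-0.07, 0.02, 0.0)),
        "OE1": ("O", (0.0, 0.0, 0.0)),
        "OE2": ("O", (-0.10, 0.13, 0.0)),
    },
    "PHE": {
        "N": ("N", (-0.62, -0.10, 0.0)),
        "H": ("H", (-0.70, -0.14, 0.0)),
        "CA": ("C", (-0.52, 0.0, 0.0)),
        "C": ("C", (-0.58, 0.13, 0.0)),
        "O": ("O", (-0.66, 0.20, 0.0)),
        "CB": ("C", (-0.38, -0.02, 0.0)),
        "CG": ("C", (-0.24, 0.0, 0.0)),
        "CD1": ("C", (-0.17, 0.12, 0.0)),
        "CD2": ("C", (-0.17, -0.12, 0.0)),
        "CE1": ("C", (-0.03, 0.12, 0.0)),
        "CE2": ("C", (-0.03, -0.12, 0.0)),
        "CZ": ("C", (0.04, 0.0, 0.0)),
    },
    "PTR": {
        "N": ("N", (-1.05, -0.05, 0.0)),
        "H": ("H", (-1.13, -0.10, 0.0)),
        "CA": ("C", (-0.95, 0.05, 0.0)),
        "C": ("C", (-1.00, 0.18, 0.0)),
        "O": ("O", (-1.08, 0.25, 0.0)),
        "CB": ("C", (-0.81, 0.0, 0.0)),
        "CG": ("C", (-0.67, 0.02, 0.0)),
        "CD1": ("C", (-0.60, 0.13, 0.0)),
        "CD2": ("C", (-0.60, -0.09, 0.0)),
        "CE1": ("C", (-0.46, 0.13, 0.0)),
        "CE2": ("C", (-0.46, -0.09, 0.0)),
        "CZ": ("C", (-0.39, 0.02, 0.0)),
        "OH": ("O", (-0.25, 0.02, 0.0)),
        "P": ("P", (-0.12, 0.01, 0.0)),
        "O1P": ("O", (0.0, 0.0, 0.0)),
        "O2P": ("O", (-0.13, 0.14, 0.03)),
        "O3P": ("O", (-0.14, -0.10, -0.08)),
    },
}

#: Governing anchor atom per (kind, residue): the point whose inter-residue
#: distance the generator controls. Centre-of-mass kinds use the side-chain
#: COM instead of a single atom.
_ANCHOR_ATOMS: dict[tuple[str, str], str] = {
    ("hbond", "SER"): "OG",
    ("hbond", "THR"): "OG1",
    ("hbond", "GLN"): "OE1",
    ("hbond", "PTR"): "O1P",
    ("salt_bridge", "ARG"): "NH1",
    ("salt_bridge", "LYS"): "NZ",
    ("salt_bridge", "GLU"): "OE1",
    ("salt_bridge", "PTR"): "O1P",
}

_DEFAULT_RESIDUES: dict[str, tuple[str, str]] = {
    "hbond": ("SER", "SER"),
    "salt_bridge": ("ARG", "PTR"),
    "hydrophobic": ("ALA", "ALA"),
    "aromatic": ("PHE", "PHE"),
}

#: Margin bands relative to the governing threshold: designed-present pairs
#: sit at 65–85% of the cutoff, designed-absent at 130–190%.
PRESENT_BAND = (0.65, 0.85)
ABSENT_BAND = (1.30, 1.90)
MAX_TILT_DEG = 12.0
CELL_SPACING = 6.0  # nm between designed pairs; no cross-pair contact possible


@dataclass(frozen=True)
class DesignedPair:
    """One designed contact: kind, the two residues, and its schedule.

    Exactly one of ``schedule`` (boolean per-frame presence) or
    ``probability`` (Bernoulli presence per frame) must be given.
    """

    kind: str
    res_a: tuple[str, int]  # (chain_id, res_seq)
    res_b: tuple[str, int]
    schedule: tuple[bool, ...] | None = None
    probability: float | None = None
    res_name_a: str | None = None
    res_name_b: str | None = None

    def __post_init__(self):
        if self.kind not in _DEFAULT_RESIDUES:
            raise ConstructionError(f"unknown interaction kind {self.kind!r}")
        if (self.schedule is None) == (self.probability is None):
            raise ConstructionError("give exactly one of schedule or probability")
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ConstructionError("probability outside [0, 1]")

    def residue_names(self) -> tuple[str, str]:
        da, db = _DEFAULT_RESIDUES[self.kind]
        return (self.res_name_a or da, self.res_name_b or db)


@dataclass(frozen=True)
class ContactScheduleSpec:
    """Full description of a designed-contact ensemble."""

    n_frames: int
    seed: int
    pairs: tuple[DesignedPair, ...]
    jitter: float = 0.003  # nm of per-atom positional noise

    def __post_init__(self):
        if self.n_frames < 1:
            raise ConstructionError("n_frames must be >= 1")
        if self.jitter < 0:
            raise ConstructionError("jitter must be >= 0")
        seen: dict[tuple[str, int], str] = {}
        for p in self.pairs:
            na, nb = p.residue_names()
            for key, name in ((p.res_a, na), (p.res_b, nb)):
                if key in seen:
                    raise ConstructionError(
                        f"residue {key} constrained by two designed pairs"
                    )
                seen[key] = name
            if p.schedule is not None and len(p.schedule) != self.n_frames:
                raise ConstructionError(
                    f"schedule length {len(p.schedule)} != n_frames {self.n_frames}"
                )


def _template(res_name: str) -> dict[str, tuple[str, np.ndarray]]:
    try:
        raw = RESIDUE_TEMPLATES[res_name]
    except KeyError:
        raise ConstructionError(f"no build template for residue {res_name!r}")
    return {n: (el, np.array(off)) for n, (el, off) in raw.items()}


def _sidechain_com_offset(res_name: str, table: ChemistryTable) -> np.ndarray:
    entry = table.get(res_name)
    if entry is None or not entry.sidechain:
        raise ConstructionError(f"{res_name} has no side chain for a COM anchor")
    tmpl = _template(res_name)
    pts, weights = [], []
    backbone_h = {"H", "H1", "H2", "H3", "HA", "HA2", "HA3"}
    for name, (el, off) in tmpl.items():
        if name in entry.sidechain or (el == "H" and name not in backbone_h):
            pts.append(off)
            weights.append(table.mass(el))
    if not pts:
        raise ConstructionError(f"{res_name} template has no side-chain atoms")
    return np.average(np.array(pts), axis=0, weights=np.array(weights))


def _anchor_offset(kind: str, res_name: str, table: ChemistryTable) -> np.ndarray:
    if kind in ("hydrophobic", "aromatic"):
        return _sidechain_com_offset(res_name, table)
    atom = _ANCHOR_ATOMS.get((kind, res_name))
    if atom is None:
        raise ConstructionError(
            f"residue {res_name!r} cannot anchor a {kind} contact"
        )
    tmpl = _template(res_name)
    if atom not in tmpl:
        raise ConstructionError(f"anchor atom {atom} missing from {res_name} template")
    return tmpl[atom][1]


_THRESHOLD_ATTR = {
    "hbond": "hbond_dist",
    "salt_bridge": "saltbridge_dist",
    "hydrophobic": "hydrophobic_dist",
    "aromatic": "hydrophobic_dist",  # qualifying criterion is the COM cutoff
}

_DETECTORS = {
    "hbond": detect_hbonds,
    "salt_bridge": detect_salt_bridges,
    "hydrophobic": detect_hydrophobic,
    "aromatic": detect_aromatic,
}

# 180° rotation about y: the partner residue faces back along -x.
_FLIP = np.diag([-1.0, 1.0, -1.0])


def _tilted_direction(rng: np.random.Generator) -> np.ndarray:
    theta = np.radians(rng.uniform(0.0, MAX_TILT_DEG))
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array(
        [np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )


def _pair_state_detected(
    pair: DesignedPair,
    topology: Sequence[AtomRecord],
    coords: np.ndarray,
    atom_slice: tuple[list[int], list[int]],
    table: ChemistryTable,
    th: Thresholds,
) -> bool:
    """Re-evaluate the designed pair's own criterion on a two-residue frame."""
    idx = atom_slice[0] + atom_slice[1]
    mini = Frame([topology[i] for i in idx], coords[idx], index=0)
    events = _DETECTORS[pair.kind](mini, table, th)
    return any(e.kind == pair.kind for e in events)


def generate_contact_ensemble(
    spec: ContactScheduleSpec,
    thresholds: Thresholds | None = None,
    table: ChemistryTable | None = None,
    out_pdb: str | Path | None = None,
    out_truth: str | Path | None = None,
) -> tuple[Ensemble, pd.DataFrame]:
    """Build an ensemble realising the designed contact schedules exactly.

    Returns the ensemble and a truth table (one row per designed pair per
    frame, column ``present``).  Optionally writes a multi-model PDB and a
    truth TSV.  Applying the detectors to the result reproduces the truth
    table exactly for every designed (pair, kind); incidental contacts of
    *other* kinds between a designed pair's residues (e.g. the side-chain COM
    contact implied by a close hydrogen bond) are deterministic functions of
    the designed state but are not part of the truth table.
    """
    th = thresholds or Thresholds()
    table = table or ChemistryTable.default()
    rng = np.random.default_rng(spec.seed)

    # Realize schedules first (fixed draw order: one block per pair).
    schedules: list[np.ndarray] = []
    for pair in spec.pairs:
        if pair.schedule is not None:
            schedules.append(np.asarray(pair.schedule, dtype=bool))
        else:
            schedules.append(rng.random(spec.n_frames) < pair.probability)

    # Static layout: each pair in its own cell; residues sorted into topology.
    residues: list[tuple[tuple[str, int], str, int]] = []  # (key, name, pair idx)
    for k, pair in enumerate(spec.pairs):
        na, nb = pair.residue_names()
        residues.append((pair.res_a, na, k))
        residues.append((pair.res_b, nb, k))
    order = sorted(range(len(residues)), key=lambda i: residues[i][0])

    topology: list[AtomRecord] = []
    atom_indices: dict[tuple[str, int], list[int]] = {}
    serial = 1
    for i in order:
        (chain, seq), name, _k = residues[i]
        tmpl = _template(name)
        idx_list = []
        for atom_name, (el, _off) in tmpl.items():
            topology.append(
                AtomRecord(
                    serial=serial,
                    name=atom_name,
                    element=el,
                    alt_loc="",
                    res_name=name,
                    chain_id=chain,
                    res_seq=seq,
                    i_code="",
                    position=np.zeros(3),
                    is_hetatm=(name == "PTR"),
                )
            )
            idx_list.append(serial - 1)
            serial += 1
        atom_indices[(chain, seq)] = idx_list

    anchors = []
    for pair in spec.pairs:
        na, nb = pair.residue_names()
        anchors.append(
            (_anchor_offset(pair.kind, na, table), _anchor_offset(pair.kind, nb, table))
        )

    coords = np.zeros((spec.n_frames, len(topology), 3))
    for f in range(spec.n_frames):
        for k, pair in enumerate(spec.pairs):
            na, nb = pair.residue_names()
            present = bool(schedules[k][f])
            cutoff = getattr(th, _THRESHOLD_ATTR[pair.kind])
            band = PRESENT_BAND if present else ABSENT_BAND
            cell = np.array([CELL_SPACING * k, 0.0, 0.0])
            anchor_a, anchor_b = anchors[k]
            tmpl_a, tmpl_b = _template(na), _template(nb)
            ia = atom_indices[pair.res_a]
            ib = atom_indices[pair.res_b]
            names_a = list(tmpl_a)
            names_b = list(tmpl_b)
            placed = False
            for _attempt in range(100):
                d = cutoff * rng.uniform(*band)
                u = _tilted_direction(rng)
                xa = np.array(
                    [cell + (tmpl_a[n][1] - anchor_a) for n in names_a]
                )
                xb = np.array(
                    [cell + d * u + (tmpl_b[n][1] - anchor_b) @ _FLIP.T for n in names_b]
                )
                if spec.jitter > 0:
                    xa = xa + rng.normal(0.0, spec.jitter, xa.shape)
                    xb = xb + rng.normal(0.0, spec.jitter, xb.shape)
                coords[f, ia] = xa
                coords[f, ib] = xb
                if (
                    _pair_state_detected(pair, topology, coords[f], (ia, ib), table, th)
                    == present
                ):
                    placed = True
                    break
            if not placed:
                raise ConstructionError(
                    f"could not realise {'presence' if present else 'absence'} of "
                    f"{pair.kind} pair {pair.res_a}-{pair.res_b} in frame {f}"
                )

    ensemble = Ensemble(topology, coords)

    truth_rows = []
    for k, pair in enumerate(spec.pairs):
        for f in range(spec.n_frames):
            truth_rows.append(
                {
                    "pair": k,
                    "kind": pair.kind,
                    "chain_a": pair.res_a[0],
                    "res_a": pair.res_a[1],
                    "chain_b": pair.res_b[0],
                    "res_b": pair.res_b[1],
                    "frame": f,
                    "present": bool(schedules[k][f]),
                }
            )
    truth = pd.DataFrame(truth_rows)

    if out_pdb is not None:
        write_pdb_models(ensemble, out_pdb)
    if out_truth is not None:
        truth.to_csv(out_truth, sep="\t", index=False)
    return ensemble, truth


def designed_occupancy(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-pair designed occupancy (%) from a truth table."""
    g = truth.groupby(["pair", "kind", "chain_a", "res_a", "chain_b", "res_b"])
    out = g["present"].agg(["sum", "count"]).reset_index()
    out["occupancy_pct"] = 100.0 * out["sum"] / out["count"]
    return out.rename(columns={"sum": "n_present", "count": "n_frames"})


def build_residue(
    res_name: str,
    chain_id: str,
    res_seq: int,
    origin: np.ndarray,
    rotation: np.ndarray | None = None,
) -> tuple[list[AtomRecord], np.ndarray]:
    """One template residue placed at ``origin`` (optionally rotated).

    Utility for constructing ad-hoc test frames; returns (atom records,
    coordinates) with positions filled in.
    """
    tmpl = _template(res_name)
    R = np.eye(3) if rotation is None else np.asarray(rotation)
    records, xyz = [], []
    for i, (atom_name, (el, off)) in enumerate(tmpl.items()):
        pos = np.asarray(origin, float) + off @ R.T
        records.append(
            AtomRecord(
                serial=i + 1,
                name=atom_name,
                element=el,
                alt_loc="",
                res_name=res_name,
                chain_id=chain_id,
                res_seq=res_seq,
                i_code="",
                position=pos,
                is_hetatm=(res_name == "PTR"),
            )
        )
        xyz.append(pos)
    return records, np.array(xyz)


# ---------------------------------------------------------------------------
# Clustering fixture
# ---------------------------------------------------------------------------

def _remove_rigid_component(disp: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Project net translation and infinitesimal rotations out of a field."""
    d = disp - disp.mean(axis=0)
    centered = ref - ref.mean(axis=0)
    rots = [
        np.cross(np.broadcast_to(axis, centered.shape), centered).ravel()
        for axis in np.eye(3)
    ]
    basis = np.array([v for v in rots if np.linalg.norm(v) > 1e-12]).T
    if basis.size:
        q, _ = np.linalg.qr(basis)
        flat = d.ravel()
        flat = flat - q @ (q.T @ flat)
        return flat.reshape(d.shape)
    return d


def generate_cluster_fixture(
    n_a: int,
    n_b: int,
    separation: float = 1.0,
    wobble: float = 0.02,
    seed: int = 0,
    n_residues: int = 10,
) -> Ensemble:
    """Two-conformer ensemble: ``n_a`` frames near A, then ``n_b`` near B.

    The A→B displacement is a non-rigid field scaled so that the post-fit
    RMSD between the conformers is ≈ ``separation``; per-frame wobble has RMS
    amplitude ``wobble`` so within-group pairwise RMSD stays below 2·wobble.
    """
    if n_a < 1:
        raise ValueError("n_a must be >= 1")
    if n_b < 0:
        raise ValueError("n_b must be >= 0")
    if wobble >= separation / 4:
        raise ValueError("wobble must be < separation / 4")
    from .ensemble_analysis import kabsch_superpose  # local import: no cycle

    rng = np.random.default_rng(seed)
    records: list[AtomRecord] = []
    base: list[np.ndarray] = []
    for r in range(n_residues):
        recs, xyz = build_residue(
            "ALA", "A", r + 1, origin=np.array([0.6 * r, 0.0, 0.0])
        )
        records.extend(recs)
        base.append(xyz)
    conf_a = np.vstack(base)
    conf_a = conf_a + rng.normal(0.0, 0.15, conf_a.shape)  # de-symmetrize

    disp = _remove_rigid_component(rng.normal(0.0, 1.0, conf_a.shape), conf_a)
    disp /= np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    conf_b = conf_a + disp * separation
    for _ in range(4):  # rescale so the post-fit RMSD hits the target
        _, _, rmsd = kabsch_superpose(conf_a, conf_b)
        if abs(rmsd - separation) < 1e-6:
            break
        conf_b = conf_a + (conf_b - conf_a) * (separation / rmsd)

    sigma = wobble / np.sqrt(3.0)  # per-coordinate sd giving RMS displacement = wobble
    frames = []
    for _ in range(n_a):
        frames.append(conf_a + rng.normal(0.0, sigma, conf_a.shape))
    for _ in range(n_b):
        frames.append(conf_b + rng.normal(0.0, sigma, conf_b.shape))
    coords = np.array(frames)
    records = [
        AtomRecord(
            serial=i + 1, name=rec.name, element=rec.element, alt_loc="",
            res_name=rec.res_name, chain_id=rec.chain_id, res_seq=rec.res_seq,
            i_code="", position=coords[0, i],
        )
        for i, rec in enumerate(records)
    ]
    return Ensemble(records, coords)


# ---------------------------------------------------------------------------
# Projection series for convergence diagnostics
# ---------------------------------------------------------------------------

def generate_projection_series(
    kind: str, n: int, mode: int = 1, seed: int = 0
) -> np.ndarray:
    """Test series for the cosine-content diagnostic.

    ``cosine`` — a pure half-cosine of the given mode (content 1);
    ``constant`` — all ones (content 0 by orthogonality);
    ``random_walk`` — cumulative sum of unit Gaussian steps, the free-diffusion
    signature whose mode-1 content is high on average.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "cosine":
        t = np.arange(n, dtype=float)
        return np.cos(mode * np.pi * t / (n - 1))
    if kind == "constant":
        return np.ones(n)
    if kind == "random_walk":
        rng = np.random.default_rng(seed)
        return np.cumsum(rng.normal(0.0, 1.0, n))
    raise ValueError(f"unknown series kind {kind!r}")
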