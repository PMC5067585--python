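"""Per-frame geometric detection of residue–residue contacts.

Four detectors over one :class:`~ifaceprof.structure_io.Frame`:

* hydrogen bonds — donor–acceptor distance below 0.35 nm and the
  hydrogen–donor–acceptor angle (at the donor vertex) below 30°;
* hydrophobic contacts — side-chain centre-of-mass distance below 0.5 nm,
  applied to every residue type with a non-empty side chain;
* salt bridges — minimum distance between any positive-group nitrogen and
  any negative-group oxygen below 0.4 nm (Barlow–Thornton convention; the
  H-bond criterion above is deliberately separate);
* aromatic contacts — the subset of hydrophobic-criterion contacts where
  both residues carry an aromatic ring (F/Y/W/H/PTR), reported with the
  ring-centroid distance.

All inequalities are strict, matching the "below"/"smaller than" phrasing of
the criteria.  Events are returned in a canonical residue-pair order so that
identical inputs yield an identical event list regardless of atom order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import (
    BACKBONE_HYDROGENS,
    ChemistryEntry,
    ChemistryTable,
    Frame,
    ResidueView,
)

logger = logging.getLogger("ifaceprof")

KINDS = ("hbond", "salt_bridge", "hydrophobic", "aromatic")

#: Residue codes whose side chain carries an aromatic ring.
AROMATIC_RESIDUES = frozenset({"PHE", "TYR", "TRP", "HIS", "PTR"})


class DegenerateGeometryError(ValueError):
    """Coincident points make an angle undefined."""


class NoSideChainError(ValueError):
    """Residue has no side-chain atoms (glycine) — no centre of mass."""


@dataclass(frozen=True)
class Thresholds:
    """Geometric cutoffs, in nm and degrees.

    Defaults are the analysis criteria: 0.35 nm / 30° for hydrogen bonds and
    0.5 nm side-chain COM distance for hydrophobic contacts; 0.4 nm minimum
    N⁺–O⁻ distance for salt bridges.  ``his_protonated`` opts histidine into
    the positive charge set (protonation is fixed upstream of this package).
    """

    hbond_dist: float = 0.35
    hbond_angle: float = 30.0
    hydrophobic_dist: float = 0.5
    saltbridge_dist: float = 0.4
    his_protonated: bool = False

    def __post_init__(self):
        for name in ("hbond_dist", "hbond_angle", "hydrophobic_dist", "saltbridge_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class InteractionEvent:
    """One detected contact in one frame.

    ``residue_a``/``residue_b`` are (chain_id, res_seq, i_code) keys stored in
    canonical order (chain, then residue number, then insertion code); atom
    names follow the same orientation.  ``atoms_a``/``atoms_b`` name the
    participating atoms ("COM" for centre-of-mass criteria).
    """

    frame_index: int
    kind: str
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    res_name_a: str
    res_name_b: str
    atoms_a: str
    atoms_b: str
    distance: float
    angle: float | None = None

    def __post_init__(self):
        if self.residue_a == self.residue_b:
            raise ValueError("self-interaction event")
        if self.residue_a > self.residue_b:
            raise ValueError("event pair not in canonical order")

    @property
    def pair_key(self) -> tuple[tuple[str, int, str], tuple[str, int, str], str]:
        return (self.residue_a, self.residue_b, self.kind)


def _make_event(
    frame_index: int,
    kind: str,
    ra: ResidueView,
    rb: ResidueView,
    atoms_a: str,
    atoms_b: str,
    distance: float,
    angle: float | None = None,
) -> InteractionEvent:
    if rb.key < ra.key:
        ra, rb = rb, ra
        atoms_a, atoms_b = atoms_b, atoms_a
    return InteractionEvent(
        frame_index, kind, ra.key, rb.key, ra.res_name, rb.res_name,
        atoms_a, atoms_b, float(distance), angle,
    )


def _sort_events(events: list[InteractionEvent]) -> list[InteractionEvent]:
    return sorted(
        events,
        key=lambda e: (e.residue_a, e.residue_b, e.kind, e.atoms_a, e.atoms_b),
    )


def hbond_geometry(
    donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray
) -> tuple[float, float]:
    """Donor–acceptor distance (nm) and the H–D–A angle at the donor (deg).

    The angle is between the donor→hydrogen and donor→acceptor directions,
    in [0, 180]; 0° means the acceptor sits exactly along the D–H bond.
    """
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    acceptor = np.asarray(acceptor, float)
    for p in (donor, hydrogen, acceptor):
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite point")
    dh = hydrogen - donor
    da = acceptor - donor
    n_dh = np.linalg.norm(dh)
    n_da = np.linalg.norm(da)
    if n_dh < 1e-12:
        raise DegenerateGeometryError("donor and hydrogen coincide")
    if n_da < 1e-12:
        raise DegenerateGeometryError("donor and acceptor coincide")
    cosang = np.clip(np.dot(dh, da) / (n_dh * n_da), -1.0, 1.0)
    return float(n_da), float(np.degrees(np.arccos(cosang)))


def _entry_for(
    residue: ResidueView, table: ChemistryTable, warned: set[str]
) -> ChemistryEntry | None:
    entry = table.get(residue.res_name)
    if entry is None and residue.res_name not in warned:
        warned.add(residue.res_name)
        logger.warning(
            "residue code %r not in chemistry table; excluded from detection",
            residue.res_name,
        )
    return entry


def detect_hbonds(
    frame: Frame,
    table: ChemistryTable,
    th: Thresholds | None = None,
    strict: bool = False,
) -> list[InteractionEvent]:
    """All (donor heavy atom, hydrogen, acceptor) triples meeting the criterion.

    One event per qualifying triple; intra-residue pairs are excluded, both
    intra- and inter-chain pairs are reported.  A donor whose listed hydrogens
    are all absent from the frame is skipped with a warning (``strict=True``
    raises instead).
    """
    th = th or Thresholds()
    warned: set[str] = set()
    residues = frame.residues()
    X = frame.coords

    donors: list[tuple[int, int, int]] = []  # (residue idx, heavy idx, hydrogen idx)
    acceptors: list[tuple[int, int]] = []  # (residue idx, atom idx)
    for ri, res in enumerate(residues):
        entry = _entry_for(res, table, warned)
        if entry is None:
            continue
        for heavy, hydrogens in entry.donors:
            hi = res.index_of(heavy)
            if hi is None:
                continue
            h_idx = [res.index_of(h) for h in hydrogens]
            h_idx = [j for j in h_idx if j is not None]
            if not h_idx:
                msg = (
                    f"donor {heavy} of {res.res_name} {res.chain_id}{res.res_seq} "
                    "has no resolvable hydrogen"
                )
                if strict:
                    raise ValueError(msg)
                logger.warning("%s; skipped", msg)
                continue
            for j in h_idx:
                donors.append((ri, hi, j))
        for acc in entry.acceptors:
            ai = res.index_of(acc)
            if ai is not None:
                acceptors.append((ri, ai))

    events: list[InteractionEvent] = []
    if not donors or not acceptors:
        return events

    d_heavy = np.array([d[1] for d in donors])
    a_atoms = np.array([a[1] for a in acceptors])
    dist = cdist(X[d_heavy], X[a_atoms])
    close = np.argwhere(dist < th.hbond_dist)
    for di, ai in close:
        ri_d, hi, hj = donors[di]
        ri_a, aj = acceptors[ai]
        if residues[ri_d].key == residues[ri_a].key:
            continue
        d, ang = hbond_geometry(X[hi], X[hj], X[aj])
        if ang < th.hbond_angle:
            res_d, res_a = residues[ri_d], residues[ri_a]
            events.append(
                _make_event(
                    frame.index, "hbond", res_d, res_a,
                    f"{frame.topology[hi].name}-{frame.topology[hj].name}",
                    frame.topology[aj].name,
                    d, ang,
                )
            )
    return _sort_events(events)


def sidechain_atom_indices(
    residue: ResidueView, frame: Frame, entry: ChemistryEntry
) -> list[int]:
    """Frame indices of the residue's side-chain atoms, hydrogens included.

    Heavy atoms come from the chemistry table; hydrogens are every H in the
    residue whose name is not a backbone hydrogen (H/H1–H3/HA/HA2/HA3).
    """
    idx = []
    for i in residue.atom_indices:
        rec = frame.topology[i]
        if rec.name in entry.sidechain:
            idx.append(i)
        elif rec.element == "H" and rec.name not in BACKBONE_HYDROGENS:
            idx.append(i)
    return idx


def sidechain_com(
    residue: ResidueView, frame: Frame, table: ChemistryTable
) -> np.ndarray:
    """Mass-weighted mean position (nm) of the residue's side-chain atoms."""
    entry = table.get(residue.res_name)
    if entry is None or not entry.sidechain:
        raise NoSideChainError(
            f"{residue.res_name} {residue.chain_id}{residue.res_seq} has no side chain"
        )
    idx = sidechain_atom_indices(residue, frame, entry)
    if not idx:
        raise NoSideChainError(
            f"no side-chain atoms present for {residue.res_name} "
            f"{residue.chain_id}{residue.res_seq}"
        )
    masses = np.array([table.mass(frame.topology[i].element) for i in idx])
    if masses.sum() <= 0:
        raise ValueError("zero total mass for side chain")
    return np.average(frame.coords[idx], axis=0, weights=masses)


def _sidechain_coms(
    frame: Frame, table: ChemistryTable, warned: set[str]
) -> tuple[list[int], np.ndarray]:
    """COMs of every residue with a computable side chain; (indices, coords)."""
    residues = frame.residues()
    keep: list[int] = []
    coms: list[np.ndarray] = []
    for ri, res in enumerate(residues):
        entry = _entry_for(res, table, warned)
        if entry is None or not entry.sidechain:
            continue
        idx = sidechain_atom_indices(res, frame, entry)
        if not idx:
            continue
        masses = np.array([table.mass(frame.topology[i].element) for i in idx])
        coms.append(np.average(frame.coords[idx], axis=0, weights=masses))
        keep.append(ri)
    return keep, (np.array(coms) if coms else np.zeros((0, 3)))


def detect_hydrophobic(
    frame: Frame,
    table: ChemistryTable,
    th: Thresholds | None = None,
    residue_filter: Iterable[str] | None = None,
) -> list[InteractionEvent]:
    """Residue pairs whose side-chain COM distance is below the cutoff.

    Applies to every residue type with a non-empty side chain (the criterion
    is purely geometric; polar residues can and do qualify).  An optional
    ``residue_filter`` restricts events to pairs where both residue codes are
    in the given set.
    """
    th = th or Thresholds()
    warned: set[str] = set()
    residues = frame.residues()
    keep, coms = _sidechain_coms(frame, table, warned)
    events: list[InteractionEvent] = []
    if len(keep) < 2:
        return events
    allowed = set(residue_filter) if residue_filter is not None else None
    dist = cdist(coms, coms)
    n = len(keep)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < th.hydrophobic_dist:
                ra, rb = residues[keep[i]], residues[keep[j]]
                if allowed is not None and (
                    ra.res_name not in allowed or rb.res_name not in allowed
                ):
                    continue
                events.append(
                    _make_event(
                        frame.index, "hydrophobic", ra, rb, "COM", "COM", dist[i, j]
                    )
                )
    return _sort_events(events)


def detect_salt_bridges(
    frame: Frame, table: ChemistryTable, th: Thresholds | None = None
) -> list[InteractionEvent]:
    """Oppositely charged residue pairs with min N⁺–O⁻ distance below cutoff."""
    th = th or Thresholds()
    warned: set[str] = set()
    residues = frame.residues()
    pos: list[tuple[int, list[int]]] = []
    neg: list[tuple[int, list[int]]] = []
    for ri, res in enumerate(residues):
        entry = _entry_for(res, table, warned)
        if entry is None:
            continue
        if entry.positive:
            if res.res_name == "HIS" and not th.his_protonated:
                pass
            else:
                nid = [
                    res.index_of(a)
                    for a in entry.positive
                    if res.index_of(a) is not None
                    and frame.topology[res.index_of(a)].element == "N"
                ]
                if nid:
                    pos.append((ri, sorted(nid)))
        if entry.negative:
            oid = [
                res.index_of(a)
                for a in entry.negative
                if res.index_of(a) is not None
                and frame.topology[res.index_of(a)].element == "O"
            ]
            if oid:
                neg.append((ri, sorted(oid)))

    events: list[InteractionEvent] = []
    for ri, nids in pos:
        for rj, oids in neg:
            if residues[ri].key == residues[rj].key:
                continue
            d = cdist(frame.coords[nids], frame.coords[oids])
            k = np.unravel_index(np.argmin(d), d.shape)
            if d[k] < th.saltbridge_dist:
                na = frame.topology[nids[k[0]]].name
                oa = frame.topology[oids[k[1]]].name
                events.append(
                    _make_event(
                        frame.index, "salt_bridge",
                        residues[ri], residues[rj], na, oa, d[k],
                    )
                )
    return _sort_events(events)


def _ring_centroid(
    residue: ResidueView, frame: Frame, entry: ChemistryEntry
) -> np.ndarray | None:
    idx = [residue.index_of(a) for a in sorted(entry.aromatic)]
    idx = [i for i in idx if i is not None]
    if not idx:
        return None
    return frame.coords[idx].mean(axis=0)


def detect_aromatic(
    frame: Frame, table: ChemistryTable, th: Thresholds | None = None
) -> list[InteractionEvent]:
    """Hydrophobic-criterion contacts between two ring-bearing residues.

    The qualifying criterion is the side-chain COM distance (identical to the
    hydrophobic detector); the reported distance is recomputed between the
    unweighted ring-atom centroids.
    """
    th = th or Thresholds()
    warned: set[str] = set()
    residues = frame.residues()
    base = detect_hydrophobic(frame, table, th)
    by_key = {res.key: res for res in residues}
    events: list[InteractionEvent] = []
    for ev in base:
        ra, rb = by_key[ev.residue_a], by_key[ev.residue_b]
        ea, eb = table.get(ra.res_name), table.get(rb.res_name)
        if ea is None or eb is None or not ea.aromatic or not eb.aromatic:
            continue
        ca = _ring_centroid(ra, frame, ea)
        cb = _ring_centroid(rb, frame, eb)
        if ca is None or cb is None:
            continue
        events.append(
            _make_event(
                frame.index, "aromatic", ra, rb, "RING", "RING",
                float(np.linalg.norm(ca - cb)),
            )
        )
    return _sort_events(events)


def detect_all(
    frame: Frame, table: ChemistryTable, th: Thresholds | None = None
) -> list[InteractionEvent]:
    """Run all four detectors on one frame."""
    th = th or Thresholds()
    events = (
        detect_hbonds(frame, table, th)
        + detect_salt_bridges(frame, table, th)
        + detect_hydrophobic(frame, table, th)
        + detect_aromatic(frame, table, th)
    )
    return _sort_events(events)


def events_to_rows(events: Sequence[InteractionEvent]) -> list[dict]:
    """Event stream as TSV-ready rows."""
    return [
        {
            "frame": e.frame_index,
            "kind": e.kind,
            "chain_a": e.residue_a[0],
            "res_a": e.residue_a[1],
            "name_a": e.atoms_a,
            "chain_b": e.residue_b[0],
            "res_b": e.residue_b[1],
            "name_b": e.atoms_b,
            "distance_nm": round(e.distance, 6),
            "angle_deg": round(e.angle, 3) if e.angle is not None else "",
        }
        for e in events
    ]
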