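"""Occupancy statistics, three-way interface partition and asymmetry.

A contact's *occupancy* (persistence) is the percentage of ensemble frames in
which the residue pair satisfies its geometric criterion.  Each residue pair
is then assigned to one of the dimer's contact classes:

* interface 1 — intermolecular PTM–SH2 (the phosphotyrosine of one monomer
  in the SH2 pocket of the other);
* interface 2 — intermolecular PTM–PTM (the disordered tail–tail contacts);
* interface 3 — intramolecular PTM–SH2 (F706 docking onto its own domain);
* linker — any pair touching the flexible linker L;
* other — everything else.

Interfaces 1 and 3 exist once per monomer; the ``orientation`` field records
which chain donates the PTM, and the asymmetry score compares the two
orientations' occupancy tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .interactions import InteractionEvent, Thresholds, detect_all
from .structure_io import ChemistryTable, Ensemble, RegionScheme

#: Regions counting as the C-terminal "percolating" unit for classification.
#: nTAD is grouped with the PTM: the F706 anchor's neighbours sit right at
#: the PTM/nTAD boundary and the tail acts as one unit in the dimer.
PTM_LIKE = ("PTM", "nTAD")

DEFAULT_PERSISTENCE_CUTOFF = 25.0  # percent; label only, never load-bearing


class InterfaceError(ValueError):
    """Chain or region cannot be classified against the declared dimer."""


@dataclass(frozen=True)
class OccupancyRecord:
    """Aggregated presence of one (residue pair, kind) over an ensemble."""

    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    kind: str
    res_name_a: str
    res_name_b: str
    n_present: int
    n_frames: int

    def __post_init__(self):
        if not (0 <= self.n_present <= self.n_frames):
            raise ValueError("n_present outside [0, n_frames]")

    @property
    def pair_key(self) -> tuple[tuple[str, int, str], tuple[str, int, str], str]:
        return (self.residue_a, self.residue_b, self.kind)

    @property
    def occupancy(self) -> float:
        """Percent of frames in which the contact is present."""
        return 100.0 * self.n_present / self.n_frames

    def persistence_label(self, cutoff: float = DEFAULT_PERSISTENCE_CUTOFF) -> str:
        return "persistent" if self.occupancy >= cutoff else "transient"


@dataclass(frozen=True)
class InterfaceAssignment:
    """Interface class of one residue pair, with PTM-donor orientation."""

    interface_id: int | str  # 1, 2, 3, "linker" or "other"
    orientation: str | None = None  # chain donating the PTM (interfaces 1/3)


def accumulate_occupancy(
    events: Iterable[InteractionEvent], n_frames: int
) -> list[OccupancyRecord]:
    """One record per distinct (pair, kind); a frame counts at most once.

    A pair linked by several simultaneous hydrogen bonds in one frame still
    contributes a single present-frame to that pair's H-bond occupancy.
    Pairs never present produce no record (the candidate universe is open).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    frames_seen: dict[tuple, set[int]] = {}
    names: dict[tuple, tuple[str, str]] = {}
    for ev in events:
        if ev.frame_index >= n_frames:
            raise ValueError(
                f"event frame_index {ev.frame_index} >= n_frames {n_frames}"
            )
        key = ev.pair_key
        frames_seen.setdefault(key, set()).add(ev.frame_index)
        names.setdefault(key, (ev.res_name_a, ev.res_name_b))
    records = [
        OccupancyRecord(
            residue_a=key[0],
            residue_b=key[1],
            kind=key[2],
            res_name_a=names[key][0],
            res_name_b=names[key][1],
            n_present=len(present),
            n_frames=n_frames,
        )
        for key, present in frames_seen.items()
    ]
    records.sort(key=lambda r: (-r.occupancy, r.residue_a, r.residue_b, r.kind))
    return records


def assign_interface(
    pair: tuple[tuple[str, int, str], tuple[str, int, str]],
    scheme: RegionScheme,
    chains: tuple[str, str],
) -> InterfaceAssignment:
    """Classify a residue pair into interface 1/2/3, linker or other."""
    (ca, ra, _), (cb, rb, _) = pair
    declared = set(chains)
    if ca not in declared or cb not in declared:
        raise InterfaceError(
            f"chain {ca!r}/{cb!r} not among declared dimer chains {chains}"
        )
    reg_a = scheme.region_of(ra)
    reg_b = scheme.region_of(rb)
    a_ptm = reg_a in PTM_LIKE
    b_ptm = reg_b in PTM_LIKE
    a_sh2 = reg_a == "SH2"
    b_sh2 = reg_b == "SH2"
    if ca != cb:
        if a_ptm and b_sh2:
            return InterfaceAssignment(1, orientation=ca)
        if b_ptm and a_sh2:
            return InterfaceAssignment(1, orientation=cb)
        if a_ptm and b_ptm:
            return InterfaceAssignment(2)
    else:
        if (a_ptm and b_sh2) or (b_ptm and a_sh2):
            return InterfaceAssignment(3, orientation=ca)
    if reg_a == "L" or reg_b == "L":
        return InterfaceAssignment("linker")
    return InterfaceAssignment("other")


_INTERFACE_ORDER = {1: 0, 2: 1, 3: 2, "linker": 3, "other": 4}


def interface_profile(
    ensemble: Ensemble,
    scheme: RegionScheme | None = None,
    table: ChemistryTable | None = None,
    th: Thresholds | None = None,
    chains: tuple[str, str] | None = None,
    persistence_cutoff: float = DEFAULT_PERSISTENCE_CUTOFF,
) -> pd.DataFrame:
    """Full contact profile of a two-chain ensemble.

    Runs all four detectors on every frame, aggregates occupancies and
    attaches the interface assignment to each record.  Rows are sorted by
    interface (1, 2, 3, linker, other), then occupancy descending.
    """
    scheme = scheme or RegionScheme()
    table = table or ChemistryTable.default()
    th = th or Thresholds()
    if chains is None:
        found = ensemble.chains()
        if len(found) != 2:
            raise InterfaceError(
                f"expected a two-chain ensemble, found chains {found}"
            )
        chains = (found[0], found[1])
    events: list[InteractionEvent] = []
    for frame in ensemble.frames():
        events.extend(detect_all(frame, table, th))
    records = accumulate_occupancy(events, ensemble.n_frames)
    rows = []
    for rec in records:
        assign = assign_interface((rec.residue_a, rec.residue_b), scheme, chains)
        rows.append(
            {
                "interface": assign.interface_id,
                "orientation": assign.orientation or "",
                "kind": rec.kind,
                "chain_a": rec.residue_a[0],
                "res_a": rec.residue_a[1],
                "aa_a": rec.res_name_a,
                "chain_b": rec.residue_b[0],
                "res_b": rec.residue_b[1],
                "aa_b": rec.res_name_b,
                "n_present": rec.n_present,
                "n_frames": rec.n_frames,
                "occupancy_pct": rec.occupancy,
                "label": rec.persistence_label(persistence_cutoff),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "interface", "orientation", "kind", "chain_a", "res_a", "aa_a",
            "chain_b", "res_b", "aa_b", "n_present", "n_frames",
            "occupancy_pct", "label",
        ],
    )
    if len(df):
        df["_ord"] = df["interface"].map(_INTERFACE_ORDER)
        df = (
            df.sort_values(
                ["_ord", "occupancy_pct", "chain_a", "res_a", "chain_b", "res_b", "kind"],
                ascending=[True, False, True, True, True, True, True],
            )
            .drop(columns="_ord")
            .reset_index(drop=True)
        )
    return df


def _orientation_tables(
    profile: pd.DataFrame, interface_id: int
) -> dict[str, dict[tuple, float]]:
    """Per-orientation occupancy maps keyed by chain-free pair identity.

    For a record with orientation ``c`` (the PTM-donating chain), the key is
    (kind, PTM-side residue number, partner residue number), which is what a
    chain relabelling maps onto itself.
    """
    sub = profile[profile["interface"] == interface_id]
    out: dict[str, dict[tuple, float]] = {}
    for _, row in sub.iterrows():
        ori = row["orientation"]
        if row["chain_a"] == ori:
            ptm_res, other_res = row["res_a"], row["res_b"]
        else:
            ptm_res, other_res = row["res_b"], row["res_a"]
        out.setdefault(ori, {})[(row["kind"], ptm_res, other_res)] = row[
            "occupancy_pct"
        ]
    return out


def asymmetry_score(profile: pd.DataFrame, interface_id: int = 1) -> float:
    """Mean |Δoccupancy| between the two orientations of interface 1 (or 3).

    Pairs are matched across orientations by (kind, PTM-side residue,
    partner residue); a pair present in only one orientation contributes its
    full occupancy (the missing partner counts as 0%).  0 means perfectly
    symmetric monomers.
    """
    tables = _orientation_tables(profile, interface_id)
    if not tables:
        raise InterfaceError(
            f"no interface-{interface_id} records in either orientation"
        )
    if len(tables) == 1:
        (only,) = tables.values()
        return float(np.mean(list(only.values()))) if only else 0.0
    (occ_a, occ_b) = list(tables.values())[:2]
    keys = set(occ_a) | set(occ_b)
    diffs = [abs(occ_a.get(k, 0.0) - occ_b.get(k, 0.0)) for k in sorted(keys)]
    return float(np.mean(diffs))


def profile_summary(profile: pd.DataFrame) -> dict:
    """Per-interface record counts plus asymmetry scores where defined."""
    counts = {
        str(k): int(v) for k, v in profile["interface"].value_counts().items()
    }
    summary: dict = {"n_records": int(len(profile)), "per_interface": counts}
    for iface in (1, 3):
        try:
            summary[f"asymmetry_interface_{iface}"] = asymmetry_score(profile, iface)
        except InterfaceError:
            summary[f"asymmetry_interface_{iface}"] = None
    return summary
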