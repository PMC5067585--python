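"""Mapping STAT5 point mutations onto the computed dimer interfaces.

Residue pockets identified by the ensemble analysis (the phosphotyrosine
coordination shell, the Val-695 hydrophobic pocket and the intramolecular
F706-acceptor interface) are catalogued here, together with a built-in table
of disease-associated and engineered STAT5A variants and their reported
cohort counts.  Cohort frequencies are recomputed from carrier/total counts,
never copied from the literature value (one table row is flagged where the
printed percentage and the counts disagree at the source).

All numbering is STAT5A; STAT5B equivalences are kept as free-text notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .structure_io import RegionScheme

MODELED_RANGE = (589, 714)


class VariantRangeError(ValueError):
    """Variant position outside the modelled fragment (589–714)."""


@dataclass(frozen=True)
class InterfaceCatalog:
    """Named residue pockets of the dimer interfaces (STAT5A numbering).

    * ``py_pocket`` — SH2 residues coordinating the phosphotyrosine of the
      opposite monomer (interface 1): the invariant R618 plus the transient
      H-bond partners and the βD5/βD7 non-polar contacts.
    * ``v695_pocket`` — the hydrophobic pocket of the opposite monomer that
      accepts the pY+1 valine (interface 1).
    * ``hydrophobic_interface`` — the intramolecular acceptor surface for
      F706 (interface 3).
    """

    py_pocket: frozenset[int] = frozenset({618, 600, 620, 622, 628, 642, 644})
    v695_pocket: frozenset[int] = frozenset({631, 641, 643})
    hydrophobic_interface: frozenset[int] = frozenset({631, 633, 641, 663, 665, 666})
    ptm_ptm_positions: frozenset[int] = frozenset(range(697, 706))  # pY+3..pY+11

    def __post_init__(self):
        sh2 = range(589, 688)
        for name in ("py_pocket", "v695_pocket", "hydrophobic_interface"):
            bad = [p for p in getattr(self, name) if p not in sh2]
            if bad:
                raise ValueError(f"{name} positions outside the SH2 range: {bad}")

    def memberships(self, position: int) -> frozenset[str]:
        out = set()
        if position in self.py_pocket:
            out.add("py_pocket")
        if position in self.v695_pocket:
            out.add("v695_pocket")
        if position in self.hydrophobic_interface:
            out.add("hydrophobic_interface")
        return frozenset(out)


@dataclass(frozen=True)
class CohortCount:
    label: str
    carriers: int
    total: int
    printed_pct: float | None = None
    printed_decimals: int = 1
    flag: str = ""

    def __post_init__(self):
        if not (0 <= self.carriers <= self.total):
            raise ValueError("carriers outside [0, total]")


@dataclass(frozen=True)
class VariantRecord:
    """One point mutation with optional cohort counts and annotations."""

    position: int
    wt_aa: str
    mut_aa: str
    cohorts: tuple[CohortCount, ...] = ()
    note: str = ""
    region: str | None = None
    memberships: frozenset[str] = frozenset()
    interfaces: frozenset[object] = frozenset()  # ints and/or "3-donor"

    @property
    def name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def variant_frequency(carriers: int, total: int, decimals: int = 1) -> float:
    """Cohort frequency 100·carriers/total, rounded half-up.

    Half-up rounding reproduces how such frequencies are printed in clinical
    cohort reports (e.g. 7/21 → 33.3, 5/68 → 7.4).
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not (0 <= carriers <= total):
        raise ValueError("carriers outside [0, total]")
    pct = Decimal(100 * carriers) / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def annotate_variant(
    variant: VariantRecord,
    catalog: InterfaceCatalog | None = None,
    scheme: RegionScheme | None = None,
) -> VariantRecord:
    """Attach region label, pocket memberships and interface classes.

    Interface attribution: phosphotyrosine-pocket and V695-pocket residues
    act in the intermolecular PTM–SH2 interface (1); the PTM positions
    pY+3..pY+11 form the PTM–PTM interface (2); the F706-acceptor surface is
    the intramolecular interface (3), with F706 itself as its donor; pY694
    through pY+2 engage the opposite SH2 domain (1).
    """
    catalog = catalog or InterfaceCatalog()
    scheme = scheme or RegionScheme()
    pos = variant.position
    lo, hi = MODELED_RANGE
    if not (lo <= pos <= hi):
        raise VariantRangeError(f"position {pos} outside modelled range {lo}-{hi}")
    region = scheme.region_of(pos)
    if region is None:
        raise VariantRangeError(f"position {pos} not covered by the region scheme")
    members = catalog.memberships(pos)
    interfaces: set[object] = set()
    if members & {"py_pocket", "v695_pocket"}:
        interfaces.add(1)
    if "hydrophobic_interface" in members:
        interfaces.add(3)
    if pos in catalog.ptm_ptm_positions:
        interfaces.add(2)
    if pos == 706:
        interfaces.add("3-donor")
    if region == "PTM" and 694 <= pos <= 696:
        interfaces.add(1)
    return replace(
        variant, region=region, memberships=members, interfaces=frozenset(interfaces)
    )


def load_variant_table(path: str | Path | None = None) -> list[VariantRecord]:
    """Variant records from a TSV (default: the packaged STAT5A table).

    Rows sharing (position, wt, mut) are merged into one record with several
    cohorts; engineered mutants carry no cohort.
    """
    if path is None:
        ref = resources.files("ifaceprof.data").joinpath("variants.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = df.fillna("")
    merged: dict[tuple[int, str, str], dict] = {}
    for _, row in df.iterrows():
        key = (int(row["position"]), row["wt"], row["mut"])
        rec = merged.setdefault(key, {"cohorts": [], "note": row.get("note", "")})
        if row.get("carriers", "-") not in ("", "-"):
            printed = row.get("printed_pct", "-")
            rec["cohorts"].append(
                CohortCount(
                    label=row["cohort_label"],
                    carriers=int(row["carriers"]),
                    total=int(row["total"]),
                    printed_pct=float(printed) if printed not in ("", "-") else None,
                    printed_decimals=int(row.get("printed_decimals") or 1)
                    if row.get("printed_decimals", "-") not in ("", "-")
                    else 1,
                    flag=row.get("flag", ""),
                )
            )
    return [
        VariantRecord(
            position=pos, wt_aa=wt, mut_aa=mut,
            cohorts=tuple(v["cohorts"]), note=v["note"],
        )
        for (pos, wt, mut), v in merged.items()
    ]


def annotate_table(
    variants: list[VariantRecord] | None = None,
    catalog: InterfaceCatalog | None = None,
    scheme: RegionScheme | None = None,
    skip_out_of_range: bool = False,
) -> pd.DataFrame:
    """Annotate a variant list into a flat report (one row per cohort).

    Variants without cohorts yield one row with empty frequency fields.
    With ``skip_out_of_range`` the run continues past unmappable positions,
    flagging them instead of raising.
    """
    variants = variants if variants is not None else load_variant_table()
    rows = []
    for var in variants:
        try:
            ann = annotate_variant(var, catalog, scheme)
        except VariantRangeError as exc:
            if not skip_out_of_range:
                raise
            rows.append(
                {
                    "variant": var.name, "position": var.position,
                    "region": "", "memberships": "", "interfaces": "",
                    "cohort": "", "carriers": "", "total": "",
                    "frequency_pct": "", "flag": f"out_of_range: {exc}",
                }
            )
            continue
        base = {
            "variant": ann.name,
            "position": ann.position,
            "region": ann.region,
            "memberships": ",".join(sorted(ann.memberships)),
            "interfaces": ",".join(str(i) for i in sorted(ann.interfaces, key=str)),
        }
        if ann.cohorts:
            for c in ann.cohorts:
                rows.append(
                    {
                        **base,
                        "cohort": c.label,
                        "carriers": c.carriers,
                        "total": c.total,
                        "frequency_pct": variant_frequency(
                            c.carriers, c.total, c.printed_decimals
                        ),
                        "flag": c.flag,
                    }
                )
        else:
            rows.append(
                {**base, "cohort": "", "carriers": "", "total": "",
                 "frequency_pct": "", "flag": ""}
            )
    return pd.DataFrame(rows)
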