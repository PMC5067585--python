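"""Independent brute-force oracles for the contact detectors.

Deliberately naive: plain nested loops over residues and atoms, direct
vector arithmetic, no shared code with the package's detection paths beyond
the chemistry table itself.  Used to validate the optimised detectors by
exhaustive comparison on small frames.
"""

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ifaceprof.structure_io import BACKBONE_HYDROGENS, ChemistryTable, Frame


def _norm(v):
    return math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)


def oracle_hbond_geometry(d, h, a):
    d, h, a = (np.asarray(x, float) for x in (d, h, a))
    dist = _norm(a - d)
    v1, v2 = h - d, a - d
    cosang = np.dot(v1, v2) / (_norm(v1) * _norm(v2))
    return dist, math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def oracle_hbonds(frame: Frame, table: ChemistryTable, th):
    """Every qualifying (donor, hydrogen, acceptor) triple, as a set of keys."""
    found = set()
    residues = frame.residues()
    for rd in residues:
        ed = table.get(rd.res_name)
        if ed is None:
            continue
        for ra in residues:
            if ra.key == rd.key:
                continue
            ea = table.get(ra.res_name)
            if ea is None:
                continue
            for heavy, hydrogens in ed.donors:
                hi = rd.index_of(heavy)
                if hi is None:
                    continue
                for hname in hydrogens:
                    hj = rd.index_of(hname)
                    if hj is None:
                        continue
                    for acc in ea.acceptors:
                        aj = ra.index_of(acc)
                        if aj is None:
                            continue
                        dist, ang = oracle_hbond_geometry(
                            frame.coords[hi], frame.coords[hj], frame.coords[aj]
                        )
                        if dist < th.hbond_dist and ang < th.hbond_angle:
                            ka, kb = rd.key, ra.key
                            da = f"{heavy}-{hname}"
                            ab = acc
                            if kb < ka:
                                ka, kb, da, ab = kb, ka, ab, da
                            found.add(("hbond", ka, kb, da, ab))
    return found


def oracle_sidechain_com(residue, frame: Frame, table: ChemistryTable):
    entry = table.get(residue.res_name)
    pts, ws = [], []
    for i in residue.atom_indices:
        rec = frame.topology[i]
        if rec.name in entry.sidechain or (
            rec.element == "H" and rec.name not in BACKBONE_HYDROGENS
        ):
            pts.append(frame.coords[i])
            ws.append(table.mass(rec.element))
    if not pts:
        return None
    pts, ws = np.array(pts), np.array(ws)
    return (pts * ws[:, None]).sum(axis=0) / ws.sum()


def oracle_hydrophobic(frame: Frame, table: ChemistryTable, th):
    found = set()
    residues = frame.residues()
    for i, ra in enumerate(residues):
        ea = table.get(ra.res_name)
        if ea is None or not ea.sidechain:
            continue
        ca = oracle_sidechain_com(ra, frame, table)
        if ca is None:
            continue
        for rb in residues[i + 1:]:
            eb = table.get(rb.res_name)
            if eb is None or not eb.sidechain:
                continue
            cb = oracle_sidechain_com(rb, frame, table)
            if cb is None:
                continue
            if _norm(cb - ca) < th.hydrophobic_dist:
                ka, kb = sorted([ra.key, rb.key])
                found.add(("hydrophobic", ka, kb))
    return found


def oracle_salt_bridges(frame: Frame, table: ChemistryTable, th):
    found = set()
    residues = frame.residues()
    for ra in residues:
        ea = table.get(ra.res_name)
        if ea is None or not ea.positive:
            continue
        if ra.res_name == "HIS" and not th.his_protonated:
            continue
        for rb in residues:
            eb = table.get(rb.res_name)
            if eb is None or not eb.negative or rb.key == ra.key:
                continue
            best = None
            for ap in ea.positive:
                ip = ra.index_of(ap)
                if ip is None or frame.topology[ip].element != "N":
                    continue
                for an in eb.negative:
                    jn = rb.index_of(an)
                    if jn is None or frame.topology[jn].element != "O":
                        continue
                    d = _norm(frame.coords[jn] - frame.coords[ip])
                    if best is None or d < best:
                        best = d
            if best is not None and best < th.saltbridge_dist:
                ka, kb = sorted([ra.key, rb.key])
                found.add(("salt_bridge", ka, kb))
    return found


def oracle_aromatic(frame: Frame, table: ChemistryTable, th):
    hydro = oracle_hydrophobic(frame, table, th)
    residues = {r.key: r for r in frame.residues()}
    found = set()
    for _, ka, kb in hydro:
        ra, rb = residues[ka], residues[kb]
        ea, eb = table.get(ra.res_name), table.get(rb.res_name)
        if not ea.aromatic or not eb.aromatic:
            continue
        ia = [ra.index_of(a) for a in ea.aromatic if ra.index_of(a) is not None]
        ib = [rb.index_of(a) for a in eb.aromatic if rb.index_of(a) is not None]
        if ia and ib:
            found.add(("aromatic", ka, kb))
    return found


def oracle_min_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Best RMSD of y onto x by numeric minimisation over rotation vectors."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)

    def cost(rv):
        R = Rotation.from_rotvec(rv).as_matrix()
        return np.mean(np.sum((yc @ R.T - xc) ** 2, axis=1))

    best = min(
        (
            minimize(cost, r0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
            for r0 in (
                np.zeros(3),
                np.array([np.pi, 0, 0]),
                np.array([0, np.pi, 0]),
                np.array([0, 0, np.pi]),
                np.array([1.0, 1.0, 1.0]),
            )
        ),
        key=lambda r: r.fun,
    )
    return float(np.sqrt(best.fun))
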