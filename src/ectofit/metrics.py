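"""Superposition, RMSD, domain centers of mass, interdomain hinge angles and
interface contact maps.

Hinge angles are the coarse collective variables used to describe flexure of
a multidomain receptor: the angle subtended at a junction domain's center of
mass by the centers of mass of the two flanking domains.  For a homodimer
the report carries one angle table per subunit plus the cross-subunit
asymmetry, and (optionally) signed deltas against a reference conformation,
negative meaning the hinge contracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structure import DomainDefinition, Selection, Structure, select


# -- superposition ------------------------------------------------------------

def kabsch_superpose(mobile: Selection | np.ndarray,
                     reference: Selection | np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (proper rotation only).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference.
    Reflections are excluded by sign-correcting the smallest singular
    direction.  Requires at least 3 non-collinear points.
    """
    P = mobile.positions if isinstance(mobile, Selection) else np.asarray(mobile, float)
    Q = reference.positions if isinstance(reference, Selection) else np.asarray(reference, float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise ValueError("need at least 3 points for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    moved = P @ R.T + t
    rmsd_val = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd_val


def rmsd(a: Selection | np.ndarray, b: Selection | np.ndarray,
         superpose: bool = False) -> float:
    """Root-mean-square deviation between paired coordinates.

    Direct (no superposition) by default; with ``superpose`` the optimal
    rigid fit is removed first.
    """
    P = a.positions if isinstance(a, Selection) else np.asarray(a, float)
    Q = b.positions if isinstance(b, Selection) else np.asarray(b, float)
    if P.shape != Q.shape:
        raise ValueError(f"atom-count mismatch: {P.shape} vs {Q.shape}")
    if superpose:
        _, _, value = kabsch_superpose(P, Q)
        return value
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


# -- centers of mass and hinge angles -----------------------------------------

def center_of_mass(sel: Selection, heavy_only: bool = True) -> np.ndarray:
    """Mass-weighted mean position of the selection's atoms (Å)."""
    work = sel.heavy() if heavy_only else sel
    if len(work) == 0:
        raise ValueError("empty selection")
    m = work.masses
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    return (work.positions * m[:, None]).sum(axis=0) / total


def hinge_angle(com_a: np.ndarray, com_vertex: np.ndarray, com_b: np.ndarray) -> float:
    """Angle (degrees, in [0, 180]) at the vertex between two COM arms."""
    a = np.asarray(com_a, float) - np.asarray(com_vertex, float)
    b = np.asarray(com_b, float) - np.asarray(com_vertex, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-length hinge arm")
    cosang = np.dot(a, b) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass(frozen=True)
class HingeDefinition:
    """A named hinge as a (arm, vertex, arm) triplet of domain names."""

    name: str
    arm_a: str
    vertex: str
    arm_b: str


#: Default triplet convention for the insulin-receptor leg L1-CR-L2-F1-F2-F3:
#: hinge "X-Y" is measured at the junction domain's COM between the COMs of
#: the flanking domains.  The convention is configurable because published
#: hinge values depend on the exact triplets and domain boundaries used.
DEFAULT_IR_HINGES: tuple[HingeDefinition, ...] = (
    HingeDefinition("L1-L2", "L1", "CR", "L2"),
    HingeDefinition("L2-F1", "CR", "L2", "F1"),
    HingeDefinition("F1-F2", "L2", "F1", "F2"),
    HingeDefinition("F2-F3", "F1", "F2", "F3"),
)


@dataclass
class HingeReport:
    """Per-subunit hinge angles, optional deltas vs a reference, asymmetry."""

    angles: dict[str, dict[str, float]]          # subunit -> hinge -> degrees
    deltas: dict[str, dict[str, float]] | None   # model − reference, signed
    asymmetry: dict[str, float]                  # hinge -> |subunit1 − subunit2|
    convention: dict[str, tuple[str, str, str]]  # hinge -> (arm, vertex, arm)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sub, table in self.angles.items():
            for hinge, ang in table.items():
                row = {"subunit": sub, "hinge": hinge, "angle_deg": ang,
                       "asymmetry_deg": self.asymmetry.get(hinge, np.nan)}
                if self.deltas is not None:
                    row["delta_deg"] = self.deltas[sub][hinge]
                rows.append(row)
        return pd.DataFrame(rows)


def _domain_coms(structure: Structure, domains: list[DomainDefinition],
                 heavy_only: bool = True) -> dict[str, dict[str, np.ndarray]]:
    """COM per (subunit chain, domain name)."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for d in domains:
        sel = select(structure, d)
        out.setdefault(d.chain_id, {})[d.name] = center_of_mass(sel, heavy_only)
    return out


def hinge_report(
    structure: Structure,
    domains: list[DomainDefinition],
    hinges: list[HingeDefinition] | tuple[HingeDefinition, ...] = DEFAULT_IR_HINGES,
    reference: Structure | None = None,
    heavy_only: bool = True,
) -> HingeReport:
    """Compute the hinge-angle table for every subunit (chain) in ``domains``.

    ``deltas`` are ``model − reference`` per hinge (negative = contraction).
    ``asymmetry`` is the absolute cross-subunit difference, defined when the
    domain config covers exactly two subunits.
    """
    coms = _domain_coms(structure, domains, heavy_only)
    angles: dict[str, dict[str, float]] = {}
    for sub, table in coms.items():
        angles[sub] = {}
        for h in hinges:
            for nm in (h.arm_a, h.vertex, h.arm_b):
                if nm not in table:
                    raise ValueError(f"domain {nm!r} missing on subunit {sub!r}")
            angles[sub][h.name] = hinge_angle(table[h.arm_a], table[h.vertex],
                                              table[h.arm_b])
    deltas = None
    if reference is not None:
        ref_coms = _domain_coms(reference, domains, heavy_only)
        deltas = {}
        for sub, table in angles.items():
            deltas[sub] = {}
            rt = ref_coms[sub]
            for h in hinges:
                ref_ang = hinge_angle(rt[h.arm_a], rt[h.vertex], rt[h.arm_b])
                deltas[sub][h.name] = table[h.name] - ref_ang
    asymmetry: dict[str, float] = {}
    subs = list(angles)
    if len(subs) == 2:
        for h in hinges:
            asymmetry[h.name] = abs(angles[subs[0]][h.name] - angles[subs[1]][h.name])
    convention = {h.name: (h.arm_a, h.vertex, h.arm_b) for h in hinges}
    return HingeReport(angles, deltas, asymmetry, convention)


def load_hinge_definitions(path: str | Path) -> list[HingeDefinition]:
    """Load hinge triplets from YAML (``hinges: [{name, arm_a, vertex, arm_b}]``)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return [HingeDefinition(h["name"], h["arm_a"], h["vertex"], h["arm_b"])
            for h in cfg.get("hinges", [])]


# -- contacts ------------------------------------------------------------------

@dataclass(frozen=True)
class ContactRecord:
    residue_a: tuple[str, int]   # (chain, resseq) in sel_a
    residue_b: tuple[str, int]   # (chain, resseq) in sel_b
    min_distance: float          # Å, minimum heavy-atom distance


def contact_map(sel_a: Selection, sel_b: Selection, cutoff: float = 5.0) -> list[ContactRecord]:
    """Residue pairs across the interface with min heavy-atom distance <= cutoff.

    The cutoff is a closed bound (a pair at exactly the cutoff is included).
    """
    if np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise ValueError("contact selections must be disjoint")
    from scipy.spatial import cKDTree

    a, b = sel_a.heavy(), sel_b.heavy()
    st = sel_a.structure
    pa, pb = a.positions, b.positions
    pairs = cKDTree(pa).query_ball_tree(cKDTree(pb), r=cutoff)
    best: dict[tuple[tuple[str, int], tuple[str, int]], float] = {}
    for ia, lst in enumerate(pairs):
        if not lst:
            continue
        gi = a.indices[ia]
        ra = (st.chain[gi], int(st.resseq[gi]))
        d = np.linalg.norm(pb[lst] - pa[ia], axis=1)
        for ib, dist in zip(lst, d):
            gj = b.indices[ib]
            rb = (sel_b.structure.chain[gj], int(sel_b.structure.resseq[gj]))
            key = (ra, rb)
            if dist <= cutoff and (key not in best or dist < best[key]):
                best[key] = float(dist)
    records = [ContactRecord(ra, rb, d) for (ra, rb), d in best.items()]
    records.sort(key=lambda r: (r.residue_a, r.residue_b))
    return records


def contacts_frame(records: list[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chain_a": r.residue_a[0], "res_a": r.residue_a[1],
          "chain_b": r.residue_b[0], "res_b": r.residue_b[1],
          "min_dist_A": r.min_distance} for r in records]
    )
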