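"""Internal-geometry restraints for map-guided fitting.

Instead of a full molecular-mechanics force field, internal structure is
preserved by harmonic terms referenced to the starting geometry — bonds and
bond angles derived from the starting coordinates, peptide omega dihedrals
held trans, an improper torsion per residue that locks Calpha chirality,
phi/psi restraints on detected secondary-structure elements, optional
positional tethers, and a soft-sphere repulsion between non-bonded atoms.
These carry the fitting-relevant physics: the map term may pull atoms, but
covalent geometry, handedness, peptide planarity and secondary structure
cannot be traded away for density overlap.

Energy convention: every harmonic term is ``k * delta**2`` (no 1/2), with k
in kcal/mol per squared unit of the deviation (Å or rad).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import soft_radius_of
from .structure import Selection, Structure

#: force constant for secondary-structure phi/psi restraints,
#: kcal mol^-1 rad^-2
K_SECONDARY_STRUCTURE = 300.0
K_BOND = 200.0        # kcal mol^-1 Å^-2
K_ANGLE = 50.0        # kcal mol^-1 rad^-2
K_OMEGA = 100.0       # kcal mol^-1 rad^-2, peptide bond held trans
K_CHIRALITY = 100.0   # kcal mol^-1 rad^-2, improper at Calpha
K_REPULSION = 20.0    # kcal mol^-1 Å^-2, soft-sphere
K_POSITIONAL = 10.0   # kcal mol^-1 Å^-2, stage tethers

_BOND_CUTOFF = 1.9    # Å, heavy-atom covalent detection
_SS_BOND_CUTOFF = 2.3  # Å, disulfides
_CHAIN_BREAK = 2.0    # Å, C(i)-N(i+1) beyond this terminates a segment


def _wrap_angle(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-pi, pi]."""
    return (delta + np.pi) % (2.0 * np.pi) - np.pi


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle in radians for one atom quadruple."""
    p = np.asarray([p1, p2, p3, p4], dtype=float)
    return float(_dihedral_batch(p[None, 0], p[None, 1], p[None, 2], p[None, 3])[0])


def _dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def _dihedral_gradients(p1, p2, p3, p4):
    """Torsion values and analytic position gradients for batches of quads.

    Returns (phi, g1, g2, g3, g4) with gi = d phi / d pi.
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    m1 = np.cross(n1, b2 / b2n[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    phi = np.arctan2(y, x)

    eps = 1e-12
    g1 = (b2n / np.maximum(n1sq, eps))[:, None] * n1
    g4 = -(b2n / np.maximum(n2sq, eps))[:, None] * n2
    d12 = np.einsum("ij,ij->i", b1, b2) / np.maximum(b2n**2, eps)
    d32 = np.einsum("ij,ij->i", b3, b2) / np.maximum(b2n**2, eps)
    g2 = -(1.0 + d12)[:, None] * g1 + d32[:, None] * g4
    g3 = d12[:, None] * g1 - (1.0 + d32)[:, None] * g4
    return phi, g1, g2, g3, g4


_EMPTY2 = np.empty((0, 2), dtype=np.int64)
_EMPTY3 = np.empty((0, 3), dtype=np.int64)
_EMPTY4 = np.empty((0, 4), dtype=np.int64)
_EMPTYF = np.empty(0)


@dataclass
class RestraintSet:
    """All restraint terms, stored as flat index/parameter arrays."""

    bonds_idx: np.ndarray = field(default_factory=lambda: _EMPTY2.copy())
    bonds_r0: np.ndarray = field(default_factory=lambda: _EMPTYF.copy())
    bonds_k: np.ndarray = field(default_factory=lambda: _EMPTYF.copy())

    angles_idx: np.ndarray = field(default_factory=lambda: _EMPTY3.copy())
    angles_t0: np.ndarray = field(default_factory=lambda: _EMPTYF.copy())
    angles_k: np.ndarray = field(default_factory=lambda: _EMPTYF.copy())

    dihedrals_idx: np.ndarray = field(default_factory=lambda: _EMPTY4.copy())
    dihedrals_t0: np.ndarray = field(default_factory=lambda: _EMPTYF.copy())
    dihedrals_k: np.ndarray = field(default_factory=lambda: _EMPTYF.copy())
    dihedrals_kind: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))

    positional_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    positional_ref: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    positional_k: np.ndarray = field(default_factory=lambda: _EMPTYF.copy())

    soft_sphere: bool = False
    repulsion_k: float = K_REPULSION
    radii: np.ndarray | None = None            # per-atom soft radii, Å
    heavy_mask: np.ndarray | None = None
    exclusions: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self):
        for k_arr in (self.bonds_k, self.angles_k, self.dihedrals_k, self.positional_k):
            if len(k_arr) and k_arr.min() < 0:
                raise ValueError("force constants must be non-negative")

    def merge(self, other: "RestraintSet") -> "RestraintSet":
        """Combine two restraint sets over the same structure."""
        return RestraintSet(
            np.vstack([self.bonds_idx, other.bonds_idx]),
            np.concatenate([self.bonds_r0, other.bonds_r0]),
            np.concatenate([self.bonds_k, other.bonds_k]),
            np.vstack([self.angles_idx, other.angles_idx]),
            np.concatenate([self.angles_t0, other.angles_t0]),
            np.concatenate([self.angles_k, other.angles_k]),
            np.vstack([self.dihedrals_idx, other.dihedrals_idx]),
            np.concatenate([self.dihedrals_t0, other.dihedrals_t0]),
            np.concatenate([self.dihedrals_k, other.dihedrals_k]),
            np.concatenate([self.dihedrals_kind, other.dihedrals_kind]),
            np.concatenate([self.positional_idx, other.positional_idx]),
            np.vstack([self.positional_ref, other.positional_ref]),
            np.concatenate([self.positional_k, other.positional_k]),
            self.soft_sphere or other.soft_sphere,
            max(self.repulsion_k, other.repulsion_k),
            self.radii if self.radii is not None else other.radii,
            self.heavy_mask if self.heavy_mask is not None else other.heavy_mask,
            self.exclusions | other.exclusions,
        )

    def with_positional(self, sel: Selection, k: float = K_POSITIONAL) -> "RestraintSet":
        """Return a copy with harmonic tethers at the atoms' current positions."""
        extra = RestraintSet(
            positional_idx=sel.indices.copy(),
            positional_ref=sel.positions.copy(),
            positional_k=np.full(len(sel), float(k)),
        )
        return self.merge(extra)


def _residue_table(structure: Structure) -> list[dict]:
    """Per-residue backbone atom indices, in file order."""
    rows: list[dict] = []
    key = None
    for i in range(structure.n_atoms):
        k = (structure.chain[i], int(structure.resseq[i]))
        if k != key:
            key = k
            rows.append({"chain": k[0], "resseq": k[1], "atoms": {}})
        rows[-1]["atoms"].setdefault(structure.name[i], i)
    return rows


def _segments(structure: Structure, residues: list[dict]) -> list[list[int]]:
    """Split consecutive residues into covalently continuous segments."""
    segs: list[list[int]] = []
    cur: list[int] = []
    for ri, row in enumerate(residues):
        if not cur:
            cur = [ri]
            continue
        prev = residues[ri - 1]
        linked = False
        if prev["chain"] == row["chain"]:
            ci, ni = prev["atoms"].get("C"), row["atoms"].get("N")
            if ci is not None and ni is not None:
                d = np.linalg.norm(structure.xyz[ci] - structure.xyz[ni])
                linked = d <= _CHAIN_BREAK
        if linked:
            cur.append(ri)
        else:
            segs.append(cur)
            cur = [ri]
    if cur:
        segs.append(cur)
    return segs


def detect_bonds(structure: Structure) -> np.ndarray:
    """Covalent heavy-atom bonds by distance; hydrogens attach to the nearest
    heavy atom within 1.2 Å."""
    from scipy.spatial import cKDTree

    xyz = structure.xyz
    heavy = np.array([e.upper() != "H" for e in structure.element])
    tree = cKDTree(xyz)
    pairs = []
    for i, j in tree.query_pairs(r=_SS_BOND_CUTOFF):
        ei = structure.element[i].upper()
        ej = structure.element[j].upper()
        d = np.linalg.norm(xyz[i] - xyz[j])
        if ei == "H" or ej == "H":
            if d <= 1.2 and (heavy[i] or heavy[j]):
                pairs.append((i, j))
        elif ei == "S" and ej == "S":
            pairs.append((i, j))
        elif d <= _BOND_CUTOFF:
            pairs.append((i, j))
    if not pairs:
        return _EMPTY2.copy()
    return np.array(sorted(tuple(sorted(p)) for p in pairs), dtype=np.int64)


def _bond_graph_exclusions(bonds: np.ndarray, n_atoms: int, depth: int = 3) -> set[tuple[int, int]]:
    """Atom pairs within ``depth`` bonds (1-2, 1-3, 1-4)."""
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(int(j))
        adj[j].add(int(i))
    excl: set[tuple[int, int]] = set()
    for start in range(n_atoms):
        frontier = {start}
        seen = {start}
        for _ in range(depth):
            nxt = set()
            for u in frontier:
                nxt |= adj[u]
            nxt -= seen
            for v in nxt:
                if start < v:
                    excl.add((start, v))
            seen |= nxt
            frontier = nxt
    return excl


K_ELASTIC = 2.0       # kcal mol^-1 Å^-2, Calpha elastic network
ELASTIC_CUTOFF = 9.0  # Å


def build_internal_restraints(
    structure: Structure,
    k_bond: float = K_BOND,
    k_angle: float = K_ANGLE,
    k_omega: float = K_OMEGA,
    k_chirality: float = K_CHIRALITY,
    soft_sphere: bool = True,
    repulsion_k: float = K_REPULSION,
    k_elastic: float = K_ELASTIC,
    elastic_cutoff: float = ELASTIC_CUTOFF,
) -> RestraintSet:
    """Derive the internal model from the starting coordinates.

    Bonds/angles are harmonic at their starting values; peptide omegas are
    restrained to 180 deg; an improper torsion (N, C, CA, CB) per residue is
    restrained to its starting value, which pins Calpha handedness (a mirror
    flip reverses its sign).  A weak Calpha elastic network (pairs closer
    than ``elastic_cutoff`` at the start) preserves tertiary packing the way
    a force field's attractive nonbonded terms would — without it a
    misoriented component can shear internally to fill density instead of
    reorienting rigidly.  The network never spans gaps wider than the cutoff,
    so well-separated domains stay free to move relative to each other.
    """
    xyz = structure.xyz
    bonds = detect_bonds(structure)
    r0 = np.linalg.norm(xyz[bonds[:, 0]] - xyz[bonds[:, 1]], axis=1) if len(bonds) else _EMPTYF.copy()

    # angles: every pair of bonds sharing an atom
    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        adj.setdefault(int(i), []).append(int(j))
        adj.setdefault(int(j), []).append(int(i))
    trip = []
    for j, nbrs in adj.items():
        nbrs = sorted(nbrs)
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                trip.append((nbrs[a], j, nbrs[b]))
    angles_idx = np.array(trip, dtype=np.int64) if trip else _EMPTY3.copy()
    if len(angles_idx):
        u = xyz[angles_idx[:, 0]] - xyz[angles_idx[:, 1]]
        v = xyz[angles_idx[:, 2]] - xyz[angles_idx[:, 1]]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        angles_t0 = np.arccos(np.clip(cosang, -1, 1))
    else:
        angles_t0 = _EMPTYF.copy()

    # omega + chirality torsions
    residues = _residue_table(structure)
    quads: list[tuple[int, int, int, int]] = []
    t0: list[float] = []
    kind: list[str] = []
    kk: list[float] = []
    for seg in _segments(structure, residues):
        for a, b in zip(seg, seg[1:]):
            ra, rb = residues[a]["atoms"], residues[b]["atoms"]
            if all(n in ra for n in ("CA", "C")) and all(n in rb for n in ("N", "CA")):
                quads.append((ra["CA"], ra["C"], rb["N"], rb["CA"]))
                t0.append(np.pi)
                kind.append("omega")
                kk.append(k_omega)
    for row in residues:
        at = row["atoms"]
        if all(n in at for n in ("N", "C", "CA", "CB")):
            q = (at["N"], at["C"], at["CA"], at["CB"])
            quads.append(q)
            t0.append(dihedral(*xyz[list(q)]))
            kind.append("chirality")
            kk.append(k_chirality)
    dih_idx = np.array(quads, dtype=np.int64) if quads else _EMPTY4.copy()

    radii = np.array([soft_radius_of(e) for e in structure.element])
    heavy = np.array([e.upper() != "H" for e in structure.element])
    excl = _bond_graph_exclusions(bonds, structure.n_atoms) if soft_sphere else set()

    bonds_k_arr = np.full(len(bonds), float(k_bond))
    if k_elastic > 0:
        from scipy.spatial import cKDTree

        ca_idx = np.array([i for i in range(structure.n_atoms)
                           if structure.name[i] == "CA"], dtype=np.int64)
        if len(ca_idx) > 1:
            pairs = cKDTree(xyz[ca_idx]).query_pairs(r=elastic_cutoff,
                                                     output_type="ndarray")
            if len(pairs):
                ei = ca_idx[pairs[:, 0]]
                ej = ca_idx[pairs[:, 1]]
                # the network preserves each chain's internal packing only —
                # an inter-chain spring would freeze the components' relative
                # placement, which is exactly what the fit must change
                same = structure.chain[ei] == structure.chain[ej]
                ei, ej = ei[same], ej[same]
                enm_idx = np.stack([ei, ej], axis=1)
                enm_r0 = np.linalg.norm(xyz[ei] - xyz[ej], axis=1)
                bonds = np.vstack([bonds, enm_idx])
                r0 = np.concatenate([r0, enm_r0])
                bonds_k_arr = np.concatenate(
                    [bonds_k_arr, np.full(len(enm_idx), float(k_elastic))])

    return RestraintSet(
        bonds_idx=bonds, bonds_r0=r0, bonds_k=bonds_k_arr,
        angles_idx=angles_idx, angles_t0=angles_t0,
        angles_k=np.full(len(angles_idx), float(k_angle)),
        dihedrals_idx=dih_idx, dihedrals_t0=np.array(t0),
        dihedrals_k=np.array(kk), dihedrals_kind=np.array(kind, dtype=object),
        soft_sphere=soft_sphere, repulsion_k=repulsion_k,
        radii=radii, heavy_mask=heavy, exclusions=excl,
    )


def assign_secondary_structure(
    structure: Structure,
    method: str = "hbond",
    k: float = K_SECONDARY_STRUCTURE,
) -> RestraintSet:
    """Detect helix/strand segments and restrain their phi/psi dihedrals.

    ``method="hbond"`` marks residues i..i+4 helical when the backbone
    O(i)–N(i+4) distance is <= 3.5 Å within a covalently continuous segment
    (a geometric proxy for the alpha-helical hydrogen bond that needs no
    explicit hydrogens).  ``method="phipsi"`` instead uses dihedral windows
    (helix: phi in (-100, -30), psi in (-80, -5); strand: phi in (-180, -90),
    psi in (90, 180)).  Restraint targets are the current dihedral values;
    loops stay unrestrained.  Chain breaks terminate segments.
    """
    xyz = structure.xyz
    residues = _residue_table(structure)
    segments = _segments(structure, residues)
    n_res = len(residues)
    marked = np.zeros(n_res, dtype=bool)

    def phi_psi(seg: list[int], pos: int) -> tuple[float | None, float | None]:
        row = residues[seg[pos]]["atoms"]
        phi = psi = None
        if pos > 0:
            prev = residues[seg[pos - 1]]["atoms"]
            if "C" in prev and all(n in row for n in ("N", "CA", "C")):
                phi = dihedral(xyz[prev["C"]], xyz[row["N"]], xyz[row["CA"]], xyz[row["C"]])
        if pos < len(seg) - 1:
            nxt = residues[seg[pos + 1]]["atoms"]
            if "N" in nxt and all(n in row for n in ("N", "CA", "C")):
                psi = dihedral(xyz[row["N"]], xyz[row["CA"]], xyz[row["C"]], xyz[nxt["N"]])
        return phi, psi

    if method == "hbond":
        for seg in segments:
            for p in range(len(seg) - 4):
                oi = residues[seg[p]]["atoms"].get("O")
                nj = residues[seg[p + 4]]["atoms"].get("N")
                if oi is None or nj is None:
                    continue
                if np.linalg.norm(xyz[oi] - xyz[nj]) <= 3.5:
                    marked[seg[p: p + 5]] = True
    elif method == "phipsi":
        for seg in segments:
            for p in range(len(seg)):
                phi, psi = phi_psi(seg, p)
                if phi is None or psi is None:
                    continue
                phi_d, psi_d = np.degrees(phi), np.degrees(psi)
                helix = -100 < phi_d < -30 and -80 < psi_d < -5
                strand = -180 <= phi_d < -90 and 90 < psi_d <= 180
                if helix or strand:
                    marked[seg[p]] = True
    else:
        raise ValueError(f"unknown secondary-structure method {method!r}")

    quads: list[tuple[int, int, int, int]] = []
    t0: list[float] = []
    kind: list[str] = []
    for seg in segments:
        for p, ri in enumerate(seg):
            if not marked[ri]:
                continue
            row = residues[ri]["atoms"]
            if p > 0:
                prev = residues[seg[p - 1]]["atoms"]
                if "C" in prev and all(n in row for n in ("N", "CA", "C")):
                    q = (prev["C"], row["N"], row["CA"], row["C"])
                    quads.append(q)
                    t0.append(dihedral(*xyz[list(q)]))
                    kind.append("ss_phi")
            if p < len(seg) - 1:
                nxt = residues[seg[p + 1]]["atoms"]
                if "N" in nxt and all(n in row for n in ("N", "CA", "C")):
                    q = (row["N"], row["CA"], row["C"], nxt["N"])
                    quads.append(q)
                    t0.append(dihedral(*xyz[list(q)]))
                    kind.append("ss_psi")
    if not quads:
        return RestraintSet()
    return RestraintSet(
        dihedrals_idx=np.array(quads, dtype=np.int64),
        dihedrals_t0=np.array(t0),
        dihedrals_k=np.full(len(quads), float(k)),
        dihedrals_kind=np.array(kind, dtype=object),
    )


def evaluate_restraints(rs: RestraintSet, xyz: np.ndarray) -> tuple[dict[str, float], np.ndarray]:
    """Total restraint energy components and the gradient w.r.t. coordinates."""
    grad = np.zeros_like(xyz)
    comps: dict[str, float] = {}

    if len(rs.bonds_idx):
        i, j = rs.bonds_idx[:, 0], rs.bonds_idx[:, 1]
        d = xyz[i] - xyz[j]
        r = np.linalg.norm(d, axis=1)
        dr = r - rs.bonds_r0
        comps["bonds"] = float(np.sum(rs.bonds_k * dr**2))
        f = (2.0 * rs.bonds_k * dr / np.maximum(r, 1e-12))[:, None] * d
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)
    else:
        comps["bonds"] = 0.0

    if len(rs.angles_idx):
        ia, ij, ik = rs.angles_idx[:, 0], rs.angles_idx[:, 1], rs.angles_idx[:, 2]
        u = xyz[ia] - xyz[ij]
        v = xyz[ik] - xyz[ij]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
        cosang = np.clip(cosang, -1 + 1e-10, 1 - 1e-10)
        theta = np.arccos(cosang)
        dtheta = theta - rs.angles_t0
        comps["angles"] = float(np.sum(rs.angles_k * dtheta**2))
        sin_t = np.sqrt(1.0 - cosang**2)
        pref = -1.0 / sin_t
        dcos_da = v / (nu * nv)[:, None] - (cosang / nu**2)[:, None] * u
        dcos_dk = u / (nu * nv)[:, None] - (cosang / nv**2)[:, None] * v
        coeff = (2.0 * rs.angles_k * dtheta * pref)[:, None]
        ga = coeff * dcos_da
        gk = coeff * dcos_dk
        np.add.at(grad, ia, ga)
        np.add.at(grad, ik, gk)
        np.add.at(grad, ij, -(ga + gk))
    else:
        comps["angles"] = 0.0

    if len(rs.dihedrals_idx):
        q = rs.dihedrals_idx
        phi, g1, g2, g3, g4 = _dihedral_gradients(xyz[q[:, 0]], xyz[q[:, 1]],
                                                  xyz[q[:, 2]], xyz[q[:, 3]])
        dphi = _wrap_angle(phi - rs.dihedrals_t0)
        comps["dihedrals"] = float(np.sum(rs.dihedrals_k * dphi**2))
        coeff = (2.0 * rs.dihedrals_k * dphi)[:, None]
        np.add.at(grad, q[:, 0], coeff * g1)
        np.add.at(grad, q[:, 1], coeff * g2)
        np.add.at(grad, q[:, 2], coeff * g3)
        np.add.at(grad, q[:, 3], coeff * g4)
    else:
        comps["dihedrals"] = 0.0

    if len(rs.positional_idx):
        d = xyz[rs.positional_idx] - rs.positional_ref
        comps["positional"] = float(np.sum(rs.positional_k * np.sum(d**2, axis=1)))
        np.add.at(grad, rs.positional_idx, (2.0 * rs.positional_k)[:, None] * d)
    else:
        comps["positional"] = 0.0

    comps["soft_sphere"] = 0.0
    if rs.soft_sphere and rs.radii is not None:
        from scipy.spatial import cKDTree

        heavy_idx = np.nonzero(rs.heavy_mask)[0] if rs.heavy_mask is not None \
            else np.arange(len(xyz))
        pts = xyz[heavy_idx]
        rmax = 2.0 * float(rs.radii.max())
        pairs = cKDTree(pts).query_pairs(r=rmax, output_type="ndarray")
        if len(pairs):
            gi = heavy_idx[pairs[:, 0]]
            gj = heavy_idx[pairs[:, 1]]
            keep = np.array([(int(min(a, b)), int(max(a, b))) not in rs.exclusions
                             for a, b in zip(gi, gj)])
            gi, gj = gi[keep], gj[keep]
            if len(gi):
                d = xyz[gi] - xyz[gj]
                r = np.linalg.norm(d, axis=1)
                r0 = rs.radii[gi] + rs.radii[gj]
                viol = r < r0
                gi, gj, d, r, r0 = gi[viol], gj[viol], d[viol], r[viol], r0[viol]
                if len(gi):
                    pen = r0 - r
                    comps["soft_sphere"] = float(rs.repulsion_k * np.sum(pen**2))
                    f = (-2.0 * rs.repulsion_k * pen / np.maximum(r, 1e-12))[:, None] * d
                    np.add.at(grad, gi, f)
                    np.add.at(grad, gj, -f)

    return comps, grad
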