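"""Synthetic multi-domain structures with analytically known ground truth.

The generator emulates, at toy scale, the geometry this package is built to
analyse: a homodimeric receptor whose subunits are chains of compact domains
with designed interdomain hinge angles, a small helical ligand, simulated
target density maps, and planted poses/deformations.  Domains are ideal
poly-alanine helical bundles; their centers of mass are placed in closed
form so that every designed hinge angle holds exactly, which makes the
metrics, fitting and docking modules testable against known answers with no
external inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import DensityGrid, combine_maps, synthesize_map
from .docking import RigidPose, clash_score_points
from .metrics import DEFAULT_IR_HINGES, HingeDefinition, center_of_mass, hinge_angle
from .structure import (DomainDefinition, Selection, Structure, concatenate,
                        select)

# ideal backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N = 121.7, 111.2, 116.2
_A_CA_C_O, _A_C_CA_CB = 120.5, 110.1
_PHI_HELIX, _PSI_HELIX, _OMEGA = -57.0, -47.0, 180.0
_T_N_C_CA_CB = -122.6  # improper torsion fixing L-chirality of Calpha


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given A-B-C with |C-D|, angle(B,C,D) and torsion(A,B,C,D)."""
    ang = np.radians(angle_deg)
    tor = -np.radians(torsion_deg)  # sign matches the measured torsion convention
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_helix(n_res: int, chain: str = "A", first_res: int = 1,
               phi: float = _PHI_HELIX, psi: float = _PSI_HELIX) -> Structure:
    """Ideal poly-ALA helix (N, CA, C, O, CB heavy atoms per residue)."""
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(_A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for _ in range(1, n_res):
        N.append(_nerf(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_nerf(CA[-1], C[-1], N[-1], _B_N_CA, _A_C_N_CA, _OMEGA))
        C.append(_nerf(C[-1], N[-1], CA[-1], _B_CA_C, _A_N_CA_C, phi))
    serial, name, element, resseq, resname, chain_ids, xyz = [], [], [], [], [], [], []
    sn = 0
    for i in range(n_res):
        psi_i = psi  # designed value; O anti to the next N
        O = _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi_i + 180.0)
        CB = _nerf(N[i], C[i], CA[i], _B_CA_CB, _A_C_CA_CB, _T_N_C_CA_CB)
        for nm, el, pos in (("N", "N", N[i]), ("CA", "C", CA[i]),
                            ("C", "C", C[i]), ("O", "O", O), ("CB", "C", CB)):
            sn += 1
            serial.append(sn)
            name.append(nm)
            element.append(el)
            resseq.append(first_res + i)
            resname.append("ALA")
            chain_ids.append(chain)
            xyz.append(pos)
    return Structure(np.array(serial), np.array(name, dtype=object),
                     np.array(element, dtype=object), np.array(resseq),
                     np.array(resname, dtype=object),
                     np.array(chain_ids, dtype=object), np.array(xyz))


def _principal_axis(pts: np.ndarray) -> np.ndarray:
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    ax = vt[0]
    return ax if ax[2] >= 0 else -ax


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if c < -1 + 1e-12:
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        K = _skew(v)
        return np.eye(3) + 2.0 * (K @ K)
    K = _skew(v)
    return np.eye(3) + K + K @ K / (1.0 + c)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    ang = np.radians(angle_deg)
    K = _skew(ax)
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def make_bundle(n_helices: int = 3, res_per_helix: int | list[int] = 10,
                chain: str = "A", first_res: int = 1,
                axis_sep: float = 10.5) -> Structure:
    """Antiparallel poly-ALA helix bundle, axes along z, one chain.

    ``res_per_helix`` may be a list of per-helix lengths; unequal lengths
    break the bundle's flip pseudo-symmetry, as unequal chains do in real
    small proteins.
    """
    lengths = ([res_per_helix] * n_helices if isinstance(res_per_helix, int)
               else list(res_per_helix))
    if len(lengths) != n_helices:
        raise ValueError("res_per_helix list must match n_helices")
    offsets_xy = [(0.0, 0.0), (axis_sep, 0.0), (axis_sep / 2, axis_sep * 0.87),
                  (-axis_sep / 2, axis_sep * 0.87)][:n_helices]
    parts = []
    res = first_res
    for hi, (ox, oy) in enumerate(offsets_xy):
        h = make_helix(lengths[hi], chain=chain, first_res=res)
        ax = _principal_axis(h.xyz[np.array([n == "CA" for n in h.name])])
        R = _rotation_between(ax, np.array([0.0, 0.0, 1.0]))
        pts = (h.xyz - h.xyz.mean(axis=0)) @ R.T
        if hi % 2 == 1:
            pts = pts @ _axis_rotation([1.0, 0.0, 0.0], 180.0).T
        h.xyz = pts + np.array([ox, oy, 0.0])
        parts.append(h)
        res += lengths[hi]
    return concatenate(parts)


def make_kinked_helix(n_first: int = 8, n_second: int = 5, bend_deg: float = 55.0,
                      chain: str = "A", first_res: int = 1) -> Structure:
    """Two helical segments joined at an angle (a helix-kink-helix peptide).

    A single ideal poly-ALA helix blurred to ~4 Å is nearly a featureless
    cylinder with a screw degeneracy — its axial register and rotation are
    unidentifiable from density.  A kink breaks that symmetry the way real
    sidechain features do, making the peptide's pose well-determined.
    """
    a = make_helix(n_first, chain=chain, first_res=first_res)
    b = make_helix(n_second, chain=chain, first_res=first_res + n_first)
    ca_a = a.xyz[np.array([n == "CA" for n in a.name])]
    ax = _principal_axis(ca_a)
    perp = np.cross(ax, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(ax, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    R = _axis_rotation(perp, bend_deg)
    # place segment B so its start continues from A's end, bent by bend_deg
    b.xyz = b.xyz @ R.T
    ca_b = b.xyz[np.array([n == "CA" for n in b.name])]
    ax_b = ax @ R.T
    offset = a.xyz[-5] + 4.5 * ax_b - b.xyz[0]
    b.xyz += offset
    return concatenate([a, b])


@dataclass
class ToySpec:
    """Design parameters for a toy multi-domain receptor."""

    hinge_angles: tuple[float, ...] = (120.0, 150.0, 90.0, 80.0)
    residues_per_domain: int = 30
    dimer: bool = True
    com_separation: float = 32.0     # Å between neighbouring domain COMs
    seed: int = 0

    def __post_init__(self):
        for a in self.hinge_angles:
            if not 0.0 < a < 180.0:
                raise ValueError("hinge angles must lie in (0, 180) degrees")
        if self.residues_per_domain < 8:
            raise ValueError("need at least 8 residues per domain")

    @property
    def n_domains(self) -> int:
        return len(self.hinge_angles) + 2


@dataclass
class GroundTruth:
    """What the generator planted, recoverable by the analysis modules."""

    domains: list[DomainDefinition] = field(default_factory=list)
    hinges: list[HingeDefinition] = field(default_factory=list)
    hinge_table: dict[str, dict[str, float]] = field(default_factory=dict)
    coms: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    pose: RigidPose | None = None
    deformation_deltas: dict[str, dict[str, float]] = field(default_factory=dict)
    start_rmsd: float | None = None


_IR_NAMES = ("L1", "CR", "L2", "F1", "F2", "F3")


def _domain_names(n: int) -> tuple[str, ...]:
    return _IR_NAMES if n == 6 else tuple(f"D{i + 1}" for i in range(n))


def _hinge_defs(names: tuple[str, ...]) -> list[HingeDefinition]:
    if names == _IR_NAMES:
        return list(DEFAULT_IR_HINGES)
    return [HingeDefinition(f"H{k + 1}", names[k], names[k + 1], names[k + 2])
            for k in range(len(names) - 2)]


def _com_polyline(angles_deg: tuple[float, ...], sep: float) -> np.ndarray:
    """COM positions in the xy-plane realising the designed interior angles."""
    pts = [np.zeros(3)]
    heading = 0.0
    direction = np.array([1.0, 0.0, 0.0])
    pts.append(pts[0] + sep * direction)
    for k, ang in enumerate(angles_deg):
        turn = (180.0 - ang) * (1.0 if k % 2 == 0 else -1.0)  # zig-zag layout
        heading += turn
        rad = np.radians(heading)
        direction = np.array([np.cos(rad), np.sin(rad), 0.0])
        pts.append(pts[-1] + sep * direction)
    out = np.array(pts)
    # reject self-intersecting layouts
    for i in range(len(out)):
        for j in range(i + 2, len(out)):
            if np.linalg.norm(out[i] - out[j]) < 0.6 * sep:
                raise ValueError("infeasible geometry: domain COMs self-intersect")
    return out


def _build_subunit(spec: ToySpec, chain: str) -> tuple[Structure, list[DomainDefinition]]:
    names = _domain_names(spec.n_domains)
    coms = _com_polyline(spec.hinge_angles, spec.com_separation)
    rph = max(spec.residues_per_domain // 3, 3)
    parts = []
    domains = []
    first = 1
    for k, nm in enumerate(names):
        dom = make_bundle(3, rph, chain=chain, first_res=first)
        # vary each domain's orientation with the chain direction
        R = _axis_rotation([0.0, 0.0, 1.0], 37.0 * k)
        dom.xyz = dom.xyz @ R.T
        com = center_of_mass(dom.select_all())
        dom.xyz += coms[k] - com
        parts.append(dom)
        domains.append(DomainDefinition(nm, chain, ((first, first + 3 * rph - 1),)))
        first += 3 * rph
    return concatenate(parts), domains


def make_toy_receptor(spec: ToySpec = ToySpec()) -> tuple[Structure, GroundTruth]:
    """Toy receptor with exactly the designed hinge angles.

    Each domain is a three-helix poly-ALA bundle translated so its
    heavy-atom COM sits on a planar polyline whose interior angles are the
    designed hinge angles; with ``dimer`` the second subunit is a two-fold
    rotation of the first (so every hinge pair is identical across
    subunits).  Deterministic for a given spec.
    """
    sub_a, domains_a = _build_subunit(spec, "A")
    structures = [sub_a]
    domains = list(domains_a)
    if spec.dimer:
        sub_b = sub_a.copy()
        sub_b.chain = np.array(["B"] * sub_b.n_atoms, dtype=object)
        coms = _com_polyline(spec.hinge_angles, spec.com_separation)
        d_last = coms[-1] - coms[-2]
        d_last /= np.linalg.norm(d_last)
        for mult in (1.0, 1.5, 2.0, 3.0):
            pivot = coms[-1] + mult * spec.com_separation * d_last
            R = _axis_rotation([0.0, 0.0, 1.0], 180.0)
            cand = (sub_a.xyz - pivot) @ R.T + pivot
            n_clash, _ = clash_score_points(sub_a.xyz, cand, 3.0)
            if n_clash == 0:
                sub_b.xyz = cand
                break
        else:
            raise ValueError("infeasible geometry: could not place second subunit")
        structures.append(sub_b)
        domains += [DomainDefinition(d.name, "B", d.ranges) for d in domains_a]
    receptor = concatenate(structures)
    for d in domains:
        receptor.add_annotation(f"{d.name}/{d.chain_id}",
                                select(receptor, d).indices)
    names = _domain_names(spec.n_domains)
    hinges = _hinge_defs(names)
    gt = GroundTruth(domains=domains, hinges=hinges)
    for ch in receptor.chains:
        gt.coms[ch] = {}
        gt.hinge_table[ch] = {}
        for d in [dd for dd in domains if dd.chain_id == ch]:
            gt.coms[ch][d.name] = center_of_mass(select(receptor, d))
        for h in hinges:
            gt.hinge_table[ch][h.name] = hinge_angle(
                gt.coms[ch][h.arm_a], gt.coms[ch][h.vertex], gt.coms[ch][h.arm_b])
    return receptor, gt


def make_deformed_pair(
    structure: Structure,
    deltas: dict[str, float],
    gt: GroundTruth,
    subunits: list[str] | None = None,
    seed: int = 0,
    clash_cutoff: float = 2.5,
) -> tuple[Structure, Structure, GroundTruth]:
    """Apply signed hinge-angle deltas (degrees) by piecewise-rigid rotation.

    For each named hinge the domains downstream of the hinge vertex are
    rotated rigidly about the vertex COM, in the plane of the two arms, by
    the delta (positive opens the hinge).  Applied per subunit; other hinge
    angles are untouched because downstream geometry moves as one rigid
    body.  Returns ``(start, target, ground_truth)`` where start is the
    input unchanged and the ground truth records the expected angle table
    and the resulting Calpha-RMSD.
    """
    from .metrics import rmsd as _rmsd

    target = structure.copy()
    subunits = subunits or target.chains
    by_chain: dict[str, list[DomainDefinition]] = {}
    for d in gt.domains:
        by_chain.setdefault(d.chain_id, []).append(d)
    for ch in by_chain:
        by_chain[ch].sort(key=lambda d: d.ranges[0][0])

    for ch in subunits:
        doms = by_chain[ch]
        order = [d.name for d in doms]
        for h in gt.hinges:
            if h.name not in deltas:
                continue
            delta = float(deltas[h.name])
            com = {d.name: center_of_mass(select(target, d)) for d in doms}
            a = com[h.arm_a] - com[h.vertex]
            b = com[h.arm_b] - com[h.vertex]
            axis = np.cross(a, b)
            nrm = np.linalg.norm(axis)
            if nrm == 0:
                raise ValueError(f"hinge {h.name}: collinear arms, axis undefined")
            R = _axis_rotation(axis / nrm, delta)
            vi = order.index(h.vertex)
            moving = doms[vi + 1:]
            idx = np.concatenate([select(target, d).indices for d in moving])
            target.xyz[idx] = (target.xyz[idx] - com[h.vertex]) @ R.T + com[h.vertex]
            by_name = {d.name: d for d in doms}
            new_ang = hinge_angle(
                center_of_mass(select(target, by_name[h.arm_a])),
                center_of_mass(select(target, by_name[h.vertex])),
                center_of_mass(select(target, by_name[h.arm_b])))
            expected = hinge_angle(com[h.arm_a], com[h.vertex], com[h.arm_b]) + delta
            if not 0.0 < expected < 180.0:
                raise ValueError(f"hinge {h.name}: delta {delta} leaves (0, 180)")
            del new_ang
        # steric feasibility between non-adjacent domains
        for i in range(len(doms)):
            for j in range(i + 2, len(doms)):
                n, _ = clash_score_points(select(target, doms[i]).heavy().positions,
                                          select(target, doms[j]).heavy().positions,
                                          clash_cutoff)
                if n:
                    raise ValueError(
                        f"deformation clashes domains {doms[i].name}/{doms[j].name} "
                        f"on subunit {ch}; reduce deltas"
                    )

    out = GroundTruth(domains=gt.domains, hinges=gt.hinges)
    for ch in structure.chains:
        out.hinge_table[ch] = {}
        for h in gt.hinges:
            base = gt.hinge_table[ch][h.name]
            out.hinge_table[ch][h.name] = base + (deltas.get(h.name, 0.0)
                                                  if ch in subunits else 0.0)
        out.deformation_deltas[ch] = {h.name: (deltas.get(h.name, 0.0)
                                               if ch in subunits else 0.0)
                                      for h in gt.hinges}
    ca = structure.select_all().calpha()
    out.start_rmsd = _rmsd(structure.xyz[ca.indices], target.xyz[ca.indices])
    return structure.copy(), target, out


def plant_pose(ligand: Structure, receptor: Structure,
               pose: RigidPose) -> tuple[Structure, GroundTruth]:
    """Place the ligand at a rigid pose next to the receptor.

    The pose rotates the ligand about its heavy-atom COM, then translates.
    Raises if the planted pose clashes with the receptor (heavy atoms within
    2.5 Å).  Ligand chains are renamed if they collide with receptor chains.
    """
    lig = ligand.copy()
    com = center_of_mass(lig.select_all())
    lig.xyz = pose.apply(lig.xyz, com)
    n_clash, _ = clash_score_points(
        lig.xyz[np.array([e.upper() != "H" for e in lig.element])],
        receptor.xyz[np.array([e.upper() != "H" for e in receptor.element])], 2.5)
    if n_clash:
        raise ValueError(f"planted pose clashes with receptor ({n_clash} pairs)")
    taken = set(receptor.chains)
    rename = {}
    pool = iter("LMNOPQRSTUVWXYZ")
    for ch in lig.chains:
        if ch in taken:
            new = next(c for c in pool if c not in taken)
            rename[ch] = new
            taken.add(new)
    if rename:
        lig.chain = np.array([rename.get(c, c) for c in lig.chain], dtype=object)
    cplx = concatenate([receptor, lig])
    cplx.add_annotation("receptor", np.arange(receptor.n_atoms))
    cplx.add_annotation("ligand", np.arange(receptor.n_atoms, cplx.n_atoms))
    gt = GroundTruth(pose=pose)
    return cplx, gt


def make_target_map(
    structure: Structure,
    components: list[DomainDefinition | str],
    resolution: float = 4.0,
    spacing: float = 1.0,
    padding: float | None = None,
) -> tuple[dict[str, DensityGrid], DensityGrid]:
    """Per-component maps on one shared grid, plus their voxel-wise sum."""
    sels = {}
    for c in components:
        sel = select(structure, c)
        sels[c if isinstance(c, str) else c.name] = sel
    union = None
    for sel in sels.values():
        union = sel if union is None else union.union(sel)
    base = synthesize_map(union, resolution=resolution, spacing=spacing,
                          padding=padding)
    per = {name: synthesize_map(sel, resolution=resolution, grid=base)
           for name, sel in sels.items()}
    return per, combine_maps(list(per.values()))


# -- end-to-end benchmarks -----------------------------------------------------

@dataclass
class FittingBenchmark:
    """Three-component flexible-fitting benchmark with known ground truth."""

    start: Structure
    truth: Structure
    component_names: tuple[str, str, str]
    maps: dict[str, DensityGrid]
    combined_map: DensityGrid
    start_rmsd: float


def make_fitting_benchmark(
    seed: int = 0,
    resolution: float = 4.0,
    spacing: float = 1.0,
    displacements: tuple[float, float, float] = (2.0, 7.5, 5.5),
    rotations_deg: tuple[float, float, float] = (5.0, 20.0, 12.0),
) -> FittingBenchmark:
    """Build the staged-fitting test case.

    Three helical components — a large bundle ("L1"), a medium two-helix
    ligand analog ("hormone") and a single helix ("alphaCT") — are placed
    clash-free; target maps are synthesized from that ground truth; the
    start structure has each component rigidly displaced/rotated, with the
    ligand analog displaced the most, giving a start Calpha-RMSD of several
    Å.  ``seed`` randomizes the displacement directions only.
    """
    rng = np.random.default_rng(seed)
    # unequal helix lengths break flip pseudo-symmetry, as unequal chains do
    # in the real hormone
    l1 = make_bundle(3, [12, 10, 8], chain="A", first_res=1)
    hormone = make_bundle(2, [12, 8], chain="B", first_res=1)
    act = make_kinked_helix(8, 5, chain="C", first_res=701)
    l1_com = center_of_mass(l1.select_all())

    def place(part: Structure, direction: np.ndarray, dist: float,
              placed: list[Structure]) -> None:
        """Slide the part outward along ``direction`` until contact-free."""
        u = direction / np.linalg.norm(direction)
        for extra in np.arange(0.0, 30.0, 1.0):
            part.xyz += (l1_com + (dist + extra) * u
                         - center_of_mass(part.select_all()))
            n = sum(clash_score_points(part.xyz, other.xyz, 4.0)[0]
                    for other in placed)
            if n == 0:
                return
        raise ValueError("could not place benchmark component contact-free")

    place(hormone, np.array([1.0, 0.0, 0.0]), 24.0, [l1])
    place(act, np.array([0.45, 1.0, 0.0]), 20.0, [l1, hormone])
    truth = concatenate([l1, hormone, act])
    n1, n2 = l1.n_atoms, l1.n_atoms + hormone.n_atoms
    truth.add_annotation("L1", np.arange(n1))
    truth.add_annotation("hormone", np.arange(n1, n2))
    truth.add_annotation("alphaCT", np.arange(n2, truth.n_atoms))

    per, combined = make_target_map(truth, ["L1", "hormone", "alphaCT"],
                                    resolution=resolution, spacing=spacing)

    start = truth.copy()
    for name, d, rot in zip(("L1", "hormone", "alphaCT"), displacements, rotations_deg):
        sel = start.select(name)
        com = center_of_mass(sel)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        direction = rng.normal(size=3)
        if name != "L1":
            # displace the smaller components tangentially — a misplaced but
            # metastable start that slides along the large component's
            # surface, not a kick into its density
            radial = com - l1_com
            radial /= np.linalg.norm(radial)
            direction -= np.dot(direction, radial) * radial
        direction /= np.linalg.norm(direction)
        R = _axis_rotation(axis, rot)
        sel.positions = (sel.positions - com) @ R.T + com + d * direction
    ca = truth.select_all().calpha()
    from .metrics import rmsd as _rmsd
    start_rmsd = _rmsd(start.xyz[ca.indices], truth.xyz[ca.indices])
    return FittingBenchmark(start, truth, ("L1", "hormone", "alphaCT"),
                            per, combined, start_rmsd)


def benchmark_protocol(bench: FittingBenchmark, xi: float | None = None,
                       max_steps: int = 2000):
    """The staged fitting protocol for the three-component benchmark.

    Mirrors the reference procedure: first the large component and the
    peptide fit their maps while the ligand analog is positionally
    restrained; then the ligand analog fits with the peptide restrained;
    finally all three refine together without positional restraints.  Each
    component is coupled to its own component map.  Returns
    ``(stages, restraints)`` bound to ``bench.start``.
    """
    from .fitting import XI_DEFAULT, StageSpec, build_map_potential
    from .restraints import assign_secondary_structure, build_internal_restraints

    if xi is None:
        xi = XI_DEFAULT
    st = bench.start
    rs = build_internal_restraints(st).merge(assign_secondary_structure(st))
    big, ligand, peptide = (st.select(n) for n in bench.component_names)
    mp = {k: build_map_potential(v, xi=xi) for k, v in bench.maps.items()}
    n_big, n_lig, n_pep = bench.component_names
    stages = [
        StageSpec("fit-%s-%s" % (n_big, n_pep), big.union(peptide),
                  [(mp[n_big], big), (mp[n_pep], peptide)],
                  positionally_restrained=ligand, max_steps=max_steps),
        StageSpec("fit-%s" % n_lig, ligand, [(mp[n_lig], ligand)],
                  positionally_restrained=peptide, max_steps=max_steps),
        StageSpec("fit-all", big.union(ligand).union(peptide),
                  [(mp[n_big], big), (mp[n_lig], ligand), (mp[n_pep], peptide)],
                  max_steps=max_steps),
    ]
    return stages, rs


@dataclass
class DockingToy:
    """Planted-pose docking test case."""

    cplx: Structure            # ligand at the start (displaced) placement
    planted_ligand_xyz: np.ndarray
    ligand_map: DensityGrid
    start_pose_offset: tuple[float, float]  # (Å, degrees) applied to the truth


def make_docking_toy(seed: int = 0, offset: float = 3.0,
                     rotation_deg: float = 20.0,
                     resolution: float = 4.0) -> DockingToy:
    """Receptor + small ligand with a planted clash-free pose.

    The ligand's target density is synthesized at its planted placement; the
    returned complex carries the ligand displaced by ``offset`` Å and rotated
    by ``rotation_deg`` so a docking search can be tested for recovery.
    """
    rng = np.random.default_rng(seed)
    receptor = make_bundle(3, 10, chain="A", first_res=1)
    ligand = make_bundle(2, 8, chain="L", first_res=1)
    shift = np.array([23.0, 2.0, 0.0]) + center_of_mass(receptor.select_all()) \
        - center_of_mass(ligand.select_all())
    pose = RigidPose(np.eye(3), shift)
    cplx, gt = plant_pose(ligand, receptor, pose)
    planted = cplx.xyz[cplx.annotations["ligand"]].copy()
    lig_sel = Selection(cplx, cplx.annotations["ligand"], "ligand")
    lig_map = synthesize_map(lig_sel, resolution=resolution, spacing=1.0)

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = _axis_rotation(axis, rotation_deg)
    com = center_of_mass(lig_sel)
    lig_sel.positions = (lig_sel.positions - com) @ R.T + com + offset * direction
    return DockingToy(cplx, planted, lig_map, (offset, rotation_deg))
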