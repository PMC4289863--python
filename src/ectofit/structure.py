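"""Structure container, PDB I/O, residue-range selections and chain grafting.

The container is array-backed: one numpy array per atom attribute, in file
order. Selections are ordered, duplicate-free index arrays into a parent
structure, which keeps every downstream computation (density synthesis,
energies, superposition) a plain vectorised numpy operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .elements import ATOMIC_MASS, mass_of

_WATER_NAMES = {"HOH", "WAT", "DOD", "TIP", "TIP3", "SOL"}


@dataclass(frozen=True)
class DomainDefinition:
    """A named set of inclusive residue ranges on one chain.

    Ranges are 1-based inclusive ``[start, end]`` pairs, the PDB convention.
    """

    name: str
    chain_id: str
    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self):
        rngs = tuple((int(a), int(b)) for a, b in self.ranges)
        object.__setattr__(self, "ranges", rngs)
        for a, b in rngs:
            if a > b:
                raise ValueError(f"domain {self.name}: range {a}-{b} has start > end")
        for i, (a1, b1) in enumerate(rngs):
            for a2, b2 in rngs[i + 1 :]:
                if a1 <= b2 and a2 <= b1:
                    raise ValueError(f"domain {self.name}: overlapping ranges")

    def residues(self) -> list[int]:
        out: list[int] = []
        for a, b in self.ranges:
            out.extend(range(a, b + 1))
        return out


class Structure:
    """Ordered collection of atoms with per-atom attribute arrays.

    Parameters mirror PDB ATOM fields. ``annotations`` maps a label (e.g. a
    domain name such as ``"L1"`` or ``"insulin"``) to an index array.
    """

    def __init__(
        self,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        resseq: np.ndarray,
        resname: np.ndarray,
        chain: np.ndarray,
        xyz: np.ndarray,
        occupancy: np.ndarray | None = None,
        bfactor: np.ndarray | None = None,
        annotations: dict[str, np.ndarray] | None = None,
    ):
        n = len(serial)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.name = np.asarray(name, dtype=object)
        self.element = np.asarray(element, dtype=object)
        self.resseq = np.asarray(resseq, dtype=np.int64)
        self.resname = np.asarray(resname, dtype=object)
        self.chain = np.asarray(chain, dtype=object)
        self.xyz = np.ascontiguousarray(xyz, dtype=np.float64).reshape(n, 3)
        self.occupancy = (
            np.ones(n) if occupancy is None else np.asarray(occupancy, dtype=np.float64)
        )
        self.bfactor = (
            np.zeros(n) if bfactor is None else np.asarray(bfactor, dtype=np.float64)
        )
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite atomic coordinates")
        self.mass = np.array([mass_of(e) for e in self.element], dtype=np.float64)
        self.annotations: dict[str, np.ndarray] = {}
        for key, idx in (annotations or {}).items():
            self.add_annotation(key, idx)

    # -- basic protocol ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        return f"<Structure {self.n_atoms} atoms, chains {','.join(self.chains)}>"

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c)
        return list(seen)

    def add_annotation(self, label: str, indices: np.ndarray) -> None:
        idx = np.asarray(indices, dtype=np.int64)
        if idx.size == 0:
            raise ValueError(f"annotation {label!r} resolves to no atoms")
        if idx.min() < 0 or idx.max() >= self.n_atoms:
            raise IndexError(f"annotation {label!r} has out-of-range indices")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"annotation {label!r} has duplicate indices")
        self.annotations[label] = idx

    def copy(self) -> "Structure":
        return Structure(
            self.serial.copy(), self.name.copy(), self.element.copy(),
            self.resseq.copy(), self.resname.copy(), self.chain.copy(),
            self.xyz.copy(), self.occupancy.copy(), self.bfactor.copy(),
            {k: v.copy() for k, v in self.annotations.items()},
        )

    def subset(self, indices: np.ndarray) -> "Structure":
        """New structure holding the given atoms (annotations dropped)."""
        idx = np.asarray(indices, dtype=np.int64)
        return Structure(
            self.serial[idx], self.name[idx], self.element[idx],
            self.resseq[idx], self.resname[idx], self.chain[idx],
            self.xyz[idx], self.occupancy[idx], self.bfactor[idx],
        )

    def validate_unique(self) -> None:
        keys = set()
        for c, r, n in zip(self.chain, self.resseq, self.name):
            k = (c, int(r), n)
            if k in keys:
                raise ValueError(f"duplicate atom identifier {k}")
            keys.add(k)

    # -- selections --------------------------------------------------------
    def select(self, spec: "DomainDefinition | str", label: str | None = None) -> "Selection":
        return select(self, spec, label=label)

    def select_all(self, label: str = "all") -> "Selection":
        return Selection(self, np.arange(self.n_atoms), label)

    def select_chain(self, chain_id: str) -> "Selection":
        idx = np.nonzero(self.chain == chain_id)[0]
        if idx.size == 0:
            raise ValueError(f"no atoms in chain {chain_id!r}")
        return Selection(self, idx, f"chain {chain_id}")


@dataclass
class Selection:
    """Ordered, duplicate-free view onto a subset of a structure's atoms."""

    structure: Structure
    indices: np.ndarray
    label: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= self.structure.n_atoms):
            raise IndexError(f"selection {self.label!r}: index out of range")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"selection {self.label!r}: duplicate indices")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def positions(self) -> np.ndarray:
        return self.structure.xyz[self.indices]

    @positions.setter
    def positions(self, value: np.ndarray) -> None:
        self.structure.xyz[self.indices] = value

    @property
    def masses(self) -> np.ndarray:
        return self.structure.mass[self.indices]

    @property
    def elements(self) -> np.ndarray:
        return self.structure.element[self.indices]

    def heavy(self) -> "Selection":
        el = self.structure.element[self.indices]
        keep = np.fromiter((e.upper() != "H" for e in el), dtype=bool, count=len(el))
        return Selection(self.structure, self.indices[keep], f"{self.label} (heavy)")

    def calpha(self) -> "Selection":
        nm = self.structure.name[self.indices]
        keep = np.fromiter((n == "CA" for n in nm), dtype=bool, count=len(nm))
        return Selection(self.structure, self.indices[keep], f"{self.label} (CA)")

    def union(self, other: "Selection") -> "Selection":
        assert other.structure is self.structure
        merged = np.union1d(self.indices, other.indices)
        return Selection(self.structure, merged, f"{self.label}|{other.label}")

    def intersection(self, other: "Selection") -> "Selection":
        assert other.structure is self.structure
        merged = np.intersect1d(self.indices, other.indices)
        return Selection(self.structure, merged, f"{self.label}&{other.label}")

    def as_structure(self) -> Structure:
        return self.structure.subset(self.indices)


def select(structure: Structure, spec: DomainDefinition | str, label: str | None = None) -> Selection:
    """Resolve a domain definition or annotation name to a selection.

    Raises if the selection would be empty, listing residues that did not
    resolve when a range is partly missing.
    """
    if isinstance(spec, str):
        if spec not in structure.annotations:
            raise KeyError(f"no annotation {spec!r} on structure")
        return Selection(structure, structure.annotations[spec].copy(), label or spec)

    on_chain = structure.chain == spec.chain_id
    wanted = spec.residues()
    mask = on_chain & np.isin(structure.resseq, wanted)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(
            f"domain {spec.name!r}: no atoms for chain {spec.chain_id!r} "
            f"residues {spec.ranges}"
        )
    present = set(structure.resseq[idx].tolist())
    missing = [r for r in wanted if r not in present]
    if missing:
        raise ValueError(
            f"domain {spec.name!r}: residues missing from chain "
            f"{spec.chain_id!r}: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    return Selection(structure, idx, label or spec.name)


# -- PDB I/O ----------------------------------------------------------------

def _element_of(atom_name: str, element: str) -> str:
    el = element.strip().upper()
    if el and el in ATOMIC_MASS:
        return el
    # fall back to the first alphabetic character of the atom name
    for ch in atom_name:
        if ch.isalpha():
            if ch.upper() in ATOMIC_MASS:
                return ch.upper()
            break
    raise ValueError(f"cannot assign element for atom {atom_name!r} ({element!r})")


def read_pdb(
    path: str | Path,
    keep_hydrogens: bool = True,
    keep_hetero: bool = False,
    model: int = 0,
) -> Structure:
    """Read ATOM records of one model into a :class:`Structure`.

    Waters and (by default) other heteroatoms are excluded; for residues with
    alternate locations only the highest-occupancy conformer is kept. Chain
    ids and residue numbering are preserved verbatim.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi errors carry the offending line
        raise ValueError(f"failed to parse {path}: {exc}") from None
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    mdl = st[model]

    serial, name, element, resseq, resname, chain, xyz, occ, bfac = (
        [], [], [], [], [], [], [], [], [])
    for ch in mdl:
        for res in ch:
            if res.name in _WATER_NAMES:
                continue
            if res.het_flag == "H" and not keep_hetero and res.name not in _WATER_NAMES:
                # standard amino acids are het_flag 'A'; skip true hetero
                continue
            by_name: dict[str, object] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            for at in by_name.values():
                el = _element_of(at.name, at.element.name)
                if el == "H" and not keep_hydrogens:
                    continue
                serial.append(at.serial)
                name.append(at.name)
                element.append(el)
                resseq.append(res.seqid.num)
                resname.append(res.name)
                chain.append(ch.name)
                xyz.append([at.pos.x, at.pos.y, at.pos.z])
                occ.append(at.occ)
                bfac.append(at.b_iso)
    if not serial:
        raise ValueError(f"{path}: empty structure (no ATOM records kept)")
    return Structure(
        np.array(serial), np.array(name, dtype=object), np.array(element, dtype=object),
        np.array(resseq), np.array(resname, dtype=object), np.array(chain, dtype=object),
        np.array(xyz), np.array(occ), np.array(bfac),
    )


def write_pdb(structure: Structure, path: str | Path, renumber: bool = True) -> None:
    """Write the structure as PDB ATOM records.

    Serials above 99999 are handled by gemmi's hybrid-36 encoding; with
    ``renumber`` (default) atoms are renumbered sequentially first.
    """
    import gemmi

    if structure.n_atoms == 0:
        raise ValueError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = "ectofit"
    mdl = gemmi.Model("1")
    cur_chain = None
    cur_res_key = None
    gch = gres = None
    serial = 0
    for i in range(structure.n_atoms):
        if structure.chain[i] != cur_chain:
            cur_chain = structure.chain[i]
            gch = gemmi.Chain(str(cur_chain))
            mdl.add_chain(gch)
            gch = mdl[-1]
            cur_res_key = None
        rk = (structure.resseq[i], structure.resname[i])
        if rk != cur_res_key:
            cur_res_key = rk
            gres = gemmi.Residue()
            gres.name = str(structure.resname[i])
            gres.seqid = gemmi.SeqId(int(structure.resseq[i]), " ")
            gres.het_flag = "A"
            gch.add_residue(gres)
            gres = gch[-1]
        at = gemmi.Atom()
        at.name = str(structure.name[i])
        at.element = gemmi.Element(str(structure.element[i]).capitalize())
        x, y, z = structure.xyz[i]
        at.pos = gemmi.Position(float(x), float(y), float(z))
        at.occ = float(structure.occupancy[i])
        at.b_iso = float(structure.bfactor[i])
        serial += 1
        at.serial = serial if renumber else int(structure.serial[i])
        gres.add_atom(at)
    st.add_model(mdl)
    st.write_pdb(str(path), gemmi.PdbWriteOptions(minimal=True))


# -- grafting ----------------------------------------------------------------

def graft_extension(
    base: Structure,
    donor: Structure,
    align_range: DomainDefinition,
    graft_range: DomainDefinition,
    rmsd_warn: float = 2.0,
) -> Structure:
    """Extend a chain of ``base`` with residues copied from ``donor``.

    The donor is rigidly superposed onto the base using the Cα atoms of
    ``align_range`` (least-squares, reflections excluded), then the atoms of
    ``graft_range`` are copied into the base chain in the superposed frame.
    Raises if the graft residues already exist in the base; warns if the
    alignment RMSD exceeds ``rmsd_warn`` Å.
    """
    from .metrics import kabsch_superpose

    sel_base = select(base, align_range).calpha()
    sel_donor = select(donor, align_range).calpha()
    if len(sel_base) != len(sel_donor):
        raise ValueError(
            f"alignment range resolves to {len(sel_base)} CA in base but "
            f"{len(sel_donor)} in donor"
        )
    rot, trans, rmsd = kabsch_superpose(sel_donor, sel_base)
    if rmsd > rmsd_warn:
        warnings.warn(
            f"graft alignment RMSD {rmsd:.2f} Å exceeds {rmsd_warn} Å", stacklevel=2
        )

    graft_sel = select(donor, graft_range)
    target_chain = align_range.chain_id
    wanted = set(graft_range.residues())
    clash = set(base.resseq[base.chain == target_chain].tolist()) & wanted
    if clash:
        raise ValueError(
            f"graft residues already present in base chain {target_chain!r}: "
            f"{sorted(clash)}"
        )

    moved = graft_sel.positions @ rot.T + trans
    frag = donor.subset(graft_sel.indices)
    frag.xyz = moved
    frag.chain = np.array([target_chain] * frag.n_atoms, dtype=object)

    # merge: insert graft atoms into the target chain in residue order
    out_order: list[tuple[int, int, str]] = []  # (source, index) with sort keys
    arrays = {k: [] for k in ("serial", "name", "element", "resseq", "resname",
                              "chain", "xyz", "occupancy", "bfactor")}

    def _push(src: Structure, i: int) -> None:
        arrays["serial"].append(src.serial[i])
        arrays["name"].append(src.name[i])
        arrays["element"].append(src.element[i])
        arrays["resseq"].append(src.resseq[i])
        arrays["resname"].append(src.resname[i])
        arrays["chain"].append(src.chain[i])
        arrays["xyz"].append(src.xyz[i])
        arrays["occupancy"].append(src.occupancy[i])
        arrays["bfactor"].append(src.bfactor[i])

    graft_done = False
    for i in range(base.n_atoms):
        _push(base, i)
        is_chain_end = (
            base.chain[i] == target_chain
            and (i + 1 == base.n_atoms or base.chain[i + 1] != target_chain)
        )
        if is_chain_end and not graft_done:
            for j in np.argsort(frag.resseq, kind="stable"):
                _push(frag, int(j))
            graft_done = True
    if not graft_done:
        raise ValueError(f"chain {target_chain!r} not found in base")

    out = Structure(
        np.array(arrays["serial"]), np.array(arrays["name"], dtype=object),
        np.array(arrays["element"], dtype=object), np.array(arrays["resseq"]),
        np.array(arrays["resname"], dtype=object), np.array(arrays["chain"], dtype=object),
        np.array(arrays["xyz"]), np.array(arrays["occupancy"]), np.array(arrays["bfactor"]),
    )
    out.validate_unique()
    return out


def concatenate(parts: list[Structure], chain_map: dict[int, str] | None = None) -> Structure:
    """Concatenate structures into one; ``chain_map`` renames chains per part."""
    cols = {k: [] for k in ("serial", "name", "element", "resseq", "resname",
                            "chain", "xyz", "occupancy", "bfactor")}
    for pi, p in enumerate(parts):
        ch = p.chain
        if chain_map and pi in chain_map:
            ch = np.array([chain_map[pi]] * p.n_atoms, dtype=object)
        cols["serial"].append(p.serial)
        cols["name"].append(p.name)
        cols["element"].append(p.element)
        cols["resseq"].append(p.resseq)
        cols["resname"].append(p.resname)
        cols["chain"].append(ch)
        cols["xyz"].append(p.xyz)
        cols["occupancy"].append(p.occupancy)
        cols["bfactor"].append(p.bfactor)
    return Structure(*[np.concatenate(cols[k]) for k in
                       ("serial", "name", "element", "resseq", "resname", "chain")],
                     np.vstack(cols["xyz"]),
                     np.concatenate(cols["occupancy"]),
                     np.concatenate(cols["bfactor"]))


def load_domain_definitions(path: str | Path) -> list[DomainDefinition]:
    """Load domain definitions from a YAML config.

    Expected layout::

        domains:
          - {name: L1, chain: A, ranges: [[1, 157]]}
          - {name: F2, chain: A, ranges: [[596, 655], [756, 808]]}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = []
    for d in cfg.get("domains", []):
        out.append(DomainDefinition(d["name"], str(d["chain"]),
                                    tuple(tuple(r) for r in d["ranges"])))
    return out


def annotate_domains(structure: Structure, domains: list[DomainDefinition]) -> None:
    """Attach each domain as an annotation named ``{name}/{chain}``."""
    for d in domains:
        sel = select(structure, d)
        structure.add_annotation(f"{d.name}/{d.chain_id}", sel.indices)
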