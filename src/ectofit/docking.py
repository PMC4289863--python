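"""Rigid-body Metropolis Monte Carlo docking and ensemble screening.

The search moves one rigid component (random rotation about its center of
mass plus random translation) against a fixed context, scoring each pose by
a weighted sum of steric clash energy and a density-fit term, and accepting
moves with the Metropolis rule exp(-dE/T).  Screening evaluates a set of
candidate receptor conformations against the density reserved for other
components: a conformation passes when it does not intrude into that density
and makes no steric clashes, the criterion used to pick receptor states able
to accommodate the ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .density import (DensityGrid, FWHM_FACTOR, MapThreshold,
                      accumulate_gaussians, sample_and_gradient)
from .structure import DomainDefinition, Selection, Structure, select

CLASH_CUTOFF = 2.5  # Å between heavy atoms; a severe-contact criterion


@dataclass
class RigidPose:
    """Proper rotation + translation of a rigid body, with its scores."""

    rotation: np.ndarray
    translation: np.ndarray
    score_components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det < 0 (improper)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def total(self) -> float:
        return self.score_components.get("total", np.inf)

    def apply(self, positions: np.ndarray, pivot: np.ndarray) -> np.ndarray:
        """Rotate about ``pivot`` then translate."""
        return (positions - pivot) @ self.rotation.T + pivot + self.translation

    @staticmethod
    def identity() -> "RigidPose":
        return RigidPose(np.eye(3), np.zeros(3))


@dataclass
class DockingResult:
    accepted: list[RigidPose]
    acceptance_rate: float
    best: RigidPose
    seed: int

    def __post_init__(self):
        if self.accepted:
            assert self.best.total <= min(p.total for p in self.accepted) + 1e-12


@dataclass
class ScreenRecord:
    conformation_id: str
    overlap: float
    clash_count: int
    clash_energy: float
    passed: bool


def clash_score(sel_a: Selection, sel_b: Selection,
                cutoff: float = CLASH_CUTOFF) -> tuple[int, float]:
    """Count and penalise heavy-atom contacts closer than ``cutoff``.

    Energy is the soft-sphere penalty ``sum (r - cutoff)^2`` over clashing
    pairs; symmetric in its arguments.
    """
    if sel_a.structure is sel_b.structure and np.intersect1d(sel_a.indices, sel_b.indices).size:
        raise ValueError("clash selections must be disjoint")
    pa = sel_a.heavy().positions
    pb = sel_b.heavy().positions
    return clash_score_points(pa, pb, cutoff)


def clash_score_points(pa: np.ndarray, pb: np.ndarray,
                       cutoff: float = CLASH_CUTOFF) -> tuple[int, float]:
    """Clash count/energy between two coordinate sets (spatial-hash search)."""
    if len(pa) == 0 or len(pb) == 0:
        return 0, 0.0
    ta = cKDTree(pa)
    tb = cKDTree(pb)
    pairs = ta.query_ball_tree(tb, r=cutoff)
    count = 0
    energy = 0.0
    for ia, lst in enumerate(pairs):
        if not lst:
            continue
        d = np.linalg.norm(pb[lst] - pa[ia], axis=1)
        close = d < cutoff
        count += int(close.sum())
        energy += float(np.sum((d[close] - cutoff) ** 2))
    return count, energy


def map_overlap(sel: Selection, grid: DensityGrid,
                threshold: MapThreshold | None = None) -> float:
    """Fraction of the selection's heavy atoms inside super-threshold density.

    Zero means the selection stays clear of the region the map reserves for
    other components; atoms outside the grid count as non-overlapping.
    """
    if threshold is None:
        threshold = MapThreshold.fraction_of_max(grid)
    pts = sel.heavy().positions
    vals, _, inside = sample_and_gradient(grid, pts)
    hits = (vals > threshold.level) & inside
    return float(hits.sum() / len(pts))


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """The Metropolis criterion: accept with probability min(1, exp(-dE/T))."""
    if delta_e <= 0:
        return True
    if temperature <= 0:
        return False
    return bool(rng.random() < np.exp(-delta_e / temperature))


def _random_rotation(max_deg: float, rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(0.0, max_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def _random_translation(max_t: float, rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.uniform(-1, 1, size=3)
        if np.dot(v, v) <= 1.0:
            return max_t * v


def mc_dock(
    mobile: Selection,
    context: Selection | None,
    maps: list,
    moveset: tuple[float, float] = (2.0, 10.0),
    temperature: float = 1.0,
    n_steps: int = 1000,
    seed: int = 0,
    w_clash: float = 1.0,
    w_map: float = 1.0,
    clash_cutoff: float = CLASH_CUTOFF,
    map_energy: str = "potential",
    ccc_target: DensityGrid | None = None,
) -> DockingResult:
    """Metropolis MC search over rigid poses of ``mobile``.

    ``maps`` is a list of :class:`~ectofit.fitting.MapPotential`.  The
    map-fit term is, per config, either the mean per-atom potential energy
    (``map_energy="potential"``, cheap but only weakly orientation-sensitive)
    or ``1 - CCC`` against ``ccc_target`` (``map_energy="ccc"``, a shape
    match; default target is the summed sources of ``maps``).  The total
    energy is ``w_clash * E_clash + w_map * E_map``.  The chain is
    reproducible given ``seed``; the mobile selection's coordinates are not
    modified — poses are returned relative to the starting placement,
    rotation taken about the mobile COM.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    max_t, max_r = moveset
    if max_t <= 0 or max_r <= 0:
        raise ValueError("moveset must be positive")
    if map_energy not in ("potential", "ccc"):
        raise ValueError(f"unknown map_energy {map_energy!r}")
    rng = np.random.default_rng(seed)
    start = mobile.heavy().positions
    masses = mobile.heavy().masses
    pivot = (start * masses[:, None]).sum(axis=0) / masses.sum()
    ctx = context.heavy().positions if context is not None and len(context) else None
    weights = masses / masses.mean()

    if map_energy == "ccc" and maps:
        if ccc_target is None:
            tv = sum(mp.source.values for mp in maps)
            ccc_target = DensityGrid(maps[0].source.origin.copy(),
                                     maps[0].source.spacing, tv,
                                     maps[0].source.resolution)
        mask = ccc_target.values > 0.01 * ccc_target.values.max()
        tvals = ccc_target.values[mask]
        t0 = tvals - tvals.mean()
        tsd = tvals.std()
        sigma = ccc_target.resolution / FWHM_FACTOR

        def map_term(pos: np.ndarray) -> float:
            model = accumulate_gaussians(pos, masses, sigma, ccc_target.origin,
                                         ccc_target.spacing, ccc_target.dims)
            mv = model[mask]
            sd = mv.std()
            if sd == 0:
                return 1.0
            return 1.0 - float(np.dot(mv - mv.mean(), t0) / (len(mv) * sd * tsd))
    else:
        def map_term(pos: np.ndarray) -> float:
            e_sum = 0.0
            for mp in maps:
                e, _ = mp.energy_and_gradient(pos, weights)
                e_sum += e / len(pos)
            return e_sum

    def energy(pos: np.ndarray) -> dict[str, float]:
        comps = {"clash": 0.0, "map": 0.0}
        if ctx is not None:
            _, e = clash_score_points(pos, ctx, clash_cutoff)
            comps["clash"] = e
        comps["map"] = map_term(pos)
        comps["total"] = w_clash * comps["clash"] + w_map * comps["map"]
        return comps

    R = np.eye(3)
    t = np.zeros(3)
    comps = energy(start)
    accepted: list[RigidPose] = [RigidPose(R.copy(), t.copy(), dict(comps))]
    best = accepted[0]
    n_acc = 0
    for _ in range(n_steps):
        dR = _random_rotation(max_r, rng)
        dt = _random_translation(max_t, rng)
        R_new = dR @ R
        t_new = t + dt
        pose = RigidPose(R_new, t_new)
        pos = pose.apply(start, pivot)
        trial = energy(pos)
        if metropolis_accept(trial["total"] - comps["total"], temperature, rng):
            R, t, comps = R_new, t_new, trial
            n_acc += 1
            rec = RigidPose(R.copy(), t.copy(), dict(comps))
            accepted.append(rec)
            if rec.total < best.total:
                best = rec
    return DockingResult(accepted, n_acc / n_steps, best, seed)


def screen_ensemble(
    conformations: list[Structure],
    fixed_component_map: DensityGrid,
    screened_selection: DomainDefinition | str,
    overlap_tol: float = 0.0,
    clash_tol: int = 0,
    threshold: MapThreshold | None = None,
    fixed_atoms: Selection | None = None,
    clash_cutoff: float = CLASH_CUTOFF,
    ids: list[str] | None = None,
) -> list[ScreenRecord]:
    """Screen receptor conformations against the density of fixed components.

    Each conformation's ``screened_selection`` is scored by its overlap
    fraction with the super-threshold region of ``fixed_component_map`` and,
    when ``fixed_atoms`` is given, by steric clashes against those atoms.
    Records are sorted by overlap then clash count; ``passed`` requires
    ``overlap <= overlap_tol`` and ``clash_count <= clash_tol``.
    """
    if not conformations:
        raise ValueError("empty ensemble")
    if threshold is None:
        threshold = MapThreshold.fraction_of_max(fixed_component_map)
    if ids is None:
        ids = [f"conf{i:04d}" for i in range(len(conformations))]
    fixed_pos = fixed_atoms.heavy().positions if fixed_atoms is not None else None
    records = []
    for cid, conf in zip(ids, conformations):
        sel = select(conf, screened_selection)
        ov = map_overlap(sel, fixed_component_map, threshold)
        count, energy = (0, 0.0)
        if fixed_pos is not None:
            count, energy = clash_score_points(sel.heavy().positions, fixed_pos,
                                               clash_cutoff)
        records.append(ScreenRecord(cid, ov, count, energy,
                                    ov <= overlap_tol and count <= clash_tol))
    records.sort(key=lambda r: (r.overlap, r.clash_count, r.conformation_id))
    return records


def screen_frame(records: list[ScreenRecord], overlap_tol: float = 0.0,
                 clash_tol: int = 0, threshold_level: float | None = None) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    df.attrs["overlap_tol"] = overlap_tol
    df.attrs["clash_tol"] = clash_tol
    if threshold_level is not None:
        df.attrs["map_threshold"] = threshold_level
    return df


def select_low_energy(
    candidates: list[Structure],
    context: Selection,
    maps: list | None = None,
    w_clash: float = 1.0,
    w_map: float = 1.0,
    clash_cutoff: float = CLASH_CUTOFF,
) -> list[tuple[int, float]]:
    """Rank candidate fragments by clash energy against a fixed context.

    All candidates must share atom composition.  Returns ``(index, energy)``
    pairs sorted ascending by energy; ties keep candidate order (stable).
    An optional map term adds the mean per-atom density-potential energy.
    """
    if not candidates:
        raise ValueError("no candidates")
    ref_names = [tuple(c.name.tolist()) for c in candidates]
    if len(set(ref_names)) != 1:
        raise ValueError("candidates differ in atom composition")
    ctx_pos = context.heavy().positions
    scored = []
    for i, cand in enumerate(candidates):
        sel = cand.select_all()
        pos = sel.heavy().positions
        _, e = clash_score_points(pos, ctx_pos, clash_cutoff)
        total = w_clash * e
        if maps:
            m = sel.heavy().masses
            w = m / m.mean()
            for mp in maps:
                me, _ = mp.energy_and_gradient(pos, w)
                total += w_map * me / len(pos)
        scored.append((i, total))
    return sorted(scored, key=lambda t: (t[1], t[0]))
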