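"""Map-guided restrained flexible fitting.

The target density map is turned into a per-atom potential
``E_i = xi * w_i * (1 - rho_hat(r_i))`` where ``rho_hat`` is the map value
normalized to [0, 1] between a background threshold and the map maximum, and
``w_i = m_i / <m>`` is the atom's mass relative to the mean mass of the
fitted atoms.  Atoms in sub-threshold (solvent) regions sit on a flat
plateau and feel no map force.  Fitting is damped gradient descent on the
total energy (map potential + internal restraints), with a hard cap on the
per-step atomic displacement for stability, run as a sequence of stages in
which different components are mobile or positionally tethered — the staged
protocol that lets one component settle into its density before the next is
released.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .density import DensityGrid, MapThreshold, ccc, combine_maps, sample_and_gradient
from .metrics import rmsd
from .restraints import RestraintSet, evaluate_restraints
from .structure import Selection, Structure

XI_DEFAULT = 0.3          # map scaling factor, kcal/mol per unit normalized density
STEP_CAP_DEFAULT = 0.2    # Å, max per-step atomic displacement
CONVERGENCE_TOL = 1e-4    # kcal/mol energy decrease per step, over a window
CONVERGENCE_WINDOW = 50   # steps


@dataclass
class MapPotential:
    """Density-derived attractive potential with scaling factor xi."""

    source: DensityGrid
    xi: float
    threshold: MapThreshold
    normalized: DensityGrid = field(init=False, repr=False)

    def __post_init__(self):
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        vmax = float(self.source.values.max())
        if vmax <= 0:
            raise ValueError("cannot build a potential from an all-zero map")
        lo = self.threshold.level
        if lo >= vmax:
            raise ValueError("threshold at or above the map maximum")
        field_ = np.clip((self.source.values - lo) / (vmax - lo), 0.0, 1.0)
        self.normalized = DensityGrid(self.source.origin.copy(), self.source.spacing,
                                      field_, self.source.resolution)

    def energy_and_gradient(self, positions: np.ndarray, weights: np.ndarray) -> tuple[float, np.ndarray]:
        """Energy and d(E)/d(position) for atoms at ``positions``.

        Atoms outside the grid interior are clamped (zero force).
        """
        vals, grads, _ = sample_and_gradient(self.normalized, positions)
        energy = float(self.xi * np.sum(weights * (1.0 - vals)))
        grad = -self.xi * weights[:, None] * grads
        return energy, grad


def build_map_potential(grid: DensityGrid, xi: float = XI_DEFAULT,
                        threshold: MapThreshold | None = None) -> MapPotential:
    """Wrap a density grid as a fitting potential (threshold default: 1% of max)."""
    if threshold is None:
        threshold = MapThreshold.fraction_of_max(grid)
    return MapPotential(grid, xi, threshold)


@dataclass
class StageSpec:
    """One stage of a fitting protocol.

    ``restarts > 1`` runs the stage that many times — the first attempt from
    the stage-start coordinates, later ones with a random rigid rotation of
    the mobile body about its COM (up to ``jitter_rotation_deg``) — and keeps
    the lowest-energy outcome.  This is the zero-temperature counterpart of
    the thermal fluctuations a dynamics-based fit relies on to escape a
    misoriented local minimum; it is deterministic given the run seed.
    """

    label: str
    mobile: Selection
    #: each entry is a MapPotential or a (MapPotential, Selection) pair; with
    #: a selection the map acts only on those atoms (the usual multi-map
    #: convention: every component is coupled to the map that describes it,
    #: so a neighbour's density skirt cannot capture it)
    active_maps: list = None
    positionally_restrained: Selection | None = None
    max_steps: int = 500
    step_cap: float = STEP_CAP_DEFAULT
    k_positional: float = 10.0
    restarts: int = 1
    jitter_rotation_deg: float = 15.0
    jitter_translation: float = 2.0  # Å, restart COM jitter (uniform ball)
    #: run a short rigid-body Metropolis search per mobile chain before the
    #: flexible relaxation — the standard way to resolve a misoriented
    #: component that a local minimizer cannot rotate through a barrier
    rigid_predock: bool = False
    predock_steps: int = 1200
    predock_temperature: float = 0.01
    predock_moveset: tuple[float, float] = (1.0, 6.0)
    predock_map_energy: str = "ccc"

    def __post_init__(self):
        if self.active_maps is None:
            self.active_maps = []
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.step_cap <= 0:
            raise ValueError("step_cap must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class FitResult:
    """Trajectory of a fitting run with per-frame bookkeeping."""

    frames: list[np.ndarray]
    energies: list[dict[str, float]]
    ccc_series: list[float]
    rmsd_series: list[float]
    stage_labels: list[str]
    steps: list[int]
    final: Structure
    rmsd_convention: str = "direct (no superposition), Calpha"

    def __post_init__(self):
        n = len(self.frames)
        for series in (self.energies, self.stage_labels, self.steps):
            assert len(series) == n, "per-frame series length mismatch"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.frames)):
            row = {"frame": i, "step": self.steps[i], "stage": self.stage_labels[i]}
            row.update(self.energies[i])
            if self.ccc_series:
                row["ccc"] = self.ccc_series[i]
            if self.rmsd_series:
                row["rmsd_A"] = self.rmsd_series[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def extend(self, other: "FitResult") -> "FitResult":
        offset = self.steps[-1] if self.steps else 0
        return FitResult(
            self.frames + other.frames,
            self.energies + other.energies,
            self.ccc_series + other.ccc_series,
            self.rmsd_series + other.rmsd_series,
            self.stage_labels + other.stage_labels,
            self.steps + [s + offset for s in other.steps],
            other.final,
            self.rmsd_convention,
        )


def _total_energy(xyz, restraints, map_terms):
    """Energy components and gradient; ``map_terms`` is a list of
    ``(MapPotential, atom_indices, per-atom weights)`` triples."""
    comps, grad = evaluate_restraints(restraints, xyz)
    map_e = 0.0
    for mp, idx, w in map_terms:
        if len(idx) == 0:
            continue
        e, g = mp.energy_and_gradient(xyz[idx], w)
        map_e += e
        grad[idx] += g
    comps["map"] = map_e
    comps["total"] = map_e + sum(v for k, v in comps.items() if k not in ("map", "total"))
    return comps, grad


def _resolve_map_terms(entries, masses, mobile_idx):
    """Normalize stage map entries to (potential, indices, weights) triples,
    restricted to mobile atoms."""
    terms = []
    for entry in entries or []:
        if isinstance(entry, tuple):
            mp, sel = entry
            idx = np.intersect1d(sel.indices, mobile_idx)
        else:
            mp, idx = entry, mobile_idx
        if len(idx):
            w = masses[idx] / masses[idx].mean()
        else:
            w = np.empty(0)
        terms.append((mp, idx, w))
    return terms


def relax(
    structure: Structure,
    stage: StageSpec,
    restraints: RestraintSet,
    seed: int = 0,
    ccc_map: DensityGrid | None = None,
    reference: Structure | None = None,
    trace_selection: Selection | None = None,
    save_every: int = 25,
    jitter: float = 0.0,
) -> FitResult:
    """Relaxation of one fitting stage (possibly with restarts).

    Only ``stage.mobile`` atoms move; ``stage.positionally_restrained`` atoms
    get harmonic tethers at their current positions.  The logged total energy
    is monotone non-increasing; the per-step atomic displacement never
    exceeds ``stage.step_cap``.  ``seed`` drives the optional start jitter
    and restart rotations; with ``restarts == 1`` and ``jitter == 0`` the run
    is fully deterministic regardless of the seed.
    """
    if stage.rigid_predock and len(stage.mobile):
        structure = _rigid_predock(structure, stage, seed)
    if stage.restarts == 1:
        return _relax_once(structure, stage, restraints, seed, ccc_map,
                           reference, trace_selection, save_every, jitter)
    rng = np.random.default_rng(seed)
    best: FitResult | None = None
    for attempt in range(stage.restarts):
        work = structure.copy()
        if attempt > 0 and len(stage.mobile):
            # jitter each mobile chain independently, as a rigid rotation
            # about its own COM
            for ch in np.unique(work.chain[stage.mobile.indices]):
                idx = stage.mobile.indices[work.chain[stage.mobile.indices] == ch]
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = np.radians(rng.uniform(0.2, 1.0) * stage.jitter_rotation_deg)
                K = np.array([[0, -axis[2], axis[1]],
                              [axis[2], 0, -axis[0]],
                              [-axis[1], axis[0], 0]])
                R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
                com = work.xyz[idx].mean(axis=0)
                shift = rng.uniform(-1, 1, size=3)
                while np.dot(shift, shift) > 1.0:
                    shift = rng.uniform(-1, 1, size=3)
                shift *= stage.jitter_translation
                work.xyz[idx] = (work.xyz[idx] - com) @ R.T + com + shift
        sub_seed = int(rng.integers(2**31 - 1))
        cand = _relax_once(work, stage, restraints, sub_seed, ccc_map,
                           reference, trace_selection, save_every, jitter)
        if best is None or cand.energies[-1]["total"] < best.energies[-1]["total"]:
            best = cand
    return best


def _rigid_predock(structure: Structure, stage: StageSpec, seed: int) -> Structure:
    """Metropolis rigid-body placement of each mobile chain against its maps.

    Chains are treated in order; each is docked as one rigid body against all
    other atoms (clash term) and the stage maps that act on it, and moved to
    the lowest-energy pose found.
    """
    from .docking import mc_dock

    work = structure.copy()
    rng = np.random.default_rng(seed)
    mob = stage.mobile.indices
    for ch in dict.fromkeys(work.chain[mob]):
        idx = mob[work.chain[mob] == ch]
        sel = Selection(work, idx, f"predock {ch}")
        ctx_idx = np.setdiff1d(np.arange(work.n_atoms), idx)
        ctx = Selection(work, ctx_idx, "context") if len(ctx_idx) else None
        maps_for = []
        for entry in stage.active_maps:
            if isinstance(entry, tuple):
                mp, msel = entry
                if np.intersect1d(msel.indices, idx).size:
                    maps_for.append(mp)
            else:
                maps_for.append(entry)
        if not maps_for:
            continue
        w_map = 1.0 if stage.predock_map_energy == "ccc" else 20.0
        res = mc_dock(sel, ctx, maps_for, moveset=stage.predock_moveset,
                      temperature=stage.predock_temperature,
                      n_steps=stage.predock_steps,
                      seed=int(rng.integers(2**31 - 1)), w_map=w_map,
                      map_energy=stage.predock_map_energy)
        hsel = sel.heavy()
        m = hsel.masses
        pivot = (hsel.positions * m[:, None]).sum(axis=0) / m.sum()
        work.xyz[idx] = res.best.apply(work.xyz[idx], pivot)
    return work


def _relax_once(
    structure: Structure,
    stage: StageSpec,
    restraints: RestraintSet,
    seed: int = 0,
    ccc_map: DensityGrid | None = None,
    reference: Structure | None = None,
    trace_selection: Selection | None = None,
    save_every: int = 25,
    jitter: float = 0.0,
) -> FitResult:
    """Single capped quasi-Newton descent (see :func:`relax`)."""
    work = structure.copy()
    mobile_idx = stage.mobile.indices
    rs = restraints
    if stage.positionally_restrained is not None and len(stage.positionally_restrained):
        rs = rs.with_positional(
            Selection(work, stage.positionally_restrained.indices, "tether"),
            stage.k_positional,
        )

    def record(frames, energies, cccs, rmsds, labels, steps, comps, step, xyz=None):
        saved = work.xyz
        if xyz is not None:
            work.xyz = xyz
        frames.append(work.xyz.copy())
        energies.append(dict(comps))
        labels.append(stage.label)
        steps.append(step)
        if ccc_map is not None:
            cccs.append(ccc(work.select_all(), ccc_map))
        if reference is not None and trace_selection is not None:
            ref_sel = Selection(reference, trace_selection.indices, "trace")
            cur_sel = Selection(work, trace_selection.indices, "trace")
            rmsds.append(rmsd(cur_sel.calpha(), ref_sel.calpha()))
        work.xyz = saved

    frames: list[np.ndarray] = []
    energies: list[dict[str, float]] = []
    cccs: list[float] = []
    rmsds: list[float] = []
    labels: list[str] = []
    steps: list[int] = []

    if len(mobile_idx) == 0:
        comps, _ = _total_energy(work.xyz, rs, [])
        record(frames, energies, cccs, rmsds, labels, steps, comps, 0)
        return FitResult(frames, energies, cccs, rmsds, labels, steps, work)

    map_terms = _resolve_map_terms(stage.active_maps, work.mass, mobile_idx)
    rng = np.random.default_rng(seed)
    if jitter > 0:
        work.xyz[mobile_idx] += rng.normal(scale=jitter, size=(len(mobile_idx), 3))

    comps, grad = _total_energy(work.xyz, rs, map_terms)
    record(frames, energies, cccs, rmsds, labels, steps, comps, 0)
    energy = comps["total"]

    # Limited-memory quasi-Newton descent with Armijo backtracking.  The
    # energy mixes very stiff harmonic terms (bonds, k = 200) with very soft
    # ones (the map potential, forces of order 0.1), so plain steepest
    # descent stalls: the stiff modes force a tiny step while the soft
    # collective modes (a rigid slide of a whole component into its density)
    # barely move.  L-BFGS curvature pairs recover those soft modes.  The
    # logged energy is monotone non-increasing by construction; a hard cap
    # bounds the per-step atomic displacement.
    n_mob = len(mobile_idx)
    x = work.xyz[mobile_idx].reshape(-1).copy()
    g_flat = grad[mobile_idx].reshape(-1).copy()
    hist_s: list[np.ndarray] = []
    hist_y: list[np.ndarray] = []
    memory = 12
    recent: list[float] = [energy]
    bad_streak = 0

    def two_loop(g: np.ndarray) -> np.ndarray:
        q = g.copy()
        alphas = []
        for s, y in zip(reversed(hist_s), reversed(hist_y)):
            rho = 1.0 / np.dot(y, s)
            a = rho * np.dot(s, q)
            q -= a * y
            alphas.append((a, rho, s, y))
        if hist_s:
            s, y = hist_s[-1], hist_y[-1]
            q *= np.dot(s, y) / np.dot(y, y)
        for a, rho, s, y in reversed(alphas):
            b = rho * np.dot(y, q)
            q += (a - b) * s
        return q

    for step in range(1, stage.max_steps + 1):
        d = -two_loop(g_flat)
        if np.dot(d, g_flat) >= 0:  # not a descent direction: reset memory
            hist_s.clear()
            hist_y.clear()
            d = -g_flat
        # cap the per-atom displacement of the unit step
        amax = np.linalg.norm(d.reshape(n_mob, 3), axis=1).max()
        scale = 1.0 if amax <= stage.step_cap else stage.step_cap / amax
        accepted = False
        s_len = scale
        slope = np.dot(g_flat, d)
        for _ in range(25):
            x_try = x + s_len * d
            work.xyz[mobile_idx] = x_try.reshape(n_mob, 3)
            t_comps, t_grad = _total_energy(work.xyz, rs, map_terms)
            if not np.isfinite(t_comps["total"]):
                raise RuntimeError(
                    f"stage {stage.label!r}: non-finite energy at step {step}")
            if t_comps["total"] <= energy + 1e-4 * s_len * slope:
                accepted = True
                break
            s_len *= 0.5
        if accepted:
            g_new = t_grad[mobile_idx].reshape(-1)
            s_vec = s_len * d
            y_vec = g_new - g_flat
            if np.dot(s_vec, y_vec) > 1e-10:
                hist_s.append(s_vec)
                hist_y.append(y_vec)
                if len(hist_s) > memory:
                    hist_s.pop(0)
                    hist_y.pop(0)
            x = x_try
            g_flat = g_new
            comps = t_comps
            energy = comps["total"]
            bad_streak = 0
        else:
            work.xyz[mobile_idx] = x.reshape(n_mob, 3)
            hist_s.clear()
            hist_y.clear()
            if abs(slope) * scale < CONVERGENCE_TOL:
                break  # no achievable decrease: already at a minimum
            bad_streak += 1
            if bad_streak >= 10:
                raise RuntimeError(
                    f"stage {stage.label!r}: energy failed to decrease for "
                    f"{bad_streak} consecutive steps"
                )
        if step % save_every == 0:
            record(frames, energies, cccs, rmsds, labels, steps, comps, step)
        recent.append(energy)
        if len(recent) > CONVERGENCE_WINDOW:
            if recent[-CONVERGENCE_WINDOW - 1] - energy < CONVERGENCE_TOL * CONVERGENCE_WINDOW:
                break
            recent.pop(0)
    work.xyz[mobile_idx] = x.reshape(n_mob, 3)

    if steps[-1] != step:
        record(frames, energies, cccs, rmsds, labels, steps, comps, step)
    return FitResult(frames, energies, cccs, rmsds, labels, steps, work)


def run_protocol(
    structure: Structure,
    stages: list[StageSpec],
    restraints: RestraintSet,
    reference: Structure | None = None,
    trace_selection: Selection | None = None,
    ccc_map: DensityGrid | None = None,
    seed: int = 0,
    save_every: int = 25,
) -> FitResult:
    """Run fitting stages in order, each from the previous stage's result.

    The concatenated trajectory keeps stage labels as boundary markers; the
    per-frame CCC is computed against ``ccc_map`` if given, otherwise against
    each stage's own combined active map.  With a ``reference``, a per-frame
    direct Calpha-RMSD trace is recorded over ``trace_selection`` (default:
    all atoms).
    """
    if not stages:
        raise ValueError("protocol needs at least one stage")
    work = structure.copy()
    result: FitResult | None = None
    for st_spec in stages:
        from dataclasses import replace as _replace

        stage = _replace(
            st_spec,
            mobile=Selection(work, st_spec.mobile.indices, st_spec.mobile.label),
            positionally_restrained=(
                None if st_spec.positionally_restrained is None
                else Selection(work, st_spec.positionally_restrained.indices,
                               "restrained")),
        )
        stage_ccc_map = ccc_map
        if stage_ccc_map is None and stage.active_maps:
            sources = [(e[0] if isinstance(e, tuple) else e).source
                       for e in stage.active_maps]
            stage_ccc_map = combine_maps(sources)
        tsel = trace_selection
        if reference is not None and tsel is None:
            tsel = work.select_all()
        try:
            part = relax(work, stage, restraints, seed=seed, ccc_map=stage_ccc_map,
                         reference=reference, trace_selection=tsel, save_every=save_every)
        except RuntimeError as exc:
            raise RuntimeError(f"protocol aborted in stage {stage.label!r}: {exc}") from exc
        work = part.final
        result = part if result is None else result.extend(part)
    return result


def rmsd_trace(result: FitResult, reference: Structure, sel: Selection,
               superpose: bool = False) -> pd.DataFrame:
    """Per-frame Calpha-RMSD of the trajectory against a reference.

    Direct (unsuperposed) by default; the convention is recorded in the
    returned table's ``convention`` attribute and column.
    """
    ca = Selection(result.final, sel.indices, sel.label).calpha()
    ref_pos = reference.xyz[ca.indices]
    rows = []
    conv = "superposed" if superpose else "direct"
    for i, frame in enumerate(result.frames):
        cur = frame[ca.indices]
        rows.append({"frame": i, "step": result.steps[i],
                     "stage": result.stage_labels[i],
                     "rmsd_A": rmsd(cur, ref_pos, superpose=superpose),
                     "convention": conv})
    df = pd.DataFrame(rows)
    df.attrs["convention"] = conv
    return df


def load_protocol(
    path: str | Path,
    structure: Structure,
    maps: dict[str, DensityGrid],
    xi: float = XI_DEFAULT,
) -> list[StageSpec]:
    """Build stages from a YAML protocol config.

    Layout::

        stages:
          - label: fit-A-C
            mobile: [A, C]          # annotation names
            restrained: [B]
            maps:                   # keys into the provided map registry;
              - {map: A, selection: A}   # scoped to a component, or
              - C                        # acting on all mobile atoms
            max_steps: 400
            step_cap: 0.2
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    stages = []
    for s in cfg["stages"]:
        mobile = None
        for name in s["mobile"]:
            part = structure.select(name)
            mobile = part if mobile is None else mobile.union(part)
        restrained = None
        for name in s.get("restrained", []):
            part = structure.select(name)
            restrained = part if restrained is None else restrained.union(part)
        active = []
        for entry in s["maps"]:
            if isinstance(entry, dict):
                mp = build_map_potential(maps[entry["map"]],
                                         xi=float(s.get("xi", xi)))
                active.append((mp, structure.select(entry["selection"])))
            else:
                active.append(build_map_potential(maps[entry],
                                                  xi=float(s.get("xi", xi))))
        stages.append(StageSpec(
            s["label"], mobile, active, restrained,
            int(s.get("max_steps", 500)), float(s.get("step_cap", STEP_CAP_DEFAULT)),
            float(s.get("k_positional", 10.0)),
            int(s.get("restarts", 1)),
        ))
    return stages
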