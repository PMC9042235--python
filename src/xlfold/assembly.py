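"""Stochastic optimization and the staged assembly protocol.

The optimizer works on the everywhere-C¹ weighted restraint score
(:mod:`xlfold.restraints`): cycles of Metropolis Monte-Carlo sampling at a
decreasing temperature (rigid-chain moves plus single-bead jitter — the
coarse-grained stand-in for short high-temperature dynamics) alternate with
gradient minimization (backtracking line search, 100 steps per cycle by
default).  A cycle's minimized model replaces the incumbent only if it scores
no worse, so the cycle-boundary score trace is non-increasing.

The staged protocol mirrors how a hetero-oligomeric complex is assembled
step by step: entities enter one stage at a time (placed at a random pose
outside the current complex), restraints activate automatically once all
their residues are present, and a stage may truncate residues (dropping
every restraint that touches them).  ``build_ensemble`` repeats the full
plan under different seeds and selects the model with the fewest cross-link
violations (ties: lowest total score, then lowest index).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .config import AnnealSchedule, ProtocolDefaults, ScoreWeights
from .core import CaModel, ComplexTopology, contiguous_chain
from .io_formats import InhibitionComplexFixture, load_inhibition_complex
from .restraints import (
    AnchorRestraint,
    CompiledScore,
    ContactRestraint,
    CrosslinkRestraint,
    MembraneSlabRestraint,
    Restraint,
    RigidGroupRestraint,
    StericsRestraint,
    _site_indices,
    count_violations,
    total_score,
)

__all__ = [
    "AnnealResult",
    "AssemblyResult",
    "Stage",
    "StagePlan",
    "StagePlanResult",
    "anneal",
    "build_ensemble",
    "inhibition_complex_plan",
    "minimize",
    "place_zinc",
    "run_stage_plan",
    "select_best",
]


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------


def _frozen_mask(model: CaModel, frozen: frozenset[str]) -> np.ndarray | None:
    if not frozen:
        return None
    mask = np.zeros(len(model.coords), dtype=bool)
    for cid in frozen:
        mask[model.chain_slice(cid)] = True
    return mask


def _minimize_coords(
    cs: CompiledScore,
    X: np.ndarray,
    steps: int,
    gtol: float = 1e-8,
    frozen_mask: np.ndarray | None = None,
    max_displacement: float = 2.0,
) -> np.ndarray:
    """Gradient descent with Armijo backtracking.

    Per-iteration displacement is capped at ``max_displacement`` Å (trust
    region): the line search only evaluates endpoints, so an uncapped step
    can jump a chain straight through another one's excluded-volume wall
    and leave it trapped on the far side; with a capped step the descent
    has to walk around obstacles instead.
    """
    X = X.copy()
    f, g = cs.energy_and_grad(X)
    if not math.isfinite(f):
        raise RuntimeError(f"non-finite score at minimization start: {f}")
    if frozen_mask is not None:
        g[frozen_mask] = 0.0
    ginf = np.abs(g).max(initial=0.0)
    t = 1.0 / max(1.0, ginf)  # first trial step moves at most ~1 Å
    for _ in range(steps):
        gn2 = float((g * g).sum())
        if math.sqrt(gn2) < gtol:
            break
        ginf = np.abs(g).max(initial=0.0)
        t_cap = max_displacement / max(ginf, 1e-12)
        t = min(t, t_cap)
        accepted = False
        for _bt in range(40):
            Xn = X - t * g
            fn = cs.energy(Xn)
            if not math.isfinite(fn):
                raise RuntimeError(
                    f"non-finite score during minimization (step size {t:.3g})"
                )
            if fn <= f - 1e-4 * t * gn2:  # Armijo sufficient decrease
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        X = Xn
        f, g = cs.energy_and_grad(X)
        if frozen_mask is not None:
            g[frozen_mask] = 0.0
        t = min(t * 1.5, 1e3)
    return X


def minimize(
    model: CaModel,
    restraint_set: list[Restraint],
    weights: ScoreWeights | None = None,
    steps: int = 100,
    frozen: frozenset[str] = frozenset(),
) -> CaModel:
    """Gradient descent (backtracking line search) on the weighted score.

    The score is non-increasing step to step; returns after ``steps``
    iterations or earlier on convergence."""
    if not np.isfinite(model.coords).all():
        raise RuntimeError("model has non-finite coordinates")
    cs = CompiledScore(model, restraint_set, weights)
    X = _minimize_coords(cs, model.coords, steps, frozen_mask=_frozen_mask(model, frozen))
    return model.with_coords(X)


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnealResult:
    model: CaModel
    trace: tuple[float, ...]  # post-minimization score at each cycle boundary


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _polish_crosslinks(
    model: CaModel,
    restraint_set: list[Restraint],
    X: np.ndarray,
    frozen: frozenset[str],
    max_iter: int = 100,
) -> np.ndarray:
    """Deterministic final polish: rigid per-chain translations descending the
    (unweighted) positive cross-link energy only.

    At a minimum of the full score, conflicting soft restraints can leave
    cross-links a few hundredths of an Å outside their bound; because model
    selection keys on the cross-link violation *count*, the annealer finishes
    by nudging chains (typically < 0.1 Å) until the cross-link energy can no
    longer be reduced by translation.  Internal chain geometry is untouched.
    """
    xls = [
        r
        for r in restraint_set
        if isinstance(r, CrosslinkRestraint) and r.polarity == "positive"
    ]
    if not xls or len(model.topology.chains) < 2:
        return X
    slices = {
        c.chain_id: model.chain_slice(c.chain_id) for c in model.topology.chains
    }
    chain_of = {}
    for cid, s in slices.items():
        for i in range(s.start, s.stop):
            chain_of[i] = cid
    cand = []
    for r in xls:
        ia = _site_indices(model, r.site_a)
        ib = _site_indices(model, r.site_b)
        cand.append((ia, ib, r.upper_bound))
    mobile = [cid for cid in slices if cid not in frozen]
    if not mobile:
        return X
    X = X.copy()

    def xl_energy_grad(Y):
        e = 0.0
        grad = {cid: np.zeros(3) for cid in mobile}
        for ia, ib, ub in cand:
            bd, best = math.inf, None
            for i in ia:
                for j in ib:
                    if i == j:
                        continue
                    d = float(np.linalg.norm(Y[i] - Y[j]))
                    if d < bd:
                        bd, best = d, (i, j)
            excess = bd - ub
            if excess > 0 and best is not None:
                e += excess * excess
                i, j = best
                u = (Y[i] - Y[j]) / max(bd, 1e-12)
                if chain_of[i] in grad:
                    grad[chain_of[i]] += 2.0 * excess * u
                if chain_of[j] in grad:
                    grad[chain_of[j]] -= 2.0 * excess * u
        return e, grad

    f, grad = xl_energy_grad(X)
    t = 0.5
    for _ in range(max_iter):
        if f == 0.0:
            break
        gn2 = sum(float((g * g).sum()) for g in grad.values())
        if gn2 < 1e-20:
            break
        accepted = False
        for _bt in range(30):
            Xn = X.copy()
            for cid in mobile:
                Xn[slices[cid]] -= t * grad[cid]
            fn, gradn = xl_energy_grad(Xn)
            if fn <= f - 1e-4 * t * gn2:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        X, f, grad = Xn, fn, gradn
        t = min(t * 1.5, 10.0)
    return X


def anneal(
    model: CaModel,
    restraint_set: list[Restraint],
    weights: ScoreWeights | None = None,
    schedule: AnnealSchedule | None = None,
    seed: int | None = None,
    frozen: frozenset[str] = frozenset(),
) -> AnnealResult:
    """Metropolis Monte-Carlo at each ladder temperature followed by
    minimization; deterministic given the seed (default: the schedule's)."""
    schedule = schedule if schedule is not None else AnnealSchedule()
    rng = np.random.default_rng(seed if seed is not None else schedule.seed)
    cs = CompiledScore(model, restraint_set, weights)
    fmask = _frozen_mask(model, frozen)

    mobile_chains = [c.chain_id for c in model.topology.chains if c.chain_id not in frozen]
    mobile_slices = {cid: model.chain_slice(cid) for cid in mobile_chains}
    mobile_beads = np.concatenate(
        [np.arange(s.start, s.stop) for s in mobile_slices.values()]
    ) if mobile_chains else np.zeros(0, dtype=int)

    X = model.coords.copy()
    if schedule.minimize_steps > 0:
        X = _minimize_coords(cs, X, schedule.minimize_steps, frozen_mask=fmask)
    f = cs.energy(X)
    trace = [f]

    for T in schedule.temperatures:
        Xc = X.copy()
        fc = f
        for _ in range(schedule.steps_per_cycle):
            if len(mobile_beads) == 0:
                break
            if rng.random() < 0.7 and mobile_chains:
                cid = mobile_chains[int(rng.integers(len(mobile_chains)))]
                s = mobile_slices[cid]
                saved = Xc[s].copy()
                t = rng.uniform(-schedule.translation_A, schedule.translation_A, 3)
                axis = rng.normal(size=3)
                angle = rng.uniform(-schedule.rotation_rad, schedule.rotation_rad)
                R = _rotation_matrix(axis, angle)
                cen = Xc[s].mean(axis=0)
                Xc[s] = (Xc[s] - cen) @ R.T + cen + t
                fn = cs.energy(Xc)
                if fn <= fc or rng.random() < math.exp(-(fn - fc) / T):
                    fc = fn
                else:
                    Xc[s] = saved
            else:
                b = int(mobile_beads[int(rng.integers(len(mobile_beads)))])
                saved_bead = Xc[b].copy()
                Xc[b] = Xc[b] + rng.normal(0.0, schedule.jitter_A, 3)
                fn = cs.energy(Xc)
                if fn <= fc or rng.random() < math.exp(-(fn - fc) / T):
                    fc = fn
                else:
                    Xc[b] = saved_bead
        if schedule.minimize_steps > 0:
            Xc = _minimize_coords(cs, Xc, schedule.minimize_steps, frozen_mask=fmask)
            fc = cs.energy(Xc)
        # elitism: a cycle only replaces the incumbent if it is no worse
        if fc <= f:
            X, f = Xc, fc
        trace.append(f)
    if schedule.steps_per_cycle > 0 or schedule.minimize_steps > 0:
        X = _polish_crosslinks(model, restraint_set, X, frozen)
    return AnnealResult(model=model.with_coords(X), trace=tuple(trace))


# ---------------------------------------------------------------------------
# staged assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stage:
    """One assembly stage: chains entering, residues truncated, chains held
    fixed, and (optionally) restraints that must be active at this stage."""

    name: str
    add_chains: tuple[str, ...] = ()
    drop_residues: tuple[tuple[str, tuple[int, ...]], ...] = ()
    freeze_chains: frozenset[str] = frozenset()
    extra_restraints: tuple[Restraint, ...] = ()
    # when False, added chains keep their provided coordinates instead of
    # being re-placed outside the current complex (a single-stage plan is
    # then exactly "anneal the provided configuration")
    place_added: bool = True


@dataclass(frozen=True)
class StagePlan:
    """Ordered stages over a full topology; every chain enters exactly once
    and the final stage leaves the target topology in place."""

    topology: ComplexTopology
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        added: list[str] = []
        for st in self.stages:
            for cid in st.add_chains:
                self.topology.chain(cid)  # KeyError if unknown
                if cid in added:
                    raise ValueError(f"chain {cid!r} added twice (stage {st.name!r})")
                added.append(cid)
        missing = set(self.topology.chain_ids) - set(added)
        if missing:
            raise ValueError(f"chains never added by any stage: {sorted(missing)}")

    @classmethod
    def single_stage(cls, topology: ComplexTopology, name: str = "all") -> "StagePlan":
        return cls(
            topology=topology,
            stages=(
                Stage(name=name, add_chains=topology.chain_ids, place_added=False),
            ),
        )


@dataclass(frozen=True)
class StagePlanResult:
    model: CaModel
    snapshots: tuple[tuple[str, CaModel], ...]
    log: tuple[str, ...]


def _restraint_restricted(r: Restraint, present: dict[str, set[int]]):
    """Restraint restricted to the present residues, or None if inactive."""
    if isinstance(r, (CrosslinkRestraint, ContactRestraint)):
        return r  # presence decided by the caller via copy resolution
    if isinstance(r, RigidGroupRestraint):
        if r.chain_id not in present:
            return None
        keep = [i for i, res in enumerate(r.residues) if res in present[r.chain_id]]
        if len(keep) < 3:
            return None
        if len(keep) == len(r.residues):
            return r
        return RigidGroupRestraint(
            chain_id=r.chain_id,
            residues=tuple(r.residues[i] for i in keep),
            reference=r.reference[keep],
            k=r.k,
        )
    if isinstance(r, AnchorRestraint):
        keep = [
            i
            for i, s in enumerate(r.sites)
            if s[0] in present and s[1] in present[s[0]]
        ]
        if not keep:
            return None
        if len(keep) == len(r.sites):
            return r
        return AnchorRestraint(
            sites=tuple(r.sites[i] for i in keep),
            reference=r.reference[keep],
            k=r.k,
        )
    if isinstance(r, MembraneSlabRestraint):
        keep = tuple(
            s for s in r.sites if s[0] in present and s[1] in present[s[0]]
        )
        if not keep:
            return None
        return MembraneSlabRestraint(sites=keep, half_width=r.half_width)
    return r  # sterics: always active


def _pair_restraint_active(
    r: CrosslinkRestraint | ContactRestraint,
    topology: ComplexTopology,
    present: dict[str, set[int]],
) -> bool:
    for label, resnum in (r.site_a, r.site_b):
        try:
            copies = topology.copies(label)
        except KeyError:
            return False
        if not any(c in present and resnum in present[c] for c in copies):
            return False
    return True


def _active_restraints(
    restraint_set: list[Restraint],
    topology: ComplexTopology,
    present: dict[str, set[int]],
) -> list[Restraint]:
    active: list[Restraint] = []
    for r in restraint_set:
        if isinstance(r, (CrosslinkRestraint, ContactRestraint)):
            if _pair_restraint_active(r, topology, present):
                active.append(r)
            continue
        restricted = _restraint_restricted(r, present)
        if restricted is not None:
            active.append(restricted)
    return active


def run_stage_plan(
    plan: StagePlan,
    chain_coords: dict[str, np.ndarray],
    restraint_set: list[Restraint],
    schedule: AnnealSchedule | None = None,
    weights: ScoreWeights | None = None,
    seed: int | None = None,
) -> StagePlanResult:
    """Execute the staged protocol.

    ``chain_coords`` supplies the internal (monomer/domain) geometry of every
    chain in plan-topology residue order; a newly added chain is placed at a
    seeded random orientation 10 Å outside the bounding sphere of the current
    complex, then the complex is annealed under the restraints whose residues
    are all present.
    """
    schedule = schedule if schedule is not None else AnnealSchedule()
    rng = np.random.default_rng(seed if seed is not None else schedule.seed)

    present: dict[str, set[int]] = {}
    placed: dict[str, np.ndarray] = {}
    snapshots: list[tuple[str, CaModel]] = []
    log: list[str] = []

    for st in plan.stages:
        for cid in st.add_chains:
            spec = plan.topology.chain(cid)
            xyz = np.asarray(chain_coords[cid], float)
            if xyz.shape != (spec.n_residues, 3):
                raise ValueError(
                    f"stage {st.name!r}: coords for chain {cid!r} have shape "
                    f"{xyz.shape}, expected ({spec.n_residues}, 3)"
                )
            if st.place_added:
                xyz = xyz - xyz.mean(axis=0)
            if st.place_added and placed:
                all_xyz = np.vstack(list(placed.values()))
                center = all_xyz.mean(axis=0)
                r_cur = float(np.linalg.norm(all_xyz - center, axis=1).max())
                r_new = float(np.linalg.norm(xyz, axis=1).max())
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                axis = rng.normal(size=3)
                angle = rng.uniform(0.0, 2.0 * math.pi)
                xyz = xyz @ _rotation_matrix(axis, angle).T
                xyz = xyz + center + direction * (r_cur + r_new + 10.0)
            placed[cid] = xyz
            present[cid] = set(spec.residue_numbers)
            log.append(f"{st.name}: added chain {cid} ({spec.n_residues} residues)")
        for cid, residues in st.drop_residues:
            if cid not in present:
                raise ValueError(
                    f"stage {st.name!r}: cannot truncate absent chain {cid!r}"
                )
            spec = plan.topology.chain(cid)
            old_order = [r for r in spec.residue_numbers if r in present[cid]]
            keep_idx = [i for i, r in enumerate(old_order) if r not in residues]
            placed[cid] = placed[cid][keep_idx]
            present[cid] -= set(residues)
            if not present[cid]:
                del present[cid], placed[cid]
            log.append(f"{st.name}: truncated {len(residues)} residues of chain {cid}")

        sub_topology = plan.topology.subset(
            {cid: frozenset(resset) for cid, resset in present.items()}
        )
        coords = np.vstack([placed[c.chain_id] for c in sub_topology.chains])
        model = CaModel(sub_topology, coords)

        for r in st.extra_restraints:
            if isinstance(r, (CrosslinkRestraint, ContactRestraint)):
                if not _pair_restraint_active(r, sub_topology, present):
                    raise ValueError(
                        f"stage {st.name!r}: restraint {r} references an entity "
                        "not yet present"
                    )
        active = _active_restraints(
            list(restraint_set) + list(st.extra_restraints), sub_topology, present
        )
        log.append(f"{st.name}: {len(active)} active restraints")
        result = anneal(
            model,
            active,
            weights=weights,
            schedule=schedule,
            seed=int(rng.integers(2**31)),
            frozen=st.freeze_chains,
        )
        for c in sub_topology.chains:
            placed[c.chain_id] = result.model.chain_coords(c.chain_id).copy()
        snapshots.append((st.name, result.model))
        log.append(f"{st.name}: final score {result.trace[-1]:.4f}")

    return StagePlanResult(
        model=snapshots[-1][1], snapshots=tuple(snapshots), log=tuple(log)
    )


# ---------------------------------------------------------------------------
# ensemble generation and selection
# ---------------------------------------------------------------------------


def select_best(
    violation_counts: list[dict[str, int]], scores: list[float]
) -> int:
    """Index of the model with the fewest cross-link violations; ties broken
    by lowest total score, then lowest index."""
    order = sorted(
        range(len(scores)),
        key=lambda i: (violation_counts[i]["crosslink"], scores[i], i),
    )
    return order[0]


@dataclass(frozen=True)
class AssemblyResult:
    models: tuple[CaModel, ...]
    violation_counts: tuple[dict, ...]
    scores: tuple[float, ...]
    selected_index: int
    seeds: tuple[int, ...]
    config: dict

    @property
    def selected_model(self) -> CaModel:
        return self.models[self.selected_index]

    def to_json(self) -> str:
        payload = {
            "selected_index": self.selected_index,
            "seeds": list(self.seeds),
            "config": self.config,
            "models": [
                {
                    "score": self.scores[i],
                    "violations": self.violation_counts[i],
                    "chains": {
                        c.chain_id: m.chain_coords(c.chain_id).tolist()
                        for c in m.topology.chains
                    },
                }
                for i, m in enumerate(self.models)
            ],
        }
        return json.dumps(payload, sort_keys=True)


def build_ensemble(
    plan: StagePlan,
    chain_coords: dict[str, np.ndarray],
    restraint_set: list[Restraint],
    schedule: AnnealSchedule | None = None,
    weights: ScoreWeights | None = None,
    n_models: int = 8,
    base_seed: int = 0,
) -> AssemblyResult:
    """Run the stage plan ``n_models`` times (seeds ``base_seed + i``) and
    select the model with the fewest cross-link violations."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    schedule = schedule if schedule is not None else AnnealSchedule()
    weights = weights if weights is not None else ScoreWeights()
    models = []
    counts = []
    scores = []
    seeds = []
    for i in range(n_models):
        seed = base_seed + i
        seeds.append(seed)
        result = run_stage_plan(
            plan, chain_coords, restraint_set, schedule=schedule,
            weights=weights, seed=seed,
        )
        final = result.model
        present = {
            c.chain_id: set(c.residue_numbers) for c in final.topology.chains
        }
        active = _active_restraints(restraint_set, final.topology, present)
        models.append(final)
        counts.append(count_violations(final, active))
        scores.append(total_score(final, active, weights).total)
    selected = select_best(counts, scores)
    config = {
        "weights": asdict(weights),
        "schedule": asdict(schedule),
        "n_models": n_models,
        "base_seed": base_seed,
    }
    return AssemblyResult(
        models=tuple(models),
        violation_counts=tuple(counts),
        scores=tuple(scores),
        selected_index=selected,
        seeds=tuple(seeds),
        config=config,
    )


# ---------------------------------------------------------------------------
# zinc placement
# ---------------------------------------------------------------------------


def place_zinc(
    model: CaModel,
    chain_group: str = "FB",
    ligand_residues: tuple[int, ...] | None = None,
    min_clearance: float = 2.0,
) -> CaModel:
    """Place one Zn²⁺ pseudo-atom per protease subunit at the centroid of
    its three active-site ligand Cα positions (defaults D137/H43/H47).

    Warns if a zinc lands within ``min_clearance`` Å of any bead."""
    if ligand_residues is None:
        ligand_residues = ProtocolDefaults().zinc_ligand_residues
    sites = []
    for cid in model.topology.copies(chain_group):
        try:
            idx = [model.index(cid, r) for r in ligand_residues]
        except KeyError as err:
            raise ValueError(f"chain {cid}: missing zinc ligand residue ({err})")
        sites.append(model.coords[idx].mean(axis=0))
    zinc = np.asarray(sites)
    dmin = np.linalg.norm(
        model.coords[None, :, :] - zinc[:, None, :], axis=2
    ).min()
    if dmin < min_clearance:
        warnings.warn(
            f"zinc site within {dmin:.2f} Å of a Cα bead (< {min_clearance} Å)",
            stacklevel=2,
        )
    return model.with_zinc(zinc)


# ---------------------------------------------------------------------------
# the built-in staged protocol
# ---------------------------------------------------------------------------


def inhibition_complex_plan(
    fixture: InhibitionComplexFixture | None = None,
) -> StagePlan:
    """Seven-stage plan for the inhibition complex: protease monomer →
    dimer → tetramer → substrate added full length (1–114) → proregion
    (residues 1–37) truncated → inhibitor BofA added → SpoIVFA added."""
    fixture = fixture if fixture is not None else load_inhibition_complex()
    pro_lo, pro_hi = ProtocolDefaults().proregion_residues
    chains = []
    substrate_id = None
    for c in fixture.topology.chains:
        if c.group == "sigK":
            substrate_id = c.chain_id
            chains.append(
                contiguous_chain(c.chain_id, pro_lo, int(c.residue_numbers[-1]),
                                 copy_group=c.copy_group)
            )
        else:
            chains.append(c)
    if substrate_id is None:
        raise ValueError("fixture lacks a substrate (sigK) chain")
    topology = ComplexTopology(tuple(chains))
    copies = topology.copies("FB")
    bofa = topology.copies("BofA")[0]
    fa = topology.copies("FA")[0]
    stages = (
        Stage(name="protease-monomer", add_chains=(copies[0],)),
        Stage(name="protease-dimer", add_chains=(copies[1],)),
        Stage(name="protease-tetramer", add_chains=tuple(copies[2:])),
        Stage(name="add-substrate", add_chains=(substrate_id,)),
        Stage(
            name="truncate-proregion",
            drop_residues=((substrate_id, tuple(range(pro_lo, pro_hi + 1))),),
        ),
        Stage(name="add-bofa", add_chains=(bofa,)),
        Stage(name="add-spoivfa", add_chains=(fa,)),
    )
    return StagePlan(topology=topology, stages=stages)
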