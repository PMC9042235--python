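"""Structure-recovery benchmark: the full pipeline on synthetic data.

``recovery_trial`` runs the complete protocol on a planted-truth benchmark:

1. generate the reference complex, simulate cross-links and a noisy contact
   map, curate the map by probability, scramble the starting pose;
2. round 1 — build an ensemble under cross-links + curated contacts +
   per-chain rigidity + sterics;
3. consensus exclusion — a contact whose restraint score exceeds the severe-
   violation cutoff (10 score-units) in the majority of round-1 models is
   unsatisfiable under the rest of the data and is excluded (the automated
   counterpart of manually editing out predicted contacts incompatible with
   the cross-linking data);
4. rebuild the ensemble under the cleaned restraints, repeating the
   exclusion pass until the excluded set stops growing (at most three
   ensembles), and select the model with the fewest cross-link violations.

False-positive contacts are upper bounds no pose can satisfy; their quadratic
penalties otherwise flatten the score landscape enough that alternative
docking poses tie with the native one.  The consensus pass removes exactly
those terms without knowing the truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import AssemblyResult, Stage, StagePlan, build_ensemble
from .config import AnnealSchedule, CurationParams, ScoreWeights
from .core import CaModel, superposed_rmsd
from .io_formats import RestraintTable
from .msa_tools import ContactMap, curate_contacts
from .restraints import (
    ContactRestraint,
    Restraint,
    RigidGroupRestraint,
    StericsRestraint,
    ambiguous_min_distance,
    class_weight,
    distance_energy,
    from_table,
)
from .synthetic_data import SynthSpec, make_reference_complex, scramble, \
    simulate_contact_map, simulate_crosslinks


def consensus_exclusions(
    cm: ContactMap,
    models: list[CaModel],
    p_thresh: float | None = None,
    violation_thresh: float | None = None,
    upper_bound: float | None = None,
    min_fraction: float = 0.5,
    weights: ScoreWeights | None = None,
) -> set[tuple[int, int]]:
    """Contact positions severely violated in at least ``min_fraction`` of
    the models (candidates for exclusion as unsatisfiable)."""
    params = CurationParams()
    p_thresh = params.probability_threshold if p_thresh is None else p_thresh
    violation_thresh = (
        params.violation_threshold if violation_thresh is None else violation_thresh
    )
    upper_bound = params.contact_upper_bound_A if upper_bound is None else upper_bound
    weights = weights if weights is not None else ScoreWeights()
    if cm.scope[0] != "inter":
        raise ValueError("consensus exclusion expects an inter-protein map")
    label_a, label_b = cm.scope[1], cm.scope[2]
    kind = "inter"
    w = class_weight(f"contact_{kind}", weights)
    out: set[tuple[int, int]] = set()
    for rec in cm.df.itertuples(index=False):
        if not rec.probability > p_thresh:
            continue
        r = ContactRestraint(
            site_a=(label_a, int(rec.i)),
            site_b=(label_b, int(rec.j)),
            upper_bound=upper_bound,
            probability=max(float(rec.probability), 1e-9),
            kind=kind,
        )
        severe = sum(
            1
            for m in models
            if w * distance_energy(ambiguous_min_distance(m, r), upper_bound)
            > violation_thresh
        )
        if severe >= min_fraction * len(models):
            out.add((int(rec.i), int(rec.j)))
    return out


@dataclass(frozen=True)
class RecoveryOutcome:
    result: AssemblyResult
    reference: CaModel
    rmsd_to_reference: float
    crosslink_violations: int
    excluded_contacts: tuple[tuple[int, int], ...]


def _structural_restraints(start: CaModel) -> list[Restraint]:
    rset: list[Restraint] = [
        RigidGroupRestraint(
            chain_id=c.chain_id,
            residues=c.residue_numbers,
            reference=start.chain_coords(c.chain_id),
        )
        for c in start.topology.chains
    ]
    rset.append(StericsRestraint())
    return rset


def recovery_trial(
    base_seed: int = 0,
    scramble_seed: int = 0,
    spec: SynthSpec | None = None,
    n_models: int = 8,
    schedule: AnnealSchedule | None = None,
    scramble_magnitude: float = 30.0,
    quick: bool = False,
) -> RecoveryOutcome:
    """Run the full two-round recovery pipeline on the standard benchmark.

    ``quick`` shrinks the annealing schedule (for smoke/determinism tests);
    the default runs the protocol schedule.
    """
    spec = spec if spec is not None else SynthSpec()
    if schedule is None:
        schedule = (
            AnnealSchedule(cycles=1, steps_per_cycle=20, temperatures=(2.0,),
                           minimize_steps=20)
            if quick
            else AnnealSchedule()
        )
    reference = make_reference_complex(spec)
    xl_table, _truth = simulate_crosslinks(reference, spec.crosslinks, seed=1)
    cm = simulate_contact_map(
        reference, spec.contacts, scope=("inter", "A", "B"), seed=2
    )
    start = scramble(reference, seed=scramble_seed, magnitude=scramble_magnitude)
    plan = StagePlan(
        topology=start.topology,
        stages=(Stage(name="dock", add_chains=start.topology.chain_ids),),
    )
    chain_coords = {
        c.chain_id: start.chain_coords(c.chain_id) for c in start.topology.chains
    }

    def ensemble(contact_table: RestraintTable, seed_offset: int) -> AssemblyResult:
        rset = list(from_table(xl_table)) + list(from_table(contact_table))
        rset += _structural_restraints(start)
        return build_ensemble(
            plan, chain_coords, rset, schedule=schedule,
            n_models=n_models, base_seed=base_seed + seed_offset,
        )

    excluded: set[tuple[int, int]] = set()
    result = ensemble(curate_contacts(cm), 0)
    for round_index in range(1, 3):
        grown = excluded | consensus_exclusions(cm, list(result.models))
        if grown == excluded:
            break  # restraint set is self-consistent
        excluded = grown
        result = ensemble(
            curate_contacts(cm, exclude=excluded), round_index * 7919
        )
    selected = result.selected_model
    return RecoveryOutcome(
        result=result,
        reference=reference,
        rmsd_to_reference=superposed_rmsd(reference.coords, selected.coords),
        crosslink_violations=result.violation_counts[result.selected_index][
            "crosslink"
        ],
        excluded_contacts=tuple(sorted(excluded)),
    )
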