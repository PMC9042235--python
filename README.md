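# xlfold

Cross-link- and contact-restrained coarse-grained assembly of membrane
protein complexes.

## The problem

Integral-membrane complexes that resist crystallography and cryo-EM can
still be modeled from sparse distance information: engineered Cys–Cys
disulfide cross-links (each a Cα–Cα upper bound between two residues, with
failed pairs as negative evidence) and residue–residue contacts predicted
from co-evolutionary couplings in paired alignments.  `xlfold` turns both
kinds of data into ambiguous distance restraints on a one-bead-per-residue
Cα model and assembles hetero-oligomeric complexes by staged simulated
annealing.  The built-in study system is the *Bacillus subtilis* sporulation
inhibition complex: the intramembrane protease SpoIVFB (a tetramer), its
inhibitors BofA and SpoIVFA, and its substrate Pro-σK.

The weighted score over a model **x** is

    E(x) = 25 · Σ_xl  max(0, d_min(x) − b)²
         + 0.25 · Σ_inter  max(0, d_min(x) − b)²
         + 0.1 · Σ_intra  max(0, d_min(x) − b)²
         + structural terms (rigid groups, 0.1 Å⁻² Cα anchors,
           membrane slab, sterics)

where `d_min` is the minimum Cα–Cα distance over all copy pairs of the two
restrained sites — contact predictions and cross-links cannot distinguish
chemically equivalent subunits of an oligomer, so restraints to a tetramer
are satisfied by the closest copy.  Ensembles of eight independently
assembled models are generated and the model with the fewest cross-link
violations is selected.

Companion modules prepare predictor-ready hybrid MSAs (two proteomes paired
by organism, 20-glycine linker, linker predictions masked), curate contact
maps (probability strictly > 0.15; severe violators > 10 score-units on a
model excluded), call alignment conservation (modal residue in ≥ 70% of
sequences), quantify immunoblot band intensities, and generate synthetic
benchmarks with planted truth.

## Worked example

Recover a synthetic two-chain helix bundle (~100 residues) from a 30 Å
scramble using 12 simulated cross-links and a noisy contact map (80% of true
contacts observed, 5% false positives):

```python
import xlfold as xf
from xlfold.benchmark import recovery_trial

out = recovery_trial(base_seed=0, scramble_seed=0)
print(f"cross-link violations: {out.crosslink_violations}")
print(f"Cα RMSD to reference:  {out.rmsd_to_reference:.2f} Å")
print(f"contacts excluded by consensus: {len(out.excluded_contacts)}")
```

prints

```
cross-link violations: 0
Cα RMSD to reference:  2.23 Å
contacts excluded by consensus: 3
```

The selected model satisfies all twelve planted cross-links and superimposes
on the hidden reference within 2.3 Å — the pose is pinned by the restraint
network alone.  Three predicted contacts were excluded automatically because
no model arrangement could satisfy them (the consensus analog of manually
editing out predictions incompatible with cross-linking data); all three
were planted false positives.

The staged protocol for the inhibition complex itself:

```python
fx = xf.load_inhibition_complex()          # topology + 8 positive, 3 negative pairs
plan = xf.inhibition_complex_plan(fx)      # monomer -> ... -> +BofA -> +SpoIVFA
print([s.name for s in plan.stages])
```

```
['protease-monomer', 'protease-dimer', 'protease-tetramer', 'add-substrate',
 'truncate-proregion', 'add-bofa', 'add-spoivfa']
```

A command-line interface mirrors the library: `xlfold config`, `xlfold
simulate`, `xlfold conserve`, `xlfold pair-msa`, `xlfold curate`, `xlfold
assemble`, `xlfold quantify`.

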