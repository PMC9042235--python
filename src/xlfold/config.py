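"""Protocol defaults for the assembly pipeline.

Every numeric constant of the modeling protocol lives here so that a single
config dump (`default_config` / `dump_default_config`) exposes all tunables:
scoring weights, the annealing schedule, contact-curation thresholds, and the
geometric conventions of the coarse-grained Cα representation.

Units: distances in Å, energies in dimensionless score-units (the relative
weighting between restraint classes is what matters, not the absolute scale),
temperatures in score-units of kT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass(frozen=True)
class ScoreWeights:
    """Relative weights of the scoring terms.

    The three restraint-class weights (cross-links 25, inter-protein contacts
    0.25, intra-protein contacts 0.1) encode the trust hierarchy of the
    protocol: experimental cross-links dominate, co-evolution-derived contacts
    guide, intra-chain contacts fine-tune.  The remaining weights belong to
    the structural-integrity terms of this implementation.
    """

    crosslink: float = 25.0
    contact_inter: float = 0.25
    contact_intra: float = 0.1
    rigid: float = 1.0
    anchor: float = 1.0
    slab: float = 1.0
    sterics: float = 1.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"score weight {name!r} must be >= 0, got {value}")


@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing schedule: cycles of Metropolis Monte-Carlo sampling
    at a (non-increasing) temperature followed by gradient minimization.

    ``minimize_steps`` defaults to the protocol's 100 minimization steps per
    cycle.  Move sizes are the per-proposal scales for rigid-chain translation
    (Å), rigid-chain rotation (rad) and single-bead jitter (Å).
    """

    cycles: int = 5
    steps_per_cycle: int = 500
    temperatures: tuple[float, ...] = (5.0, 3.0, 2.0, 1.0, 0.5)
    translation_A: float = 2.0
    rotation_rad: float = 0.3
    jitter_A: float = 0.5
    minimize_steps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("schedule needs at least one cycle")
        if len(self.temperatures) != self.cycles:
            raise ValueError("temperature ladder length must equal cycles")
        temps = self.temperatures
        if any(t <= 0 for t in temps):
            raise ValueError("temperatures must be positive")
        if any(b > a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperature ladder must be non-increasing")
        if self.steps_per_cycle < 0 or self.minimize_steps < 0:
            raise ValueError("step counts must be >= 0")


@dataclass(frozen=True)
class CurationParams:
    """Contact-map curation thresholds.

    A predicted contact is retained only if its probability is *strictly*
    greater than ``probability_threshold``; when a model is available, a
    contact whose weighted restraint score on that model exceeds
    ``violation_threshold`` (score-units) is discarded as a severe violation.
    """

    probability_threshold: float = 0.15
    violation_threshold: float = 10.0
    contact_upper_bound_A: float = 10.0


@dataclass(frozen=True)
class ProtocolDefaults:
    """The full default parameter set of the pipeline."""

    weights: ScoreWeights = field(default_factory=ScoreWeights)
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    curation: CurationParams = field(default_factory=CurationParams)
    # harmonic positional restraint on every Cα, score-units per Å²
    anchor_force_constant: float = 0.1
    # Cα–Cα upper bound for disulfide-competent engineered Cys pairs
    crosslink_upper_bound_A: float = 12.0
    ensemble_size: int = 8
    # models are ranked by (cross-link violations, total score, index)
    selection_keys: tuple[str, ...] = ("crosslink_violations", "total_score", "index")
    # glycines inserted between the two proteins of a hybrid MSA
    linker_glycines: int = 20
    conservation_threshold: float = 0.70
    membrane_half_width_A: float = 15.0
    steric_min_distance_A: float = 4.0
    virtual_bond_A: float = 3.8
    # active-site zinc ligands per protease subunit (D137, H43, H47)
    zinc_ligand_residues: tuple[int, ...] = (137, 43, 47)
    # substrate proregion removed before inhibitor docking (inclusive range)
    proregion_residues: tuple[int, int] = (1, 37)


def default_config() -> dict:
    """Return the full default configuration as a plain nested dict."""
    return asdict(ProtocolDefaults())


def dump_default_config() -> str:
    """YAML dump of the default configuration (the observable protocol)."""
    return yaml.safe_dump(default_config(), sort_keys=False)
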