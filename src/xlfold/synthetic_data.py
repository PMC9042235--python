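"""Synthetic benchmark generators.

Every stage of the pipeline can be exercised without downloads: this module
builds reference complexes with the geometric structure the analysis assumes
(multi-chain α-helical bundles with membrane-embedded segments), then derives
observations from them — cross-link tables with controllable false-positive
counts, contact maps with tunable true-/false-positive rates, and alignments
with per-column conservation targets — so that generator/consumer round trips
(planted truth in, called truth out) are testable end to end.

Geometry: ideal α-helix Cα traces (rise 1.5 Å per residue, 100° twist,
2.3 Å radius, consecutive Cα ≈ 3.8 Å) with helix axes along z (the membrane
normal), packed on a clash-free grid; helices of one chain are joined by
short connector beads placed with exact 3.8 Å virtual bonds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import CaModel, ChainSpec, ComplexTopology
from .io_formats import RESTRAINT_COLUMNS, RestraintTable
from .msa_tools import Alignment, AlignmentRow, ContactMap

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrosslinkSpec:
    n_true_positive: int = 12
    n_true_negative: int = 3
    n_false_positive: int = 0
    bound_A: float = 12.0
    negative_margin_A: float = 5.0  # negatives/false positives come from d > bound + margin

    def __post_init__(self) -> None:
        if min(self.n_true_positive, self.n_true_negative, self.n_false_positive) < 0:
            raise ValueError("cross-link counts must be >= 0")


@dataclass(frozen=True)
class ContactSpec:
    cutoff_A: float = 10.0
    tp_rate: float = 0.8
    fp_rate: float = 0.05
    # probability distributions: overlapping but separable around the 0.15
    # curation threshold
    true_beta: tuple[float, float] = (5.0, 2.0)
    true_support: tuple[float, float] = (0.15, 1.0)
    false_beta: tuple[float, float] = (2.0, 5.0)
    false_support: tuple[float, float] = (0.0, 0.3)
    min_sequence_separation: int = 5  # for intra maps

    def __post_init__(self) -> None:
        if not (0 <= self.tp_rate <= 1 and 0 <= self.fp_rate <= 1):
            raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class MsaSpec:
    n_rows: int = 20
    conservation_targets: tuple[float, ...] = (0.5, 0.69, 0.70, 0.71, 1.0)

    def __post_init__(self) -> None:
        if self.n_rows < 2:
            raise ValueError("need at least 2 rows")
        for t in self.conservation_targets:
            if not (1.0 / self.n_rows) <= t <= 1.0:
                raise ValueError(
                    f"conservation target {t} outside [1/n_rows, 1]"
                )


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    n_chains: int = 2
    helices_per_chain: int = 3
    helix_length: int = 14
    membrane_half_width_A: float = 15.0
    crosslinks: CrosslinkSpec = field(default_factory=CrosslinkSpec)
    contacts: ContactSpec = field(default_factory=ContactSpec)
    msa: MsaSpec = field(default_factory=MsaSpec)

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.helices_per_chain < 1 or self.helix_length < 4:
            raise ValueError("invalid complex dimensions")


# ---------------------------------------------------------------------------
# reference geometry
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = math.radians(100.0)
HELIX_RADIUS = 2.3  # Å
BOND = 3.8  # Å, consecutive-Cα virtual bond
HELIX_SPACING = 10.2  # Å between adjacent helix axes
CHAIN_SPACING = 10.3  # Å between chain rows


def ideal_helix(n: int, up: bool = True, phase: float = 0.0) -> np.ndarray:
    """Cα trace of an ideal α-helix along z, centered at the origin."""
    t = np.arange(n)
    theta = phase + HELIX_TWIST * t
    x = HELIX_RADIUS * np.cos(theta)
    y = HELIX_RADIUS * np.sin(theta)
    z = HELIX_RISE * (t - (n - 1) / 2.0)
    coords = np.column_stack([x, y, z])
    if not up:
        # proper rotation (pi about x): keeps the right-handed helix sense
        coords = coords * np.array([1.0, -1.0, -1.0])
    return coords


def _connector_beads(E: np.ndarray, S: np.ndarray, bulge: np.ndarray) -> np.ndarray:
    """Beads joining E to S with exact 3.8 Å steps along a circular arc
    bulging toward ``bulge`` (equal chords spread the bend evenly, keeping
    1-3 distances well above excluded volume).  Intermediate beads only."""
    from scipy.optimize import brentq

    L = float(np.linalg.norm(S - E))
    if L < 1e-9:
        raise ValueError("connector endpoints coincide")
    n = max(1, math.ceil(L / BOND - 1e-9))
    if abs(n * BOND - L) < 1e-9:  # straight line fits exactly
        return np.asarray([E + (S - E) * k / n for k in range(1, n)])
    if n == 1:
        n = 2
    u = (S - E) / L
    w = bulge - np.dot(bulge, u) * u
    wn = np.linalg.norm(w)
    if wn < 1e-9:  # bulge parallel to the gap: pick any perpendicular
        w = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(w) < 1e-9:
            w = np.cross(u, [0.0, 1.0, 0.0])
        wn = np.linalg.norm(w)
    w = w / wn

    def turn_mismatch(R: float) -> float:
        return n * math.asin(BOND / (2 * R)) - math.asin(L / (2 * R))

    r_lo = max(BOND, L) / 2 * (1 + 1e-12)
    if turn_mismatch(r_lo) >= 0:
        raise ValueError(
            f"connector gap {L:.2f} Å needs more than a semicircular arc"
        )
    R = brentq(turn_mismatch, r_lo, 1e9, xtol=1e-12)
    theta = 2 * math.asin(L / (2 * R))
    m = math.sqrt(max(R * R - L * L / 4, 0.0))
    center = (E + S) / 2 - m * w
    beads = []
    for k in range(1, n):
        alpha = -theta / 2 + k * theta / n
        beads.append(center + R * (math.sin(alpha) * u + math.cos(alpha) * w))
    return np.asarray(beads)


def _build_chain(spec: SynthSpec, chain_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """One chain: helices alternating up/down joined by connectors.

    Each chain gets its own helix phase (golden-angle offset per chain), so
    chains are distinct rigid bodies the way distinct proteins are — a
    complex of exact copies would make the docking problem artificially
    symmetric.  Returns (coords, is_helix_bead)."""
    coords: list[np.ndarray] = []
    helical: list[bool] = []
    prev_end: np.ndarray | None = None
    phase = 2.399963 * chain_index
    for h in range(spec.helices_per_chain):
        up = h % 2 == 0
        helix = ideal_helix(spec.helix_length, up=up, phase=phase + 0.9 * h) + np.array(
            [h * HELIX_SPACING, 0.0, 0.0]
        )
        if prev_end is not None:
            # odd helices start at the top (previous one ended there): bulge up
            bulge = np.array([0.0, 0.0, 1.0 if h % 2 == 1 else -1.0])
            # cap beads exit/enter along the helix axis so the junction
            # 1-3 distances clear the excluded volume at any helix phase
            exit_cap = prev_end + BOND * bulge
            entry_cap = helix[0] + BOND * bulge
            loop = [exit_cap, *_connector_beads(exit_cap, entry_cap, bulge), entry_cap]
            for b in loop:
                coords.append(b)
                helical.append(False)
        for b in helix:
            coords.append(b)
            helical.append(True)
        prev_end = helix[-1]
    return np.asarray(coords), np.asarray(helical)


def make_reference_complex(spec: SynthSpec) -> CaModel:
    """Deterministic clash-free reference complex for the given spec.

    Chains are labeled "A", "B", ...; residues are numbered 1..n per chain;
    helix beads with |z| <= membrane half-width are annotated as
    membrane-embedded.
    """
    chains = []
    coords = []
    for c in range(spec.n_chains):
        chain_coords, helical = _build_chain(spec, chain_index=c)
        cid = chr(ord("A") + c)
        offset = np.array([0.0, c * CHAIN_SPACING, 0.0])
        xyz = chain_coords + offset
        membrane = frozenset(
            i + 1
            for i in range(len(xyz))
            if helical[i] and abs(xyz[i, 2]) <= spec.membrane_half_width_A
        )
        chains.append(
            ChainSpec(
                chain_id=cid,
                residue_numbers=tuple(range(1, len(xyz) + 1)),
                membrane_residues=membrane,
            )
        )
        coords.append(xyz)
    model = CaModel(ComplexTopology(tuple(chains)), np.vstack(coords))
    _check_geometry(model)
    return model


def _check_geometry(model: CaModel) -> None:
    X = model.coords
    for c in model.topology.chains:
        xc = model.chain_coords(c.chain_id)
        d = np.linalg.norm(np.diff(xc, axis=0), axis=1)
        if np.any(np.abs(d - BOND) > 0.1):
            raise RuntimeError(
                f"chain {c.chain_id}: virtual bond outside 3.8±0.1 Å "
                f"(worst {d[np.argmax(np.abs(d - BOND))]:.3f})"
            )
    D = cdist(X, X)
    n = len(X)
    bonded = np.zeros((n, n), bool)
    for c in model.topology.chains:
        s = model.chain_slice(c.chain_id)
        idx = np.arange(s.start, s.stop - 1)
        bonded[idx, idx + 1] = True
    bonded |= bonded.T
    np.fill_diagonal(bonded, True)
    if np.any((D < 4.0) & ~bonded):
        raise RuntimeError("reference complex has non-bonded beads closer than 4 Å")


# ---------------------------------------------------------------------------
# simulated observations
# ---------------------------------------------------------------------------


def _inter_chain_pairs(model: CaModel):
    """All inter-chain (chain_a, res_a, chain_b, res_b, distance) tuples."""
    chains = model.topology.chains
    out = []
    for a in range(len(chains)):
        for b in range(a + 1, len(chains)):
            ca, cb = chains[a], chains[b]
            D = cdist(model.chain_coords(ca.chain_id), model.chain_coords(cb.chain_id))
            for i, ra in enumerate(ca.residue_numbers):
                for j, rb in enumerate(cb.residue_numbers):
                    out.append((ca.chain_id, ra, cb.chain_id, rb, D[i, j]))
    return out


def simulate_crosslinks(
    model: CaModel,
    spec: CrosslinkSpec | None = None,
    seed: int = 0,
) -> tuple[RestraintTable, pd.DataFrame]:
    """Simulated disulfide cross-linking survey on a reference complex.

    True positives are inter-chain pairs within the bound, true negatives
    pairs beyond bound + margin, and false positives distant pairs that are
    nevertheless labeled positive.  Returns the restraint table plus a truth
    sidecar (``truth`` in {tp, fp, tn} and the reference distance) for test
    oracles.
    """
    spec = spec if spec is not None else CrosslinkSpec()
    rng = np.random.default_rng(seed)
    pairs = _inter_chain_pairs(model)
    near = [p for p in pairs if p[4] <= spec.bound_A]
    far = [p for p in pairs if p[4] > spec.bound_A + spec.negative_margin_A]
    if len(near) < spec.n_true_positive:
        raise ValueError(
            f"only {len(near)} pairs within {spec.bound_A} Å; "
            f"cannot sample {spec.n_true_positive} true positives"
        )
    if len(far) < spec.n_true_negative + spec.n_false_positive:
        raise ValueError("not enough distant pairs for negatives/false positives")
    tp_idx = rng.choice(len(near), size=spec.n_true_positive, replace=False)
    far_idx = rng.choice(
        len(far), size=spec.n_true_negative + spec.n_false_positive, replace=False
    )
    tn_idx = far_idx[: spec.n_true_negative]
    fp_idx = far_idx[spec.n_true_negative :]

    rows, truth = [], []
    for kind, chosen, pool, cls in (
        ("tp", tp_idx, near, "crosslink_positive"),
        ("fp", fp_idx, far, "crosslink_positive"),
        ("tn", tn_idx, far, "crosslink_negative"),
    ):
        for k in chosen:
            ca, ra, cb, rb, d = pool[int(k)]
            rows.append(
                {
                    "chain_a": ca,
                    "res_a": ra,
                    "chain_b": cb,
                    "res_b": rb,
                    "class": cls,
                    "probability": np.nan,
                    "upper_bound": spec.bound_A,
                }
            )
            truth.append(
                {
                    "chain_a": ca,
                    "res_a": ra,
                    "chain_b": cb,
                    "res_b": rb,
                    "truth": kind,
                    "distance_A": d,
                }
            )
    table = RestraintTable(pd.DataFrame(rows, columns=list(RESTRAINT_COLUMNS)))
    return table, pd.DataFrame(truth)


def _scaled_beta(rng, ab: tuple[float, float], support: tuple[float, float], size):
    lo, hi = support
    return lo + (hi - lo) * rng.beta(ab[0], ab[1], size=size)


def simulate_contact_map(
    model: CaModel,
    spec: ContactSpec | None = None,
    scope: tuple = ("inter", "A", "B"),
    seed: int = 0,
) -> ContactMap:
    """Predictor-style contact map for one chain pair (or one chain).

    Every true contact (reference distance <= cutoff) is emitted with
    probability ``tp_rate`` carrying a high probability value; every
    non-contact pair is emitted with probability ``fp_rate`` carrying a low
    value straddling the 0.15 curation threshold.  Positions are 1-based
    residue numbers.
    """
    spec = spec if spec is not None else ContactSpec()
    rng = np.random.default_rng(seed)
    if scope[0] == "inter":
        ca = model.topology.chain(scope[1])
        cb = model.topology.chain(scope[2])
        D = cdist(model.chain_coords(ca.chain_id), model.chain_coords(cb.chain_id))
        pairs = [
            (ra, rb, D[i, j])
            for i, ra in enumerate(ca.residue_numbers)
            for j, rb in enumerate(cb.residue_numbers)
        ]
    else:
        c = model.topology.chain(scope[1])
        X = model.chain_coords(c.chain_id)
        D = cdist(X, X)
        nums = c.residue_numbers
        pairs = [
            (nums[i], nums[j], D[i, j])
            for i in range(len(nums))
            for j in range(i + 1, len(nums))
            if nums[j] - nums[i] >= spec.min_sequence_separation
        ]
    records = []
    for ra, rb, d in pairs:
        if d <= spec.cutoff_A:
            if rng.random() < spec.tp_rate:
                p = float(_scaled_beta(rng, spec.true_beta, spec.true_support, None))
                records.append((ra, rb, p))
        elif rng.random() < spec.fp_rate:
            p = float(_scaled_beta(rng, spec.false_beta, spec.false_support, None))
            records.append((ra, rb, p))
    df = pd.DataFrame(records, columns=["i", "j", "probability"])
    return ContactMap(df=df, scope=scope, linker_masked=True)


def simulate_msa(
    spec: MsaSpec | None = None,
    seed: int = 0,
    name: str = "prot",
) -> Alignment:
    """Alignment with one column per conservation target: the modal residue
    is planted in floor(target * n_rows) rows (always including the reference
    row), remaining rows draw uniformly from the other residues (re-drawn if
    a competing residue would reach the modal count).  Organism tags are
    ``org000``, ``org001``, ... so independently generated alignments pair by
    construction."""
    spec = spec if spec is not None else MsaSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_rows
    columns = []
    for target in spec.conservation_targets:
        count = int(math.floor(target * n + 1e-9))
        modal = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        others = [aa for aa in AMINO_ACIDS if aa != modal]
        members = {0}
        if count > 1:
            members |= set(rng.choice(np.arange(1, n), size=count - 1, replace=False).tolist())
        for _ in range(100):
            fill = rng.choice(len(others), size=n - count)
            fill_counts = np.bincount(fill, minlength=len(others))
            if count == n or fill_counts.max(initial=0) < count:
                break
        else:
            raise RuntimeError("could not realize conservation target without ties")
        column, k = [], 0
        for r in range(n):
            if r in members:
                column.append(modal)
            else:
                column.append(others[int(fill[k])])
                k += 1
        columns.append(column)
    rows = []
    for r in range(n):
        seq = "".join(columns[c][r] for c in range(len(columns)))
        seq_id = f"{name}_ref" if r == 0 else f"{name}_h{r:03d}"
        rows.append(AlignmentRow(seq_id=seq_id, organism=f"org{r:03d}", seq=seq))
    return Alignment(rows=tuple(rows), reference_row=0)


def simulate_paired_msas(
    spec: MsaSpec | None = None,
    seed: int = 0,
    names: tuple[str, str] = ("protA", "protB"),
) -> tuple[Alignment, Alignment]:
    """Two alignments over the same organism set (for hybrid-MSA pairing)."""
    return (
        simulate_msa(spec, seed=seed, name=names[0]),
        simulate_msa(spec, seed=seed + 1, name=names[1]),
    )


def scramble(model: CaModel, seed: int = 0, magnitude: float = 30.0) -> CaModel:
    """Apply a seeded random rigid-body transform to every chain: rotation
    about the chain centroid plus a translation with components uniform in
    [-magnitude, magnitude] Å.  Internal chain geometry is untouched;
    magnitude 0 is the identity."""
    if magnitude == 0:
        return model.copy()
    rng = np.random.default_rng(seed)
    X = model.coords.copy()
    for c in model.topology.chains:
        s = model.chain_slice(c.chain_id)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        t = rng.uniform(-magnitude, magnitude, size=3)
        cen = X[s].mean(axis=0)
        X[s] = (X[s] - cen) @ R.T + cen + t
    return model.with_coords(X)
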