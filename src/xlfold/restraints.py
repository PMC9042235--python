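"""Typed restraints, their energies, weighted scoring and violation counts.

Restraint classes
-----------------
* :class:`CrosslinkRestraint` — Cα–Cα upper bound from an engineered Cys–Cys
  disulfide cross-link.  ``polarity="negative"`` records a pair that *failed*
  to cross-link; negative restraints never contribute energy, they only enter
  violation diagnostics (proximity where none was observed).
* :class:`ContactRestraint` — upper bound from a predicted residue contact,
  ``kind`` intra or inter.
* :class:`RigidGroupRestraint` — keeps the internal pairwise distances of a
  residue group (a helix, a domain) near reference values while the group
  moves freely as a whole.
* :class:`AnchorRestraint` — harmonic positional restraint on Cα beads
  (force constant 0.1 score-units/Å² by default).
* :class:`MembraneSlabRestraint` — keeps membrane-annotated beads inside a
  slab |z| <= half-width.
* :class:`StericsRestraint` — chain-integrity springs (3.8 Å virtual bonds
  between consecutive residues) plus soft-core excluded volume (quadratic
  penalty below 4.0 Å between non-bonded beads).

Ambiguity: any restraint site whose label names a copy group with several
chain copies is evaluated as the *minimum* distance over all copy pairs —
cross-links and predicted contacts cannot distinguish chemically equivalent
subunits of an oligomer.

Energies are flat-bottom (zero when satisfied) and everywhere C¹, so plain
gradient descent applies.  ``total_score`` is the weighted sum over a
restraint set; :class:`CompiledScore` is the vectorized equivalent (with
analytic gradient) used by the optimizer and cross-checked against the
reference implementation in the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .config import CurationParams, ProtocolDefaults, ScoreWeights
from .core import CaModel, ComplexTopology

Site = tuple[str, int]  # (chain id or copy-group label, author residue number)


# ---------------------------------------------------------------------------
# restraint types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrosslinkRestraint:
    site_a: Site
    site_b: Site
    upper_bound: float = 12.0
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValueError("cross-link upper bound must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


@dataclass(frozen=True)
class ContactRestraint:
    site_a: Site
    site_b: Site
    upper_bound: float = 10.0
    probability: float = 1.0
    kind: str = "inter"

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValueError("contact upper bound must be positive")
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("contact probability must be in (0, 1]")
        if self.kind not in ("inter", "intra"):
            raise ValueError("contact kind must be 'inter' or 'intra'")


@dataclass(frozen=True, eq=False)
class RigidGroupRestraint:
    """Internal pairwise-distance restraint over >=3 residues of one chain."""

    chain_id: str
    residues: tuple[int, ...]
    reference: np.ndarray  # (m, 3) reference coordinates of the members
    k: float = 1.0

    def __post_init__(self) -> None:
        if len(self.residues) < 3:
            raise ValueError("rigid group needs at least 3 members")
        ref = np.asarray(self.reference, float)
        if ref.shape != (len(self.residues), 3):
            raise ValueError("reference shape must be (n_members, 3)")
        object.__setattr__(self, "reference", ref)
        if self.k < 0:
            raise ValueError("force constant must be >= 0")

    @property
    def reference_distances(self) -> np.ndarray:
        """Condensed (pdist-ordered) reference distance vector."""
        return pdist(self.reference)


@dataclass(frozen=True, eq=False)
class AnchorRestraint:
    """Harmonic positional restraints: k * sum ||x_i - ref_i||^2."""

    sites: tuple[Site, ...]
    reference: np.ndarray  # (m, 3)
    k: float = 0.1

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, float)
        if ref.shape != (len(self.sites), 3):
            raise ValueError("reference shape must be (n_sites, 3)")
        object.__setattr__(self, "reference", ref)
        if self.k < 0:
            raise ValueError("force constant must be >= 0")


@dataclass(frozen=True)
class MembraneSlabRestraint:
    sites: tuple[Site, ...]
    half_width: float = 15.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("slab half-width must be positive")


@dataclass(frozen=True)
class StericsRestraint:
    """Whole-model term: virtual-bond springs + soft-core repulsion.

    The repulsion floor is sequence-separation-aware, as in standard Cα
    force fields: ``min_distance`` applies to near-in-sequence pairs of one
    chain (|i−j| <= ``local_range``, covering tight turns and helix i,i+3
    geometry at ~4.3–5.1 Å), while ``nonlocal_min_distance`` applies to
    long-range and inter-chain pairs, whose Cα–Cα distances in real
    structures essentially never fall below ~5 Å.  A single permissive
    floor would let chains interpenetrate deeply enough to over-satisfy
    upper-bound restraint networks."""

    min_distance: float = 4.0
    nonlocal_min_distance: float = 5.0
    local_range: int = 4
    bond_length: float = 3.8


Restraint = (
    CrosslinkRestraint
    | ContactRestraint
    | RigidGroupRestraint
    | AnchorRestraint
    | MembraneSlabRestraint
    | StericsRestraint
)


def restraint_chains(r: Restraint, topology: ComplexTopology) -> frozenset[str]:
    """Chain ids a restraint touches (empty set == applies to whole model)."""
    if isinstance(r, (CrosslinkRestraint, ContactRestraint)):
        return frozenset(topology.copies(r.site_a[0])) | frozenset(
            topology.copies(r.site_b[0])
        )
    if isinstance(r, RigidGroupRestraint):
        return frozenset((r.chain_id,))
    if isinstance(r, (AnchorRestraint, MembraneSlabRestraint)):
        return frozenset(itertools.chain.from_iterable(
            topology.copies(s[0]) for s in r.sites
        ))
    return frozenset()


def restraint_class(r: Restraint) -> str:
    if isinstance(r, CrosslinkRestraint):
        return "crosslink" if r.polarity == "positive" else "crosslink_negative"
    if isinstance(r, ContactRestraint):
        return f"contact_{r.kind}"
    if isinstance(r, RigidGroupRestraint):
        return "rigid"
    if isinstance(r, AnchorRestraint):
        return "anchor"
    if isinstance(r, MembraneSlabRestraint):
        return "slab"
    if isinstance(r, StericsRestraint):
        return "sterics"
    raise TypeError(f"unknown restraint type {type(r)!r}")


def class_weight(cls: str, weights: ScoreWeights) -> float:
    return {
        "crosslink": weights.crosslink,
        "crosslink_negative": 0.0,  # diagnostics only, never an energy term
        "contact_inter": weights.contact_inter,
        "contact_intra": weights.contact_intra,
        "rigid": weights.rigid,
        "anchor": weights.anchor,
        "slab": weights.slab,
        "sterics": weights.sterics,
    }[cls]


# ---------------------------------------------------------------------------
# reference (per-restraint) energies
# ---------------------------------------------------------------------------


def distance_energy(d: float, upper_bound: float) -> float:
    """Flat-bottom harmonic: 0 inside the bound, (d - bound)^2 outside."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    excess = d - upper_bound
    return excess * excess if excess > 0 else 0.0


def _site_indices(model: CaModel, site: Site) -> list[int]:
    label, resnum = site
    idx = [
        model.index(c, resnum)
        for c in model.topology.copies(label)
        if model.has(c, resnum)
    ]
    if not idx:
        raise KeyError(f"site {label}:{resnum} resolves to no residue in model")
    return idx


def ambiguous_min_distance(
    model: CaModel, r: CrosslinkRestraint | ContactRestraint
) -> float:
    """Minimum Cα–Cα distance over the copy-equivalence sets of both sites."""
    ia = _site_indices(model, r.site_a)
    ib = _site_indices(model, r.site_b)
    best = math.inf
    for i in ia:
        for j in ib:
            if i == j:
                continue
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            best = min(best, d)
    if not math.isfinite(best):
        raise ValueError("ambiguous distance over identical single-residue sets")
    return best


def _bond_pairs(model: CaModel) -> list[tuple[int, int]]:
    pairs = []
    for c in model.topology.chains:
        s = model.chain_slice(c.chain_id)
        pairs.extend((i, i + 1) for i in range(s.start, s.stop - 1))
    return pairs


def _steric_floors(model: CaModel, r: StericsRestraint) -> np.ndarray:
    """(N, N) matrix of excluded-volume floors: the local floor within
    ``local_range`` sequence positions of one chain, the non-local floor
    everywhere else."""
    n = len(model.coords)
    floors = np.full((n, n), r.nonlocal_min_distance)
    for c in model.topology.chains:
        s = model.chain_slice(c.chain_id)
        idx = np.arange(s.start, s.stop)
        for off in range(1, r.local_range + 1):
            if off >= len(idx):
                break
            floors[idx[:-off], idx[off:]] = r.min_distance
            floors[idx[off:], idx[:-off]] = r.min_distance
    return floors


def restraint_energy(model: CaModel, r: Restraint) -> float:
    """Unweighted energy of one restraint on a model (class weights are
    applied at aggregation in :func:`total_score`)."""
    if isinstance(r, CrosslinkRestraint):
        if r.polarity == "negative":
            return 0.0
        return distance_energy(ambiguous_min_distance(model, r), r.upper_bound)
    if isinstance(r, ContactRestraint):
        return distance_energy(ambiguous_min_distance(model, r), r.upper_bound)
    if isinstance(r, RigidGroupRestraint):
        idx = [model.index(r.chain_id, res) for res in r.residues]
        d = pdist(model.coords[idx])
        return float(r.k * ((d - r.reference_distances) ** 2).sum())
    if isinstance(r, AnchorRestraint):
        idx = []
        for s in r.sites:
            cand = _site_indices(model, s)
            if len(cand) != 1:
                raise ValueError("anchor sites must resolve to a single residue")
            idx.append(cand[0])
        diff = model.coords[idx] - r.reference
        return float(r.k * (diff**2).sum())
    if isinstance(r, MembraneSlabRestraint):
        idx = [i for s in r.sites for i in _site_indices(model, s)]
        excess = np.maximum(np.abs(model.coords[idx, 2]) - r.half_width, 0.0)
        return float((excess**2).sum())
    if isinstance(r, StericsRestraint):
        bonds = _bond_pairs(model)
        e = 0.0
        for i, j in bonds:
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            e += (d - r.bond_length) ** 2
        bonded = set(bonds)
        n = len(model.coords)
        floors = _steric_floors(model, r)
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonded:
                    continue
                d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
                if d < floors[i, j]:
                    e += (floors[i, j] - d) ** 2
        return e
    raise TypeError(f"unknown restraint type {type(r)!r}")


@dataclass(frozen=True)
class ScoreBreakdown:
    total: float
    per_class: dict[str, float] = field(default_factory=dict)


def total_score(
    model: CaModel,
    restraint_set: list[Restraint],
    weights: ScoreWeights | None = None,
) -> ScoreBreakdown:
    """Weighted total score with per-class subtotals (reference path)."""
    weights = weights if weights is not None else ScoreWeights()
    per_class: dict[str, float] = {}
    total = 0.0
    for r in restraint_set:
        cls = restraint_class(r)
        contribution = class_weight(cls, weights) * restraint_energy(model, r)
        per_class[cls] = per_class.get(cls, 0.0) + contribution
        total += contribution
    return ScoreBreakdown(total=total, per_class=per_class)


def count_violations(
    model: CaModel,
    restraint_set: list[Restraint],
    tol: float = 0.0,
) -> dict[str, int]:
    """Per-class violation counts for distance-type restraints.

    A positive cross-link or contact is violated iff its ambiguous minimum
    distance exceeds ``upper_bound + tol``; a negative cross-link is violated
    iff the distance falls *below* its bound (proximity where the experiment
    saw none).
    """
    counts = {
        "crosslink": 0,
        "crosslink_negative": 0,
        "contact_inter": 0,
        "contact_intra": 0,
    }
    for r in restraint_set:
        if isinstance(r, CrosslinkRestraint):
            d = ambiguous_min_distance(model, r)
            if r.polarity == "positive":
                if d > r.upper_bound + tol:
                    counts["crosslink"] += 1
            elif d < r.upper_bound:
                counts["crosslink_negative"] += 1
        elif isinstance(r, ContactRestraint):
            if ambiguous_min_distance(model, r) > r.upper_bound + tol:
                counts[f"contact_{r.kind}"] += 1
    counts["total"] = sum(counts.values())
    return counts


# ---------------------------------------------------------------------------
# restraint-table conversion
# ---------------------------------------------------------------------------


def from_table(
    table,
    crosslink_bound: float | None = None,
    contact_bound: float | None = None,
) -> list[Restraint]:
    """Build restraint objects from a :class:`~xlfold.io_formats.RestraintTable`.

    Per-row ``upper_bound`` values take precedence; rows without one fall back
    to ``crosslink_bound`` / ``contact_bound`` (protocol defaults if None).
    """
    defaults = ProtocolDefaults()
    if crosslink_bound is None:
        crosslink_bound = defaults.crosslink_upper_bound_A
    if contact_bound is None:
        contact_bound = defaults.curation.contact_upper_bound_A
    out: list[Restraint] = []
    df = table.df.rename(columns={"class": "clazz"})
    for row in df.itertuples(index=False):
        cls = row.clazz
        site_a = (row.chain_a, int(row.res_a))
        site_b = (row.chain_b, int(row.res_b))
        bound = float(row.upper_bound) if pd.notna(row.upper_bound) else None
        if cls in ("crosslink_positive", "crosslink_negative"):
            out.append(
                CrosslinkRestraint(
                    site_a=site_a,
                    site_b=site_b,
                    upper_bound=bound if bound is not None else crosslink_bound,
                    polarity="positive" if cls == "crosslink_positive" else "negative",
                )
            )
        else:
            out.append(
                ContactRestraint(
                    site_a=site_a,
                    site_b=site_b,
                    upper_bound=bound if bound is not None else contact_bound,
                    probability=float(row.probability),
                    kind="inter" if cls == "contact_inter" else "intra",
                )
            )
    return out


# ---------------------------------------------------------------------------
# compiled (vectorized) scoring with analytic gradient
# ---------------------------------------------------------------------------


class CompiledScore:
    """Vectorized energy/gradient of a weighted restraint set on a fixed
    topology.  Equality with the reference path (``total_score``) is a tested
    invariant; this class exists purely for optimizer throughput."""

    def __init__(
        self,
        model: CaModel,
        restraint_set: list[Restraint],
        weights: ScoreWeights | None = None,
    ):
        self.weights = weights if weights is not None else ScoreWeights()
        self.n = len(model.coords)
        w = self.weights

        # flat-bottom pair restraints (with ambiguity candidates)
        cand_i: list[int] = []
        cand_j: list[int] = []
        offsets: list[int] = []
        bounds: list[float] = []
        pair_w: list[float] = []
        for r in restraint_set:
            if not isinstance(r, (CrosslinkRestraint, ContactRestraint)):
                continue
            if isinstance(r, CrosslinkRestraint) and r.polarity == "negative":
                continue
            ia = _site_indices(model, r.site_a)
            ib = _site_indices(model, r.site_b)
            pairs = [(i, j) for i in ia for j in ib if i != j]
            if not pairs:
                raise ValueError("restraint with empty candidate pair set")
            offsets.append(len(cand_i))
            cand_i.extend(p[0] for p in pairs)
            cand_j.extend(p[1] for p in pairs)
            bounds.append(r.upper_bound)
            pair_w.append(class_weight(restraint_class(r), w))
        self._pi = np.asarray(cand_i, dtype=np.intp)
        self._pj = np.asarray(cand_j, dtype=np.intp)
        self._poff = np.asarray(offsets, dtype=np.intp)
        self._pub = np.asarray(bounds, dtype=float)
        self._pw = np.asarray(pair_w, dtype=float)
        seg = np.zeros(len(self._pi), dtype=np.intp)
        if len(self._poff) > 1:
            seg[self._poff[1:]] = 1
            seg = np.cumsum(seg)
        self._pseg = seg

        # rigid groups
        ri: list[int] = []
        rj: list[int] = []
        rd: list[float] = []
        rk: list[float] = []
        for r in restraint_set:
            if not isinstance(r, RigidGroupRestraint):
                continue
            idx = [model.index(r.chain_id, res) for res in r.residues]
            ref = r.reference_distances
            kk = 0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    ri.append(idx[a])
                    rj.append(idx[b])
                    rd.append(ref[kk])
                    rk.append(w.rigid * r.k)
                    kk += 1
        self._ri = np.asarray(ri, dtype=np.intp)
        self._rj = np.asarray(rj, dtype=np.intp)
        self._rd = np.asarray(rd, dtype=float)
        self._rk = np.asarray(rk, dtype=float)

        # anchors
        ai: list[int] = []
        aref: list[np.ndarray] = []
        ak: list[float] = []
        for r in restraint_set:
            if not isinstance(r, AnchorRestraint):
                continue
            for s, ref in zip(r.sites, r.reference):
                cand = _site_indices(model, s)
                if len(cand) != 1:
                    raise ValueError("anchor sites must resolve to a single residue")
                ai.append(cand[0])
                aref.append(ref)
                ak.append(w.anchor * r.k)
        self._ai = np.asarray(ai, dtype=np.intp)
        self._aref = (
            np.asarray(aref, dtype=float) if aref else np.zeros((0, 3))
        )
        self._ak = np.asarray(ak, dtype=float)

        # membrane slab
        si: list[int] = []
        shw: list[float] = []
        for r in restraint_set:
            if not isinstance(r, MembraneSlabRestraint):
                continue
            for s in r.sites:
                for i in _site_indices(model, s):
                    si.append(i)
                    shw.append(r.half_width)
        self._si = np.asarray(si, dtype=np.intp)
        self._shw = np.asarray(shw, dtype=float)

        # sterics
        self._sterics = next(
            (r for r in restraint_set if isinstance(r, StericsRestraint)), None
        )
        if self._sterics is not None:
            bonds = _bond_pairs(model)
            self._bi = np.asarray([p[0] for p in bonds], dtype=np.intp)
            self._bj = np.asarray([p[1] for p in bonds], dtype=np.intp)
            excl = np.zeros((self.n, self.n), dtype=bool)
            excl[self._bi, self._bj] = True
            excl |= excl.T
            np.fill_diagonal(excl, True)
            self._excl = excl
            self._floors = _steric_floors(model, self._sterics)

    # -- energy -----------------------------------------------------------
    def energy(self, coords: np.ndarray) -> float:
        return self._eval(coords, want_grad=False)[0]

    def energy_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return self._eval(coords, want_grad=True)

    def _eval(self, X: np.ndarray, want_grad: bool):
        e = 0.0
        g = np.zeros_like(X) if want_grad else None

        if len(self._pi):
            diff = X[self._pi] - X[self._pj]
            d = np.sqrt((diff**2).sum(axis=1))
            dmin = np.minimum.reduceat(d, self._poff)
            excess = np.maximum(dmin - self._pub, 0.0)
            e += float((self._pw * excess**2).sum())
            if want_grad:
                active = excess > 0
                if active.any():
                    # first candidate achieving the segment minimum
                    is_min = d <= dmin[self._pseg] + 1e-12
                    cand_pos = np.flatnonzero(is_min)
                    seg_of = self._pseg[cand_pos]
                    _, first = np.unique(seg_of, return_index=True)
                    best = cand_pos[first]  # one per restraint, in order
                    for r_idx in np.flatnonzero(active):
                        k = best[r_idx]
                        dk = d[k]
                        if dk < 1e-12:
                            continue
                        coeff = 2.0 * self._pw[r_idx] * excess[r_idx] / dk
                        gi = coeff * diff[k]
                        g[self._pi[k]] += gi
                        g[self._pj[k]] -= gi

        if len(self._ri):
            diff = X[self._ri] - X[self._rj]
            d = np.sqrt((diff**2).sum(axis=1))
            delta = d - self._rd
            e += float((self._rk * delta**2).sum())
            if want_grad:
                safe = np.maximum(d, 1e-12)
                coeff = (2.0 * self._rk * delta / safe)[:, None]
                np.add.at(g, self._ri, coeff * diff)
                np.add.at(g, self._rj, -coeff * diff)

        if len(self._ai):
            diff = X[self._ai] - self._aref
            e += float((self._ak * (diff**2).sum(axis=1)).sum())
            if want_grad:
                np.add.at(g, self._ai, 2.0 * self._ak[:, None] * diff)

        if len(self._si):
            z = X[self._si, 2]
            excess = np.maximum(np.abs(z) - self._shw, 0.0)
            e += float((self.weights.slab * excess**2).sum())
            if want_grad:
                gz = 2.0 * self.weights.slab * excess * np.sign(z)
                np.add.at(g[:, 2], self._si, gz)

        if self._sterics is not None:
            st = self._sterics
            ws = self.weights.sterics
            diff = X[self._bi] - X[self._bj]
            d = np.sqrt((diff**2).sum(axis=1))
            delta = d - st.bond_length
            e += float(ws * (delta**2).sum())
            if want_grad:
                safe = np.maximum(d, 1e-12)
                coeff = (2.0 * ws * delta / safe)[:, None]
                np.add.at(g, self._bi, coeff * diff)
                np.add.at(g, self._bj, -coeff * diff)
            D = cdist(X, X)
            mask = (D < self._floors) & ~self._excl
            ii, jj = np.nonzero(np.triu(mask, 1))
            if len(ii):
                dv = X[ii] - X[jj]
                dd = np.maximum(D[ii, jj], 1e-12)
                short = self._floors[ii, jj] - dd
                e += float(ws * (short**2).sum())
                if want_grad:
                    coeff = (-2.0 * ws * short / dd)[:, None]
                    np.add.at(g, ii, coeff * dv)
                    np.add.at(g, jj, -coeff * dv)

        return (e, g) if want_grad else (e, None)
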