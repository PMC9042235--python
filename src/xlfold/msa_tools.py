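"""Alignment conservation calling, paired (hybrid) MSA construction and
contact-map curation.

Workflow context: inter-protein residue contacts are predicted by a
co-evolution contact predictor from a *hybrid* MSA — the two interacting
proteins' sequences concatenated per organism, with a 20-glycine linker
between the reference sequences so that predictions near the artificial
junction are meaningless by construction and can be masked out.  This module
prepares predictor-ready hybrid alignments, masks the linker out of returned
contact maps, and curates contact maps into distance restraints (probability
strictly greater than 0.15; optional exclusion of contacts that are severely
violated, score > 10 score-units, on an existing model).

Conservation calling implements the orthology-analysis rule: an alignment
column is conserved when the modal non-gap residue occurs in at least 70% of
the sequences.  Gaps never count toward identity but stay in the denominator
(the strict reading of "identical in at least N% of the sequences").

Conventions: contact-map positions on a hybrid alignment are 0-based columns
of the hybrid reference row; after linker masking they are re-indexed to
1-based positions within each protein.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from biotite.sequence.io.fasta import FastaFile

from .config import CurationParams, ScoreWeights
from .core import CaModel
from .io_formats import RESTRAINT_COLUMNS, RestraintTable
from .restraints import (
    ContactRestraint,
    ambiguous_min_distance,
    class_weight,
    distance_energy,
)

GAP = "-"


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRow:
    seq_id: str
    organism: str
    seq: str


@dataclass(frozen=True)
class Alignment:
    """Rows of equal-length gapped sequences; one row is the reference whose
    ungapped positions define the coordinate system."""

    rows: tuple[AlignmentRow, ...]
    reference_row: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0].seq)
        if any(len(r.seq) != ncol for r in self.rows):
            raise ValueError("alignment rows differ in length")
        if not 0 <= self.reference_row < len(self.rows):
            raise ValueError("reference_row out of range")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].seq)

    @property
    def reference(self) -> AlignmentRow:
        return self.rows[self.reference_row]

    def reference_positions(self) -> list[int | None]:
        """Per column: 1-based ungapped position in the reference row, or
        None where the reference is gapped."""
        out: list[int | None] = []
        pos = 0
        for ch in self.reference.seq:
            if ch == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out


def read_alignment(path, reference_row: int = 0) -> Alignment:
    """Read an aligned FASTA.  The organism tag is the free text after the
    first '|' of each header (empty if absent)."""
    fasta = FastaFile.read(str(path))
    rows = []
    for header, seq in fasta.items():
        if "|" in header:
            seq_id, organism = header.split("|", 1)
        else:
            seq_id, organism = header, ""
        rows.append(AlignmentRow(seq_id.strip(), organism.strip(), str(seq)))
    return Alignment(rows=tuple(rows), reference_row=reference_row)


def write_alignment(aln: Alignment, path) -> None:
    fasta = FastaFile()
    for r in aln.rows:
        header = f"{r.seq_id}|{r.organism}" if r.organism else r.seq_id
        fasta[header] = r.seq
    fasta.write(str(path))


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConservationCall:
    """Per-column identity fractions and conservation flags.

    ``identity_fraction[c]`` is (count of rows carrying the modal non-gap
    residue of column c) / (total rows); ``conserved[c]`` iff the fraction
    reaches the threshold; ``reference_positions[c]`` maps columns to 1-based
    ungapped reference positions (None where the reference is gapped)."""

    identity_fraction: np.ndarray
    conserved: np.ndarray
    reference_positions: tuple[int | None, ...]
    threshold: float

    def conserved_reference_positions(self) -> list[int]:
        return [
            p
            for p, c in zip(self.reference_positions, self.conserved)
            if c and p is not None
        ]


def call_conservation(aln: Alignment, threshold: float = 0.70) -> ConservationCall:
    """Flag alignment columns whose modal non-gap residue occurs in at least
    ``threshold`` of all rows (gaps count in the denominator, never as the
    modal residue)."""
    if aln.n_rows < 2:
        raise ValueError("conservation calling needs at least 2 rows")
    n = aln.n_rows
    fractions = np.zeros(aln.n_columns)
    for c in range(aln.n_columns):
        counts = Counter(r.seq[c] for r in aln.rows)
        counts.pop(GAP, None)
        fractions[c] = (max(counts.values()) / n) if counts else 0.0
    conserved = fractions >= threshold
    return ConservationCall(
        identity_fraction=fractions,
        conserved=conserved,
        reference_positions=tuple(aln.reference_positions()),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# hybrid (paired) MSAs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HybridMSA:
    """Concatenated two-protein alignment for inter-protein contact
    prediction: reference row is refA + 20 glycines + refB; homolog rows are
    paired by organism tag with the linker region gapped."""

    alignment: Alignment
    len_a: int
    len_b: int
    linker_start: int
    linker_stop: int
    name_a: str
    name_b: str
    pair_manifest: tuple[tuple[str, str, str], ...]
    drop_log: tuple[str, ...] = ()

    @property
    def linker_columns(self) -> range:
        return range(self.linker_start, self.linker_stop)

    @property
    def n_columns(self) -> int:
        return self.alignment.n_columns


def _project_to_reference(aln: Alignment) -> list[tuple[str, str, str]]:
    """Restrict every row to the columns where the reference is ungapped, so
    row strings become coordinates of the ungapped reference sequence."""
    keep = [i for i, ch in enumerate(aln.reference.seq) if ch != GAP]
    return [
        (r.seq_id, r.organism, "".join(r.seq[i] for i in keep)) for r in aln.rows
    ]


def build_hybrid_msa(
    msa_a: Alignment,
    msa_b: Alignment,
    linker_length: int = 20,
) -> HybridMSA:
    """Pair two per-protein alignments into one hybrid alignment.

    Homolog rows are matched by organism tag (first occurrence wins on
    collision, with a warning); rows without a partner are dropped and
    logged.  Both alignments must carry the reference organism (the two
    reference rows must share the same tag)."""
    ref_org = msa_a.reference.organism
    if not ref_org or msa_b.reference.organism != ref_org:
        raise ValueError(
            "reference organism missing from one of the alignments "
            f"({msa_a.reference.organism!r} vs {msa_b.reference.organism!r})"
        )
    proj_a = _project_to_reference(msa_a)
    proj_b = _project_to_reference(msa_b)
    len_a = len(proj_a[msa_a.reference_row][2])
    len_b = len(proj_b[msa_b.reference_row][2])

    def by_organism(rows, skip_index):
        table: dict[str, tuple[str, str, str]] = {}
        for i, row in enumerate(rows):
            if i == skip_index:
                continue
            if row[1] in table:
                warnings.warn(
                    f"duplicate organism tag {row[1]!r}; keeping first occurrence",
                    stacklevel=3,
                )
                continue
            table[row[1]] = row
        return table

    a_rows = by_organism(proj_a, msa_a.reference_row)
    b_rows = by_organism(proj_b, msa_b.reference_row)

    name_a = proj_a[msa_a.reference_row][0]
    name_b = proj_b[msa_b.reference_row][0]
    linker_ref = "G" * linker_length
    linker_gap = GAP * linker_length
    ref_row = AlignmentRow(
        seq_id=f"{name_a}+{name_b}",
        organism=ref_org,
        seq=proj_a[msa_a.reference_row][2] + linker_ref + proj_b[msa_b.reference_row][2],
    )
    hybrid_rows = [ref_row]
    manifest = [(name_a, name_b, ref_org)]
    drop_log: list[str] = []
    for org in a_rows:
        if org not in b_rows:
            drop_log.append(f"A:{a_rows[org][0]} ({org}) has no partner")
            continue
        ida, _, seqa = a_rows[org]
        idb, _, seqb = b_rows[org]
        hybrid_rows.append(
            AlignmentRow(seq_id=f"{ida}+{idb}", organism=org, seq=seqa + linker_gap + seqb)
        )
        manifest.append((ida, idb, org))
    for org in b_rows:
        if org not in a_rows:
            drop_log.append(f"B:{b_rows[org][0]} ({org}) has no partner")

    return HybridMSA(
        alignment=Alignment(rows=tuple(hybrid_rows), reference_row=0),
        len_a=len_a,
        len_b=len_b,
        linker_start=len_a,
        linker_stop=len_a + linker_length,
        name_a=name_a,
        name_b=name_b,
        pair_manifest=tuple(manifest),
        drop_log=tuple(drop_log),
    )


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ContactMap:
    """Residue-pair contact probabilities for one protein or protein pair.

    ``scope`` is ``("intra", name)`` or ``("inter", name_a, name_b)``.
    Positions are 1-based protein positions, except for maps produced on a
    hybrid alignment before :func:`mask_linker`, which use 0-based hybrid
    columns."""

    df: pd.DataFrame  # columns i, j, probability
    scope: tuple
    linker_masked: bool = False

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        for col in ("i", "j", "probability"):
            if col not in df.columns:
                raise ValueError(f"contact map missing column {col!r}")
        df["i"] = df["i"].astype(int)
        df["j"] = df["j"].astype(int)
        df["probability"] = df["probability"].astype(float)
        if ((df["probability"] < 0) | (df["probability"] > 1)).any():
            raise ValueError("contact probabilities must be in [0, 1]")
        if self.scope[0] not in ("intra", "inter"):
            raise ValueError("scope must start with 'intra' or 'inter'")
        if self.scope[0] == "intra" and (df["i"] >= df["j"]).any():
            raise ValueError("intra-map records require i < j")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)


def read_contact_map(path, scope: tuple, linker_masked: bool = False) -> ContactMap:
    df = pd.read_csv(path, sep="\t")
    return ContactMap(df=df, scope=scope, linker_masked=linker_masked)


def write_contact_map(cm: ContactMap, path) -> None:
    cm.df.to_csv(path, sep="\t", index=False)


def mask_linker(cm: ContactMap, hybrid: HybridMSA) -> ContactMap:
    """Drop predictions touching the glycine linker of a hybrid map and
    re-index the surviving inter-protein records to per-protein 1-based
    positions.

    Records lying entirely within one protein's block are not part of the
    inter map and are tallied (not returned); counts are recorded in the
    returned map's ``df.attrs['dropped']``."""
    n = hybrid.n_columns
    if len(cm) and ((cm.df[["i", "j"]] < 0).any().any() or (cm.df[["i", "j"]] >= n).any().any()):
        raise ValueError("contact position outside the hybrid alignment")
    lo, hi = hybrid.linker_start, hybrid.linker_stop
    kept = []
    dropped_linker = 0
    dropped_within = 0
    for row in cm.df.itertuples(index=False):
        i, j = int(row.i), int(row.j)
        if lo <= i < hi or lo <= j < hi:
            dropped_linker += 1
            continue
        a, b = min(i, j), max(i, j)
        if b < lo:  # both in protein A
            dropped_within += 1
            continue
        if a >= hi:  # both in protein B
            dropped_within += 1
            continue
        kept.append((a + 1, b - hi + 1, float(row.probability)))
    df = pd.DataFrame(kept, columns=["i", "j", "probability"])
    out = ContactMap(
        df=df,
        scope=("inter", hybrid.name_a, hybrid.name_b),
        linker_masked=True,
    )
    out.df.attrs["dropped"] = {
        "linker": dropped_linker,
        "within_protein": dropped_within,
    }
    return out


def curate_contacts(
    cm: ContactMap,
    model: CaModel | None = None,
    p_thresh: float = 0.15,
    violation_thresh: float = 10.0,
    upper_bound: float | None = None,
    chain_map: dict[str, str] | None = None,
    exclude: set[tuple[int, int]] | None = None,
    weights: ScoreWeights | None = None,
) -> RestraintTable:
    """Filter a contact map into contact restraints.

    Order of the filters: (1) keep records with probability strictly greater
    than ``p_thresh``; (2) if a model is given, drop records whose weighted
    flat-bottom restraint score on that model exceeds ``violation_thresh``
    score-units; (3) apply the manual exclusion list (unordered position
    pairs, e.g. contacts incompatible with cross-linking data).
    """
    params = CurationParams()
    if upper_bound is None:
        upper_bound = params.contact_upper_bound_A
    weights = weights if weights is not None else ScoreWeights()
    chain_map = chain_map or {}
    if cm.scope[0] == "inter":
        name_a, name_b = cm.scope[1], cm.scope[2]
        cls = "contact_inter"
    else:
        name_a = name_b = cm.scope[1]
        cls = "contact_intra"
    label_a = chain_map.get(name_a, name_a)
    label_b = chain_map.get(name_b, name_b)
    w = class_weight(cls, weights)
    exclude_set = {tuple(sorted(p)) for p in (exclude or set())}

    rows = []
    for rec in cm.df.itertuples(index=False):
        if not rec.probability > p_thresh:
            continue
        i, j = int(rec.i), int(rec.j)
        if model is not None:
            r = ContactRestraint(
                site_a=(label_a, i),
                site_b=(label_b, j),
                upper_bound=upper_bound,
                probability=max(float(rec.probability), 1e-9),
                kind="inter" if cls == "contact_inter" else "intra",
            )
            score = w * distance_energy(ambiguous_min_distance(model, r), upper_bound)
            if score > violation_thresh:
                continue
        if tuple(sorted((i, j))) in exclude_set:
            continue
        rows.append(
            {
                "chain_a": label_a,
                "res_a": i,
                "chain_b": label_b,
                "res_b": j,
                "class": cls,
                "probability": float(rec.probability),
                "upper_bound": upper_bound,
            }
        )
    df = pd.DataFrame(rows, columns=list(RESTRAINT_COLUMNS))
    return RestraintTable(df)
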