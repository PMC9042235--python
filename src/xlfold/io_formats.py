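"""Readers/writers for the external formats of the pipeline, plus the
built-in inhibition-complex fixture.

Formats
-------
* Cα-trace PDB (wwPDB v3.3 fixed-width, via biotite): templates in, models
  out; one CA atom per residue, author numbering preserved, optional HETATM
  ZN records for placed zinc ions.  Insertion codes are rejected — the
  template and synthetic inputs this pipeline consumes do not use them.
* Restraint tables: TSV with header
  ``chain_a res_a chain_b res_b class probability upper_bound`` where class is
  one of ``crosslink_positive``, ``crosslink_negative``, ``contact_inter``,
  ``contact_intra``.  Probability is present iff the class is a contact class.

The fixture (:func:`load_inhibition_complex`) ships the topology and the
experimentally derived disulfide cross-linking network of the B. subtilis
SpoIVFB·BofA·SpoIVFA·Pro-σK inhibition complex: a SpoIVFB tetramer with one
BofA, the Pro-σK C-terminal part (residues 38–114) and SpoIVFA 65–111,
with eight observed (positive) and three non-observed (negative) Cys–Cys
cross-link pairs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from .core import CaModel, ChainSpec, ComplexTopology, contiguous_chain

RESTRAINT_CLASSES = (
    "crosslink_positive",
    "crosslink_negative",
    "contact_inter",
    "contact_intra",
)
_CONTACT_CLASSES = ("contact_inter", "contact_intra")
RESTRAINT_COLUMNS = (
    "chain_a",
    "res_a",
    "chain_b",
    "res_b",
    "class",
    "probability",
    "upper_bound",
)


# ---------------------------------------------------------------------------
# Cα PDB
# ---------------------------------------------------------------------------


@dataclass
class ChainRecord:
    """One chain as read from / written to a Cα PDB file."""

    chain_id: str
    sequence: str
    residue_numbers: list[int]
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.residue_numbers):
            raise ValueError("sequence and residue_numbers length mismatch")
        nums = self.residue_numbers
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, float)
            if self.coords.shape != (len(self.sequence), 3):
                raise ValueError("coords shape must be (n_residues, 3)")


def read_ca_pdb(path) -> list[ChainRecord]:
    """Read a PDB file, keeping only Cα coordinates.

    Altlocs resolve to highest occupancy; ordered residues lacking a CA atom
    are skipped with a warning; a file without any CA atom is a hard error.
    """
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as err:  # biotite errors carry the offending line
        raise ValueError(f"unparseable PDB file {path}: {err}") from err
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() and (atoms.ins_code != "").any():
        raise ValueError(f"{path}: insertion codes are not supported")
    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"{path}: no CA atoms found")

    records: list[ChainRecord] = []
    for chain_id in np.unique(atoms.chain_id).tolist():
        chain_atoms = atoms[atoms.chain_id == chain_id]
        chain_ca = ca[ca.chain_id == chain_id]
        ordered = np.unique(chain_atoms.res_id)
        with_ca = set(chain_ca.res_id.tolist())
        missing = [int(r) for r in ordered if r not in with_ca]
        if missing:
            warnings.warn(
                f"{path}: chain {chain_id} residues {missing} lack a CA atom; skipped",
                stacklevel=2,
            )
        if chain_ca.array_length() == 0:
            continue
        order = np.argsort(chain_ca.res_id, kind="stable")
        chain_ca = chain_ca[order]
        seq = "".join(_three_to_one(rn) for rn in chain_ca.res_name)
        records.append(
            ChainRecord(
                chain_id=str(chain_id),
                sequence=seq,
                residue_numbers=[int(r) for r in chain_ca.res_id],
                coords=chain_ca.coord.astype(float),
            )
        )
    return records


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except Exception:
        return "X"


def _one_to_three(letter: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(letter)
    except Exception:
        return "UNK"


def write_ca_pdb(model: CaModel, path) -> None:
    """Write a CaModel as a Cα-only PDB (one HETATM ZN per placed zinc)."""
    if not np.isfinite(model.coords).all():
        raise ValueError("model contains non-finite coordinates")
    if model.zinc is not None and not np.isfinite(model.zinc).all():
        raise ValueError("zinc sites contain non-finite coordinates")
    n_zn = 0 if model.zinc is None else len(model.zinc)
    n = model.topology.n_residues + n_zn
    atoms = struc.AtomArray(n)
    pos = 0
    for chain in model.topology.chains:
        if len(chain.chain_id) != 1:
            raise ValueError(
                f"PDB chain ids must be one character, got {chain.chain_id!r}"
            )
        for i, resnum in enumerate(chain.residue_numbers):
            atoms.chain_id[pos] = chain.chain_id
            atoms.res_id[pos] = resnum
            atoms.res_name[pos] = (
                _one_to_three(chain.sequence[i]) if chain.sequence else "UNK"
            )
            atoms.atom_name[pos] = "CA"
            atoms.element[pos] = "C"
            atoms.hetero[pos] = False
            pos += 1
    atoms.coord[: model.topology.n_residues] = model.coords
    for k in range(n_zn):
        atoms.chain_id[pos] = "z"
        atoms.res_id[pos] = k + 1
        atoms.res_name[pos] = "ZN"
        atoms.atom_name[pos] = "ZN"
        atoms.element[pos] = "ZN"
        atoms.hetero[pos] = True
        atoms.coord[pos] = model.zinc[k]
        pos += 1
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def records_from_model(model: CaModel) -> list[ChainRecord]:
    return [
        ChainRecord(
            chain_id=c.chain_id,
            sequence=c.sequence if c.sequence else "X" * c.n_residues,
            residue_numbers=list(c.residue_numbers),
            coords=model.chain_coords(c.chain_id).copy(),
        )
        for c in model.topology.chains
    ]


def model_from_records(
    records: list[ChainRecord],
    copy_groups: dict[str, str] | None = None,
) -> CaModel:
    """Assemble a CaModel from chain records (all must carry coordinates).

    ``copy_groups`` optionally maps chain ids to copy-group names."""
    copy_groups = copy_groups or {}
    chains = []
    coords = []
    for rec in records:
        if rec.coords is None:
            raise ValueError(f"chain {rec.chain_id!r} has no coordinates")
        chains.append(
            ChainSpec(
                chain_id=rec.chain_id,
                residue_numbers=tuple(rec.residue_numbers),
                copy_group=copy_groups.get(rec.chain_id),
                sequence=rec.sequence,
            )
        )
        coords.append(rec.coords)
    return CaModel(ComplexTopology(tuple(chains)), np.vstack(coords))


# ---------------------------------------------------------------------------
# restraint tables
# ---------------------------------------------------------------------------


class RestraintTable:
    """Validated table of typed residue-pair restraints.

    Wraps a pandas DataFrame with columns ``chain_a res_a chain_b res_b class
    probability upper_bound``.  Chain fields may name either a chain id or a
    copy-equivalence group.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in RESTRAINT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"restraint table missing columns: {missing}")
        df = df.loc[:, list(RESTRAINT_COLUMNS)].reset_index(drop=True)
        for col in ("res_a", "res_b"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        for col in ("probability", "upper_bound"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("chain_a", "chain_b"):
            df[col] = df[col].astype(str)

        bad = set(df["class"]) - set(RESTRAINT_CLASSES)
        if bad:
            raise ValueError(
                f"unknown restraint class(es) {sorted(bad)}; "
                f"allowed: {list(RESTRAINT_CLASSES)}"
            )
        selfpair = (df["chain_a"] == df["chain_b"]) & (df["res_a"] == df["res_b"])
        if selfpair.any():
            raise ValueError(f"self-pairs at rows {list(df.index[selfpair])}")
        is_contact = df["class"].isin(_CONTACT_CLASSES)
        if df.loc[~is_contact, "probability"].notna().any():
            raise ValueError("probability is only allowed on contact classes")
        if df.loc[is_contact, "probability"].isna().any():
            raise ValueError("contact rows require a probability")
        p = df.loc[is_contact, "probability"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must be in [0, 1]")
        ub = df["upper_bound"].dropna()
        if (ub <= 0).any():
            raise ValueError("upper bounds must be positive")
        self.df = df

    @classmethod
    def from_records(cls, rows: list[dict]) -> "RestraintTable":
        df = pd.DataFrame(rows, columns=list(RESTRAINT_COLUMNS))
        return cls(df)

    @classmethod
    def empty(cls) -> "RestraintTable":
        return cls(pd.DataFrame(columns=list(RESTRAINT_COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    def class_counts(self) -> dict[str, int]:
        counts = self.df["class"].value_counts().to_dict()
        return {cls: int(counts.get(cls, 0)) for cls in RESTRAINT_CLASSES}

    def __eq__(self, other) -> bool:
        if not isinstance(other, RestraintTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.df, other.df, check_dtype=False)
        except AssertionError:
            return False
        return True


def read_restraints(path) -> RestraintTable:
    df = pd.read_csv(path, sep="\t", dtype={"chain_a": str, "chain_b": str})
    return RestraintTable(df)


def write_restraints(table: RestraintTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# built-in inhibition-complex fixture
# ---------------------------------------------------------------------------

# Engineered Cys–Cys pairs probed by disulfide cross-linking.  Site 214 of the
# protease interdomain linker is reported with an ambiguous amino-acid
# identity (A214/Y214) in the source experiments; only the position is stored
# and the identity is deliberately left unresolved.
_POSITIVE_PAIRS = (
    ("FB", 44, "BofA", 46),
    ("FB", 135, "BofA", 46),
    ("FB", 231, "sigK", 97),
    ("FB", 44, "sigK", 20),
    ("FB", 44, "sigK", 24),
    ("FB", 70, "sigK", 18),
    ("FB", 70, "sigK", 24),
    ("FB", 214, "sigK", 41),
)
_NEGATIVE_PAIRS = (
    ("FB", 70, "BofA", 46),
    ("FB", 44, "sigK", 18),
    ("FB", 44, "sigK", 21),
)


@dataclass(frozen=True)
class InhibitionComplexFixture:
    """Topology + cross-link network of the protease inhibition complex."""

    topology: ComplexTopology
    restraints: RestraintTable
    protease_group: str = "FB"
    zinc_ligand_residues: tuple[int, ...] = (137, 43, 47)
    crosslink_bound: float = 12.0
    notes: str = (
        "Cross-link site 214 (protease interdomain linker) is stored by "
        "position only; its amino-acid identity is reported ambiguously "
        "(A214/Y214) and is not resolved here."
    )

    def checksum(self) -> str:
        """SHA-256 over a canonical serialization of the fixture content."""
        payload = {
            "chains": [
                [
                    c.chain_id,
                    c.group,
                    int(c.residue_numbers[0]),
                    int(c.residue_numbers[-1]),
                ]
                for c in self.topology.chains
            ],
            "restraints": sorted(
                [
                    str(r["chain_a"]),
                    int(r["res_a"]),
                    str(r["chain_b"]),
                    int(r["res_b"]),
                    str(r["class"]),
                    float(r["upper_bound"]),
                ]
                for _, r in self.restraints.df.iterrows()
            ),
        }
        blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()


def load_inhibition_complex(crosslink_bound: float = 12.0) -> InhibitionComplexFixture:
    """The built-in study system: protease tetramer (chains A–D, group
    ``FB``, residues 1–288), one inhibitor BofA (chain E, 1–87), the
    substrate C-terminal part Pro-σK 38–114 (chain F, group ``sigK``) and
    SpoIVFA 65–111 (chain G, group ``FA``); eight positive and three negative
    cross-link pairs.  Deterministic; ``crosslink_bound`` (Å, Cα–Cα) is the
    only parameter."""
    topology = ComplexTopology(
        chains=(
            contiguous_chain("A", 1, 288, copy_group="FB"),
            contiguous_chain("B", 1, 288, copy_group="FB"),
            contiguous_chain("C", 1, 288, copy_group="FB"),
            contiguous_chain("D", 1, 288, copy_group="FB"),
            contiguous_chain("E", 1, 87, copy_group="BofA"),
            contiguous_chain("F", 38, 114, copy_group="sigK"),
            contiguous_chain("G", 65, 111, copy_group="FA"),
        )
    )
    rows = [
        {
            "chain_a": a,
            "res_a": ra,
            "chain_b": b,
            "res_b": rb,
            "class": "crosslink_positive",
            "probability": np.nan,
            "upper_bound": crosslink_bound,
        }
        for (a, ra, b, rb) in _POSITIVE_PAIRS
    ] + [
        {
            "chain_a": a,
            "res_a": ra,
            "chain_b": b,
            "res_b": rb,
            "class": "crosslink_negative",
            "probability": np.nan,
            "upper_bound": crosslink_bound,
        }
        for (a, ra, b, rb) in _NEGATIVE_PAIRS
    ]
    return InhibitionComplexFixture(
        topology=topology,
        restraints=RestraintTable.from_records(rows),
        crosslink_bound=crosslink_bound,
    )
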