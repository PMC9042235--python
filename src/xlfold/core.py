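"""Core containers: chain topology and the coarse-grained Cα model.

The pipeline represents a protein complex as one bead per residue at the Cα
position.  A :class:`ComplexTopology` describes which chains exist, their
author residue numbering, copy-equivalence groups (chemically identical
subunits of a homo-oligomer, e.g. the four protease subunits of a tetramer)
and membrane-embedded residues.  A :class:`CaModel` couples a topology with
one 3-D coordinate per residue, stored in a single ``(N, 3)`` array ordered
chain by chain.

Residues are addressed throughout by ``(chain_label, author_number)``; a label
may be either a chain id or a copy-group name, in which case it refers to all
copies at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class ChainSpec:
    """One chain: id, author residue numbers, optional sequence/annotations.

    ``copy_group`` names the equivalence class of chemically identical copies;
    it defaults to the chain id (a single-copy chain is its own group).
    ``membrane_residues`` flags residues annotated as membrane-embedded.
    """

    chain_id: str
    residue_numbers: tuple[int, ...]
    copy_group: str | None = None
    sequence: str | None = None
    membrane_residues: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        nums = self.residue_numbers
        if len(nums) == 0:
            raise ValueError(f"chain {self.chain_id!r} has no residues")
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError(
                f"chain {self.chain_id!r}: residue numbers must be strictly increasing"
            )
        if self.sequence is not None and len(self.sequence) != len(nums):
            raise ValueError(
                f"chain {self.chain_id!r}: sequence length {len(self.sequence)} "
                f"!= {len(nums)} residues"
            )
        extra = self.membrane_residues - set(nums)
        if extra:
            raise ValueError(
                f"chain {self.chain_id!r}: membrane residues {sorted(extra)} not in chain"
            )

    @property
    def group(self) -> str:
        return self.copy_group if self.copy_group is not None else self.chain_id

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)


def contiguous_chain(
    chain_id: str,
    first: int,
    last: int,
    copy_group: str | None = None,
    sequence: str | None = None,
    membrane_residues: frozenset[int] = frozenset(),
) -> ChainSpec:
    """Convenience constructor for a chain numbered ``first..last`` inclusive."""
    return ChainSpec(
        chain_id=chain_id,
        residue_numbers=tuple(range(first, last + 1)),
        copy_group=copy_group,
        sequence=sequence,
        membrane_residues=membrane_residues,
    )


@dataclass(frozen=True)
class ComplexTopology:
    chains: tuple[ChainSpec, ...]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chain ids in topology")

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(c.chain_id for c in self.chains)

    @property
    def n_residues(self) -> int:
        return sum(c.n_residues for c in self.chains)

    def chain(self, chain_id: str) -> ChainSpec:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in topology")

    def copies(self, label: str) -> tuple[str, ...]:
        """Chain ids addressed by ``label`` (a chain id or a copy-group name)."""
        ids = tuple(c.chain_id for c in self.chains if c.chain_id == label)
        if ids:
            return ids
        ids = tuple(c.chain_id for c in self.chains if c.group == label)
        if not ids:
            raise KeyError(f"label {label!r} matches no chain or copy group")
        return ids

    def subset(self, present: dict[str, frozenset[int] | None]) -> "ComplexTopology":
        """Topology restricted to ``present`` chains (optionally to a residue
        subset per chain; ``None`` keeps the full chain).  Chain order is
        preserved."""
        chains = []
        for c in self.chains:
            if c.chain_id not in present:
                continue
            keep = present[c.chain_id]
            if keep is None:
                chains.append(c)
                continue
            idx = [i for i, r in enumerate(c.residue_numbers) if r in keep]
            if not idx:
                continue
            chains.append(
                ChainSpec(
                    chain_id=c.chain_id,
                    residue_numbers=tuple(c.residue_numbers[i] for i in idx),
                    copy_group=c.copy_group,
                    sequence=(
                        "".join(c.sequence[i] for i in idx) if c.sequence else None
                    ),
                    membrane_residues=c.membrane_residues & keep,
                )
            )
        return ComplexTopology(chains=tuple(chains))


class CaModel:
    """Coordinates (one bead per residue) bound to a topology.

    ``coords`` is ``(N, 3)`` float64 in Å, rows ordered by topology chain
    order then residue order.  ``zinc`` optionally holds ``(k, 3)`` positions
    of placed Zn²⁺ pseudo-atoms.
    """

    def __init__(
        self,
        topology: ComplexTopology,
        coords: np.ndarray,
        zinc: np.ndarray | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (topology.n_residues, 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({topology.n_residues}, 3)"
            )
        self.topology = topology
        self.coords = coords
        self.zinc = None if zinc is None else np.asarray(zinc, dtype=float)
        offsets: dict[str, int] = {}
        index: dict[str, dict[int, int]] = {}
        pos = 0
        for c in topology.chains:
            offsets[c.chain_id] = pos
            index[c.chain_id] = {r: pos + i for i, r in enumerate(c.residue_numbers)}
            pos += c.n_residues
        self._offsets = offsets
        self._index = index

    # -- addressing -------------------------------------------------------
    def index(self, chain_id: str, resnum: int) -> int:
        try:
            return self._index[chain_id][resnum]
        except KeyError:
            raise KeyError(f"residue {chain_id}:{resnum} not in model") from None

    def has(self, chain_id: str, resnum: int) -> bool:
        return chain_id in self._index and resnum in self._index[chain_id]

    def chain_slice(self, chain_id: str) -> slice:
        start = self._offsets[chain_id]
        return slice(start, start + self.topology.chain(chain_id).n_residues)

    def chain_coords(self, chain_id: str) -> np.ndarray:
        return self.coords[self.chain_slice(chain_id)]

    # -- functional updates ----------------------------------------------
    def with_coords(self, coords: np.ndarray) -> "CaModel":
        return CaModel(self.topology, coords, zinc=self.zinc)

    def with_zinc(self, zinc: np.ndarray | None) -> "CaModel":
        return CaModel(self.topology, self.coords, zinc=zinc)

    def copy(self) -> "CaModel":
        return CaModel(
            self.topology,
            self.coords.copy(),
            zinc=None if self.zinc is None else self.zinc.copy(),
        )


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Cα RMSD between two ``(N, 3)`` coordinate sets after optimal
    (proper-rotation) superposition of ``b`` onto ``a``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(ac, bc)
    diff = ac - rot.apply(bc)
    return float(np.sqrt((diff**2).sum() / len(a)))
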