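import numpy as np
import pytest

from xlfold.core import CaModel, ChainSpec, ComplexTopology


def make_model(chains: dict[str, np.ndarray], groups: dict[str, str] | None = None,
               first_residue: int = 1) -> CaModel:
    """Build a CaModel from {chain_id: (n,3) coords}; residues numbered from
    ``first_residue``."""
    groups = groups or {}
    specs = []
    coords = []
    for cid, xyz in chains.items():
        xyz = np.asarray(xyz, float)
        specs.append(
            ChainSpec(
                chain_id=cid,
                residue_numbers=tuple(range(first_residue, first_residue + len(xyz))),
                copy_group=groups.get(cid),
            )
        )
        coords.append(xyz)
    return CaModel(ComplexTopology(tuple(specs)), np.vstack(coords))


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def two_bead_model():
    """Two single-residue chains 20 Å apart."""
    return make_model({"A": [[0.0, 0.0, 0.0]], "B": [[20.0, 0.0, 0.0]]})


def random_model(rng, n_chains=2, n_res=8, spread=25.0) -> CaModel:
    chains = {}
    for c in range(n_chains):
        cid = chr(ord("A") + c)
        base = rng.uniform(-spread, spread, 3)
        steps = rng.normal(0, 1, (n_res, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        chains[cid] = base + np.cumsum(3.8 * steps, axis=0)
    return make_model(chains)
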