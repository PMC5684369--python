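import numpy as np
import pytest

from widedock import Branch, LigandAtom, TorsionTree


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_chain_tree(n_heavy: int = 6, n_rot: int = 3) -> TorsionTree:
    """Zigzag carbon chain with ``n_rot`` nested rotatable bonds."""
    coords = np.array([[1.4 * i, 0.7 * (i % 2), 0.05 * i]
                       for i in range(n_heavy)], float)
    atoms = [LigandAtom(element="C", coords=c, name=f"C{i+1}", serial=i + 1,
                        ad_type="C") for i, c in enumerate(coords)]
    n_root = n_heavy - n_rot
    branches = [Branch(parent=n_root - 1 + k, child=n_root + k,
                       moved=list(range(n_root + k, n_heavy)))
                for k in range(n_rot)]
    tree = TorsionTree(atoms=atoms, root_atoms=list(range(n_root)),
                       branches=branches, torsdof=n_rot)
    tree.validate()
    return tree


@pytest.fixture
def chain_tree():
    return make_chain_tree()
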