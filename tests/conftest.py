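import numpy as np
import pytest

from allokit.constants import mass_of
from allokit.scenario import default_scaffold
from allokit.synthetic import build_ideal_helix, build_toy_receptor
from allokit.trajectory import Ensemble, Topology


def make_topology(spec):
    """Build a Topology from (atom_name, element, res_name, res_id, chain) rows."""
    names, elements, res_names, res_ids, chains = zip(*spec)
    return Topology(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_names=np.array(res_names, dtype=object),
        res_ids=np.array(res_ids, dtype=int),
        chain_ids=np.array(chains, dtype=object),
        masses=np.array([mass_of(e) for e in elements]),
    )


@pytest.fixture(scope="session")
def peptide_topology():
    """5-residue backbone-only peptide with one arginine side chain."""
    rows = []
    res_names = ["ALA", "ARG", "GLY", "ASP", "ALA"]
    for i, rn in enumerate(res_names, start=1):
        for an, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            rows.append((an, el, rn, i, "A"))
    rows.append(("CZ", "C", "ARG", 2, "A"))
    rows.append(("CG", "C", "ASP", 4, "A"))
    return make_topology(rows)


@pytest.fixture(scope="session")
def peptide_ensemble(peptide_topology):
    rng = np.random.default_rng(42)
    coords = rng.uniform(0.0, 20.0, size=(3, peptide_topology.n_atoms, 3))
    return Ensemble(peptide_topology, coords)


@pytest.fixture(scope="session")
def helix22():
    return build_ideal_helix(22)


@pytest.fixture(scope="session")
def toy_receptor():
    return build_toy_receptor(default_scaffold())


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
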