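import numpy as np
import pytest

from bilayerlab.structures import Configuration


def random_hbond_configuration(rng, n_units=30, box=(3.0, 3.0, 3.0)):
    """Random periodic donor/H/acceptor soup for oracle cross-checks.

    Each unit is one donor–hydrogen molecule plus one free acceptor
    molecule, placed uniformly in the box so some donor–acceptor pairs bond
    across the periodic boundary.
    """
    box = np.asarray(box)
    pos, mol, roles = [], [], []
    m = 0
    for _ in range(n_units):
        m += 1
        d = rng.uniform(0, 1, 3) * box
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        pos += [d, d + 0.1 * direction]
        mol += [m, m]
        roles += ["donor", "hydrogen"]
        m += 1
        pos.append(rng.uniform(0, 1, 3) * box)
        mol.append(m)
        roles.append("acceptor")
    n = len(pos)
    return Configuration(
        positions=np.array(pos), box=box, mol_ids=np.array(mol),
        mol_kinds=np.array(["water"] * n, dtype=object),
        roles=np.array(roles, dtype=object), masses=np.ones(n),
    )


def random_solute_configuration(rng, n_mols=12, atoms_per_mol=3,
                                box=(2.5, 2.5, 2.5)):
    """Random periodic multi-atom solute molecules for cluster oracle checks."""
    box = np.asarray(box)
    pos, mol = [], []
    for m in range(1, n_mols + 1):
        center = rng.uniform(0, 1, 3) * box
        for _ in range(atoms_per_mol):
            pos.append(center + rng.uniform(-0.08, 0.08, 3))
            mol.append(m)
    n = len(pos)
    return Configuration(
        positions=np.array(pos), box=box, mol_ids=np.array(mol),
        mol_kinds=np.array(["solute"] * n, dtype=object),
        roles=np.array(["other"] * n, dtype=object), masses=np.ones(n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
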