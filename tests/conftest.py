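"""Shared fixtures: synthetic datasets and trained toy potentials.

Training fixtures are session-scoped so the (seconds-long) fits are paid once.
"""

import numpy as np
import pytest

import walklrp as w


@pytest.fixture(scope="session")
def morse() -> w.PairPotentialParams:
    return w.PairPotentialParams()  # D = 3 kcal/mol, r_e = 1.5 Å, a = 1.2 /Å


@pytest.fixture(scope="session")
def cluster6_data(morse):
    """200 Morse-labelled 6-atom clusters (the standard training ensemble)."""
    spec = w.GeneratorSpec(
        topology="random_cluster", n_atoms=6, min_distance=1.1, n_samples=200, seed=7
    )
    return w.label_conformers(w.generate_conformers(spec), morse)


@pytest.fixture(scope="session")
def trained6(cluster6_data):
    """Depth-2 potential fitted to the 6-atom Morse ensemble."""
    return w.MessagePassingPotential(
        depth=2,
        cutoff=4.0,
        embedding_dim=16,
        filter_hidden=16,
        readout_hidden=16,
        epochs=400,
        lr=8e-3,
        seed=0,
        checkpoint_epochs=(0,),
    ).fit(cluster6_data, [c.energy for c in cluster6_data])


@pytest.fixture(scope="session")
def trained9(morse):
    """Depth-2 potential on 9-atom clusters whose diameter exceeds the cutoff,
    so distant pairs are only reachable through multi-hop walks."""
    spec = w.GeneratorSpec(
        topology="random_cluster",
        n_atoms=9,
        min_distance=1.1,
        box_length=6.0,
        n_samples=120,
        seed=11,
    )
    data = w.label_conformers(w.generate_conformers(spec), morse)
    return w.MessagePassingPotential(
        depth=2,
        cutoff=3.5,
        embedding_dim=12,
        filter_hidden=12,
        readout_hidden=12,
        epochs=250,
        lr=8e-3,
        seed=1,
    ).fit(data, [c.energy for c in data])


@pytest.fixture(scope="session")
def cluster9_test(morse):
    spec = w.GeneratorSpec(
        topology="random_cluster",
        n_atoms=9,
        min_distance=1.1,
        box_length=6.0,
        n_samples=15,
        seed=99,
    )
    return w.label_conformers(w.generate_conformers(spec), morse)


@pytest.fixture()
def small_cluster():
    return w.generate_conformers(
        w.GeneratorSpec(
            topology="random_cluster", n_atoms=6, min_distance=1.0, n_samples=1, seed=5
        )
    )[0]


@pytest.fixture()
def small_config():
    return w.ModelConfig(
        depth=2,
        cutoff=4.0,
        embedding_dim=8,
        filter_hidden=8,
        readout_hidden=8,
        elements=("C",),
    )
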