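from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from molcluster.model_io import (
    BindingRule,
    ModelSpec,
    MoleculeType,
    ObservableDef,
    SeedSpecies,
    SimParams,
)


def make_model(
    molecule_types,
    seeds,
    rules,
    observables=(),
    t_end=10.0,
    n_steps=10,
    n_runs=1,
    seed=1,
):
    return ModelSpec(
        molecule_types=tuple(molecule_types),
        seeds=tuple(seeds),
        rules=tuple(rules),
        observables=tuple(observables),
        sim_params=SimParams(t_end=t_end, n_steps=n_steps, n_runs=n_runs, seed=seed),
    )


@pytest.fixture
def ab_model():
    """A(a) + B(b) <-> A(a!1).B(b!1): single-site heterodimerization."""
    return make_model(
        [MoleculeType("A", ("a",)), MoleculeType("B", ("b",))],
        [SeedSpecies("A", 10), SeedSpecies("B", 10)],
        [BindingRule("R1", ("A", "a"), ("B", "b"), 1.0, 1.0)],
        [ObservableDef("A_free", "free_molecule", "A"),
         ObservableDef("bonds", "bond_count", "R1")],
    )


@pytest.fixture
def chain_model():
    """A(a) monovalent, B(b1,b2) bivalent: supports A-B-A chains."""
    return make_model(
        [MoleculeType("A", ("a",)), MoleculeType("B", ("b1", "b2"))],
        [SeedSpecies("A", 10), SeedSpecies("B", 5)],
        [
            BindingRule("R1", ("A", "a"), ("B", "b1"), 1.0, 0.5),
            BindingRule("R2", ("A", "a"), ("B", "b2"), 1.0, 0.5),
        ],
    )


@pytest.fixture
def nnn_model():
    from molcluster.examples import load_example

    return load_example("nephrin_nck_nwasp")


@pytest.fixture
def nnn_weak_model():
    from molcluster.examples import load_example

    return load_example("nephrin_nck_nwasp_weak")


@pytest.fixture
def dimer_model():
    from molcluster.examples import load_example

    return load_example("dimer")
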