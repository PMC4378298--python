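import pytest

from lfo_gcnet import NetworkSpec, default_network, simulate_var


@pytest.fixture(scope="session")
def base_network():
    return default_network()


@pytest.fixture(scope="session")
def unidirectional_spec():
    """x drives y with coefficient 0.4 at lag 1; both self-regress at 0.5."""
    return NetworkSpec(
        region_names=("x", "y"),
        edges=(("x", "y", 0.4, 1),),
        ar_self=0.5,
        tr_s=2.0,
    )


@pytest.fixture(scope="session")
def decoupled_spec():
    return NetworkSpec(region_names=("x", "y"), edges=(), ar_self=0.5, tr_s=2.0)


@pytest.fixture(scope="session")
def long_unidirectional_series(unidirectional_spec):
    return simulate_var(unidirectional_spec, 10_000, seed=2024)

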