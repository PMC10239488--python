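import pytest

from repeatlens import synthetic_data as sim


@pytest.fixture(scope="session")
def truth():
    """One deterministic simulated genome with the default composition."""
    return sim.place_insertions(sim.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def emitted(truth, tmp_path_factory):
    """The same genome emitted as .out/.align/FASTA files."""
    prefix = tmp_path_factory.mktemp("emitted") / "species"
    return sim.emit_annotation(truth, prefix)


@pytest.fixture(scope="session")
def domain_profiles():
    from repeatlens.orf_screen import load_domain_profiles

    return load_domain_profiles()
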