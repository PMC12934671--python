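import pytest
from hypothesis import settings

from kinactive.fixtures import all_pass_spec, build_toy_kinase, violation_specs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_active():
    """All-pass nonTYR toy kinase: (model, motif map, residual report)."""
    return build_toy_kinase(all_pass_spec("nonTYR", seed=0))


@pytest.fixture(scope="session")
def toy_active_tyr():
    return build_toy_kinase(all_pass_spec("TYR", seed=0))


@pytest.fixture(scope="session")
def toy_active_noape():
    return build_toy_kinase(all_pass_spec("noAPE", seed=0))


@pytest.fixture(scope="session")
def toy_violations():
    """name -> (model, map, report) with exactly one criterion violated each."""
    return {
        name: build_toy_kinase(spec) for name, spec in violation_specs("nonTYR").items()
    }


@pytest.fixture(scope="session")
def toy_with_ctd():
    """All-pass toy kinase extended with a 40-residue C-lobe tail (for RMSD work)."""
    return build_toy_kinase(all_pass_spec("nonTYR", seed=0, ctd_residues=40))
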