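import pytest

from bindgate import CompetitionCurveSpec, LigandSpec, ReceptorModel, default_grid

# Canonical ligands of the assay: an inverse-agonist labeled toxin, an
# inverse-agonist small-molecule competitor, an affinity-switching agonist,
# and a closed-state-stabilizing allosteric modulator.

LABEL = LigandSpec("toxin", "orthosteric", kd_closed=1e-9, kd_open=1e-8)
INVERSE = LigandSpec("mla", "orthosteric", kd_closed=5e-9, kd_open=5e-8)
AGONIST = LigandSpec("nicotine", "orthosteric", kd_closed=1e-6, kd_open=1e-8)
NAM = LigandSpec("ivm", "allosteric", kd_closed=1e-6, kd_open=1e-5)


@pytest.fixture
def closed_receptor() -> ReceptorModel:
    """Predominantly closed receptor with toxin + inverse-agonist competitor."""
    return ReceptorModel(gating_unliganded=1e-6, ligands=(LABEL, INVERSE),
                         n_ortho=5, n_allo=0)


@pytest.fixture
def agonist_receptor() -> ReceptorModel:
    """Receptor whose agonist saturation flips it open (1e-4 * 100**5 >> 1)."""
    return ReceptorModel(gating_unliganded=1e-4, ligands=(LABEL, AGONIST),
                         n_ortho=5, n_allo=0)


@pytest.fixture
def modulated_receptor() -> ReceptorModel:
    """Agonist-competition receptor carrying allosteric modulator sites."""
    return ReceptorModel(gating_unliganded=1e-4, ligands=(LABEL, AGONIST, NAM),
                         n_ortho=5, n_allo=5)


@pytest.fixture
def inverse_spec() -> CompetitionCurveSpec:
    return CompetitionCurveSpec(label="toxin", competitor="mla",
                                competitor_grid=default_grid(1e-11, 1e-6, 25))


@pytest.fixture
def agonist_spec() -> CompetitionCurveSpec:
    return CompetitionCurveSpec(label="toxin", competitor="nicotine",
                                competitor_grid=default_grid(1e-10, 1e-4, 33))
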