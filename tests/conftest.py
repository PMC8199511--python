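import numpy as np
import pytest

from elfx.fixtures import builtin_geometry
from elfx.wavefunction import compute_wavefunction


@pytest.fixture(scope="session")
def water_wf():
    """HF/STO-3G water wavefunction (shared, ~1 s)."""
    return compute_wavefunction(builtin_geometry("water"))


@pytest.fixture(scope="session")
def water_sites():
    """Water reactive-site model at the default desk-scale settings."""
    from elfx.pipeline import site_model_for
    model, diag = site_model_for("water", spacing=0.25, margin=5.0)
    return model, diag


@pytest.fixture(scope="session")
def gc_pipeline(tmp_path_factory):
    """Full guanine+cytosine pipeline at the acceptance conditions.

    Expensive (several minutes); shared by every test that inspects the
    base-pair scan.
    """
    from elfx.pipeline import run_pipeline
    out = tmp_path_factory.mktemp("gcrun")
    return run_pipeline({"basis": "sto-3g+"}, out_dir=out)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
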