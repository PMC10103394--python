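import warnings

import pytest

import gliostage as gs

warnings.filterwarnings("ignore", message="zero-centering a sparse")


@pytest.fixture(scope="session")
def bulk_sim():
    """Default-condition bulk cohort (4 groups x 30 samples, seed 42)."""
    return gs.simulate_bulk_cohort(gs.SimConfig(seed=42))


@pytest.fixture(scope="session")
def sc_sim():
    """Default single-cell mixture: 500 malignant + contaminants, seed 42."""
    return gs.simulate_single_cell(gs.SimConfig(seed=42))


@pytest.fixture(scope="session")
def sc_pipeline(sc_sim):
    """QC -> normalize/embed/cluster on the default single-cell mixture."""
    filtered, report = gs.qc_filter(sc_sim.counts)
    emb = gs.normalize_and_embed(filtered, seed=7)
    return filtered, report, emb


@pytest.fixture(scope="session")
def methyl_sim():
    return gs.simulate_methylomes(gs.SimConfig(seed=42))
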