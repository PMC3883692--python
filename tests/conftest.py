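import numpy as np
import pytest

import diallelome as dm


@pytest.fixture(scope="session")
def design4():
    """The study layout: 4 parents, 12 reciprocal hybrids, 6 reps, 3 batches."""
    return dm.make_design(["P1", "P2", "P3", "P4"], n_replicates=6, n_batches=3)


@pytest.fixture(scope="session")
def strong_fixture(design4):
    """Planted dataset with strong effects: 24 metabolites, 6 drivers, 12 driven."""
    table, truth = dm.simulate_dataset(
        design4, m=24, n_drivers=6, n_driven=12, effect_size=5.0,
        noise_sd=0.1, batch_sd=0.1, seed=11,
    )
    return table, truth


@pytest.fixture(scope="session")
def strong_pipeline(design4, strong_fixture):
    """Normalized table, balanced CRL matrix and X_pp for the strong fixture."""
    table, truth = strong_fixture
    normalized, report = dm.normalize_pipeline(table)
    crl = dm.balance_filter(dm.assign_labels(normalized, None, design4))
    xpp = dm.build_xpp(normalized, design4, seed=11)
    return {
        "table": table,
        "truth": truth,
        "normalized": normalized,
        "report": report,
        "crl": crl,
        "xpp": xpp,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
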