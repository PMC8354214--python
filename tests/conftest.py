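import numpy as np
import pytest

from mrbiom import core_io, diffexpr
from mrbiom.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic study, shared read-only across tests."""
    return simulate_cohort(SimConfig(seed=3))


@pytest.fixture(scope="session")
def discovery(cohort):
    """Discovery-cohort sample table (paired 20+20)."""
    t = cohort.samples.table
    return core_io.SampleTable(t[t["cohort"] == "discovery"].copy())


@pytest.fixture(scope="session")
def de_matrices(cohort, discovery):
    """DE-screened expression matrices restricted to discovery samples."""
    keep = discovery.sample_ids
    mats = {
        "mRNA": cohort.mrna.subset_samples(keep),
        "miRNA": cohort.mirna.subset_samples(keep),
        "lncRNA": cohort.lncrna.subset_samples(keep),
    }
    results = diffexpr.screen_all_classes(
        mats["mRNA"], mats["miRNA"], mats["lncRNA"], discovery
    )
    out = {}
    for cls in mats:
        ids = [r.feature_id for r in results[cls]]
        out[cls] = core_io.subset_features(mats[cls], ids)
    out["results"] = results
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_expression(rng, n_features=5, n_samples=6, prefix="f"):
    values = rng.uniform(0.5, 100.0, size=(n_features, n_samples))
    return core_io.ExpressionMatrix(
        [f"{prefix}{i}" for i in range(n_features)],
        [f"s{j}" for j in range(n_samples)],
        values,
    )
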