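import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methylage.cohort import Cohort
from methylage.panel import CpGPanel, CpGSite, load_default_panel
from methylage.simulate import default_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def null_scenario():
    # session-scoped: noise calibration is cached but still worth sharing
    return default_scenario("null")


@pytest.fixture(scope="session")
def shifted_scenario():
    return default_scenario("two_shifted")


def make_panel(n_sites: int = 3) -> CpGPanel:
    """Small synthetic panel for unit tests that do not need the default 22 sites."""
    return CpGPanel(
        [
            CpGSite(
                gene=f"GENE{j + 1}",
                cpg_index=1,
                chrom="Chr.1",
                position=1000 + j,
                probe_id=None,
                direction=1,
                r_german=0.9,
                r_japanese=0.9,
            )
            for j in range(n_sites)
        ]
    )


def make_cohort(panel, ages, sexes=None, populations=None, meth=None) -> Cohort:
    """Hand-built cohort from raw vectors; methylation defaults to 50%."""
    n = len(ages)
    data = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "population": populations if populations is not None else ["pop_a"] * n,
            "sex": sexes if sexes is not None else ["female"] * n,
            "age_years": np.asarray(ages, dtype=float),
        }
    )
    if meth is None:
        meth = np.full((n, len(panel)), 50.0)
    data[panel.columns] = np.asarray(meth, dtype=float)
    return Cohort(panel, data)
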