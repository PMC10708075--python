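import numpy as np
import pandas as pd
import pytest

from flavoromics import datasets
from flavoromics.profile import CompoundRecord, PeakTable
from flavoromics.simulate import generate_peak_table, make_preset


@pytest.fixture(scope="session")
def profiles():
    """Published mean ± SD relative-content profiles, keyed RS / RR."""
    return datasets.load_group_profiles()


@pytest.fixture(scope="session")
def rs_profile(profiles):
    return profiles["RS"]


@pytest.fixture(scope="session")
def rr_profile(profiles):
    return profiles["RR"]


@pytest.fixture(scope="session")
def thresholds():
    return datasets.load_thresholds()


@pytest.fixture(scope="session")
def vip_gini():
    return datasets.load_vip_gini()


@pytest.fixture
def tiny_table():
    """3 compounds x 4 samples in 2 groups, hand-checkable areas."""
    areas = pd.DataFrame(
        {
            "alpha": [2.0, 4.0, 1.0, 1.0],
            "beta": [3.0, 6.0, 1.0, 1.0],
            "gamma": [5.0, 10.0, 8.0, 8.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    groups = pd.Series(["g1", "g1", "g2", "g2"], index=areas.index)
    compounds = {
        "alpha": CompoundRecord("alpha", chem_class="ester"),
        "beta": CompoundRecord("beta", chem_class="ester"),
        "gamma": CompoundRecord("gamma", chem_class="aldehyde"),
    }
    return PeakTable(areas=areas, groups=groups, compounds=compounds)


@pytest.fixture(scope="session")
def signal_table():
    """One strong-signal synthetic table (4 planted discriminants)."""
    return generate_peak_table(make_preset("strong-signal"), seed=0)


@pytest.fixture(scope="session")
def planted_compounds():
    return sorted(make_preset("strong-signal").discriminant)
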