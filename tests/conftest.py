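import numpy as np
import pandas as pd
import pytest

from oronasal.simulate import CohortConfig, simulate_cohort
from oronasal.tables import AbundanceTable


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic paired cohort (90 samples, 60 genera)."""
    return simulate_cohort(CohortConfig(seed=11))


def make_table(values, taxa=None, samples=None, mode="counts"):
    values = np.asarray(values)
    taxa = taxa or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceTable(pd.DataFrame(values, index=taxa, columns=samples), mode)


def make_metadata(sample_ids, groups, niches, age_classes):
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [s.rsplit("_", 1)[0] for s in sample_ids],
            "group": groups,
            "niche": niches,
            "age_class": age_classes,
        }
    )
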