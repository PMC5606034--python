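import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rumenomics as rm

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SAMPLES = ["LC1", "LC2", "LC3", "MC1", "MC2", "MC3"]
GROUPS = pd.Series(["LC"] * 3 + ["MC"] * 3, index=SAMPLES, name="group")


def make_otu_table(counts: np.ndarray, otus=None, taxonomy=None) -> rm.OtuTable:
    """Small OtuTable with an automatic two-genus taxonomy."""
    otus = otus or [f"OTU_{j}" for j in range(counts.shape[1])]
    frame = pd.DataFrame(counts, index=SAMPLES[: counts.shape[0]], columns=otus)
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {
                "phylum": ["Firmicutes" if j % 2 == 0 else "Bacteroidetes"
                           for j in range(len(otus))],
                "genus": [f"Genus_{j % 2}" for j in range(len(otus))],
            },
            index=otus,
        )
    return rm.OtuTable(
        counts=frame, taxonomy=taxonomy, groups=GROUPS.loc[frame.index]
    )


def make_abundance(fractions: np.ndarray, taxa=None, groups=None) -> rm.AbundanceTable:
    taxa = taxa or [f"T{j}" for j in range(fractions.shape[1])]
    index = list(groups.index) if groups is not None else SAMPLES[: fractions.shape[0]]
    frame = pd.DataFrame(fractions, index=index, columns=taxa)
    g = groups if groups is not None else GROUPS.loc[frame.index]
    return rm.AbundanceTable(fractions=frame, groups=g)


@pytest.fixture(scope="session")
def study():
    """Default-condition synthetic study (3 animals per group)."""
    return rm.simulate_study(rm.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def abundance(study):
    return rm.relative_abundance(rm.filter_min_count(study.otu_table))
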