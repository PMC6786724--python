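import numpy as np
import pandas as pd
import pytest

from fmtselect import GenusAbundanceTable, SampleMetadata, TaxonPanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """3 samples x 4 genera, rows summing to 1."""
    data = pd.DataFrame(
        [
            [0.2, 0.1, 0.6, 0.1],
            [0.0, 0.5, 0.25, 0.25],
            [0.4, 0.4, 0.1, 0.1],
        ],
        index=["s1", "s2", "s3"],
        columns=["Faecalibacterium", "Roseburia", "Bacteroides", "Prevotella"],
    )
    return GenusAbundanceTable(data)


@pytest.fixture
def butyrate_pair_panel():
    return TaxonPanel("pair", frozenset({"Faecalibacterium", "Roseburia"}))


def random_composition(rng, n_samples, n_genera, prefix="G"):
    """A random valid relative-abundance table."""
    vals = rng.dirichlet(np.full(n_genera, 0.8), size=n_samples)
    return GenusAbundanceTable(
        pd.DataFrame(
            vals,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"{prefix}{j}" for j in range(n_genera)],
        )
    )


def linked_metadata(donor_ids, patient_ids, linked, responses):
    df = pd.DataFrame(
        {
            "role": ["donor"] * len(donor_ids) + ["patient"] * len(patient_ids),
            "study": "t",
            "response": [None] * len(donor_ids) + list(responses),
            "linked_donor": [None] * len(donor_ids) + list(linked),
        },
        index=list(donor_ids) + list(patient_ids),
    )
    return SampleMetadata(df)
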