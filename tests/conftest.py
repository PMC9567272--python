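import numpy as np
import pandas as pd
import pytest

from mycoflow import CohortSpec, FeatureTable, TaxonomyLineage, simulate_amplicon_cohort
from mycoflow.core_io import validate_metadata


@pytest.fixture
def tiny_metadata() -> pd.DataFrame:
    rows = [
        ("S1", "tissue", "breast tumor", "L1", 1.0),
        ("S2", "tissue", "breast tumor", "L1", 10.0),
        ("S3", "tissue", "colon tumor", "L2", 1.0),
        ("S4", "extraction_control", "", "L2", 1.0),
        ("S5", "paraffin_control", "", "L1", 1.0),
    ]
    md = pd.DataFrame(rows, columns=["sample_id", "sample_class", "condition",
                                     "library_id", "dilution_factor"])
    return validate_metadata(md)


@pytest.fixture
def tiny_table() -> FeatureTable:
    counts = pd.DataFrame(
        [[1500, 0, 2400, 0, 0],
         [999, 3000, 0, 1200, 0],
         [0, 0, 5000, 0, 2000]],
        index=["A1", "A2", "A3"],
        columns=["S1", "S2", "S3", "S4", "S5"],
        dtype=np.int64,
    )
    taxonomy = {
        "A1": TaxonomyLineage.from_string(
            "k__Fungi;p__Ascomycota;c__Sordariomycetes;o__Hypocreales;"
            "f__Nectriaceae;g__Fusarium;s__Fusarium_oxysporum"),
        "A2": TaxonomyLineage.from_string(
            "k__Fungi;p__Ascomycota;c__Dothideomycetes;o__Capnodiales;"
            "f__Cladosporiaceae;g__Cladosporium;s__"),
        "A3": TaxonomyLineage.from_string(
            "k__Fungi;p__Ascomycota;c__Dothideomycetes;o__Capnodiales;"
            "f__Cladosporiaceae;g__Cladosporium;s__"),
    }
    return FeatureTable(counts=counts, taxonomy=taxonomy)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused across tests (pure function of its spec)."""
    spec = CohortSpec(conditions={"breast tumor": 40, "colon tumor": 40},
                      n_extraction_controls=20, n_paraffin_controls=20,
                      seed=7)
    return simulate_amplicon_cohort(spec)
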