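import pandas as pd
import pytest

import phenochron as pc


@pytest.fixture(scope="session")
def graph():
    return pc.load_ontology(pc.fixture_path("mini_hp.obo"))


@pytest.fixture(scope="session")
def dictionary(graph):
    return pc.load_dictionary(pc.fixture_path("mini_dictionary.tsv"), graph)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic null cohort shared by mapping/temporal tests."""
    return pc.null_cohort(n=40, seed=7)


@pytest.fixture(scope="session")
def small_tensor(graph, dictionary, small_cohort):
    mapped, _ = pc.map_encounters(small_cohort.encounters, dictionary)
    windows = pc.usage_windows(small_cohort.encounters)
    return pc.build_presence(mapped, graph, pc.BinGrid(), windows)


def encounters_frame(rows):
    """rows: (individual_id, age_years, source_code, icd_code)"""
    return pd.DataFrame(rows, columns=["individual_id", "age_years", "source_code", "icd_code"])
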