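import pytest

from pvsignal import synthetic
from pvsignal.drug_mapping import DrugArchive


@pytest.fixture(scope="session")
def small_scenario():
    """A compact scenario with clone/aberrant injection left at defaults."""
    return synthetic.default_scenario(n_reports=800, seed=42)


@pytest.fixture(scope="session")
def small_tables(small_scenario):
    tables, truth = synthetic.generate(small_scenario)
    return tables, truth


@pytest.fixture(scope="session")
def archive(small_scenario):
    return synthetic.build_archive(small_scenario)


@pytest.fixture(scope="session")
def catalogue(small_scenario):
    return synthetic.build_catalogue(small_scenario)


@pytest.fixture(scope="session")
def tiny_archive():
    """Hand-built archive: the five TKIs plus decoys, brands and ATC."""
    return DrugArchive(
        entries={
            "Gleevec": "imatinib",
            "Glivec": "imatinib",
            "Tasigna": "nilotinib",
            "Sprycel": "dasatinib",
            "Bosulif": "bosutinib",
            "Iclusig": "ponatinib",
            "Taxol": "paclitaxel",
            "Dolorex": "paracetamive",
        },
        atc_index={
            "imatinib": {"L01XE01"},
            "nilotinib": {"L01XE08"},
            "dasatinib": {"L01XE06"},
            "bosutinib": {"L01XE14"},
            "ponatinib": {"L01XE24"},
            "paclitaxel": {"L01CD01"},
            "paracetamive": {"N02BE99"},
        },
    )
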