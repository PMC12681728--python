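import pandas as pd
import pytest

from g6pdscreen import SyntheticConfig, build_cohort, classify_table, generate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """One medium synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticConfig(n_participants=6000, seed=11))


@pytest.fixture(scope="session")
def analysis_rows(default_bundle):
    rows, ledger = build_cohort(
        default_bundle.participants,
        default_bundle.draws,
        default_bundle.genotypes,
    )
    return rows


@pytest.fixture(scope="session")
def screen_results(analysis_rows):
    return classify_table(analysis_rows)


@pytest.fixture()
def toy_draws():
    """Hand-built draw table for one participant with ties and boundaries."""
    return pd.DataFrame(
        {
            "participant_id": ["p1"] * 5,
            "draw_date": ["2014-01-01", "2015-06-01", "2012-03-01", "2016-01-01", "2013-01-01"],
            "glucose": [101.0, 88.0, 88.0, 95.0, 250.0],
            "hba1c": [5.5, 5.6, 5.7, 5.4, 7.0],
            "rdw": [13.0, 12.5, 12.0, 14.0, 13.5],
        }
    )
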