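import numpy as np
import pandas as pd
import pytest

import audiophen as ap
from audiophen.synthetic import AC_COLUMNS


@pytest.fixture(scope="session")
def demo_specs():
    """The nine illustrative subtypes at their default spread."""
    return ap.default_subtypes()


@pytest.fixture(scope="session")
def separated_pair():
    """Two spherical components 60 dB apart on every frequency."""
    return [
        ap.SubtypeSpec("low", 0.5, [10] * 6, np.eye(6) * 25.0),
        ap.SubtypeSpec("high", 0.5, [70] * 6, np.eye(6) * 25.0),
    ]


@pytest.fixture(scope="session")
def overlapping_pair():
    """Two heavily overlapping components (15 dB apart, sd 20 dB)."""
    return [
        ap.SubtypeSpec("a", 0.5, [30] * 6, np.eye(6) * 400.0),
        ap.SubtypeSpec("b", 0.5, [45] * 6, np.eye(6) * 400.0),
    ]


def curve_row(
    patient_id="P1",
    ear="L",
    test_date="2020-01-01",
    modality="AC",
    thresholds=(20, 20, 20, 20, 20, 20),
    age=50,
    sex="M",
    record_index=0,
):
    """One raw curve-table row; ``thresholds`` may contain None for missing."""
    row = {
        "patient_id": patient_id,
        "ear": ear,
        "test_date": test_date,
        "modality": modality,
        "age": age,
        "sex": sex,
        "record_index": record_index,
    }
    for col, val in zip(AC_COLUMNS, thresholds):
        row[col] = val
    return row


def curve_table(rows):
    df = pd.DataFrame(rows)
    for c in AC_COLUMNS:
        df[c] = pd.array(df[c], dtype="Float64")
    df["age"] = pd.array(df["age"], dtype="Float64")
    df["sex"] = df["sex"].astype("string")
    return df
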