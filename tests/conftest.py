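import numpy as np
import pandas as pd
import pytest

from homeshare.cohort import ChemicalSpec, Cohort, validate_cohort


def make_participants(rows):
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "household_id", "age", "gender", "kit_return_date", "lab"],
    )
    df["kit_return_date"] = pd.to_datetime(df["kit_return_date"])
    return df


def make_cohort(participants, behaviors=None, measurements=None, chemicals=None):
    b = pd.DataFrame(behaviors or [], columns=["participant_id", "behavior_id", "response"])
    m = pd.DataFrame(
        measurements or [], columns=["participant_id", "chemical_id", "value", "mrl", "censored"]
    )
    return validate_cohort(Cohort(participants, b, m, chemicals or {}))


@pytest.fixture
def tiny_cohort():
    """Two shared households (sizes 2 and 3) plus one singleton."""
    p = make_participants(
        [
            ("p1", "h1", 40, "female", "2018-01-01", "LAB_A"),
            ("p2", "h1", 42, "male", "2018-01-03", "LAB_A"),
            ("p3", "h2", 35, "female", "2018-02-01", "LAB_B"),
            ("p4", "h2", 8, "male", "2018-02-02", "LAB_B"),
            ("p5", "h2", 11, "female", "2018-02-02", "LAB_B"),
            ("p6", "h3", 29, "male", "2018-03-01", "LAB_A"),
        ]
    )
    behaviors = [
        ("p1", "shampoo", "yes"),
        ("p2", "shampoo", "yes"),
        ("p3", "shampoo", "no"),
        ("p4", "shampoo", "yes"),
        ("p5", "shampoo", "missing"),
        ("p6", "shampoo", "no"),
    ]
    measurements = [
        ("p1", "chemA", 2.0, 0.5, False),
        ("p2", "chemA", 3.0, 0.5, False),
        ("p3", "chemA", 0.5, 0.5, True),
        ("p4", "chemA", 1.5, 0.5, False),
        ("p5", "chemA", 4.0, 0.5, False),
        ("p6", "chemA", 1.0, 0.5, False),
    ]
    chems = {
        "chemA": ChemicalSpec("chemA", "chemical A", "paraben", ("shampoo",)),
    }
    return make_cohort(p, behaviors, measurements, chems)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
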