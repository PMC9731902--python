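"""Cohort data model: participants, households, behaviors, censored measurements.

A :class:`Cohort` is the single validated container that every analysis stage
consumes.  It is assembled either from four CSV tables (:func:`load_cohort`)
or by the synthetic generator (:mod:`homeshare.simulate`).

Conventions
-----------
* A participant is in a *shared home* iff at least two participants carry the
  same household id.  All members of a household must have been analyzed by
  the same laboratory.
* A measurement below its sample-specific method reporting limit (MRL) is
  left-censored; the stored value then equals the MRL.
* Within-household pairs are classified adult-adult / adult-child /
  child-child at an age-18 cutoff, and are analysis-eligible only when the
  two kit-return dates fall within a configurable window (default 28 days,
  with 7 days as the sensitivity setting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ADULT_AGE = 18
DEFAULT_MAX_DAYS = 28
SENSITIVITY_MAX_DAYS = 7
DEFAULT_DETECTION_GATE = 0.35

GENDERS = ("female", "male", "unreported")
LABS = ("LAB_A", "LAB_B")
RESPONSES = ("yes", "no", "missing")
CHEMICAL_CLASSES = ("paraben", "uv_filter", "antimicrobial", "dichlorophenol", "bisphenol")
PAIR_TYPES = ("adult_adult", "adult_child", "child_child")

PARTICIPANT_COLUMNS = ["participant_id", "household_id", "age", "gender", "kit_return_date", "lab"]
BEHAVIOR_COLUMNS = ["participant_id", "behavior_id", "response"]
MEASUREMENT_COLUMNS = ["participant_id", "chemical_id", "value", "mrl", "censored"]
CHEMICAL_COLUMNS = ["chemical_id", "name", "class", "predictor_behaviors"]


class CohortValidationError(ValueError):
    """Raised when input tables violate a cohort invariant; names offending rows."""


@dataclass(frozen=True)
class ChemicalSpec:
    """One target analyte and its a-priori predictor behaviors."""

    chemical_id: str
    name: str
    chemical_class: str
    predictor_behaviors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise CohortValidationError(
                f"chemical {self.chemical_id!r}: unknown class {self.chemical_class!r}"
            )
        if not self.predictor_behaviors:
            raise CohortValidationError(
                f"chemical {self.chemical_id!r}: predictor_behaviors must be non-empty"
            )


@dataclass
class Cohort:
    """Validated cohort tables.

    Attributes
    ----------
    participants
        One row per participant: participant_id, household_id, age, gender,
        kit_return_date (datetime), lab, shared_home (derived).
    behaviors
        Long table of binary survey responses (yes/no/missing).
    measurements
        Per participant per chemical: value (ng/ml), mrl (ng/ml), censored.
    chemicals
        chemical_id -> :class:`ChemicalSpec`.
    """

    participants: pd.DataFrame
    behaviors: pd.DataFrame
    measurements: pd.DataFrame
    chemicals: dict[str, ChemicalSpec] = field(default_factory=dict)

    def household_sizes(self) -> pd.Series:
        return self.participants.groupby("household_id").size()

    def shared_participants(self) -> pd.DataFrame:
        return self.participants[self.participants["shared_home"]]

    def surveyed_ids(self) -> set[str]:
        """Participants with at least one non-missing survey response."""
        b = self.behaviors
        return set(b.loc[b["response"] != "missing", "participant_id"].unique())


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{table}: missing columns {missing}")


def validate_cohort(cohort: Cohort) -> Cohort:
    """Check all cohort invariants, derive ``shared_home``, and return the cohort.

    Raises :class:`CohortValidationError` naming the offending rows on the
    first violated invariant.
    """
    p = cohort.participants
    _require_columns(p, PARTICIPANT_COLUMNS, "participants")
    dup = p[p["participant_id"].duplicated(keep=False)]
    if len(dup):
        raise CohortValidationError(
            f"participants: duplicate participant_id rows {sorted(dup['participant_id'].unique())}"
        )
    bad_gender = p[~p["gender"].isin(GENDERS)]
    if len(bad_gender):
        raise CohortValidationError(
            f"participants: invalid gender for {bad_gender['participant_id'].tolist()}"
        )
    bad_lab = p[~p["lab"].isin(LABS)]
    if len(bad_lab):
        raise CohortValidationError(
            f"participants: invalid lab for {bad_lab['participant_id'].tolist()}"
        )
    if (p["age"] < 0).any():
        raise CohortValidationError(
            f"participants: negative age for {p.loc[p['age'] < 0, 'participant_id'].tolist()}"
        )
    # one lab per household (household samples always analyzed by the same lab)
    labs_per_house = p.groupby("household_id")["lab"].nunique()
    mixed = labs_per_house[labs_per_house > 1]
    if len(mixed):
        raise CohortValidationError(
            f"participants: households with mixed labs: {sorted(mixed.index)}"
        )
    sizes = p.groupby("household_id")["participant_id"].transform("size")
    p = p.copy()
    p["shared_home"] = (sizes >= 2).to_numpy()
    cohort.participants = p
    known_ids = set(p["participant_id"])

    b = cohort.behaviors
    _require_columns(b, BEHAVIOR_COLUMNS, "behaviors")
    bad_resp = b[~b["response"].isin(RESPONSES)]
    if len(bad_resp):
        raise CohortValidationError(f"behaviors: invalid responses at rows {bad_resp.index.tolist()}")
    dup_b = b[b.duplicated(subset=["participant_id", "behavior_id"], keep=False)]
    if len(dup_b):
        raise CohortValidationError(
            f"behaviors: duplicate (participant, behavior) rows {dup_b.index.tolist()}"
        )
    unknown = b[~b["participant_id"].isin(known_ids)]
    if len(unknown):
        raise CohortValidationError(
            f"behaviors: unknown participants {sorted(unknown['participant_id'].unique())}"
        )

    m = cohort.measurements
    _require_columns(m, MEASUREMENT_COLUMNS, "measurements")
    if len(m) == 0:
        return cohort
    m = m.copy()
    m["value"] = m["value"].astype(float)
    m["mrl"] = m["mrl"].astype(float)
    m["censored"] = m["censored"].astype(bool)
    cohort.measurements = m
    unknown_m = m[~m["participant_id"].isin(known_ids)]
    if len(unknown_m):
        raise CohortValidationError(
            f"measurements: unknown participants {sorted(unknown_m['participant_id'].unique())}"
        )
    # mrl == 0 is admitted as the "no censoring possible" limit
    if (m["value"] <= 0).any() or (m["mrl"] < 0).any():
        bad = m[(m["value"] <= 0) | (m["mrl"] < 0)]
        raise CohortValidationError(f"measurements: non-positive value/mrl at rows {bad.index.tolist()}")
    cens = m["censored"].astype(bool)
    off = m[cens & ~np.isclose(m["value"], m["mrl"], rtol=1e-9)]
    if len(off):
        raise CohortValidationError(
            f"measurements: censored rows where value != mrl: {off.index.tolist()}"
        )
    below = m[~cens & (m["value"] < m["mrl"] * (1 - 1e-12))]
    if len(below):
        raise CohortValidationError(
            f"measurements: detected rows below their MRL: {below.index.tolist()}"
        )
    for chem_id, spec in cohort.chemicals.items():
        if spec.chemical_id != chem_id:
            raise CohortValidationError(f"chemicals: key {chem_id!r} != spec id {spec.chemical_id!r}")
    return cohort


def load_cohort(directory: str | Path) -> Cohort:
    """Read ``participants.csv``, ``behaviors.csv``, ``measurements.csv`` and
    ``chemicals.csv`` from *directory*, validate, and return a :class:`Cohort`.

    CSV dialect: UTF-8, comma-separated, ISO-8601 dates, header row mandatory.
    ``chemicals.csv`` lists predictor behaviors semicolon-separated.
    """
    directory = Path(directory)
    p = pd.read_csv(directory / "participants.csv", dtype={"participant_id": str, "household_id": str})
    _require_columns(p, PARTICIPANT_COLUMNS, "participants")
    p["kit_return_date"] = pd.to_datetime(p["kit_return_date"], format="ISO8601")
    b = pd.read_csv(directory / "behaviors.csv", dtype={"participant_id": str, "behavior_id": str})
    m = pd.read_csv(directory / "measurements.csv", dtype={"participant_id": str, "chemical_id": str})
    if "censored" in m.columns:
        m["censored"] = m["censored"].astype(bool)
    chem_path = directory / "chemicals.csv"
    chemicals: dict[str, ChemicalSpec] = {}
    if chem_path.exists():
        c = pd.read_csv(chem_path, dtype=str)
        _require_columns(c, CHEMICAL_COLUMNS, "chemicals")
        for _, row in c.iterrows():
            behaviors = tuple(s for s in str(row["predictor_behaviors"]).split(";") if s)
            chemicals[row["chemical_id"]] = ChemicalSpec(
                chemical_id=row["chemical_id"],
                name=row["name"],
                chemical_class=row["class"],
                predictor_behaviors=behaviors,
            )
    return validate_cohort(Cohort(participants=p, behaviors=b, measurements=m, chemicals=chemicals))


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """Write the four cohort CSV tables (inverse of :func:`load_cohort`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = cohort.participants.copy()
    p["kit_return_date"] = pd.to_datetime(p["kit_return_date"]).dt.strftime("%Y-%m-%d")
    p[PARTICIPANT_COLUMNS].to_csv(directory / "participants.csv", index=False)
    cohort.behaviors[BEHAVIOR_COLUMNS].to_csv(directory / "behaviors.csv", index=False)
    cohort.measurements[MEASUREMENT_COLUMNS].to_csv(directory / "measurements.csv", index=False)
    rows = [
        {
            "chemical_id": s.chemical_id,
            "name": s.name,
            "class": s.chemical_class,
            "predictor_behaviors": ";".join(s.predictor_behaviors),
        }
        for s in cohort.chemicals.values()
    ]
    pd.DataFrame(rows, columns=CHEMICAL_COLUMNS).to_csv(directory / "chemicals.csv", index=False)


def _pair_type(age1: int, age2: int) -> str:
    adults = (age1 >= ADULT_AGE) + (age2 >= ADULT_AGE)
    return {2: "adult_adult", 1: "adult_child", 0: "child_child"}[adults]


def _gender_combo(g1: str, g2: str) -> str:
    if "unreported" in (g1, g2):
        return "unknown"
    initials = sorted(g[0].upper() for g in (g1, g2))
    return "".join(initials)


def enumerate_pairs(cohort: Cohort, max_days: int = DEFAULT_MAX_DAYS) -> pd.DataFrame:
    """Enumerate all analysis-eligible unordered within-household pairs.

    A household of size *m* yields at most C(m, 2) pairs; a pair is eligible
    when the two kit-return dates are at most *max_days* apart.  Members are
    canonically ordered by participant_id, so the result is invariant to the
    row order of the input tables.

    Returns a DataFrame with columns member_1, member_2, household_id,
    pair_type, gender_combo, days_between_returns.
    """
    if max_days < 0:
        raise ValueError("max_days must be >= 0")
    p = cohort.participants.sort_values("participant_id")
    rows = []
    for hid, grp in p.groupby("household_id"):
        if len(grp) < 2:
            continue
        records = grp.to_dict("records")
        for r1, r2 in combinations(records, 2):
            days = abs((r1["kit_return_date"] - r2["kit_return_date"]).days)
            if days > max_days:
                continue
            rows.append(
                {
                    "member_1": r1["participant_id"],
                    "member_2": r2["participant_id"],
                    "household_id": hid,
                    "pair_type": _pair_type(r1["age"], r2["age"]),
                    "gender_combo": _gender_combo(r1["gender"], r2["gender"]),
                    "days_between_returns": days,
                }
            )
    cols = ["member_1", "member_2", "household_id", "pair_type", "gender_combo", "days_between_returns"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["member_1", "member_2"]).reset_index(drop=True)


def detection_gate(cohort: Cohort, min_fraction: float = DEFAULT_DETECTION_GATE) -> list[str]:
    """Chemicals whose detection frequency strictly exceeds *min_fraction*.

    Detection frequency is the fraction of measurements above the MRL.
    Chemicals with zero measurements are excluded with a logged warning.
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    m = cohort.measurements
    out = []
    for chem_id in sorted(cohort.chemicals) if cohort.chemicals else sorted(m["chemical_id"].unique()):
        sub = m[m["chemical_id"] == chem_id]
        if len(sub) == 0:
            logger.warning("detection_gate: chemical %s has zero measurements; excluded", chem_id)
            continue
        frac = float((~sub["censored"].astype(bool)).mean())
        if frac > min_fraction:
            out.append(chem_id)
    return out
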