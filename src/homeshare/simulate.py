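"""Synthetic biomonitoring cohorts with known ground truth.

The original crowdsourced cohort behind this analysis is not publicly
deposited, so every downstream stage is exercised on synthetic cohorts drawn
from the same generative structure the hierarchical model assumes:

* households of 2-6 members (sizes drawn from the observed proportions:
  about 82% two-member homes, 11% three-member) plus a singleton cohort;
* binary 24-hour product-use behaviors, correlated within a household
  through a shared logit offset (an odds multiplier);
* for participant j, an expected concentration that adds up on the
  concentration scale,

      M_j = H_{h(j)} + sum_k beta_k x_jk + sum_k gamma_k s_jk,

  where H_h is a lognormal household background, x_jk the participant's own
  behaviors, and s_jk the count of *other* household members reporting
  behavior k; singletons replace H by a fixed singleton intercept;
* a lognormal measurement draw with arithmetic mean M_j (log-median
  log M_j - sigma^2/2) and a group-specific log-scale shape sigma;
* left-censoring at the analyzing lab's method reporting limit, with the
  stored value set to the MRL.

:func:`generate` returns the cohort together with a :class:`GroundTruth`
recording the true coefficients, household draws, and the implied true
contribution fractions (computed with exactly the estimand used by
:func:`homeshare.contribution.relative_contributions`), enabling
parameter-recovery tests.  Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort import ChemicalSpec, Cohort, validate_cohort

DEFAULT_SIZE_PROBS = (0.82, 0.11, 0.012, 0.024, 0.012)  # sizes 2..6, renormalized
OTHERS_CAP = 5


@dataclass(frozen=True)
class BehaviorSim:
    """One survey behavior: marginal use probability and household clustering.

    ``household_odds_multiplier`` omega shifts a household's shared logit by
    +/- log(omega)/2 (sign drawn per household), so members of one home are
    concordant; omega = 1 means independent responses.
    """

    behavior_id: str
    marginal_prob: float
    household_odds_multiplier: float = 1.0


@dataclass(frozen=True)
class ChemicalSim:
    """Generating parameters for one chemical (all concentrations ng/ml)."""

    chemical_id: str
    name: str
    chemical_class: str
    beta: dict[str, float]  # behavior_id -> personal contribution per use
    gamma: dict[str, float]  # behavior_id -> contribution per reporting housemate
    household_log_median: float
    household_log_sd: float
    shape_shared: float
    shape_singleton: float
    mrl_by_lab: dict[str, float]
    singleton_background: float | None = None  # default: mean household background

    def spec(self) -> ChemicalSpec:
        return ChemicalSpec(
            chemical_id=self.chemical_id,
            name=self.name,
            chemical_class=self.chemical_class,
            predictor_behaviors=tuple(sorted(set(self.beta) | set(self.gamma))),
        )

    @property
    def b0(self) -> float:
        if self.singleton_background is not None:
            return self.singleton_background
        return float(np.exp(self.household_log_median + self.household_log_sd**2 / 2))


@dataclass
class GeneratorConfig:
    n_households: int
    n_singletons: int
    behaviors: list[BehaviorSim]
    chemicals: list[ChemicalSim]
    household_size_probs: tuple[float, ...] = DEFAULT_SIZE_PROBS
    adult_child_prob: float = 0.25  # probability a multi-member home is multigenerational
    lab_probs: tuple[float, float] = (0.55, 0.45)  # LAB_A, LAB_B
    return_span_days: int = 7  # household members return kits within this span
    missing_survey_prob: float = 0.0  # participant answers no survey at all
    start_date: date = date(2017, 2, 1)
    recruitment_days: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households < 0 or self.n_singletons < 0:
            raise ValueError("cohort sizes must be non-negative")
        probs = np.asarray(self.household_size_probs, dtype=float)
        if probs.min() < 0 or probs.sum() <= 0:
            raise ValueError("household_size_probs must be a valid probability vector")
        for chem in self.chemicals:
            if any(v < 0 for v in chem.beta.values()) or any(v < 0 for v in chem.gamma.values()):
                raise ValueError(f"{chem.chemical_id}: coefficients must be >= 0")
            if chem.household_log_sd < 0 or chem.shape_shared <= 0 or chem.shape_singleton <= 0:
                raise ValueError(f"{chem.chemical_id}: scale parameters must be positive")


@dataclass
class GroundTruth:
    """Generator-side record of the true parameters and contribution fractions."""

    beta: dict[str, dict[str, float]]  # chemical -> behavior -> coefficient
    gamma: dict[str, dict[str, float]]
    household_background: dict[str, dict[str, float]]  # chemical -> household -> H_h
    singleton_background: dict[str, float]
    fractions: dict[str, tuple[float, float, float]]  # (personal, others, household)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "gamma": self.gamma,
            "singleton_background": self.singleton_background,
            "fractions": {k: list(v) for k, v in self.fractions.items()},
        }


def generate(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one synthetic cohort and its ground truth; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    size_probs = np.asarray(config.household_size_probs, dtype=float)
    size_probs = size_probs / size_probs.sum()

    part_rows = []
    house_of: list[str] = []

    def add_participant(pid, hid, age, gender, lab, ret):
        part_rows.append(
            {
                "participant_id": pid,
                "household_id": hid,
                "age": int(age),
                "gender": gender,
                "kit_return_date": pd.Timestamp(ret),
                "lab": lab,
            }
        )
        house_of.append(hid)

    shared_house_ids = []
    for h in range(config.n_households):
        hid = f"H{h:04d}"
        shared_house_ids.append(hid)
        size = int(rng.choice(np.arange(2, 7), p=size_probs))
        lab = "LAB_A" if rng.random() < config.lab_probs[0] else "LAB_B"
        base = config.start_date + timedelta(days=int(rng.integers(0, config.recruitment_days)))
        multigen = rng.random() < config.adult_child_prob
        for m in range(size):
            if multigen and m >= 2:
                age = int(rng.integers(3, 18))
            elif multigen and m == 1 and size == 2:
                age = int(rng.integers(3, 18))
            else:
                age = int(rng.integers(25, 66))
            gender = "female" if rng.random() < 0.6 else "male"
            ret = base + timedelta(days=int(rng.integers(0, config.return_span_days + 1)))
            add_participant(f"{hid}P{m}", hid, age, gender, lab, ret)
    for s in range(config.n_singletons):
        hid = f"S{s:04d}"
        lab = "LAB_A" if rng.random() < config.lab_probs[0] else "LAB_B"
        ret = config.start_date + timedelta(days=int(rng.integers(0, config.recruitment_days)))
        gender = "female" if rng.random() < 0.6 else "male"
        add_participant(f"{hid}P0", hid, int(rng.integers(25, 66)), gender, lab, ret)

    participants = pd.DataFrame(part_rows)
    n = len(participants)
    house_of_arr = np.asarray(house_of)
    all_house_ids = sorted(set(house_of))

    # true behaviors: household-shared logit offset, then Bernoulli per member
    behavior_ids = [b.behavior_id for b in config.behaviors]
    x_true = np.zeros((n, len(config.behaviors)), dtype=int)
    for k, beh in enumerate(config.behaviors):
        offset = np.log(beh.household_odds_multiplier) / 2.0
        house_sign = {hid: (1.0 if rng.random() < 0.5 else -1.0) for hid in all_house_ids}
        eta = np.array([logit(beh.marginal_prob) + house_sign[h] * offset for h in house_of_arr])
        x_true[:, k] = rng.random(n) < expit(eta)

    surveyed = rng.random(n) >= config.missing_survey_prob
    beh_rows = []
    for j in range(n):
        pid = participants.loc[j, "participant_id"]
        for k, bid in enumerate(behavior_ids):
            if surveyed[j]:
                resp = "yes" if x_true[j, k] else "no"
            else:
                resp = "missing"
            beh_rows.append({"participant_id": pid, "behavior_id": bid, "response": resp})
    behaviors = pd.DataFrame(beh_rows)

    # others' counts from true behaviors of co-resident participants
    s_counts = np.zeros_like(x_true)
    for hid in shared_house_ids:
        idx = np.flatnonzero(house_of_arr == hid)
        tot = x_true[idx].sum(axis=0)
        s_counts[idx] = np.minimum(tot[None, :] - x_true[idx], OTHERS_CAP)

    is_shared = np.isin(house_of_arr, shared_house_ids)
    lab_arr = participants["lab"].to_numpy()

    meas_rows = []
    gt_beta, gt_gamma, gt_house, gt_b0, gt_frac = {}, {}, {}, {}, {}
    k_index = {bid: k for k, bid in enumerate(behavior_ids)}
    for chem in config.chemicals:
        for bid in list(chem.beta) + list(chem.gamma):
            if bid not in k_index:
                raise ValueError(f"{chem.chemical_id}: unknown predictor behavior {bid!r}")
        beta_vec = np.zeros(len(behavior_ids))
        gamma_vec = np.zeros(len(behavior_ids))
        for bid, v in chem.beta.items():
            beta_vec[k_index[bid]] = v
        for bid, v in chem.gamma.items():
            gamma_vec[k_index[bid]] = v
        H = {
            hid: float(np.exp(rng.normal(chem.household_log_median, chem.household_log_sd)))
            for hid in shared_house_ids
        }
        H_arr = np.array([H[h] if sh else 0.0 for h, sh in zip(house_of_arr, is_shared)])
        personal = x_true @ beta_vec
        others = s_counts @ gamma_vec
        M = np.where(is_shared, H_arr + personal + others, chem.b0 + personal)
        shape = np.where(is_shared, chem.shape_shared, chem.shape_singleton)
        y = np.exp(rng.normal(np.log(M) - shape**2 / 2.0, shape))
        mrl = np.array([chem.mrl_by_lab[lab] for lab in lab_arr])
        censored = y < mrl
        value = np.where(censored, mrl, y)
        for j in range(n):
            meas_rows.append(
                {
                    "participant_id": participants.loc[j, "participant_id"],
                    "chemical_id": chem.chemical_id,
                    "value": float(value[j]),
                    "mrl": float(mrl[j]),
                    "censored": bool(censored[j]),
                }
            )
        t_personal = float(personal[is_shared].sum())
        t_others = float(others[is_shared].sum())
        t_house = float(H_arr[is_shared].sum())
        total = t_personal + t_others + t_house
        gt_beta[chem.chemical_id] = dict(chem.beta)
        gt_gamma[chem.chemical_id] = dict(chem.gamma)
        gt_house[chem.chemical_id] = H
        gt_b0[chem.chemical_id] = chem.b0
        gt_frac[chem.chemical_id] = (t_personal / total, t_others / total, t_house / total)

    cohort = Cohort(
        participants=participants,
        behaviors=behaviors,
        measurements=pd.DataFrame(
            meas_rows, columns=["participant_id", "chemical_id", "value", "mrl", "censored"]
        ),
        chemicals={c.chemical_id: c.spec() for c in config.chemicals},
    )
    truth = GroundTruth(
        beta=gt_beta,
        gamma=gt_gamma,
        household_background=gt_house,
        singleton_background=gt_b0,
        fractions=gt_frac,
    )
    return validate_cohort(cohort), truth


def default_behaviors() -> list[BehaviorSim]:
    """A survey catalog resembling 24-hour product-use questions."""
    items = [
        ("shampoo", 0.80, 2.0),
        ("conditioner", 0.60, 2.5),
        ("lotion", 0.55, 2.0),
        ("sunscreen", 0.30, 3.0),
        ("makeup", 0.35, 1.2),
        ("toothpaste", 0.95, 1.5),
        ("hand_soap", 0.90, 2.0),
        ("bar_soap", 0.45, 2.5),
        ("deodorant", 0.85, 1.5),
        ("canned_food", 0.35, 3.0),
        ("canned_beverage", 0.25, 1.5),
        ("plastic_water_bottle", 0.40, 3.0),
        ("takeout_food", 0.30, 3.5),
        ("receipt_handling", 0.45, 1.5),
        ("air_freshener", 0.20, 4.0),
        ("hepa_vacuum", 0.35, 5.0),
        ("damp_cloth_cleaning", 0.40, 2.5),
        ("weed_killer", 0.05, 4.0),
    ]
    return [BehaviorSim(b, p, w) for b, p, w in items]


def default_chemicals() -> list[ChemicalSim]:
    """Ten phenolic chemicals spanning the three source regimes.

    Coefficients are set so parabens, benzophenone-3 and triclosan are
    dominated by personal behaviors, benzophenone-3 carries a noticeable
    others'-behavior share, and the dichlorophenols and bisphenols are
    dominated by the shared-household background — the qualitative pattern
    expected for these chemical classes.  Scales are in the ng/ml range of
    urinary biomonitoring data.
    """
    mrl_ab = lambda a, b: {"LAB_A": a, "LAB_B": b}
    return [
        ChemicalSim("mepb", "methylparaben", "paraben",
                    beta={"shampoo": 12.0, "lotion": 9.0, "makeup": 6.0},
                    gamma={"shampoo": 0.4, "lotion": 0.3},
                    household_log_median=np.log(1.5), household_log_sd=0.7,
                    shape_shared=1.1, shape_singleton=1.1, mrl_by_lab=mrl_ab(0.7, 1.0)),
        ChemicalSim("etpb", "ethylparaben", "paraben",
                    beta={"lotion": 4.0, "makeup": 3.0, "deodorant": 2.0},
                    gamma={"lotion": 0.15},
                    household_log_median=np.log(0.4), household_log_sd=0.7,
                    shape_shared=1.2, shape_singleton=1.2, mrl_by_lab=mrl_ab(0.6, 0.8)),
        ChemicalSim("prpb", "propylparaben", "paraben",
                    beta={"shampoo": 3.0, "lotion": 2.5, "makeup": 2.0},
                    gamma={"shampoo": 0.1, "lotion": 0.1},
                    household_log_median=np.log(0.3), household_log_sd=0.7,
                    shape_shared=1.2, shape_singleton=1.2, mrl_by_lab=mrl_ab(0.2, 0.3)),
        ChemicalSim("bp3", "benzophenone-3", "uv_filter",
                    beta={"sunscreen": 60.0, "lotion": 15.0, "plastic_water_bottle": 10.0},
                    gamma={"sunscreen": 12.0, "lotion": 3.0, "plastic_water_bottle": 2.0},
                    household_log_median=np.log(2.0), household_log_sd=0.8,
                    shape_shared=1.3, shape_singleton=1.3, mrl_by_lab=mrl_ab(0.28, 0.4)),
        ChemicalSim("tcs", "triclosan", "antimicrobial",
                    beta={"hand_soap": 6.0, "toothpaste": 5.0, "deodorant": 3.0},
                    gamma={"hand_soap": 0.4},
                    household_log_median=np.log(1.0), household_log_sd=0.8,
                    shape_shared=1.8, shape_singleton=1.8, mrl_by_lab=mrl_ab(1.8, 2.3)),
        ChemicalSim("dcp24", "2,4-dichlorophenol", "dichlorophenol",
                    beta={"air_freshener": 0.15, "weed_killer": 0.3},
                    gamma={"air_freshener": 0.05},
                    household_log_median=np.log(0.45), household_log_sd=0.9,
                    shape_shared=0.9, shape_singleton=0.9, mrl_by_lab=mrl_ab(0.1, 0.15)),
        ChemicalSim("dcp25", "2,5-dichlorophenol", "dichlorophenol",
                    beta={"air_freshener": 1.2},
                    gamma={"air_freshener": 0.4},
                    household_log_median=np.log(2.8), household_log_sd=1.1,
                    shape_shared=1.0, shape_singleton=1.0, mrl_by_lab=mrl_ab(0.2, 0.3)),
        ChemicalSim("bpa", "bisphenol A", "bisphenol",
                    beta={"canned_food": 0.35, "takeout_food": 0.2, "receipt_handling": 0.15},
                    gamma={"canned_food": 0.1},
                    household_log_median=np.log(0.8), household_log_sd=0.7,
                    shape_shared=0.9, shape_singleton=0.9, mrl_by_lab=mrl_ab(0.28, 0.4)),
        ChemicalSim("bpf", "bisphenol F", "bisphenol",
                    beta={"canned_food": 0.8, "takeout_food": 0.5},
                    gamma={"canned_food": 0.2},
                    household_log_median=np.log(1.2), household_log_sd=0.9,
                    shape_shared=1.4, shape_singleton=1.4, mrl_by_lab=mrl_ab(0.24, 0.35)),
        ChemicalSim("bps", "bisphenol S", "bisphenol",
                    beta={"receipt_handling": 0.25, "canned_beverage": 0.2},
                    gamma={"receipt_handling": 0.08},
                    household_log_median=np.log(0.5), household_log_sd=0.8,
                    shape_shared=1.1, shape_singleton=1.1, mrl_by_lab=mrl_ab(0.28, 0.4)),
    ]


def default_config(seed: int = 0) -> GeneratorConfig:
    """Cohort emulating the study scale: 82 shared homes (about 185 members)
    plus 541 singleton participants, ten chemicals, full survey catalog."""
    return GeneratorConfig(
        n_households=82,
        n_singletons=541,
        behaviors=default_behaviors(),
        chemicals=default_chemicals(),
        missing_survey_prob=0.25,
        seed=seed,
    )


def recovery_config(
    seed: int = 0,
    n_households: int = 80,
    n_singletons: int = 200,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> GeneratorConfig:
    """Single-chemical config whose expected contribution fractions hit a target.

    Two behaviors with marginal probability 0.5 and odds multiplier 2.  With
    mean household size about 2.26, expected per-participant contributions are
    0.5 (b1 + b2) personal, 0.63 (g1 + g2) others, and exp(mu_H + s_H^2/2)
    household; coefficients below solve for the requested fraction targets at
    a household mean of 2 ng/ml.  Realized fractions (returned in
    GroundTruth) differ from the target by sampling noise only.
    """
    fp, fo, fh = fractions
    e_house = 2.0
    total = e_house / fh
    beta_k = (fp * total) / (2 * 0.5)
    gamma_k = (fo * total) / (2 * 0.63)
    sigma_h = 0.5
    behaviors = [BehaviorSim("beh_a", 0.5, 2.0), BehaviorSim("beh_b", 0.5, 2.0)]
    chem = ChemicalSim(
        "chem_x", "synthetic test chemical", "paraben",
        beta={"beh_a": beta_k, "beh_b": beta_k},
        gamma={"beh_a": gamma_k, "beh_b": gamma_k},
        household_log_median=float(np.log(e_house) - sigma_h**2 / 2),
        household_log_sd=sigma_h,
        shape_shared=0.5,
        shape_singleton=0.5,
        mrl_by_lab={"LAB_A": 0.8, "LAB_B": 0.8},
    )
    return GeneratorConfig(
        n_households=n_households,
        n_singletons=n_singletons,
        behaviors=behaviors,
        chemicals=[chem],
        seed=seed,
    )
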