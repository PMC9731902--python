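"""Generator contracts: determinism, censoring, mean structure, concordance."""

import numpy as np
import pandas as pd
import pytest

from homeshare.simulate import (
    BehaviorSim,
    ChemicalSim,
    GeneratorConfig,
    default_config,
    generate,
    recovery_config,
)


def small_config(seed=0, **chem_kwargs):
    defaults = dict(
        beta={"beh": 2.0},
        gamma={"beh": 0.5},
        household_log_median=0.0,
        household_log_sd=0.5,
        shape_shared=0.5,
        shape_singleton=0.5,
        mrl_by_lab={"LAB_A": 0.5, "LAB_B": 0.5},
    )
    defaults.update(chem_kwargs)
    return GeneratorConfig(
        n_households=20,
        n_singletons=30,
        behaviors=[BehaviorSim("beh", 0.5, 2.0)],
        chemicals=[ChemicalSim("c1", "chem one", "paraben", **defaults)],
        seed=seed,
    )


def test_same_seed_reproduces_cohort_exactly():
    c1, t1 = generate(small_config(seed=7))
    c2, t2 = generate(small_config(seed=7))
    pd.testing.assert_frame_equal(c1.participants, c2.participants)
    pd.testing.assert_frame_equal(c1.measurements, c2.measurements)
    assert t1.fractions == t2.fractions


def test_zero_mrl_yields_zero_censored():
    cohort, _ = generate(small_config(mrl_by_lab={"LAB_A": 0.0, "LAB_B": 0.0}))
    assert not cohort.measurements["censored"].any()


def test_censored_records_stored_at_mrl():
    cohort, _ = generate(small_config(mrl_by_lab={"LAB_A": 2.0, "LAB_B": 2.0}))
    m = cohort.measurements
    cens = m[m["censored"]]
    assert len(cens) > 0
    assert (cens["value"] == cens["mrl"]).all()
    assert (m.loc[~m["censored"], "value"] >= m.loc[~m["censored"], "mrl"]).all()


def test_truth_fractions_sum_to_one():
    _, truth = generate(recovery_config(seed=3, n_households=15, n_singletons=10))
    for fr in truth.fractions.values():
        assert sum(fr) == pytest.approx(1.0, abs=1e-12)


def test_detection_frequency_monotone_in_mrl():
    counts = []
    for mrl in (0.2, 0.6, 1.5, 4.0):
        cohort, _ = generate(small_config(seed=5, mrl_by_lab={"LAB_A": mrl, "LAB_B": mrl}))
        counts.append(int(cohort.measurements["censored"].sum()))
    assert counts == sorted(counts)


def test_empirical_mean_matches_mean_structure():
    # law of large numbers on the uncensored generator: the sample mean of
    # concentrations approaches the mean of the per-participant expectations
    cfg = GeneratorConfig(
        n_households=1100,  # ~2500 participants
        n_singletons=2500,
        behaviors=[BehaviorSim("beh", 0.5, 2.0)],
        chemicals=[
            ChemicalSim(
                "c1", "chem one", "paraben",
                beta={"beh": 2.0}, gamma={"beh": 0.5},
                household_log_median=0.0, household_log_sd=0.5,
                shape_shared=0.5, shape_singleton=0.5,
                mrl_by_lab={"LAB_A": 0.0, "LAB_B": 0.0},
            )
        ],
        seed=11,
    )
    cohort, truth = generate(cfg)
    m = cohort.measurements.set_index("participant_id")["value"]
    # reconstruct M_j from the cohort tables and the recorded truth
    p = cohort.participants.set_index("participant_id")
    yes = cohort.behaviors[cohort.behaviors["response"] == "yes"]
    users = set(yes["participant_id"])
    house_members: dict[str, set] = {}
    for pid, hid in p["household_id"].items():
        house_members.setdefault(hid, set()).add(pid)
    H = truth.household_background["c1"]
    b0 = truth.singleton_background["c1"]
    beta = truth.beta["c1"]["beh"]
    gamma = truth.gamma["c1"]["beh"]
    M = []
    for pid, row in p.iterrows():
        x = beta * (pid in users)
        if row["shared_home"]:
            others = sum(1 for q in house_members[row["household_id"]] if q != pid and q in users)
            M.append(H[row["household_id"]] + x + gamma * others)
        else:
            M.append(b0 + x)
    M = np.asarray(M)
    vals = m.loc[p.index].to_numpy()
    mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - M.mean()) <= 3 * mc_se


def test_within_pair_concordance_increases_with_odds_multiplier():
    def concordance(mult):
        cfg = GeneratorConfig(
            n_households=1000,
            n_singletons=0,
            behaviors=[BehaviorSim("beh", 0.5, mult)],
            chemicals=[],
            household_size_probs=(1.0, 0, 0, 0, 0),  # all pairs
            seed=21,
        )
        cohort, _ = generate(cfg)
        yes = cohort.behaviors[cohort.behaviors["response"] == "yes"]
        users = set(yes["participant_id"])
        agree = 0
        for hid, grp in cohort.participants.groupby("household_id"):
            ids = list(grp["participant_id"])
            agree += (ids[0] in users) == (ids[1] in users)
        return agree / 1000

    c1, c4, c16 = concordance(1.0), concordance(4.0), concordance(16.0)
    assert c1 < c4 < c16


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="coefficients"):
        small_config(beta={"beh": -1.0})
    with pytest.raises(ValueError, match="probability"):
        GeneratorConfig(
            n_households=2, n_singletons=0, behaviors=[], chemicals=[],
            household_size_probs=(-1, 2, 0, 0, 0),
        )


def test_default_config_scale():
    cohort, truth = generate(default_config(seed=0))
    n_shared = int(cohort.participants["shared_home"].sum())
    assert cohort.participants["household_id"].nunique() == 82 + 541
    assert 160 <= n_shared <= 220  # ~185 at the observed size mix
    assert set(truth.fractions) == set(cohort.chemicals)
    # regimes: parabens personal-dominant, dichlorophenols household-dominant
    assert truth.fractions["mepb"][0] > 0.75
    assert truth.fractions["dcp25"][2] > 0.5
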