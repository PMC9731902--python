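"""Hierarchical model: design assembly, likelihood oracles, posterior checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from homeshare.cohort import ChemicalSpec
from homeshare.contribution import (
    ModelParams,
    Priors,
    build_model_data,
    fit,
    log_likelihood,
    relative_contributions,
)
from homeshare.simulate import BehaviorSim, ChemicalSim, GeneratorConfig, generate, recovery_config

from conftest import make_cohort, make_participants


def three_person_household_cohort():
    p = make_participants(
        [
            ("a", "h1", 40, "female", "2018-01-01", "LAB_A"),
            ("b", "h1", 41, "male", "2018-01-01", "LAB_A"),
            ("c", "h1", 42, "female", "2018-01-01", "LAB_A"),
            ("s", "h9", 30, "male", "2018-01-01", "LAB_A"),
        ]
    )
    behaviors = [
        ("a", "beh", "yes"),
        ("b", "beh", "yes"),
        ("c", "beh", "no"),
        ("s", "beh", "yes"),
    ]
    meas = [(pid, "chem", 2.0, 0.5, False) for pid in ("a", "b", "c", "s")]
    chems = {"chem": ChemicalSpec("chem", "chem", "paraben", ("beh",))}
    return make_cohort(p, behaviors, meas, chems)


def test_others_counts_and_singleton_rows():
    cohort = three_person_household_cohort()
    data = build_model_data(cohort, cohort.chemicals["chem"])
    rows = dict(zip(data.participant_ids, data.S[:, 0]))
    # both housemates of c report the behavior
    assert rows["c"] == 2
    assert rows["a"] == rows["b"] == 1
    assert rows["s"] == 0  # singleton: no co-residents
    assert data.house_idx[data.participant_ids.index("s")] == -1


def test_six_person_household_caps_others_at_five():
    p = make_participants(
        [(f"p{i}", "h1", 30, "female", "2018-01-01", "LAB_A") for i in range(6)]
    )
    behaviors = [(f"p{i}", "beh", "yes") for i in range(6)]
    meas = [(f"p{i}", "chem", 2.0, 0.5, False) for i in range(6)]
    chems = {"chem": ChemicalSpec("chem", "chem", "paraben", ("beh",))}
    cohort = make_cohort(p, behaviors, meas, chems)
    data = build_model_data(cohort, cohort.chemicals["chem"])
    assert data.S.max() == 5


def test_missing_survey_imputed_or_dropped():
    cohort = three_person_household_cohort()
    cohort.behaviors.loc[cohort.behaviors["participant_id"] == "a", "response"] = "missing"
    data = build_model_data(cohort, cohort.chemicals["chem"])
    assert data.n_missing_survey == 1
    assert data.X[data.participant_ids.index("a"), 0] == 0  # imputed non-user
    dropped = build_model_data(cohort, cohort.chemicals["chem"], drop_missing_survey=True)
    assert "a" not in dropped.participant_ids


def lognormal_logpdf_mean_param(y, mean, sigma):
    """Density of a lognormal with arithmetic mean `mean` and log-sd sigma."""
    scale = np.exp(np.log(mean) - sigma**2 / 2)
    return stats.lognorm.logpdf(y, s=sigma, scale=scale)


def test_likelihood_reduces_to_lognormal_density():
    cohort = three_person_household_cohort()
    data = build_model_data(cohort, cohort.chemicals["chem"])
    H = 1.7
    params = ModelParams(
        beta=np.array([0.0]),
        gamma=np.array([0.0]),
        household=np.array([H]),
        b0=2.2,
        sigma_shared=0.6,
        sigma_singleton=0.4,
    )
    ll = log_likelihood(data, params)
    expected = sum(
        lognormal_logpdf_mean_param(2.0, H, 0.6) for _ in range(3)
    ) + lognormal_logpdf_mean_param(2.0, 2.2, 0.4)
    assert ll == pytest.approx(expected, rel=1e-12)


def test_censored_term_vanishes_as_limit_grows():
    cohort = three_person_household_cohort()
    cohort.measurements.loc[:, ["value", "mrl"]] = 50.0
    cohort.measurements["censored"] = True
    data = build_model_data(cohort, cohort.chemicals["chem"])
    params = ModelParams(np.array([0.0]), np.array([0.0]), np.array([1.0]), 1.0, 0.5, 0.5)
    # log CDF at a limit far above the distribution tends to 0
    assert log_likelihood(data, params) == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("mean,sigma,mrl", [(2.0, 0.5, 1.0), (5.0, 1.2, 0.3), (0.8, 0.9, 0.7)])
def test_censored_likelihood_matches_quadrature(mean, sigma, mrl):
    p = make_participants([("a", "h1", 30, "female", "2018-01-01", "LAB_A"),
                           ("b", "h1", 31, "male", "2018-01-01", "LAB_A")])
    meas = [("a", "chem", mrl, mrl, True), ("b", "chem", max(mean, mrl), mrl, False)]
    behaviors = [("a", "beh", "no"), ("b", "beh", "no")]
    chems = {"chem": ChemicalSpec("chem", "chem", "paraben", ("beh",))}
    cohort = make_cohort(p, behaviors, meas, chems)
    data = build_model_data(cohort, cohort.chemicals["chem"])
    params = ModelParams(np.array([0.0]), np.array([0.0]), np.array([mean]), 1.0, sigma, 0.5)
    ll = log_likelihood(data, params)
    dens, _ = integrate.quad(
        lambda t: np.exp(lognormal_logpdf_mean_param(t, mean, sigma)), 0, mrl
    )
    expected = np.log(dens) + lognormal_logpdf_mean_param(max(mean, mrl), mean, sigma)
    assert ll == pytest.approx(expected, rel=1e-6)


@pytest.fixture(scope="module")
def small_fit():
    cfg = recovery_config(seed=2, n_households=15, n_singletons=25)
    cohort, truth = generate(cfg)
    data = build_model_data(cohort, cohort.chemicals["chem_x"])
    res = fit(data, chains=2, draws=250, warmup=250, seed=0, check=False)
    return res, truth


def test_fraction_draws_sum_to_one(small_fit):
    res, _ = small_fit
    post = relative_contributions(res)
    sums = post.fractions.sum(axis=-1)
    assert np.allclose(sums, 1.0, atol=1e-12)
    assert np.all(post.fractions >= 0)


def test_fit_deterministic_given_seed():
    cfg = recovery_config(seed=4, n_households=8, n_singletons=10)
    cohort, _ = generate(cfg)
    data = build_model_data(cohort, cohort.chemicals["chem_x"])
    r1 = fit(data, chains=2, draws=60, warmup=120, seed=3, check=False)
    r2 = fit(data, chains=2, draws=60, warmup=120, seed=3, check=False)
    assert np.array_equal(r1.beta, r2.beta)
    assert np.array_equal(r1.household, r2.household)


def test_mrl_column_inert_without_censored_rows():
    # the censoring machinery only acts through censored rows: rewriting the
    # MRLs of fully detected data must not change the posterior at all
    cfg = recovery_config(seed=6, n_households=8, n_singletons=10)
    cohort, _ = generate(cfg)
    cohort.measurements["censored"] = False
    cohort.measurements["mrl"] = 1e-6
    data1 = build_model_data(cohort, cohort.chemicals["chem_x"])
    cohort.measurements["mrl"] = 1e-3
    data2 = build_model_data(cohort, cohort.chemicals["chem_x"])
    r1 = fit(data1, chains=2, draws=60, warmup=120, seed=3, check=False)
    r2 = fit(data2, chains=2, draws=60, warmup=120, seed=3, check=False)
    assert np.array_equal(r1.beta, r2.beta)


def test_prior_only_posterior_matches_forward_sampling():
    # with the likelihood switched off, the sampled fraction quantiles must
    # reproduce a direct Monte-Carlo push-forward of the priors
    cfg = recovery_config(seed=8, n_households=10, n_singletons=10)
    cohort, _ = generate(cfg)
    data = build_model_data(cohort, cohort.chemicals["chem_x"])
    priors = Priors(tau=2.0, mu0=0.5)
    res = fit(data, priors=priors, chains=2, draws=1500, warmup=500, seed=1,
              prior_only=True, check=False)
    post = relative_contributions(res)

    rng = np.random.default_rng(77)
    n_mc = 4000
    K = data.X.shape[1]
    sh = data.is_shared
    x_col = data.X[sh].sum(axis=0)
    s_col = data.S[sh].sum(axis=0)
    members = np.bincount(data.house_idx[sh], minlength=data.n_households).astype(float)
    beta = np.abs(rng.normal(0, priors.tau, (n_mc, K)))
    gamma = np.abs(rng.normal(0, priors.tau, (n_mc, K)))
    mu_H = rng.normal(priors.mu0, priors.sd_mu, n_mc)
    sigma_H = np.abs(rng.normal(0, priors.sd_sigma, n_mc))
    z = rng.standard_normal((n_mc, data.n_households))
    H = np.exp(mu_H[:, None] + sigma_H[:, None] * z)
    tp = beta @ x_col
    to = gamma @ s_col
    th = H @ members
    frac = np.stack([tp, to, th], axis=-1)
    frac /= frac.sum(axis=-1, keepdims=True)
    for i in range(3):
        assert np.median(post.fractions[..., i]) == pytest.approx(
            np.median(frac[:, i]), abs=0.05
        )


def test_raising_personal_coefficient_raises_personal_fraction():
    medians = []
    for scale in (0.5, 1.0, 2.0):
        cfg = recovery_config(seed=9, n_households=25, n_singletons=40)
        chem = cfg.chemicals[0]
        from dataclasses import replace

        cfg.chemicals[0] = replace(
            chem, beta={k: v * scale for k, v in chem.beta.items()}
        )
        cohort, _ = generate(cfg)
        data = build_model_data(cohort, cohort.chemicals["chem_x"])
        res = fit(data, chains=2, draws=250, warmup=250, seed=2, check=False)
        medians.append(relative_contributions(res).median[0])
    assert medians[0] < medians[1] < medians[2]
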