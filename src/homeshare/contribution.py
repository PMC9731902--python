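"""Bayesian hierarchical source apportionment of urinary concentrations.

The model partitions each shared-home participant's expected concentration
into three additive, non-negative sources on the concentration scale:

    M_j = H_{h(j)} + sum_k beta_k X_jk + sum_k gamma_k S_jk     (shared home)
    M_j = b0      + sum_k beta_k X_jk                           (singleton)

* ``beta_k`` — personal contribution (ng/ml) of reporting predictor behavior
  k in the last 24 h; shared between the shared-home and singleton groups, so
  the full cohort informs it.
* ``gamma_k`` — contribution per *other* household member reporting behavior
  k (S_jk counts reporting housemates, capped at 5).
* ``H_h`` — household background: everything co-residents share (building
  materials, water, products not asked about), modeled as a lognormal random
  variable, H_h = exp(mu_H + sigma_H z_h), z_h ~ N(0,1) (non-centered).
  The shared-home intercept is the hyper-median exp(mu_H); singletons get
  their own intercept b0.

Concentrations are lognormal with *arithmetic mean* M_j — the log-median is
log M_j - sigma_g^2 / 2 — with separate shape parameters sigma_g for the
shared-home and singleton groups.  Observations below their sample-specific
method reporting limit contribute the lognormal CDF at the limit
(left-censored likelihood).

Priors (weakly informative, scale-aware; all configurable):
beta_k, gamma_k ~ HalfNormal(tau) with tau the chemical's detect median;
mu_H ~ Normal(log median detect, 2); sigma_H, sigma_shared, sigma_singleton
~ HalfNormal(1); log b0 ~ Normal(log median detect, 2).

Sampling uses the package's NUTS implementation with analytic gradients
(:mod:`homeshare.hmc`); convergence is screened with split-R-hat, bulk ESS
and divergence counts via arviz.

The reported estimand is the *relative contribution fraction*: per posterior
draw, each component's total over shared-home participants divided by the
three components' combined total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy.special import log_ndtr

from .cohort import ChemicalSpec, Cohort

logger = logging.getLogger(__name__)

OTHERS_CAP = 5
_LOG_2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    """Sampler diagnostics exceeded their thresholds."""


@dataclass
class ModelData:
    """Design matrices and censored outcomes for one chemical."""

    chemical_id: str
    participant_ids: list[str]
    y: np.ndarray  # stored concentration (MRL where censored), ng/ml
    censored: np.ndarray
    mrl: np.ndarray
    X: np.ndarray  # (n, K) personal-behavior indicators
    S: np.ndarray  # (n, K) counts of other reporting housemates (0 for singletons)
    is_shared: np.ndarray
    house_idx: np.ndarray  # household index for shared rows, -1 for singletons
    house_ids: list[str]
    behavior_ids: list[str]
    n_missing_survey: int

    @property
    def n_households(self) -> int:
        return len(self.house_ids)


@dataclass
class ModelParams:
    """Natural-scale parameters (all non-negative as constructed)."""

    beta: np.ndarray  # (K,)
    gamma: np.ndarray  # (K,)
    household: np.ndarray  # (n_households,) H_h > 0
    b0: float
    sigma_shared: float
    sigma_singleton: float


@dataclass
class Priors:
    """Hyperparameters; ``tau`` and the intercept location are data-scale aware."""

    tau: float  # HalfNormal scale for beta and gamma
    mu0: float  # location of mu_H and log b0 priors
    sd_mu: float = 2.0
    sd_sigma: float = 1.0  # HalfNormal scale of the three shape parameters

    @classmethod
    def from_data(cls, data: ModelData) -> "Priors":
        detects = data.y[~data.censored]
        med = float(np.median(detects)) if len(detects) else 1.0
        return cls(tau=max(med, 1e-6), mu0=float(np.log(max(med, 1e-6))))


@dataclass
class FitResult:
    """Posterior draws (chain, draw, ...) plus sampler bookkeeping."""

    data: ModelData
    beta: np.ndarray
    gamma: np.ndarray
    household: np.ndarray
    mu_H: np.ndarray
    sigma_H: np.ndarray
    b0: np.ndarray
    sigma_shared: np.ndarray
    sigma_singleton: np.ndarray
    divergences: int
    n_chains: int
    n_draws: int
    seed: int
    sampler_stats: list = field(default_factory=list)


@dataclass
class ContributionPosterior:
    """Posterior of the (personal, others, household) contribution fractions."""

    chemical_id: str
    fractions: np.ndarray  # (chain, draw, 3), rows sum to 1
    quantiles: dict[int, np.ndarray]  # percent -> (3,)
    rhat: np.ndarray  # (3,)
    ess_bulk: np.ndarray  # (3,)
    divergences: int
    n_draws: int
    seed: int
    n_excluded_draws: int = 0

    @property
    def median(self) -> np.ndarray:
        return self.quantiles[50]


def build_model_data(
    cohort: Cohort, chemical_spec: ChemicalSpec, drop_missing_survey: bool = False
) -> ModelData:
    """Assemble outcomes and behavior matrices for one chemical.

    Participants whose survey is wholly missing have their X and S entries
    imputed as zero (count reported); pass ``drop_missing_survey=True`` to
    exclude them instead (sensitivity analysis).  Others' counts are computed
    only from co-resident study participants and capped at 5.
    """
    behaviors = list(chemical_spec.predictor_behaviors)
    if not behaviors:
        raise ValueError(f"{chemical_spec.chemical_id}: no predictor behaviors")
    m = cohort.measurements
    m = m[m["chemical_id"] == chemical_spec.chemical_id]
    if len(m) == 0:
        raise ValueError(f"no measurements for {chemical_spec.chemical_id}")
    m = m.set_index("participant_id")
    p = cohort.participants.set_index("participant_id")
    surveyed = cohort.surveyed_ids()

    b = cohort.behaviors
    b = b[b["behavior_id"].isin(behaviors)]
    yes = b[b["response"] == "yes"]
    yes_map = {bid: set(g["participant_id"]) for bid, g in yes.groupby("behavior_id")}

    pids = sorted(m.index)
    n = len(pids)
    K = len(behaviors)
    X = np.zeros((n, K))
    for k, bid in enumerate(behaviors):
        ids = yes_map.get(bid, set())
        X[:, k] = [pid in ids for pid in pids]
    missing = [pid not in surveyed for pid in pids]
    n_missing = int(np.sum(missing))
    if n_missing:
        logger.info(
            "build_model_data(%s): %d participants without survey%s",
            chemical_spec.chemical_id,
            n_missing,
            " dropped" if drop_missing_survey else " imputed as non-users",
        )

    shared_flag = p.loc[pids, "shared_home"].to_numpy(bool)
    house_all = p.loc[pids, "household_id"].to_numpy()
    # others' counts: reporting co-residents among study participants
    S = np.zeros((n, K))
    by_house: dict[str, list[int]] = {}
    for i, (hid, sh) in enumerate(zip(house_all, shared_flag)):
        if sh:
            by_house.setdefault(hid, []).append(i)
    for hid, idxs in by_house.items():
        tot = X[idxs].sum(axis=0)
        S[idxs] = np.minimum(tot[None, :] - X[idxs], OTHERS_CAP)

    keep = np.ones(n, dtype=bool)
    if drop_missing_survey:
        keep = ~np.asarray(missing)
    pids_k = [pid for pid, k_ in zip(pids, keep) if k_]
    X = X[keep]
    S = S[keep]
    shared_flag = shared_flag[keep]
    house_all = house_all[keep]
    house_ids = sorted(set(house_all[shared_flag]))
    house_pos = {h: i for i, h in enumerate(house_ids)}
    house_idx = np.array(
        [house_pos[h] if sh else -1 for h, sh in zip(house_all, shared_flag)], dtype=int
    )
    vals = m.loc[pids_k]
    return ModelData(
        chemical_id=chemical_spec.chemical_id,
        participant_ids=pids_k,
        y=vals["value"].to_numpy(float),
        censored=vals["censored"].to_numpy(bool),
        mrl=vals["mrl"].to_numpy(float),
        X=X,
        S=S,
        is_shared=shared_flag,
        house_idx=house_idx,
        house_ids=house_ids,
        behavior_ids=behaviors,
        n_missing_survey=n_missing,
    )


def _group_loglik(logy, cens, logM, sigma):
    """Log-likelihood, d/dlogM per observation, and summed d/dsigma for one group.

    ``logy`` holds log concentrations; censored entries hold the log limit, so
    the standardized residual r = (logy - logM)/sigma + sigma/2 serves both
    the density and the censored-CDF terms.
    """
    a = logy - logM
    r = a / sigma + sigma / 2.0
    dr_dsigma = -a / sigma**2 + 0.5
    ll = np.empty_like(r)
    g = np.empty_like(r)  # d loglik / d logM
    dsig = np.empty_like(r)
    obs = ~cens
    ll[obs] = -logy[obs] - np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * r[obs] ** 2
    g[obs] = r[obs] / sigma
    dsig[obs] = -1.0 / sigma - r[obs] * dr_dsigma[obs]
    if cens.any():
        rc = r[cens]
        log_phi = log_ndtr(rc)
        ll[cens] = log_phi
        w = np.exp(-0.5 * rc**2 - 0.5 * _LOG_2PI - log_phi)  # pdf/CDF ratio
        g[cens] = -w / sigma
        dsig[cens] = w * dr_dsigma[cens]
    return float(ll.sum()), g, float(dsig.sum())


def log_likelihood(data: ModelData, params: ModelParams) -> float:
    """Total left-censored lognormal log-likelihood at natural-scale parameters."""
    if np.any(params.beta < 0) or np.any(params.gamma < 0):
        raise ValueError("coefficients must be non-negative")
    if np.any(params.household <= 0) or params.b0 <= 0:
        raise ValueError("background terms must be positive")
    M = np.where(
        data.is_shared,
        np.where(data.is_shared, params.household[np.maximum(data.house_idx, 0)], 0.0)
        + data.X @ params.beta
        + data.S @ params.gamma,
        params.b0 + data.X @ params.beta,
    )
    logy = np.log(data.y)
    total = 0.0
    for grp, sigma in ((data.is_shared, params.sigma_shared), (~data.is_shared, params.sigma_singleton)):
        if grp.any():
            ll, _, _ = _group_loglik(logy[grp], data.censored[grp], np.log(M[grp]), sigma)
            total += ll
    if not np.isfinite(total):
        raise ValueError("non-finite log-likelihood")
    return total


class _Posterior:
    """Unconstrained log-posterior with analytic gradient.

    Parameter vector: [u_beta (K), u_gamma (K), mu_H, v_H, z (n_house),
    log_b0, v_shared, v_singleton], where beta = exp(u_beta) etc. and
    sigma = exp(v).  Jacobians of the exp transforms are included.
    """

    def __init__(self, data: ModelData, priors: Priors, prior_only: bool = False):
        self.data = data
        self.priors = priors
        self.prior_only = prior_only
        self.K = data.X.shape[1]
        self.nh = data.n_households
        self.dim = 2 * self.K + 3 + self.nh + 2
        sh = data.is_shared
        self.sh = sh
        self.Xs, self.Ss = data.X[sh], data.S[sh]
        self.Xi = data.X[~sh]
        self.hidx = data.house_idx[sh]
        self.logy_s = np.log(data.y[sh])
        self.cens_s = data.censored[sh]
        self.logy_i = np.log(data.y[~sh])
        self.cens_i = data.censored[~sh]

    def unpack(self, theta):
        K, nh = self.K, self.nh
        ub = theta[:K]
        ug = theta[K : 2 * K]
        mu_H = theta[2 * K]
        vH = theta[2 * K + 1]
        z = theta[2 * K + 2 : 2 * K + 2 + nh]
        lb0 = theta[2 * K + 2 + nh]
        vsh = theta[2 * K + 3 + nh]
        vsi = theta[2 * K + 4 + nh]
        return ub, ug, mu_H, vH, z, lb0, vsh, vsi

    def __call__(self, theta):
        # extreme points visited during step-size search can overflow exp();
        # they surface as -inf log density and are rejected by the sampler
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(theta)

    def _logp_grad(self, theta):
        pr = self.priors
        K, nh = self.K, self.nh
        ub, ug, mu_H, vH, z, lb0, vsh, vsi = self.unpack(theta)
        beta, gamma = np.exp(ub), np.exp(ug)
        sigma_H = np.exp(vH)
        b0 = np.exp(lb0)
        s_sh, s_si = np.exp(vsh), np.exp(vsi)
        H = np.exp(mu_H + sigma_H * z)

        grad = np.zeros_like(theta)
        # --- priors (constants dropped) ---
        lp = float(
            np.sum(-(beta**2) / (2 * pr.tau**2) + ub)
            + np.sum(-(gamma**2) / (2 * pr.tau**2) + ug)
            - (mu_H - pr.mu0) ** 2 / (2 * pr.sd_mu**2)
            - sigma_H**2 / (2 * pr.sd_sigma**2) + vH
            - 0.5 * float(z @ z)
            - (lb0 - pr.mu0) ** 2 / (2 * pr.sd_mu**2)
            - s_sh**2 / (2 * pr.sd_sigma**2) + vsh
            - s_si**2 / (2 * pr.sd_sigma**2) + vsi
        )
        grad[:K] = 1.0 - beta**2 / pr.tau**2
        grad[K : 2 * K] = 1.0 - gamma**2 / pr.tau**2
        grad[2 * K] = -(mu_H - pr.mu0) / pr.sd_mu**2
        grad[2 * K + 1] = 1.0 - sigma_H**2 / pr.sd_sigma**2
        grad[2 * K + 2 : 2 * K + 2 + nh] = -z
        grad[2 * K + 2 + nh] = -(lb0 - pr.mu0) / pr.sd_mu**2
        grad[2 * K + 3 + nh] = 1.0 - s_sh**2 / pr.sd_sigma**2
        grad[2 * K + 4 + nh] = 1.0 - s_si**2 / pr.sd_sigma**2
        if self.prior_only:
            return lp, grad

        # --- likelihood ---
        Ms = H[self.hidx] + self.Xs @ beta + self.Ss @ gamma
        Mi = b0 + self.Xi @ beta
        ll_s, g_s, dsig_s = _group_loglik(self.logy_s, self.cens_s, np.log(Ms), s_sh)
        ll_i, g_i, dsig_i = _group_loglik(self.logy_i, self.cens_i, np.log(Mi), s_si)
        lp += ll_s + ll_i
        w_s = g_s / Ms  # d loglik / d M_j
        w_i = g_i / Mi
        grad[:K] += beta * (self.Xs.T @ w_s + self.Xi.T @ w_i)
        grad[K : 2 * K] += gamma * (self.Ss.T @ w_s)
        dH = np.bincount(self.hidx, weights=w_s, minlength=nh)  # d loglik / d H_h
        grad[2 * K] += float(np.sum(dH * H))
        grad[2 * K + 1] += float(np.sum(dH * H * z)) * sigma_H
        grad[2 * K + 2 : 2 * K + 2 + nh] += dH * H * sigma_H
        grad[2 * K + 2 + nh] += b0 * float(np.sum(w_i))
        grad[2 * K + 3 + nh] += s_sh * dsig_s
        grad[2 * K + 4 + nh] += s_si * dsig_i
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(theta)
        return lp, grad

    def initial_point(self, rng):
        pr = self.priors
        q = np.zeros(self.dim)
        q[: 2 * self.K] = np.log(0.1 * pr.tau)
        q[2 * self.K] = pr.mu0
        q[2 * self.K + 1] = np.log(0.5)
        q[2 * self.K + 2 + self.nh] = pr.mu0
        q[2 * self.K + 3 + self.nh :] = np.log(0.5)
        return q + 0.2 * rng.standard_normal(self.dim)


def fit(
    data: ModelData,
    priors: Priors | None = None,
    chains: int = 4,
    draws: int = 1000,
    warmup: int | None = None,
    seed: int = 0,
    prior_only: bool = False,
    check: bool = True,
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
    max_divergence_frac: float = 0.005,
) -> FitResult:
    """Sample the posterior with NUTS; deterministic given seed and settings.

    With ``check=True`` the fit fails loudly (:class:`ConvergenceError`) when
    split-R-hat of any contribution fraction exceeds ``rhat_max``, its bulk
    ESS falls below ``ess_min``, or divergences exceed
    ``max_divergence_frac`` of all post-warmup draws.
    """
    from .hmc import nuts

    if chains < 2 and check:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    priors = priors or Priors.from_data(data)
    post = _Posterior(data, priors, prior_only=prior_only)
    warmup = draws if warmup is None else warmup
    K, nh = post.K, post.nh

    chain_draws = []
    stats_all = []
    divergences = 0
    seeds = np.random.SeedSequence(seed).generate_state(2 * chains) % (2**31)
    for c in range(chains):
        rng = np.random.default_rng(int(seeds[2 * c]))
        q0 = post.initial_point(rng)
        d, st = nuts(post, q0, n_warmup=warmup, n_draws=draws, seed=int(seeds[2 * c + 1]))
        chain_draws.append(d)
        stats_all.append(st)
        divergences += st.divergences
    theta = np.stack(chain_draws)  # (chains, draws, dim)

    ub = theta[..., :K]
    ug = theta[..., K : 2 * K]
    mu_H = theta[..., 2 * K]
    sigma_H = np.exp(theta[..., 2 * K + 1])
    z = theta[..., 2 * K + 2 : 2 * K + 2 + nh]
    lb0 = theta[..., 2 * K + 2 + nh]
    result = FitResult(
        data=data,
        beta=np.exp(ub),
        gamma=np.exp(ug),
        household=np.exp(mu_H[..., None] + sigma_H[..., None] * z),
        mu_H=mu_H,
        sigma_H=sigma_H,
        b0=np.exp(lb0),
        sigma_shared=np.exp(theta[..., 2 * K + 3 + nh]),
        sigma_singleton=np.exp(theta[..., 2 * K + 4 + nh]),
        divergences=divergences,
        n_chains=chains,
        n_draws=draws,
        seed=seed,
        sampler_stats=stats_all,
    )
    if check:
        posterior = relative_contributions(result)
        problems = []
        if np.any(posterior.rhat > rhat_max):
            problems.append(f"split-Rhat {posterior.rhat.round(4).tolist()} > {rhat_max}")
        if np.any(posterior.ess_bulk < ess_min):
            problems.append(f"bulk ESS {posterior.ess_bulk.round(1).tolist()} < {ess_min}")
        if divergences > max_divergence_frac * chains * draws:
            problems.append(f"{divergences} divergences")
        if problems:
            raise ConvergenceError(
                f"{data.chemical_id}: " + "; ".join(problems)
            )
    return result


def relative_contributions(result: FitResult) -> ContributionPosterior:
    """Posterior contribution fractions over shared-home participants.

    Per draw: T_personal = sum_j sum_k beta_k X_jk, T_others with gamma and
    S, T_household = sum_j H_h(j), all over shared-home participants; each
    fraction is its T over the total.  Draws with zero total (possible only
    in degenerate prior-only runs) are excluded with a logged count.
    """
    data = result.data
    sh = data.is_shared
    x_col = data.X[sh].sum(axis=0)  # (K,)
    s_col = data.S[sh].sum(axis=0)
    members_per_house = np.bincount(data.house_idx[sh], minlength=data.n_households).astype(float)
    t_personal = result.beta @ x_col
    t_others = result.gamma @ s_col
    t_house = result.household @ members_per_house
    total = t_personal + t_others + t_house
    bad = total <= 0
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("relative_contributions: %d zero-total draws excluded", n_bad)
        total = np.where(bad, np.nan, total)
    fractions = np.stack([t_personal, t_others, t_house], axis=-1) / total[..., None]
    quantiles = {
        q: np.nanpercentile(fractions.reshape(-1, 3), q, axis=0) for q in (5, 25, 50, 75, 95)
    }
    rhat = np.array([_scalar_rhat(fractions[..., i]) for i in range(3)])
    ess = np.array([_scalar_ess(fractions[..., i]) for i in range(3)])
    return ContributionPosterior(
        chemical_id=data.chemical_id,
        fractions=fractions,
        quantiles=quantiles,
        rhat=rhat,
        ess_bulk=ess,
        divergences=result.divergences,
        n_draws=result.n_chains * result.n_draws,
        seed=result.seed,
        n_excluded_draws=n_bad,
    )


def _scalar_rhat(arr: np.ndarray) -> float:
    if np.isnan(arr).any():
        arr = np.where(np.isnan(arr), np.nanmean(arr), arr)
    return float(az.rhat(az.convert_to_dataset(arr[..., None]))["x"].values.ravel()[0])


def _scalar_ess(arr: np.ndarray) -> float:
    if np.isnan(arr).any():
        arr = np.where(np.isnan(arr), np.nanmean(arr), arr)
    return float(az.ess(az.convert_to_dataset(arr[..., None]), method="bulk")["x"].values.ravel()[0])
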