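"""Kendall's tau-b rank correlation between housemates' concentrations,
accounting for left-censoring, with a joint-pair bootstrap.

The point estimate generalizes the classical concordance count: a comparison
between two pairs is *determinate* in a margin only when the ordering of the
two concentrations is knowable despite censoring.

* both detected: ordered by value (equal values tie);
* one censored at limit L, the other detected at y: determinate (censored is
  smaller) iff y >= L, otherwise indeterminate;
* both censored: always indeterminate — two values known only to lie below
  their limits are unordered.

Indeterminate comparisons are counted as ties in that margin, and enter the
tau-b denominator through the usual tie correction:

    tau_b = (C - D) / sqrt((n0 - t_x) (n0 - t_y)),   n0 = C(n, 2).

With no censoring this is exactly the classical tau-b.

The bootstrap resamples pairs jointly and, within each replicate, imputes
censored values from the below-limit tail of a censored-lognormal marginal
fitted once to the full sample (this is where a lognormal assumption can act
on a rank statistic: it breaks the artificial ties that censoring creates).
The p-value is the two-sided sign-crossing proportion of the bootstrap
distribution, floored at 1/n_boot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .censored_stats import CensoredSample

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 10_000
PAIR_FILTERS = ("all", "adult_adult", "adult_child", "child_child")


class TauUndefinedError(ValueError):
    """All pair comparisons indeterminate: tau-b has a zero denominator."""


class EmptyPairSetError(ValueError):
    """No pairs remain after filtering."""


@dataclass(frozen=True)
class TauResult:
    chemical_id: str
    pair_filter: str
    n_pairs: int
    tau: float
    ci95: tuple[float, float]
    p_value: float
    n_boot: int
    seed: int


def _comparison_signs(values: np.ndarray, censored: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pairwise comparison outcomes in one margin.

    Entry (i, j) is sign(x_j - x_i) when determinate, 0 for a tie or an
    indeterminate comparison.
    """
    v = values[None, :] - values[:, None]
    sign = np.sign(v)
    ci = censored[:, None]
    cj = censored[None, :]
    both_cens = ci & cj
    # i censored at limit values[i], j detected: determinate iff x_j >= limit
    i_cens = ci & ~cj
    j_cens = cj & ~ci
    indet_i = i_cens & (values[None, :] < values[:, None])  # detect strictly below limit
    indet_j = j_cens & (values[:, None] < values[None, :])
    sign = np.where(i_cens, np.where(indet_i, 0.0, 1.0), sign)
    sign = np.where(j_cens, np.where(indet_j, 0.0, -1.0), sign)
    sign = np.where(both_cens, 0.0, sign)
    np.fill_diagonal(sign, 0.0)
    return sign


def tau_b_censored(x: CensoredSample, y: CensoredSample) -> float:
    """Tie-corrected Kendall's tau-b for two aligned left-censored vectors.

    ``x[i]`` and ``y[i]`` are the two members of pair *i*.  Raises
    :class:`TauUndefinedError` when every comparison is indeterminate in one
    of the margins.
    """
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must be aligned")
    if n < 2:
        raise ValueError("need at least two pairs")
    sx = _comparison_signs(x.values, x.censored)
    sy = _comparison_signs(y.values, y.censored)
    iu = np.triu_indices(n, k=1)
    sxu, syu = sx[iu], sy[iu]
    n0 = n * (n - 1) // 2
    c_minus_d = float(np.sum(sxu * syu))
    t_x = int(np.sum(sxu == 0))
    t_y = int(np.sum(syu == 0))
    denom = np.sqrt(float(n0 - t_x) * float(n0 - t_y))
    if denom == 0:
        raise TauUndefinedError("all comparisons indeterminate in at least one margin")
    return c_minus_d / denom


def _tau_b_batch(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Classical tau-b for a batch of fully observed replicates.

    ``xb``, ``yb``: arrays (B, n).  Vectorized over replicates; memory use is
    kept bounded by the caller chunking B.
    """
    sx = np.sign(xb[:, None, :] - xb[:, :, None])
    sy = np.sign(yb[:, None, :] - yb[:, :, None])
    n = xb.shape[1]
    n0 = n * (n - 1) / 2.0
    c_minus_d = np.einsum("bij,bij->b", sx, sy) / 2.0
    t_x = (np.sum(sx == 0, axis=(1, 2)) - n) / 2.0
    t_y = (np.sum(sy == 0, axis=(1, 2)) - n) / 2.0
    denom = np.sqrt((n0 - t_x) * (n0 - t_y))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, c_minus_d / denom, np.nan)


def fit_censored_lognormal(sample: CensoredSample) -> tuple[float, float]:
    """Maximum-likelihood (mu, sigma) of a lognormal under left-censoring.

    Detects contribute the lognormal density, nondetects the CDF at their
    limit.  Raises ``ValueError`` when the sample is all-censored or the
    optimizer fails.
    """
    det = ~sample.censored
    if det.sum() == 0:
        raise ValueError("cannot fit lognormal: no detects")
    logv = np.log(sample.values)
    log_det = logv[det]
    log_lim = logv[~det]

    def nll(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        ll = np.sum(stats.norm.logpdf(log_det, mu, sigma))
        if len(log_lim):
            ll += np.sum(special.log_ndtr((log_lim - mu) / sigma))
        return -ll

    x0 = np.array([log_det.mean(), np.log(max(log_det.std(), 0.1))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
    if not res.success:
        raise ValueError(f"censored lognormal fit failed: {res.message}")
    return float(res.x[0]), float(np.exp(res.x[1]))


def tau_bootstrap(
    x: CensoredSample,
    y: CensoredSample,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    chemical_id: str = "",
    pair_filter: str = "all",
    impute: bool = True,
    chunk: int = 200,
) -> TauResult:
    """Bootstrap CI and p-value for the censored tau-b of paired concentrations.

    Pairs ``(x_i, y_i)`` are resampled jointly with replacement.  When
    ``impute`` is true (default) each replicate's censored entries are drawn
    from the below-limit tail of censored-lognormal marginals fitted to the
    full sample; set it false for a pure concordance bootstrap.  The reported
    point estimate is always the deterministic concordance tau-b of the
    original data.  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    tau_hat = tau_b_censored(x, y)
    n = len(x)
    rng = np.random.default_rng(seed)

    params = []
    use_impute = impute
    if impute:
        try:
            params = [fit_censored_lognormal(x), fit_censored_lognormal(y)]
        except ValueError as exc:
            logger.warning("lognormal fit failed (%s); falling back to limit substitution", exc)
            use_impute = False

    taus = np.empty(n_boot)
    pos = 0
    while pos < n_boot:
        b = min(chunk, n_boot - pos)
        idx = rng.integers(0, n, size=(b, n))
        xb = x.values[idx]
        yb = y.values[idx]
        if use_impute:
            cxb = x.censored[idx]
            cyb = y.censored[idx]
            (mux, sdx), (muy, sdy) = params
            xb = _impute_batch(xb, cxb, mux, sdx, rng)
            yb = _impute_batch(yb, cyb, muy, sdy, rng)
        taus[pos : pos + b] = _tau_b_batch(xb, yb)
        pos += b

    valid = taus[~np.isnan(taus)]
    n_bad = n_boot - len(valid)
    if n_bad:
        logger.warning("tau_bootstrap: %d replicates with undefined tau dropped", n_bad)
    if len(valid) == 0:
        raise TauUndefinedError("all bootstrap replicates undefined")
    lo, hi = np.percentile(valid, [2.5, 97.5])
    n_le = int(np.sum(valid <= 0))
    n_ge = int(np.sum(valid >= 0))
    p = 2.0 * min(n_le, n_ge) / len(valid)
    p = min(max(p, 1.0 / len(valid)), 1.0)
    return TauResult(
        chemical_id=chemical_id,
        pair_filter=pair_filter,
        n_pairs=n,
        tau=float(tau_hat),
        ci95=(float(lo), float(hi)),
        p_value=float(p),
        n_boot=n_boot,
        seed=seed,
    )


def _impute_batch(vals, cens, mu, sigma, rng):
    """Tail-impute censored entries of a (B, n) resampled value matrix."""
    out = vals.copy()
    mask = cens.astype(bool)
    if mask.any():
        lims = vals[mask]
        p_lim = special.ndtr((np.log(lims) - mu) / sigma)
        u = rng.uniform(0.0, p_lim)
        out[mask] = np.exp(mu + sigma * special.ndtri(u))
    return out


def pairwise_concentrations(
    cohort,
    pairs: pd.DataFrame,
    chemical_id: str,
    pair_filter: str = "all",
) -> tuple[CensoredSample, CensoredSample]:
    """Aligned member-1/member-2 censored vectors for one chemical.

    Pairs missing either member's measurement are dropped (count logged).
    Raises :class:`EmptyPairSetError` when nothing remains.
    """
    if pair_filter not in PAIR_FILTERS:
        raise ValueError(f"unknown pair filter {pair_filter!r}")
    sel = pairs if pair_filter == "all" else pairs[pairs["pair_type"] == pair_filter]
    if len(sel) == 0:
        raise EmptyPairSetError(f"no pairs for filter {pair_filter!r}")
    m = cohort.measurements
    m = m[m["chemical_id"] == chemical_id].set_index("participant_id")
    keep, x_rows, y_rows = 0, [], []
    dropped = 0
    for _, row in sel.iterrows():
        if row["member_1"] in m.index and row["member_2"] in m.index:
            x_rows.append(m.loc[row["member_1"]])
            y_rows.append(m.loc[row["member_2"]])
            keep += 1
        else:
            dropped += 1
    if dropped:
        logger.info("pairwise_concentrations: dropped %d pairs missing %s data", dropped, chemical_id)
    if keep == 0:
        raise EmptyPairSetError(f"no complete pairs for chemical {chemical_id!r}")
    xs = pd.DataFrame(x_rows)
    ys = pd.DataFrame(y_rows)
    x = CensoredSample(xs["value"].to_numpy(), xs["censored"].to_numpy(bool), xs["mrl"].to_numpy())
    y = CensoredSample(ys["value"].to_numpy(), ys["censored"].to_numpy(bool), ys["mrl"].to_numpy())
    return x, y
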