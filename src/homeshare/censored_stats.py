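"""Kaplan-Meier descriptive statistics for left-censored concentration data.

Urinary concentrations routinely fall below the sample-specific method
reporting limit (MRL) and are reported only as "< MRL".  Substituting such
nondetects (by the limit, half the limit, etc.) biases means and variances,
so this module follows the standard nonparametric approach from the
water-quality / environmental-chemistry literature (Helsel, *Statistics for
Censored Environmental Data*): left-censored concentrations are *flipped*
into right-censored survival times,

    z_i = K - x_i,      K = (1 + eps) * max(x),

the Kaplan-Meier product-limit estimator is fitted to the flipped data, and
summary statistics are obtained by back-transforming the estimated
distribution.  The estimated mean is invariant to the choice of K.

Conventions (fixed, not tuned to any published table):

* **Restricted mean.**  When the smallest observation is censored, the
  flipped survival curve never reaches zero; the mean integral is truncated
  at the largest flipped observation, which places the unresolved probability
  mass at the smallest censoring limit.  This matches the behaviour of the
  NADA R package and biases the mean upward by a bounded amount.
* **SD** from the Kaplan-Meier second moment (same truncation); with no
  censoring this is the population-style SD (denominator n).
* **Median**: the smallest concentration at which the back-transformed CDF
  reaches >= 0.5 (step function, no interpolation).
* **Upper percentiles** (95th/99th) use MRL-substituted empirical quantiles
  with linear interpolation (numpy default, type 7), because the product-
  limit estimator carries no information above the largest detect.  They are
  flagged invalid when the requested level does not exceed the censoring
  fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

FLIP_EPS = 1e-9


class CensoredDataError(ValueError):
    """Raised on samples the product-limit estimator cannot summarize."""


@dataclass
class CensoredSample:
    """Concentrations for one chemical with left-censoring indicators.

    ``values`` holds the measured concentration for detects and the MRL for
    nondetects; ``limits`` holds the per-observation MRL (equal to ``values``
    where censored).
    """

    values: np.ndarray
    censored: np.ndarray
    limits: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.limits is None:
            # without explicit limits, censored values sit at their limit
            self.limits = self.values.copy()
        self.limits = np.asarray(self.limits, dtype=float)
        if not (len(self.values) == len(self.censored) == len(self.limits)):
            raise CensoredDataError("values, censored and limits must have equal length")
        if np.any(self.values <= 0):
            raise CensoredDataError("concentrations must be positive")
        if not np.allclose(self.values[self.censored], self.limits[self.censored], rtol=1e-9):
            raise CensoredDataError("censored observations must be stored at their limit")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def detect_fraction(self) -> float:
        return float((~self.censored).mean())


@dataclass(frozen=True)
class KMStats:
    """Kaplan-Meier summary of one left-censored sample (all ng/ml)."""

    n: int
    detect_fraction: float
    mean: float
    sd: float
    median: float
    median_estimable: bool
    p95: float
    p95_valid: bool
    p99: float
    p99_valid: bool
    detect_range: tuple[float, float]


def _survival_steps(sample: CensoredSample, flip_constant: float):
    """Flipped product-limit curve as step arrays (times, survival after time)."""
    z = flip_constant - sample.values
    if np.any(z < 0):
        raise CensoredDataError("flip constant must exceed every observation")
    kmf = KaplanMeierFitter()
    kmf.fit(z, event_observed=~sample.censored)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    return times, surv, z


def km_stats(sample: CensoredSample, flip_constant: float | None = None) -> KMStats:
    """Kaplan-Meier mean, SD, median and tail quantiles of a censored sample.

    Parameters
    ----------
    sample
        At least two observations, at least one of them a detect.
    flip_constant
        Override for the flipping constant K (used by invariance tests);
        defaults to ``max(values) * (1 + 1e-9)``.
    """
    if len(sample) < 2:
        raise CensoredDataError("need at least two observations")
    if sample.censored.all():
        raise CensoredDataError("no detects: all observations censored")

    x = sample.values
    K = float(x.max()) * (1.0 + FLIP_EPS) if flip_constant is None else float(flip_constant)
    times, surv, z = _survival_steps(sample, K)
    z_max = float(z.max())  # truncation point: largest flipped observation

    # integrate the step survival curve on [0, z_max]:
    #   E[Z]  = int S(z) dz,   E[Z^2] = int 2 z S(z) dz
    knots = np.concatenate([times[times < z_max], [z_max]])
    if knots[0] > 0.0:
        knots = np.concatenate([[0.0], knots])
    # survival value on [knots[i], knots[i+1]) is the curve after knots[i]
    s_at = np.ones(len(knots))
    idx = np.searchsorted(times, knots, side="right") - 1
    valid = idx >= 0
    s_at[valid] = surv[idx[valid]]
    widths = np.diff(knots)
    seg_s = s_at[:-1]
    ez = float(np.sum(seg_s * widths))
    ez2 = float(np.sum(seg_s * (knots[1:] ** 2 - knots[:-1] ** 2)))  # = int 2 z S dz
    mean = K - ez
    var = ez2 - ez**2
    sd = float(np.sqrt(max(var, 0.0)))

    # back-transformed CDF: mass dS at flipped event time t sits at x = K - t;
    # F_x(K - t) = S(t^-), so the survival value *before* each drop is the CDF.
    drops = np.flatnonzero(np.diff(np.concatenate([[1.0], surv])) < 0)
    event_times = times[drops]
    s_before = np.concatenate([[1.0], surv])[drops]
    # events in the flipped domain are detects; snap K - t back onto the exact
    # observed detect values to undo float error from the flip
    detect_vals = np.sort(np.unique(x[~sample.censored]))
    x_events = K - event_times
    nearest = np.searchsorted(detect_vals, x_events)
    nearest = np.clip(nearest, 0, len(detect_vals) - 1)
    prev = np.clip(nearest - 1, 0, len(detect_vals) - 1)
    pick_prev = np.abs(detect_vals[prev] - x_events) <= np.abs(detect_vals[nearest] - x_events)
    x_events = np.where(pick_prev, detect_vals[prev], detect_vals[nearest])
    order = np.argsort(x_events)
    x_events = x_events[order]
    cdf_at_event = s_before[order]
    # tolerance absorbs float error accumulated in the product-limit products
    median_idx = np.flatnonzero(cdf_at_event >= 0.5 - 1e-10)
    if len(median_idx):
        median = float(x_events[median_idx[0]])
        median_estimable = True
    else:
        median = float("nan")
        median_estimable = False

    cens_frac = 1.0 - sample.detect_fraction
    p95 = float(np.quantile(x, 0.95))
    p99 = float(np.quantile(x, 0.99))
    detects = x[~sample.censored]
    return KMStats(
        n=len(sample),
        detect_fraction=sample.detect_fraction,
        mean=float(mean),
        sd=sd,
        median=median,
        median_estimable=median_estimable,
        p95=p95,
        p95_valid=0.95 > cens_frac,
        p99=p99,
        p99_valid=0.99 > cens_frac,
        detect_range=(float(detects.min()), float(detects.max())),
    )
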