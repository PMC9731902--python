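"""Centered Jaccard similarity of self-reported behaviors between housemates.

For one behavior, each within-household pair falls into one of four cells:
both report it (a), only member 1 (b), only member 2 (c), neither (d).  The
Jaccard coefficient J = a / (a + b + c) measures how often the behavior is
shared given that at least one member reports it, but its magnitude depends
on how common the behavior is.  We therefore *center* it by subtracting its
exact expectation under independence with fixed margins: holding m1 = a + b
member-1 yeses and m2 = a + c member-2 yeses fixed and permuting member-2
responses across pairs, the both-yes count is hypergeometric,

    a* ~ Hypergeometric(n, m1, m2),
    E[J] = sum_a P(a* = a) * a / (m1 + m2 - a)      (J := 0 when m1 + m2 = 0),

so centered J = J - E[J] is zero in expectation for unrelated respondents.
The expectation is computed analytically, not by simulation.

Confidence intervals bootstrap pairs with replacement, re-centering each
replicate on its own margins (the centered statistic is the estimand).
Households contributing several pairs induce mild dependence between pairs;
the interval treats pairs as exchangeable, a caveat documented in the
methods note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1_000
DEFAULT_MIN_USERS = 10
DEFAULT_MIN_NONUSERS = 10


class JaccardUndefinedError(ValueError):
    """No pair has any user of the behavior: J = a/(a+b+c) is undefined."""


@dataclass(frozen=True)
class JaccardResult:
    behavior_id: str
    n_pairs: int
    a: int
    b: int
    c: int
    d: int
    jaccard: float
    expected_jaccard: float
    centered: float
    ci95: tuple[float, float] | None
    n_users: int


def expected_jaccard(n: int, m1: int, m2: int) -> float:
    """Exact E[J] under the fixed-margins (hypergeometric) independence null."""
    if m1 + m2 == 0:
        return 0.0
    lo = max(0, m1 + m2 - n)
    hi = min(m1, m2)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, m1, m2)
    with np.errstate(invalid="ignore"):
        j = np.where(m1 + m2 - support > 0, support / (m1 + m2 - support), 1.0)
    return float(np.sum(pmf * j))


def _counts(r1: np.ndarray, r2: np.ndarray) -> tuple[int, int, int, int]:
    a = int(np.sum(r1 & r2))
    b = int(np.sum(r1 & ~r2))
    c = int(np.sum(~r1 & r2))
    d = int(np.sum(~r1 & ~r2))
    return a, b, c, d


def _pair_responses(pairs: pd.DataFrame, responses: pd.DataFrame, behavior_id: str):
    """Boolean response vectors (member 1, member 2) over complete pairs.

    Pairs where either member's response is missing or absent are dropped.
    """
    sub = responses[responses["behavior_id"] == behavior_id]
    if len(sub) == 0:
        raise KeyError(f"behavior {behavior_id!r} absent from responses")
    resp = sub.set_index("participant_id")["response"]
    r1, r2 = [], []
    for _, row in pairs.iterrows():
        v1 = resp.get(row["member_1"], "missing")
        v2 = resp.get(row["member_2"], "missing")
        if v1 == "missing" or v2 == "missing":
            continue
        r1.append(v1 == "yes")
        r2.append(v2 == "yes")
    return np.asarray(r1, dtype=bool), np.asarray(r2, dtype=bool)


def jaccard_per_behavior(
    pairs: pd.DataFrame, responses: pd.DataFrame, behavior_id: str
) -> JaccardResult:
    """Observed and null-expected Jaccard for one behavior (no CI)."""
    r1, r2 = _pair_responses(pairs, responses, behavior_id)
    n = len(r1)
    if n == 0:
        raise ValueError(f"behavior {behavior_id!r}: no complete pairs")
    a, b, c, d = _counts(r1, r2)
    if a + b + c == 0:
        raise JaccardUndefinedError(f"behavior {behavior_id!r}: no user in any pair")
    j = a / (a + b + c)
    ej = expected_jaccard(n, a + b, a + c)
    # distinct participants (among pair members) reporting the behavior
    members = set(pairs["member_1"]) | set(pairs["member_2"])
    sub = responses[responses["behavior_id"] == behavior_id]
    n_users = int(
        sub[(sub["participant_id"].isin(members)) & (sub["response"] == "yes")][
            "participant_id"
        ].nunique()
    )
    return JaccardResult(
        behavior_id=behavior_id,
        n_pairs=n,
        a=a,
        b=b,
        c=c,
        d=d,
        jaccard=float(j),
        expected_jaccard=float(ej),
        centered=float(j - ej),
        ci95=None,
        n_users=n_users,
    )


def jaccard_with_ci(
    pairs: pd.DataFrame,
    responses: pd.DataFrame,
    behavior_id: str,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> JaccardResult:
    """Centered Jaccard with a percentile bootstrap 95% CI.

    Resamples pairs with replacement; each replicate recomputes J and its
    exact null expectation from the replicate's own margins.  Replicates with
    undefined J (no users drawn) are dropped with a logged count.
    Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = jaccard_per_behavior(pairs, responses, behavior_id)
    r1, r2 = _pair_responses(pairs, responses, behavior_id)
    n = len(r1)
    rng = np.random.default_rng(seed)
    centered = []
    dropped = 0
    ej_cache: dict[tuple[int, int], float] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        a, b, c, _ = _counts(r1[idx], r2[idx])
        if a + b + c == 0:
            dropped += 1
            continue
        key = (a + b, a + c) if a + b <= a + c else (a + c, a + b)
        if key not in ej_cache:
            ej_cache[key] = expected_jaccard(n, key[0], key[1])
        centered.append(a / (a + b + c) - ej_cache[key])
    if dropped:
        logger.info("jaccard_with_ci(%s): %d undefined replicates dropped", behavior_id, dropped)
    if not centered:
        raise JaccardUndefinedError(f"behavior {behavior_id!r}: every bootstrap replicate undefined")
    lo, hi = np.percentile(centered, [2.5, 97.5])
    return replace(point, ci95=(float(lo), float(hi)))


def behavior_filter(
    results: list[JaccardResult],
    participants: pd.DataFrame,
    responses: pd.DataFrame,
    min_users: int = DEFAULT_MIN_USERS,
    min_nonusers: int = DEFAULT_MIN_NONUSERS,
) -> list[JaccardResult]:
    """Drop behaviors used by almost nobody or almost everybody; sort by J.

    User counts are taken over the participants entering the pair analysis
    (``participants``, typically the shared-home subset): a behavior needs at
    least ``min_users`` users and ``min_nonusers`` non-users to be retained.
    Sorted by raw Jaccard, descending.
    """
    ids = set(participants["participant_id"])
    sub = responses[responses["participant_id"].isin(ids)]
    kept = []
    for res in results:
        r = sub[sub["behavior_id"] == res.behavior_id]
        users = int((r["response"] == "yes").sum())
        nonusers = int((r["response"] == "no").sum())
        if users >= min_users and nonusers >= min_nonusers:
            kept.append(res)
    if not kept:
        logger.warning("behavior_filter: all behaviors excluded")
    return sorted(kept, key=lambda r: r.jaccard, reverse=True)
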