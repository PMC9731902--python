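"""Censored tau-b: hand oracles, classical reduction, censoring monotonicity."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from homeshare.censored_stats import CensoredSample
from homeshare.cohort import enumerate_pairs
from homeshare.correlation import (
    EmptyPairSetError,
    TauUndefinedError,
    pairwise_concentrations,
    tau_b_censored,
    tau_bootstrap,
)


def uncensored(values):
    values = np.asarray(values, float)
    return CensoredSample(values, np.zeros(len(values), bool))


def brute_force_tau_b(x, y):
    """Classical tau-b by direct double loop (independent oracle)."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[j] - x[i])
            sy = np.sign(y[j] - y[i])
            if sx == 0:
                tx += 1
            if sy == 0:
                ty += 1
            if sx * sy > 0:
                c += 1
            elif sx * sy < 0:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / np.sqrt((n0 - tx) * (n0 - ty))


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
    ],
)
def test_perfect_concordance_and_discordance(x, y, expected):
    assert tau_b_censored(uncensored(x), uncensored(y)) == pytest.approx(expected)


def test_censored_hand_enumeration_one_third():
    # x = {<1, 2, 3}, y = {<1, 3, 2}: C=2, D=1 over three determinate comparisons
    x = CensoredSample(np.array([1.0, 2, 3]), np.array([True, False, False]))
    y = CensoredSample(np.array([1.0, 3, 2]), np.array([True, False, False]))
    assert tau_b_censored(x, y) == pytest.approx(1 / 3, abs=1e-15)


def test_censored_hand_enumeration_with_tie_correction():
    # x = {<1, <1, 2}, y = {<1, 2, 3}: the both-censored x comparison is a tie,
    # so tau = (2 - 0) / sqrt((3-1)(3-0)) = 2/sqrt(6)
    x = CensoredSample(np.array([1.0, 1, 2]), np.array([True, True, False]))
    y = CensoredSample(np.array([1.0, 2, 3]), np.array([True, False, False]))
    assert tau_b_censored(x, y) == pytest.approx(2 / np.sqrt(6), abs=1e-15)


def test_reduces_to_classical_tau_b_without_censoring(rng):
    for _ in range(30):
        n = int(rng.integers(2, 30))
        x = rng.integers(1, 9, n).astype(float)  # integer grid to force ties
        y = rng.integers(1, 9, n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        ours = tau_b_censored(uncensored(x), uncensored(y))
        assert ours == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)
        assert ours == pytest.approx(kendalltau(x, y, variant="b").statistic, abs=1e-12)


def test_antisymmetry_on_uncensored_data(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    t1 = tau_b_censored(uncensored(np.exp(x)), uncensored(np.exp(y)))
    t2 = tau_b_censored(uncensored(np.exp(x)), uncensored(np.exp(-y)))
    assert t1 == pytest.approx(-t2, abs=1e-12)


def test_raising_limits_shrinks_concordance_excess(rng):
    # progressively censoring from below is pure information loss: each
    # determinate comparison either keeps its sign or becomes a tie, so the
    # net concordance count |C - D| is non-increasing (the tie-corrected
    # tau-b itself can fluctuate slightly because its denominator shrinks too)
    from homeshare.correlation import _comparison_signs

    def net_concordance(xs, ys):
        sx = _comparison_signs(xs.values, xs.censored)
        sy = _comparison_signs(ys.values, ys.censored)
        iu = np.triu_indices(len(xs), k=1)
        return abs(float(np.sum(sx[iu] * sy[iu])))

    for _ in range(10):
        x = rng.lognormal(0, 1, 30)
        y = x * rng.lognormal(0, 0.3, 30)  # positively correlated
        ys = uncensored(y)
        prev = net_concordance(uncensored(x), ys)
        for q in (0.2, 0.4, 0.6):
            lim = np.quantile(x, q)
            cens = x < lim
            xs = CensoredSample(np.where(cens, lim, x), cens)
            cur = net_concordance(xs, ys)
            assert cur <= prev + 1e-12
            prev = cur


def test_all_indeterminate_raises():
    x = CensoredSample(np.array([1.0, 1.0]), np.array([True, True]))
    y = CensoredSample(np.array([1.0, 2.0]), np.array([False, False]))
    with pytest.raises(TauUndefinedError):
        tau_b_censored(x, y)


def test_bootstrap_deterministic_and_floor_p_for_perfect_correlation():
    x = uncensored([1.0, 2, 3, 4, 5, 6, 7, 8])
    res1 = tau_bootstrap(x, x, n_boot=499, seed=42)
    res2 = tau_bootstrap(x, x, n_boot=499, seed=42)
    assert res1 == res2
    assert res1.tau == pytest.approx(1.0)
    assert res1.p_value == pytest.approx(1 / 499)


def test_bootstrap_imputation_handles_censoring(rng):
    x_raw = rng.lognormal(0, 1, 60)
    y_raw = x_raw * rng.lognormal(0, 0.5, 60)
    lim = np.quantile(x_raw, 0.3)
    cens = x_raw < lim
    x = CensoredSample(np.where(cens, lim, x_raw), cens)
    y = uncensored(y_raw)
    res = tau_bootstrap(x, y, n_boot=499, seed=0)
    assert res.ci95[0] <= res.tau <= res.ci95[1]
    assert res.p_value < 0.05  # strong dependence survives censoring


def test_pairwise_concentrations_alignment_and_drops(tiny_cohort):
    pairs = enumerate_pairs(tiny_cohort)
    x, y = pairwise_concentrations(tiny_cohort, pairs, "chemA", "all")
    assert len(x) == len(y) == len(pairs)
    # drop p5's measurement: pairs (p3,p5) and (p4,p5) become incomplete
    tiny_cohort.measurements = tiny_cohort.measurements[
        tiny_cohort.measurements["participant_id"] != "p5"
    ]
    x2, _ = pairwise_concentrations(tiny_cohort, pairs, "chemA", "all")
    assert len(x2) == len(pairs) - 2
    with pytest.raises(EmptyPairSetError):
        pairwise_concentrations(tiny_cohort, pairs, "chemA", "child_child")
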