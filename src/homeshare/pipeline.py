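"""End-to-end orchestration: cohort -> descriptive, correlation, similarity
and contribution tables, with a manifest that fully determines the outputs.

Stages are individually invokable (each is a plain function returning a
DataFrame) and :func:`run_pipeline` chains them, writing

* ``table2.csv``   — censored Kaplan-Meier summaries per chemical,
* ``fig1_table.csv`` — censored tau-b per chemical and pair-type stratum,
* ``fig2_table.csv`` — centered Jaccard per behavior with bootstrap CIs,
* ``fig3_table.csv`` — posterior contribution-fraction quantiles,
* ``diagnostics.json`` and ``manifest.json``.

One global seed deterministically derives per-stage seeds (SeedSequence with
a fixed stage index), so a stage can be replayed in isolation and a rerun
with the same manifest is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .censored_stats import CensoredDataError, CensoredSample, km_stats
from .cohort import Cohort, detection_gate, enumerate_pairs, load_cohort
from .contribution import build_model_data, fit, relative_contributions
from .correlation import EmptyPairSetError, TauUndefinedError, pairwise_concentrations, tau_bootstrap
from .similarity import JaccardUndefinedError, behavior_filter, jaccard_with_ci

logger = logging.getLogger(__name__)

_STAGE_INDEX = {"correlate": 1, "similarity": 2, "contributions": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(global_seed) state at a
    fixed stage index, reduced below 2**31."""
    state = np.random.SeedSequence(global_seed).generate_state(8)
    return int(state[_STAGE_INDEX[stage]] % (2**31))


@dataclass
class RunConfig:
    cohort_dir: str
    out_dir: str
    max_days: int = 28
    detection_gate_fraction: float = 0.35
    chemicals: list[str] | None = None  # explicit analysis list; None -> gate
    model_chemicals: list[str] | None = None  # None -> same as `chemicals`
    n_boot_tau: int = 10_000
    n_boot_jaccard: int = 1_000
    min_users: int = 10
    min_nonusers: int = 10
    chains: int = 4
    draws: int = 1000
    check_convergence: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def describe_table(cohort: Cohort, chemicals: list[str], shared_only: bool = True) -> pd.DataFrame:
    """Kaplan-Meier descriptive statistics, one row per chemical."""
    m = cohort.measurements
    if shared_only:
        ids = set(cohort.shared_participants()["participant_id"])
        m = m[m["participant_id"].isin(ids)]
    rows = []
    for chem in chemicals:
        sub = m[m["chemical_id"] == chem]
        if len(sub) < 2:
            logger.warning("describe: %s has <2 measurements; skipped", chem)
            continue
        sample = CensoredSample(
            sub["value"].to_numpy(), sub["censored"].to_numpy(bool), sub["mrl"].to_numpy()
        )
        try:
            st = km_stats(sample)
        except CensoredDataError as exc:
            logger.warning("describe: %s skipped (%s)", chem, exc)
            continue
        rows.append(
            {
                "chemical_id": chem,
                "n": st.n,
                "pct_detect": round(100 * st.detect_fraction, 1),
                "median_mrl": float(np.median(sample.limits)),
                "km_mean": st.mean,
                "km_sd": st.sd,
                "km_median": st.median,
                "p95": st.p95,
                "p99": st.p99,
                "detect_min": st.detect_range[0],
                "detect_max": st.detect_range[1],
            }
        )
    return pd.DataFrame(rows)


def correlation_table(
    cohort: Cohort,
    pairs: pd.DataFrame,
    chemicals: list[str],
    n_boot: int,
    seed: int,
    pair_filters: tuple[str, ...] = ("all", "adult_adult", "adult_child"),
) -> pd.DataFrame:
    """Censored tau-b with bootstrap CI/p per chemical and pair-type stratum."""
    rows = []
    for chem in chemicals:
        for flt in pair_filters:
            try:
                x, y = pairwise_concentrations(cohort, pairs, chem, flt)
                res = tau_bootstrap(x, y, n_boot=n_boot, seed=seed, chemical_id=chem, pair_filter=flt)
            except (EmptyPairSetError, TauUndefinedError) as exc:
                logger.info("correlate: %s/%s skipped (%s)", chem, flt, exc)
                continue
            rows.append(
                {
                    "chemical_id": chem,
                    "pair_filter": flt,
                    "n_pairs": res.n_pairs,
                    "tau": res.tau,
                    "ci_lo": res.ci95[0],
                    "ci_hi": res.ci95[1],
                    "p_value": res.p_value,
                    "significant": res.p_value < 0.05,
                    "n_boot": res.n_boot,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)


def similarity_table(
    cohort: Cohort,
    pairs: pd.DataFrame,
    n_boot: int,
    seed: int,
    min_users: int = 10,
    min_nonusers: int = 10,
) -> pd.DataFrame:
    """Centered Jaccard per behavior, filtered and sorted as in the figure."""
    behaviors = sorted(cohort.behaviors["behavior_id"].unique())
    results = []
    for bid in behaviors:
        try:
            results.append(jaccard_with_ci(pairs, cohort.behaviors, bid, n_boot=n_boot, seed=seed))
        except (JaccardUndefinedError, ValueError, KeyError) as exc:
            logger.info("similarity: %s skipped (%s)", bid, exc)
    pair_members = cohort.participants[
        cohort.participants["participant_id"].isin(set(pairs["member_1"]) | set(pairs["member_2"]))
    ]
    kept = behavior_filter(results, pair_members, cohort.behaviors, min_users, min_nonusers)
    return pd.DataFrame(
        [
            {
                "behavior_id": r.behavior_id,
                "n_pairs": r.n_pairs,
                "a_both": r.a,
                "b_only1": r.b,
                "c_only2": r.c,
                "d_neither": r.d,
                "jaccard": r.jaccard,
                "expected_jaccard": r.expected_jaccard,
                "centered": r.centered,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "n_users": r.n_users,
            }
            for r in kept
        ]
    )


def contribution_table(
    cohort: Cohort,
    chemicals: list[str],
    chains: int,
    draws: int,
    seed: int,
    check: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Posterior contribution-fraction quantiles per chemical + diagnostics."""
    rows = []
    diagnostics = {}
    for i, chem in enumerate(chemicals):
        data = build_model_data(cohort, cohort.chemicals[chem])
        res = fit(data, chains=chains, draws=draws, seed=seed + i, check=check)
        post = relative_contributions(res)
        for ci, comp in enumerate(("personal", "others", "household")):
            rows.append(
                {
                    "chemical_id": chem,
                    "component": comp,
                    "q5": post.quantiles[5][ci],
                    "q25": post.quantiles[25][ci],
                    "median": post.quantiles[50][ci],
                    "q75": post.quantiles[75][ci],
                    "q95": post.quantiles[95][ci],
                }
            )
        diagnostics[chem] = {
            "rhat": post.rhat.tolist(),
            "ess_bulk": post.ess_bulk.tolist(),
            "divergences": post.divergences,
            "n_draws": post.n_draws,
            "n_missing_survey": data.n_missing_survey,
            "seed": seed + i,
        }
    return pd.DataFrame(rows), diagnostics


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(config.cohort_dir)
    pairs = enumerate_pairs(cohort, max_days=config.max_days)
    chemicals = config.chemicals or detection_gate(cohort, config.detection_gate_fraction)
    if not chemicals:
        raise ValueError("no chemicals pass the detection gate and none were specified")

    tables: dict[str, pd.DataFrame] = {}
    tables["table2"] = describe_table(cohort, chemicals)
    tables["fig1_table"] = correlation_table(
        cohort, pairs, chemicals, config.n_boot_tau, stage_seed(config.seed, "correlate")
    )
    tables["fig2_table"] = similarity_table(
        cohort,
        pairs,
        config.n_boot_jaccard,
        stage_seed(config.seed, "similarity"),
        config.min_users,
        config.min_nonusers,
    )
    model_chems = config.model_chemicals or chemicals
    tables["fig3_table"], diagnostics = contribution_table(
        cohort,
        model_chems,
        config.chains,
        config.draws,
        stage_seed(config.seed, "contributions"),
        check=config.check_convergence,
    )
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    manifest = {
        "config": asdict(config),
        "chemicals": chemicals,
        "model_chemicals": model_chems,
        "n_pairs": int(len(pairs)),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_INDEX},
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables


def sensitivity_compare(run_a: str | Path, run_b: str | Path) -> pd.DataFrame:
    """Side-by-side tau and contribution medians from two completed runs.

    Raises ``ValueError`` when the two runs analyzed different chemical sets.
    """
    run_a, run_b = Path(run_a), Path(run_b)
    fig1_a = pd.read_csv(run_a / "fig1_table.csv")
    fig1_b = pd.read_csv(run_b / "fig1_table.csv")
    if set(fig1_a["chemical_id"]) != set(fig1_b["chemical_id"]):
        raise ValueError("runs analyzed different chemical sets")
    tau = fig1_a.merge(
        fig1_b, on=["chemical_id", "pair_filter"], suffixes=("_a", "_b"), how="inner"
    )[["chemical_id", "pair_filter", "n_pairs_a", "n_pairs_b", "tau_a", "tau_b"]]
    tau["quantity"] = "tau"
    tau = tau.rename(columns={"tau_a": "value_a", "tau_b": "value_b"})
    frames = [tau]
    f3a, f3b = run_a / "fig3_table.csv", run_b / "fig3_table.csv"
    if f3a.exists() and f3b.exists():
        fa = pd.read_csv(f3a)
        fb = pd.read_csv(f3b)
        fr = fa.merge(fb, on=["chemical_id", "component"], suffixes=("_a", "_b"), how="inner")
        fr = fr[["chemical_id", "component", "median_a", "median_b"]].rename(
            columns={"median_a": "value_a", "median_b": "value_b", "component": "pair_filter"}
        )
        fr["quantity"] = "contribution_median"
        fr["n_pairs_a"] = fr["n_pairs_b"] = np.nan
        frames.append(fr)
    out = pd.concat(frames, ignore_index=True)
    out["abs_diff"] = (out["value_a"] - out["value_b"]).abs()
    return out
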