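"""Comparator methods and the simulation benchmarking harness.

The functional test is compared against the two approaches in routine use
for differential HDX-MS:

- a two-sample t test applied pointwise at each exposure time, the many
  per-time p-values combined into one per-peptide p-value by the harmonic
  mean;
- a linear mixed model with fixed effects for time (as a factor, or
  shifted-log continuous time), condition and their interaction, and a
  random intercept per replicate; the condition-related coefficient
  p-values are again combined by harmonic mean.

Calls at a fixed FDR threshold (BH-adjusted p < 0.05) are scored against
the simulation ground truth with precision, recall and their harmonic mean
(the F-score).  A null-permutation harness relabels replicates of a single
condition into two pseudo-conditions to count false positives, the standard
empirical check of FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import HDXDataset
from .kinetics import ModelSpec
from .simulate import Scenario, simulate_experiment
from .testing import adjust_bh, run_functional_test

METHODS = ("functional", "t_test", "lmm")


def pointwise_t_test(
    dataset: HDXDataset, analyte_id: str, equal_var: bool = False
) -> pd.DataFrame:
    """Two-sample t test at each exposure time for one analyte.

    Welch's form by default (``equal_var=False``); ``equal_var=True`` pools
    variances.  A time point needs at least two replicates in each condition
    and non-degenerate variance, else its p-value is NaN; in particular the
    t = 0 point, where both conditions are undeuterated by construction, is
    typically degenerate and excluded that way.

    Returns a frame with columns ``exposure_s`` and ``p_value``.
    """
    sub = dataset.analyte_table(analyte_id, drop_missing=True)
    conds = [c for c in dataset.conditions if (sub["condition"] == c).any()]
    if len(conds) != 2:
        raise ValueError("pointwise t test requires exactly two observed conditions")
    rows = []
    for t in np.sort(sub["exposure_s"].unique()):
        at_t = sub[sub["exposure_s"] == t]
        g1 = at_t.loc[at_t["condition"] == conds[0], "value"].to_numpy()
        g2 = at_t.loc[at_t["condition"] == conds[1], "value"].to_numpy()
        p = np.nan
        if g1.size >= 2 and g2.size >= 2 and (np.ptp(g1) > 0 or np.ptp(g2) > 0):
            p = float(stats.ttest_ind(g1, g2, equal_var=equal_var).pvalue)
        rows.append({"exposure_s": float(t), "p_value": p})
    return pd.DataFrame(rows, columns=["exposure_s", "p_value"])


def harmonic_mean_p(p_values) -> float:
    """Harmonic-mean combination k / sum(1/p_j) over the non-NaN values.

    NaN if every input is NaN; 0 if any input is exactly 0.  Values must lie
    in [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return np.nan
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        return 0.0
    return float(p.size / np.sum(1.0 / p))


def lmm_test(
    dataset: HDXDataset, analyte_id: str, time_as_factor: bool = True
) -> tuple[pd.DataFrame, float]:
    """Random-intercept mixed-model comparator for one analyte.

    Fits value ~ time * condition with a random intercept per replicate
    (statsmodels ``MixedLM``); time enters as a factor by default, or as
    shifted-log continuous time log(t + delta) with delta the smallest
    positive observed time.  Returns the per-coefficient p-values for every
    condition-related term (main effect and interactions) and their
    harmonic-mean combination.  Singular or unreplicated designs yield NaN
    with a warning rather than an exception.
    """
    import statsmodels.formula.api as smf

    sub = dataset.analyte_table(analyte_id, drop_missing=True).copy()
    conds = sorted(sub["condition"].unique())
    if len(conds) < 2:
        raise ValueError("lmm test requires at least two observed conditions")
    empty = pd.DataFrame(columns=["term", "p_value"])
    if sub["replicate"].nunique() < 2:
        warnings.warn("no nested replicate structure; mixed model inapplicable")
        return empty, np.nan
    if time_as_factor:
        sub["time"] = sub["exposure_s"].astype(str)
        formula = "value ~ C(time) * C(condition)"
    else:
        delta = float(sub.loc[sub["exposure_s"] > 0, "exposure_s"].min())
        sub["logt"] = np.log(sub["exposure_s"] + delta)
        formula = "value ~ logt * C(condition)"
    pvals = None
    # The replicate variance is often at its zero boundary; the derivative-
    # free optimiser is the robust first choice there.
    for method in ("powell", None):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, sub, groups=sub["replicate"])
                fitres = (
                    model.fit(reml=True, method=method)
                    if method
                    else model.fit(reml=True)
                )
            pvals = fitres.pvalues
            break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if pvals is None:
        warnings.warn(f"singular mixed-model fit for {analyte_id}")
        return empty, np.nan
    cond_terms = [
        term for term in pvals.index
        if "condition" in term and term != "Group Var"
    ]
    table = pd.DataFrame(
        {"term": cond_terms, "p_value": [float(pvals[t]) for t in cond_terms]}
    )
    return table, harmonic_mean_p(table["p_value"].to_numpy())


def f_score(truth: pd.DataFrame, calls: pd.DataFrame) -> dict:
    """Precision/recall/F of significance calls against simulation truth.

    ``truth`` has columns (analyte_id, perturbed); ``calls`` has columns
    (analyte_id, significant).  Both must cover the same analyte set.
    Conventions: F = 0 when tp = 0 with any fp or fn; F = 1 on an all-null
    dataset called clean.
    """
    t = truth.set_index("analyte_id")["perturbed"].astype(bool)
    c = calls.set_index("analyte_id")["significant"].astype(bool)
    if set(t.index) != set(c.index):
        raise ValueError("truth and calls cover different analyte sets")
    c = c.reindex(t.index)
    tp = int((t & c).sum())
    fp = int((~t & c).sum())
    fn = int((t & ~c).sum())
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if fn == 0 else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    if tp == 0:
        f = 1.0 if (fp == 0 and fn == 0) else 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": precision, "recall": recall, "f_score": f,
    }


def _method_calls(
    dataset: HDXDataset,
    method: str,
    spec: ModelSpec | None,
    fdr: float,
) -> pd.DataFrame:
    """Per-analyte significance calls at BH-adjusted p < fdr for one method."""
    if method == "functional":
        res = run_functional_test(dataset, spec=spec, fdr_level=fdr)
        out = res[["analyte_id", "p_adjusted"]].copy()
    else:
        combined = []
        for analyte_id in dataset.analyte_ids:
            if method == "t_test":
                per_t = pointwise_t_test(dataset, analyte_id)
                combined.append(harmonic_mean_p(per_t["p_value"].to_numpy()))
            elif method == "lmm":
                _, p = lmm_test(dataset, analyte_id)
                combined.append(p)
            else:
                raise ValueError(f"unknown method: {method!r}")
        out = pd.DataFrame(
            {"analyte_id": dataset.analyte_ids, "p_value": combined}
        )
        out["p_adjusted"] = adjust_bh(out["p_value"].to_numpy())
    out["significant"] = out["p_adjusted"] < fdr
    # NaN adjusted values (untestable analytes) are never called.
    out.loc[~np.isfinite(out["p_adjusted"]), "significant"] = False
    return out[["analyte_id", "p_adjusted", "significant"]]


def run_benchmark(
    scenarios: dict[int, Scenario],
    methods=("functional", "t_test"),
    n_reps: int = 10,
    seed: int = 0,
    spec: ModelSpec | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Simulate, test and score each scenario x method x repetition.

    Every repetition draws a fresh dataset from the scenario (seeds derived
    deterministically from ``seed``), runs each method, calls significance
    at BH-adjusted p < ``fdr`` and scores the calls against ground truth.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method: {m!r}")
    rows = []
    root = np.random.SeedSequence(seed)
    for scen_id, scenario in scenarios.items():
        child_seeds = root.spawn(n_reps)
        for rep in range(n_reps):
            rep_seed = int(child_seeds[rep].generate_state(1)[0] % (2**31))
            dataset, truth = simulate_experiment(scenario, seed=rep_seed)
            for method in methods:
                calls = _method_calls(dataset, method, spec, fdr)
                score = f_score(truth, calls)
                rows.append(
                    {"scenario": scen_id, "method": method, "rep": rep, **score}
                )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario", "method", "rep", "tp", "fp", "fn",
            "precision", "recall", "f_score",
        ],
    )


def null_permutation_experiment(
    dataset: HDXDataset,
    split: tuple[int, int] = (3, 4),
    n_perms: int = 6,
    methods=("functional", "t_test"),
    spec: ModelSpec | None = None,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """False-positive counts from falsely splitting one condition in two.

    The dataset must carry a single condition with at least ``sum(split)``
    replicates.  For each permutation, replicates are relabelled at random
    into pseudo-conditions A (``split[0]`` replicates) and B (``split[1]``),
    each method is run, and analytes with BH-adjusted p < ``fdr`` are
    counted.  Since the data are genuine replicates, every call is a false
    positive.
    """
    if dataset.n_conditions != 1:
        raise ValueError("null permutation requires a single-condition dataset")
    replicates = sorted(dataset.table["replicate"].unique())
    if len(replicates) < sum(split):
        raise ValueError(
            f"need at least {sum(split)} replicates, found {len(replicates)}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for perm in range(n_perms):
        order = rng.permutation(replicates)
        group_a = set(order[: split[0]])
        table = dataset.table.drop(columns=["analyte_id"]).copy()
        table["condition"] = np.where(
            table["replicate"].isin(group_a), "A", "B"
        )
        pseudo = HDXDataset(table)
        for method in methods:
            calls = _method_calls(pseudo, method, spec, fdr)
            rows.append(
                {
                    "permutation": perm,
                    "method": method,
                    "false_positives": int(calls["significant"].sum()),
                    "n_analytes": len(calls),
                }
            )
    return pd.DataFrame(
        rows, columns=["permutation", "method", "false_positives", "n_analytes"]
    )
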