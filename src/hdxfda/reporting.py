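"""Residue-level summaries and plot-ready tables.

Peptide-level p-values are projected onto the protein sequence by taking,
at each residue, the harmonic mean of the p-values of every peptide whose
span covers it — a visualisation aid, not an inferential quantity.
Manhattan tables arrange peptides along the sequence against
-log10(adjusted p) with a significance flag, and kinetic-plot tables bundle
the observed points with the fitted null/alternative curves on a log-time
grid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .benchmark import harmonic_mean_p
from .dataset import HDXDataset
from .effects import evaluation_grid
from .kinetics import evaluate_model
from .testing import NestedFitPair, adjust_bh


def residue_pvalues(
    results: pd.DataFrame,
    spans: pd.DataFrame,
    protein_length: int,
    p_column: str = "p_value",
) -> pd.DataFrame:
    """Residue-level harmonic-mean p-values.

    ``results`` carries analyte_id and p-value columns; ``spans`` carries
    analyte_id, start, end (1-based inclusive).  For each residue j the
    summary is the harmonic mean of the p-values of all covering peptides;
    uncovered residues get NaN.  Both the raw harmonic mean and its
    BH-adjusted counterpart are reported, along with -log10 values.
    """
    merged = results.merge(spans[["analyte_id", "start", "end"]], on="analyte_id")
    if len(merged) and (
        (merged["start"] < 1).any() or (merged["end"] > protein_length).any()
    ):
        raise ValueError("peptide span outside protein [1, J]")
    per_residue: list[list[float]] = [[] for _ in range(protein_length)]
    for _, row in merged.iterrows():
        p = row[p_column]
        if not np.isfinite(p):
            continue
        for j in range(int(row["start"]) - 1, int(row["end"])):
            per_residue[j].append(float(p))
    rows = []
    for j, ps in enumerate(per_residue, start=1):
        p_hm = harmonic_mean_p(ps) if ps else np.nan
        rows.append({"residue": j, "coverage": len(ps), "p_hm": p_hm})
    out = pd.DataFrame(rows, columns=["residue", "coverage", "p_hm"])
    out["p_hm_adjusted"] = adjust_bh(out["p_hm"].to_numpy())
    with np.errstate(divide="ignore"):
        out["neg_log10"] = -np.log10(out["p_hm_adjusted"])
    return out


def manhattan_table(results: pd.DataFrame, spans: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Peptides ordered along the sequence against -log10(adjusted p).

    The significance flag uses a strict inequality, so a peptide sitting
    exactly at the threshold is not flagged.
    """
    df = results.merge(spans[["analyte_id", "start", "end"]], on="analyte_id")
    df = df.sort_values(["start", "end", "analyte_id"], kind="stable").reset_index(drop=True)
    with np.errstate(divide="ignore"):
        df["neg_log10_p_adjusted"] = -np.log10(df["p_adjusted"])
    df["significant"] = df["p_adjusted"] < fdr
    df.loc[~np.isfinite(df["p_adjusted"]), "significant"] = False
    cols = [
        "analyte_id", "start", "end", "p_value", "p_adjusted",
        "neg_log10_p_adjusted", "significant",
    ]
    return df[[c for c in cols if c in df.columns]]


def kinetic_plot_data(
    dataset: HDXDataset,
    analyte_id: str,
    fits: NestedFitPair | None = None,
) -> dict[str, pd.DataFrame]:
    """Observed points plus fitted curves for one analyte's kinetic plot.

    Returns a dict with an ``observed`` table (exposure_s, condition,
    replicate, value) and, when fits are supplied, a ``curves`` table
    evaluated on the log-time grid with a ``model`` column taking the value
    "null" or the condition label.
    """
    obs = dataset.analyte_table(analyte_id, drop_missing=True)[
        ["exposure_s", "condition", "replicate", "value"]
    ].reset_index(drop=True)
    out: dict[str, pd.DataFrame] = {"observed": obs}
    if fits is None:
        return out
    t_obs = obs["exposure_s"].to_numpy(dtype=float)
    grid = evaluation_grid(float(t_obs.min()), float(t_obs.max()))
    frames = [
        pd.DataFrame(
            {"exposure_s": grid, "model": "null",
             "value": evaluate_model(fits.null_fit.params, grid)}
        )
    ]
    for cond, fit in fits.alt_fits.items():
        frames.append(
            pd.DataFrame(
                {"exposure_s": grid, "model": cond,
                 "value": evaluate_model(fit.params, grid)}
            )
        )
    out["curves"] = pd.concat(frames, ignore_index=True)
    return out


def plot_kinetics(plot_data: dict[str, pd.DataFrame], ax=None, title: str | None = None):
    """Render a kinetic plot (observed points + fitted curves); optional layer.

    Requires matplotlib; the tabular `kinetic_plot_data` output is the
    tested surface and this is a thin convenience on top of it.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    obs = plot_data["observed"]
    for cond, grp in obs.groupby("condition"):
        ax.scatter(grp["exposure_s"], grp["value"], label=f"{cond} (obs)", s=18)
    if "curves" in plot_data:
        for model, grp in plot_data["curves"].groupby("model"):
            style = "--" if model == "null" else "-"
            ax.plot(grp["exposure_s"], grp["value"], style, label=model)
    ax.set_xscale("symlog", linthresh=max(obs["exposure_s"][obs["exposure_s"] > 0].min(), 1e-9))
    ax.set_xlabel("exposure (s)")
    ax.set_ylabel("centroid mass (Da)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
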