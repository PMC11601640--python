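"""PDX copy-number consensus calling and expression association.

Numeric copy number maps to a categorical status (2 = diploid, >2 and <5 =
gain, >=5 = amplification; <2 is a flagged ``loss`` outside the three-class
scheme).  Per gene and model the consensus is the majority vote over samples,
ties breaking toward the more severe class.  Model-level expression is the
arithmetic mean FPKM, and the association between consensus class and
expression is a one-way fixed-effects ANOVA.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

STATUS_ORDER = ("loss", "diploid", "gain", "amplification")
STATUS_RANK = {s: i for i, s in enumerate(STATUS_ORDER)}
AMPLIFICATION_CN = 5.0


def call_status(cn: float) -> str:
    """Map numeric copy number to categorical status (fractional CN allowed)."""
    if not np.isfinite(cn) or cn < 0:
        raise ValueError(f"copy number must be finite and >= 0, got {cn}")
    if cn < 2:
        return "loss"
    if cn == 2:
        return "diploid"
    if cn < AMPLIFICATION_CN:
        return "gain"
    return "amplification"


def consensus_by_majority(statuses: list[str] | tuple[str, ...]) -> tuple[str, bool]:
    """Modal status over samples; returns (status, tie_flag).

    ``loss`` votes are outside the three-class scheme and excluded from the
    denominator; ties break toward the higher-rank (more severe) status.
    """
    if len(statuses) == 0:
        raise ValueError("empty vote set")
    for s in statuses:
        if s not in STATUS_RANK:
            raise ValueError(f"unknown status {s!r}")
    votes = [s for s in statuses if s != "loss"]
    if not votes:
        return "loss", False
    counts = Counter(votes)
    top = max(counts.values())
    winners = [s for s, c in counts.items() if c == top]
    tie = len(winners) > 1
    winner = max(winners, key=lambda s: STATUS_RANK[s])
    return winner, tie


def model_expression(fpkm: list[float] | np.ndarray) -> tuple[float, int]:
    """Arithmetic mean FPKM over samples; returns (mean, n_missing)."""
    arr = np.asarray(fpkm, dtype=float)
    missing = int(np.sum(~np.isfinite(arr)))
    vals = arr[np.isfinite(arr)]
    if vals.size == 0:
        return np.nan, missing
    return float(vals.mean()), missing


def consensus_table(cn: pd.DataFrame, fpkm: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (gene, model): consensus status, tie flag, vote counts and mean FPKM.

    ``cn`` needs columns gene/sample/model/cn; ``fpkm`` gene/sample/model/fpkm.
    """
    cn = cn.copy()
    cn["status"] = cn["cn"].map(call_status)
    rows = []
    for (gene, model), grp in cn.groupby(["gene", "model"], sort=True):
        status, tie = consensus_by_majority(list(grp["status"]))
        rows.append(
            {
                "gene": gene,
                "model": model,
                "consensus": status,
                "tie": tie,
                "n_samples": len(grp),
                "n_loss_excluded": int((grp["status"] == "loss").sum()),
            }
        )
    out = pd.DataFrame(rows)
    if fpkm is not None:
        means = (
            fpkm.groupby(["gene", "model"])["fpkm"]
            .apply(lambda v: model_expression(v.to_numpy())[0])
            .rename("mean_fpkm")
            .reset_index()
        )
        out = out.merge(means, on=["gene", "model"], how="left")
    return out


def amplification_frequency(
    consensus: pd.DataFrame,
    annotation: pd.DataFrame,
    loess_frac: float = 0.3,
    smooth: bool = True,
) -> pd.DataFrame:
    """Percent of models amplified per gene, ordered along the chromosome.

    ``annotation`` needs columns gene/chrom/start (1-based start, used only
    for ordering).  Genes without annotation are excluded with a warning.
    Adds a loess (tricube local linear regression) trend when ``smooth``.
    """
    n_models = consensus["model"].nunique()
    freq = (
        consensus.assign(amp=consensus["consensus"] == "amplification")
        .groupby("gene")["amp"]
        .sum()
        .mul(100.0 / n_models)
        .rename("pct_amplified")
        .reset_index()
    )
    missing = set(freq["gene"]) - set(annotation["gene"])
    if missing:
        warnings.warn(f"{len(missing)} genes lack annotation and were excluded")
    out = freq.merge(annotation[["gene", "chrom", "start"]], on="gene", how="inner")
    out = out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if smooth and len(out) >= 3:
        trends = []
        for _, grp in out.groupby("chrom", sort=False):
            sm = lowess(
                grp["pct_amplified"].to_numpy(),
                grp["start"].to_numpy(dtype=float),
                frac=loess_frac,
                return_sorted=False,
            )
            trends.append(pd.Series(sm, index=grp.index))
        out["loess"] = pd.concat(trends).sort_index()
    return out


def cn_expression_anova(
    model_table: pd.DataFrame,
    status_col: str = "consensus",
    value_col: str = "mean_fpkm",
) -> dict:
    """One-way fixed-effects ANOVA of model-level expression across CN classes.

    Returns {"F", "p", "groups": {status: n}}.  Requires >= 2 non-empty groups
    and >= 3 total observations.
    """
    df = model_table[[status_col, value_col]].dropna()
    groups = {s: g[value_col].to_numpy(dtype=float) for s, g in df.groupby(status_col)}
    groups = {s: v for s, v in groups.items() if v.size > 0}
    if len(groups) < 2:
        raise ValueError("ANOVA undefined for fewer than 2 groups")
    if sum(v.size for v in groups.values()) < 3:
        raise ValueError("ANOVA needs at least 3 observations")
    f, p = stats.f_oneway(*groups.values())
    return {"F": float(f), "p": float(p), "groups": {s: int(v.size) for s, v in groups.items()}}
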