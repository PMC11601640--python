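"""TMT protein-group filtering, normalization and differential abundance.

Mirrors a standard Perseus-style post-quantification workflow: drop reverse /
only-identified-by-site / potential-contaminant groups, log2-transform, keep
rows with all values present and >= 2 unique+razor peptides, median-subtract
per channel, per-protein two-sample Student's t-tests, then classify with
|Log2FC| >= 1.0 and -log10 p >= 2.0 (both inclusive).  Log2FC is
treated - control.  No multiple-testing correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

INTENSITY_PREFIX = "Reporter intensity corrected"
PEPTIDE_COL = "Razor + unique peptides"
FLAG_COLS = ("Reverse", "Only identified by site", "Potential contaminant")
LOG2FC_THRESHOLD = 1.0
NEG_LOG10_P_THRESHOLD = 2.0
_P_FLOOR = 1e-300  # keeps p in (0, 1] when group variance is zero


def intensity_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c.startswith(INTENSITY_PREFIX)]


def clean_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove flagged protein groups; returns (filtered, removal counts)."""
    keep = pd.Series(True, index=matrix.index)
    counts: dict[str, int] = {}
    for col in FLAG_COLS:
        if col in matrix.columns:
            flagged = matrix[col].astype(str).str.strip() == "+"
            counts[col] = int((flagged & keep).sum())
            keep &= ~flagged
        else:
            counts[col] = 0
    return matrix.loc[keep].copy(), counts


def transform_and_filter(matrix: pd.DataFrame, min_peptides: int = 2) -> pd.DataFrame:
    """Log2 transform; keep rows with all channel values present (and
    positive) and at least ``min_peptides`` unique+razor peptides."""
    cols = intensity_columns(matrix)
    if not cols:
        raise ValueError("no reporter-intensity columns found")
    intens = matrix[cols].apply(pd.to_numeric, errors="coerce")
    complete = intens.notna().all(axis=1) & (intens > 0).all(axis=1)
    if PEPTIDE_COL in matrix.columns:
        complete &= pd.to_numeric(matrix[PEPTIDE_COL], errors="coerce") >= min_peptides
    return np.log2(intens.loc[complete])


def median_normalize(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each channel's median; every channel median becomes 0."""
    if log2_matrix.empty:
        raise ValueError("empty matrix")
    return log2_matrix - log2_matrix.median(axis=0)


def differential_test(
    normalized: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = True,
    lfc_threshold: float = LOG2FC_THRESHOLD,
    neg_log10_p_threshold: float = NEG_LOG10_P_THRESHOLD,
) -> pd.DataFrame:
    """Per-protein two-sample t-test of group A (treated) vs B (control).

    Returns columns log2fc (mean A - mean B), t, p, neg_log10_p and
    classification in {up, down, unchanged}.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 channels per group")
    a = normalized[list(group_a)].to_numpy(dtype=float)
    b = normalized[list(group_b)].to_numpy(dtype=float)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p = np.where(zero_var & (log2fc == 0), 1.0, p)
    p = np.where(zero_var & (log2fc != 0), _P_FLOOR, p)
    p = np.clip(p, _P_FLOOR, 1.0)
    nlp = -np.log10(p)
    cls = np.where(
        (log2fc >= lfc_threshold) & (nlp >= neg_log10_p_threshold),
        "up",
        np.where(
            (log2fc <= -lfc_threshold) & (nlp >= neg_log10_p_threshold),
            "down",
            "unchanged",
        ),
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "neg_log10_p": nlp, "classification": cls},
        index=normalized.index,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.clip(adj, 0, 1)
    return out


def overlap_sets(ids_a, ids_b) -> dict:
    """Venn counts for two protein-group id sets."""
    sa, sb = set(ids_a), set(ids_b)
    inter = sa & sb
    return {
        "n_a": len(sa),
        "n_b": len(sb),
        "intersection": len(inter),
        "only_a": len(sa - sb),
        "only_b": len(sb - sa),
        "shared_ids": sorted(inter),
    }


@dataclass
class TMTPipelineResult:
    removed: dict[str, int]
    n_quantified: int
    results: pd.DataFrame


def run_tmt_pipeline(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    min_peptides: int = 2,
    equal_var: bool = True,
) -> TMTPipelineResult:
    """clean -> log2/filter -> median-normalize -> test, in one call."""
    cleaned, removed = clean_matrix(matrix)
    log2m = transform_and_filter(cleaned, min_peptides=min_peptides)
    norm = median_normalize(log2m)
    res = differential_test(norm, group_a, group_b, equal_var=equal_var)
    return TMTPipelineResult(removed=removed, n_quantified=len(norm), results=res)


def read_maxquant(path, sep: str = "\t") -> pd.DataFrame:
    """Thin reader for a MaxQuant proteinGroups-style TSV."""
    df = pd.read_csv(path, sep=sep)
    id_col = next(
        (c for c in ("protein_group", "Protein IDs", "Majority protein IDs") if c in df.columns),
        None,
    )
    if id_col is not None:
        df = df.set_index(id_col)
    return df
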