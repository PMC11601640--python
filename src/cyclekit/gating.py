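"""Bivariate DNA-content / EdU cell-cycle phase gating.

DNA values are rescaled so the dominant histogram mode sits at 2N (ties break
toward the lower mode, so a balanced G1/G2 population anchors on G1).  The
EdU-positivity threshold is mean + k*sd of the EdU-negative mode.  Phases:
S if EdU-positive, else G1 below the mid-cut (default 3N), else G2/M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class PhaseGates:
    dna_2n: float  # anchor, original units
    dna_4n: float
    mid_cut_n: float = 3.0  # N-units
    edu_threshold: float = np.nan
    anchor_tolerance: float = 0.1

    def __post_init__(self) -> None:
        if self.dna_2n <= 0 or self.dna_4n <= 0:
            raise ValueError("anchors must be positive")
        if abs(self.dna_4n - 2 * self.dna_2n) > self.anchor_tolerance * 2 * self.dna_2n:
            raise ValueError("4N anchor must be ~2x the 2N anchor")


def _histogram_mode(values: np.ndarray, bins: int = 128, smooth_sigma: float = 2.0) -> float:
    """Dominant mode by smoothed histogram; ties break toward the lower bin."""
    counts, edges = np.histogram(values, bins=bins)
    sm = ndimage.gaussian_filter1d(counts.astype(float), smooth_sigma)
    if sm.max() <= 0:
        raise ValueError("no detectable mode (flat histogram)")
    i = int(np.argmax(sm))  # argmax returns the first (lowest) maximal bin
    center = 0.5 * (edges[i] + edges[i + 1])
    width = edges[1] - edges[0]
    near = values[(values >= center - width) & (values <= center + width)]
    return float(np.median(near)) if near.size else center


def normalize_dna(dna: np.ndarray | pd.Series) -> tuple[np.ndarray, PhaseGates]:
    """Rescale DNA signal to N-units; returns (n_units, gates with anchors)."""
    values = np.asarray(dna, dtype=float)
    if values.size == 0:
        raise ValueError("no measurements")
    if np.any(values < 0):
        raise ValueError("DNA signal must be >= 0")
    anchor = _histogram_mode(values)
    if anchor <= 0:
        raise ValueError("degenerate 2N anchor")
    gates = PhaseGates(dna_2n=anchor, dna_4n=2 * anchor)
    return values / anchor * 2.0, gates


def set_edu_threshold(
    edu: np.ndarray | pd.Series,
    k: float = 3.0,
    bins: int = 128,
    smooth_sigma: float = 2.0,
    max_positive_fraction: float = 0.6,
    max_negative_cv: float = 0.25,
) -> float:
    """Threshold = mean + k*sd of the EdU-negative (lower) mode.

    The negative mode is the lowest local maximum of the smoothed histogram;
    its sd is estimated from the left half of the mode (values below it,
    reflected), which is robust to a bright positive population.  A lone mode
    must be tight (sd/mode <= ``max_negative_cv``, characteristic of technical
    background spread) - a single broad peak, or more than
    ``max_positive_fraction`` of cells above the candidate threshold, means
    there is no negative population to gate on.
    """
    values = np.asarray(edu, dtype=float)
    if values.size == 0:
        raise ValueError("no measurements")
    counts, edges = np.histogram(values, bins=bins)
    sm = ndimage.gaussian_filter1d(counts.astype(float), smooth_sigma)
    # local maxima carrying real mass (>= 5% of the tallest smoothed peak)
    floor = 0.05 * sm.max()
    peaks = [
        i
        for i in range(len(sm))
        if sm[i] >= floor
        and (i == 0 or sm[i] >= sm[i - 1])
        and (i == len(sm) - 1 or sm[i] > sm[i + 1])
    ]
    if not peaks:
        raise ValueError("no EdU-negative mode detectable")
    lo = peaks[0]
    center = 0.5 * (edges[lo] + edges[lo + 1])
    width = edges[1] - edges[0]
    near = values[(values >= center - 1.5 * width) & (values <= center + 1.5 * width)]
    mode = float(np.median(near)) if near.size else center
    left = values[values <= mode]
    if left.size < 2:
        raise ValueError("no EdU-negative mode detectable")
    # symmetric-sd estimate from the left tail
    sd = float(np.sqrt(np.mean((left - mode) ** 2)))
    if len(peaks) == 1 and sd > max_negative_cv * mode:
        raise ValueError(
            "EdU distribution appears unimodal-high; cannot place a negative gate"
        )
    neg = values[(values >= mode - k * sd) & (values <= mode + k * sd)]
    thr = float(np.mean(neg) + k * np.std(neg))
    if np.mean(values > thr) > max_positive_fraction:
        raise ValueError(
            "EdU distribution appears unimodal-high; cannot place a negative gate"
        )
    return thr


def gate_phases(measurements: pd.DataFrame, gates: PhaseGates) -> pd.DataFrame:
    """Assign one phase per cell and summarize fractions per condition.

    ``measurements`` needs columns dna, edu and optionally condition.  Returns
    the table with added ``dna_n`` and ``phase`` columns; per-condition
    fractions are available via :func:`phase_fractions`.
    """
    if not np.isfinite(gates.edu_threshold):
        raise ValueError("gates.edu_threshold not set")
    out = measurements.copy()
    out["dna_n"] = out["dna"].to_numpy(dtype=float) / gates.dna_2n * 2.0
    edu = out["edu"].to_numpy(dtype=float)
    s_mask = edu > gates.edu_threshold
    g1_mask = ~s_mask & (out["dna_n"].to_numpy() < gates.mid_cut_n)
    phase = np.where(s_mask, "S", np.where(g1_mask, "G1", "G2/M"))
    out["phase"] = phase
    return out


def phase_fractions(gated: pd.DataFrame) -> pd.DataFrame:
    """Fractions of G1/S/G2M per condition; each row sums to 1."""
    group = gated.get("condition", pd.Series(["all"] * len(gated), index=gated.index))
    tab = (
        gated.assign(condition=group)
        .groupby("condition")["phase"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for col in ("G1", "S", "G2/M"):
        if col not in tab:
            tab[col] = 0.0
    return tab[["G1", "S", "G2/M"]]
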