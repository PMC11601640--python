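"""Tabular synthetic inputs: CN/FPKM tables, PK profiles, EdU/DNA populations
and TMT reporter matrices, each returned with its generating truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

CN_CLASSES = ("diploid", "gain", "amplification")
CN_RANK = {c: i for i, c in enumerate(CN_CLASSES)}
# Representative numeric copy number drawn for each latent class.
_CLASS_CN = {"diploid": 2.0, "gain": 3.0, "amplification": 6.0}

#: Plasma sampling scheme used in the source study's PK experiments (hours).
DEFAULT_PK_TIMES = (0.083, 0.25, 0.5, 1.0, 2.0, 4.0, 7.0, 24.0)


def generate_cn_tables(
    n_models: int,
    samples_per_model: int,
    n_genes: int,
    class_probs: tuple[float, float, float] = (0.7, 0.2, 0.1),
    expression_effect: float = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    perturb_prob: float = 0.0,
    baseline_fpkm: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-model latent CN class per gene; samples vote for the class.

    Returns ``(cn_table, fpkm_table, truth)``.  ``cn_table`` has columns
    gene/sample/model/cn, ``fpkm_table`` gene/sample/model/fpkm, ``truth``
    gene/model/true_status/latent_mean_fpkm.  A ``perturb_prob`` minority of
    samples is shifted to a neighbouring class; FPKM is
    ``baseline * effect**rank(class) * lognormal(0, noise_sd)``.
    """
    if samples_per_model < 1:
        raise ValueError("samples_per_model must be >= 1")
    if n_models < 1 or n_genes < 1:
        raise ValueError("n_models and n_genes must be >= 1")
    probs = np.asarray(class_probs, dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("class_probs must sum to 1")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    models = [f"M{i:03d}" for i in range(n_models)]
    latent = rng.choice(len(CN_CLASSES), size=(n_genes, n_models), p=probs)

    cn_rows, fpkm_rows, truth_rows = [], [], []
    for mi, model in enumerate(models):
        samples = [f"{model}_S{j}" for j in range(samples_per_model)]
        for gi, gene in enumerate(genes):
            cls = CN_CLASSES[latent[gi, mi]]
            mean_fpkm = baseline_fpkm * expression_effect ** CN_RANK[cls]
            truth_rows.append((gene, model, cls, mean_fpkm))
            for s in samples:
                scls = cls
                if perturb_prob > 0 and rng.random() < perturb_prob:
                    others = [c for c in CN_CLASSES if c != cls]
                    scls = others[rng.integers(len(others))]
                cn_rows.append((gene, s, model, _CLASS_CN[scls]))
                noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                fpkm_rows.append((gene, s, model, mean_fpkm * noise))

    cn = pd.DataFrame(cn_rows, columns=["gene", "sample", "model", "cn"])
    fpkm = pd.DataFrame(fpkm_rows, columns=["gene", "sample", "model", "fpkm"])
    truth = pd.DataFrame(truth_rows, columns=["gene", "model", "true_status", "latent_mean_fpkm"])
    return cn, fpkm, truth


def generate_pk_profile(
    dose_time: float = 0.0,
    lambda_true: float = 0.3,
    c0: float = 1000.0,
    times: tuple[float, ...] = DEFAULT_PK_TIMES,
    n_animals: int = 3,
    lognormal_sd: float = 0.0,
    lloq: float = 1.0,
    seed: int = 0,
    analyte: str = "analyte",
    matrix: str = "plasma",
) -> pd.DataFrame:
    """Mono-exponential decay ``C(t) = c0 * exp(-lambda * (t - dose_time))``
    with per-observation lognormal noise; rows below LLOQ are flagged but keep
    their true value so LLOQ policies can be tested against truth."""
    if lambda_true <= 0:
        raise ValueError("lambda_true must be positive")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("times must be strictly increasing and >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        for ti in t:
            c = c0 * np.exp(-lambda_true * max(ti - dose_time, 0.0))
            if lognormal_sd > 0:
                c *= np.exp(rng.normal(0.0, lognormal_sd))
            rows.append((analyte, matrix, f"A{a}", ti, c, "ng/mL", c < lloq))
    return pd.DataFrame(
        rows, columns=["analyte", "matrix", "animal", "time_h", "conc", "units", "lloq_flag"]
    )


def generate_edu_dna_population(
    n_per_phase: dict[str, int],
    dna_2n: float = 100.0,
    edu_neg: float = 100.0,
    edu_pos: float = 1500.0,
    dna_cv: float = 0.05,
    edu_cv: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell (dna, edu, true_phase) table.

    G1 at 2N / EdU-negative, S spread uniformly in (2N, 4N) / EdU-positive,
    G2/M at 4N / EdU-negative; lognormal spread per channel (``*_cv`` of 0
    gives a separable, noise-free population).
    """
    for phase, n in n_per_phase.items():
        if phase not in ("G1", "S", "G2/M"):
            raise ValueError(f"unknown phase {phase!r}")
        if n < 0:
            raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)

    def spread(center: np.ndarray, cv: float) -> np.ndarray:
        if cv == 0:
            return np.asarray(center, dtype=float)
        return center * np.exp(rng.normal(0.0, cv, size=np.shape(center)))

    rows = []
    for phase, n in n_per_phase.items():
        if n == 0:
            continue
        if phase == "G1":
            dna = spread(np.full(n, dna_2n), dna_cv)
            edu = spread(np.full(n, edu_neg), edu_cv)
        elif phase == "G2/M":
            dna = spread(np.full(n, 2 * dna_2n), dna_cv)
            edu = spread(np.full(n, edu_neg), edu_cv)
        else:  # S
            dna = spread(rng.uniform(1.2 * dna_2n, 1.8 * dna_2n, size=n), dna_cv)
            edu = spread(np.full(n, edu_pos), edu_cv)
        for d, e in zip(dna, edu):
            rows.append((d, e, phase))
    df = pd.DataFrame(rows, columns=["dna", "edu", "true_phase"])
    df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    df["condition"] = "synthetic"
    return df


def generate_tmt_matrix(
    n_proteins: int,
    n_channels_per_group: int = 3,
    spike_up: frozenset | set = frozenset(),
    spike_down: frozenset | set = frozenset(),
    effect_log2: float = 2.0,
    sd: float = 0.3,
    missing_rate: float = 0.0,
    peptide_counts: dict[int, int] | None = None,
    seed: int = 0,
    n_contaminants: int = 0,
    n_reverse: int = 0,
    n_site_only: int = 0,
    group_labels: tuple[str, str] = ("treated", "control"),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """MaxQuant-style protein-group reporter matrix with spiked effects.

    Spiked proteins (by integer index) are shifted by +/- ``effect_log2`` in
    the treated channels.  Returns ``(table, channel_groups)`` where the table
    carries intensity columns plus "Razor + unique peptides", flag columns and
    a ``true_class`` annotation.
    """
    spike_up, spike_down = set(spike_up), set(spike_down)
    if spike_up & spike_down:
        raise ValueError("spike_up and spike_down must be disjoint")
    if max(spike_up | spike_down, default=-1) >= n_proteins:
        raise ValueError("spike index out of range")
    rng = np.random.default_rng(seed)

    treated = [f"{group_labels[0]}_{i + 1}" for i in range(n_channels_per_group)]
    control = [f"{group_labels[1]}_{i + 1}" for i in range(n_channels_per_group)]
    channels = treated + control
    base = rng.normal(20.0, 2.0, size=n_proteins)  # log2 abundance
    log2 = np.tile(base[:, None], (1, len(channels))) + rng.normal(
        0.0, sd, size=(n_proteins, len(channels))
    )
    for i in spike_up:
        log2[i, : n_channels_per_group] += effect_log2
    for i in spike_down:
        log2[i, : n_channels_per_group] -= effect_log2
    intens = np.power(2.0, log2)
    if missing_rate > 0:
        mask = rng.random(size=intens.shape) < missing_rate
        intens[mask] = np.nan

    ids = [f"P{i:05d}" for i in range(n_proteins)]
    df = pd.DataFrame(intens, index=pd.Index(ids, name="protein_group"))
    df.columns = [f"Reporter intensity corrected {c}" for c in channels]
    peptides = np.full(n_proteins, 5, dtype=int)
    if peptide_counts:
        for i, c in peptide_counts.items():
            peptides[i] = c
    df["Razor + unique peptides"] = peptides
    # Flag unspiked proteins from the tail of the index space, one flag each.
    pool = [i for i in range(n_proteins - 1, -1, -1) if i not in spike_up | spike_down]
    offset = 0
    for col, n_flag in (
        ("Potential contaminant", n_contaminants),
        ("Reverse", n_reverse),
        ("Only identified by site", n_site_only),
    ):
        flags = np.full(n_proteins, "", dtype=object)
        for i in pool[offset : offset + n_flag]:
            flags[i] = "+"
        offset += n_flag
        df[col] = flags
    cls = np.full(n_proteins, "null", dtype=object)
    for i in spike_up:
        cls[i] = "up"
    for i in spike_down:
        cls[i] = "down"
    df["true_class"] = cls

    groups = {f"Reporter intensity corrected {c}": group_labels[0] for c in treated}
    groups.update({f"Reporter intensity corrected {c}": group_labels[1] for c in control})
    return df, groups
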