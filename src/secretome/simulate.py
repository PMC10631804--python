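"""Synthetic data generators with known ground truth for every pipeline stage.

Three generators emulate the structures the analysis consumes:

``simulate_evidence``
    A dynamic-labeling experiment: per-peptide heavy/light intensities at the
    1/2/6/24 h collections, consistent with RIA(t) = A(1 - e^(-kt)).  Two
    pools are planted with disjoint rate-constant ranges straddling the
    0.01 h^-1 classification cutoff: secreted k ~ U[0.05, 1.0] h^-1 and
    intracellular k ~ U[0.0005, 0.005] h^-1.  The total secreted pool in
    medium accumulates linearly with time (constant secretion into a fixed
    volume); the intracellular leak stays nearly flat.  Multiplicative
    lognormal noise (default CV 20%) and per-point dropout are configurable.

``simulate_lfq``
    A label-free cohort: Gamma-distributed abundances (default shape 20)
    whose log-mean carries planted tissue offsets, per-year age slopes and
    sex offsets for chosen proteins, over a 30-donor metadata template
    (16 adipose- / 14 bone-marrow-derived, ages spanning 1.5-24 years) with
    optional missingness.

``simulate_assay``
    The orthogonal assays: an activity time course with per-donor random
    intercepts and fixed time, age and time x age effects (27 donors, reads
    at 10/20/30/40 min), and a Gamma-distributed concentration with donor
    covariate effects (24 donors).

All generators are fully determined by (config, seed); per-stage substreams
are spawned from the one seed.  Emitted tables use the same MaxQuant/CSV
dialects the readers consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvidenceSimConfig",
    "LfqSimConfig",
    "AssaySimConfig",
    "make_donor_metadata",
    "simulate_evidence",
    "simulate_lfq",
    "simulate_assay",
    "evidence_raw_file_hours",
]

TIME_POINTS = (1.0, 2.0, 6.0, 24.0)


def _cv_to_sigma(cv: float) -> float:
    """Lognormal sigma giving a multiplicative noise of coefficient-of-variation cv."""
    return float(np.sqrt(np.log1p(cv**2)))


# ---------------------------------------------------------------------------
# Dynamic-labeling evidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvidenceSimConfig:
    n_proteins: int = 200
    peptides_per_protein: int = 4
    secreted_fraction: float = 0.66  # roughly two thirds of classified proteins
    time_points: tuple[float, ...] = TIME_POINTS
    secreted_k_range: tuple[float, float] = (0.05, 1.0)  # h^-1
    intracellular_k_range: tuple[float, float] = (0.0005, 0.005)  # h^-1
    plateau_range: tuple[float, float] = (0.7, 1.0)
    noise_cv: float = 0.20
    dropout: float = 0.0  # per peptide/time-point probability of non-quantification
    log_base_abundance: tuple[float, float] = (np.log(1e5), np.log(1e7))
    peptide_sigma: float = 0.5  # lognormal spread of per-peptide response factors
    n_decoys: int = 0  # reverse/contaminant rows to exercise filtering


def evidence_raw_file_hours(
    config: EvidenceSimConfig | None = None,
) -> dict[str, float]:
    """Raw-file -> hours map matching the generator's file naming."""
    tps = (config or EvidenceSimConfig()).time_points
    return {f"SIDLS_{t:05.1f}h": float(t) for t in tps}


def simulate_evidence(
    config: EvidenceSimConfig = EvidenceSimConfig(), seed: int = 17
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a MaxQuant-dialect evidence table plus its truth table.

    Returns ``(evidence, truth)``.  ``evidence`` has the default
    ``evidence.txt`` headers; ``truth`` has one row per protein with
    ``pool``, ``true_k``, ``true_plateau``, ``base_abundance``, ``true_P``
    and ``true_flux`` (the noiseless abundance delta between the 24 h and
    6 h collections, and its product with k).
    """
    if config.peptides_per_protein < 1:
        raise ValueError("peptides_per_protein must be >= 1")
    rng = np.random.default_rng(seed)
    n = config.n_proteins
    n_secreted = int(round(n * config.secreted_fraction))
    pools = np.array(["secreted"] * n_secreted + ["intracellular"] * (n - n_secreted))
    rng.shuffle(pools)

    k = np.where(
        pools == "secreted",
        rng.uniform(*config.secreted_k_range, size=n),
        rng.uniform(*config.intracellular_k_range, size=n),
    )
    plateau = rng.uniform(*config.plateau_range, size=n)
    base = np.exp(rng.uniform(*config.log_base_abundance, size=n))
    sigma = _cv_to_sigma(config.noise_cv)
    tps = np.asarray(config.time_points)

    def total_pool(pool: str, base_i: float, t: np.ndarray) -> np.ndarray:
        if pool == "secreted":
            # constant secretion into fixed medium volume: linear accumulation
            return base_i * (0.05 + t / 24.0)
        return base_i * (1.0 + 0.002 * t)  # slow leak, nearly flat

    rows = []
    truth_rows = []
    raw_files = {t: f"SIDLS_{t:05.1f}h" for t in tps}
    for i in range(n):
        protein = f"P{i:04d}"
        pep_factors = (
            np.exp(rng.normal(0.0, config.peptide_sigma, size=config.peptides_per_protein))
            if config.peptide_sigma > 0
            else np.ones(config.peptides_per_protein)
        )
        totals_t = total_pool(pools[i], base[i], tps)
        ria_t = plateau[i] * -np.expm1(-k[i] * tps)
        for j in range(config.peptides_per_protein):
            seq = f"PEPTIDE{i:04d}X{j}"
            for t_idx, t in enumerate(tps):
                if config.dropout > 0 and rng.random() < config.dropout:
                    heavy = light = 0.0
                else:
                    total = totals_t[t_idx] * pep_factors[j]
                    noise_h = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                    noise_l = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                    heavy = total * ria_t[t_idx] * noise_h
                    light = total * (1.0 - ria_t[t_idx]) * noise_l
                rows.append(
                    {
                        "Sequence": seq,
                        "Leading razor protein": protein,
                        "Raw file": raw_files[t],
                        "Intensity L": light,
                        "Intensity H": heavy,
                        "Reverse": "",
                        "Potential contaminant": "",
                    }
                )
        mean_24 = float(np.mean(totals_t[tps == 24.0]) * np.mean(pep_factors)) if 24.0 in tps else np.nan
        mean_6 = float(np.mean(totals_t[tps == 6.0]) * np.mean(pep_factors)) if 6.0 in tps else np.nan
        true_p = mean_24 - mean_6
        truth_rows.append(
            {
                "protein_id": protein,
                "pool": pools[i],
                "true_k": k[i],
                "true_plateau": plateau[i],
                "base_abundance": base[i],
                "true_P": true_p,
                "true_flux": true_p * k[i],
            }
        )

    for d in range(config.n_decoys):
        rows.append(
            {
                "Sequence": f"DECOYPEP{d}",
                "Leading razor protein": f"REV__P{d:04d}",
                "Raw file": raw_files[tps[0]],
                "Intensity L": 1000.0,
                "Intensity H": 10.0,
                "Reverse": "+" if d % 2 == 0 else "",
                "Potential contaminant": "" if d % 2 == 0 else "+",
            }
        )
    evidence = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows).set_index("protein_id")
    return evidence, truth


# ---------------------------------------------------------------------------
# Label-free cohort
# ---------------------------------------------------------------------------

def make_donor_metadata(
    n_asc: int = 16,
    n_bmsc: int = 14,
    age_range: tuple[float, float] = (1.5, 24.0),
    seed: int = 17,
) -> pd.DataFrame:
    """Donor metadata template: two tissues, near-balanced sexes, ages
    spanning ``age_range`` (evenly spaced, then shuffled across donors)."""
    rng = np.random.default_rng(seed)
    n = n_asc + n_bmsc
    tissues = np.array(["ASC"] * n_asc + ["BMSC"] * n_bmsc)
    sexes = np.array(["M", "F"] * (n // 2 + 1))[:n]
    ages = np.linspace(age_range[0], age_range[1], n)
    order = rng.permutation(n)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(n)],
            "tissue": tissues,
            "sex": sexes[order],
            "age_years": ages[order],
        }
    )


@dataclass(frozen=True)
class LfqSimConfig:
    n_proteins: int = 100
    gamma_shape: float = 20.0
    log_baseline_range: tuple[float, float] = (np.log(1e5), np.log(1e7))
    n_tissue_effect: int = 15
    tissue_log2fc: float = 1.0  # BMSC vs ASC, applied on alternating sign
    n_age_effect: int = 5
    age_slope: float = -0.03  # per year on the log scale (~2-fold over 23 y)
    n_sex_effect: int = 3
    sex_log2fc: float = 0.8  # M vs F
    mcar_rate: float = 0.0
    n_high_missing: int = 0  # proteins forced above the 30% missingness filter
    high_missing_rate: float = 0.35
    unique_peptides_range: tuple[int, int] = (2, 20)


def simulate_lfq(
    config: LfqSimConfig = LfqSimConfig(),
    metadata: pd.DataFrame | None = None,
    seed: int = 17,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a proteinGroups-dialect table, metadata, and the truth table.

    Effects act on the log of the Gamma mean: planted tissue offsets
    (alternating sign, first ``n_tissue_effect`` proteins), then age slopes,
    then sex offsets, on disjoint protein blocks.  Returns ``(protein_groups,
    metadata, truth)``.
    """
    rng = np.random.default_rng(seed)
    if metadata is None:
        metadata = make_donor_metadata(seed=seed)
    n, m = config.n_proteins, len(metadata)
    n_effects = config.n_tissue_effect + config.n_age_effect + config.n_sex_effect
    if n_effects + config.n_high_missing > n:
        raise ValueError(
            f"effect and high-missingness proteins ({n_effects} + "
            f"{config.n_high_missing}) exceed n_proteins ({n})"
        )
    is_bmsc = (metadata["tissue"] == "BMSC").to_numpy(dtype=float)
    is_male = (metadata["sex"] == "M").to_numpy(dtype=float)
    ages = metadata["age_years"].to_numpy(dtype=float)

    baseline = rng.uniform(*config.log_baseline_range, size=n)
    tissue_off = np.zeros(n)
    age_slope = np.zeros(n)
    sex_off = np.zeros(n)
    idx = 0
    signs = np.where(np.arange(config.n_tissue_effect) % 2 == 0, 1.0, -1.0)
    tissue_off[idx : idx + config.n_tissue_effect] = signs * config.tissue_log2fc * np.log(2)
    idx += config.n_tissue_effect
    age_slope[idx : idx + config.n_age_effect] = config.age_slope
    idx += config.n_age_effect
    sex_off[idx : idx + config.n_sex_effect] = config.sex_log2fc * np.log(2)

    log_mean = (
        baseline[:, None]
        + tissue_off[:, None] * is_bmsc[None, :]
        + age_slope[:, None] * ages[None, :]
        + sex_off[:, None] * is_male[None, :]
    )
    mean = np.exp(log_mean)
    values = rng.gamma(config.gamma_shape, mean / config.gamma_shape)

    missing = np.zeros((n, m), dtype=bool)
    if config.mcar_rate > 0:
        missing |= rng.random((n, m)) < config.mcar_rate
    high_missing = np.zeros(n, dtype=bool)
    if config.n_high_missing > 0:
        high_missing[-config.n_high_missing :] = True
        forced = rng.random((config.n_high_missing, m)) < config.high_missing_rate
        # guarantee the planted proteins exceed the 30% removal threshold
        for r in range(config.n_high_missing):
            need = int(np.ceil(0.30 * m)) + 1 - forced[r].sum()
            if need > 0:
                extra = rng.choice(np.flatnonzero(~forced[r]), size=need, replace=False)
                forced[r, extra] = True
        missing[-config.n_high_missing :] |= forced
    values = np.where(missing, 0.0, values)  # MaxQuant writes 0 for non-detection

    protein_ids = [f"Q{i:04d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "Protein IDs": protein_ids,
            "Gene names": [f"GENE{i}" for i in range(n)],
            "Unique peptides": rng.integers(
                config.unique_peptides_range[0],
                config.unique_peptides_range[1] + 1,
                size=n,
            ),
            "Reverse": "",
            "Potential contaminant": "",
        }
    )
    for j, sample in enumerate(metadata["sample_id"]):
        table[f"LFQ intensity {sample}"] = values[:, j]

    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "log_baseline": baseline,
            "tissue_log_offset": tissue_off,
            "age_log_slope": age_slope,
            "sex_log_offset": sex_off,
            "gamma_shape": config.gamma_shape,
            "high_missing": high_missing,
        }
    ).set_index("protein_id")
    return table, metadata, truth


# ---------------------------------------------------------------------------
# Orthogonal assays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssaySimConfig:
    # activity time course (per-donor reads at fixed incubation minutes)
    n_donors_activity: int = 27
    read_times_min: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0)
    activity_intercept: float = 100.0
    activity_time_slope: float = 2.0
    activity_age_slope: float = 0.5
    activity_time_age: float = -0.05  # per (minute x year)
    donor_sd: float = 3.0
    resid_sd: float = 5.0
    # concentration assay (one read per donor)
    n_donors_concentration: int = 24
    conc_log_baseline: float = np.log(200.0)  # pg/mL
    conc_age_slope: float = 0.08  # per year, log scale
    conc_sex_offset: float = 0.0
    conc_tissue_offset: float = 0.0
    conc_gamma_shape: float = 20.0
    age_range: tuple[float, float] = (1.5, 24.0)


def simulate_assay(
    kind: str, config: AssaySimConfig = AssaySimConfig(), seed: int = 17
) -> tuple[pd.DataFrame, dict]:
    """Generate assay measurements plus the generating parameters.

    ``kind='activity'``: long-format reads with per-donor random intercepts.
    ``kind='concentration'``: one Gamma-distributed concentration per donor.
    """
    rng = np.random.default_rng(seed)
    if kind == "activity":
        n = config.n_donors_activity
        ages = np.linspace(*config.age_range, n)
        intercepts = rng.normal(0.0, config.donor_sd, size=n)
        rows = []
        for d in range(n):
            for t in config.read_times_min:
                mu = (
                    config.activity_intercept
                    + config.activity_time_slope * t
                    + config.activity_age_slope * ages[d]
                    + config.activity_time_age * t * ages[d]
                    + intercepts[d]
                )
                rows.append(
                    {
                        "donor_id": f"D{d + 1:02d}",
                        "age_years": ages[d],
                        "time_min": t,
                        "response": mu + rng.normal(0.0, config.resid_sd),
                    }
                )
        truth = {
            "intercept": config.activity_intercept,
            "time": config.activity_time_slope,
            "age": config.activity_age_slope,
            "time_age": config.activity_time_age,
            "donor_sd": config.donor_sd,
            "resid_sd": config.resid_sd,
        }
        return pd.DataFrame(rows), truth
    if kind == "concentration":
        n = config.n_donors_concentration
        ages = np.linspace(*config.age_range, n)
        sexes = np.array(["M", "F"] * (n // 2 + 1))[:n]
        tissues = np.array(["ASC", "BMSC"] * (n // 2 + 1))[:n]
        log_mu = (
            config.conc_log_baseline
            + config.conc_age_slope * ages
            + config.conc_sex_offset * (sexes == "M")
            + config.conc_tissue_offset * (tissues == "BMSC")
        )
        response = rng.gamma(config.conc_gamma_shape, np.exp(log_mu) / config.conc_gamma_shape)
        frame = pd.DataFrame(
            {
                "donor_id": [f"D{d + 1:02d}" for d in range(n)],
                "age_years": ages,
                "sex": sexes,
                "tissue": tissues,
                "response": response,
            }
        )
        truth = {
            "log_baseline": config.conc_log_baseline,
            "age": config.conc_age_slope,
            "sex_M": config.conc_sex_offset,
            "tissue_BMSC": config.conc_tissue_offset,
            "gamma_shape": config.conc_gamma_shape,
        }
        return frame, truth
    raise ValueError(f"unknown assay kind: {kind!r}")
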