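"""Label-free quantification workflow: missingness, imputation, clustering.

Operates on an LFQ intensity matrix (pandas DataFrame, proteins as rows,
samples as columns, ``NaN`` marking non-detection).  Provides the
missingness filter, the three imputation variants, a PCA overview, donor-age
binning, duplicate-sample averaging, per-protein standardization, fuzzy
c-means and DTW-based time-course clustering over age-ordered profiles, and
NMF consensus clustering with cophenetic rank selection.

Stochastic steps (sample-based imputation, cluster initialisation, NMF
restarts) all take an explicit seed; the package default is 17.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

__all__ = [
    "DEFAULT_SEED",
    "filter_missingness",
    "impute",
    "pca_overview",
    "bin_ages",
    "average_duplicates",
    "standardize_rows",
    "fuzzy_cmeans",
    "dtw_distance",
    "dtw_cluster",
    "NmfModel",
    "nmf_multiplicative",
    "nmf_consensus",
    "recommend_rank",
    "nmf_top_features",
]

DEFAULT_SEED = 17


# ---------------------------------------------------------------------------
# Missingness and imputation
# ---------------------------------------------------------------------------

def filter_missingness(lfq: pd.DataFrame, max_missing_frac: float = 0.30) -> pd.DataFrame:
    """Drop proteins missing in more than ``max_missing_frac`` of samples.

    The boundary is inclusive for retention: a protein missing in exactly
    30% of samples stays ("more than 30%" is the removal rule).
    """
    frac = lfq.isna().mean(axis=1)
    return lfq.loc[frac <= max_missing_frac].copy()


def impute(
    lfq: pd.DataFrame,
    mode: str = "none",
    seed: int = DEFAULT_SEED,
    downshift: float = 1.8,
    width: float = 0.3,
) -> pd.DataFrame:
    """Handle missing LFQ values under one of three modes.

    ``none``
        Complete-case: drop every protein with any missing value.
    ``sample``
        Missing-not-at-random-style low-abundance imputation: each missing
        cell in sample *s* is drawn from ``Normal(mu_s - downshift*sd_s,
        width*sd_s)`` in log2 space of the observed values of *s*, then
        back-transformed (the Perseus-style down-shifted draw).
    ``protein``
        Each missing cell is replaced by the protein's observed mean across
        samples.
    """
    if mode == "none":
        return lfq.dropna(axis=0).copy()
    if mode == "protein":
        if lfq.isna().all(axis=1).any():
            bad = lfq.index[lfq.isna().all(axis=1)]
            raise ValueError(f"protein(s) with no observed values: {list(bad[:5])}")
        means = lfq.mean(axis=1, skipna=True)
        return lfq.apply(lambda row: row.fillna(means[row.name]), axis=1)
    if mode == "sample":
        rng = np.random.default_rng(seed)
        out = lfq.copy()
        log = np.log2(out.where(out > 0))
        for sample in out.columns:
            missing = out[sample].isna()
            if not missing.any():
                continue
            obs = log[sample].dropna()
            if obs.empty:
                raise ValueError(f"sample {sample!r} has no observed values")
            mu, sd = float(obs.mean()), float(obs.std(ddof=1))
            sd = sd if np.isfinite(sd) and sd > 0 else 0.0
            draws = rng.normal(mu - downshift * sd, width * sd, size=int(missing.sum()))
            out.loc[missing, sample] = np.power(2.0, draws)
        return out
    raise ValueError(f"unknown imputation mode: {mode!r}")


# ---------------------------------------------------------------------------
# Overview and reshaping
# ---------------------------------------------------------------------------

def pca_overview(
    lfq: pd.DataFrame, log_transform: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2, per-protein standardized intensities.

    Returns ``(scores, variance_fractions)``: sample scores for all
    components (rows = samples) and the explained-variance fractions, which
    sum to 1.
    """
    if lfq.isna().any().any():
        raise ValueError("PCA requires a complete matrix; impute or drop first")
    if lfq.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = np.log2(lfq) if log_transform else lfq.copy()
    x = standardize_rows(x)
    pca = PCA()
    scores = pca.fit_transform(x.T.to_numpy())
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=lfq.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def bin_ages(
    metadata: pd.DataFrame, width_years: float = 5.0, min_per_bin: int = 3
) -> pd.Series:
    """Assign samples to half-open age bins [0,w), [w,2w), ...

    Emits a warning for bins holding fewer than ``min_per_bin`` samples (the
    binning exists to give each age group enough replicates).
    """
    ages = metadata["age_years"].to_numpy(dtype=float)
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    left = np.floor(ages / width_years) * width_years
    labels = pd.Series(
        [f"[{lo:g},{lo + width_years:g})" for lo in left],
        index=metadata["sample_id"].to_numpy(),
        name="age_bin",
    )
    counts = labels.value_counts()
    small = counts[counts < min_per_bin]
    if len(small):
        warnings.warn(
            f"age bin(s) with fewer than {min_per_bin} samples: "
            f"{', '.join(small.index)}"
        )
    return labels


def average_duplicates(lfq: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Average columns sharing (tissue, sex, age), then order by age.

    Returns a matrix whose columns are a MultiIndex ``(tissue, sex,
    age_years)`` sorted by ascending age (ties broken by tissue then sex).
    """
    if lfq.isna().any().any():
        raise ValueError("duplicate averaging requires a complete matrix")
    meta = metadata.set_index("sample_id").loc[list(lfq.columns)]
    key = pd.MultiIndex.from_frame(
        meta[["tissue", "sex", "age_years"]], names=["tissue", "sex", "age_years"]
    )
    out = lfq.T.groupby(key).mean().T
    order = sorted(out.columns, key=lambda c: (c[2], c[0], c[1]))
    return out[order]


def standardize_rows(lfq: pd.DataFrame) -> pd.DataFrame:
    """Center each protein to mean 0, SD 1 (sample SD, ddof=1).

    Constant rows carry no profile information and are dropped with a
    warning.
    """
    means = lfq.mean(axis=1)
    sds = lfq.std(axis=1, ddof=1)
    constant = ~(sds > 0)
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant protein row(s)")
    kept = lfq.loc[~constant]
    return kept.sub(means[~constant], axis=0).div(sds[~constant], axis=0)


# ---------------------------------------------------------------------------
# Fuzzy c-means over age-ordered profiles
# ---------------------------------------------------------------------------

def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 16,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fuzzy c-means clustering of protein profiles (rows).

    Alternates centroid and membership updates with exponent ``fuzzifier``
    until the largest membership change drops below ``tol``.  Returns
    ``(membership, centroids)``; memberships are proteins x clusters and sum
    to 1 per protein.
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if c >= n:
        raise ValueError(f"need fewer clusters ({c}) than proteins ({n})")
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(c), size=n)  # n x c

    exponent = 2.0 / (fuzzifier - 1.0)
    for _ in range(max_iter):
        um = u ** fuzzifier
        centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-exponent / 2.0) if exponent != 2.0 else 1.0 / d2
        new_u = inv / inv.sum(axis=1, keepdims=True)
        shift = float(np.max(np.abs(new_u - u)))
        u = new_u
        if shift < tol:
            break
    membership = pd.DataFrame(
        u, index=profiles.index, columns=[f"cluster_{j + 1}" for j in range(c)]
    )
    return membership, centroids


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------

def dtw_distance(x, y, cost: str = "squared") -> float:
    """Classic DTW with symmetric steps and no window constraint.

    Local cost is the squared difference by default (``cost='absolute'`` for
    |x - y|); the returned value is the minimum cumulative cost over all
    monotone alignment paths.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW requires non-empty series")
    diff = x[:, None] - y[None, :]
    local = diff ** 2 if cost == "squared" else np.abs(diff)
    n, m = local.shape
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = local[i - 1, j - 1] + min(
                acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1]
            )
    return float(acc[n, m])


def dtw_pairwise(profiles: pd.DataFrame, cost: str = "squared") -> np.ndarray:
    x = profiles.to_numpy(dtype=float)
    n = len(x)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = dtw_distance(x[i], x[j], cost=cost)
    return dist


def dtw_cluster(
    profiles: pd.DataFrame,
    k_clusters: int = 8,
    cost: str = "squared",
    seed: int = DEFAULT_SEED,
    max_iter: int = 100,
) -> tuple[pd.Series, list]:
    """Partitional k-medoids clustering of profiles under DTW distance.

    Returns ``(assignments, medoid_ids)``; assignments are 1-based cluster
    indices per protein.  Seeded medoid initialisation makes runs
    reproducible.
    """
    n = len(profiles)
    if k_clusters > n:
        raise ValueError(f"k_clusters ({k_clusters}) exceeds profiles ({n})")
    dist = dtw_pairwise(profiles, cost=cost)
    rng = np.random.default_rng(seed)
    medoids = np.sort(rng.choice(n, size=k_clusters, replace=False))

    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for j in range(k_clusters):
            members = np.flatnonzero(assign == j)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[j] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = np.sort(new_medoids)
    assign = np.argmin(dist[:, medoids], axis=1)
    assignments = pd.Series(assign + 1, index=profiles.index, name="cluster")
    return assignments, [profiles.index[m] for m in medoids]


# ---------------------------------------------------------------------------
# NMF consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class NmfModel:
    """Best factorization at one rank plus run-stability summaries."""

    rank: int
    W: np.ndarray  # proteins x rank, non-negative basis
    H: np.ndarray  # rank x samples, non-negative coefficients
    consensus: np.ndarray  # samples x samples co-assignment frequency
    cophenetic: float
    objective_trace: np.ndarray = field(repr=False, default=None)
    sample_ids: list = field(default_factory=list)
    protein_ids: list = field(default_factory=list)

    @property
    def assignments(self) -> pd.Series:
        """Hard sample assignment: argmax over the coefficient rows (1-based)."""
        return pd.Series(
            np.argmax(self.H, axis=0) + 1, index=self.sample_ids, name="cluster"
        )


def nmf_multiplicative(
    x: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frobenius NMF by multiplicative updates from a random start.

    Returns ``(W, H, objective_trace)``; the squared-error objective is
    non-increasing across updates (Lee-Seung).
    """
    eps = 1e-10
    n, m = x.shape
    scale = np.sqrt(x.mean() / max(rank, 1))
    w = rng.uniform(eps, 1.0, size=(n, rank)) * scale
    h = rng.uniform(eps, 1.0, size=(rank, m)) * scale
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        h *= (w.T @ x) / (w.T @ w @ h + eps)
        w *= (x @ h.T) / (w @ h @ h.T + eps)
        obj = float(np.linalg.norm(x - w @ h) ** 2)
        trace.append(obj)
        if prev - obj < tol * max(prev, 1.0):
            break
        prev = obj
    return w, h, np.asarray(trace)


def _consensus_cophenetic(consensus: np.ndarray) -> float:
    """Cophenetic correlation of average-linkage clustering of 1 - consensus."""
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        # every pair equally (un)stable: trivially perfect hierarchy
        return 1.0
    link = linkage(condensed, method="average")
    coph, _ = cophenet(link, condensed)
    return float(coph)


def nmf_consensus(
    lfq: pd.DataFrame,
    ranks=range(2, 7),
    n_runs: int = 30,
    seed: int = DEFAULT_SEED,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> dict[int, NmfModel]:
    """NMF consensus clustering of samples across a range of ranks.

    For each rank, ``n_runs`` random-start factorizations are computed;
    samples are hard-assigned by the argmax coefficient, the consensus matrix
    is the co-assignment frequency over runs, and its cophenetic correlation
    summarises stability.  The most stable rank (see
    :func:`recommend_rank`) is the one to carry forward.
    """
    x = lfq.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("NMF requires a complete matrix")
    if (x < 0).any():
        raise ValueError("NMF requires non-negative values")
    seeds = np.random.SeedSequence(seed).spawn(len(list(ranks)))
    models: dict[int, NmfModel] = {}
    for rank_seed, rank in zip(seeds, ranks):
        child = np.random.default_rng(rank_seed)
        n_samples = x.shape[1]
        co = np.zeros((n_samples, n_samples))
        best = None
        for _ in range(n_runs):
            w, h, trace = nmf_multiplicative(x, rank, child, max_iter=max_iter, tol=tol)
            labels = np.argmax(h, axis=0)
            co += (labels[:, None] == labels[None, :]).astype(float)
            if best is None or trace[-1] < best[2][-1]:
                best = (w, h, trace)
        consensus = co / n_runs
        models[rank] = NmfModel(
            rank=rank,
            W=best[0],
            H=best[1],
            consensus=consensus,
            cophenetic=_consensus_cophenetic(consensus),
            objective_trace=best[2],
            sample_ids=list(lfq.columns),
            protein_ids=list(lfq.index),
        )
    return models


def recommend_rank(models: dict[int, NmfModel]) -> int:
    """Rank with the highest cophenetic correlation (smallest wins ties)."""
    return max(sorted(models), key=lambda r: models[r].cophenetic)


def nmf_top_features(
    model: NmfModel, per_cluster: int = 10, dominance: float = 0.8
) -> dict[int, pd.DataFrame]:
    """Proteins driving each NMF cluster, by normalized basis contribution.

    Each protein's W row is normalized to sum 1; the protein is a top
    feature of cluster ``j`` when its normalized weight there exceeds
    ``dominance``.  Returns per-cluster frames (protein_id, score) ranked by
    score, truncated to ``per_cluster`` rows.
    """
    w = model.W
    row_sums = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(row_sums > 0, w / np.where(row_sums > 0, row_sums, 1.0), 0.0)
    out: dict[int, pd.DataFrame] = {}
    for j in range(model.rank):
        mask = norm[:, j] > dominance
        frame = pd.DataFrame(
            {
                "protein_id": np.asarray(model.protein_ids)[mask],
                "score": norm[mask, j],
            }
        ).sort_values("score", ascending=False, kind="mergesort")
        out[j + 1] = frame.head(per_cluster).reset_index(drop=True)
    return out
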