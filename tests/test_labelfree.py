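import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import NMF as SklearnNMF

from secretome import labelfree as lf


def _matrix(values, proteins=None, samples=None):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=proteins, columns=samples)


# ---------------------------------------------------------------------------
# Missingness and imputation
# ---------------------------------------------------------------------------

def test_missingness_filter_boundary_is_more_than():
    x = np.full((3, 30), 100.0)
    x[0, :10] = np.nan  # 33.3% -> removed
    x[1, :9] = np.nan   # 30.0% -> retained ("more than 30%" removes)
    m = _matrix(x)
    kept = lf.filter_missingness(m, 0.30)
    assert list(kept.index) == ["P1", "P2"]
    complete = _matrix(np.ones((4, 5)))
    pd.testing.assert_frame_equal(lf.filter_missingness(complete), complete)


def test_impute_none_keeps_only_complete_cases():
    x = np.ones((4, 5)) * 7
    x[1, 2] = np.nan
    out = lf.impute(_matrix(x), mode="none")
    assert list(out.index) == ["P0", "P2", "P3"]
    assert not out.isna().any().any()


def test_impute_protein_mean_fills_row_mean():
    out = lf.impute(_matrix([[10.0, np.nan, 20.0], [1.0, 2.0, 3.0]]), mode="protein")
    assert out.iloc[0, 1] == pytest.approx(15.0)
    assert out.iloc[1].tolist() == [1.0, 2.0, 3.0]


def test_impute_protein_all_missing_row_errors():
    with pytest.raises(ValueError, match="no observed"):
        lf.impute(_matrix([[np.nan, np.nan], [1.0, 2.0]]), mode="protein")


def test_impute_sample_deterministic_under_seed_and_low_abundance():
    rng = np.random.default_rng(0)
    x = rng.lognormal(10, 1, size=(40, 6))
    x[rng.random(x.shape) < 0.15] = np.nan
    m = _matrix(x)
    a = lf.impute(m, mode="sample", seed=17)
    b = lf.impute(m, mode="sample", seed=17)
    pd.testing.assert_frame_equal(a, b)
    # imputed draws sit below the observed centre of each sample (down-shift)
    for s in m.columns:
        missing = m[s].isna()
        if missing.any():
            assert np.log2(a.loc[missing, s]).mean() < np.log2(m[s].dropna()).mean()


# ---------------------------------------------------------------------------
# PCA, binning, reshaping, standardization
# ---------------------------------------------------------------------------

def test_pca_duplicate_samples_get_identical_scores_and_variance_sums_to_one():
    rng = np.random.default_rng(1)
    x = rng.lognormal(12, 1, size=(25, 6))
    x[:, 3] = x[:, 0]  # duplicated sample
    scores, var = lf.pca_overview(_matrix(x))
    np.testing.assert_allclose(
        scores.iloc[0].to_numpy(), scores.iloc[3].to_numpy(), atol=1e-8
    )
    assert var.sum() == pytest.approx(1.0, abs=1e-9)


def test_pca_planted_tissue_offset_dominates_pc1(donor_metadata):
    rng = np.random.default_rng(2)
    is_bmsc = (donor_metadata["tissue"] == "BMSC").to_numpy(dtype=float)
    log_mu = 12 + np.outer(np.ones(40), is_bmsc) * 1.5
    x = np.exp(log_mu + rng.normal(0, 0.2, size=log_mu.shape))
    scores, var = lf.pca_overview(_matrix(x, samples=list(donor_metadata["sample_id"])))
    assert var[0] > var[1:].max()
    pc1 = scores["PC1"].to_numpy()
    assert (pc1[is_bmsc == 1].mean() - pc1[is_bmsc == 0].mean()) ** 2 > (
        pc1.var()  # groups separated well beyond within-group spread
    )


def test_pca_rejects_missing_or_tiny_input():
    with pytest.raises(ValueError, match="complete"):
        lf.pca_overview(_matrix([[1.0, np.nan, 2.0]]))
    with pytest.raises(ValueError, match="3 samples"):
        lf.pca_overview(_matrix(np.ones((4, 2))))


def test_age_bins_half_open_convention():
    meta = pd.DataFrame(
        {
            "sample_id": ["A", "B", "C"],
            "tissue": ["ASC"] * 3,
            "sex": ["F"] * 3,
            "age_years": [11.7, 5.0, 1.5],
        }
    )
    with pytest.warns(UserWarning, match="fewer than"):
        bins = lf.bin_ages(meta)
    assert bins["A"] == "[10,15)"
    assert bins["B"] == "[5,10)"  # boundary age joins the bin it opens
    assert bins["C"] == "[0,5)"


def test_age_bins_span_study_range(donor_metadata):
    # 1.5-24 years covers five 5-year bins, each with enough samples
    bins = lf.bin_ages(donor_metadata)
    assert {"[0,5)", "[20,25)"} <= set(bins)
    assert bins.value_counts().min() >= 3


def test_average_duplicates_means_and_age_order():
    meta = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "tissue": ["ASC", "ASC", "BMSC"],
            "sex": ["F", "F", "M"],
            "age_years": [10.0, 10.0, 2.0],
        }
    )
    m = _matrix([[2.0, 4.0, 9.0], [1.0, 1.0, 5.0]], samples=["S1", "S2", "S3"])
    out = lf.average_duplicates(m, meta)
    assert out.shape[1] == 2
    assert out.columns[0] == ("BMSC", "M", 2.0)  # ordered by age
    assert out[("ASC", "F", 10.0)].tolist() == [3.0, 1.0]


def test_standardize_rows_closed_form_and_constant_drop():
    with pytest.warns(UserWarning, match="constant"):
        out = lf.standardize_rows(_matrix([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))
    np.testing.assert_allclose(out.iloc[0], [-1.0, 0.0, 1.0])  # sample SD (ddof=1)
    assert len(out) == 1
    assert np.abs(out.mean(axis=1)).max() < 1e-12


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------

def _archetype_profiles(n_per=25, n_t=10, noise=0.1, seed=5):
    rng = np.random.default_rng(seed)
    up = np.linspace(-1, 1, n_t)
    rows = [up + rng.normal(0, noise, n_t) for _ in range(n_per)]
    rows += [-up + rng.normal(0, noise, n_t) for _ in range(n_per)]
    truth = np.array([0] * n_per + [1] * n_per)
    return _matrix(np.asarray(rows)), truth


def test_fuzzy_cmeans_recovers_planted_archetypes():
    profiles, truth = _archetype_profiles()
    membership, _ = lf.fuzzy_cmeans(profiles, c=2, seed=17)
    top = membership.to_numpy().argmax(axis=1)
    accuracy = max((top == truth).mean(), (top != truth).mean())
    assert accuracy == 1.0
    assert membership.max(axis=1).min() > 0.9


def test_fuzzy_memberships_normalized_and_seed_stable():
    profiles, _ = _archetype_profiles(n_per=10)
    m1, c1 = lf.fuzzy_cmeans(profiles, c=3, seed=17)
    m2, c2 = lf.fuzzy_cmeans(profiles, c=3, seed=17)
    np.testing.assert_allclose(m1.sum(axis=1), 1.0, atol=1e-9)
    pd.testing.assert_frame_equal(m1, m2)
    np.testing.assert_array_equal(c1, c2)


def test_fuzzy_cmeans_rejects_too_many_clusters():
    profiles, _ = _archetype_profiles(n_per=3)
    with pytest.raises(ValueError):
        lf.fuzzy_cmeans(profiles, c=10)


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------

def _dtw_oracle(x, y, cost="squared"):
    """Enumerate every monotone alignment path explicitly (tiny series only)."""
    n, m = len(x), len(y)

    def local(i, j):
        d = x[i] - y[j]
        return d * d if cost == "squared" else abs(d)

    def paths(i, j):
        if i == n - 1 and j == m - 1:
            yield [(i, j)]
            return
        if i < n - 1:
            for rest in paths(i + 1, j):
                yield [(i, j)] + rest
        if j < m - 1:
            for rest in paths(i, j + 1):
                yield [(i, j)] + rest
        if i < n - 1 and j < m - 1:
            for rest in paths(i + 1, j + 1):
                yield [(i, j)] + rest

    return min(sum(local(i, j) for i, j in p) for p in paths(0, 0))


def test_dtw_identical_series_distance_zero():
    assert lf.dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_dtw_constant_offset_absolute_cost():
    # each aligned pair costs 1 on the diagonal path of length 3
    assert lf.dtw_distance([0, 0, 0], [1, 1, 1], cost="absolute") == pytest.approx(3.0)


def test_dtw_matches_exhaustive_path_oracle():
    rng = np.random.default_rng(3)
    for _ in range(30):
        nx, ny = rng.integers(1, 6, size=2)
        x = rng.integers(-3, 4, size=nx).astype(float)
        y = rng.integers(-3, 4, size=ny).astype(float)
        for cost in ("squared", "absolute"):
            assert lf.dtw_distance(x, y, cost=cost) == pytest.approx(
                _dtw_oracle(x, y, cost), rel=1e-12
            )
            assert lf.dtw_distance(x, y, cost=cost) == pytest.approx(
                lf.dtw_distance(y, x, cost=cost)
            )


def test_dtw_cluster_groups_time_shifted_profiles():
    # lagged copies of one profile co-cluster despite the shift
    base = np.sin(np.linspace(0, 2 * np.pi, 12))
    rows = [np.roll(base, s) for s in (0, 1, 2)] + [
        -np.roll(base, s) for s in (0, 1, 2)
    ]
    assignments, _ = lf.dtw_cluster(_matrix(np.asarray(rows)), k_clusters=2, seed=17)
    a = assignments.to_numpy()
    assert len(set(a[:3])) == 1 and len(set(a[3:])) == 1 and a[0] != a[3]


def test_dtw_cluster_singletons_and_seed_stability():
    profiles, _ = _archetype_profiles(n_per=4)
    singles, _ = lf.dtw_cluster(profiles, k_clusters=len(profiles), seed=17)
    assert singles.nunique() == len(profiles)
    a1, m1 = lf.dtw_cluster(profiles, k_clusters=2, seed=17)
    a2, m2 = lf.dtw_cluster(profiles, k_clusters=2, seed=17)
    pd.testing.assert_series_equal(a1, a2)
    assert m1 == m2


# ---------------------------------------------------------------------------
# NMF consensus
# ---------------------------------------------------------------------------

def _block_matrix(n_per_block=10, n_samples_per=8, seed=7):
    rng = np.random.default_rng(seed)
    x = np.zeros((2 * n_per_block, 2 * n_samples_per))
    x[:n_per_block, :n_samples_per] = 5.0
    x[n_per_block:, n_samples_per:] = 5.0
    return _matrix(x + rng.uniform(0.1, 0.5, size=x.shape))


def test_nmf_rank_one_exact_reconstruction():
    u = np.array([1.0, 2.0, 3.0])
    v = np.array([4.0, 5.0])
    x = np.outer(u, v)
    w, h, trace = lf.nmf_multiplicative(x, 1, np.random.default_rng(0), max_iter=5000, tol=0)
    assert np.linalg.norm(x - w @ h) ** 2 < 1e-6


def test_nmf_objective_nonincreasing():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 1, size=(15, 8))
    _, _, trace = lf.nmf_multiplicative(x, 3, np.random.default_rng(1), max_iter=300, tol=0)
    assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))


def test_nmf_objective_competitive_with_sklearn():
    # independent cross-check of the factorization quality
    rng = np.random.default_rng(9)
    x = rng.uniform(0, 1, size=(20, 10))
    _, _, trace = lf.nmf_multiplicative(x, 3, np.random.default_rng(2), max_iter=2000, tol=1e-10)
    ref = SklearnNMF(n_components=3, init="random", random_state=0, max_iter=2000)
    ref.fit(x)
    assert trace[-1] <= 1.2 * ref.reconstruction_err_ ** 2


def test_nmf_consensus_block_structure_perfectly_stable_at_rank_two():
    models = lf.nmf_consensus(_block_matrix(), ranks=range(2, 4), n_runs=15, seed=17)
    m2 = models[2]
    assert m2.cophenetic == pytest.approx(1.0)
    assert set(np.round(np.unique(m2.consensus), 9)) <= {0.0, 1.0}
    for model in models.values():
        c = model.consensus
        assert np.allclose(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert c.min() >= 0.0 and c.max() <= 1.0


def test_nmf_consensus_rejects_negative_or_missing():
    with pytest.raises(ValueError, match="non-negative"):
        lf.nmf_consensus(_matrix([[1.0, -1.0], [2.0, 2.0], [1.0, 1.0]]), ranks=[2])
    with pytest.raises(ValueError, match="complete"):
        lf.nmf_consensus(_matrix([[1.0, np.nan], [2.0, 2.0], [1.0, 1.0]]), ranks=[2])


def test_nmf_top_features_dominance_rule():
    model = lf.NmfModel(
        rank=4,
        W=np.array([[10.0, 0, 0, 0], [1.0, 1.0, 1.0, 1.0], [0, 0, 0, 9.0]]),
        H=np.ones((4, 2)),
        consensus=np.eye(2),
        cophenetic=1.0,
        sample_ids=["S1", "S2"],
        protein_ids=["A", "B", "C"],
    )
    tops = lf.nmf_top_features(model)
    assert tops[1]["protein_id"].tolist() == ["A"]
    assert tops[1]["score"].iloc[0] == pytest.approx(1.0)
    assert tops[4]["protein_id"].tolist() == ["C"]
    # the uniform row appears in no cluster's top list
    for frame in tops.values():
        assert "B" not in set(frame["protein_id"])


def test_nmf_top_features_recover_planted_blocks():
    m = _block_matrix(n_per_block=8, n_samples_per=6, seed=11)
    models = lf.nmf_consensus(m, ranks=[2], n_runs=5, seed=17)
    tops = lf.nmf_top_features(models[2], per_cluster=8, dominance=0.8)
    recovered = [set(frame["protein_id"]) for frame in tops.values()]
    expected = [set(m.index[:8]), set(m.index[8:])]
    assert recovered in ([expected[0], expected[1]], [expected[1], expected[0]])
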