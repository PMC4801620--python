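"""SPA, VIP and random-frog wavelength selection."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsiph import (
    PhantomConfig,
    fit_pls,
    generate_sample_set,
    informative_band_indices,
    random_frog,
    spa_projection_chain,
    spa_select,
    vip_scores,
    vip_select,
)


def brute_force_spa_chain(X, start, k, center=True):
    """Reference SPA: explicit projection matrices at every step."""
    X = np.asarray(X, dtype=float)
    if center:
        X = X - X.mean(axis=0)
    chain = [start]
    for _ in range(k - 1):
        A = X[:, chain]
        P = np.eye(X.shape[0]) - A @ np.linalg.pinv(A)
        norms = np.linalg.norm(P @ X, axis=0)
        norms[chain] = -1
        chain.append(int(np.argmax(norms)))
    return chain


from _helpers import contains_all_features, feature_windows


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def test_spa_chain_matches_projection_oracle():
    """Deflation-based chains equal explicit projection-matrix chains for
    every start column of random 6x5 matrices."""
    for seed in range(3):
        X = np.random.default_rng(seed).normal(size=(6, 5))
        for start in range(5):
            got = spa_projection_chain(X, start, 3)
            want = brute_force_spa_chain(X, start, 3)
            assert got == want, f"seed={seed} start={start}"


def test_spa_on_orthogonal_columns_selects_everything():
    X = np.eye(3)
    chain = spa_projection_chain(X, 0, 3, center=False)
    assert sorted(chain) == [0, 1, 2]


def test_spa_never_selects_a_duplicate_column(rng):
    base = rng.normal(size=(8, 4))
    X = np.column_stack([base, base[:, 0]])  # column 4 duplicates column 0
    chain = spa_projection_chain(X, 0, 4)
    assert 4 not in chain


def test_spa_rank_exhaustion_raises(rng):
    X = np.column_stack([np.ones(6), np.ones(6) * 2.0, rng.normal(size=6)])
    with pytest.raises(ValueError, match="k must be|rank exhausted"):
        spa_projection_chain(X, 0, 3, center=True)  # centred rank is 1


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 200))
def test_spa_chain_is_permutation_equivariant(seed):
    r = np.random.default_rng(seed)
    X = r.normal(size=(7, 5))
    perm = r.permutation(5)
    chain = spa_projection_chain(X, 2, 3)
    where = np.argsort(perm)  # column j of X sits at position where[j]
    chain_p = spa_projection_chain(X[:, perm], int(where[2]), 3)
    assert [int(perm[i]) for i in chain_p] == chain


def test_spa_select_single_band_proportional_response(rng):
    X = rng.normal(size=(12, 6))
    y = 3.0 * X[:, 4]
    res = spa_select(X, y, k_min=1, k_max=1, folds=3)
    assert list(res.selected_indices) == [4]


def test_spa_select_recovers_planted_bands(coarse_config):
    """The best CV-scored chain contains a band within 2 steps of each of the
    three planted absorption centres in >= 90 % of seeded runs."""
    hits = 0
    for seed in range(20):
        cfg = PhantomConfig(**{**coarse_config.__dict__, "seed": seed})
        spectra, ph = generate_sample_set(cfg, 60)
        res = spa_select(spectra.data, ph, 3, 10, seed=seed,
                         wavelengths=spectra.wavelengths)
        hits += contains_all_features(res.selected_indices,
                                      informative_band_indices(cfg))
    assert hits >= 18


def test_selection_defaults_mirror_study_settings():
    import inspect
    spa_sig = inspect.signature(spa_select)
    assert (spa_sig.parameters["k_min"].default,
            spa_sig.parameters["k_max"].default) == (5, 30)
    rf_sig = inspect.signature(random_frog)
    assert rf_sig.parameters["n_iterations"].default == 10_000
    vip_sig = inspect.signature(vip_scores)
    assert vip_sig.parameters["threshold"].default == 1.21


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def test_vip_single_variable_is_one(rng):
    X = rng.normal(size=(10, 1))
    y = 2.0 * X[:, 0] + rng.normal(0, 0.01, 10)
    v = vip_scores(fit_pls(X, y, 1))
    assert np.allclose(v.scores, [1.0], atol=1e-10)


def test_vip_single_component_closed_form():
    """One LV with weight vector (1, 0) gives VIP scores (sqrt(2), 0)."""
    X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.5, 0.0], [-0.5, 0.0]])
    y = np.array([1.0, -1.0, 0.5, -0.5])
    model = fit_pls(X, y, 1)
    assert np.allclose(np.abs(model.x_weights[:, 0]), [1.0, 0.0], atol=1e-12)
    v = vip_scores(model)
    assert np.allclose(v.scores, [np.sqrt(2.0), 0.0], atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 500), n_comp=st.integers(1, 4))
def test_vip_mean_squared_score_is_one(seed, n_comp):
    r = np.random.default_rng(seed)
    X = r.normal(size=(15, 6))
    y = X @ r.normal(size=6) + 0.1 * r.normal(size=15)
    v = vip_scores(fit_pls(X, y, n_comp))
    assert abs(np.mean(v.scores ** 2) - 1.0) < 1e-10


def test_vip_select_threshold_behaviour():
    from hsiph.selection import VIPResult
    res = vip_select(VIPResult(scores=np.array([1.3, 0.9]), threshold=1.21))
    assert list(res.selected_indices) == [0]
    with pytest.warns(UserWarning, match="empty"):
        res = vip_select(VIPResult(scores=np.ones(4), threshold=1.21))
    assert res.n_selected == 0


# ---------------------------------------------------------------------------
# random frog
# ---------------------------------------------------------------------------

def _small_problem(seed=0):
    cfg = PhantomConfig(n_bands=32, pixel_noise_sd=0.001, seed=seed)
    spectra, ph = generate_sample_set(cfg, 40)
    return spectra.data, ph


def test_random_frog_is_deterministic_under_seed():
    X, y = _small_problem()
    t1, r1 = random_frog(X, y, n_iterations=200, seed=5)
    t2, r2 = random_frog(X, y, n_iterations=200, seed=5)
    assert np.array_equal(t1.selection_probabilities, t2.selection_probabilities)
    assert np.array_equal(r1.selected_indices, r2.selected_indices)


def test_random_frog_probabilities_are_exact_frequencies():
    X, y = _small_problem(1)
    trace, _ = random_frog(X, y, n_iterations=250, seed=2)
    counts = trace.selection_probabilities * trace.n_iterations
    assert np.allclose(counts, np.round(counts), atol=1e-9)
    assert trace.selection_probabilities.min() >= 0.0
    assert trace.selection_probabilities.max() <= 1.0


def test_random_frog_rejects_too_few_iterations():
    X, y = _small_problem()
    with pytest.raises(ValueError, match="n_iterations"):
        random_frog(X, y, n_iterations=50)


def test_random_frog_ranks_planted_bands_highly(coarse_config):
    """Median selection probability of the planted bands beats the 90th
    percentile of the noise-band probabilities in >= 90 % of seeded runs."""
    hits = 0
    n_runs = 10
    for seed in range(n_runs):
        cfg = PhantomConfig(**{**coarse_config.__dict__, "seed": seed})
        spectra, ph = generate_sample_set(cfg, 93)
        trace, _ = random_frog(spectra.data, ph, n_iterations=2000, seed=seed)
        centers = informative_band_indices(cfg)
        probs = trace.selection_probabilities
        informative = [probs[max(0, c - 2):c + 3].max() for c in centers]
        _, noise = feature_windows(centers, cfg.n_bands)
        if np.median(informative) > np.quantile(probs[noise], 0.9):
            hits += 1
    assert hits >= 9


def test_random_frog_is_indifferent_on_noise_response():
    """With a pure-noise response no band is preferred: the probability
    profiles of two random halves of the bands are indistinguishable
    (two-sample KS at alpha = 0.01, three seeds)."""
    from scipy.stats import ks_2samp
    for seed in range(3):
        cfg = PhantomConfig(n_bands=48, pixel_noise_sd=0.001, seed=seed)
        spectra, _ = generate_sample_set(cfg, 50)
        r = np.random.default_rng(seed + 100)
        y_noise = r.normal(size=50)
        trace, _ = random_frog(spectra.data, y_noise, n_iterations=1500,
                               seed=seed)
        half = r.permutation(cfg.n_bands)
        a = trace.selection_probabilities[half[:24]]
        b = trace.selection_probabilities[half[24:]]
        assert ks_2samp(a, b).pvalue > 0.01
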