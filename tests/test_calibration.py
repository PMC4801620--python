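"""PLS1, BPNN, model-size selection and evaluation metrics."""
import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from hsiph import (
    BPNNTrainConfig,
    PhantomConfig,
    choose_n_components,
    evaluate_model,
    fit_bpnn,
    fit_pls,
    generate_sample_set,
    generate_sample_pixels,
    hidden_node_candidates,
    informative_band_indices,
    mean_sample_spectrum,
    percent_decrease,
    reduction_percentage,
    select_bpnn_nodes,
)
from hsiph.io import SpectraMatrix

from _helpers import three_factor_data


class _Identity:
    """Stub regressor returning a stored vector; for metric tests."""

    def __init__(self, values):
        self.values = np.asarray(values, dtype=float)
        self.n_inputs = 1

    def predict(self, X):
        return self.values[: len(np.atleast_2d(X))]


# ---------------------------------------------------------------------------
# PLS1
# ---------------------------------------------------------------------------

def test_rank_one_response_needs_one_component(rng):
    t = rng.normal(size=10)
    X = np.outer(t, rng.normal(size=6))
    y = 2.0 * t + 1.0
    model = fit_pls(X, y, 1)
    assert np.abs(model.predict(X) - y).max() < 1e-10


def test_full_rank_pls_equals_least_squares(rng):
    X = rng.normal(size=(12, 5))
    y = X @ rng.normal(size=5) + rng.normal(0, 0.3, 12)
    model = fit_pls(X, y, 5)
    A = np.column_stack([np.ones(12), X])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    assert np.abs(model.predict(X) - A @ beta).max() < 1e-8


def test_pls_matches_sklearn_reference(rng):
    X = rng.normal(size=(20, 8))
    y = X @ rng.normal(size=8) + 0.1 * rng.normal(size=20)
    for a in (1, 3, 5):
        mine = fit_pls(X, y, a)
        ref = PLSRegression(n_components=a, scale=False).fit(X, y[:, None])
        assert np.abs(mine.predict(X) - ref.predict(X).ravel()).max() < 1e-8


def test_pls_scores_are_orthogonal(rng):
    X = rng.normal(size=(15, 7))
    y = X @ rng.normal(size=7)
    T = fit_pls(X, y, 4).x_scores
    G = T.T @ T
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()


def test_pls_coefficient_and_deflation_predictions_agree(rng):
    X = rng.normal(size=(14, 6))
    y = X @ rng.normal(size=6) + 0.2 * rng.normal(size=14)
    model = fit_pls(X, y, 3)
    Xq = rng.normal(size=(5, 6))
    assert np.abs(model.predict(Xq) - model.predict_by_deflation(Xq)).max() < 1e-10


def test_pls_prediction_shifts_with_response_offset(rng):
    X = rng.normal(size=(14, 6))
    y = X @ rng.normal(size=6)
    m0 = fit_pls(X, y, 3)
    m1 = fit_pls(X, y + 5.0, 3)
    assert np.allclose(m1.predict(X), m0.predict(X) + 5.0, atol=1e-10)


def test_pls_rank_exhaustion_truncates_with_warning(rng):
    t = rng.normal(size=10)
    X = np.outer(t, rng.normal(size=4))  # rank 1
    y = t.copy()
    with pytest.warns(UserWarning, match="truncated"):
        model = fit_pls(X, y, 3)
    assert model.n_components == 1


# ---------------------------------------------------------------------------
# model-size selection
# ---------------------------------------------------------------------------

def test_cross_validation_recovers_three_latent_factors():
    hits = 0
    for seed in range(10):
        X, y = three_factor_data(seed)
        a, curve = choose_n_components(X, y, 10, folds=5, seed=seed)
        assert curve.shape == (10,)
        hits += a in (3, 4)
    assert hits >= 8


def test_single_candidate_component_is_returned(rng):
    X = rng.normal(size=(20, 5))
    y = X @ rng.normal(size=5)
    a, _ = choose_n_components(X, y, 1)
    assert a == 1


# ---------------------------------------------------------------------------
# BPNN
# ---------------------------------------------------------------------------

def test_hidden_node_candidates_follow_the_heuristic():
    assert hidden_node_candidates(8, 1) == list(range(4, 14))      # holds 6
    assert hidden_node_candidates(160, 1) == list(range(14, 24))   # holds 14
    assert hidden_node_candidates(3, 1) == list(range(3, 13))


def test_bpnn_training_is_deterministic():
    cfg = PhantomConfig(n_bands=32, seed=0)
    spectra, ph = generate_sample_set(cfg, 30)
    X = spectra.data[:, informative_band_indices(cfg)]
    m1 = fit_bpnn(X, ph, 4, BPNNTrainConfig(epochs=200, seed=3))
    m2 = fit_bpnn(X, ph, 4, BPNNTrainConfig(epochs=200, seed=3))
    assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)
    assert np.array_equal(m1.loss_curve, m2.loss_curve)


def test_bpnn_fits_noiseless_phantom_below_five_millipH():
    cfg = PhantomConfig(n_bands=64, pixel_noise_sd=0.0, scan_noise_sd=0.0,
                        amp_jitter_sd=0.0, seed=1)
    spectra, ph = generate_sample_set(cfg, 60)
    X = spectra.data[:, informative_band_indices(cfg)]
    model = fit_bpnn(X, ph, 6)
    rmse = np.sqrt(np.mean((model.predict(X) - ph) ** 2))
    assert rmse < 0.005
    assert model.loss_curve[-1] <= model.loss_curve[0]


def test_bpnn_node_selection_scans_the_heuristic_candidates():
    cfg = PhantomConfig(n_bands=32, seed=2)
    spectra, ph = generate_sample_set(cfg, 40)
    X = spectra.data[:, informative_band_indices(cfg)]
    tc = BPNNTrainConfig(epochs=150, seed=0)
    model, nodes, scores = select_bpnn_nodes(
        X[:30], ph[:30], validation=(X[30:], ph[30:]), train_config=tc)
    assert sorted(scores) == hidden_node_candidates(X.shape[1], 1)
    assert scores[nodes] == min(scores.values())
    assert model.n_hidden == nodes


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def test_perfect_and_offset_predictions(rng):
    y = rng.uniform(7.1, 7.5, 10)
    rep = evaluate_model(_Identity(y), np.zeros((10, 1)), y,
                         np.zeros((10, 1)), y)
    assert rep.r_c == pytest.approx(1.0) and rep.rmsec == pytest.approx(0.0)
    rep2 = evaluate_model(_Identity(y + 0.1), np.zeros((10, 1)), y,
                          np.zeros((10, 1)), y)
    assert rep2.r_p == pytest.approx(1.0)
    assert rep2.rmsep == pytest.approx(0.1)


def test_constant_predictions_warn_and_return_nan(rng):
    y = rng.uniform(7.1, 7.5, 8)
    with pytest.warns(UserWarning, match="constant"):
        rep = evaluate_model(_Identity(np.full(8, 7.3)), np.zeros((8, 1)), y,
                             np.zeros((8, 1)), y)
    assert np.isnan(rep.r_c)


def test_reduction_percentage_worked_examples():
    assert reduction_percentage(160, 8) == pytest.approx(95.0)
    assert reduction_percentage(160, 15) == pytest.approx(90.625)
    assert reduction_percentage(160, 20) == pytest.approx(87.5)
    assert reduction_percentage(17, 17) == 0.0
    with pytest.raises(ValueError):
        reduction_percentage(10, 11)


def test_percent_decrease_worked_example():
    assert round(percent_decrease(0.880, 0.822), 2) == 6.59


def test_prediction_error_grows_with_pixel_noise():
    """Median full-spectrum PLS RMSEP over 10 paired seeds increases
    monotonically with pixel noise SD across {0.001, 0.005, 0.01, 0.02}."""
    levels = (0.001, 0.005, 0.01, 0.02)
    rmseps = {sd: [] for sd in levels}
    for seed in range(10):
        for sd in levels:
            cfg = PhantomConfig(n_bands=64, pixel_noise_sd=sd, seed=seed)
            rows, phs = [], []
            for pixels, ph_i in generate_sample_pixels(cfg, 45, n_pixels=16):
                rows.append(mean_sample_spectrum(
                    SpectraMatrix(pixels.data, pixels.wavelengths, pixels.ids)))
                phs.append(ph_i)
            X, y = np.stack(rows), np.array(phs)
            model = fit_pls(X[:30], y[:30], 4)
            rmseps[sd].append(
                np.sqrt(np.mean((model.predict(X[30:]) - y[30:]) ** 2)))
    medians = [np.median(rmseps[sd]) for sd in levels]
    assert all(a < b for a, b in zip(medians, medians[1:])), medians
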