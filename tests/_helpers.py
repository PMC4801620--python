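"""Shared phantom constructions used by both unit and acceptance tests."""
import numpy as np

from hsiph import PhantomConfig
from hsiph.synthetic import clean_reflectance


def three_factor_data(seed, n=60, noise=0.001):
    """Spectra driven by three independent absorption-amplitude factors of
    unequal scale, with a response loading equally on all three.

    The mismatch between factor variances and response coefficients makes
    three latent variables genuinely necessary, so cross-validated component
    selection should land on 3 (or 4 with noise).
    """
    cfg = PhantomConfig(n_bands=64, pixel_noise_sd=0.0, scan_noise_sd=0.0,
                        amp_jitter_sd=0.0)
    r = np.random.default_rng(seed)
    scales = np.array([0.03, 0.015, 0.008])
    coeffs = np.array([1.0, -1.0, 1.0])
    F = r.normal(0, 1, (n, 3)) * scales
    X = np.stack([clean_reflectance(cfg, cfg.ph_mean, F[i]) for i in range(n)])
    X += r.normal(0, noise, X.shape)
    y = (F / scales) @ coeffs
    y += r.normal(0, 0.05 * y.std(), n)
    return X, y


def contains_all_features(selected, centers, window=2):
    """True if the selection holds a band within ``window`` steps of every
    planted absorption centre."""
    return all(any(abs(int(i) - int(c)) <= window for i in selected)
               for c in centers)


def feature_windows(centers, n_bands, window=2):
    """(window indices, complement) around the planted centres."""
    win = np.unique(np.concatenate(
        [np.arange(max(0, c - window), min(n_bands, c + window + 1))
         for c in centers]))
    return win, np.delete(np.arange(n_bands), win)
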