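"""Spectral preprocessing: wavelet denoising, sample averaging, set splitting.

Per-pixel NIR spectra are noisy; each pixel spectrum is denoised by a
multilevel discrete wavelet transform (default Daubechies-5, level 5):
detail coefficients are soft-thresholded with the universal threshold
sigma * sqrt(2 ln n), sigma estimated from the median absolute deviation
of the finest detail level, then the spectrum is reconstructed.  The
dish-mean of the denoised pixel spectra is the sample spectrum.

Samples are split into calibration and prediction sets at a 2:1 ratio,
re-drawing until the prediction-set pH range is covered by the
calibration-set range (so the model never extrapolates on its own
prediction set).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .io import SpectraMatrix

__all__ = [
    "WaveletSpec",
    "SampleSplit",
    "wavelet_denoise",
    "mean_sample_spectrum",
    "split_samples",
]


@dataclass(frozen=True)
class WaveletSpec:
    basis: str = "db5"
    level: int = 5
    threshold_rule: str = "universal-soft"  # or "universal-hard"
    padding: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("wavelet level must be >= 1")
        if self.threshold_rule not in ("universal-soft", "universal-hard"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")


def _check_level(n: int, spec: WaveletSpec) -> None:
    # hard feasibility: every decomposition level must keep >= 2 samples;
    # pywt's dwt_max_level is a stricter advisory bound and short NIR spectra
    # are routinely decomposed beyond it
    max_level = max(int(np.log2(n)), 0) if n >= 2 else 0
    if spec.level > max_level:
        raise ValueError(
            f"spectrum of length {n} supports at most level {max_level} "
            f"for {spec.basis}, got {spec.level}"
        )


def wavelet_denoise(
    spectrum: np.ndarray,
    spec: WaveletSpec = WaveletSpec(),
    threshold: float | None = None,
) -> np.ndarray:
    """Denoise one spectrum by thresholding wavelet detail coefficients.

    ``threshold`` overrides the universal threshold (0 disables shrinkage,
    giving perfect reconstruction).
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1:
        raise ValueError("spectrum must be 1-D")
    n = x.size
    _check_level(n, spec)
    with warnings.catch_warnings():
        # pywt warns when level exceeds its advisory maximum; feasibility is
        # checked above against the hard bound
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, spec.basis, mode=spec.padding, level=spec.level)
    details = coeffs[1:]
    if threshold is None:
        finest = details[-1]
        sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
        threshold = sigma * np.sqrt(2.0 * np.log(n))
    mode = "soft" if spec.threshold_rule == "universal-soft" else "hard"
    if threshold > 0:
        details = [pywt.threshold(d, threshold, mode=mode) for d in details]
    rec = pywt.waverec([coeffs[0], *details], spec.basis, mode=spec.padding)
    return rec[:n]


def mean_sample_spectrum(
    pixels: SpectraMatrix,
    spec: WaveletSpec = WaveletSpec(),
    threshold: float | None = None,
) -> np.ndarray:
    """Denoise every pixel spectrum, then average: the sample spectrum."""
    if pixels.n_samples < 1:
        raise ValueError("empty spectra matrix")
    den = np.empty_like(pixels.data)
    for i in range(pixels.n_samples):
        den[i] = wavelet_denoise(pixels.data[i], spec, threshold=threshold)
    return den.mean(axis=0)


# ---------------------------------------------------------------------------
# calibration / prediction split
# ---------------------------------------------------------------------------

def _set_stats(ph: np.ndarray) -> dict:
    return {
        "n": int(ph.size),
        "min": float(ph.min()),
        "max": float(ph.max()),
        "mean": float(ph.mean()),
        "sd": float(ph.std(ddof=1)) if ph.size > 1 else 0.0,
    }


@dataclass
class SampleSplit:
    calibration_ids: list
    prediction_ids: list
    seed: int
    ratio: tuple[int, int]
    attempts: int
    calibration_stats: dict = field(default_factory=dict)
    prediction_stats: dict = field(default_factory=dict)

    @property
    def n_calibration(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_prediction(self) -> int:
        return len(self.prediction_ids)


class SplitCoverageError(RuntimeError):
    """Raised when no random split covers the prediction pH range."""


def split_samples(
    ids,
    ph: np.ndarray,
    ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
    max_attempts: int = 1000,
) -> SampleSplit:
    """Random calibration/prediction partition at ``ratio`` with range coverage.

    The draw is repeated (up to ``max_attempts``) until the prediction set's
    pH min/max lie inside the calibration set's, so that evaluating on the
    prediction set never extrapolates.  Same seed, same partition.
    """
    ids = list(ids)
    ph = np.asarray(ph, dtype=float)
    n = len(ids)
    if n != ph.size:
        raise ValueError("ids and ph lengths differ")
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if min(ratio) <= 0:
        raise ValueError("ratio parts must be positive")
    n_cal = int(round(n * ratio[0] / (ratio[0] + ratio[1])))
    n_cal = min(max(n_cal, 1), n - 1)
    rng = np.random.default_rng(seed)
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(n)
        cal, pred = perm[:n_cal], perm[n_cal:]
        if (ph[pred].min() >= ph[cal].min()) and (ph[pred].max() <= ph[cal].max()):
            return SampleSplit(
                calibration_ids=[ids[i] for i in cal],
                prediction_ids=[ids[i] for i in pred],
                seed=seed,
                ratio=tuple(ratio),
                attempts=attempt,
                calibration_stats=_set_stats(ph[cal]),
                prediction_stats=_set_stats(ph[pred]),
            )
    raise SplitCoverageError(
        f"no coverage-respecting split found in {max_attempts} attempts; "
        "consider assigning the extreme-pH samples to the calibration set "
        "deterministically"
    )
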