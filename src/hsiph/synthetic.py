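"""Phantom hyperspectral scenes of anaerobic-digestion liquid.

No raw images accompany the study this package operationalises, so every
stage is exercised on synthetic phantoms: a Petri dish of digestion liquid
imaged by a 256-band NIR camera (nominal 874-1734 nm).  The optical model
is deliberately simple chemometrics, not radiative transfer:

* reflectance(pH, lambda) = baseline(lambda) - sum_k A_k * g_k(lambda),
  with Gaussian absorption features g_k and amplitudes affine in pH,
  A_k = base_k + slope_k * (pH - pH_mean) + delta_k;
* delta_k is a per-sample compositional jitter independent of pH,
  standing in for the non-pH matrix variability real digestate shows;
* each scan additionally carries a spectrally white, spatially constant
  reflectance error (white-reference / illumination drift between scans):
  unlike pixel noise it does not average out over the dish, which is what
  keeps real averaged sample spectra off the exact model manifold and
  bounds the coefficient norms any honest calibration can earn;
* the dish sits on a dark background and has a bright, spectrally flat
  rim whose spectrum differs from the liquid;
* raw counts are dark + (white - dark) * (reflectance + noise) with
  i.i.d. Gaussian pixel noise, so white/dark flat-field correction
  recovers reflectance + noise exactly;
* per-pixel true pH is drawn from a normal distribution truncated to
  [pH_min, pH_max], with the parent (mu, sigma) solved numerically so the
  *truncated* distribution matches the target mean/SD as closely as the
  family allows.

The default wavelength grid is even with step (1578.13 - 1042.16)/159 nm,
anchored so that 1042.16 nm is a grid point: the working-range crop
1042.16-1578.13 nm then contains exactly 160 bands, consistent with the
study's band-reduction arithmetic (8/160 = 5 % etc.).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import Hypercube, SpectraMatrix, write_envi

__all__ = [
    "DEFAULT_WL_STEP",
    "DEFAULT_WL_START",
    "DEFAULT_WL_END",
    "PhantomConfig",
    "PhantomTruth",
    "truncated_normal_ph",
    "generate_phantom_cube",
    "generate_sample_set",
    "generate_sample_pixels",
    "informative_band_indices",
    "save_phantom",
    "save_sample_set",
]

# Even grid anchored so band 50 is 1042.16 nm and band 209 is 1578.13 nm:
# the cropped working range holds exactly 160 bands.
DEFAULT_WL_STEP = (1578.13 - 1042.16) / 159
DEFAULT_WL_START = 1042.16 - 50 * DEFAULT_WL_STEP
DEFAULT_WL_END = DEFAULT_WL_START + 255 * DEFAULT_WL_STEP


class ConfigurationError(ValueError):
    """Raised for an inconsistent phantom configuration."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, optics and pH population of the phantom scene."""

    n_rows: int = 64
    n_cols: int = 64
    n_bands: int = 256
    wl_start: float = DEFAULT_WL_START
    wl_end: float = DEFAULT_WL_END
    dish_center: tuple[int, int] = (32, 32)
    dish_radius: float = 26.0
    edge_ring_width: float = 4.0
    band_centers: tuple[float, ...] = (1200.0, 1395.0, 1520.0)
    band_widths: tuple[float, ...] = (45.0, 35.0, 40.0)
    band_slopes: tuple[float, ...] = (0.060, -0.080, 0.050)  # absorbance / pH unit
    band_base_amps: tuple[float, ...] = (0.16, 0.22, 0.13)
    baseline_params: tuple[float, ...] = (0.78, -0.08, -0.05)  # poly in scaled lambda
    amp_jitter_sd: float = 0.003
    scan_noise_sd: float = 0.002
    pixel_noise_sd: float = 0.005
    ph_mean: float = 7.34
    ph_sd: float = 0.10
    ph_min: float = 7.13
    ph_max: float = 7.48
    background_reflectance: float = 0.12
    ring_reflectance: float = 0.95
    white_level: float = 3000.0
    dark_level: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wl_start >= self.wl_end:
            raise ConfigurationError("wl_start must be < wl_end")
        if self.n_bands < 2:
            raise ConfigurationError("n_bands must be >= 2")
        if not (self.ph_min <= self.ph_mean <= self.ph_max):
            raise ConfigurationError("require ph_min <= ph_mean <= ph_max")
        if self.pixel_noise_sd < 0:
            raise ConfigurationError("pixel_noise_sd must be >= 0")
        if self.amp_jitter_sd < 0:
            raise ConfigurationError("amp_jitter_sd must be >= 0")
        if self.scan_noise_sd < 0:
            raise ConfigurationError("scan_noise_sd must be >= 0")
        if self.edge_ring_width < 0 or self.edge_ring_width >= self.dish_radius:
            raise ConfigurationError("edge_ring_width must be in [0, dish_radius)")
        r0, c0 = self.dish_center
        if (r0 - self.dish_radius < 0 or r0 + self.dish_radius > self.n_rows - 1
                or c0 - self.dish_radius < 0 or c0 + self.dish_radius > self.n_cols - 1):
            raise ConfigurationError("dish does not fit inside the image frame")
        k = len(self.band_centers)
        if not (len(self.band_widths) == len(self.band_slopes)
                == len(self.band_base_amps) == k):
            raise ConfigurationError("absorption-band parameter lists differ in length")

    @property
    def n_absorption_bands(self) -> int:
        return len(self.band_centers)

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_start, self.wl_end, self.n_bands)


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom: per-pixel pH, clean cube, mask."""

    ph_map: np.ndarray
    clean_cube: np.ndarray
    mask: np.ndarray
    jitter: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# pH population
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _truncnorm_parent(lo: float, hi: float, mean: float, sd: float):
    """Solve for the parent (mu, sigma) whose [lo, hi]-truncation best matches
    the target mean and SD.

    An exact match may be infeasible (the truncated-normal SD on a fixed
    interval is bounded above by the tilted-uniform limit); the least-squares
    fit then lands on the closest attainable moments, with the mean weighted
    more heavily.
    """
    def resid(params):
        mu, logsig = params
        sig = float(np.exp(logsig))
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [3.0 * (float(m) - mean), float(np.sqrt(v)) - sd]

    span = hi - lo
    sol = optimize.least_squares(
        resid,
        [mean, np.log(sd)],
        bounds=([lo - 10 * span, np.log(sd / 20)], [hi + 20 * span, np.log(20 * span)]),
    )
    mu, sig = float(sol.x[0]), float(np.exp(sol.x[1]))
    return mu, sig


def truncated_normal_ph(config: PhantomConfig):
    """Frozen truncated-normal distribution of true pH for ``config``."""
    if config.ph_sd <= 0:
        raise ConfigurationError("ph_sd must be > 0")
    mu, sig = _truncnorm_parent(config.ph_min, config.ph_max,
                                config.ph_mean, config.ph_sd)
    a, b = (config.ph_min - mu) / sig, (config.ph_max - mu) / sig
    return stats.truncnorm(a, b, loc=mu, scale=sig)


# ---------------------------------------------------------------------------
# optical model
# ---------------------------------------------------------------------------

def _baseline(config: PhantomConfig, wl: np.ndarray) -> np.ndarray:
    u = 2 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1  # scaled to [-1, 1]
    return np.polynomial.polynomial.polyval(u, config.baseline_params)

def _band_profiles(config: PhantomConfig, wl: np.ndarray) -> np.ndarray:
    """(k, n_bands) unit-height Gaussian absorption profiles."""
    c = np.asarray(config.band_centers)[:, None]
    w = np.asarray(config.band_widths)[:, None]
    return np.exp(-0.5 * ((wl[None, :] - c) / w) ** 2)


def clean_reflectance(
    config: PhantomConfig,
    ph: np.ndarray | float,
    jitter: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free liquid reflectance for pH value(s); shape ``ph.shape + (bands,)``."""
    wl = config.wavelengths()
    ph = np.asarray(ph, dtype=float)
    base = _baseline(config, wl)
    g = _band_profiles(config, wl)
    amps = (np.asarray(config.band_base_amps)[:, None]
            + np.asarray(config.band_slopes)[:, None]
            * (ph.reshape(1, -1) - config.ph_mean))
    if jitter is not None:
        amps = amps + np.asarray(jitter, dtype=float)[:, None]
    refl = base[None, :] - amps.T @ g
    return refl.reshape(ph.shape + (config.n_bands,))


def informative_band_indices(config: PhantomConfig) -> np.ndarray:
    """Band index nearest each planted absorption-feature centre."""
    wl = config.wavelengths()
    return np.array([int(np.argmin(np.abs(wl - c))) for c in config.band_centers])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_phantom_cube(
    config: PhantomConfig,
    ph_value: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Hypercube, Hypercube, Hypercube, PhantomTruth]:
    """Generate a raw/white/dark cube triple plus ground truth.

    ``ph_value`` forces a spatially uniform dish; otherwise each interior
    pixel draws an independent pH from the truncated-normal population.
    Reproducible bit-for-bit for a fixed config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wl = config.wavelengths()
    r0, c0 = config.dish_center
    rr, cc = np.mgrid[0:config.n_rows, 0:config.n_cols]
    dist = np.hypot(rr - r0, cc - c0)
    interior = dist <= config.dish_radius - config.edge_ring_width
    ring = (dist <= config.dish_radius) & ~interior

    ph_map = np.full((config.n_rows, config.n_cols), np.nan)
    n_in = int(interior.sum())
    if ph_value is None:
        ph_map[interior] = truncated_normal_ph(config).rvs(n_in, random_state=rng)
    else:
        ph_map[interior] = float(ph_value)
    jitter = rng.normal(0.0, config.amp_jitter_sd, config.n_absorption_bands) \
        if config.amp_jitter_sd > 0 else np.zeros(config.n_absorption_bands)
    scan = rng.normal(0.0, config.scan_noise_sd, config.n_bands) \
        if config.scan_noise_sd > 0 else np.zeros(config.n_bands)

    clean = np.empty((config.n_rows, config.n_cols, config.n_bands))
    clean[:] = config.background_reflectance
    clean[ring] = config.ring_reflectance
    clean[interior] = clean_reflectance(config, ph_map[interior], jitter)

    illum = 1.0 - 0.15 * (2 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1) ** 2
    white_plane = config.dark_level + (config.white_level - config.dark_level) * illum
    white = np.broadcast_to(white_plane, clean.shape).copy()
    dark = np.full(clean.shape, config.dark_level)

    refl = clean + scan  # scan-level drift hits every pixel identically
    if config.pixel_noise_sd > 0:
        refl = refl + rng.normal(0.0, config.pixel_noise_sd, clean.shape)
    raw = dark + (white - dark) * refl

    meta = {"phantom": True, "seed": config.seed}
    truth = PhantomTruth(ph_map=ph_map, clean_cube=clean, mask=interior, jitter=jitter)
    return (Hypercube(raw, wl, dict(meta, kind="raw")),
            Hypercube(white, wl, dict(meta, kind="white")),
            Hypercube(dark, wl, dict(meta, kind="dark")),
            truth)


def _interior_pixel_count(config: PhantomConfig) -> int:
    r0, c0 = config.dish_center
    rr, cc = np.mgrid[0:config.n_rows, 0:config.n_cols]
    dist = np.hypot(rr - r0, cc - c0)
    return int((dist <= config.dish_radius - config.edge_ring_width).sum())


def generate_sample_set(
    config: PhantomConfig,
    n_samples: int,
    rng: np.random.Generator | None = None,
    method: str = "closed_form",
) -> tuple[SpectraMatrix, np.ndarray]:
    """Per-sample dish-mean spectra paired with true pH.

    Each sample is an independently generated uniform-pH phantom dish.  With
    ``method='closed_form'`` the dish-mean spectrum is computed analytically:
    clean reflectance plus Gaussian noise of SD ``pixel_noise_sd / sqrt(n_px)``
    (the mean of n_px i.i.d. pixel noises).  ``method='image'`` renders full
    cubes and averages interior pixels; it is equivalent in distribution and
    exists for cross-checks.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if method not in ("closed_form", "image"):
        raise ValueError(f"unknown method {method!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dist = truncated_normal_ph(config)
    ph = np.asarray(dist.rvs(n_samples, random_state=rng))
    wl = config.wavelengths()
    rows = np.empty((n_samples, config.n_bands))
    if method == "closed_form":
        n_px = _interior_pixel_count(config)
        sd_eff = config.pixel_noise_sd / np.sqrt(n_px)
        for i in range(n_samples):
            jit = rng.normal(0.0, config.amp_jitter_sd, config.n_absorption_bands) \
                if config.amp_jitter_sd > 0 else None
            rows[i] = clean_reflectance(config, ph[i], jit)
            if config.scan_noise_sd > 0:
                rows[i] += rng.normal(0.0, config.scan_noise_sd, config.n_bands)
            if sd_eff > 0:
                rows[i] += rng.normal(0.0, sd_eff, config.n_bands)
    else:
        for i in range(n_samples):
            raw, white, dark, truth = generate_phantom_cube(
                config, ph_value=ph[i], rng=rng)
            refl = (raw.data - dark.data) / (white.data - dark.data)
            rows[i] = refl[truth.mask].mean(axis=0)
    ids = [f"s{i:03d}" for i in range(n_samples)]
    return SpectraMatrix(rows, wl, ids), ph


def generate_sample_pixels(
    config: PhantomConfig,
    n_samples: int,
    rng: np.random.Generator | None = None,
    n_pixels: int | None = None,
):
    """Yield ``(pixels, ph)`` per sample: noisy pixel spectra of a uniform dish.

    This is the input the denoise-then-average preprocessing consumes; unlike
    :func:`generate_sample_set` it keeps the individual noisy pixel spectra,
    so nonlinear per-pixel preprocessing (wavelet shrinkage) acts on the same
    noise level at training time as at map time.  ``n_pixels`` subsamples the
    dish interior for speed (the mean's noise floor scales as 1/sqrt(n)).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_full = _interior_pixel_count(config)
    n_px = n_full if n_pixels is None else int(min(n_pixels, n_full))
    if n_px < 1:
        raise ValueError("n_pixels must be >= 1")
    dist = truncated_normal_ph(config)
    wl = config.wavelengths()
    for i in range(n_samples):
        ph_i = float(dist.rvs(random_state=rng))
        jit = rng.normal(0.0, config.amp_jitter_sd, config.n_absorption_bands) \
            if config.amp_jitter_sd > 0 else None
        clean = clean_reflectance(config, ph_i, jit)
        if config.scan_noise_sd > 0:
            clean = clean + rng.normal(0.0, config.scan_noise_sd, config.n_bands)
        pix = np.tile(clean, (n_px, 1))
        if config.pixel_noise_sd > 0:
            pix = pix + rng.normal(0.0, config.pixel_noise_sd, pix.shape)
        ids = [f"s{i:03d}_px{j}" for j in range(n_px)]
        yield SpectraMatrix(pix, wl, ids), ph_i


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------

def save_phantom(out_dir: str | os.PathLike, config: PhantomConfig) -> dict:
    """Write a phantom scene (ENVI raw/white/dark + truth CSVs); returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    raw, white, dark, truth = generate_phantom_cube(config)
    paths = {}
    for name, cube in (("raw", raw), ("white", white), ("dark", dark)):
        paths[name] = write_envi(cube, os.path.join(out_dir, f"{name}.img"),
                                 dtype=np.float32)
    ph_path = os.path.join(out_dir, "truth_ph_map.csv")
    np.savetxt(ph_path, truth.ph_map, delimiter=",", fmt="%.6f")
    mask_path = os.path.join(out_dir, "truth_mask.csv")
    np.savetxt(mask_path, truth.mask.astype(int), delimiter=",", fmt="%d")
    paths.update(ph_map=ph_path, mask=mask_path)
    return paths


def save_sample_set(
    path: str | os.PathLike,
    spectra: SpectraMatrix,
    ph: np.ndarray,
) -> None:
    """Write a sample set as CSV: id, pH, then one column per band (nm)."""
    cols = [f"{w:.4f}" for w in spectra.wavelengths]
    df = pd.DataFrame(spectra.data, columns=cols)
    df.insert(0, "ph", ph)
    df.insert(0, "id", [str(i) for i in spectra.ids])
    df.to_csv(path, index=False)


def load_sample_set(path: str | os.PathLike) -> tuple[SpectraMatrix, np.ndarray]:
    df = pd.read_csv(path)
    ids = df["id"].astype(str).tolist()
    ph = df["ph"].to_numpy(float)
    wl = np.array([float(c) for c in df.columns[2:]])
    return SpectraMatrix(df.iloc[:, 2:].to_numpy(float), wl, ids), ph
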