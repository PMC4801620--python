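"""Pixel-wise pH prediction and distribution-map rendering.

Applying a spectrum->pH calibration model to every ROI pixel of a
calibrated, cropped cube turns the scene into a pH distribution map.
Pixel spectra are denoised with the same wavelet settings used at
training time, subset to the selected bands if the model was built on a
selection, and predicted.  Predictions outside the calibration pH range
are kept but flagged (the model is extrapolating there) and rendered in
a sentinel colour.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib import cm  # noqa: E402
from PIL import Image  # noqa: E402

from .io import Hypercube, ROIMask
from .preprocess import WaveletSpec, wavelet_denoise
from .selection import SelectionResult

__all__ = ["DistributionMap", "predict_map", "render_map"]

BACKGROUND_RGB = (200, 200, 200)
OUT_OF_RANGE_RGB = (255, 0, 255)


@dataclass
class DistributionMap:
    """Predicted pH per ROI pixel (NaN elsewhere) plus extrapolation flags."""

    values: np.ndarray
    mask: ROIMask
    out_of_range: np.ndarray
    calibration_range: tuple[float, float]

    @property
    def n_flagged(self) -> int:
        return int(self.out_of_range.sum())

    @property
    def fraction_flagged(self) -> float:
        n = self.mask.n_pixels
        return self.n_flagged / n if n else 0.0


def predict_map(
    cube: Hypercube,
    roi: ROIMask,
    model,
    selection: SelectionResult | None = None,
    wavelet: WaveletSpec | None = None,
    calibration_range: tuple[float, float] | None = None,
) -> DistributionMap:
    """Predict pH for every ROI pixel of a calibrated, cropped cube.

    ``calibration_range`` defaults to the y-range the model was trained on
    (a BPNN stores it as its output scaling; a PLS model has no intrinsic
    range, so pass it explicitly for meaningful flags).
    """
    if roi.mask.shape != cube.data.shape[:2]:
        raise ValueError("ROI grid shape does not match cube spatial shape")
    if roi.n_pixels < 1:
        raise ValueError("empty ROI")
    n_expected = model.n_inputs
    n_available = (selection.n_selected if selection is not None
                   else cube.n_bands)
    if n_expected != n_available:
        raise ValueError(
            f"model expects {n_expected} bands but "
            f"{'selection provides' if selection is not None else 'cube has'} "
            f"{n_available}")
    if calibration_range is None:
        if hasattr(model, "y_min"):
            calibration_range = (float(model.y_min), float(model.y_max))
        else:
            raise ValueError("calibration_range required for this model type")
    lo, hi = calibration_range

    spectra = cube.data[roi.mask]
    if wavelet is not None:
        spectra = np.stack([wavelet_denoise(s, wavelet) for s in spectra])
    if selection is not None:
        spectra = spectra[:, selection.selected_indices]
    preds = model.predict(spectra)

    values = np.full(roi.mask.shape, np.nan)
    values[roi.mask] = preds
    out_of_range = np.zeros(roi.mask.shape, dtype=bool)
    out_of_range[roi.mask] = (preds < lo) | (preds > hi)
    return DistributionMap(values=values, mask=roi,
                           out_of_range=out_of_range,
                           calibration_range=(lo, hi))


def render_map(
    dist_map: DistributionMap,
    path: str | os.PathLike,
    colormap_name: str = "jet",
    display_range: tuple[float, float] | None = None,
) -> str:
    """Render the map as an 8-bit colour PNG at the cube's pixel dimensions.

    Values are clipped to ``display_range`` for colouring only (stored values
    are untouched); flagged extrapolating pixels get a sentinel colour and
    non-ROI pixels a neutral background.  A colourbar legend and a JSON
    sidecar (calibration range, flagged fraction) are written alongside.
    """
    if dist_map.mask.n_pixels < 1:
        raise ValueError("empty map; nothing to render")
    path = str(path)
    if display_range is None:
        display_range = dist_map.calibration_range
    lo, hi = display_range
    if not hi > lo:
        raise ValueError("display_range must have hi > lo")
    cmap = plt.get_cmap(colormap_name)
    norm = np.clip((dist_map.values - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.empty(dist_map.values.shape + (3,), dtype=np.uint8)
    rgb[:] = BACKGROUND_RGB
    inside = dist_map.mask.mask
    colored = (cmap(np.nan_to_num(norm))[:, :, :3] * 255).astype(np.uint8)
    rgb[inside] = colored[inside]
    rgb[dist_map.out_of_range] = OUT_OF_RANGE_RGB
    Image.fromarray(rgb).save(path)

    stem, _ = os.path.splitext(path)
    fig, ax = plt.subplots(figsize=(1.6, 3.2))
    fig.subplots_adjust(left=0.35, right=0.6)
    sm = cm.ScalarMappable(cmap=cmap,
                           norm=matplotlib.colors.Normalize(lo, hi))
    fig.colorbar(sm, cax=ax, label="pH")
    fig.savefig(stem + "_legend.png", dpi=120)
    plt.close(fig)

    with open(stem + "_map.json", "w") as fh:
        json.dump({
            "calibration_range": list(dist_map.calibration_range),
            "display_range": [lo, hi],
            "n_roi_pixels": dist_map.mask.n_pixels,
            "fraction_out_of_range": dist_map.fraction_flagged,
        }, fh, indent=2)
    np.savetxt(stem + "_values.csv", dist_map.values, delimiter=",", fmt="%.5f")
    return path
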