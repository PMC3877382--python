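"""Membrane-potential dye intensity in soma ROIs, normalized to control.

Potential-sensitive dyes (MitoTracker Red, TMRM) accumulate in mitochondria
in proportion to the inner-membrane potential, so mean somatic fluorescence
is a relative proxy for ψ_m — reported as percent of the control-group
mean, never as a calibrated voltage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon


@dataclass
class IntensityRecord:
    cell_id: int
    mean_intensity: float
    background: float
    group: str = ""
    n_pixels: int = 0


def _roi_mask(shape, poly) -> np.ndarray:
    poly = np.asarray(poly, dtype=float)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def measure_soma_intensity(image: np.ndarray, rois: list[dict],
                           background_mode: str = "none",
                           group: str = "") -> list[IntensityRecord]:
    """Mean pixel intensity inside each ROI polygon.

    ``rois`` entries need ``cell_id`` and ``polygon`` ([[x, y], ...] px).
    ``background_mode``: 'none' (default) or 'mode' — subtract the modal
    intensity of the non-ROI pixels.
    """
    image = np.asarray(image, dtype=float)
    if background_mode not in ("none", "mode"):
        raise ValueError("background_mode must be 'none' or 'mode'")
    masks = []
    for roi in rois:
        mask = _roi_mask(image.shape, roi["polygon"])
        if not mask.any():
            raise ValueError(f"ROI for cell {roi['cell_id']} is empty")
        masks.append(mask)
    bg = 0.0
    if background_mode == "mode":
        outside = ~np.logical_or.reduce(masks) if masks else np.ones(image.shape, bool)
        vals, counts = np.unique(np.round(image[outside]), return_counts=True)
        bg = float(vals[counts.argmax()])
    return [IntensityRecord(cell_id=int(roi["cell_id"]),
                            mean_intensity=float(image[mask].mean()) - bg,
                            background=bg, group=group,
                            n_pixels=int(mask.sum()))
            for roi, mask in zip(rois, masks)]


def normalize_to_control(records: list[IntensityRecord],
                         control_group: str) -> pd.DataFrame:
    """Express every cell's intensity as percent of the control-group mean.

    The control group's normalized mean is exactly 100%; normalization is
    invariant to a global intensity rescaling.
    """
    ctrl = [r.mean_intensity for r in records if r.group == control_group]
    if not ctrl:
        raise ValueError(f"control group {control_group!r} is empty")
    denom = float(np.mean(ctrl))
    if denom == 0:
        raise ValueError("control-group mean intensity is zero")
    return pd.DataFrame([{
        "cell_id": r.cell_id, "group": r.group,
        "mean_intensity": r.mean_intensity,
        "normalized_pct": 100.0 * r.mean_intensity / denom,
    } for r in records])
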