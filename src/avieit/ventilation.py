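"""Breath-wise functional images and distribution-of-ventilation variables.

For each breath the functional (tidal) image is the end-inspiration frame
minus the start-inspiration frame.  From its ventilation-positive part
(negative pixels are clamped to zero for the distribution metrics, but kept
in the raw image) the following are computed:

* centre of ventilation, right-left (CoV_RL) and ventral-dorsal (CoV_VD), as
  a percentage of the mask bounding-box extent — 0% means all ventilation at
  the subject's right / at the ventral edge, 100% at the left / dorsal edge;
* the right-to-left ratio of ventilation-weighted impedance change;
* eight regional percentages — four equal-height horizontal bands of the
  bounding box (dorsal, central-dorsal, central-ventral, ventral) split at
  the right-left midline — which sum to 100%.

All metrics are computed on the outer-contour mask only; no organ ROI enters
the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .breaths import BreathSegment
from .greit import ImageStream

__all__ = [
    "FunctionalImage",
    "VentilationVariables",
    "tidal_image",
    "centre_of_ventilation",
    "rl_ratio",
    "regional_distribution",
    "variables_for_breaths",
    "REGION_NAMES",
]

REGION_NAMES = ("R_D", "R_CD", "R_CV", "R_V", "L_D", "L_CD", "L_CV", "L_V")


@dataclass
class FunctionalImage:
    pixels: np.ndarray  # (32, 32), AU; may contain negative values
    mask: np.ndarray

    @property
    def clamped(self) -> np.ndarray:
        return np.where(self.mask, np.clip(self.pixels, 0.0, None), 0.0)


@dataclass
class VentilationVariables:
    cov_rl: float
    cov_vd: float
    rl_ratio: float
    regions: dict
    tiv: float
    t_insp: float
    brp: str | None = None

    def as_dict(self) -> dict:
        out = {
            "cov_rl": self.cov_rl,
            "cov_vd": self.cov_vd,
            "rl_ratio": self.rl_ratio,
            "tiv": self.tiv,
            "t_insp": self.t_insp,
        }
        out.update({f"dz_{k}": v for k, v in self.regions.items()})
        if self.brp is not None:
            out["brp"] = self.brp
        return out


def tidal_image(images: ImageStream, b: BreathSegment) -> FunctionalImage:
    """End-inspiration frame minus start-inspiration frame for one breath."""
    if not (0 <= b.i_start_insp < images.n_frames and 0 <= b.i_end_insp < images.n_frames):
        raise IndexError("breath indices outside image stream")
    pix = images.frames[b.i_end_insp] - images.frames[b.i_start_insp]
    return FunctionalImage(pixels=pix, mask=images.mask.copy())


def _bbox(mask: np.ndarray):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return rows[0], rows[-1], cols[0], cols[-1]


def centre_of_ventilation(f: FunctionalImage, axis: str = "rl") -> float:
    """Impedance-weighted focal point of ventilation along one axis, in %.

    Coordinates are pixel centres normalised to the mask bounding box:
    ``rl`` runs 0 at the subject's right edge to 1 at the left edge, ``vd``
    0 at the ventral edge to 1 at the dorsal edge.
    """
    w = f.clamped
    total = w.sum()
    if total <= 0:
        raise ValueError("no ventilation signal (all-zero functional image)")
    r0, r1, c0, c1 = _bbox(f.mask)
    rows, cols = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
    if axis.lower() == "rl":
        u = (cols - c0) / max(c1 - c0, 1)  # column 0 is the subject's right
    elif axis.lower() == "vd":
        u = (r1 - rows) / max(r1 - r0, 1)  # row 0 is dorsal, so invert
    else:
        raise ValueError("axis must be 'rl' or 'vd'")
    return float(100.0 * (w * u).sum() / total)


def _right_fraction(mask: np.ndarray, ncol: int) -> np.ndarray:
    """Per-column fraction lying on the subject's right of the bounding-box
    midline; a column straddling the midline is split half-half."""
    _, _, c0, c1 = _bbox(mask)
    mid = (c0 + c1 + 1) / 2.0  # in pixel-edge coordinates
    cols = np.arange(ncol)
    return np.clip(mid - cols, 0.0, 1.0)


def rl_ratio(f: FunctionalImage) -> float:
    """Ventilation-weighted right/left ratio about the bounding-box midline."""
    w = f.clamped
    fr = _right_fraction(f.mask, w.shape[1])
    right = float((w * fr[None, :]).sum())
    left = float((w * (1.0 - fr)[None, :]).sum())
    if left <= 0:
        raise ZeroDivisionError("undefined RL ratio: no left-side signal")
    return right / left


def regional_distribution(f: FunctionalImage) -> dict:
    """Eight regional percentages of total impedance change.

    The mask bounding box is cut into four equal-height horizontal bands
    (dorsal to ventral); pixel rows straddling a band edge are apportioned by
    overlap, so the eight percentages sum to exactly 100.
    """
    w = f.clamped
    total = w.sum()
    if total <= 0:
        raise ValueError("no ventilation signal (all-zero functional image)")
    r0, r1, c0, c1 = _bbox(f.mask)
    height = r1 - r0 + 1
    edges = r0 + height * np.arange(5) / 4.0  # in pixel-edge row coordinates
    nrow, ncol = w.shape
    rows = np.arange(nrow)
    # overlap of pixel row [r, r+1) with band k [edges[k], edges[k+1])
    band_frac = np.zeros((4, nrow))
    for k in range(4):
        lo, hi = edges[k], edges[k + 1]
        band_frac[k] = np.clip(np.minimum(rows + 1, hi) - np.maximum(rows, lo), 0.0, 1.0)
    fr = _right_fraction(f.mask, ncol)
    out = {}
    band_names = ("D", "CD", "CV", "V")  # row index grows ventral-ward
    for k, band in enumerate(band_names):
        wk = w * band_frac[k][:, None]
        out[f"R_{band}"] = float(100.0 * (wk * fr[None, :]).sum() / total)
        out[f"L_{band}"] = float(100.0 * (wk * (1.0 - fr)[None, :]).sum() / total)
    return {name: out[name] for name in REGION_NAMES}


def variables_for_breaths(images: ImageStream, breaths) -> tuple:
    """Per-breath variables plus their arithmetic means over the breaths.

    Returns ``(per_breath: DataFrame, means: Series)``; one row per breath in
    input order.
    """
    breaths = list(breaths)
    if not breaths:
        raise ValueError("no breaths to analyse")
    records = []
    for b in breaths:
        f = tidal_image(images, b)
        v = VentilationVariables(
            cov_rl=centre_of_ventilation(f, "rl"),
            cov_vd=centre_of_ventilation(f, "vd"),
            rl_ratio=rl_ratio(f),
            regions=regional_distribution(f),
            tiv=b.tiv,
            t_insp=b.t_insp,
        )
        records.append(v.as_dict())
    df = pd.DataFrame.from_records(records)
    return df, df.mean(numeric_only=True)
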