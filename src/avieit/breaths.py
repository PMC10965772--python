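"""Global impedance curve, cardiac-flutter removal and breath segmentation.

The global signal is the per-frame sum of in-mask pixel values.  Small
heart-rate-synchronous oscillations ride on it; they are removed with a
zero-phase low-pass filter whose cutoff sits between the respiratory band
(< 0.5 Hz at typical anaesthetised rates) and the cardiac band (> 3 Hz).
Breaths are then segmented as trough-peak-trough triplets, and a run of six
to ten consecutive artefact-free breaths is selected for analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .greit import ImageStream

__all__ = [
    "GlobalCurve",
    "BreathSegment",
    "global_curve",
    "remove_cardiac",
    "detect_breaths",
    "select_artefact_free",
]


@dataclass
class GlobalCurve:
    z: np.ndarray
    fps: float
    filtered: bool = False


@dataclass
class BreathSegment:
    """One breath: start-inspiration, end-inspiration, end-expiration frames.

    ``tiv`` is the tidal impedance variation, the global impedance change
    between start and end of inspiration (defined non-negative, i.e. the
    magnitude of the inspiratory rise); ``t_insp`` the inspiratory time in
    seconds.
    """

    i_start_insp: int
    i_end_insp: int
    i_end_exp: int
    tiv: float
    t_insp: float

    def __post_init__(self) -> None:
        if not (self.i_start_insp < self.i_end_insp < self.i_end_exp):
            raise ValueError("breath indices must be strictly increasing")
        if self.tiv < 0:
            raise ValueError("tiv must be non-negative")

    @property
    def duration_frames(self) -> int:
        return self.i_end_exp - self.i_start_insp


def global_curve(images: ImageStream) -> GlobalCurve:
    """Sum of in-mask pixel values per frame."""
    if images.n_frames == 0:
        raise ValueError("empty image stream")
    flat = images.frames.reshape(images.n_frames, -1)
    z = flat[:, images.mask.ravel()].sum(axis=1)
    return GlobalCurve(z=z, fps=images.fps, filtered=False)


def remove_cardiac(c: GlobalCurve, cutoff_hz: float = 1.5, order: int = 4) -> GlobalCurve:
    """Zero-phase Butterworth low-pass to strip heart-synchronous flutter."""
    nyq = c.fps / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=c.fps, output="sos")
    z = signal.sosfiltfilt(sos, c.z)
    return GlobalCurve(z=z, fps=c.fps, filtered=True)


def detect_breaths(c: GlobalCurve, prominence_frac: float = 0.2):
    """Segment breaths as alternating minima and maxima of the global curve.

    Peaks (end-inspiration) and troughs (start-inspiration / end-expiration)
    are accepted at a prominence of ``prominence_frac`` times the median
    peak-to-trough excursion, estimated from a permissive first pass.
    """
    z = np.asarray(c.z, float)
    span = z.max() - z.min() if len(z) else 0.0
    if len(z) < 5 or span <= 0:
        warnings.warn("no respiratory cycles found")
        return []
    rough_peaks, props = signal.find_peaks(z, prominence=0.05 * span)
    if len(rough_peaks) == 0:
        warnings.warn("no respiratory cycles found")
        return []
    excursion = float(np.median(props["prominences"]))
    prom = prominence_frac * excursion
    peaks, _ = signal.find_peaks(z, prominence=prom)
    troughs, _ = signal.find_peaks(-z, prominence=prom)
    # a cycle cut by the recording edge has no enclosing trough pair and is
    # dropped; only complete trough-peak-trough triples become breaths
    breaths = []
    for pk in peaks:
        before = troughs[troughs < pk]
        after = troughs[troughs > pk]
        if len(before) == 0 or len(after) == 0:
            continue
        i0, i2 = int(before[-1]), int(after[0])
        breaths.append(
            BreathSegment(
                i_start_insp=i0,
                i_end_insp=int(pk),
                i_end_exp=i2,
                tiv=float(z[pk] - z[i0]),
                t_insp=(int(pk) - i0) / c.fps,
            )
        )
    if not breaths:
        warnings.warn("no respiratory cycles found")
    return breaths


def select_artefact_free(
    breaths,
    min_n: int = 6,
    max_n: int = 10,
    tol_frac: float = 0.5,
    max_gap_s: float = 10.0,
    fps: float = 48.0,
):
    """Longest run of consecutive artefact-free breaths, truncated to
    ``max_n`` (earliest run preferred on ties).

    A breath qualifies when its TIV and its total duration both lie within
    the recording median +/- ``tol_frac`` (50% by default).  Runs are broken
    by a disqualified breath or by an apnoeic gap longer than ``max_gap_s``.
    """
    breaths = list(breaths)
    if not breaths:
        raise ValueError("insufficient artefact-free breaths")
    tivs = np.array([b.tiv for b in breaths])
    durs = np.array([b.duration_frames for b in breaths], float)
    med_t, med_d = np.median(tivs), np.median(durs)
    ok = (np.abs(tivs - med_t) <= tol_frac * med_t) & (
        np.abs(durs - med_d) <= tol_frac * med_d
    )
    runs = []
    start = None
    for i, good in enumerate(ok):
        gap_broken = (
            i > 0 and (breaths[i].i_start_insp - breaths[i - 1].i_end_exp) / fps > max_gap_s
        )
        if not good:
            if start is not None:
                runs.append((start, i))
            start = None
        elif start is None:
            start = i
        elif gap_broken:
            runs.append((start, i))
            start = i
    if start is not None:
        runs.append((start, len(ok)))
    if not runs:
        raise ValueError("insufficient artefact-free breaths")
    best = max(runs, key=lambda r: r[1] - r[0])  # max is stable: earliest wins ties
    if best[1] - best[0] < min_n:
        raise ValueError("insufficient artefact-free breaths")
    sel = breaths[best[0] : best[1]]
    return sel[:max_n]
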