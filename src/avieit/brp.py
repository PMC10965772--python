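"""Breathing-pattern (BrP) classification from expiratory curve morphology.

Anaesthetised chickens show four expiratory morphologies on the global
impedance curve:

* BrP1 — concave-linear decay, no pause;
* BrP2 — convex-linear decay, no pause;
* BrP3 — an impedance pause (momentary expiratory plateau, a transient
  breath-hold during exhalation) starting early, while remaining impedance
  change is above 50% of the tidal swing;
* BrP4 — a pause starting late, at or below the 50% level.

A recording is assigned a single pattern only when at least 95% of its
analysed breaths share one category; otherwise it is labelled ``mixed``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .breaths import BreathSegment, GlobalCurve

__all__ = [
    "ExpiratoryCurve",
    "PauseEvent",
    "BrPLabel",
    "extract_expiration",
    "detect_pause",
    "classify_breath",
    "classify_recording",
]

BRP_CATEGORIES = ("BrP1", "BrP2", "BrP3", "BrP4")


@dataclass
class ExpiratoryCurve:
    """Expiratory limb, normalised to 1 at end-inspiration and 0 at
    end-expiration, on a time axis normalised to [0, 1]."""

    z_norm: np.ndarray
    tau: np.ndarray
    duration_s: float


@dataclass
class PauseEvent:
    tau_onset: float
    tau_offset: float
    level: float  # z_norm at pause onset

    @property
    def duration_frac(self) -> float:
        return self.tau_offset - self.tau_onset


@dataclass
class BrPLabel:
    value: str  # BrP1..BrP4 or "mixed"
    pause_level: float | None = None

    def __post_init__(self) -> None:
        has_pause = self.value in ("BrP3", "BrP4")
        if has_pause != (self.pause_level is not None):
            raise ValueError("pause_level present iff label is BrP3 or BrP4")


def extract_expiration(c: GlobalCurve, b: BreathSegment) -> ExpiratoryCurve:
    """Normalised expiratory limb of one breath."""
    seg = np.asarray(c.z[b.i_end_insp : b.i_end_exp + 1], float)
    if len(seg) < 5:
        raise ValueError("expiration too short")
    span = seg[0] - seg[-1]
    if span == 0:
        raise ValueError("flat expiration segment")
    z_norm = (seg - seg[-1]) / span
    tau = np.linspace(0.0, 1.0, len(seg))
    return ExpiratoryCurve(z_norm=z_norm, tau=tau, duration_s=(len(seg) - 1) / c.fps)


def detect_pause(
    e: ExpiratoryCurve,
    min_pause_s: float = 0.3,
    slope_frac: float = 0.1,
    tail_excluded: float = 0.05,
):
    """Longest expiratory plateau, or None.

    A plateau is an interval whose slope magnitude |dz/dtau| drops to at
    most ``slope_frac`` of the mean absolute expiratory slope, lasting at
    least ``min_pause_s``; the final ``tail_excluded`` fraction of
    expiration is ignored so the terminal baseline is never read as a pause.

    Implementation: the slope is estimated with a short Savitzky-Golay
    derivative (robust to residual flutter); strictly-flat core samples
    (|dz| <= slope_frac * mean) are grown by hysteresis to the surrounding
    near-flat region (|dz| <= 5 * slope_frac * mean), which recovers the
    plateau extent that low-pass smoothing of its corners would otherwise
    eat.  A pause must lie strictly *within* exhalation: at least 10% of the
    tidal drop must precede its onset (rejecting the flat start of the
    concave BrP1 shape, whose slope also vanishes at end-inspiration) and at
    least 5% must follow its offset (rejecting the creeping tail of the
    convex BrP2 shape).
    """
    n = len(e.z_norm)
    win = max(5, (int(round(0.05 * n)) // 2) * 2 + 1)
    if win < n:
        from scipy.signal import savgol_filter

        dz = savgol_filter(e.z_norm, win, polyorder=2, deriv=1) * (n - 1)
    else:
        dz = np.gradient(e.z_norm, e.tau)
    mean_slope = float(np.mean(np.abs(dz)))
    if mean_slope <= 0:
        return None
    in_window = e.tau <= 1.0 - tail_excluded
    core = (np.abs(dz) <= slope_frac * mean_slope) & in_window
    near = (np.abs(dz) <= 5.0 * slope_frac * mean_slope) & in_window
    best = None
    i = 0
    while i < n:
        if not core[i]:
            i += 1
            continue
        lo = i
        while lo > 0 and near[lo - 1]:
            lo -= 1
        hi = i
        while hi + 1 < n and near[hi + 1]:
            hi += 1
        span_tau = e.tau[hi] - e.tau[lo]
        within_exhalation = e.z_norm[lo] <= 0.9 and e.z_norm[hi] >= 0.05
        if within_exhalation and (best is None or span_tau > best[1] - best[0]):
            best = (e.tau[lo], e.tau[hi], i)
        i = hi + 1
    if best is None:
        return None
    if (best[1] - best[0]) * e.duration_s < min_pause_s:
        return None
    return PauseEvent(tau_onset=best[0], tau_offset=best[1], level=float(e.z_norm[best[2]]))


def classify_breath(e: ExpiratoryCurve, pause=None) -> BrPLabel:
    """Assign BrP1-4 from pause presence/level or curve-vs-chord area.

    With a pause: BrP3 when onset level > 0.5 (early pause), BrP4 otherwise.
    Without: the signed area between the curve and the straight chord
    ``1 - tau`` decides — at or above the chord (concave) is BrP1, below
    (convex) is BrP2.
    """
    if pause is not None:
        if pause.level > 0.5:
            return BrPLabel("BrP3", pause_level=pause.level)
        return BrPLabel("BrP4", pause_level=pause.level)
    area = float(np.trapezoid(e.z_norm - (1.0 - e.tau), e.tau))
    return BrPLabel("BrP1" if area >= 0 else "BrP2")


def classify_recording(labels, uniform_frac: float = 0.95) -> BrPLabel:
    """Per-recording pattern under the >= 95% uniformity rule."""
    labels = list(labels)
    if not labels:
        raise ValueError("no breath labels")
    values = [l.value if isinstance(l, BrPLabel) else str(l) for l in labels]
    counts = Counter(v for v in values if v in BRP_CATEGORIES)
    if not counts:
        return BrPLabel("mixed")
    modal, n_modal = counts.most_common(1)[0]
    if n_modal / len(values) >= uniform_frac:
        levels = [
            l.pause_level
            for l in labels
            if isinstance(l, BrPLabel) and l.value == modal and l.pause_level is not None
        ]
        if modal in ("BrP3", "BrP4"):
            level = float(np.mean(levels)) if levels else float("nan")
            return BrPLabel(modal, pause_level=level)
        return BrPLabel(modal)
    return BrPLabel("mixed")
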