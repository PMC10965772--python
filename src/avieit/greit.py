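"""Linear GREIT-style difference-image reconstruction.

A reconstruction matrix R (pixels x channels) is trained on the voltage
signatures of many small circular conductivity perturbations distributed over
the body cross-section, against desired images that place a compact blob at
each target position.  Applied to normalised voltage differences it yields
32x32 impedance-change images masked by the outer body contour.

Sign convention (single source of truth, asserted by simulator and analysis):
positive pixel values mean a conductivity *decrease* relative to the
reference frame, i.e. air filling during inspiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import shapely

from .forward import ForwardSolver, StimulationPattern, VoltageFrame

__all__ = ["ReconstructionModel", "ImageStream", "train_greit", "reconstruct"]


@dataclass
class ReconstructionModel:
    R: np.ndarray  # (n_pixels, n_channels)
    mask: np.ndarray  # (32, 32) bool
    shape: tuple
    training_meta: dict = field(default_factory=dict)


@dataclass
class ImageStream:
    """Per-frame impedance-change images (AU); out-of-mask pixels are 0."""

    frames: np.ndarray  # (F, 32, 32)
    fps: float
    mask: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _noise_figure(R: np.ndarray, y_ref: np.ndarray) -> float:
    """Ratio of image-domain noise gain to signal gain.

    Noise gain: RMS in-mask pixel response to unit-variance iid channel noise
    relative to unit RMS channel noise (= ||R||_F / sqrt(C)).  Signal gain:
    ||R y|| / ||y|| for the reference (central) target.
    """
    c = R.shape[1]
    g_noise = np.linalg.norm(R) / np.sqrt(c)
    g_signal = np.linalg.norm(R @ y_ref) / np.linalg.norm(y_ref)
    return g_noise / g_signal


def train_greit(
    phantom,
    pattern: StimulationPattern,
    n_targets: int = 1000,
    target_radius: float = 0.05,
    noise_figure: float = 0.5,
    seed: int = 0,
    current_a: float = 5e-3,
    blob_factor: float = 2.0,
    sigma_base: float = 1.0,
) -> ReconstructionModel:
    """Train the reconstruction matrix for one phantom/pattern.

    ``target_radius`` is a fraction of the pixel-grid side; desired images
    are blobs of ``blob_factor`` times the target radius.  The Tikhonov
    weight is calibrated by bisection so the model's image-domain noise
    amplification matches ``noise_figure``.  Channel-noise weighting is
    uniform (no per-channel covariance is published for the hardware).
    """
    if n_targets < 50:
        raise ValueError("n_targets < 50 would undertrain the model")
    grid = phantom.grid
    mask = grid.mask
    side = grid.pixel_size * grid.shape[0]
    r_t = target_radius * side
    r_blob = blob_factor * r_t

    solver = ForwardSolver(phantom, pattern, current_a)
    sigma0 = np.full(phantom.n_elements, float(sigma_base))
    v0 = solver.solve(sigma0)
    if np.any(v0 == 0):
        raise ZeroDivisionError("reference frame has a zero channel")
    jac = solver.jacobian(sigma0) / v0[:, None]  # normalised-difference Jacobian

    outer = phantom.contours.outer.polygon
    xmin, ymin = phantom.contours.outer.points.min(axis=0)
    xmax, ymax = phantom.contours.outer.points.max(axis=0)
    rng = np.random.default_rng(seed)
    # targets are sampled in right-left mirror pairs so the trained matrix
    # carries no spurious lateral bias on symmetric phantoms (the centre of
    # ventilation is exquisitely sensitive to such bias); mirrored partners
    # falling outside an asymmetric outer contour are skipped
    x_mid = 0.5 * (xmin + xmax)
    centres = []
    n_tries = 0
    while len(centres) < n_targets and n_tries < 200 * n_targets:
        pts = np.column_stack(
            [rng.uniform(xmin, xmax, n_targets), rng.uniform(ymin, ymax, n_targets)]
        )
        mirrored = np.column_stack([2 * x_mid - pts[:, 0], pts[:, 1]])
        both = np.stack([pts, mirrored], axis=1)  # (n, 2 points, 2)
        ok = shapely.contains_xy(outer, both[..., 0].ravel(), both[..., 1].ravel())
        pair_ok = ok.reshape(-1, 2).all(axis=1)
        centres.extend(both[pair_ok].reshape(-1, 2))
        n_tries += n_targets
    if len(centres) < n_targets:
        warnings.warn("some training targets fell outside the mask; skipped")
    centres = np.asarray(centres[:n_targets])

    cent = phantom.element_centroids()
    px, py = grid.pixel_centres()
    pxf, pyf = px.ravel(), py.ravel()
    in_mask = mask.ravel()

    Y = np.empty((pattern.n_channels, len(centres)))
    D = np.zeros((mask.size, len(centres)))
    amp = 0.1 * sigma_base  # linear regime; overall scale cancels in training
    for t, (cx, cy) in enumerate(centres):
        sel = (cent[:, 0] - cx) ** 2 + (cent[:, 1] - cy) ** 2 <= r_t**2
        if not sel.any():
            sel = np.zeros(len(cent), bool)
            sel[np.argmin((cent[:, 0] - cx) ** 2 + (cent[:, 1] - cy) ** 2)] = True
        dsig = np.zeros(phantom.n_elements)
        dsig[sel] = -amp  # conductivity decrease -> positive desired image
        Y[:, t] = jac @ dsig
        blob = ((pxf - cx) ** 2 + (pyf - cy) ** 2 <= r_blob**2) & in_mask
        D[blob, t] = 1.0

    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    DV = D @ Vt.T

    # central target for noise-figure calibration
    c_idx = int(np.argmin(np.sum((centres - centres.mean(axis=0)) ** 2, axis=1)))
    y_ref = Y[:, c_idx]

    def build(lam: float) -> np.ndarray:
        return (DV * (S / (S**2 + lam**2))) @ U.T

    lo, hi = -8.0, 4.0  # log10 lambda, relative to max singular value
    s0 = S[0]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        nf = _noise_figure(build(s0 * 10.0**mid), y_ref)
        if nf > noise_figure:
            lo = mid  # more regularisation needed
        else:
            hi = mid
    lam = s0 * 10.0 ** (0.5 * (lo + hi))
    R = build(lam)
    R[~in_mask] = 0.0
    return ReconstructionModel(
        R=R,
        mask=mask.copy(),
        shape=grid.shape,
        training_meta={
            "n_targets": int(len(centres)),
            "target_radius": float(target_radius),
            "blob_factor": float(blob_factor),
            "noise_figure": float(noise_figure),
            "achieved_nf": float(_noise_figure(R, y_ref)),
            "lambda": float(lam),
            "seed": int(seed),
            "current_a": float(current_a),
        },
    )


def reconstruct(model: ReconstructionModel, v_ref, frames, fps: float = 48.0) -> ImageStream:
    """Apply the trained model to a voltage stream.

    Per frame the image is ``R @ dv`` with the normalised difference
    ``dv = (v - v_ref) / v_ref`` (element-wise).  The reference frame should
    be an end-expiration frame so inspiration yields positive pixels.
    """
    v_ref = v_ref.v if isinstance(v_ref, VoltageFrame) else np.asarray(v_ref, float)
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        V = frames.astype(float)
    else:
        V = np.array(
            [f.v if isinstance(f, VoltageFrame) else np.asarray(f, float) for f in frames]
        )
    if V.shape[1] != model.R.shape[1] or v_ref.shape[0] != model.R.shape[1]:
        raise ValueError(
            f"channel mismatch: model expects {model.R.shape[1]}, got {V.shape[1]}"
        )
    zero = np.flatnonzero(v_ref == 0)
    if zero.size:
        raise ZeroDivisionError(f"reference frame has zero voltage on channel {zero[0]}")
    dv = (V - v_ref) / v_ref
    imgs = (model.R @ dv.T).T.reshape(-1, *model.shape)
    return ImageStream(frames=imgs, fps=fps, mask=model.mask.copy())
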