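"""Quasi-static 2-D FEM forward model for EIT.

Solves the conductivity equation div(sigma grad u) = 0 on the phantom mesh
with point current sources at the electrode nodes (gap model) and a zero-mean
potential constraint per injection.  Linear (P1) triangular elements; one
sparse LU factorisation is reused across all injections of a frame.

The 192 kHz carrier of the acquisition hardware is metadata only: difference
imaging of ventilation is modelled as real-valued quasi-static conduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "StimulationPattern",
    "make_pattern",
    "VoltageFrame",
    "VoltageRecording",
    "ForwardSolver",
    "solve_forward",
    "jacobian",
]


@dataclass
class StimulationPattern:
    """Rotating pair-drive stimulation with pair measurements.

    ``injections[k] = (source, sink)`` electrode indices; channel ``i`` is the
    differential measurement ``meas_plus[i] - meas_minus[i]`` taken during
    injection ``channel_injection[i]``.  Measurement pairs that include an
    injecting electrode are omitted (injecting electrodes never measure
    within their own injection).
    """

    n_electrodes: int
    skip: int
    injections: np.ndarray
    channel_injection: np.ndarray
    meas_plus: np.ndarray
    meas_minus: np.ndarray

    @property
    def n_channels(self) -> int:
        return len(self.meas_plus)


def make_pattern(n_electrodes: int, skip: int = 0) -> StimulationPattern:
    """Adjacent/skip rotating pattern: inject (i, i+1+skip), measure with the
    same offset over all electrode pairs not touching the injecting pair.

    With 32 electrodes and skip=0 this yields 32 x 29 = 928 channels.
    """
    n = n_electrodes
    if not (0 <= skip <= n - 2):
        raise ValueError(f"skip must be in [0, {n - 2}]")
    off = 1 + skip
    injections = np.array([(i, (i + off) % n) for i in range(n)])
    ch_inj, mp, mm = [], [], []
    for k, (a, b) in enumerate(injections):
        for j in range(n):
            p, m = j, (j + off) % n
            if p in (a, b) or m in (a, b):
                continue
            ch_inj.append(k)
            mp.append(p)
            mm.append(m)
    return StimulationPattern(
        n_electrodes=n,
        skip=skip,
        injections=injections,
        channel_injection=np.array(ch_inj),
        meas_plus=np.array(mp),
        meas_minus=np.array(mm),
    )


@dataclass
class VoltageFrame:
    v: np.ndarray
    frame_index: int = 0
    timestamp: float = 0.0


@dataclass
class VoltageRecording:
    """frames x channels boundary-voltage matrix plus acquisition metadata."""

    voltages: np.ndarray
    time: np.ndarray
    fps: float
    pattern: StimulationPattern
    current_a: float = 5e-3
    carrier_hz: float = 192_000.0
    ref_frame: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.voltages.shape[0]

    def frame(self, i: int) -> VoltageFrame:
        return VoltageFrame(self.voltages[i], i, float(self.time[i]))


class ForwardSolver:
    """Assembles and solves the FEM system for arbitrary conductivities.

    The element geometry factors (areas, basis gradients, the 3x3 unit-
    conductivity stiffness blocks and the global sparsity pattern) are
    precomputed once; per-frame work is a scaled assembly plus one sparse LU.
    """

    def __init__(self, phantom, pattern: StimulationPattern, current_a: float = 5e-3):
        if current_a <= 0:
            raise ValueError("current must be positive")
        self.phantom = phantom
        self.pattern = pattern
        self.current_a = float(current_a)
        nodes, elems = phantom.nodes, phantom.elements
        self.n_nodes = len(nodes)
        x = nodes[elems]  # (E, 3, 2)
        v1 = x[:, 1] - x[:, 0]
        v2 = x[:, 2] - x[:, 0]
        det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
        self.areas = 0.5 * np.abs(det)
        # gradients of the three P1 basis functions per element: (E, 2, 3)
        b = np.stack(
            [x[:, 1, 1] - x[:, 2, 1], x[:, 2, 1] - x[:, 0, 1], x[:, 0, 1] - x[:, 1, 1]],
            axis=1,
        )
        c = np.stack(
            [x[:, 2, 0] - x[:, 1, 0], x[:, 0, 0] - x[:, 2, 0], x[:, 1, 0] - x[:, 0, 0]],
            axis=1,
        )
        self.grads = np.stack([b, c], axis=1) / det[:, None, None]  # (E, 2, 3)
        gtg = np.einsum("eki,ekj->eij", self.grads, self.grads)
        self.k_unit = gtg * self.areas[:, None, None]  # (E, 3, 3)
        rows = np.repeat(elems, 3, axis=1).reshape(-1, 3, 3)
        cols = np.tile(elems[:, None, :], (1, 3, 1))
        # augmented system: zero-mean constraint via a Lagrange multiplier row
        aug = self.n_nodes
        ones_rows = np.concatenate(
            [np.full(self.n_nodes, aug), np.arange(self.n_nodes)]
        )
        ones_cols = np.concatenate(
            [np.arange(self.n_nodes), np.full(self.n_nodes, aug)]
        )
        self._rows = np.concatenate([rows.ravel(), ones_rows])
        self._cols = np.concatenate([cols.ravel(), ones_cols])
        self._ones_data = np.ones(2 * self.n_nodes)
        # unit-current RHS for every electrode as single source
        rhs = np.zeros((self.n_nodes + 1, pattern.n_electrodes))
        rhs[phantom.electrode_nodes, np.arange(pattern.n_electrodes)] = 1.0
        self._rhs = rhs
        # small systems go through a dense Cholesky of the grounded SPD
        # system instead of sparse LU of the augmented one: with the ground
        # node acting as current return, pair differences of the electrode
        # fields are identical in either gauge, and the dense path is much
        # faster per frame on meshes of a few hundred nodes
        self._dense = self.n_nodes <= 700
        if self._dense:
            elec = set(int(e) for e in phantom.electrode_nodes)
            self._ground = next(i for i in range(self.n_nodes) if i not in elec)
            flat = (self._rows[: 9 * len(elems)] * self.n_nodes
                    + self._cols[: 9 * len(elems)])
            self._flat_idx = flat.astype(np.int64)

    def _check_sigma(self, sigma: np.ndarray) -> np.ndarray:
        sigma = np.asarray(sigma, float)
        if sigma.shape != (self.phantom.n_elements,):
            raise ValueError("sigma must be per-element")
        if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
            raise ValueError("conductivity must be strictly positive and finite")
        return sigma

    def _factorise(self, sigma: np.ndarray):
        data = np.concatenate(
            [(self.k_unit * sigma[:, None, None]).ravel(), self._ones_data]
        )
        n = self.n_nodes + 1
        K = sp.coo_matrix((data, (self._rows, self._cols)), shape=(n, n)).tocsc()
        try:
            return spla.splu(K)
        except RuntimeError as exc:
            raise RuntimeError(f"singular FEM system: {exc}") from exc

    def electrode_potentials(self, sigma: np.ndarray) -> np.ndarray:
        """Nodal potentials for a unit current source at each electrode
        (zero-mean gauge); (n_nodes, n_electrodes)."""
        sigma = self._check_sigma(sigma)
        if self._dense:
            phi = self._dense_potentials(sigma)
        else:
            phi = self._factorise(sigma).solve(self._rhs)[: self.n_nodes]
        return phi - phi.mean(axis=0)

    def _dense_potentials(self, sigma: np.ndarray) -> np.ndarray:
        import scipy.linalg as sla

        n = self.n_nodes
        data = (self.k_unit * sigma[:, None, None]).ravel()
        K = np.bincount(self._flat_idx, weights=data, minlength=n * n).reshape(n, n)
        g = self._ground
        K[g, :] = 0.0
        K[:, g] = 0.0
        K[g, g] = 1.0
        rhs = self._rhs[:n]
        try:
            cho = sla.cho_factor(K, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"singular FEM system: {exc}") from exc
        return sla.cho_solve(cho, rhs, check_finite=False)

    def solve(self, sigma: np.ndarray) -> np.ndarray:
        """Per-channel differential voltages for one conductivity field."""
        phi = self.electrode_potentials(sigma)
        pat = self.pattern
        phi_e = phi[self.phantom.electrode_nodes]  # (n_elec sites, n_elec sources)
        u = self.current_a * (
            phi_e[:, pat.injections[:, 0]] - phi_e[:, pat.injections[:, 1]]
        )  # (n_elec, n_inj)
        return (
            u[pat.meas_plus, pat.channel_injection]
            - u[pat.meas_minus, pat.channel_injection]
        )

    def jacobian(self, sigma0: np.ndarray) -> np.ndarray:
        """Sensitivity dv/dsigma_e about ``sigma0`` via the adjoint-field
        product: J[ch, e] = -area_e * grad(u_drive) . grad(u_meas)|_e, with
        the measurement field driven by unit current."""
        sigma0 = self._check_sigma(sigma0)
        phi = self.electrode_potentials(sigma0)
        # per-element gradient of each single-electrode field: (E, 2, n_elec)
        g = np.einsum("ekj,ejn->ekn", self.grads, phi[self.phantom.elements])
        pat = self.pattern
        gd = (
            g[:, :, pat.injections[:, 0]] - g[:, :, pat.injections[:, 1]]
        ) * self.current_a
        gm = g[:, :, pat.meas_plus] - g[:, :, pat.meas_minus]
        gd_ch = gd[:, :, pat.channel_injection]
        dot = np.einsum("ekc,ekc->ec", gd_ch, gm)
        return -(self.areas[:, None] * dot).T  # (channels, elements)


def solve_forward(phantom, sigma, pattern: StimulationPattern,
                  current_a: float = 5e-3, frame_index: int = 0,
                  timestamp: float = 0.0) -> VoltageFrame:
    """One-shot forward solve returning a :class:`VoltageFrame`."""
    solver = ForwardSolver(phantom, pattern, current_a)
    return VoltageFrame(solver.solve(np.asarray(sigma, float)), frame_index, timestamp)


def jacobian(phantom, sigma0, pattern: StimulationPattern,
             current_a: float = 5e-3) -> np.ndarray:
    """Channels x elements sensitivity matrix about ``sigma0``."""
    solver = ForwardSolver(phantom, pattern, current_a)
    return solver.jacobian(np.asarray(sigma0, float))
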