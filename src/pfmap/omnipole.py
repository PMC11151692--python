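"""Bipolar and omnipolar electrogram derivation from a clique recording.

The omnipolar electrogram is orientation-independent: from the in-plane
electric-field loop E(t) = -grad(phi)(t), estimated by least squares over the
clique's unipolar potentials, the omnipolar voltage is the maximum over
projection orientations of the peak-to-peak of pitch * (E . d_theta).  A
common-mode (far-field) potential contributes no spatial gradient, so it is
rejected exactly; a local wavefront crossing the clique produces a loop with
a dominant axis along the propagation direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .synthgen import CliqueRecording

__all__ = [
    "EFieldLoop",
    "bipolar_egm",
    "efield_loop",
    "omnipolar_voltage",
    "omnipolar_egm",
    "omnipolar_orientation",
]

#: Orientation grid over [0, pi): 1 degree steps, ties broken toward smaller theta.
_THETA = np.deg2rad(np.arange(0.0, 180.0, 1.0))


@dataclass(frozen=True)
class EFieldLoop:
    """In-plane electric-field components (mV/mm) over time."""

    ex_t: np.ndarray
    ey_t: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.ex_t, dtype=float)
        ey = np.asarray(self.ey_t, dtype=float)
        if ex.shape != ey.shape or ex.ndim != 1:
            raise ValueError("ex_t and ey_t must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(ex)) and np.all(np.isfinite(ey))):
            raise ValueError("E-field components must be finite")
        object.__setattr__(self, "ex_t", ex)
        object.__setattr__(self, "ey_t", ey)

    def __len__(self) -> int:
        return len(self.ex_t)


def bipolar_egm(rec: CliqueRecording, pair: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Sample-wise difference u_a - u_b between two clique electrodes (mV)."""
    a, b = pair
    n = rec.n_electrodes
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"electrode indices {pair} out of range for {n} electrodes")
    if a == b:
        raise ValueError("bipole requires two distinct electrodes")
    return rec.signals[a] - rec.signals[b]


def _triangle_gradient(rec: CliqueRecording, idx: tuple[int, ...]) -> np.ndarray | None:
    design = np.column_stack([np.ones(3), rec.coords[list(idx)]])
    if abs(np.linalg.det(design)) < 1e-12:
        return None  # collinear sub-clique
    return np.linalg.inv(design)[1:] @ rec.signals[list(idx)]  # (2, n_samples)


def efield_loop(rec: CliqueRecording) -> EFieldLoop:
    """In-plane E field from the clique's unipolar potentials.

    At each sample the potential is modelled as locally linear,
    phi(r) ~ c + g . r, fitted by least squares over a 3-electrode sub-clique
    (for which the fit interpolates exactly); E = -g.  Among all non-collinear
    sub-cliques the one whose projected loop attains the largest peak-to-peak
    over orientations is returned.

    Fitting per sub-clique rather than averaging the gradient over the whole
    clique matters when the local wavelength of a propagating deflection is
    comparable to the electrode pitch: the clique-mean gradient averages
    phase-shifted bipole pairs against each other, which can leave the
    omnipolar voltage below individual bipoles.  With the maximal sub-clique,
    every pitch-normalised clique bipole is one orientation's projection of
    the returned loop, so omnipolar dominance holds by construction.

    Requires >= 3 non-collinear electrodes (raises on degenerate geometry).
    """
    if rec.n_electrodes < 3:
        raise ValueError("E-field fit needs >= 3 electrodes")
    best: np.ndarray | None = None
    best_ptp = -1.0
    for idx in combinations(range(rec.n_electrodes), 3):
        grad = _triangle_gradient(rec, idx)
        if grad is None:
            continue
        proj = np.cos(_THETA)[:, None] * grad[0][None, :] + np.sin(_THETA)[:, None] * grad[1][None, :]
        ptp = float((proj.max(axis=1) - proj.min(axis=1)).max())
        if ptp > best_ptp:
            best_ptp, best = ptp, grad
    if best is None:
        raise ValueError("degenerate (collinear) electrode geometry")
    return EFieldLoop(ex_t=-best[0], ey_t=-best[1])


def _projections(loop: EFieldLoop, pitch: float) -> np.ndarray:
    """Projected bipole-like signals for every orientation: (n_theta, n_samples)."""
    return pitch * (
        np.cos(_THETA)[:, None] * loop.ex_t[None, :]
        + np.sin(_THETA)[:, None] * loop.ey_t[None, :]
    )


def omnipolar_orientation(loop: EFieldLoop, pitch: float = 2.0) -> float:
    """Orientation theta (radians, in [0, pi)) maximising projected peak-to-peak."""
    proj = _projections(loop, pitch)
    ptp = proj.max(axis=1) - proj.min(axis=1)
    return float(_THETA[int(np.argmax(ptp))])  # argmax -> smallest theta on ties


def omnipolar_voltage(loop: EFieldLoop, pitch: float = 2.0) -> float:
    """Omnipolar peak-to-peak voltage in mV.

    Maximum over orientations (1 degree grid on [0, pi)) of the peak-to-peak
    of ``pitch * (ex cos(theta) + ey sin(theta))``.  Scaling by the physical
    electrode pitch keeps the result in mV, commensurate with bipolar
    voltage cutoffs.
    """
    proj = _projections(loop, pitch)
    return float((proj.max(axis=1) - proj.min(axis=1)).max())


def omnipolar_egm(loop: EFieldLoop, pitch: float = 2.0) -> np.ndarray:
    """Omnipolar electrogram (mV): the loop projected onto the orientation of
    maximal peak-to-peak (the omnipolar-voltage orientation).  This is the
    signal fed to PF annotation for the PF_omni modality."""
    theta = omnipolar_orientation(loop, pitch)
    return pitch * (np.cos(theta) * loop.ex_t + np.sin(theta) * loop.ey_t)
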