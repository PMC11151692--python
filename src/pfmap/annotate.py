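"""Per-site annotation: derive the four modality scalars from one recording.

Bipolar convention: a single bipole is direction-dependent — a wavefront
propagating perpendicular to the bipole axis cancels in the subtraction — so
grid-catheter mapping annotates the best of the orthogonal bipole pairs of
the clique.  V_bi is the largest peak-to-peak over the side bipoles; PF_bi is
the larger PF of the maximal-voltage bipole of each axis family.  The
omnipolar modality projects the E-field loop onto its maximal-voltage
orientation before PF annotation and is direction-independent by
construction.
"""

from __future__ import annotations

import numpy as np

from .classify import SiteAnnotation
from .omnipole import EFieldLoop, bipolar_egm, efield_loop, omnipolar_egm, omnipolar_voltage
from .pf_core import FrequencyGrid, ThresholdPolicy, _window_slice, annotate_pf, annotate_voltage
from .synthgen import CliqueRecording

__all__ = ["adjacent_pairs", "axis_families", "annotate_site"]


def adjacent_pairs(coords: np.ndarray) -> list[tuple[int, int]]:
    """Electrode pairs at the minimal inter-electrode distance (side bipoles)."""
    c = np.asarray(coords, dtype=float)
    n = len(c)
    dists = {
        (a, b): float(np.linalg.norm(c[a] - c[b]))
        for a in range(n)
        for b in range(a + 1, n)
    }
    dmin = min(dists.values())
    return [p for p, d in dists.items() if d <= dmin * (1 + 1e-9)]


def axis_families(coords: np.ndarray) -> list[list[tuple[int, int]]]:
    """Side bipoles grouped by axis orientation (sign-insensitive)."""
    c = np.asarray(coords, dtype=float)
    groups: dict[tuple[float, float], list[tuple[int, int]]] = {}
    for a, b in adjacent_pairs(c):
        d = c[b] - c[a]
        d = d / np.linalg.norm(d)
        if d[0] < 0 or (d[0] == 0 and d[1] < 0):
            d = -d
        groups.setdefault((round(d[0], 6), round(d[1], 6)), []).append((a, b))
    return list(groups.values())


def annotate_site(
    rec: CliqueRecording,
    grid: FrequencyGrid | None = None,
    policy: ThresholdPolicy | None = None,
    window: tuple[float, float] | None = None,
    pitch: float | None = None,
    wavelet_bandwidth: float = 1.5,
) -> SiteAnnotation:
    """Compute V_bi, V_omni (mV) and PF_bi, PF_omni (Hz) for one site.

    ``pitch`` defaults to the minimal inter-electrode distance of the clique.
    ``window`` is a half-open [t_start, t_end) interval in ms (full record by
    default — the simulator produces single-activation records).
    """
    if pitch is None:
        c = rec.coords
        pitch = min(
            float(np.linalg.norm(c[a] - c[b]))
            for a in range(len(c))
            for b in range(a + 1, len(c))
        )
    v_bi = 0.0
    pf_bi = 0.0
    for family in axis_families(rec.coords):
        bipoles = [bipolar_egm(rec, p) for p in family]
        ptps = [annotate_voltage(b, rec.fs, window) for b in bipoles]
        best = int(np.argmax(ptps))
        v_bi = max(v_bi, *ptps)
        pf_bi = max(
            pf_bi,
            annotate_pf(bipoles[best], rec.fs, grid, policy, window, wavelet_bandwidth),
        )

    loop = efield_loop(rec)
    if window is None:
        v_omni = omnipolar_voltage(loop, pitch)
    else:
        # the omnipolar voltage is orientation-maximal within the window
        sl = _window_slice(len(loop), rec.fs, window)
        v_omni = omnipolar_voltage(EFieldLoop(loop.ex_t[sl], loop.ey_t[sl]), pitch)
    omni = omnipolar_egm(loop, pitch)
    pf_omni = annotate_pf(omni, rec.fs, grid, policy, window, wavelet_bandwidth)
    return SiteAnnotation(
        site_id=rec.site_id, v_bi=v_bi, v_omni=v_omni, pf_bi=pf_bi, pf_omni=pf_omni
    )
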