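"""Threshold criteria for calling gap vs block per site, and segment roll-up.

A mapping site is called a conduction gap when its annotation value meets or
exceeds the criterion cutoff, for every modality: residual high voltage on
the ablation line indicates surviving tissue just as a high peak frequency
does, so both directions read ">= cutoff => gap".  Ties at the cutoff are
classified as gap (the safer clinical direction).  Segment calls are
existential: a pulmonary-vein line segment is a gap segment if any of its
sites is called gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import BLOCK, GAP

__all__ = [
    "MODALITIES",
    "CLINICAL_CUTOFFS",
    "SiteAnnotation",
    "CriterionConfig",
    "classify_site",
    "segment_call",
    "default_criteria",
]

MODALITIES = ("v_bi", "v_omni", "pf_bi", "pf_omni")

#: Gap cutoffs reported from clinical ROC/Youden analysis: bipolar and
#: omnipolar peak-to-peak voltage (mV), bipolar and omnipolar peak frequency (Hz).
CLINICAL_CUTOFFS: dict[str, float] = {
    "v_bi": 0.20,
    "v_omni": 0.32,
    "pf_bi": 190.25,
    "pf_omni": 222.82,
}


@dataclass(frozen=True)
class SiteAnnotation:
    """The four per-site scalars: voltages in mV, peak frequencies in Hz."""

    site_id: int
    v_bi: float
    v_omni: float
    pf_bi: float
    pf_omni: float

    def __post_init__(self) -> None:
        for name in MODALITIES:
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")

    def value(self, modality: str) -> float:
        if modality not in MODALITIES:
            raise KeyError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
        return float(getattr(self, modality))


@dataclass(frozen=True)
class CriterionConfig:
    """One classification criterion: ``value >= cutoff => gap``."""

    modality: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if not (np.isfinite(self.cutoff) and self.cutoff > 0):
            raise ValueError("cutoff must be positive and finite")


def default_criteria() -> list[CriterionConfig]:
    """The four clinical criteria at their reported cutoffs."""
    return [CriterionConfig(m, CLINICAL_CUTOFFS[m]) for m in MODALITIES]


def classify_site(ann: SiteAnnotation, crit: CriterionConfig) -> str:
    """Call one site gap or block under one criterion (tie at cutoff -> gap)."""
    return GAP if ann.value(crit.modality) >= crit.cutoff else BLOCK


def segment_call(site_calls: list[str], segment_id: int | None = None) -> str:
    """Existential segment aggregation: gap iff any member site is gap."""
    if not site_calls:
        raise ValueError(f"segment {segment_id!r} has no sites")
    bad = set(site_calls) - {GAP, BLOCK}
    if bad:
        raise ValueError(f"unknown site calls {sorted(bad)}")
    return GAP if GAP in site_calls else BLOCK
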