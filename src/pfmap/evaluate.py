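"""Two-phase diagnostic evaluation of gap-vs-block criteria.

Phase 1: per-modality ROC analysis of annotation scores against site truth,
with AUC (trapezoidal, equal to the pair-concordance statistic) and the
Youden-optimal cutoff (J = SE + SP - 1).

Phase 2: contingency-table accuracy (sensitivity, specificity, PPV, NPV) of
fixed-cutoff criteria against ground truth at the segment level.

This module also carries the integer count-reconstruction oracle: given
published (SE, SP, PPV, NPV) percentage rows that share one negative-class
denominator, it enumerates all integer contingency tables consistent with
the printed one-decimal values.

Percentages are held as exact floats internally; one-decimal rounding
(half away from zero) happens only at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthgen import GAP

__all__ = [
    "ContingencyTable",
    "RocResult",
    "UndefinedMetricError",
    "NoConsistentCountsError",
    "round_report",
    "contingency_metrics",
    "reconstruct_counts",
    "roc_analysis",
    "youden_cutoff",
    "run_phase1",
    "run_phase2",
]

METRIC_NAMES = ("se", "sp", "ppv", "npv")


class UndefinedMetricError(ZeroDivisionError):
    """A requested contingency metric has a zero denominator."""


class NoConsistentCountsError(ValueError):
    """No integer contingency table reproduces the printed percentages."""


def round_report(x: float, decimals: int = 1) -> float:
    """Round half away from zero — the convention of printed clinical tables
    (python's round() rounds half to even and cannot reproduce them)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def n_gap(self) -> int:
        return self.tp + self.fn

    @property
    def n_block(self) -> int:
        return self.fp + self.tn


def contingency_metrics(
    t: ContingencyTable, metrics: tuple[str, ...] = METRIC_NAMES
) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV in percent (exact, unrounded).

    Raises UndefinedMetricError when a requested metric's denominator is zero
    (an undefined proportion is an error, never reported as 0).
    """
    denoms = {
        "se": (t.tp, t.tp + t.fn),
        "sp": (t.tn, t.tn + t.fp),
        "ppv": (t.tp, t.tp + t.fp),
        "npv": (t.tn, t.tn + t.fn),
    }
    out: dict[str, float] = {}
    for m in metrics:
        if m not in denoms:
            raise KeyError(f"unknown metric {m!r}")
        num, den = denoms[m]
        if den == 0:
            raise UndefinedMetricError(f"metric {m!r} undefined: zero denominator")
        out[m] = 100.0 * num / den
    return out


@dataclass(frozen=True)
class CountSolution:
    """One consistent reconstruction: shared n_block and per-row tables."""

    n_block: int
    tables: tuple[ContingencyTable, ...]


def _rounds_to(values: np.ndarray, target: float) -> np.ndarray:
    scaled = np.floor(np.abs(values) * 10.0 + 0.5) / 10.0
    return np.abs(scaled - target) < 1e-9


def reconstruct_counts(
    metric_rows: list[tuple[float, float, float, float]],
    n_gap: int,
    n_block_max: int = 1000,
) -> list[CountSolution]:
    """Recover integer contingency tables from printed percentage rows.

    Each row is (SE, SP, PPV, NPV) in percent, printed at one decimal (half
    away from zero).  All rows share the positive-class size ``n_gap`` and an
    unknown common negative-class size; the search enumerates
    tp in [0, n_gap], n_block in [1, n_block_max], fp in [0, n_block] and
    keeps every n_block for which all rows admit at least one (tp, fp) whose
    four metrics simultaneously round to the printed values.

    Returns the consistent solutions in increasing n_block order and asserts
    that the minimal-n_block solution is unique (exactly one (tp, fp) per
    row); raises NoConsistentCountsError when nothing fits.
    """
    if n_gap < 1:
        raise ValueError("n_gap must be >= 1")
    rows = [tuple(float(v) for v in r) for r in metric_rows]
    for r in rows:
        if len(r) != 4 or not all(0.0 <= v <= 100.0 for v in r):
            raise ValueError(f"each row needs four percentages in [0, 100], got {r}")

    tps = np.arange(n_gap + 1)
    # tp candidates per row from SE alone (sharp filter; SE = 100 tp / n_gap)
    tp_cands = [tps[_rounds_to(100.0 * tps / n_gap, se)] for (se, _, _, _) in rows]
    if any(len(c) == 0 for c in tp_cands):
        raise NoConsistentCountsError("no tp reproduces a printed sensitivity")

    solutions: list[CountSolution] = []
    for n_block in range(1, n_block_max + 1):
        fp = np.arange(n_block + 1)
        tn = n_block - fp
        per_row: list[list[ContingencyTable]] = []
        for (se, sp, ppv, npv), cands in zip(rows, tp_cands):
            sp_ok = _rounds_to(100.0 * tn / n_block, sp)
            row_hits: list[ContingencyTable] = []
            for tp in cands:
                fn = n_gap - int(tp)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ppv_vals = 100.0 * tp / (tp + fp)
                    npv_vals = 100.0 * tn / (tn + fn)
                ok = sp_ok.copy()
                ok &= np.where(tp + fp > 0, _rounds_to(ppv_vals, ppv), False)
                ok &= np.where(tn + fn > 0, _rounds_to(npv_vals, npv), False)
                row_hits.extend(
                    ContingencyTable(tp=int(tp), fp=int(f), fn=fn, tn=int(n_block - f))
                    for f in fp[ok]
                )
            if not row_hits:
                break
            per_row.append(row_hits)
        else:
            if all(len(h) == 1 for h in per_row):
                solutions.append(
                    CountSolution(n_block=n_block, tables=tuple(h[0] for h in per_row))
                )
            elif not solutions:
                # ambiguous candidate before any unique one: minimal solution
                # would not be unique
                raise NoConsistentCountsError(
                    f"minimal consistent n_block={n_block} admits multiple tables"
                )
    if not solutions:
        raise NoConsistentCountsError(
            f"no integer tables reproduce the printed rows for n_gap={n_gap}, "
            f"n_block <= {n_block_max}"
        )
    return solutions


@dataclass(frozen=True)
class RocResult:
    """Threshold sweep for a '>= threshold => positive' criterion.

    thresholds ascend; se_curve/sp_curve are aligned fractions in [0, 1];
    youden_cutoff follows the midpoint convention (see youden_cutoff).
    """

    thresholds: np.ndarray
    se_curve: np.ndarray
    sp_curve: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    youden_threshold: float


def _sweep(scores: np.ndarray, is_gap: np.ndarray):
    uniq = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    # se(t) = P(score >= t | gap), sp(t) = P(score < t | block)
    gap_sorted = np.sort(scores[is_gap])
    block_sorted = np.sort(scores[~is_gap])
    se = 1.0 - np.searchsorted(gap_sorted, thresholds, side="left") / gap_sorted.size
    sp = np.searchsorted(block_sorted, thresholds, side="left") / block_sorted.size
    return thresholds, se, sp


def roc_analysis(scores, labels) -> RocResult:
    """ROC curve of annotation scores against gap/block truth.

    ``labels`` may be the strings "gap"/"block" or booleans (True = gap).
    Thresholds are the unique observed scores plus -inf/+inf sentinels; AUC is
    the trapezoidal area over (1-SP, SE), which equals the Mann-Whitney
    pair-concordance probability (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    is_gap = lab == GAP if lab.dtype.kind in "UOS" else lab.astype(bool)
    if s.shape != is_gap.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if is_gap.all() or (~is_gap).all():
        raise ValueError("ROC analysis needs both classes present")

    thresholds, se, sp = _sweep(s, is_gap)
    fpr = 1.0 - sp
    # traverse the curve with ascending (fpr, se): vertical risers contribute
    # no area and tied-score diagonals get the half-credit of the U statistic
    order = np.lexsort((se, fpr))
    auc = float(np.trapezoid(se[order], fpr[order]))
    res = RocResult(
        thresholds=thresholds,
        se_curve=se,
        sp_curve=sp,
        auc=auc,
        youden_cutoff=np.nan,
        youden_j=np.nan,
        youden_threshold=np.nan,
    )
    cutoff, j, thr = _youden(res)
    return RocResult(
        thresholds=thresholds,
        se_curve=se,
        sp_curve=sp,
        auc=auc,
        youden_cutoff=cutoff,
        youden_j=j,
        youden_threshold=thr,
    )


def _youden(roc: RocResult, interpolate: bool = True) -> tuple[float, float, float]:
    j = roc.se_curve + roc.sp_curve - 1.0
    jmax = j.max()
    ties = np.flatnonzero(j >= jmax - 1e-12)
    # ties broken toward higher specificity; sp rises with threshold, so the
    # qualifying tie with the largest threshold wins
    best = ties[np.argmax(roc.sp_curve[ties])]
    thr = float(roc.thresholds[best])
    cutoff = thr
    if interpolate and np.isfinite(thr):
        lower = roc.thresholds[(roc.thresholds < thr) & np.isfinite(roc.thresholds)]
        if lower.size:
            cutoff = (thr + float(lower[-1])) / 2.0
    return cutoff, float(jmax), thr


def youden_cutoff(roc: RocResult, interpolate: bool = True) -> float:
    """Youden-optimal cutoff: the threshold maximising J = SE + SP - 1.

    Ties go to the threshold with higher specificity.  With
    ``interpolate=True`` (default) the reported cutoff is the midpoint
    between the optimal threshold and the next lower unique score — the
    value printed by clinical ROC software; ``interpolate=False`` returns
    the raw observed threshold.
    """
    return _youden(roc, interpolate=interpolate)[0]


def run_phase1(annotations, truths) -> dict[str, RocResult]:
    """Per-modality ROC analysis of a cohort.

    ``annotations``: list of SiteAnnotation; ``truths``: aligned gap/block
    labels (strings or SiteLabel.truth values).  Returns one RocResult per
    modality ("v_bi", "v_omni", "pf_bi", "pf_omni").
    """
    from .classify import MODALITIES

    out: dict[str, RocResult] = {}
    for m in MODALITIES:
        scores = [a.value(m) for a in annotations]
        out[m] = roc_analysis(scores, truths)
    return out


def phase1_summary(results: dict[str, RocResult]) -> "pd.DataFrame":
    """Four-row phase-1 table: AUC, Youden cutoff, and SE/SP (%) at the cutoff."""
    import pandas as pd

    rows = []
    for m, r in results.items():
        at = np.searchsorted(r.thresholds, r.youden_threshold)
        rows.append(
            {
                "modality": m,
                "auc": r.auc,
                "cutoff": r.youden_cutoff,
                "se_pct": 100.0 * r.se_curve[at],
                "sp_pct": 100.0 * r.sp_curve[at],
            }
        )
    return pd.DataFrame(rows)


def run_phase2(
    calls_by_criterion: dict[str, dict[int, str]], truth_by_segment: dict[int, str]
) -> dict[str, tuple[ContingencyTable, dict[str, float]]]:
    """Contingency accuracy of per-segment calls against segment truth.

    ``calls_by_criterion``: criterion name -> {segment_id: "gap"/"block"};
    ``truth_by_segment``: {segment_id: "gap"/"block"}.  Every criterion must
    cover exactly the truth's segment universe.  Returns, per criterion, the
    ContingencyTable and its exact (unrounded) SE/SP/PPV/NPV percentages;
    metrics whose denominator is zero (e.g. PPV under all-block calls) are
    omitted from the dict rather than reported as 0.
    """
    universe = set(truth_by_segment)
    out: dict[str, tuple[ContingencyTable, dict[str, float]]] = {}
    for crit, calls in calls_by_criterion.items():
        if set(calls) != universe:
            raise ValueError(f"criterion {crit!r}: segment sets differ from truth")
        tp = fp = fn = tn = 0
        for seg, truth in truth_by_segment.items():
            called_gap = calls[seg] == GAP
            if truth == GAP:
                tp, fn = tp + called_gap, fn + (not called_gap)
            else:
                fp, tn = fp + called_gap, tn + (not called_gap)
        table = ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        metrics: dict[str, float] = {}
        for m in METRIC_NAMES:
            try:
                metrics[m] = contingency_metrics(table, (m,))[m]
            except UndefinedMetricError:
                continue
        out[crit] = (table, metrics)
    return out
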