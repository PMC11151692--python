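"""File formats, run configuration, and the end-to-end pipeline.

Interchange is plain CSV with a JSON sidecar: one ``site_NNNN.csv`` per site
(columns ``time_ms, u1..u4``) plus ``cohort.json`` carrying coordinates,
sampling rate, labels, the full config echo and its hash.  Floats are written
with shortest round-trip repr, so a write/read cycle is bit-exact.  Every
output file carries the config hash and seed, and a rerun at a fixed seed
reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .annotate import annotate_site
from .classify import CriterionConfig, SiteAnnotation, classify_site, default_criteria, segment_call
from .evaluate import contingency_metrics, phase1_summary, round_report, run_phase1, run_phase2
from .pf_core import FrequencyGrid, ThresholdPolicy
from .synthgen import GAP, CliqueRecording, SiteLabel, SynthConfig, simulate_cohort

__all__ = [
    "RunConfig",
    "CohortFormatError",
    "write_cohort",
    "read_cohort",
    "write_annotations",
    "read_annotations",
    "run_pipeline",
]


class CohortFormatError(ValueError):
    """Malformed or inconsistent cohort/annotation files."""


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthSettings(_Forbid):
    fs: float = 2000.0
    duration_ms: float = 500.0
    nf_freq_range: tuple[float, float] = (180.0, 400.0)
    ff_freq_range: tuple[float, float] = (40.0, 120.0)
    nf_amp_range: tuple[float, float] = (0.03, 0.5)
    ff_amp_range: tuple[float, float] = (0.1, 1.5)
    nf_width_ms: float = 3.0
    ff_width_ms: float = 15.0
    noise_sd: float = 0.01
    ff_jitter: float = 0.02
    velocity_mm_ms: float = 0.5
    pitch_mm: float = 2.0
    gap_prevalence: float = 0.5
    n_sites: int = 192


class GridSettings(_Forbid):
    f_min: float = 30.0
    f_max: float = 500.0
    n: int = 64


class PolicySettings(_Forbid):
    rel_frac: float = 0.1
    #: pipeline default floor (mV) at 2x the unipolar noise SD: above the
    #: record-maximum of noise-only scalogram ridges on both derived-signal
    #: paths, so broadband noise never qualifies as a component
    abs_floor: float = 0.02


class CriterionSettings(_Forbid):
    modality: str
    cutoff: float


class RunConfig(_Forbid):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    seed: int = 0
    synth: SynthSettings = Field(default_factory=SynthSettings)
    grid: GridSettings = Field(default_factory=GridSettings)
    policy: PolicySettings = Field(default_factory=PolicySettings)
    criteria: list[CriterionSettings] = Field(
        default_factory=lambda: [
            CriterionSettings(modality=m, cutoff=c)
            for m, c in (("v_bi", 0.20), ("v_omni", 0.32), ("pf_bi", 190.25), ("pf_omni", 222.82))
        ]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def synth_config(self) -> SynthConfig:
        return SynthConfig(seed=self.seed, **self.synth.model_dump())

    def frequency_grid(self) -> FrequencyGrid:
        return FrequencyGrid.log_spaced(self.grid.f_min, self.grid.f_max, self.grid.n)

    def threshold_policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(self.policy.rel_frac, self.policy.abs_floor)

    def criterion_configs(self) -> list[CriterionConfig]:
        return [CriterionConfig(c.modality, c.cutoff) for c in self.criteria]

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_line(config_hash: str, seed: int) -> str:
    return f"# pfmap config_hash={config_hash} seed={seed}\n"


def write_cohort(
    sites: list[tuple[CliqueRecording, SiteLabel]],
    outdir: str | Path,
    config: SynthConfig | None = None,
    config_hash: str = "",
    seed: int | None = None,
) -> Path:
    """Write one CSV per site plus a ``cohort.json`` sidecar; returns the dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not sites:
        raise ValueError("cohort is empty")
    fs = sites[0][0].fs
    seed = seed if seed is not None else (config.seed if config else 0)
    for rec, _ in sites:
        df = pd.DataFrame({"time_ms": rec.times_ms})
        for e in range(rec.n_electrodes):
            df[f"u{e + 1}"] = rec.signals[e]
        path = outdir / f"site_{rec.site_id:04d}.csv"
        with open(path, "w") as fh:
            fh.write(_provenance_line(config_hash, seed))
            df.to_csv(fh, index=False, float_format="%.17g")
    sidecar = {
        "fs": fs,
        "coords_mm": np.asarray(sites[0][0].coords).tolist(),
        "seed": seed,
        "config_hash": config_hash,
        "config": dataclasses.asdict(config) if config else None,
        "labels": [dataclasses.asdict(lab) for _, lab in sites],
    }
    (outdir / "cohort.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return outdir


def read_cohort(indir: str | Path) -> tuple[list[tuple[CliqueRecording, SiteLabel]], dict]:
    """Read a cohort directory back; raises CohortFormatError on malformed or
    internally inconsistent files (e.g. sidecar fs vs CSV time axis)."""
    indir = Path(indir)
    sidecar_path = indir / "cohort.json"
    if not sidecar_path.exists():
        raise CohortFormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    fs = float(sidecar["fs"])
    coords = np.asarray(sidecar["coords_mm"], dtype=float)
    sites = []
    for lab_d in sidecar["labels"]:
        lab = SiteLabel(**lab_d)
        path = indir / f"site_{lab.site_id:04d}.csv"
        if not path.exists():
            raise CohortFormatError(f"missing channel file {path}")
        try:
            df = pd.read_csv(path, comment="#", float_precision="round_trip")
        except Exception as exc:  # pandas names the offending line
            raise CohortFormatError(f"{path}: {exc}") from exc
        expected = ["time_ms"] + [f"u{e + 1}" for e in range(len(coords))]
        if list(df.columns) != expected:
            raise CohortFormatError(
                f"{path}: malformed header {list(df.columns)}, expected {expected}"
            )
        if df.isna().any().any():
            line = int(df.isna().any(axis=1).idxmax()) + 3  # provenance + header
            raise CohortFormatError(f"{path}: missing values at line {line}")
        if len(df) > 1:
            dt = float(df["time_ms"].iloc[1] - df["time_ms"].iloc[0])
            if abs(dt - 1000.0 / fs) > 1e-9:
                raise CohortFormatError(
                    f"{path}: CSV time step {dt} ms inconsistent with sidecar fs={fs} Hz"
                )
        sig = df[expected[1:]].to_numpy().T
        sites.append(
            (CliqueRecording(signals=sig, coords=coords, fs=fs, site_id=lab.site_id), lab)
        )
    return sites, sidecar


def write_annotations(
    annotations: list[SiteAnnotation],
    path: str | Path,
    config_hash: str = "",
    seed: int = 0,
) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"site_id": a.site_id, "v_bi": a.v_bi, "v_omni": a.v_omni,
             "pf_bi": a.pf_bi, "pf_omni": a.pf_omni}
            for a in annotations
        ]
    )
    with open(path, "w") as fh:
        fh.write(_provenance_line(config_hash, seed))
        df.to_csv(fh, index=False)
    return path


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise CohortFormatError(f"{path}: {exc}") from exc
    expected = ["site_id", "v_bi", "v_omni", "pf_bi", "pf_omni"]
    if list(df.columns) != expected:
        raise CohortFormatError(f"{path}: malformed header {list(df.columns)}")
    return [
        SiteAnnotation(site_id=int(r.site_id), v_bi=r.v_bi, v_omni=r.v_omni,
                       pf_bi=r.pf_bi, pf_omni=r.pf_omni)
        for r in df.itertuples()
    ]


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """simulate -> annotate -> classify -> evaluate, all artifacts on disk.

    Deterministic: rerunning with the same config and seed yields
    byte-identical files.  Any stage failure aborts with a stage-tagged
    message.  Returns the paths of the written artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    chash = cfg.hash()

    def _stage(name: str):
        log_lines.append(f"[{name}]")

    try:
        _stage("validate")
        synth_cfg = cfg.synth_config()
        if synth_cfg.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        grid = cfg.frequency_grid()
        policy = cfg.threshold_policy()
        criteria = cfg.criterion_configs()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"[validate] {exc}") from exc

    try:
        _stage("simulate")
        sites = simulate_cohort(synth_cfg)
        log_lines.append(f"sites={len(sites)}")
        cohort_dir = write_cohort(sites, outdir / "cohort", synth_cfg, chash, cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    try:
        _stage("annotate")
        annotations = [annotate_site(rec, grid, policy) for rec, _ in sites]
        ann_path = write_annotations(annotations, outdir / "annotations.csv", chash, cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"[annotate] {exc}") from exc

    try:
        _stage("classify")
        labels = [lab for _, lab in sites]
        # phase-2 unit: the patient-segment (16 PV-line segments per patient,
        # patients tiled over site ids) — the universe whose gap/block split
        # mirrors clinical per-segment denominators
        def _unit(lab: SiteLabel) -> int:
            return (lab.site_id // 16) * 16 + lab.segment_id

        call_rows = []
        seg_calls: dict[str, dict[int, str]] = {}
        for crit in criteria:
            per_seg: dict[int, list[str]] = {}
            for ann, lab in zip(annotations, labels):
                call = classify_site(ann, crit)
                call_rows.append(
                    {"site_id": ann.site_id, "patient_id": lab.site_id // 16,
                     "segment_id": lab.segment_id,
                     "criterion": crit.modality, "call": call}
                )
                per_seg.setdefault(_unit(lab), []).append(call)
            seg_calls[crit.modality] = {s: segment_call(c, s) for s, c in per_seg.items()}
        calls_path = outdir / "calls.csv"
        with open(calls_path, "w") as fh:
            fh.write(_provenance_line(chash, cfg.seed))
            pd.DataFrame(call_rows).to_csv(fh, index=False)
        log_lines.append(f"criteria={len(criteria)} segments={len(next(iter(seg_calls.values())))}")
    except Exception as exc:
        raise RuntimeError(f"[classify] {exc}") from exc

    try:
        _stage("evaluate")
        truths = [lab.truth for lab in labels]
        phase1 = run_phase1(annotations, truths)
        seg_truth: dict[int, str] = {}
        for lab in labels:
            unit = (lab.site_id // 16) * 16 + lab.segment_id
            if lab.truth == GAP:
                seg_truth[unit] = GAP
            else:
                seg_truth.setdefault(unit, lab.truth)
        phase2 = run_phase2(seg_calls, seg_truth)
        metrics = {
            "config_hash": chash,
            "seed": cfg.seed,
            "phase1": {
                m: {"auc": r.auc, "youden_cutoff": r.youden_cutoff, "youden_j": r.youden_j}
                for m, r in phase1.items()
            },
            "phase2": {
                crit: {
                    "tp": tab.tp, "fp": tab.fp, "fn": tab.fn, "tn": tab.tn,
                    **{k: round_report(v) for k, v in vals.items()},
                }
                for crit, (tab, vals) in phase2.items()
            },
        }
        metrics_path = outdir / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=1, sort_keys=True))
        csv_path = outdir / "metrics.csv"
        with open(csv_path, "w") as fh:
            fh.write(_provenance_line(chash, cfg.seed))
            phase1_summary(phase1).to_csv(fh, index=False)
        log_lines.append(f"phase2_segments={len(seg_truth)}")
    except Exception as exc:
        raise RuntimeError(f"[evaluate] {exc}") from exc

    log_path = outdir / "run.log"
    log_path.write_text(
        _provenance_line(chash, cfg.seed) + "\n".join(log_lines) + "\n"
    )
    return {
        "cohort": cohort_dir,
        "annotations": ann_path,
        "calls": calls_path,
        "metrics_json": metrics_path,
        "metrics_csv": csv_path,
        "log": log_path,
    }
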