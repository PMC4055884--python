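"""End-to-end orchestration: simulate -> detect -> normalize -> summarize -> test.

A :class:`RunConfig` (usually loaded from YAML) fully determines a run; every
output file records the config hash, seed and package version, and a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, robust_stats
from .activity_metrics import bin_series, normalize, stable_window
from .errors import NormalizationError, PipelineError, TailflipError
from .flip_detection import DetectorConfig, counts_per_minute, detect_flips
from .longitudinal_inference import LongitudinalDataset, fit_rank_model, pairwise_group_test
from .synthetic_data import (
    DOSING_GROUPS,
    BehaviorProfile,
    EffectCurve,
    GroupSpec,
    MeasurementModel,
    StudyDesign,
    Timeline,
    simulate_study,
)
from .types import ActivitySeries

__all__ = ["RunConfig", "ValidationReport", "validate_config", "run_study"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a study run."""

    design: StudyDesign
    fidelity: str = "counts"  # counts | events | trace
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    stable_window_min: int = 20
    gamma_per_tail: float = 0.10
    alpha: float = 0.05

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        profile_kwargs = dict(raw.get("profile", {}))
        base_profile = BehaviorProfile(**profile_kwargs)
        groups = []
        for g in raw.get("groups", []):
            label = g["label"]
            if "effect" in g:
                curve = EffectCurve(**g["effect"])
            elif label in DOSING_GROUPS:
                curve = DOSING_GROUPS[label]
            else:
                curve = EffectCurve()
            profile = replace(base_profile, effect_curve=curve)
            groups.append(GroupSpec(label=label, profile=profile, n_fish=int(g["n_fish"])))
        timeline = Timeline(**raw.get("timeline", {}))
        design = StudyDesign(
            groups=tuple(groups),
            timeline=timeline,
            bin_width_min=float(raw.get("bin_width_min", 15.0)),
            seed=int(raw.get("seed", 0)),
        )
        detector = DetectorConfig(
            **{k: tuple(v) if isinstance(v, list) else v for k, v in raw.get("detector", {}).items()}
        )
        measurement = MeasurementModel(**raw.get("measurement", {}))
        return cls(
            design=design,
            fidelity=raw.get("fidelity", "counts"),
            measurement=measurement,
            detector=detector,
            stable_window_min=int(raw.get("stable_window_min", 20)),
            gamma_per_tail=float(raw.get("gamma_per_tail", 0.10)),
            alpha=float(raw.get("alpha", 0.05)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict[str, Any]:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return enc(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "configuration valid"
        return "configuration invalid:\n" + "\n".join(f"  - {m}" for m in self.issues)


def validate_config(config: RunConfig, declared_post_span_min: float | None = None) -> ValidationReport:
    """Check every embedded invariant; returns a report instead of raising."""
    issues: list[str] = []
    tl = config.design.timeline
    if declared_post_span_min is not None and not np.isclose(
        tl.post_span_min, declared_post_span_min
    ):
        issues.append(
            f"recovery ({tl.recovery_min}) + post ({tl.post_min}) = {tl.post_span_min} min "
            f"!= declared post-injection span {declared_post_span_min} min"
        )
    nyq = config.measurement.sample_rate / 2.0
    if config.detector.band_hz[1] >= nyq:
        issues.append(
            f"detector band_high {config.detector.band_hz[1]} Hz >= Nyquist {nyq} Hz"
        )
    if config.fidelity not in ("counts", "events", "trace"):
        issues.append(f"unknown fidelity {config.fidelity!r}")
    if not (0 <= config.gamma_per_tail < 0.5):
        issues.append(f"gamma_per_tail {config.gamma_per_tail} outside [0, 0.5)")
    if config.stable_window_min > tl.baseline_min:
        issues.append(
            f"stable window ({config.stable_window_min} min) exceeds baseline ({tl.baseline_min} min)"
        )
    if tl.post_min < config.design.bin_width_min:
        issues.append("post recording shorter than one bin")
    for g in config.design.groups:
        if g.profile.effect_curve.asymptote > 5:
            issues.append(f"group {g.label!r}: implausible effect asymptote")
    return ValidationReport(tuple(issues))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except TailflipError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_study(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the whole chain and write the results bundle into ``outdir``.

    Outputs: ``normalized.csv`` (per-fish binned normalized series),
    ``summary.csv`` (group x bin Winsorized mean and SE), ``tests.json``
    (factorial ATS tests plus all pairwise group contrasts) and
    ``manifest.json`` (config hash, seed, version, exclusions).
    Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = validate_config(config)
    if not report.ok:
        raise PipelineError("validate", str(report))

    records = simulate_study(config.design, config.fidelity, config.measurement)

    excluded: list[dict[str, str]] = []
    normalized = []
    tl = config.design.timeline
    for rec in records:
        if config.fidelity == "trace":
            pre_counts = counts_per_minute(detect_flips(rec.pre_trace, config.detector))
            post_counts = counts_per_minute(detect_flips(rec.post_trace, config.detector))
            pre_counts = ActivitySeries(pre_counts.values, phase="pre", fish_id=rec.fish_id)
            post_counts = ActivitySeries(post_counts.values, phase="post", fish_id=rec.fish_id)
        else:
            pre_counts, post_counts = rec.pre_counts, rec.post_counts
        try:
            sw = stable_window(pre_counts, config.stable_window_min)
            ns = normalize(post_counts, sw.median, time_offset_min=tl.recovery_min, group=rec.group)
        except (NormalizationError, TailflipError) as exc:
            excluded.append({"fish_id": rec.fish_id, "group": rec.group, "reason": str(exc)})
            continue
        normalized.append(bin_series(ns, config.design.bin_width_min))

    if not normalized:
        raise PipelineError("normalize", "all fish excluded")
    io.write_normalized(normalized, outdir / "normalized.csv")

    rows = []
    frame = pd.concat(
        [
            pd.DataFrame(
                {"group": ns.group, "bin_start_min": ns.time_min, "value": ns.values}
            )
            for ns in normalized
        ]
    )
    for (group, start), sub in frame.groupby(["group", "bin_start_min"], sort=True):
        summ = robust_stats.summarize(sub["value"].to_numpy(), config.gamma_per_tail)
        rows.append(
            {
                "group": group,
                "bin_start_min": start,
                "n": summ.n,
                "winsorized_mean": summ.mean,
                "winsorized_se": summ.se,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False, float_format="%.10g")

    data = LongitudinalDataset.from_series(normalized)
    model = fit_rank_model(data, alpha=config.alpha)
    tests: dict[str, Any] = {
        "relative_effects": {
            g: model.relative_effects.loc[g].round(6).tolist() for g in model.relative_effects.index
        },
        "time_bins": [float(b) for b in data.time_bins],
        "effects": {
            r.effect: {
                "statistic": r.statistic,
                "df1": r.df1,
                "df2": None if np.isinf(r.df2) else r.df2,
                "pvalue": r.pvalue,
            }
            for r in (model.group, model.time, model.interaction)
        },
        "pairwise": {},
    }
    labels = data.groups
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            res = pairwise_group_test(data, ga, gb)
            tests["pairwise"][f"{ga} vs {gb}"] = {"statistic": res.statistic, "pvalue": res.pvalue}
    (outdir / "tests.json").write_text(json.dumps(tests, indent=2, sort_keys=True) + "\n")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.design.seed,
        "version": __version__,
        "n_fish_simulated": len(records),
        "n_fish_analyzed": len(normalized),
        "excluded": excluded,
        "outputs": ["normalized.csv", "summary.csv", "tests.json"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
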