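"""End-to-end pipeline configuration and runner.

``PipelineConfig`` nests every stage's config under one document that
round-trips through YAML (unknown keys are rejected).
``run_pipeline`` executes simulate -> preprocess -> features -> stats ->
classify -> report and writes the five product files plus a config echo
and a run-metadata manifest into the output directory:

    manifest.csv             cohort labels (and session files if requested)
    features.csv             the 460 x 35 window feature table
    stats.csv                per-frequency group comparisons
    report.json              confusion matrix + metrics
    session_predictions.csv  per-session majority-vote table
    config_echo.yaml, run_info.json

A failed stage leaves an ``INCOMPLETE`` marker naming the stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as qio
from .classify import (
    ClassifierConfig,
    confusion_matrix,
    cross_validated_predictions,
    report_metrics,
    session_level_predictions,
)
from .errors import ConfigError, QeegPainError
from .preprocessing import PreprocessConfig, preprocess_session
from .spectral import PsdConfig, build_feature_dataset
from .stats import per_frequency_comparison
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("qeegpain")


@dataclass
class StatsOptions:
    scheme: str = "quartiles"  # "pain-binary" | "quartiles" | "both"
    alpha: float = 0.05
    protected: bool = True
    strict_pairs: bool = False
    unit: str = "window"


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    psd: PsdConfig = field(default_factory=PsdConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    stats: StatsOptions = field(default_factory=StatsOptions)
    out_dir: str = "qeegpain_run"
    seed: int | None = None
    write_sessions: bool = False
    session_format: str = "csv"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # a single global seed overrides per-stage seeds for one-flag reproducibility
        if self.seed is not None:
            self.generator.seed = int(self.seed)
            self.classifier.seed = int(self.seed)
        self.validate()

    def validate(self) -> None:
        self.generator.validate()
        self.preprocess.validate(sample_rate_hz=self.generator.sample_rate_hz)
        self.psd.validate()
        self.classifier.validate()
        if self.stats.scheme not in ("pain-binary", "quartiles", "both"):
            raise ConfigError(f"unknown stats scheme {self.stats.scheme!r}")

    # -- YAML round trip ----------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        sections = {
            "generator": GeneratorConfig,
            "preprocess": PreprocessConfig,
            "psd": PsdConfig,
            "classifier": ClassifierConfig,
            "stats": StatsOptions,
        }
        for name, section_cls in sections.items():
            section = data.pop(name, {}) or {}
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(section) - known
            if unknown:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            if name == "generator" and "level_gain" in section:
                section["level_gain"] = {
                    k: np.asarray(v, dtype=float) for k, v in section["level_gain"].items()
                }
            if name == "classifier":
                for grid in ("cost_grid", "gamma_grid"):
                    if grid in section:
                        section[grid] = tuple(section[grid])
            if name == "generator":
                for key in ("emg_burst", "motion_transient"):
                    if key in section:
                        section[key] = tuple(section[key])
                if "oscillations" in section:
                    section["oscillations"] = [tuple(o) for o in section["oscillations"]]
            kwargs[name] = section_cls(**section)
        top_known = {f.name for f in dataclasses.fields(cls)} - set(sections)
        unknown = set(data) - top_known
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                out[f.name] = plain(dataclasses.asdict(value))
            else:
                out[f.name] = plain(value)
        return out

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def _versions() -> dict:
    import importlib.metadata as im

    out = {}
    for pkg in ("qeegpain", "numpy", "scipy", "pandas", "scikit-learn"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:  # pragma: no cover
            out[pkg] = "unknown"
    return out


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full pipeline and write all products to ``config.out_dir``.

    Returns a dict of in-memory results (manifest, dataset, stats frame,
    report, session table) for programmatic use.
    """
    config = config or PipelineConfig()
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "INCOMPLETE"
    stage = "simulate"
    try:
        marker.write_text("stage=simulate\n")
        log.info("simulate: generating synthetic cohort (seed=%d)", config.generator.seed)
        manifest = generate_cohort(config.generator)
        if config.write_sessions:
            qio.write_cohort(manifest, out_dir, fmt=config.session_format)
        else:
            import pandas as pd

            rows = [
                {
                    "subject_id": s.subject_id,
                    "phase": s.phase,
                    "nrs": s.nrs,
                    "quartile": s.quartile.label,
                    "file": "",
                }
                for s in manifest.sessions
            ]
            pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")

        stage = "preprocess"
        marker.write_text("stage=preprocess\n")
        log.info("preprocess: %d sessions", len(manifest))
        segment_sets = [preprocess_session(s, config.preprocess) for s in manifest.sessions]

        stage = "features"
        marker.write_text("stage=features\n")
        dataset = build_feature_dataset(segment_sets, manifest, config.psd)
        qio.write_features(dataset, out_dir / "features.csv")
        log.info("features: %d windows x %d features", len(dataset), 35)

        stage = "stats"
        marker.write_text("stage=stats\n")
        opts = config.stats
        schemes = ["pain-binary", "quartiles"] if opts.scheme == "both" else [opts.scheme]
        import pandas as pd

        stats_frame = pd.concat(
            [
                per_frequency_comparison(
                    dataset,
                    scheme=scheme,
                    alpha=opts.alpha,
                    protected=opts.protected,
                    strict_pairs=opts.strict_pairs,
                    unit=opts.unit,
                )
                for scheme in schemes
            ],
            ignore_index=True,
        )
        qio.write_stats(stats_frame, out_dir / "stats.csv")
        log.info("stats: %d comparisons", len(stats_frame))

        stage = "classify"
        marker.write_text("stage=classify\n")
        predictions = cross_validated_predictions(dataset, config.classifier)
        matrix = confusion_matrix(predictions["quartile"], predictions["prediction"])
        report = report_metrics(matrix)
        log.info("classify: out-of-fold accuracy %.3f", report.overall_accuracy)

        stage = "report"
        marker.write_text("stage=report\n")
        windows_per_session = int(
            (
                config.generator.session_duration_s
                - config.preprocess.trim_start_s
                - config.preprocess.trim_end_s
            )
            / config.preprocess.window_length_s
        )
        session_table = session_level_predictions(predictions, windows_per_session)
        report_dict = report.to_dict()
        report_dict["cv_scheme"] = config.classifier.cv_scheme
        report_dict["seed"] = config.generator.seed
        qio.write_report_json(report_dict, out_dir / "report.json")
        qio.write_session_table(session_table, out_dir / "session_predictions.csv")
        config.to_yaml(out_dir / "config_echo.yaml")
        qio.write_report_json(
            {"seed": config.generator.seed, "versions": _versions()},
            out_dir / "run_info.json",
        )
        marker.unlink(missing_ok=True)
    except QeegPainError as exc:
        marker.write_text(f"stage={stage}\nerror={exc}\n")
        raise QeegPainError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return {
        "manifest": manifest,
        "dataset": dataset,
        "stats": stats_frame,
        "predictions": predictions,
        "report": report,
        "session_table": session_table,
    }
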