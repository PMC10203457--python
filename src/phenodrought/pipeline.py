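"""End-to-end orchestration: observations → means → TDRI → statistics.

One call runs every stage on a long-format observation table and writes
a deterministic report bundle:

* ``means.csv``    — wide per-line trait means (``trait:treatment`` columns)
* ``tdri.csv``     — stress ratios, TDRI, rank and tolerance band per line
* ``summary.csv``  — descriptive statistics with CV bands and genotype
  significance per (trait, treatment)
* ``letters.csv``  — per-trait LSD compact letter displays
* ``corr.csv`` / ``corr_long.csv`` — Pearson correlation matrix over
  stress-treatment line means, square and long forms
* ``report.txt``   — run log: versions, seed, config hash, stage notes

Re-running with identical inputs and configuration reproduces the CSVs
byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import (SchemaError, TDRI_TRAITS, aggregate_means,
                   read_observations)
from .derived import derive_water_traits, percent_reduction_series, read_pot_weights
from .imaging import SegmentationThresholds
from .stats import (anova_lsd, correlation_long_table, correlation_matrix,
                    summarize_trial)
from .tdri import DEFAULT_BANDS, tdri_table

logger = logging.getLogger("phenodrought")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; serialisable to/from YAML."""

    observations: str = "observations.csv"
    pot_weights: str | None = None
    out_dir: str = "phenodrought_out"
    tdri_bands: tuple[float, float] = DEFAULT_BANDS
    cv_bands: tuple[float, float] = (15.0, 30.0)
    alpha: float = 0.05
    correlation_treatment: str = "WS"
    green_hue: tuple[float, float] = (70.0, 165.0)
    blue_hue: tuple[float, float] = (190.0, 260.0)
    min_saturation: float = 0.25
    min_value: float = 0.15
    card_area_cm2: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("tdri_bands", "cv_bands", "green_hue", "blue_hue"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} cut points must be ascending")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def thresholds(self) -> SegmentationThresholds:
        return SegmentationThresholds(
            tuple(self.green_hue), tuple(self.blue_hue),
            self.min_saturation, self.min_value,
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _letters_table(obs: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """LSD letter displays per (trait, treatment) where replication allows."""
    rows = []
    for (trait, trt), sub in obs.groupby(["trait", "treatment"], sort=True):
        groups = {str(l): g["value"].to_numpy() for l, g in sub.groupby("line_id")}
        if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
            continue
        res = anova_lsd(groups, alpha)
        for line in sorted(groups):
            rows.append((trait, trt, line, res.means[line],
                         res.letters[line], res.F, res.p, res.lsd))
    return pd.DataFrame(rows, columns=[
        "trait", "treatment", "line_id", "mean", "letters", "F", "p", "lsd"])


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths.

    Any stage failure aborts with an exception naming the stage and the
    offending records.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notes: list[str] = []

    def stage(name: str):
        logger.info("stage: %s", name)
        notes.append(name)

    stage("read_observations")
    try:
        obs = read_observations(cfg.observations)
    except SchemaError as exc:
        raise SchemaError(f"[read_observations] {exc}") from exc

    if cfg.pot_weights:
        stage("derive_water_traits")
        obs = derive_water_traits(obs, read_pot_weights(cfg.pot_weights))

    stage("aggregate_means")
    matrix = aggregate_means(obs)
    incomplete = {l: matrix.missing_tdri_entries(l) for l in matrix.lines}
    incomplete = {l: m for l, m in incomplete.items() if m}
    if incomplete:
        raise SchemaError(f"[aggregate_means] incomplete TDRI traits: {incomplete}")

    stage("tdri")
    tdri_df = tdri_table(matrix, cfg.tdri_bands)

    stage("summary_statistics")
    summary = summarize_trial(obs, cfg.alpha, cfg.cv_bands)
    letters = _letters_table(obs, cfg.alpha)

    stage("correlations")
    trt = cfg.correlation_treatment
    frame = matrix.treatment_means(trt, list(TDRI_TRAITS) + ["WU", "WUE"])
    frame["PR_SDW"] = percent_reduction_series(matrix)
    frame = frame.dropna(axis=1, how="all")
    corr = correlation_matrix(frame, list(frame.columns))
    corr_long = correlation_long_table(corr)

    paths = {
        "means": out / "means.csv",
        "tdri": out / "tdri.csv",
        "summary": out / "summary.csv",
        "letters": out / "letters.csv",
        "corr": out / "corr.csv",
        "corr_long": out / "corr_long.csv",
        "report": out / "report.txt",
    }
    matrix.to_wide_csv(paths["means"])
    tdri_df.to_csv(paths["tdri"], index=False)
    summary.to_csv(paths["summary"], index=False)
    letters.to_csv(paths["letters"], index=False)
    corr.r.round(12).to_csv(paths["corr"], index_label="trait")
    corr_long.to_csv(paths["corr_long"], index=False)

    bands = tdri_df["band"].value_counts().to_dict()
    report = "\n".join([
        f"phenodrought {__version__}",
        f"seed: {cfg.seed}",
        f"config_hash: {cfg.config_hash()}",
        f"lines: {len(matrix.lines)}  observations: {len(obs)}",
        f"bands: " + ", ".join(f"{b}={bands.get(b, 0)}"
                               for b in ("tolerant", "moderate", "low")),
        "stages: " + " -> ".join(notes),
        "note: trait grouping (tertile rule) is a reconstruction, not a "
        "published procedure",
    ]) + "\n"
    paths["report"].write_text(report)
    logger.info("pipeline complete: %s", out)
    return paths
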