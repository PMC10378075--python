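"""End-to-end pipeline: simulate -> extract -> features -> stats -> model.

A :class:`PipelineConfig` fully determines a run; every artifact lands in
the output directory together with a manifest recording the config hash,
seeds and package version, so identical configs reproduce identical runs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import io, modeling, simulate, stats

log = logging.getLogger("kymovoice")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full simulation-and-analysis run."""

    # acquisition emulation
    fps: float = 3200.0
    n_frames: int = 2000
    # cohort
    counts: dict = dataclasses.field(
        default_factory=lambda: {"normophonic": 38, "benign": 64, "malignant": 36}
    )
    # kymography
    section_position: float = 0.5
    contrast_floor: float = 0.1
    # segmentation
    closure_threshold: float = 0.25
    min_cycles: int = 10
    # modeling
    train_fraction: float = 0.7
    trials: int = 50
    feature_mode: str = "published"  # published | auto
    seed: int = 0
    out_dir: str = "runs/default"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must lie in (0, 1]")
        if not 0 <= self.section_position <= 1:
            raise ValueError("section_position must lie in [0, 1]")
        if not 0 < self.closure_threshold < 1:
            raise ValueError("closure_threshold must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_frames / self.fps


def run_pipeline(config: PipelineConfig, plots: bool = True) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages: cohort simulation, feature extraction, Kruskal-Wallis table,
    per-parameter ROC, stratified split, model training/evaluation/SHAP
    for both diagnostic tasks. Any stage failure raises with a
    stage-tagged message; artifacts written so far are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        log.info("[%7.2fs] stage: %s", time.time() - t0, name)

    try:
        stage("simulate")
        spec = simulate.CohortSpec(counts=dict(config.counts), fps=config.fps,
                                   n_frames=config.n_frames, seed=config.seed)
        cohort = simulate.generate_cohort(spec)
        cohort.manifest().to_csv(out / "cohort_manifest.csv", index=False)

        stage("features")
        feats = simulate.cohort_features(cohort, min_cycles=config.min_cycles,
                                         on_error="skip")
        stage("statistics")
        kw = stats.kruskal_wallis_table(feats)
        io.write_features_csv(kw, out / "kruskal_wallis.csv")
        roc_rows = []
        for contrast in stats.CONTRASTS:
            tbl = stats.roc_table(feats, contrast)
            roc_rows.append(tbl)
            if plots:
                top = [stats.roc_analysis(feats, p, contrast)
                       for p in tbl["parameter"].head(3)]
                stats.plot_roc(top, out / f"roc_{contrast}.png")
        io.write_features_csv(pd.concat(roc_rows), out / "roc_parameters.csv")

        stage("split")
        feats = modeling.split_dataset(feats, train_fraction=config.train_fraction,
                                       seed=config.seed)
        io.write_features_csv(feats, out / "features.csv")

        reports = {}
        for task in modeling.TASKS:
            stage(f"model:{task}")
            clf = modeling.LesionClassifier(feats, task=task,
                                            features=config.feature_mode)
            res = clf.fit(seed=config.seed, trials=config.trials)
            res.to_json(out / f"model_{task}.json")
            (out / f"summary_{task}.txt").write_text(res.summary() + "\n")
            reports[task] = res.report()
            if plots:
                table, _ = res.shap_table()
                modeling.plot_shap_summary(
                    table, clf.data[res.features], out / f"shap_{task}.png")

        stage("manifest")
        # hash over the analysis-relevant settings (the output path does not
        # change the computation)
        hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
        io.write_manifest(out / "manifest.json", hashed, extra={
            "duration_ms": config.duration_ms,
            "n_subjects": len(cohort),
            "n_analyzable": int(len(feats)),
            "split_chi2_p": feats.attrs.get("split_chi2_p"),
            "reports": reports,
        })
    except Exception as exc:  # annotate failures with the failing stage
        raise RuntimeError(
            f"pipeline failed at stage {current['stage']!r}: {exc}") from exc
    return out
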