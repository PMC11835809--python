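"""End-to-end pipeline: simulate -> extract -> stats -> classify -> report.

A single :class:`PipelineConfig` (loadable from YAML) holds every tunable;
one global seed fans out deterministically to the per-stage seeds, so a
rerun with the same configuration reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vitalkin import classify as _cls
from vitalkin.classify import BUILTIN_SUBSETS, ClassifierSpec, chance_level
from vitalkin.errors import ConfigurationError
from vitalkin.features import ExtractionConfig, build_table
from vitalkin.kinematics import FilterConfig, SegmentationConfig
from vitalkin.stats import (
    SIGNIFICANT_FEATURES,
    compare_actors,
    principal_factor_analysis,
    screen_features,
)
from vitalkin.synthetic import (
    CONDITIONS,
    REFERENCE_COUNTS,
    SynthClassParams,
    SynthDatasetConfig,
    default_class_params,
    generate_dataset,
    write_dataset,
)

log = logging.getLogger(__name__)


@dataclass
class ClassifyConfig:
    loocv_algorithms: tuple = ("svm_rbf", "knn", "rf")
    logo_algorithms: tuple = ("svm_rbf", "svm_poly", "knn", "mlp", "rf")
    exponent_range: tuple = (1, 9)
    rf_trees: int = 300
    mlp_hidden: int = 32
    mlp_epochs: int = 300
    seed: int = 0
    run_single_feature_ranking: bool = False
    run_subset_evaluation: bool = False
    feature_subset: tuple = tuple(SIGNIFICANT_FEATURES)


@dataclass
class PipelineConfig:
    seed: int = 0
    fps: float = 100.0
    counts: dict = field(default_factory=lambda: {a: dict(c) for a, c in REFERENCE_COUNTS.items()})
    class_params: dict | None = None  # condition -> SynthClassParams kwargs
    filter: FilterConfig = field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    variability_cutoff_hz: float = 2.0
    outlier_k: float = 2.5
    alpha: float = 0.05
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    write_trials: bool = False  # per-trial CSVs are bulky; off by default

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if dataclasses.is_dataclass(cur) and isinstance(val, dict):
                setattr(cfg, key, dataclasses.replace(cur, **val))
            else:
                setattr(cfg, key, val)
        return cfg

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return enc({f.name: getattr(self, f.name) for f in dataclasses.fields(self)})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _class_param_map(cfg: PipelineConfig) -> dict:
    if cfg.class_params is None:
        return default_class_params()
    return {cond: SynthClassParams(**kw) for cond, kw in cfg.class_params.items()}


def _json_dump(obj, path: Path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Execute every stage; artifacts land in ``outdir``.

    Outputs: the feature table, the discard report, the screening summary
    (published-table layout), assumption checks, the actor comparison, the
    factor model, per-scheme/algorithm evaluation reports with confusion
    matrices, and a manifest with the config and its hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        ds_cfg = SynthDatasetConfig(
            counts=cfg.counts, seed=stage_seed(cfg.seed, "simulate"), fps=cfg.fps
        )
        trials = generate_dataset(ds_cfg, _class_param_map(cfg))
        log.info("simulate: %d trials", len(trials))
        if cfg.write_trials:
            write_dataset(trials, outdir / "dataset")
        else:
            meta_rows = [
                {
                    "trial_id": t.meta.trial_id,
                    "actor": t.meta.actor,
                    "action": t.meta.action,
                    "condition": t.meta.condition,
                    "direction": t.meta.direction,
                    "seed": t.meta.extras.get("seed", ""),
                }
                for t in trials
            ]
            pd.DataFrame(meta_rows).to_csv(outdir / "metadata.csv", index=False)

        stage = "extract"
        ext = ExtractionConfig(
            filter=cfg.filter,
            segmentation=cfg.segmentation,
            variability_cutoff_hz=cfg.variability_cutoff_hz,
        )
        table, discards = build_table(trials, ext)
        table.to_csv(outdir / "features.csv", index=False)
        discards.to_csv(outdir / "discards.csv", index=False)
        log.info("extract: %d rows, %d discards", len(table), len(discards))

        stage = "stats"
        results, summary = screen_features(table, outlier_k=cfg.outlier_k, alpha=cfg.alpha)
        summary.to_csv(outdir / "screening.csv", index=False)
        assumptions = pd.DataFrame(
            [
                {
                    "feature": r.feature,
                    "mauchly_w": r.mauchly_w,
                    "mauchly_p": r.mauchly_p,
                    "gg_applied": r.gg_applied,
                    "gg_epsilon": r.gg_epsilon,
                    **{f"ks_p_{c}": r.ks_p.get(c, np.nan) for c in CONDITIONS},
                }
                for r in results
            ]
        )
        assumptions.to_csv(outdir / "assumptions.csv", index=False)
        compare_actors(table).to_csv(outdir / "actor_comparison.csv", index=False)
        fm = principal_factor_analysis(table)
        fm.loadings.round(6).to_csv(outdir / "factor_loadings.csv")
        _json_dump(
            {
                "n_components": fm.n_components,
                "representatives": fm.representatives,
                "eigenvalues": [round(float(e), 6) for e in fm.eigenvalues],
            },
            outdir / "factor_model.json",
        )

        stage = "classify"
        feats = list(cfg.classify.feature_subset)
        cseed = stage_seed(cfg.seed, "classify")
        reports = {}
        for alg in cfg.classify.loocv_algorithms:
            spec = _make_spec(alg, cfg.classify, cseed)
            rep = _cls.loocv_evaluate(table, spec, feats)
            reports[f"loocv_{alg}"] = rep
        for alg in cfg.classify.logo_algorithms:
            spec = _make_spec(alg, cfg.classify, cseed)
            rep = _cls.logo_evaluate(table, spec, feats, cfg.classify.exponent_range)
            reports[f"logo_{alg}"] = rep
        for name, rep in reports.items():
            _json_dump(rep.to_dict(), outdir / f"eval_{name}.json")
            rep.confusion.to_csv(outdir / f"confusion_{name}.csv")
        logo_scores = {
            alg: reports[f"logo_{alg}"].per_fold["f_score"].tolist()
            for alg in cfg.classify.logo_algorithms
            if f"logo_{alg}" in reports
        }
        if len(logo_scores) >= 2:
            F, p, tukey = _cls.compare_fold_scores(logo_scores)
            tukey.to_csv(outdir / "logo_fscore_tukey.csv", index=False)
            _json_dump({"F": F, "p": p}, outdir / "logo_fscore_anova.json")
        if cfg.classify.run_single_feature_ranking:
            _cls.single_feature_ranking(
                table, feats, ClassifierSpec("rf", n_trees=cfg.classify.rf_trees, seed=cseed)
            ).to_csv(outdir / "single_feature_ranking.csv", index=False)
        if cfg.classify.run_subset_evaluation:
            _cls.subset_evaluation(
                table, BUILTIN_SUBSETS, ClassifierSpec("rf", n_trees=cfg.classify.rf_trees, seed=cseed)
            ).to_csv(outdir / "subset_evaluation.csv", index=False)

        stage = "report"
        _json_dump(
            {
                "config": cfg.to_dict(),
                "config_hash": cfg.config_hash(),
                "n_trials": len(trials),
                "n_retained": len(table),
                "chance_level_pct": round(chance_level(table["condition"]), 2),
                "significant_features": summary.loc[summary["significant"], "feature"].tolist(),
                "metrics": {
                    name: {
                        "accuracy": round(r.accuracy, 2),
                        "f_score": round(r.f_score, 2),
                        "precision": round(r.precision, 2),
                        "recall": round(r.recall, 2),
                    }
                    for name, r in reports.items()
                },
            },
            outdir / "manifest.json",
        )
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    return outdir


def _make_spec(alg: str, ccfg: ClassifyConfig, seed: int) -> ClassifierSpec:
    return ClassifierSpec(
        alg,
        n_trees=ccfg.rf_trees,
        hidden=ccfg.mlp_hidden,
        max_epochs=ccfg.mlp_epochs,
        seed=seed,
    )


def make_fixtures(outdir, seed: int = 0, trials_per_cell: int = 5) -> Path:
    """Miniature end-to-end run (default 5 trials per action x condition
    cell) that exercises every stage quickly."""
    cfg = PipelineConfig(
        seed=seed,
        counts={a: {c: trials_per_cell for c in CONDITIONS} for a in REFERENCE_COUNTS},
        classify=ClassifyConfig(
            loocv_algorithms=("knn",),
            logo_algorithms=("knn", "rf"),
            exponent_range=(3, 5),
            rf_trees=100,
        ),
    )
    return run_pipeline(cfg, outdir)
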