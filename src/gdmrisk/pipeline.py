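"""End-to-end orchestration: simulate -> preprocess -> select -> bench ->
explain -> report, under one config and one root seed.

Each stage draws its randomness from a named substream derived from the
root seed, so the stages are independently reproducible.  Artifacts are
written to an output directory and summarized in a run manifest with
file checksums; a rerun with the identical config reproduces identical
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import bench, explain, select, thresholds
from .config import GeneratorConfig
from .preprocess import prepare
from .simulate import generate_cohort, write_cohort

log = logging.getLogger("gdmrisk")

_STAGE_KEYS = {"simulate": 0, "split": 1, "smote": 2, "select": 3, "bench": 4, "explain": 5}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fanned out from the root seed."""
    ss = np.random.SeedSequence(entropy=root_seed, spawn_key=(1000 + _STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Every knob of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    root_seed: int = 42
    train_fraction: float = 0.8
    split_seed: int = 42  # the fixed published split seed
    smote_k: int = 5
    top_k: int = 10
    models: tuple[str, ...] = bench.MODEL_NAMES
    tuned: bool = True
    cv_folds: int = 10
    n_background: int = 100
    n_explain: int = 50
    n_coalitions: int = 2048

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        gen = GeneratorConfig.from_dict(raw.pop("generator", {}))
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(generator=gen, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = {k: getattr(self, k) for k in (
            "root_seed", "train_fraction", "split_seed", "smote_k", "top_k",
            "tuned", "cv_folds", "n_background", "n_explain", "n_coalitions",
        )}
        d["models"] = list(self.models)
        d["generator"] = self.generator.to_dict()
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: RunConfig, out_dir: str | Path, use_cache: bool = True) -> dict[str, Any]:
    """Execute every stage in order; returns the run manifest (also written).

    A stage whose primary artifact already exists in ``out_dir`` is
    reloaded rather than recomputed when ``use_cache`` is true, so a
    failed run restarts from its last completed stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": cfg.to_dict(), "stages": {}, "files": {}}
    t0 = time.time()

    def _stage_done(name: str, **info) -> None:
        info["elapsed_s"] = round(time.time() - t0, 2)
        manifest["stages"][name] = info
        log.info("stage %s done: %s", name, info)

    # 1. simulate -----------------------------------------------------------
    cohort_path = out / "cohort.csv"
    if use_cache and cohort_path.exists():
        from .simulate import read_cohort

        cohort = read_cohort(cohort_path)
    else:
        cohort = generate_cohort(cfg.generator)
        write_cohort(cohort, cohort_path, cfg.generator)
    _stage_done("simulate", n=len(cohort), gdm_positive=int(cohort["gdm"].sum()))

    # 2. preprocess ---------------------------------------------------------
    balanced_train, test, split = prepare(
        cohort,
        train_fraction=cfg.train_fraction,
        split_seed=cfg.split_seed,
        smote_k=cfg.smote_k,
        smote_seed=stage_seed(cfg.root_seed, "smote"),
    )
    train_csv = split.train.values.assign(gdm=split.train.labels)
    train_csv.to_csv(out / "train.csv", index=False)
    test.values.assign(gdm=test.labels).to_csv(out / "test.csv", index=False)
    balanced_train.values.assign(gdm=balanced_train.labels).to_csv(
        out / "train_balanced.csv", index=False
    )
    (out / "scaling_params.json").write_text(
        json.dumps(split.train.scaling_params, indent=2)
    )
    _stage_done(
        "preprocess",
        train=len(split.train.values),
        test=len(test.values),
        balanced_train=len(balanced_train.values),
        train_class_counts=split.train.labels.value_counts().to_dict(),
        balanced_class_counts=balanced_train.labels.value_counts().to_dict(),
    )

    # 3. consensus feature selection ---------------------------------------
    vectors = select.compute_all_importances(
        balanced_train, seed=stage_seed(cfg.root_seed, "select")
    )
    consensus = select.consensus_rank(vectors)
    consensus.to_csv(out / "consensus.csv", index=False)
    top_features = select.select_top_k(consensus, cfg.top_k)
    _stage_done("select", top_features=top_features)

    # 4. benchmark — models see only the consensus top-k feature space
    from .preprocess import FeatureMatrix

    bench_train = FeatureMatrix(
        balanced_train.values[top_features], balanced_train.labels,
        balanced_train.scaling_params,
    )
    bench_test = FeatureMatrix(
        test.values[top_features], test.labels, test.scaling_params
    )
    specs = bench.default_model_specs(
        seed=stage_seed(cfg.root_seed, "bench"), tuned=cfg.tuned, models=cfg.models
    )
    rows, models = bench.run_benchmark(
        bench_train, bench_test, specs=specs, cv_folds=cfg.cv_folds,
        seed=stage_seed(cfg.root_seed, "bench"),
    )
    board = bench.leaderboard_frame(rows)
    board.to_csv(out / "leaderboard.csv", index=False)
    per_model = {
        r.model: {
            "confusion": {"tn": r.confusion.tn, "fp": r.confusion.fp,
                          "fn": r.confusion.fn, "tp": r.confusion.tp},
            "chosen_params": r.chosen_params,
            "weighted_f1": r.weighted_f1,
            "auc_roc": r.auc_roc,
        }
        for r in rows
    }
    (out / "models.json").write_text(json.dumps(per_model, indent=2))
    best_name = rows[0].model
    best_model = models[best_name]
    _stage_done("bench", best_model=best_name,
                leaderboard=[(r.model, round(r.weighted_f1, 4)) for r in rows])

    # 5. explain ------------------------------------------------------------
    background, instances, _labels = explain.sample_explain_sets(
        bench_test, n_background=min(cfg.n_background, len(test.values)),
        n_explain=min(cfg.n_explain, len(test.values)),
        seed=stage_seed(cfg.root_seed, "explain"),
    )
    attributions = explain.attribute(
        best_model, background, instances, n_coalitions=cfg.n_coalitions,
        seed=stage_seed(cfg.root_seed, "explain"),
    )
    attributions.contributions.to_csv(out / "attributions.csv", index=False)
    explain.global_importance(attributions).to_csv(out / "shap_importance.csv", index=False)
    ledger = explain.waterfall(attributions, instance=0)
    ledger.to_json(out / "waterfall_instance0.json", orient="records", indent=2)
    _stage_done("explain", base_value=attributions.base_value,
                max_additivity_gap=float(attributions.additivity_gap().max()))

    # 6. per-patient risk reports (explained subset) -------------------------
    proba = bench.predict_proba(best_model, instances.to_numpy(dtype=float))
    reports = []
    for i in range(len(instances)):
        # tiers are classified on the original (unscaled) test-set labs
        raw = _unscale_row(instances.iloc[i], test.scaling_params)
        reports.append(
            thresholds.risk_report(
                raw, float(proba[i]), attributions=attributions.contributions.iloc[i]
            )
        )
    with open(out / "reports.jsonl", "w") as fh:
        for rep in reports:
            fh.write(thresholds.report_to_json(rep) + "\n")
    _stage_done("report", n_reports=len(reports))

    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*")) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _unscale_row(row: pd.Series, scaling_params: dict | None) -> pd.Series:
    """Invert standardization for one feature row (for tier classification).

    Zero-imputed OGTT values scale to a nonzero z-score; after unscaling
    they return to ~0, which is below every analyte's valid range and is
    treated as untested (dropped) rather than classified.
    """
    raw = row.astype(float).copy()
    if scaling_params:
        for col, (mean, sd) in scaling_params.items():
            if col in raw.index:
                raw[col] = raw[col] * sd + mean
    from .constants import LAB_RANGES

    for analyte, (lo, hi) in LAB_RANGES.items():
        if analyte in raw.index and not (lo <= raw[analyte] <= hi):
            raw = raw.drop(analyte)
    return raw
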