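"""End-to-end pipeline orchestration with manifests, seeds and logging.

``run_pipeline`` chains the stages — simulate → preprocess (templates) →
augment → train → segment → measure/QC → analyze — on a synthetic phantom
set plus a simulated cohort, writing every tabular product as CSV and a
JSON manifest per stage (inputs, outputs, seed, version, counts).  A stage
failure aborts with the stage named; partial outputs are preserved.

All problem sizes live in :class:`PipelineConfig`; the defaults are a small
smoke-scale demonstration.  The master seed derives every stage seed, so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .augment import AugmentationSpec, augment_dataset
from .icv import DEFAULT_QC_THRESHOLD, qc_gate, qc_score, ICVResult
from .metrics import compare_groups, evaluate_segmentation
from .net import NetworkConfig, save_checkpoint
from .preprocess import build_template
from .stats import best_scan_per_wave, change_rates, fit_wave_model, welch_t
from .synthetic import CohortSpec, make_annotated_set, simulate_cohort
from .train import HyperparameterSpace, bayes_opt_search, build_ensemble, kfold_split
from .volumes import VolumeGrid, normalize_intensity, write_mask, write_volume

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (JSON-serializable)."""

    out_dir: str = "pipeline_out"
    master_seed: int = 0
    # phantom set
    grid_size: int = 16
    spacing_mm: float = 1.0
    n_train_per_wave: int = 4
    n_test_per_wave: int = 2
    # augmentation
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    # search / training
    space: HyperparameterSpace = field(default_factory=HyperparameterSpace)
    search_budget: int = 1
    k_folds: int = 3
    depth: int = 2
    kernel_sizes: tuple[int, ...] = (3, 3)
    epochs: int = 1
    steps_per_epoch: int | None = 2
    dropout_rate: float = 0.5
    # QC / measurement
    qc_threshold: float = DEFAULT_QC_THRESHOLD
    # cohort analysis
    cohort: CohortSpec = field(default_factory=lambda: CohortSpec(n_subjects=150))
    cohort_mode: str = "longitudinal"
    # optional pre-existing template directory (must exist if set)
    template_dir: str | None = None

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if "augmentation" in d:
            d["augmentation"] = AugmentationSpec.from_json(
                json.dumps(d["augmentation"])
            )
        if "space" in d:
            d["space"] = HyperparameterSpace(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["space"].items()
            })
        if "cohort" in d:
            c = d["cohort"]
            c.pop("wave_mean_icv", None)  # curves are code-level defaults
            for k in ("interval_days",):
                if k in c:
                    c[k] = tuple(c[k])
            for k in ("wave1_age_days", "wave2_age_days", "growth_rate"):
                if k in c:
                    c[k] = {s: tuple(v) for s, v in c[k].items()}
            d["cohort"] = CohortSpec(**c)
        if "kernel_sizes" in d:
            d["kernel_sizes"] = tuple(d["kernel_sizes"])
        return cls(**d)

    def validate(self) -> None:
        if self.template_dir is not None and not Path(self.template_dir).is_dir():
            raise PipelineError(
                f"config validation: template_dir {self.template_dir!r} does not exist"
            )
        if self.grid_size % 2**self.depth != 0:
            raise PipelineError(
                "config validation: grid_size must be divisible by 2**depth"
            )


def _write_manifest(out_dir: Path, stage: str, seed, inputs, outputs, counts):
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,
        "counts": counts,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of key output paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    seeds = np.random.SeedSequence(config.master_seed).generate_state(8) % (2**31)
    artifacts: dict = {}

    stage = "simulate"
    try:
        grid = VolumeGrid((config.grid_size,) * 3, config.spacing_mm)
        n_total = config.n_train_per_wave + config.n_test_per_wave
        items = make_annotated_set(n_total, seed=int(seeds[0]), grid=grid)
        by_wave = {"20w": [], "30w": []}
        for v, m, w in items:
            by_wave[w].append((normalize_intensity(v), m))
        train_items, test_items = [], []
        for w in ("20w", "30w"):
            train_items += [(v, m, w) for v, m in by_wave[w][: config.n_train_per_wave]]
            test_items += [(v, m, w) for v, m in by_wave[w][config.n_train_per_wave:]]
        data_dir = out / "data"
        for i, (v, m, w) in enumerate(train_items + test_items):
            split = "train" if i < len(train_items) else "test"
            write_volume(v, data_dir / f"{split}_{i:03d}_{w}_vol.nii.gz")
            write_mask(m, data_dir / f"{split}_{i:03d}_{w}_mask.nii.gz")
        cohort = simulate_cohort(
            config.cohort.with_(seed=int(seeds[1])), mode=config.cohort_mode
        )
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        artifacts["cohort"] = cohort_path
        logger.info(
            "simulate: %d phantoms (%d train / %d test), cohort of %d scans",
            len(items) * 1, len(train_items), len(test_items), len(cohort),
        )
        _write_manifest(
            out, stage, int(seeds[0]),
            {"grid_size": config.grid_size},
            {"data_dir": str(data_dir), "cohort": str(cohort_path)},
            {"n_train": len(train_items), "n_test": len(test_items),
             "n_cohort_rows": len(cohort)},
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "preprocess"
    try:
        templates = {}
        for w in ("20w", "30w"):
            pairs = [(v, m) for v, m, ww in train_items if ww == w]
            templates[w] = build_template(pairs, wave=w)
            write_volume(templates[w].template_volume, out / f"template_{w}_vol.nii.gz")
            write_mask(templates[w].template_mask, out / f"template_{w}_mask.nii.gz")
        _write_manifest(
            out, stage, None, {"n_train": len(train_items)},
            {"templates": [f"template_{w}" for w in templates]},
            {"n_templates": len(templates)},
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "augment"
    try:
        aug = dataclasses.replace(config.augmentation, seed=int(seeds[2]))
        pairs = [(v, m) for v, m, w in train_items]
        augmented = augment_dataset(pairs, aug)
        # augmented copies belong to the subject of their original
        subject_ids = list(range(len(pairs))) + [
            i // max(1, aug.copies_per_volume)
            for i in range(len(augmented) - len(pairs))
        ]
        logger.info("augment: %d -> %d training pairs", len(pairs), len(augmented))
        _write_manifest(
            out, stage, int(seeds[2]), {"n_in": len(pairs)},
            {}, {"n_out": len(augmented)},
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "train"
    try:
        folds_idx = kfold_split(
            augmented, config.k_folds, subject_ids, seed=int(seeds[3])
        )
        folds = [
            ([augmented[i] for i in tr], [augmented[i] for i in va])
            for tr, va in folds_idx
        ]
        base_cfg = NetworkConfig(
            depth=config.depth,
            kernel_sizes=config.kernel_sizes,
            input_shape=(config.grid_size,) * 3,
            epochs=config.epochs,
            steps_per_epoch=config.steps_per_epoch,
            dropout_rate=config.dropout_rate,
        )
        result = bayes_opt_search(
            config.space, folds, budget=config.search_budget,
            base_config=base_cfg, seed=int(seeds[4]),
        )
        log_rows = [
            {
                "fold": e.fold, "iteration": e.iteration,
                "f": e.config.base_filters, "batch": e.config.batch_size,
                "lr": e.config.learning_rate,
                "mean_dsc": e.mean_dsc,
                "mean_acc": float(np.mean(e.val_accuracy)) if e.val_accuracy else np.nan,
            }
            for e in result.entries
        ]
        search_log = out / "search_log.csv"
        pd.DataFrame(log_rows).to_csv(search_log, index=False)
        ensemble, winners = build_ensemble(result)
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for w in winners:
            save_checkpoint(w.network, models_dir / f"member_fold{w.fold}.npz")
        artifacts["search_log"] = search_log
        _write_manifest(
            out, stage, int(seeds[4]),
            {"budget": config.search_budget, "k": config.k_folds},
            {"models_dir": str(models_dir), "search_log": str(search_log)},
            {"n_networks": len(result.entries)},
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "segment"
    try:
        rows, evals = [], {"20w": [], "30w": []}
        preds = []
        for i, (v, m, w) in enumerate(test_items):
            pred = ensemble.predict(v)
            preds.append(pred)
            ev = evaluate_segmentation(pred, m)
            evals[w].append(ev)
            rows.append(
                {"id": f"test_{i:03d}", "wave": w,
                 "accuracy": ev.voxel_accuracy, "dsc": ev.dsc,
                 "hd_voxel": ev.hd_voxel, "hd_physical": ev.hd_physical}
            )
        eval_path = out / "eval.csv"
        pd.DataFrame(rows).to_csv(eval_path, index=False)
        artifacts["eval"] = eval_path
        group_cmp = (
            compare_groups(evals["20w"], evals["30w"])
            if evals["20w"] and evals["30w"]
            else {}
        )
        _write_manifest(
            out, stage, None, {"n_test": len(test_items)},
            {"eval": str(eval_path)},
            {"mean_dsc": float(np.mean([r["dsc"] for r in rows])),
             "group_comparison": group_cmp},
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "measure"
    try:
        results = []
        for i, ((v, m, w), pred) in enumerate(zip(test_items, preds)):
            score = qc_score(pred, v, templates[w])
            icv_ml = pred.n_voxels * pred.grid.voxel_volume_ml
            results.append(
                ICVResult(
                    scan_id=f"test_{i:03d}", subject_id=f"P{i:03d}", wave=w,
                    age_days=155 if w == "20w" else 211,
                    n_voxels=pred.n_voxels, icv_ml=icv_ml,
                    qc_dsc=score, qc_pass=score > config.qc_threshold,
                )
            )
        retained, qc_report = qc_gate(results, config.qc_threshold)
        icv_path = out / "icv.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            icv_path, index=False
        )
        artifacts["icv"] = icv_path
        logger.info(
            "measure: %d scans, %.0f%% passing QC, %d subjects with >= 1 pass",
            qc_report["n_scans"], 100 * qc_report["scan_retention"],
            qc_report["n_subjects_retained"],
        )
        _write_manifest(
            out, stage, None, {"qc_threshold": config.qc_threshold},
            {"icv": str(icv_path)}, qc_report,
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "analyze"
    try:
        report_dir = out / "report"
        report_dir.mkdir(exist_ok=True)
        report: dict = {}
        best = best_scan_per_wave(cohort)
        for w in ("20w", "30w"):
            try:
                fit = fit_wave_model(cohort, w)
                report[f"wave_{w}"] = {
                    "coefficients": fit.coefficients,
                    "std_errors": fit.std_errors,
                    "lrt_p": fit.lrt_p,
                    "n_obs": fit.n_obs,
                    "n_subjects": fit.n_subjects,
                }
            except ValueError as exc:
                report[f"wave_{w}"] = {"error": str(exc)}
        records = change_rates(best)
        if records:
            boys = [r.rate_ml_per_day for r in records if r.sex == "boy"]
            girls = [r.rate_ml_per_day for r in records if r.sex == "girl"]
            growth = {
                "n": len(records),
                "mean_rate_boys": float(np.mean(boys)) if boys else None,
                "mean_rate_girls": float(np.mean(girls)) if girls else None,
            }
            if len(boys) >= 2 and len(girls) >= 2:
                t, df, p = welch_t(boys, girls)
                growth.update({"welch_t": t, "welch_df": df, "welch_p": p})
            report["growth"] = growth
        (report_dir / "report.json").write_text(json.dumps(report, indent=2))
        lines = [f"fetalvol analysis report (v{__version__})", ""]
        for key, val in report.items():
            lines.append(f"[{key}]")
            lines.append(json.dumps(val, indent=2))
            lines.append("")
        (report_dir / "report.txt").write_text("\n".join(lines))
        artifacts["report"] = report_dir
        _write_manifest(
            out, stage, None, {"cohort": str(artifacts["cohort"])},
            {"report": str(report_dir)}, {"keys": sorted(report)},
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    artifacts["checksums"] = {
        name: _file_checksum(p)
        for name, p in artifacts.items()
        if isinstance(p, Path) and p.is_file()
    }
    return artifacts
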