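"""End-to-end runner: fuse -> split -> bootstrap selection -> final model -> test.

``run_pipeline`` executes the full discriminant workflow on either a
synthetic cohort or block CSV tables: the chosen blocks are fused, the
Kennard-Stone balanced split separates a model set from a test set, optional
bootstrap VIP or SR selection reduces the variables, a final PLS-DA model of
LOO-CV-selected complexity is fitted on the autoscaled model set, and the
test set is scored (AUC, sensitivity, specificity, efficiency).  The report
is a plain, JSON-serializable dict carrying every seed and cut-off, so two
runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluate import auc, confusion_metrics, overlap_stats
from .plsda import fit_plsda, predict, select_complexity_loo
from .preprocess import autoscale, fuse_blocks
from .selection import _encode_labels, bootstrap_plsda, sr_selection, vip_selection_rounds
from .split import balanced_split
from .synthetic import SyntheticSpec, generate_cohort
from .table import ConfigurationError, MetaboliteTable

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` or ``block_csvs`` must be given.
    ``criterion`` is ``"none"``, ``"vip"``, ``"sr"`` or ``"both"``.  With
    ``sr_cutoff=None`` the SR cut-off comes from the DIVA/MCCR test.
    """

    synthetic: SyntheticSpec | None = None
    block_csvs: dict[str, str] | None = None
    blocks: list[str] | None = None
    criterion: str = "none"
    vip_cutoff: float = 0.8
    vip_rounds: int = 3
    sr_cutoff: float | None = None
    mccr_threshold: float = 60.0
    split_fraction: float = 0.75
    B: int = 1000
    A_max: int = 5
    seed: int = 0
    positive_class: str | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.block_csvs is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' or 'block_csvs' must be provided"
            )
        if self.criterion not in ("none", "vip", "sr", "both"):
            raise ConfigurationError("criterion must be none|vip|sr|both")
        if self.B < 2:
            raise ConfigurationError("B must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        return cls(**raw)


def _load_table(config: PipelineConfig) -> MetaboliteTable:
    if config.synthetic is not None:
        table = generate_cohort(config.synthetic)
    else:
        tables = [MetaboliteTable.read_csv(p) for p in config.block_csvs.values()]
        table = fuse_blocks(tables)
    if config.blocks:
        table = table.select_blocks(config.blocks)
    return table


def _final_model_report(model_table, test_table, config, variables, label):
    """Fit the final PLS-DA on the selected variables and score the test set."""
    mt = model_table.select_variables(variables)
    tt = test_table.select_variables(variables)
    y, coding = _encode_labels(mt, config.positive_class)
    scaled, params = autoscale(mt)
    A = select_complexity_loo(mt.values, y, config.A_max)
    model = fit_plsda(scaled.values, y, A, scaling=params, y_coding=coding,
                      variable_names=variables)
    scores, pred = predict(model, tt.values)
    positive = next(k for k, v in coding.items() if v == 1)
    y_test = np.where(tt.group_labels == positive, 1.0, -1.0)
    report = confusion_metrics(pred, tt.group_labels, positive)
    report.auc_test = auc(scores, y_test)
    report.complexity = A
    report.variables = list(variables)

    boot = bootstrap_plsda(mt, A_max=config.A_max, B=config.B,
                           seed=config.seed, collect="none",
                           positive_class=config.positive_class)
    out = report.as_dict()
    out["model_auc_mean"] = round(boot.mean_auc, 4)
    out["model_auc_se"] = round(boot.se, 4)
    out["label"] = label
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured workflow and return the report bundle."""
    table = _load_table(config)
    plan = balanced_split(table, fraction=config.split_fraction)
    model_table = table.select_samples(plan.model_samples)
    test_table = table.select_samples(plan.test_samples)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "criterion": config.criterion,
            "blocks": config.blocks or table.blocks,
            "vip_cutoff": config.vip_cutoff,
            "vip_rounds": config.vip_rounds,
            "sr_cutoff": config.sr_cutoff,
            "mccr_threshold": config.mccr_threshold,
            "split_fraction": config.split_fraction,
            "B": config.B,
            "A_max": config.A_max,
            "seed": config.seed,
        },
        "split": {
            "model_ids": plan.model_ids,
            "test_ids": plan.test_ids,
            "model_sizes": {g: len(v) for g, v in plan.model_ids.items()},
            "test_sizes": {g: len(v) for g, v in plan.test_ids.items()},
        },
        "models": [],
    }

    selections: dict[str, list[str]] = {}
    if config.criterion in ("vip", "both"):
        sel = vip_selection_rounds(
            model_table, cutoff=config.vip_cutoff, rounds=config.vip_rounds,
            B=config.B, seed=config.seed, A_max=config.A_max,
            positive_class=config.positive_class,
        )
        selections["vip"] = sel.retained
        entry = _final_model_report(model_table, test_table, config,
                                    sorted(sel.retained,
                                           key=model_table.variable_names.index),
                                    "VIP-PLS-DA")
        entry["selection"] = {
            "criterion": sel.criterion,
            "cutoff": sel.cutoff,
            "rounds_applied": sel.rounds_applied,
            "identity": len(sel.retained) == model_table.n_variables,
            "audit": sel.audit,
        }
        report["models"].append(entry)
    if config.criterion in ("sr", "both"):
        sel, curve = sr_selection(
            model_table, cutoff=config.sr_cutoff, B=config.B, seed=config.seed,
            A_max=config.A_max, positive_class=config.positive_class,
            mccr_threshold=config.mccr_threshold,
        )
        selections["sr"] = sel.retained
        entry = _final_model_report(model_table, test_table, config,
                                    sorted(sel.retained,
                                           key=model_table.variable_names.index),
                                    "SR-PLS-DA")
        entry["selection"] = {
            "criterion": sel.criterion,
            "cutoff": sel.cutoff,
            "rounds_applied": sel.rounds_applied,
            "identity": len(sel.retained) == model_table.n_variables,
            "audit": sel.audit,
        }
        if curve is not None:
            entry["selection"]["mccr_curve"] = {
                "edges": curve.edges,
                "mccr": [round(m, 2) for m in curve.mccr],
                "threshold": curve.threshold,
            }
        report["models"].append(entry)
    if config.criterion == "none":
        entry = _final_model_report(model_table, test_table, config,
                                    list(model_table.variable_names), "PLS-DA")
        entry["selection"] = {"criterion": "none", "identity": True}
        report["models"].append(entry)

    if len(selections) == 2:
        report["overlap"] = overlap_stats(
            selections["vip"], selections["sr"], model_table.n_variables
        ).as_dict()
    return report


def write_report(report: dict, out_dir) -> None:
    """Write report.json plus flat CSV tables (performance, overlap)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

    with open(out / "performance.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model", "complexity", "model_auc_mean", "model_auc_se",
                    "auc_test", "sensitivity", "specificity", "efficiency",
                    "n_variables"])
        for m in report["models"]:
            w.writerow([
                m["label"], m.get("complexity"), m.get("model_auc_mean"),
                m.get("model_auc_se"), m.get("auc_test"),
                f"{m['sensitivity']:.2f}", f"{m['specificity']:.2f}",
                f"{m['efficiency']:.2f}", len(m.get("variables", [])),
            ])
    if "overlap" in report:
        with open(out / "overlap.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["common_count", "percent", "common_variables"])
            w.writerow([
                report["overlap"]["count"], report["overlap"]["percent"],
                ";".join(report["overlap"]["common"]),
            ])
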