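"""End-to-end study orchestration.

One YAML/dict config drives the whole workflow: load (or synthesize) a
compound table, assign the four-set split per replicate split (external
split labels in the input always win), optionally grid-search (T*, N*),
run the Monte Carlo probes, fit and validate the model on all four sets,
compute the applicability domain, classify promoters, run Y-randomization
and write the report files (prediction CSV, metrics JSON, promoter and
defect TSVs, scatter/residual plots).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .applicability_domain import ad_coverage, build_defect_table, in_domain, write_defect_report
from .cw_model import QsarModel, save_model
from .dataset_io import Dataset, apply_split, make_split, read_dataset, write_predictions
from .monte_carlo import OptimizerConfig, build_model, grid_search_TN, optimize, run_probes
from .smiles_attributes import profile_dataset
from .synthetic_data import GeneratorConfig, generate_dataset
from .validation import (
    MetricsReport,
    classify_promoters,
    evaluate_sets,
    write_promoter_report,
    y_randomization,
)

__all__ = ["RunManifest", "SplitResult", "load_config", "run_study", "report"]

DEFAULT_CONFIG: dict[str, Any] = {
    "data": {
        "path": None,
        "smiles_col": "smiles",
        "endpoint_col": "endpoint",
        "id_col": "id",
        "set_col": "set",
    },
    "generator": {},
    "splits": {
        "n_splits": 3,
        "proportions": [0.34, 0.35, 0.15, 0.16],
        "seed": 0,
    },
    "optimizer": {
        "T": 1,
        "n_epochs": 15,
        "iic_weight": 0.2,
        "dr_weight": 0.1,
        "init_low": 0.0,
        "init_high": 0.2,
        "step": 0.5,
        "seed": 0,
        "n_probes": 3,
        "use_bond": True,
    },
    "grid": {"enabled": False, "T_values": [1, 2, 3, 4, 5], "N_values": [5, 10, 15, 20, 30]},
    "y_randomization": {"n_shuffles": 10},
    "plots": True,
}


@dataclass
class SplitResult:
    split_index: int
    T_star: int
    N_star: int
    model: QsarModel
    probe_models: list[QsarModel]
    metrics: MetricsReport
    coverage: dict[str, float]
    trajectory: list[float]


@dataclass
class RunManifest:
    config: dict[str, Any]
    seeds: dict[str, int]
    splits: list[SplitResult]
    output_files: list[str]
    started: float
    finished: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "splits": [
                {
                    "split_index": s.split_index,
                    "T_star": s.T_star,
                    "N_star": s.N_star,
                    "c0": s.model.c0,
                    "c1": s.model.c1,
                    "metrics": s.metrics.to_dict(),
                    "ad_coverage": s.coverage,
                    "final_tfm": s.trajectory[-1],
                }
                for s in self.splits
            ],
            "output_files": self.output_files,
            "started": self.started,
            "finished": self.finished,
        }


def _merge(base: dict, override: Mapping | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict: str | Path | Mapping | None) -> dict[str, Any]:
    """Merge a YAML file or dict over the defaults."""
    if path_or_dict is None:
        override: Mapping | None = None
    elif isinstance(path_or_dict, Mapping):
        override = path_or_dict
    else:
        override = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    return _merge(DEFAULT_CONFIG, override)


def _load_or_generate(cfg: dict[str, Any]) -> Dataset:
    data_cfg = cfg["data"]
    if data_cfg.get("path"):
        return read_dataset(
            data_cfg["path"],
            smiles_col=data_cfg.get("smiles_col", "smiles"),
            endpoint_col=data_cfg.get("endpoint_col", "endpoint"),
            id_col=data_cfg.get("id_col"),
            set_col=data_cfg.get("set_col"),
        )
    gen_cfg = GeneratorConfig(**cfg.get("generator", {}))
    dataset, _ = generate_dataset(gen_cfg)
    return dataset


def run_study(
    config: str | Path | Mapping | None = None,
    out_dir: str | Path = "smilescw-out",
) -> RunManifest:
    """Execute the full study and write all artifacts under ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    outputs: list[str] = []

    dataset = _load_or_generate(cfg)
    profiles = profile_dataset(dataset)
    opt_cfg = OptimizerConfig(**cfg["optimizer"])
    split_cfg = cfg["splits"]
    n_splits = int(split_cfg.get("n_splits", 3))
    external_labels = dataset.has_labels()

    results: list[SplitResult] = []
    for split_i in range(1, n_splits + 1):
        if external_labels:
            labelled = dataset
            if split_i > 1:
                break  # externally labelled data defines a single split
        else:
            assignment = make_split(
                dataset,
                split_cfg.get("proportions", (0.34, 0.35, 0.15, 0.16)),
                seed=int(split_cfg.get("seed", 0)) + split_i,
            )
            labelled = apply_split(dataset, assignment)

        split_opt = replace(opt_cfg, seed=opt_cfg.seed + 100 * split_i)
        grid = cfg["grid"]
        if grid.get("enabled"):
            t_star, n_star = grid_search_TN(
                labelled,
                profiles,
                grid.get("T_values", (1, 2, 3, 4, 5)),
                grid.get("N_values", (5, 10, 15, 20, 30)),
                split_opt,
            )
            split_opt = replace(split_opt, T=t_star, n_epochs=n_star)
        else:
            t_star, n_star = split_opt.T, split_opt.n_epochs

        # probe 0 doubles as the reporting model; extra probes differ by seed
        table0, trajectory = optimize(labelled, profiles, split_opt)
        model = build_model(labelled, profiles, table0, split_opt)
        probes = [model]
        for i in range(1, split_opt.n_probes):
            cfg_i = replace(split_opt, seed=split_opt.seed + i)
            table_i, _ = optimize(labelled, profiles, cfg_i)
            probes.append(build_model(labelled, profiles, table_i, cfg_i))

        metrics = evaluate_sets(labelled, profiles, model)
        yr_cfg = cfg.get("y_randomization", {})
        n_shuffles = int(yr_cfg.get("n_shuffles", 10))
        mean_rr2, crp2, _ = y_randomization(
            labelled, profiles, split_opt, n_shuffles, real_model=model
        )
        metrics.mean_rr2 = mean_rr2
        metrics.crp2 = crp2

        defects = build_defect_table(labelled, profiles, T=split_opt.T, use_bond=split_opt.use_bond)
        coverage = ad_coverage(labelled, defects)
        promoters = classify_promoters(probes, labelled, profiles, defects)

        prefix = out / f"split{split_i}"
        predicted = {c.id: model.predict_one(profiles[c.id]) for c in labelled.compounds}
        ad_flags = {
            c.id: in_domain(defects.molecule_defects[c.id], defects.mean_training_defect)
            for c in labelled.compounds
        }
        outputs.append(str(write_predictions(labelled, predicted, ad_flags, prefix.with_suffix(".predictions.csv"))))
        outputs.append(str(write_defect_report(defects, prefix.with_suffix(".defects.tsv"))))
        outputs.append(str(write_promoter_report(promoters, prefix.with_suffix(".promoters.tsv"))))
        for p in save_model(model, out / f"split{split_i}.model"):
            outputs.append(str(p))
        metrics_path = prefix.with_suffix(".metrics.json")
        metrics_path.write_text(json.dumps(metrics.to_dict(), indent=2, sort_keys=True) + "\n")
        outputs.append(str(metrics_path))
        if cfg.get("plots", True):
            outputs.extend(
                str(p) for p in _plots(labelled, predicted, prefix)
            )

        results.append(
            SplitResult(
                split_index=split_i,
                T_star=t_star,
                N_star=n_star,
                model=model,
                probe_models=probes,
                metrics=metrics,
                coverage=coverage,
                trajectory=trajectory,
            )
        )

    manifest = RunManifest(
        config=cfg,
        seeds={"split": int(split_cfg.get("seed", 0)), "optimizer": opt_cfg.seed},
        splits=results,
        output_files=outputs,
        started=started,
        finished=time.time(),
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True, default=float) + "\n"
    )
    return manifest


def _plots(dataset: Dataset, predicted: Mapping[str, float], prefix: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = np.array([c.endpoint for c in dataset.compounds])
    pred = np.array([predicted[c.id] for c in dataset.compounds])
    labels = [c.set_label or "" for c in dataset.compounds]
    paths = []
    for kind in ("scatter", "residual"):
        fig, ax = plt.subplots(figsize=(5, 4))
        ydata = obs if kind == "scatter" else obs - pred
        for label in sorted(set(labels)):
            mask = np.array([l == label for l in labels])
            ax.scatter(pred[mask], ydata[mask], s=12, label=label or "unlabelled", alpha=0.7)
        if kind == "scatter":
            lims = [min(obs.min(), pred.min()), max(obs.max(), pred.max())]
            ax.plot(lims, lims, "k--", lw=0.8)
            ax.set_ylabel("experimental pIC50")
        else:
            ax.axhline(0.0, color="k", ls="--", lw=0.8)
            ax.set_ylabel("residual pIC50")
        ax.set_xlabel("predicted pIC50")
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = prefix.with_suffix(f".{kind}.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def report(manifest: RunManifest) -> str:
    """Human-readable per-split, per-set metric table."""
    lines = []
    for s in manifest.splits:
        lines.append(f"Split {s.split_index}  (T*={s.T_star}, N*={s.N_star}, "
                     f"pIC50 = {s.model.c0:.4f} + {s.model.c1:.4f}·DCW)")
        header = (
            f"{'set':<18}{'n':>5}{'R2':>9}{'CCC':>9}{'IIC':>9}{'Q2':>9}"
            f"{'QF1':>9}{'QF2':>9}{'QF3':>9}{'Rm2':>9}{'s':>8}{'MAE':>8}{'F':>9}"
        )
        lines.append(header)
        for label, m in s.metrics.per_set.items():
            def fmt(v, w=9):
                return f"{v:>{w}.4f}" if v is not None else " " * w
            lines.append(
                f"{label:<18}{m.n:>5}{fmt(m.r2)}{fmt(m.ccc)}{fmt(m.iic)}{fmt(m.q2)}"
                f"{fmt(m.qf1)}{fmt(m.qf2)}{fmt(m.qf3)}{fmt(m.rm2)}"
                f"{fmt(m.s, 8)}{fmt(m.mae, 8)}{fmt(m.f)}"
            )
        if s.metrics.crp2 is not None:
            lines.append(
                f"{'Y-randomization':<18} mean Rr2 = {s.metrics.mean_rr2:.4f}, "
                f"CRp2 = {s.metrics.crp2:.4f}"
            )
        cov = ", ".join(f"{k}: {v:.1f}%" for k, v in s.coverage.items())
        lines.append(f"{'AD coverage':<18} {cov}")
        lines.append("")
    return "\n".join(lines)
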