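"""End-to-end orchestration: simulate → fit → hierarchy → trajectory.

Each stage writes its outputs before the next starts; a JSON report
records per-stage timings, output checksums, the seed and a hash of the
configuration, plus the headline tables (threshold hierarchy, gaps,
slope summary).  A ``provenance.json`` sidecar in the output directory
carries the config hash, seed and package version for every file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .data_model import (
    KATZ_ITEMS,
    PanelDataset,
    apply_inclusion_filter,
    load_panel,
    standardize_covariates,
    write_exclusion_report,
    write_panel,
)
from .grm import item_parameters_to_json
from .hierarchy import (
    applicability_check,
    classify_discrimination,
    entries_from_item_parameters,
    rank_thresholds,
    threshold_gap,
)
from .lirt import McmcConfig, convergence_diagnostics, run_mcmc, summarize_posterior
from .synthetic import GeneratorConfig, generate_dataset, write_truth
from .trajectory import (
    DEFAULT_FIXED_TERMS,
    extract_scored_visits,
    fit_mixed_model,
    group_trajectories,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a replay hint."""

    def __init__(self, stage: str, replay: str, cause: BaseException):
        super().__init__(
            f"pipeline stage {stage!r} failed ({cause}); replay with: {replay}"
        )
        self.stage = stage
        self.replay = replay
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Configuration of a full run; CLI flags override file values."""

    out_dir: Path = Path("pipeline_out")
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    hierarchy_scheme: str = "baker_logistic"
    trajectory_grouping: str = "sex_residence"
    trajectory_terms: tuple[str, ...] = DEFAULT_FIXED_TERMS
    min_age: float = 60.0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        if "out_dir" in raw:
            cfg.out_dir = Path(raw["out_dir"])
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        for section, target in (("generator", cfg.generator), ("mcmc", cfg.mcmc)):
            for k, v in raw.get(section, {}).items():
                if not hasattr(target, k):
                    raise ValueError(f"unknown {section} option {k!r}")
                setattr(target, k, v)
        cfg.hierarchy_scheme = raw.get("hierarchy_scheme", cfg.hierarchy_scheme)
        cfg.trajectory_grouping = raw.get("trajectory_grouping", cfg.trajectory_grouping)
        if "trajectory_terms" in raw:
            cfg.trajectory_terms = tuple(raw["trajectory_terms"])
        cfg.min_age = float(raw.get("min_age", cfg.min_age))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def propagate_seed(self) -> None:
        """Derive per-stage seeds deterministically from the global seed."""
        self.generator.seed = self.seed
        self.mcmc.seed = self.seed + 1

    def hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages in order; returns (and writes) the run report."""
    config.propagate_seed()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "stages": {},
    }

    def finish_stage(name: str, t0: float, files: list[Path]) -> None:
        report["stages"][name] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # ---- stage 1: simulate -------------------------------------------
    t0 = time.time()
    try:
        dataset, truth = generate_dataset(config.generator)
        resp_path = out / "responses.csv"
        subj_path = out / "subjects.csv"
        write_panel(dataset, resp_path, subj_path)
        write_truth(truth, out / "truth.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", f"adlirt simulate --seed {config.seed}", e)
    finish_stage("simulate", t0, [resp_path, subj_path, out / "truth.json"])

    # ---- stage 2: fit-lirt -------------------------------------------
    t0 = time.time()
    try:
        panel = load_panel(resp_path, subj_path)
        panel, exclusions = apply_inclusion_filter(panel, min_age=config.min_age)
        write_exclusion_report(exclusions, out / "exclusions.json")
        standardize_covariates(panel)
        chains = run_mcmc(panel, config.mcmc)
        summary = summarize_posterior(chains)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        diag = convergence_diagnostics(chains)
        diag.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
        np.savez_compressed(out / "chains.npz", **chains.structural)
        item_params = chains.item_parameters()
        item_parameters_to_json(item_params, out / "item_parameters.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(
            "fit-lirt",
            f"adlirt fit-lirt --responses {resp_path} --subjects {subj_path} "
            f"--seed {config.seed}",
            e,
        )
    finish_stage(
        "fit-lirt",
        t0,
        [
            out / "exclusions.json",
            out / "summary.tsv",
            out / "diagnostics.tsv",
            out / "item_parameters.json",
        ],
    )

    # ---- stage 3: hierarchy ------------------------------------------
    t0 = time.time()
    try:
        entries = entries_from_item_parameters(item_params)
        ranked = rank_thresholds(entries)
        hier_rows = [
            {"rank": i + 1, "item": e.item.value, "level": e.level, "kappa": e.kappa}
            for i, e in enumerate(ranked)
        ]
        gaps = {it.value: threshold_gap(entries, it) for it in KATZ_ITEMS}
        applic = applicability_check(item_params)
        import pandas as pd

        pd.DataFrame(hier_rows).to_csv(out / "hierarchy.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"item": k, "gap": v} for k, v in gaps.items()]
        ).to_csv(out / "gaps.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "item": it.value,
                    "alpha": item_params[it].alpha,
                    "band": classify_discrimination(
                        item_params[it].alpha, config.hierarchy_scheme
                    ),
                    "applicable": applic["per_item"][it.value],
                }
                for it in KATZ_ITEMS
            ]
        ).to_csv(out / "discrimination.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(
            "hierarchy", f"adlirt hierarchy --summary {out / 'summary.tsv'}", e
        )
    finish_stage(
        "hierarchy", t0, [out / "hierarchy.tsv", out / "gaps.tsv", out / "discrimination.tsv"]
    )

    # ---- stage 4: trajectory -----------------------------------------
    t0 = time.time()
    try:
        import pandas as pd

        visits = extract_scored_visits(chains, panel)
        fit = fit_mixed_model(visits, terms=config.trajectory_terms)
        pd.DataFrame(
            [
                {"term": t, "estimate": fit.fixed_effects[t], "se": fit.se[t]}
                for t in fit.terms
            ]
        ).to_csv(out / "mixed_fit.tsv", sep="\t", index=False)
        curves = group_trajectories(visits, fit, grouping=config.trajectory_grouping)
        curves_path = out / f"curves_{config.trajectory_grouping}.tsv"
        curves["curves"].to_csv(curves_path, sep="\t", index=False)
        obs_path = out / f"observed_{config.trajectory_grouping}.tsv"
        curves["observed"].to_csv(obs_path, sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(
            "trajectory", f"adlirt trajectory --out-dir {out} --seed {config.seed}", e
        )
    finish_stage("trajectory", t0, [out / "mixed_fit.tsv", curves_path, obs_path])

    # ---- headline numbers + provenance --------------------------------
    report["headline"] = {
        "n_subjects": panel.n_subjects,
        "gaps": gaps,
        "hierarchy_first": f"{ranked[0].item.value}_{ranked[0].level}",
        "hierarchy_last": f"{ranked[-1].item.value}_{ranked[-1].level}",
        "mu_posterior_mean": float(summary.loc[summary.parameter == "mu", "mean"].iloc[0]),
        "applicability": applic["overall"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    provenance = {
        "config_hash": report["config_hash"],
        "seed": config.seed,
        "version": __version__,
        "files": {
            name: info
            for stage in report["stages"].values()
            for name, info in stage["outputs"].items()
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return report
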