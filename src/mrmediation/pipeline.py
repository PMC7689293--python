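"""End-to-end analysis pipeline: config, orchestration and reporting.

Runs the full workflow for each exposure–outcome pair — harmonization
audit, instrument summary, univariable MR with diagnostics, multivariable
MR conditioned on the mediator, mediation report, directionality test,
genetic correlation, and (when a cohort is available) individual-level
two-stage estimates — writing one TSV per table plus a machine-readable
JSON of all estimates and a run log with seeds and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import ivw, mr_report
from .instruments import LDReference, clump, combined_instrument, prs_model
from .ldsc import compute_ld_scores, rg_regression
from .mvmr import mediate, mvmr_fit
from .simulate import (
    SimulationTruth,
    TwoSampleStudy,
    make_two_sample,
    simulate_cohort,
)
from .steiger import steiger_test
from .sumstats import SummaryStats, harmonize, harmonize_many, read_sumstats
from .twostage import TwoStageError, two_stage

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML.

    File-based runs give paths (and optional column maps) for the exposure,
    mediator and outcome summary statistics plus an LD reference; synthetic
    runs set ``simulate: true`` and optionally override truth parameters.
    """

    outdir: str = "mr_output"
    seed: int = 0
    simulate: bool = True
    truth_overrides: dict = field(default_factory=dict)
    n_exposure: int = 20_000
    n_outcome: int = 20_000
    n_cohort: int = 0  # individual-level cohort size; 0 disables 2SPS
    exposure: str = "smoking"
    mediator: str = "bmi"
    outcomes: list = field(default_factory=lambda: ["t2d", "cad"])
    # file-based inputs (used when simulate is false)
    exposure_path: str | None = None
    mediator_path: str | None = None
    outcome_paths: dict = field(default_factory=dict)
    ld_path: str | None = None
    exposure_type: str = "binary"
    mediator_type: str = "continuous"
    outcome_types: dict = field(default_factory=dict)
    # thresholds
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    window_bp: int = 250_000
    palindrome_eaf_window: float = 0.08
    n_boot: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analytic settings (the output location is excluded,
        so reruns into different directories compare equal)."""
        settings = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = yaml.safe_dump(settings, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _load_study(config: PipelineConfig) -> TwoSampleStudy:
    if config.simulate:
        truth = SimulationTruth.generate(seed=config.seed, **config.truth_overrides)
        return make_two_sample(
            truth,
            config.n_exposure,
            config.n_outcome,
            seed=config.seed,
            exposure_traits=(config.exposure, config.mediator),
            outcome_traits=tuple(config.outcomes),
        )
    if not (config.exposure_path and config.mediator_path and config.ld_path):
        raise ValueError("file-based run needs exposure_path, mediator_path, ld_path")
    exposure = read_sumstats(
        config.exposure_path, trait_type=config.exposure_type,
        trait_name=config.exposure,
    )
    mediator = read_sumstats(
        config.mediator_path, trait_type=config.mediator_type,
        trait_name=config.mediator,
    )
    outcomes = {
        name: read_sumstats(
            path, trait_type=config.outcome_types.get(name, "binary"),
            trait_name=name,
        )
        for name, path in config.outcome_paths.items()
    }
    ld = LDReference.read_tsv(config.ld_path)
    truth = None
    return TwoSampleStudy(
        exposure={config.exposure: exposure, config.mediator: mediator},
        outcome=outcomes,
        ld=ld,
        truth=truth,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns the report dictionary (also written as estimates.json).  A
    stage failure keeps earlier outputs on disk and re-raises with the
    stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "pairs": {},
    }
    stage = "load"
    try:
        study = _load_study(config)
        exp_name, med_name = config.exposure, config.mediator
        exp_stats = study.exposure[exp_name]
        med_stats = study.exposure[med_name]

        stage = "instrument"
        inst = clump(
            exp_stats, study.ld, config.p_threshold, config.r2_threshold,
            config.window_bp,
        )
        inst.to_tsv(outdir / "instrument_exposure.tsv")
        med_inst = clump(
            med_stats, study.ld, config.p_threshold, config.r2_threshold,
            config.window_bp,
        )
        union_ids = combined_instrument(
            [exp_stats, med_stats], study.ld, config.p_threshold,
            config.r2_threshold, config.window_bp,
        )
        pd.DataFrame(
            [inst.summary(), med_inst.summary()]
        ).to_csv(outdir / "instrument_summary.tsv", sep="\t", index=False)
        report["instruments"] = {
            exp_name: inst.summary(),
            med_name: med_inst.summary(),
            "combined_k": len(union_ids),
        }

        mr_rows, med_rows, steiger_rows, rg_rows = [], [], [], []
        for out_name, out_stats in study.outcome.items():
            if out_name == med_name:
                continue
            stage = f"mr:{out_name}"
            h = harmonize(
                exp_stats.subset(inst.snp_ids), out_stats,
                config.palindrome_eaf_window,
            )
            h.to_tsv(outdir / f"harmonized_{exp_name}_{out_name}.tsv")
            rep = mr_report(h, n_boot=config.n_boot, seed=config.seed)
            for row in rep["estimates"]:
                mr_rows.append({"exposure": exp_name, "outcome": out_name, **row})
            pair: dict = {
                "mr": rep["estimates"],
                "diagnostics": rep["diagnostics"],
                "harmonization": h.data["action"].value_counts().to_dict(),
            }

            stage = f"mvmr:{out_name}"
            h_multi = harmonize_many(
                [exp_stats.subset(union_ids), med_stats.subset(union_ids)],
                out_stats, config.palindrome_eaf_window,
            )
            mv = mvmr_fit(h_multi)
            med_res = mediate(
                rep["ivw"], mv, exp_name, out_name,
                outcome_type=out_stats.trait_type,
            )
            med_rows.append(med_res.as_row())
            pair["mvmr"] = {
                name: est.as_row() for name, est in mv.estimates.items()
            }
            pair["mvmr_conditional_f"] = mv.conditional_f
            pair["mediation"] = med_res.as_row()

            stage = f"steiger:{out_name}"
            st = steiger_test(h)
            steiger_rows.append(
                {"exposure": exp_name, "outcome": out_name, **st.as_row()}
            )
            pair["steiger"] = st.as_row()

            stage = f"rg:{out_name}"
            shared = exp_stats.data.merge(
                out_stats.data, on="snp_id", suffixes=("_e", "_o")
            )
            if len(shared) >= 200:
                scores = compute_ld_scores(study.ld, shared["snp_id"].tolist())
                z1 = (shared["beta_e"] / shared["se_e"]).to_numpy()
                z2 = (shared["beta_o"] / shared["se_o"]).to_numpy()
                rg = rg_regression(
                    z1, z2, float(shared["n_e"].median()),
                    float(shared["n_o"].median()), scores,
                )
                rg_rows.append(rg.as_row(p1=exp_name, p2=out_name))
                pair["rg"] = rg.as_row(p1=exp_name, p2=out_name)
            report["pairs"][f"{exp_name}~{out_name}"] = pair

        pd.DataFrame(mr_rows).to_csv(outdir / "mr_results.tsv", sep="\t", index=False)
        pd.DataFrame(med_rows).to_csv(
            outdir / "mvmr_mediation.tsv", sep="\t", index=False
        )
        pd.DataFrame(steiger_rows).to_csv(
            outdir / "steiger.tsv", sep="\t", index=False
        )
        if rg_rows:
            pd.DataFrame(rg_rows).to_csv(outdir / "rg.tsv", sep="\t", index=False)

        if config.simulate and config.n_cohort > 0:
            stage = "twostage"
            cohort = simulate_cohort(
                study.truth, config.n_cohort, seed=config.seed + 1
            )
            smk_prs = prs_model(inst)
            # mediator reweighting loses palindromic/unmatched variants;
            # tolerate up to half before calling the weight source unusable
            bmi_prs = prs_model(inst, weights_from=med_stats, max_missing=0.5)
            ts_rows = []
            for out_name in ["bmi"] + [o for o in config.outcomes if o != "bmi"]:
                total = two_stage(cohort, smk_prs, out_name)
                ts_rows.append({"model": "total", **total.as_row()})
                if out_name != "bmi":
                    adj = two_stage(cohort, smk_prs, out_name, bmi_weights=bmi_prs)
                    ts_rows.append({"model": "adjusted", **adj.as_row()})
            pd.DataFrame(ts_rows).to_csv(
                outdir / "twostage.tsv", sep="\t", index=False
            )
            report["twostage"] = ts_rows

        stage = "report"
        report_json = _jsonable(report)
        with open(outdir / "estimates.json", "w") as fh:
            json.dump(report_json, fh, indent=2, sort_keys=True)
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write(
                f"mrmediation {__version__}\n"
                f"python {platform.python_version()} numpy {np.__version__} "
                f"pandas {pd.__version__}\n"
                f"seed {config.seed}\nconfig_hash {config.digest()}\n"
            )
        config.to_yaml(outdir / "config_used.yaml")
        return report_json
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise PipelineStageError(stage) from exc


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str):
        super().__init__(f"pipeline failed at stage {stage!r}")
        self.stage = stage


def demo(outdir: str | Path, seed: int = 0, scale: str = "full") -> dict:
    """Single-command synthetic vignette.

    ``scale="full"`` uses the generator defaults (M = 5000 variants,
    cohorts of 20 000); ``"small"`` is a 1/4-size run for quick smoke
    tests.
    """
    overrides = {}
    n = 20_000
    n_cohort = 20_000
    if scale == "small":
        overrides = {"m_snps": 1500, "n_causal_smk": 90, "n_causal_bmi": 90}
        n = 8000
        n_cohort = 8000
    config = PipelineConfig(
        outdir=str(outdir), seed=seed, simulate=True,
        truth_overrides=overrides, n_exposure=n, n_outcome=n, n_cohort=n_cohort,
    )
    return run_pipeline(config)
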