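"""End-to-end orchestration of the full analysis.

Reads (or receives) a pedigree, applies the infection-exclusion flag,
runs the change-score analysis, the kinship-correlation table, age/sex
residualization, the ordered list of variance-component model fits with
comparisons against the fullest model, and writes one machine-readable
report plus human-readable tables (sample composition, kinship
correlations, variance components, model comparison).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from qolped.changescore import change_summary_for_pedigree
from qolped.kincor import kinship_correlation_table
from qolped.pedigree import Pedigree, read_pedigree
from qolped.simulate import summarize_sample
from qolped.varcomp import FitResult, ModelSpec, compare, fit, residualize_pedigree

logger = logging.getLogger("qolped")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class PipelineConfig:
    pedigree_path: str | Path
    apply_exclusions: bool = True
    models: tuple[str, ...] = ("ACDE", "ACE", "ADE", "AE")
    seed: int = 0
    output_dir: str | Path = "qolped_report"
    standard_errors: bool = True
    alpha: float = 0.05

    def __post_init__(self):
        if not self.models:
            raise ValueError("models must be non-empty")


def _setup_logging(outdir: Path):
    logger.setLevel(logging.INFO)
    for h in list(logger.handlers):
        logger.removeHandler(h)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "pipeline.log")):
        h.setFormatter(fmt)
        logger.addHandler(h)


def run_pipeline(config: PipelineConfig, ped: Pedigree | None = None) -> dict:
    """Execute the full pipeline; returns the report dict and writes
    report.json plus table1/table2/table3/model_comparison TSVs to the
    output directory.  Deterministic given data and seed."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    import qolped

    report: dict = {"version": qolped.__version__, "seed": config.seed, "stages": {}}
    stage = "read"
    try:
        t0 = time.time()
        if ped is None:
            ped = read_pedigree(config.pedigree_path, )
        n_before = ped.n_phenotyped
        if config.apply_exclusions:
            stage = "exclusions"
            ped = ped.drop_excluded()
        report["sample"] = {
            "n_individuals": ped.n_phenotyped,
            "n_excluded_covid": n_before - ped.n_phenotyped,
            "n_families": ped.n_families,
        }
        logger.info("read %d phenotyped individuals in %d families (%d excluded)",
                    ped.n_phenotyped, ped.n_families, n_before - ped.n_phenotyped)

        stage = "composition"
        table1 = summarize_sample(ped)
        table1.to_csv(outdir / "table1.tsv", sep="\t", index=False)

        stage = "changescore"
        report["changescore"] = change_summary_for_pedigree(ped, seed=config.seed)
        logger.info("change scores: %s", report["changescore"]["change"])

        stage = "kincor"
        table2 = kinship_correlation_table(ped)
        table2.to_csv(outdir / "table2.tsv", sep="\t", index=False)
        report["kinship_correlations"] = table2.to_dict("records")

        stage = "residualize"
        resid = residualize_pedigree(ped)

        stage = "varcomp"
        fits: dict[str, FitResult] = {}
        for label in config.models:
            t1 = time.time()
            fits[label] = fit(
                resid, ModelSpec.from_label(label), seed=config.seed,
                standard_errors=config.standard_errors,
            )
            logger.info("fit %s: loglik=%.3f (%.1fs)", label,
                        fits[label].loglik, time.time() - t1)
        report["fits"] = {k: f.to_dict() for k, f in fits.items()}

        stage = "compare"
        full_label = max(config.models, key=lambda m: len(m))
        comparisons = []
        for label, f in fits.items():
            if label == full_label:
                continue
            chi2, df, p = compare(fits[full_label], f)
            comparisons.append(
                {"full": full_label, "nested": label, "chi2": chi2, "df": df, "p": p}
            )
        report["model_comparison"] = comparisons
        # most parsimonious model not rejected against the full one
        keep = [c for c in comparisons if c["p"] >= config.alpha]
        if keep:
            best = min(keep, key=lambda c: (3 * len(c["nested"]) + 2, -c["p"]))["nested"]
        else:
            best = full_label
        report["best_model"] = best
        logger.info("best model: %s", best)

        stage = "write"
        pd.DataFrame(comparisons).to_csv(outdir / "model_comparison.tsv", sep="\t", index=False)
        _write_table3(fits[best], outdir / "table3.tsv")
        report["timing_seconds"] = round(time.time() - t0, 2)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        return report
    except Exception as e:  # noqa: BLE001 - abort with stage + partial manifest
        if isinstance(e, PipelineError):
            raise
        with open(outdir / "partial_manifest.json", "w") as fh:
            json.dump({"failed_stage": stage, "completed": list(report)}, fh, indent=2)
        raise PipelineError(stage, e, report) from e


def _write_table3(fitres: FitResult, path: Path):
    rows = []
    for comp in fitres.spec.components:
        cm = fitres.estimates[comp]
        rows.append(
            {
                "component": comp,
                "v_pre": cm.v_pre, "se_v_pre": cm.se_v_pre,
                "v_pan": cm.v_pan, "se_v_pan": cm.se_v_pan,
                "cov": cm.cov, "se_cov": cm.se_cov,
                "std_pre": fitres.standardized[comp]["pre"],
                "std_pan": fitres.standardized[comp]["pan"],
                "cov_share": fitres.covariance_shares[comp],
                "cross_time_corr": fitres.component_corr[comp],
            }
        )
    rows.append(
        {
            "component": "P",
            "v_pre": fitres.total_var[0], "v_pan": fitres.total_var[1],
            "cov": fitres.total_cov,
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
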