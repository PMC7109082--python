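"""End-to-end orchestration: footprints -> variants -> TMB -> concordance -> regression.

Runs the whole analysis from files (annotation GTF, panel gene lists,
per-sample VCFs, sample metadata) and writes the report bundle: footprint
summary, per-sample profiles, the confusion grid over the cut-off sweep, ROC
summaries with calibrated cut-points, the ML~TMB regressions, a JSON summary
and a run log with versions, seed and input digests. The analysis itself is
deterministic; identical inputs give byte-identical machine-readable output.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    ExomeModel,
    PanelDesign,
    build_exome_model,
    build_panel_footprint,
    read_gene_models,
    read_panel_gene_list,
    write_footprint_bed,
    write_footprint_summary,
)
from .concordance import (
    PAN_CANCER,
    DEFAULT_CUTOFFS,
    roc_summary_frames,
    table1_frame,
)
from .regression import RegressionError, fit_ml_vs_tmb, predict_ml
from .tmb import build_profiles, read_profiles_tsv, write_profiles_tsv
from .variants import read_somatic_vcf

logger = logging.getLogger("paneltmb")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    annotation: Path
    panels_dir: Path
    vcf_dir: Path
    metadata: Path
    out_dir: Path
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    exome_cutoff: float = 10.0
    exome_denominator_mb: float | str = 30.0
    stratify_types: tuple[str, ...] | None = None
    ns_key: str = "NS"
    nonsynonymous_only: bool = False
    regression_tmb: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cutoffs = tuple(sorted(float(c) for c in self.cutoffs))
        if any(c <= 0 for c in self.cutoffs):
            raise PipelineError("cutoffs must be positive")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def read_metadata(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "tumour_type"} - set(df.columns)
    if missing:
        raise PipelineError(
            f"metadata {path} missing column(s): {', '.join(sorted(missing))}"
        )
    return df


def load_panels(panels_dir: Path, annotation) -> list[PanelDesign]:
    paths = sorted(Path(panels_dir).glob("*.txt"))
    if not paths:
        raise PipelineError(f"no panel gene lists (*.txt) found in {panels_dir}")
    panels = []
    for p in paths:
        design = build_panel_footprint(p.stem, read_panel_gene_list(p), annotation)
        logger.info(
            "panel %s: %d genes matched, %d unmatched, footprint %.4f Mb",
            design.name, len(design.matched_genes), len(design.unmatched_genes),
            design.footprint_mb,
        )
        panels.append(design)
    return panels


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    logger.info("paneltmb %s, seed %d", __version__, config.seed)
    for name in ("annotation", "metadata"):
        path = Path(getattr(config, name))
        logger.info("input %s: %s sha256:%s", name, path, _digest(path))

    try:
        annotation = read_gene_models(config.annotation)
    except Exception as exc:
        raise PipelineError(f"stage footprint: cannot read annotation: {exc}") from exc
    panels = load_panels(config.panels_dir, annotation)
    exome = build_exome_model(annotation, config.exome_denominator_mb)
    logger.info(
        "exome: %.4f Mb CDS union, %.4f Mb denominator", exome.regions_mb,
        exome.denominator_mb,
    )
    write_footprint_summary(panels, out / "footprint_summary.tsv")
    for p in panels:
        write_footprint_bed(p, out / f"footprint_{p.name}.bed")

    meta = read_metadata(Path(config.metadata))
    tumour_types = dict(zip(meta["sample_id"], meta["tumour_type"]))
    variants_by_sample = {}
    for sid in meta["sample_id"]:
        vcf_path = Path(config.vcf_dir) / f"{sid}.vcf"
        if not vcf_path.exists():
            vcf_path = vcf_path.with_suffix(".vcf.gz")
        if not vcf_path.exists():
            raise PipelineError(f"stage variants: no VCF for sample {sid}")
        variants_by_sample[sid] = read_somatic_vcf(vcf_path, sid, config.ns_key)
    n_variants = sum(len(v) for v in variants_by_sample.values())
    logger.info("read %d variants across %d samples", n_variants, len(meta))

    with_ml = all(
        v.non_synonymous is not None
        for vs in variants_by_sample.values()
        for v in vs
    )
    if not with_ml:
        logger.warning(
            "non-synonymous annotation absent for some variants; "
            "mutational load and regression stages skipped"
        )
    try:
        profiles = build_profiles(
            variants_by_sample, tumour_types, panels, exome,
            with_ml=with_ml, nonsynonymous_only=config.nonsynonymous_only,
        )
    except Exception as exc:
        raise PipelineError(f"stage tmb: {exc}") from exc
    write_profiles_tsv(profiles, out / "profiles.tsv")

    panel_names = [p.name for p in panels]
    table1 = table1_frame(profiles, panel_names, config.cutoffs)
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)

    strata = [PAN_CANCER] + sorted(
        set(config.stratify_types)
        if config.stratify_types
        else set(meta["tumour_type"])
    )
    auc_df, roc_points, skipped = roc_summary_frames(
        profiles, panel_names, config.exome_cutoff, strata
    )
    for s in skipped:
        logger.warning("stratum %r skipped: only one exome class (ROC undefined)", s)
    auc_df.to_csv(out / "auc_summary.tsv", sep="\t", index=False)
    roc_points.to_csv(out / "roc_points.tsv", sep="\t", index=False)
    cutpoints = auc_df[auc_df["stratum"] == PAN_CANCER][
        ["panel", "optimal_cutpoint", "optimal_accuracy", "auc"]
    ]
    cutpoints.to_csv(out / "calibrated_cutpoints.tsv", sep="\t", index=False)

    regression_rows = []
    if with_ml:
        for ttype in sorted(set(meta["tumour_type"])):
            try:
                fit = fit_ml_vs_tmb(profiles, ttype)
            except RegressionError as exc:
                logger.warning("stage regression: %s", exc)
                continue
            regression_rows.append(
                {
                    "tumour_type": ttype,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n": fit.n,
                    f"ml_at_tmb{config.regression_tmb:g}": predict_ml(
                        fit, config.regression_tmb
                    ),
                }
            )
        pd.DataFrame(regression_rows).to_csv(
            out / "regression_summary.tsv", sep="\t", index=False
        )

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": len(profiles),
        "n_variants": n_variants,
        "exome_denominator_mb": exome.denominator_mb,
        "panels": {
            p.name: {
                "footprint_mb": p.footprint_mb,
                "n_genes_matched": len(p.matched_genes),
                "n_genes_unmatched": len(p.unmatched_genes),
            }
            for p in panels
        },
        "misclassified_pct": {
            f"{row.panel}@{row.cutoff:g}": row.misclassified_pct
            for row in table1.itertuples()
        },
        "auc": {
            f"{row.panel}@{row.stratum}": row.auc for row in auc_df.itertuples()
        },
        "calibrated_cutpoints": {
            row.panel: row.optimal_cutpoint for row in cutpoints.itertuples()
        },
        "regression": regression_rows,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("report bundle written to %s", out)
    return summary
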