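"""File formats, run configuration and the end-to-end orchestrator.

Formats are plain text throughout: pedigree PED-style, expression as a
samples × probes TSV plus a probe-annotation TSV (probe_id, is_control,
gene_symbol), phenotypes as CSV, gene sets as GMT, machine-readable
summaries as JSON.

All randomness in a run flows from the single top-level seed, expanded
per stage as ``default_rng([seed, stage_index])`` so any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssociationResult, transcriptome_scan
from .bivariate import bivariate_scan
from .detection import DetectionInputError, RawExpressionStudy, detect_expressed
from .enrichment import GeneSetCollection, collapse_to_genes, enrich, read_gmt
from .normalization import normalize_expression
from .pedigree import (
    compute_kinship,
    read_pedigree,
    write_block_manifest,
    write_kinship_tsv,
    write_pedigree,
)
from .simulate import (
    SimulationConfig,
    make_synthetic_gmt,
    simulate_study,
    write_gmt,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters for a full pipeline run."""

    out_dir: str = "pedexpress_run"
    seed: int = 0
    # input paths; all None means simulate first
    pedigree_path: str | None = None
    expression_path: str | None = None
    probe_annotation_path: str | None = None
    phenotype_path: str | None = None
    gmt_path: str | None = None
    # stage parameters
    detect_fdr: float = 0.05
    detect_quantile: float = 0.95
    pooled_null: bool = False
    n_bins: int = 10
    inverse_normal_offset: str = "blom"
    exposure: str = "smoker"
    scan_fdr: float = 0.05
    covariates: tuple[str, ...] = ("sex", "age", "agexsex")
    bivar_top: int = 50
    bivar_qmc: int = 256
    enrich_fdr: float = 0.05
    allow_missing: bool = False
    simulate: SimulationConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim)
        if isinstance(cfg.covariates, list):
            cfg.covariates = tuple(cfg.covariates)
        return cfg

    def validate_preflight(self) -> None:
        """Check every stage's preconditions before any compute."""
        if self.simulate is None:
            for name in ("pedigree_path", "expression_path",
                         "probe_annotation_path", "phenotype_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} required when not simulating")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
        for name in ("detect_fdr", "scan_fdr", "enrich_fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.detect_quantile < 1.0:
            raise ValueError("detect_quantile must be in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


# ---------------------------------------------------------------------------
# readers / writers


def write_expression_tsv(study: RawExpressionStudy, matrix_path, annotation_path) -> None:
    pd.DataFrame(
        study.signal, index=study.sample_ids, columns=study.probe_ids
    ).to_csv(matrix_path, sep="\t", index_label="sample_id")
    pd.DataFrame(
        {
            "probe_id": study.probe_ids,
            "is_control": study.is_control.astype(int),
            "gene_symbol": [study.gene_map.get(p, "") for p in study.probe_ids],
        }
    ).to_csv(annotation_path, sep="\t", index=False)


def read_expression_tsv(matrix_path, annotation_path) -> RawExpressionStudy:
    mat = pd.read_csv(matrix_path, sep="\t", index_col="sample_id",
                      float_precision="round_trip")
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"probe_id": str})
    ann = ann.set_index("probe_id").loc[list(mat.columns)]
    gene_map = {
        p: str(g)
        for p, g in ann["gene_symbol"].items()
        if isinstance(g, str) and g.strip() or (not pd.isna(g) and str(g).strip())
    }
    return RawExpressionStudy(
        sample_ids=[str(s) for s in mat.index],
        probe_ids=[str(p) for p in mat.columns],
        signal=mat.to_numpy(dtype=float),
        is_control=ann["is_control"].to_numpy(dtype=bool),
        gene_map=gene_map,
    )


def write_phenotypes_csv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, dtype={"id": str})
    required = {"id", "smoker", "cigs_per_day", "cotinine", "age", "sex"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype file missing column(s): {sorted(missing)}")
    if pheno["id"].duplicated().any():
        raise ValueError("duplicate individual ids in phenotype file")
    if (pheno["age"] < 0).any():
        raise ValueError("negative ages in phenotype file")
    inconsistent = (pheno["cigs_per_day"] > 0) & (pheno["smoker"] == 0)
    if inconsistent.any():
        log.warning(
            "%d non-smokers report positive cigarettes/day", int(inconsistent.sum())
        )
    return pheno


def _align_samples(study, pheno, kin_ids, allow_missing: bool):
    """Strict id join across inputs; with allow_missing, intersect and log."""
    expr_ids = set(study.sample_ids)
    pheno_ids = set(pheno["id"])
    kin_set = set(kin_ids)
    common = expr_ids & pheno_ids & kin_set
    union = expr_ids | pheno_ids | kin_set
    if common != union:
        dropped = sorted(union - common)
        if not allow_missing:
            raise ValueError(
                f"{len(dropped)} id(s) present in some inputs but not all "
                f"(e.g. {dropped[:5]}); pass allow_missing to drop them"
            )
        log.warning("dropping %d id(s) absent from at least one input", len(dropped))
    keep = [s for s in study.sample_ids if s in common]
    rows = [study.sample_ids.index(s) for s in keep]
    study = RawExpressionStudy(
        sample_ids=keep,
        probe_ids=list(study.probe_ids),
        signal=study.signal[rows],
        is_control=study.is_control,
        gene_map=dict(study.gene_map),
    )
    pheno = pheno.set_index("id").loc[keep].reset_index()
    return study, pheno


# ---------------------------------------------------------------------------
# orchestrator


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute simulate? → detect → normalize → scan → bivar → enrich.

    Writes per-stage tables, a machine-readable ``summary.json`` and a
    human-readable log into ``cfg.out_dir``; returns that directory.
    A stage failure halts the run with the stage name while earlier
    outputs are retained.
    """
    cfg.validate_preflight()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("pedexpress")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": cfg.seed,
                     "parameters": _cfg_dict(cfg)}
    try:
        # --- inputs ---------------------------------------------------
        stage = "simulate"
        if cfg.simulate is not None:
            sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
            sim = simulate_study(sim_cfg)
            ped, kin, pheno, study = sim.pedigree, sim.kinship, sim.phenotypes, sim.study
            write_pedigree(ped, out / "pedigree.ped")
            write_expression_tsv(study, out / "expression.tsv", out / "probes.tsv")
            write_phenotypes_csv(pheno, out / "phenotypes.csv")
            sim.truth.write(out / "truth.json")
            gmt = make_synthetic_gmt(study, sim.truth, seed=cfg.seed)
            write_gmt(gmt, out / "gene_sets.gmt")
            gene_sets = GeneSetCollection(gmt, provenance="synthetic")
            log.info("simulated %d individuals, %d probes", len(kin.ids),
                     len(study.probe_ids))
        else:
            stage = "load"
            ped = read_pedigree(cfg.pedigree_path)
            kin = compute_kinship(ped)
            study = read_expression_tsv(cfg.expression_path, cfg.probe_annotation_path)
            pheno = read_phenotypes_csv(cfg.phenotype_path)
            gene_sets = read_gmt(cfg.gmt_path) if cfg.gmt_path else None
        stage = "align"
        study, pheno = _align_samples(study, pheno, kin.ids, cfg.allow_missing)
        write_kinship_tsv(kin, out / "kinship.tsv")
        write_block_manifest(kin, out / "blocks.tsv")

        # --- detection ------------------------------------------------
        stage = "detect"
        det = detect_expressed(
            study, fdr=cfg.detect_fdr, quantile=cfg.detect_quantile,
            pooled_null=cfg.pooled_null,
        )
        det.write(out / "detection.tsv", out / "detection_summary.json")
        summary["n_detected"] = det.n_detected
        if det.n_detected < 2 * cfg.n_bins:
            raise DetectionInputError(
                f"only {det.n_detected} transcripts detected; cannot normalize"
            )

        # --- normalization --------------------------------------------
        stage = "normalize"
        detected_study = study.subset_probes(
            det.detected_probes + [p for p, c in zip(study.probe_ids, study.is_control) if c]
        )
        expr = normalize_expression(
            detected_study, transcripts=det.detected_probes,
            n_bins=cfg.n_bins, offset=cfg.inverse_normal_offset,
        )
        expr.write(out / "normalized.tsv", out / "normalization.json")

        # --- association scan ----------------------------------------
        stage = "scan"
        scan = transcriptome_scan(
            expr, pheno, kin, exposure=cfg.exposure, fdr=cfg.scan_fdr,
            covariates=cfg.covariates,
        )
        scan.write(out / "association.tsv", out / "association_summary.json")
        summary["scan"] = scan.summary()
        hits = scan.table.sort_values("p", kind="mergesort")
        hits = hits.loc[hits["significant"], "transcript"].tolist()

        # --- bivariate decomposition ----------------------------------
        stage = "bivar"
        if hits:
            bivar = bivariate_scan(
                expr, hits, pheno, kin, covariates=cfg.covariates,
                top=cfg.bivar_top, compute_se=True,
            )
            bivar.to_csv(out / "bivariate.tsv", sep="\t", index=False)
            summary["bivariate_top"] = bivar.head(5).to_dict(orient="records")
        else:
            pd.DataFrame().to_csv(out / "bivariate.tsv", sep="\t", index=False)
            summary["bivariate_top"] = []
            log.info("no significant transcripts: bivariate stage is a no-op")

        # --- enrichment -----------------------------------------------
        stage = "enrich"
        if gene_sets is not None and hits:
            sig_genes, n_unmapped = collapse_to_genes(hits, study.gene_map)
            ref_genes, _ = collapse_to_genes(det.detected_probes, study.gene_map)
            enr = enrich(sig_genes, gene_sets, ref_genes, fdr=cfg.enrich_fdr)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "n_categories": int(len(enr)),
                "n_enriched": int(enr["enriched"].sum()),
                "n_unmapped_transcripts": n_unmapped,
            }
        else:
            pd.DataFrame().to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {"n_categories": 0, "n_enriched": 0}
            log.info("enrichment stage skipped (no gene sets or no hits)")

        _validate_summary(summary)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_safe))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _cfg_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _json_safe(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


_SUMMARY_REQUIRED = {"version", "seed", "parameters", "n_detected", "scan",
                     "bivariate_top", "enrichment"}


def _validate_summary(summary: dict) -> None:
    missing = _SUMMARY_REQUIRED - set(summary)
    if missing:
        raise ValueError(f"summary schema violation, missing keys: {sorted(missing)}")
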