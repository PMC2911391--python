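"""Replicated simulation studies that score the pipeline against truth.

These drive both the test suite's calibration checks and the
repository's reproduction script: each function simulates data with
known ground truth, runs the relevant pipeline stages from scratch and
returns the realized operating characteristics (false-discovery
proportions, parameter-recovery errors, test sizes).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .association import PolygenicFitter, build_design, transcriptome_scan
from .bivariate import BivariateFitter
from .detection import detect_expressed
from .normalization import NormalizedExpression, normalize_expression
from .pedigree import compute_kinship
from .simulate import (
    FamilyTemplate,
    SimulationConfig,
    generate_pedigrees,
    simulate_detection_study,
    simulate_normalized_expression,
    simulate_phenotypes,
    simulate_study,
)


def scan_fdp_replicates(
    n_replicates: int = 20,
    seed: int = 1,
    cfg: SimulationConfig | None = None,
    fdr: float = 0.05,
) -> np.ndarray:
    """False-discovery proportion of the detect→normalize→scan pipeline.

    Each replicate simulates the default study design (about 600
    individuals in families plus singletons, 2,000 transcripts, 5%
    carrying true smoking effects), runs detection, the three-stage
    standardization and the variance-components scan at the given BH
    level, and scores the fraction of declared discoveries whose true
    effect is zero.  Replicates with no discoveries score 0.
    """
    base = cfg if cfg is not None else SimulationConfig()
    fdps = np.empty(n_replicates)
    for r in range(n_replicates):
        rep_cfg = dataclasses.replace(base, seed=(int(seed) * 100_003 + r) % 2**31)
        sim = simulate_study(rep_cfg)
        det = detect_expressed(sim.study, fdr=0.05)
        expr = normalize_expression(sim.study, transcripts=det.detected_probes)
        scan = transcriptome_scan(expr, sim.phenotypes, sim.kinship,
                                  exposure="smoker", fdr=fdr)
        sig = set(scan.significant_transcripts)
        if not sig:
            fdps[r] = 0.0
            continue
        false = sig - set(sim.truth.affected)
        fdps[r] = len(false) / len(sig)
    return fdps


def detection_fdp_replicates(
    n_replicates: int = 20,
    seed: int = 1,
    fdr: float = 0.05,
    n_samples: int = 400,
    n_controls: int = 300,
    n_null: int = 1000,
    n_expressed: int = 200,
) -> np.ndarray:
    """False-detection proportion of the tail-test stage with BH.

    Pure-null probes share the control distribution; expressed probes
    are elevated in a random 20-80% subset of samples.
    """
    fdps = np.empty(n_replicates)
    for r in range(n_replicates):
        study, expressed = simulate_detection_study(
            n_samples=n_samples, n_controls=n_controls, n_null=n_null,
            n_expressed=n_expressed, seed=(int(seed) * 100_003 + r) % 2**31,
        )
        det = detect_expressed(study, fdr=fdr)
        hits = set(det.detected_probes)
        fdps[r] = len(hits - expressed) / len(hits) if hits else 0.0
    return fdps


def _recovery_pedigree(n_families: int, family_size: int, seed: int):
    """Identical nuclear families of the requested size (couple + kids)."""
    cfg = SimulationConfig(
        n_families=n_families,
        n_singletons=0,
        family_template=FamilyTemplate(
            n_generations=2, children_range=(family_size - 2, family_size - 2)
        ),
        seed=seed,
    )
    ped = generate_pedigrees(cfg)
    return cfg, ped


def h2_recovery(
    n_replicates: int = 200,
    seed: int = 1,
    h2_true: float = 0.5,
    n_families: int = 50,
    family_size: int = 5,
) -> np.ndarray:
    """Heritability estimates from the polygenic ML fit, one per replicate.

    Each replicate is an independent trait simulated on a cohort of
    identical nuclear families with h2 fixed at ``h2_true`` and no
    exposure effect; the fit uses the standard covariate design.
    """
    cfg, ped = _recovery_pedigree(n_families, family_size, seed)
    cfg = dataclasses.replace(
        cfg,
        n_transcripts=n_replicates,
        prop_affected_transcripts=0.0,
        h2_range=(h2_true, h2_true),
        age_effect=0.0,
        sex_effect=0.0,
    )
    kin = compute_kinship(ped)
    pheno = simulate_phenotypes(ped, cfg, kin=kin)
    Y, transcripts, _ = simulate_normalized_expression(ped, pheno, cfg, kin=kin)
    X = build_design(pheno)
    fitter = PolygenicFitter(kin, X)
    Yr = fitter.rotate_matrix(Y)
    return np.array([fitter.fit(Yr[:, k], rotated=True).h2 for k in range(n_replicates)])


def lrt_null_pvalues(
    n_null: int = 2000,
    seed: int = 1,
    n_families: int = 40,
    family_size: int = 6,
) -> np.ndarray:
    """Exposure-LRT p-values for traits simulated with no exposure effect.

    Traits are heritable and familial, and the smoking liability is
    itself heritable, so this exercises exactly the confounding the
    polygenic model must absorb; under the null the p-values should be
    uniform.
    """
    cfg, ped = _recovery_pedigree(n_families, family_size, seed)
    cfg = dataclasses.replace(
        cfg,
        n_transcripts=n_null,
        prop_affected_transcripts=0.0,
        h2_range=(0.1, 0.8),
    )
    kin = compute_kinship(ped)
    pheno = simulate_phenotypes(ped, cfg, kin=kin)
    Y, transcripts, _ = simulate_normalized_expression(ped, pheno, cfg, kin=kin)
    expr = NormalizedExpression(
        sample_ids=kin.ids, transcript_ids=transcripts, values=Y, provenance={}
    )
    scan = transcriptome_scan(expr, pheno, kin, exposure="smoker", fdr=0.05)
    return scan.table["p"].to_numpy()


def rho_recovery(
    n_replicates: int = 100,
    seed: int = 1,
    rho_g: float = 0.0,
    rho_e: float = 0.4,
    h2_expr: float = 0.5,
    h2_liab: float = 0.4,
    n_families: int = 60,
    family_size: int = 6,
    n_batches: int | None = None,
    n_qmc: int = 64,
) -> dict:
    """Bivariate-model recovery of (rho_g, rho_e) under known truth.

    Traits are simulated with pure correlation coupling (no fixed
    exposure effect) on cohorts of identical nuclear families.  By
    default every replicate redraws its own smoking liability —
    replicates sharing one liability have correlated estimates, which
    inflates the variance of the replicate mean.  Returns the
    per-replicate estimates and the rho_g = 0 / rho_e = 0 LRT p-values.
    """
    if n_batches is None:
        n_batches = n_replicates
    per_batch = int(np.ceil(n_replicates / n_batches))
    est_g, est_e, est_t = [], [], []
    p_g, p_e = [], []
    done = 0
    for b in range(n_batches):
        if done >= n_replicates:
            break
        k = min(per_batch, n_replicates - done)
        cfg, ped = _recovery_pedigree(n_families, family_size, (seed + 7919 * b) % 2**31)
        cfg = dataclasses.replace(
            cfg,
            n_transcripts=k,
            prop_affected_transcripts=1.0,
            effect_size_range=(0.0, 0.0),
            h2_range=(h2_expr, h2_expr),
            smoking_liability_h2=h2_liab,
            rho_g=rho_g,
            rho_e=rho_e,
            age_effect=0.0,
            sex_effect=0.0,
            misclassification_rate=0.0,
        )
        kin = compute_kinship(ped)
        pheno = simulate_phenotypes(ped, cfg, kin=kin)
        Y, transcripts, _ = simulate_normalized_expression(ped, pheno, cfg, kin=kin)
        fitter = BivariateFitter(pheno, kin, n_qmc=n_qmc)
        for j in range(k):
            row = fitter.fit_transcript(transcripts[j], Y[:, j], compute_se=False)
            est_g.append(row.rho_g)
            est_e.append(row.rho_e)
            est_t.append(row.threshold)
            p_g.append(row.p_rho_g)
            p_e.append(row.p_rho_e)
        done += k
    return {
        "rho_g": np.array(est_g),
        "rho_e": np.array(est_e),
        "threshold": np.array(est_t),
        "p_rho_g": np.array(p_g),
        "p_rho_e": np.array(p_e),
    }
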