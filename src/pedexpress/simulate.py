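"""Synthetic family study generator with exported ground truth.

Emulates the statistical structure the analysis pipeline assumes:

* extended pedigrees plus unrelated singletons;
* binary smoking generated on a liability scale — a latent standard
  normal with familial (additive genetic) correlation structure,
  thresholded at the quantile matching the target prevalence (default
  24%);
* cigarettes/day and plasma cotinine as noisy functions of smoking
  status, with a small rate of misclassified self-report;
* per-transcript expression with heritability h², optional fixed
  smoking effects β, and optional genetic/environmental correlation
  (ρg, ρe) between expression and the smoking liability;
* raw microarray-like signals with per-sample scale/offset artifacts
  and embedded control probes defining a null signal distribution.

Every latent quantity needed to score the pipeline (true effect set,
h², ρg/ρe, pre-misclassification smoking status, artifact parameters)
is exported as :class:`SyntheticTruth`.

All randomness derives from ``cfg.seed`` through fixed per-stage
substreams, so each generator function is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bivariate import threshold_from_prevalence
from .detection import RawExpressionStudy
from .pedigree import Individual, KinshipMatrix, Pedigree, compute_kinship


class ConfigError(ValueError):
    pass


# substream indices for the documented seed derivation default_rng([seed, stage])
_STAGE_PED, _STAGE_PHENO, _STAGE_EXPR = 0, 1, 2


@dataclass
class FamilyTemplate:
    """Family-structure template.

    With ``size_range`` set (the reference design uses 5-8), each
    family is drawn to a total size uniform in that range: a founder
    couple with two or three children and, for sizes above five, one
    child married to an unrelated spouse with grandchildren — three
    generations at sizes six and up.

    With ``size_range=None`` a branching process is used instead:
    starting from one founder couple, each couple has a uniform number
    of children in ``children_range``; in non-terminal generations each
    child marries an unrelated spouse (a new founder) with probability
    ``p_marry`` and the couple reproduces in the next generation.
    Family sizes then vary much more widely.
    """

    n_generations: int = 3
    children_range: tuple[int, int] = (2, 3)
    p_marry: float = 0.5
    size_range: tuple[int, int] | None = None


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe the reference design used throughout the test
    suite: ~600 individuals in multigeneration families of about 5-8
    plus singletons, 2,000 transcripts of which 5% carry standardized
    smoking effects with |β| in [0.4, 0.8], smoking prevalence 24% on a
    heritable liability scale, and per-transcript heritability uniform
    on [0.1, 0.8].
    """

    n_families: int = 80
    family_template: FamilyTemplate = field(
        default_factory=lambda: FamilyTemplate(size_range=(5, 8))
    )
    n_singletons: int = 40
    n_transcripts: int = 2000
    n_controls: int = 300
    prop_affected_transcripts: float = 0.05
    prop_unexpressed: float = 0.0
    effect_size_range: tuple[float, float] = (0.4, 0.8)
    prob_effect_negative: float = 0.5
    h2_range: tuple[float, float] = (0.1, 0.8)
    smoking_prevalence: float = 0.24
    smoking_liability_h2: float = 0.5
    rho_g: float = 0.0
    rho_e: float = 0.0
    age_range: tuple[float, float] = (16.0, 94.0)
    age_effect: float = 0.1
    sex_effect: float = 0.1
    # raw-signal artifact model: log x = a_s + b_s * (latent log abundance)
    artifact_offset_sd: float = 0.3
    artifact_scale_sd: float = 0.15
    baseline_range: tuple[float, float] = (3.0, 7.0)
    null_baseline_range: tuple[float, float] = (0.0, 2.0)
    null_noise_sd: float = 0.5
    expression_scale: float = 0.5
    # self-report and biomarker model
    misclassification_rate: float = 0.017
    cigs_per_day_lognorm: tuple[float, float] = (np.log(15.0), 0.6)
    cotinine_lognorm_nonsmoker: tuple[float, float] = (np.log(3.0), 0.6)
    cotinine_lognorm_smoker: tuple[float, float] = (np.log(150.0), 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.family_template, dict):
            self.family_template = FamilyTemplate(**self.family_template)
        for name in ("smoking_prevalence", "smoking_liability_h2",
                     "misclassification_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        for name in ("prop_affected_transcripts", "prop_unexpressed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.smoking_prevalence <= 0.0:
            raise ConfigError("smoking_prevalence must be positive")
        lo, hi = self.h2_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError("h2_range must satisfy 0 <= lo <= hi < 1")
        if abs(self.rho_g) > 1.0 or abs(self.rho_e) > 1.0:
            raise ConfigError("|rho_g| and |rho_e| must not exceed 1")
        if self.rho_g != 0.0 and self.smoking_liability_h2 == 0.0:
            raise ConfigError("rho_g requires smoking_liability_h2 > 0")

    def implied_rho_p(self, h2_expr: float) -> float:
        h2l = self.smoking_liability_h2
        return self.rho_g * np.sqrt(h2_expr * h2l) + self.rho_e * np.sqrt(
            (1.0 - h2_expr) * (1.0 - h2l)
        )


@dataclass
class SyntheticTruth:
    """Ground-truth parameters exported by the simulator."""

    affected: dict[str, float]          # transcript id -> true beta
    h2: dict[str, float]                # transcript id -> true h2
    rho_g: float
    rho_e: float
    expressed: list[str]                # transcripts with real signal
    smoker_true: dict[str, int]         # pre-misclassification status
    artifact_offset: dict[str, float]   # sample id -> a_s
    artifact_scale: dict[str, float]    # sample id -> b_s

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _stage_rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def generate_pedigrees(cfg: SimulationConfig) -> Pedigree:
    """Generate ``n_families`` template families plus singletons."""
    tpl = cfg.family_template
    if tpl.children_range[1] <= 0 and tpl.n_generations > 1:
        raise ConfigError("family template with no offspring cannot span generations")
    rng = _stage_rng(cfg, _STAGE_PED)
    individuals: list[Individual] = []
    for f in range(cfg.n_families):
        fam = f"FAM{f:03d}"
        counter = [0]

        def new_id() -> str:
            counter[0] += 1
            return f"{fam}_I{counter[0]:02d}"

        def rand_sex() -> str:
            return "male" if rng.random() < 0.5 else "female"

        dad, mom = new_id(), new_id()
        individuals.append(Individual(fam, dad, None, None, "male"))
        individuals.append(Individual(fam, mom, None, None, "female"))
        if tpl.size_range is not None:
            # size-targeted construction: couple, 2-3 children, and for
            # larger sizes one married child with grandchildren
            size = int(rng.integers(tpl.size_range[0], tpl.size_range[1] + 1))
            if size <= 5:
                n_children, n_grand = size - 2, 0
            else:
                n_children = 2 + (1 if size >= 8 else 0)
                n_grand = size - 3 - n_children
            children = []
            for _ in range(n_children):
                cid = new_id()
                children.append((cid, rand_sex()))
                individuals.append(Individual(fam, cid, dad, mom, children[-1][1]))
            if n_grand > 0:
                married, m_sex = children[0]
                spouse = new_id()
                s_sex = "female" if m_sex == "male" else "male"
                individuals.append(Individual(fam, spouse, None, None, s_sex))
                g_fa, g_mo = (married, spouse) if m_sex == "male" else (spouse, married)
                for _ in range(n_grand):
                    gid = new_id()
                    individuals.append(Individual(fam, gid, g_fa, g_mo, rand_sex()))
            continue
        couples = [(dad, mom)]
        for gen in range(1, tpl.n_generations):
            next_couples = []
            for (fa, mo) in couples:
                k = int(rng.integers(tpl.children_range[0], tpl.children_range[1] + 1))
                for _ in range(k):
                    child_sex = "male" if rng.random() < 0.5 else "female"
                    child = new_id()
                    individuals.append(Individual(fam, child, fa, mo, child_sex))
                    if gen < tpl.n_generations - 1 and rng.random() < tpl.p_marry:
                        spouse = new_id()
                        spouse_sex = "female" if child_sex == "male" else "male"
                        individuals.append(Individual(fam, spouse, None, None, spouse_sex))
                        pair = (child, spouse) if child_sex == "male" else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples
    for s in range(cfg.n_singletons):
        sex = "male" if rng.random() < 0.5 else "female"
        individuals.append(Individual(f"S{s:03d}", f"S{s:03d}_I01", None, None, sex))
    return Pedigree(individuals)


def _draw_block_mvn(rng, chol_2phi, n_draws: int) -> np.ndarray:
    """Draws (d, n_draws) from N(0, 2*Phi_block)."""
    z = rng.standard_normal((chol_2phi.shape[0], n_draws))
    return chol_2phi @ z


def simulate_phenotypes(
    ped: Pedigree, cfg: SimulationConfig, kin: KinshipMatrix | None = None
) -> pd.DataFrame:
    """Simulate smoking, cigarettes/day, cotinine, age and sex.

    Smoking is a thresholded latent liability ℓ = g + e with
    g ~ N(0, h²_liab · 2Φ) per pedigree block and e ~ N(0, (1-h²_liab)I);
    an individual is a true smoker iff ℓ exceeds the threshold implied
    by the target prevalence.  Reported status flips with the
    configured misclassification rate; cotinine tracks *true* status.

    The standardized liability components are attached under
    ``DataFrame.attrs`` for downstream expression coupling; they are
    simulation internals absent from real data.
    """
    if kin is None:
        kin = compute_kinship(ped)
    rng = _stage_rng(cfg, _STAGE_PHENO)
    n = len(kin.ids)
    a_g = np.zeros(n)   # genetic liability component, marginal Var = diag(2Phi)
    for block in kin.blocks:
        c = np.linalg.cholesky(2.0 * kin.phi[np.ix_(block, block)])
        a_g[block] = _draw_block_mvn(rng, c, 1)[:, 0]
    a_e = rng.standard_normal(n)
    h2l = cfg.smoking_liability_h2
    liability = np.sqrt(h2l) * a_g + np.sqrt(1.0 - h2l) * a_e
    t = threshold_from_prevalence(cfg.smoking_prevalence)
    smoker_true = (liability > t).astype(int)
    flips = rng.random(n) < cfg.misclassification_rate
    smoker_reported = np.where(flips, 1 - smoker_true, smoker_true)

    age = rng.uniform(*cfg.age_range, size=n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")

    mu_cpd, sd_cpd = cfg.cigs_per_day_lognorm
    cpd = np.where(
        smoker_reported == 1,
        np.maximum(1, np.round(rng.lognormal(mu_cpd, sd_cpd, size=n))),
        0,
    ).astype(int)
    mu0, sd0 = cfg.cotinine_lognorm_nonsmoker
    mu1, sd1 = cfg.cotinine_lognorm_smoker
    cot = np.where(
        smoker_true == 1, rng.lognormal(mu1, sd1, size=n), rng.lognormal(mu0, sd0, size=n)
    )

    pheno = pd.DataFrame(
        {
            "id": kin.ids,
            "smoker": smoker_reported,
            "cigs_per_day": cpd,
            "cotinine": cot,
            "age": age,
            "sex": sex,
        }
    )
    pheno.attrs["liability_genetic_std"] = a_g
    pheno.attrs["liability_environmental_std"] = a_e
    pheno.attrs["smoker_true"] = smoker_true
    return pheno


def _simulate_latent(
    ped: Pedigree,
    pheno: pd.DataFrame,
    cfg: SimulationConfig,
    kin: KinshipMatrix,
    rng: np.random.Generator,
):
    """Latent normalized expression shared by the raw and direct paths."""
    if list(pheno["id"]) != kin.ids:
        raise ConfigError("phenotype table and pedigree ids are misaligned")
    for h2 in np.asarray(cfg.h2_range):
        rp = cfg.implied_rho_p(h2)
        if abs(rp) > 1.0:
            raise ConfigError(f"implied phenotypic correlation {rp:.3f} exceeds 1")
    n = len(kin.ids)
    T = cfg.n_transcripts

    a_g = pheno.attrs.get("liability_genetic_std")
    a_e = pheno.attrs.get("liability_environmental_std")
    smoker_true = pheno.attrs.get("smoker_true", pheno["smoker"].to_numpy())
    if (cfg.rho_g != 0.0 or cfg.rho_e != 0.0) and (a_g is None or a_e is None):
        raise ConfigError(
            "rho_g/rho_e coupling requires liability components from simulate_phenotypes"
        )

    transcripts = [f"T{k:05d}" for k in range(T)]
    n_expressed = T - int(round(cfg.prop_unexpressed * T))
    expressed_idx = rng.choice(T, size=n_expressed, replace=False)
    expressed_mask = np.zeros(T, dtype=bool)
    expressed_mask[expressed_idx] = True

    n_affected = int(round(cfg.prop_affected_transcripts * T))
    affected_idx = rng.choice(expressed_idx, size=n_affected, replace=False)
    affected_mask = np.zeros(T, dtype=bool)
    affected_mask[affected_idx] = True

    h2 = rng.uniform(cfg.h2_range[0], cfg.h2_range[1], size=T)
    beta = np.zeros(T)
    lo, hi = cfg.effect_size_range
    mag = rng.uniform(lo, hi, size=n_affected)
    sign = np.where(rng.random(n_affected) < cfg.prob_effect_negative, -1.0, 1.0)
    beta[affected_idx] = sign * mag

    # independent familial and environmental innovations per transcript
    g_ind = np.zeros((n, T))
    for block in kin.blocks:
        c = np.linalg.cholesky(2.0 * kin.phi[np.ix_(block, block)])
        g_ind[block, :] = _draw_block_mvn(rng, c, T)
    e_ind = rng.standard_normal((n, T))

    rg = np.where(affected_mask, cfg.rho_g, 0.0)
    re = np.where(affected_mask, cfg.rho_e, 0.0)
    g_part = rg[None, :] * (a_g[:, None] if a_g is not None else 0.0) + np.sqrt(
        1.0 - rg**2
    )[None, :] * g_ind
    e_part = re[None, :] * (a_e[:, None] if a_e is not None else 0.0) + np.sqrt(
        1.0 - re**2
    )[None, :] * e_ind

    age_std = (pheno["age"].to_numpy() - np.mean(cfg.age_range)) / (
        (cfg.age_range[1] - cfg.age_range[0]) / 4.0
    )
    sex_num = (pheno["sex"].to_numpy() == "female").astype(float)
    fixed = (
        beta[None, :] * smoker_true[:, None]
        + cfg.age_effect * age_std[:, None]
        + cfg.sex_effect * (sex_num[:, None] - 0.5)
    )
    y = fixed + np.sqrt(h2)[None, :] * g_part + np.sqrt(1.0 - h2)[None, :] * e_part
    return y, transcripts, expressed_mask, affected_idx, h2, beta, smoker_true


def _truth(cfg, kin, transcripts, expressed_mask, affected_idx, h2, beta,
           smoker_true, a_s=None, b_s=None) -> SyntheticTruth:
    n = len(kin.ids)
    T = len(transcripts)
    return SyntheticTruth(
        affected={transcripts[k]: float(beta[k]) for k in sorted(affected_idx)},
        h2={transcripts[k]: float(h2[k]) for k in range(T)},
        rho_g=cfg.rho_g,
        rho_e=cfg.rho_e,
        expressed=[transcripts[k] for k in range(T) if expressed_mask[k]],
        smoker_true={kin.ids[i]: int(smoker_true[i]) for i in range(n)},
        artifact_offset={} if a_s is None else {kin.ids[i]: float(a_s[i]) for i in range(n)},
        artifact_scale={} if b_s is None else {kin.ids[i]: float(b_s[i]) for i in range(n)},
    )


def simulate_normalized_expression(
    ped: Pedigree,
    pheno: pd.DataFrame,
    cfg: SimulationConfig,
    kin: KinshipMatrix | None = None,
) -> tuple[np.ndarray, list[str], SyntheticTruth]:
    """Latent expression on the normalized scale, skipping the raw layer.

    Returns (samples × transcripts matrix, transcript ids, truth).  Used
    to test the variance-components machinery in isolation from the
    signal-artifact model; shares the latent draw with
    :func:`simulate_expression` at equal seed.
    """
    if kin is None:
        kin = compute_kinship(ped)
    rng = _stage_rng(cfg, _STAGE_EXPR)
    y, transcripts, expressed_mask, affected_idx, h2, beta, smoker_true = (
        _simulate_latent(ped, pheno, cfg, kin, rng)
    )
    truth = _truth(cfg, kin, transcripts, expressed_mask, affected_idx, h2,
                   beta, smoker_true)
    return y, transcripts, truth


def simulate_expression(
    ped: Pedigree,
    pheno: pd.DataFrame,
    cfg: SimulationConfig,
    kin: KinshipMatrix | None = None,
) -> tuple[RawExpressionStudy, SyntheticTruth]:
    """Simulate raw probe signals plus embedded controls.

    Latent normalized expression per transcript:

        y = β·smoker_true + γ_age·age* + γ_sex·sex + g + e

    with g ~ N(0, h²·2Φ) and e ~ N(0, (1-h²)I).  For affected
    transcripts the genetic/environmental parts are correlated (ρg, ρe)
    with the corresponding parts of the smoking liability.  Raw signal
    is exp(a_s + b_s·(μ_t + σ·y)) with per-sample artifacts (a_s, b_s);
    control probes and any unexpressed transcripts are drawn from the
    artifact-scaled null.
    """
    if kin is None:
        kin = compute_kinship(ped)
    rng = _stage_rng(cfg, _STAGE_EXPR)
    y, transcripts, expressed_mask, affected_idx, h2, beta, smoker_true = (
        _simulate_latent(ped, pheno, cfg, kin, rng)
    )
    n = len(kin.ids)
    T = cfg.n_transcripts

    # raw-signal layer
    a_s = rng.normal(0.0, cfg.artifact_offset_sd, size=n)
    b_s = rng.lognormal(0.0, cfg.artifact_scale_sd, size=n)
    mu_t = rng.uniform(*cfg.baseline_range, size=T)
    # background signal is exchangeable across probes and samples, so
    # unexpressed probes share the control-pool distribution exactly
    log_latent = np.where(
        expressed_mask[None, :],
        mu_t[None, :] + cfg.expression_scale * y,
        rng.uniform(*cfg.null_baseline_range, size=(n, T))
        + rng.normal(0.0, cfg.null_noise_sd, size=(n, T)),
    )
    controls = [f"CTRL{k:04d}" for k in range(cfg.n_controls)]
    log_ctrl = rng.uniform(*cfg.null_baseline_range, size=(n, cfg.n_controls)) + rng.normal(
        0.0, cfg.null_noise_sd, size=(n, cfg.n_controls)
    )

    log_all = np.concatenate([log_latent, log_ctrl], axis=1)
    signal = np.exp(a_s[:, None] + b_s[:, None] * log_all)

    probe_ids = transcripts + controls
    is_control = np.array([False] * T + [True] * cfg.n_controls)
    gene_map = {t: f"GENE{k // 2:05d}" for k, t in enumerate(transcripts)}
    study = RawExpressionStudy(
        sample_ids=kin.ids,
        probe_ids=probe_ids,
        signal=signal,
        is_control=is_control,
        gene_map=gene_map,
    )
    truth = _truth(cfg, kin, transcripts, expressed_mask, affected_idx, h2,
                   beta, smoker_true, a_s=a_s, b_s=b_s)
    return study, truth


@dataclass
class SimulatedStudy:
    pedigree: Pedigree
    kinship: KinshipMatrix
    phenotypes: pd.DataFrame
    study: RawExpressionStudy
    truth: SyntheticTruth


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """End-to-end generation: pedigree → phenotypes → expression."""
    ped = generate_pedigrees(cfg)
    kin = compute_kinship(ped)
    pheno = simulate_phenotypes(ped, cfg, kin=kin)
    study, truth = simulate_expression(ped, pheno, cfg, kin=kin)
    return SimulatedStudy(ped, kin, pheno, study, truth)


def make_synthetic_gmt(
    study: RawExpressionStudy,
    truth: SyntheticTruth,
    n_categories: int = 20,
    category_size_range: tuple[int, int] = (10, 60),
    n_enriched: int = 3,
    enriched_affected_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Synthetic gene-set collection over the simulated gene universe.

    Most categories are uniform draws from the gene universe; the first
    ``n_enriched`` draw half their members from genes of truly affected
    transcripts, giving the enrichment stage known positives.
    """
    rng = np.random.default_rng([seed, 4])
    universe = sorted({g for g in study.gene_map.values()})
    affected_genes = sorted(
        {study.gene_map[t] for t in truth.affected if t in study.gene_map}
    )
    cats: dict[str, set[str]] = {}
    lo, hi = category_size_range
    for c in range(n_categories):
        size = int(rng.integers(lo, hi + 1))
        if c < n_enriched and affected_genes:
            n_aff = min(len(affected_genes), int(round(enriched_affected_fraction * size)))
            chosen = set(rng.choice(affected_genes, size=n_aff, replace=False))
            rest = rng.choice(universe, size=size - n_aff, replace=False)
            cats[f"ENRICHED_{c:02d}"] = chosen | set(rest)
        else:
            cats[f"RANDOM_{c:02d}"] = set(rng.choice(universe, size=size, replace=False))
    return cats


def write_gmt(categories: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in categories.items():
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")


def simulate_detection_study(
    n_samples: int = 400,
    n_controls: int = 300,
    n_null: int = 1000,
    n_expressed: int = 200,
    expressed_fraction_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> tuple[RawExpressionStudy, set[str]]:
    """Array simulation for scoring the detection stage alone.

    Pure-null probes are drawn from the same distribution as the
    control probes; expressed probes are elevated far above the control
    95th percentile in a random 20-80% subset of samples and null
    elsewhere.  Returns the study plus the set of truly expressed
    probe ids.
    """
    rng = np.random.default_rng([seed, 3])
    a_s = rng.normal(0.0, 0.3, size=n_samples)
    b_s = rng.lognormal(0.0, 0.15, size=n_samples)

    def null_block(n_probes: int) -> np.ndarray:
        # background is exchangeable across probes and samples: fresh draw
        # from the same mixture the controls sample
        return rng.uniform(0.0, 2.0, size=(n_samples, n_probes)) + rng.normal(
            0.0, 0.5, size=(n_samples, n_probes)
        )

    log_ctrl = null_block(n_controls)
    log_null = null_block(n_null)
    frac = rng.uniform(*expressed_fraction_range, size=n_expressed)
    on = rng.random((n_samples, n_expressed)) < frac[None, :]
    log_expr = np.where(
        on,
        rng.uniform(4.0, 6.0, size=n_expressed)[None, :]
        + rng.normal(0.0, 0.5, size=(n_samples, n_expressed)),
        null_block(n_expressed),
    )
    log_all = np.concatenate([log_null, log_expr, log_ctrl], axis=1)
    signal = np.exp(a_s[:, None] + b_s[:, None] * log_all)
    probes = (
        [f"NULL{k:05d}" for k in range(n_null)]
        + [f"EXPR{k:05d}" for k in range(n_expressed)]
        + [f"CTRL{k:04d}" for k in range(n_controls)]
    )
    is_control = np.array([False] * (n_null + n_expressed) + [True] * n_controls)
    study = RawExpressionStudy(
        sample_ids=[f"S{k:04d}" for k in range(n_samples)],
        probe_ids=probes,
        signal=signal,
        is_control=is_control,
    )
    return study, {p for p in probes if p.startswith("EXPR")}
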