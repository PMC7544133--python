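"""Synthetic cohorts and GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of a polygenic-height →
atrial-fibrillation Mendelian-randomization study at desk scale: hundreds of
independent biallelic variants in Hardy–Weinberg equilibrium, a standardized
quantitative exposure with a configurable instrument heritability, a binary
outcome drawn from a logistic model with a configurable causal log-odds per SD
of exposure, optional balanced or directional horizontal pleiotropy, a shared
confounder, case-control ascertainment of the outcome GWAS, configurable
exposure/outcome sample overlap, and a biobank-style individual-level cohort
with clinical covariates and an echocardiographic measurement with
missingness.

Two generation modes are provided:

* **individual-level** (``simulate_cohort`` + ``summary_stats_from_cohort``):
  genotypes are drawn explicitly and GWAS summary statistics come from true
  per-variant marginal regressions on the sampled individuals;
* **summary-level** (``simulate_summary_pair``): effect estimates are drawn
  directly from the sampling distribution the individual-level model implies
  (βx̂ ~ N(βx, se_x), βŷ ~ N(θβx + α_j, se_y), with errors correlated under
  sample overlap). This mode makes hundreds of replicates cheap and is
  cross-checked against the individual-level mode in the test suite.

Everything is reproducible bit-identically from (SimConfig, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._glm import marginal_linear, marginal_logistic
from .individual import BINARY_COVARIATES, Cohort
from .sumstats import COLUMNS, LDPanel

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

#: baseline prevalence and extra log-odds among outcome cases for each
#: comorbidity column of the synthetic cohort (loosely biobank-like)
_COMORBIDITY_PARAMS = {
    "hypertension": (0.5, 0.8), "coronary_artery_disease": (0.48, 0.4),
    "heart_failure": (0.27, 1.2), "hyperlipidemia": (0.5, 0.5),
    "diabetes": (0.17, 0.0), "chronic_kidney_disease": (0.11, 0.6),
    "sleep_apnea": (0.12, 0.7), "stroke": (0.16, 0.5),
    "thyroid_disease": (0.02, 0.3), "cardiac_surgery": (0.23, 1.9),
    "valve_disease": (0.25, 0.9), "smoking": (0.47, 0.1),
}


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic MR study (desk-scale preset).

    Defaults mirror the study conditions at reduced scale: 200 independent
    instrument variants jointly explaining 11.2% of the exposure variance, a
    causal odds ratio of 1.34 per SD of exposure, an exposure GWAS of 20,000,
    an outcome GWAS of 2,000 cases / 8,000 controls under case-control
    ascertainment, and an individual-level cohort of 6,000 with ~30% outcome
    prevalence (the biobank cohort is case-enriched).
    """

    n_variants: int = 200
    maf_low: float = 0.05
    maf_high: float = 0.5
    h2_instrument: float = 0.112
    causal_log_or: float = float(np.log(1.34))
    pleiotropy_mode: str = "none"          # none | balanced | directional
    pleiotropy_mean: float = 0.02          # per exposure-increasing allele
    pleiotropy_sd: float = 0.02
    pleiotropy_fraction: float = 1.0       # share of variants with pleiotropy
    confounder_effect_exposure: float = 0.2
    confounder_effect_outcome: float = 0.2
    outcome_prevalence: float = 0.1
    cohort_prevalence: float = 0.3
    n_exposure_sample: int = 20_000
    n_outcome_cases: int = 2_000
    n_outcome_controls: int = 8_000
    n_cohort: int = 6_000
    overlap_fraction: float = 0.0
    # variants affecting the outcome only (the reverse-direction instrument);
    # zero exposure effect, direct log-odds ~ ±N(outcome_variant_log_or, 0.05)
    n_outcome_variants: int = 0
    outcome_variant_log_or: float = 0.3
    n_pcs: int = 10
    height_mean_cm: float = 170.0
    height_sd_cm: float = 11.0
    age_log_or: float = 0.3                # outcome log-odds per SD of age
    sex_log_or: float = -0.3               # female (sex = 1) vs male
    la_missing_rate: float = 0.567
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 4:
            raise ValueError("n_variants must be at least 4")
        for name in ("h2_instrument", "outcome_prevalence", "cohort_prevalence",
                     "overlap_fraction", "pleiotropy_fraction", "maf_low",
                     "maf_high", "la_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        resid = 1.0 - self.h2_instrument - self.confounder_effect_exposure ** 2
        if resid <= 0:
            raise ValueError(
                "infeasible exposure model: h2_instrument + confounder "
                f"variance = {1 - resid:.3f} ≥ 1")


@dataclass
class SimTruth:
    """Realized ground truth of one synthetic dataset."""

    maf: np.ndarray
    variant_effects: np.ndarray       # per effect allele, SD-exposure scale
    pleiotropy_effects: np.ndarray    # direct log-odds per effect allele
    invalid_mask: np.ndarray          # variants with nonzero direct effects
    causal_log_or: float
    confounder_effect_exposure: float
    confounder_effect_outcome: float
    variants: pd.DataFrame
    overlap_ids: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "causal_log_or": self.causal_log_or,
            "confounder_effect_exposure": self.confounder_effect_exposure,
            "confounder_effect_outcome": self.confounder_effect_outcome,
            "maf": self.maf.tolist(),
            "variant_effects": self.variant_effects.tolist(),
            "pleiotropy_effects": self.pleiotropy_effects.tolist(),
            "invalid": self.invalid_mask.astype(int).tolist(),
            "config": self.config,
        }


def _variant_table(rng: np.random.Generator, k: int) -> pd.DataFrame:
    """Variant metadata: ids, positions spaced far beyond the clump window."""
    chroms = [str(1 + i % 22) for i in range(k)]
    pos = [25_000_000 * (1 + i // 22) for i in range(k)]
    pairs = [_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
             for _ in range(k)]
    return pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(k)],
        "chrom": chroms, "pos": pos,
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
    })


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> SimTruth:
    k = config.n_variants
    k_total = k + config.n_outcome_variants
    maf = rng.uniform(config.maf_low, config.maf_high, size=k_total)
    # effect magnitudes shifted-exponential: an instrument of genome-wide
    # significant hits has no near-null effects, and per-variant strength is
    # right-skewed with min F ≈ 0.2 × mean F (study-like profile)
    magnitude = 0.5 + rng.exponential(0.5, size=k)
    raw = magnitude * rng.choice([-1.0, 1.0], size=k)
    var_per = 2.0 * maf[:k] * (1.0 - maf[:k]) * raw ** 2
    scale = np.sqrt(config.h2_instrument / var_per.sum())
    b = np.concatenate([raw * scale, np.zeros(config.n_outcome_variants)])

    a = np.zeros(k_total)
    invalid = np.zeros(k_total, dtype=bool)
    if config.pleiotropy_mode != "none":
        n_invalid = int(round(config.pleiotropy_fraction * k))
        idx = rng.choice(k, size=n_invalid, replace=False)
        invalid[idx] = True
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        # drawn per exposure-increasing allele, then mapped to the effect
        # allele so "directional" stays directional after Egger orientation
        a_oriented = rng.normal(mean, config.pleiotropy_sd, size=n_invalid)
        a[idx] = a_oriented * np.sign(b[idx])
    if config.n_outcome_variants:
        signs = rng.choice([-1.0, 1.0], size=config.n_outcome_variants)
        a[k:] = signs * rng.normal(config.outcome_variant_log_or, 0.05,
                                   size=config.n_outcome_variants)
    return SimTruth(
        maf=maf, variant_effects=b, pleiotropy_effects=a, invalid_mask=invalid,
        causal_log_or=config.causal_log_or,
        confounder_effect_exposure=config.confounder_effect_exposure,
        confounder_effect_outcome=config.confounder_effect_outcome,
        variants=_variant_table(rng, k_total), config=asdict(config),
    )


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept α with mean sigmoid(α + eta) = prevalence."""
    def f(alpha):
        return special.expit(alpha + eta).mean() - prevalence
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("infeasible target prevalence for the linear predictor")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _simulate_individuals(config: SimConfig, truth: SimTruth, n: int,
                          prevalence: float, rng: np.random.Generator):
    """Genotypes, exposure, outcome and latent confounder for n individuals."""
    k = len(truth.maf)
    G = rng.binomial(2, truth.maf, size=(n, k)).astype(np.float64)
    U = rng.normal(size=n)
    resid_sd = np.sqrt(1.0 - config.h2_instrument
                       - config.confounder_effect_exposure ** 2)
    height_liab = ((G - 2.0 * truth.maf) @ truth.variant_effects
                   + config.confounder_effect_exposure * U
                   + resid_sd * rng.normal(size=n))
    age = np.clip(rng.normal(62.0, 13.0, size=n), 20.0, 95.0)
    sex = rng.binomial(1, 0.38, size=n).astype(float)  # 1 = female
    age_std = (age - age.mean()) / age.std()
    eta = (config.causal_log_or * height_liab
           + (G - 2.0 * truth.maf) @ truth.pleiotropy_effects
           + config.confounder_effect_outcome * U
           + config.age_log_or * age_std
           + config.sex_log_or * (sex - sex.mean()))
    alpha = _solve_intercept(eta, prevalence)
    y = rng.binomial(1, special.expit(alpha + eta)).astype(int)
    return G, height_liab, age, sex, U, y


def simulate_cohort(config: SimConfig, n: int | None = None,
                    prevalence: float | None = None,
                    rng: np.random.Generator | None = None,
                    truth: SimTruth | None = None,
                    ) -> tuple[Cohort, SimTruth]:
    """Generate an individual-level biobank-style cohort with known truth.

    Genotypes are binomial(2, maf) (Hardy–Weinberg); the exposure is built on
    a standardized liability scale so the instrument explains
    ``h2_instrument`` of its variance; the binary outcome follows a logistic
    model whose intercept is solved numerically for the target prevalence.
    Clinical covariates, principal components (independent standard normals)
    and a height- and outcome-associated left atrial diameter with missingness
    are attached.
    """
    rng = rng or np.random.default_rng(config.seed)
    if truth is None:
        truth = _draw_truth(config, rng)
    n = n or config.n_cohort
    prevalence = prevalence if prevalence is not None else config.cohort_prevalence
    G, height_liab, age, sex, U, y = _simulate_individuals(
        config, truth, n, prevalence, rng)

    height_cm = config.height_mean_cm + config.height_sd_cm * height_liab
    bmi = np.clip(rng.normal(29.0, 6.0, size=n), 15.0, 60.0)
    weight = bmi * (height_cm / 100.0) ** 2

    pheno = pd.DataFrame({
        "height": height_cm, "weight": weight, "age": age, "sex": sex,
        "outcome": y,
    }, index=pd.RangeIndex(n, name="id"))
    for name in BINARY_COVARIATES:
        base, assoc = _COMORBIDITY_PARAMS[name]
        p = special.expit(special.logit(base) + assoc * (y - y.mean()))
        pheno[name] = rng.binomial(1, p)
    la = (3.92 + 0.02 * (height_cm - config.height_mean_cm)
          + 0.40 * y + rng.normal(0.0, 0.70, size=n))
    missing = rng.random(n) < config.la_missing_rate
    pheno["left_atrial_diameter"] = np.where(missing, np.nan, la)
    for i in range(1, config.n_pcs + 1):
        pheno[f"PC{i}"] = rng.normal(size=n)

    dosages = pd.DataFrame(G, index=pheno.index,
                           columns=truth.variants["variant_id"])
    cohort = Cohort(pheno, dosages, variants=truth.variants)
    return cohort, truth


def summary_stats_from_cohort(cohort: Cohort, trait: str,
                              sample_ids=None) -> pd.DataFrame:
    """Per-variant marginal GWAS on a subset of a simulated cohort.

    ``trait="exposure"`` runs linear regressions of within-subset standardized
    height on dosage; ``trait="outcome"`` runs univariate logistic regressions
    of the binary outcome. Monomorphic variants are emitted with beta 0 and an
    infinite SE, flagged in ``attrs["monomorphic"]``.
    """
    if trait not in ("exposure", "outcome"):
        raise ValueError("trait must be 'exposure' or 'outcome'")
    pheno = cohort.phenotypes
    dos = cohort.dosages
    if sample_ids is not None:
        if len(sample_ids) == 0:
            raise ValueError("empty sample subset")
        pheno = pheno.loc[sample_ids]
        dos = dos.loc[sample_ids]
    G = dos.to_numpy(dtype=float)
    n = len(pheno)
    if trait == "exposure":
        h = pheno["height"].to_numpy(dtype=float)
        yv = (h - h.mean()) / h.std()
        beta, se, p = marginal_linear(G, yv)
    else:
        yv = pheno["outcome"].to_numpy(dtype=float)
        beta, se, p = marginal_logistic(G, yv)
    eaf = G.mean(axis=0) / 2.0
    out = cohort.variants.copy()
    out["eaf"] = eaf
    out["beta"] = beta
    out["se"] = se
    out["pvalue"] = p
    out["n"] = n
    out = out[COLUMNS]
    out.attrs["monomorphic"] = (~np.isfinite(se)).tolist()
    return out


def make_ld_panel(cohort: Cohort) -> LDPanel:
    """Pairwise-r² panel from the cohort's dosages (squared Pearson corr)."""
    if len(cohort) < 2:
        raise ValueError("LD panel requires at least 2 individuals")
    chrom = None
    if cohort.variants is not None:
        chrom = dict(zip(cohort.variants["variant_id"],
                         cohort.variants["chrom"]))
    return LDPanel.from_dosages(cohort.dosages, chrom=chrom)


# ---------------------------------------------------------------------------
# Two-sample study generation (individual-level, case-control ascertainment)
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """A full synthetic two-sample study plus the individual-level cohort."""

    exposure_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    cohort: Cohort
    ld_panel: LDPanel
    truth: SimTruth
    realized_overlap: float


def _sample_outcome_ids(y: np.ndarray, pool_exposure: np.ndarray,
                        pool_disjoint: np.ndarray, n_cases: int,
                        n_controls: int, overlap_fraction: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Case-control sample with a target share drawn from the exposure sample."""
    chosen = []
    for want, status in ((n_cases, 1), (n_controls, 0)):
        n_from_overlap = int(round(overlap_fraction * want))
        from_exp = pool_exposure[y[pool_exposure] == status]
        from_dis = pool_disjoint[y[pool_disjoint] == status]
        if len(from_exp) < n_from_overlap or \
                len(from_dis) < want - n_from_overlap:
            raise ValueError(
                f"cannot draw {want} outcome {'cases' if status else 'controls'}"
                f" at overlap {overlap_fraction}: pools hold "
                f"{len(from_exp)}/{len(from_dis)}")
        chosen.append(rng.choice(from_exp, size=n_from_overlap, replace=False))
        chosen.append(rng.choice(from_dis, size=want - n_from_overlap,
                                 replace=False))
    return np.concatenate(chosen)


def simulate_study(config: SimConfig) -> StudyBundle:
    """End-to-end synthetic study: exposure GWAS, ascertained outcome GWAS,
    individual-level cohort, LD panel, and ground truth.

    A single population is generated and disjoint-or-overlapping subsets
    provide the exposure and outcome samples (controlled by
    ``config.overlap_fraction``); the individual-level cohort is generated
    separately at ``config.cohort_prevalence``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)

    prev = config.outcome_prevalence
    need_cases = config.n_outcome_cases
    need_controls = config.n_outcome_controls
    n_pool = int(np.ceil(max(need_cases / prev, need_controls / (1 - prev))
                         * 1.3))
    n_pop = config.n_exposure_sample + n_pool
    G, height_liab, age, sex, U, y = _simulate_individuals(
        config, truth, n_pop, prev, rng)
    pheno = pd.DataFrame({
        "height": config.height_mean_cm + config.height_sd_cm * height_liab,
        "age": age, "sex": sex, "outcome": y,
    }, index=pd.RangeIndex(n_pop, name="id"))
    dosages = pd.DataFrame(G, index=pheno.index,
                           columns=truth.variants["variant_id"])
    population = Cohort(pheno.assign(weight=70.0), dosages,
                        variants=truth.variants)

    ids = np.arange(n_pop)
    exposure_ids = ids[:config.n_exposure_sample]
    disjoint_ids = ids[config.n_exposure_sample:]
    outcome_ids = _sample_outcome_ids(
        y, exposure_ids, disjoint_ids, need_cases, need_controls,
        config.overlap_fraction, rng)
    realized = len(np.intersect1d(exposure_ids, outcome_ids)) / len(outcome_ids)
    truth.overlap_ids = np.intersect1d(exposure_ids, outcome_ids)

    exposure_stats = summary_stats_from_cohort(population, "exposure",
                                               sample_ids=exposure_ids)
    outcome_stats = summary_stats_from_cohort(population, "outcome",
                                              sample_ids=outcome_ids)

    # the biobank cohort shares the study's ground truth (same variant
    # effects), so GRS weights from the simulated GWAS transfer to it
    cohort, _ = simulate_cohort(config, rng=rng, truth=truth)
    # LD reference from a modest subset of the population
    ref = Cohort(pheno.assign(weight=70.0).iloc[:1000], dosages.iloc[:1000],
                 variants=truth.variants)
    ld_panel = make_ld_panel(ref)
    return StudyBundle(exposure_stats=exposure_stats,
                       outcome_stats=outcome_stats, cohort=cohort,
                       ld_panel=ld_panel, truth=truth,
                       realized_overlap=float(realized))


# ---------------------------------------------------------------------------
# Summary-level generation
# ---------------------------------------------------------------------------

@dataclass
class SummaryPair:
    """Summary-level synthetic exposure/outcome GWAS pair."""

    exposure_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    truth: SimTruth

    @property
    def harmonized(self) -> pd.DataFrame:
        """Harmonized-instrument frame (alleles aligned by construction)."""
        e, o = self.exposure_stats, self.outcome_stats
        return pd.DataFrame({
            "variant_id": e["variant_id"], "chrom": e["chrom"],
            "pos": e["pos"], "effect_allele": e["effect_allele"],
            "other_allele": e["other_allele"],
            "beta_exposure": e["beta"], "se_exposure": e["se"],
            "pvalue_exposure": e["pvalue"], "eaf_exposure": e["eaf"],
            "n_exposure": e["n"],
            "beta_outcome": o["beta"], "se_outcome": o["se"],
            "pvalue_outcome": o["pvalue"], "eaf_outcome": o["eaf"],
            "n_outcome": o["n"], "action": "unchanged",
        })


def simulate_summary_pair(config: SimConfig,
                          rng: np.random.Generator | None = None,
                          pheno_corr: float = 0.15) -> SummaryPair:
    """Draw a two-sample GWAS pair directly at the summary level.

    Exposure estimates are βx̂_j ~ N(βx_j, se_x_j) with
    se_x_j = 1/sqrt(2 p_j (1−p_j) n_x) (standardized exposure); outcome
    estimates are βŷ_j ~ N(θ βx_j + α_j, se_y_j) with
    se_y_j = 1/sqrt(2 p_j (1−p_j) n_y φ(1−φ)) for case fraction φ. Under
    sample overlap the estimation errors are correlated with coefficient
    overlap_fraction × ``pheno_corr``.
    """
    rng = rng or np.random.default_rng(config.seed)
    truth = _draw_truth(config, rng)
    k = len(truth.maf)
    het = 2.0 * truth.maf * (1.0 - truth.maf)
    n_x = config.n_exposure_sample
    n_y = config.n_outcome_cases + config.n_outcome_controls
    phi = config.n_outcome_cases / n_y
    se_x = 1.0 / np.sqrt(het * n_x)
    se_y = 1.0 / np.sqrt(het * n_y * phi * (1.0 - phi))

    rho = config.overlap_fraction * pheno_corr
    zx = rng.normal(size=k)
    zy = rho * zx + np.sqrt(1.0 - rho ** 2) * rng.normal(size=k)
    bx_hat = truth.variant_effects + se_x * zx
    by_true = (config.causal_log_or * truth.variant_effects
               + truth.pleiotropy_effects)
    by_hat = by_true + se_y * zy

    from scipy import stats as _st
    meta = truth.variants
    def frame(beta, se, n):
        p = np.clip(2.0 * _st.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
        out = meta.copy()
        out["eaf"] = truth.maf
        out["beta"] = beta
        out["se"] = se
        out["pvalue"] = p
        out["n"] = n
        return out[COLUMNS]

    return SummaryPair(exposure_stats=frame(bx_hat, se_x, n_x),
                       outcome_stats=frame(by_hat, se_y, n_y), truth=truth)
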