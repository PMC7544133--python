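"""Individual-level analyses: genetic risk score, two-stage MR, cohort tables.

The cohort is a biobank-style table (height, weight, age, sex, atrial
fibrillation status, cardiometabolic comorbidity flags, echocardiographic left
atrial diameter with missingness, genetic principal components) together with
an imputed-dosage matrix over the instrument variants.

The height genetic risk score (GRS) is the dosage-weighted sum of exposure
effect sizes, standardized within the cohort. Two-stage MR for the binary
outcome fits stage 1 (height ~ GRS + covariates, on outcome-free individuals
only), predicts height for everyone, and fits stage 2 (outcome ~ predicted
height + covariates) by logistic regression with heteroskedasticity-robust
(HC1) standard errors; the effect is reported per 1 SD of height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

#: binary comorbidity columns carried by the cohort (Table-1 characteristics)
BINARY_COVARIATES = [
    "hypertension", "coronary_artery_disease", "heart_failure",
    "hyperlipidemia", "diabetes", "chronic_kidney_disease", "sleep_apnea",
    "stroke", "thyroid_disease", "cardiac_surgery", "valve_disease", "smoking",
]

#: covariate sets of the three nested two-stage models
MODEL_COVARIATES = {
    "base": [],
    "model1_clinical": ["weight"] + BINARY_COVARIATES,
    "model2_la_size": ["weight"] + BINARY_COVARIATES + ["left_atrial_diameter"],
}


class Cohort:
    """Individual-level phenotypes plus a dosage matrix.

    Parameters
    ----------
    phenotypes
        DataFrame indexed by individual id with columns height, weight, age,
        sex (1 = female, 0 = male), outcome (atrial fibrillation, 0/1), the
        binary comorbidities, left_atrial_diameter (NaN = not measured), and
        PC1..PCk.
    dosages
        DataFrame (individuals × variants) of allele dosages in [0, 2], same
        index as ``phenotypes``.
    variants
        Optional variant metadata (variant_id, chrom, pos, effect_allele,
        other_allele) aligned to the dosage columns.
    """

    def __init__(self, phenotypes: pd.DataFrame, dosages: pd.DataFrame,
                 variants: pd.DataFrame | None = None):
        if not phenotypes.index.equals(dosages.index):
            raise ValueError("phenotype and dosage tables must share an index")
        d = dosages.to_numpy()
        if d.size and (d.min() < 0 or d.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if (phenotypes["height"] <= 0).any():
            raise ValueError("heights must be positive")
        self.phenotypes = phenotypes
        self.dosages = dosages
        self.variants = variants

    def __len__(self) -> int:
        return len(self.phenotypes)

    @property
    def n_pcs(self) -> int:
        return sum(c.startswith("PC") for c in self.phenotypes.columns)

    def pc_columns(self, n_pcs: int) -> list[str]:
        cols = [f"PC{i}" for i in range(1, n_pcs + 1)]
        missing = [c for c in cols if c not in self.phenotypes.columns]
        if missing:
            raise ValueError(f"cohort lacks principal components {missing}")
        return cols

    @classmethod
    def from_files(cls, phenotype_path, dosage_path,
                   variant_path=None) -> "Cohort":
        """Read delimited phenotype and dosage (variants × individuals) tables."""
        pheno = pd.read_csv(phenotype_path, sep=None, engine="python",
                            index_col=0)
        dosages = pd.read_csv(dosage_path, sep=None, engine="python",
                              index_col=0).T
        dosages.index = dosages.index.astype(pheno.index.dtype)
        dosages = dosages.loc[pheno.index]
        variants = None
        if variant_path is not None:
            variants = pd.read_csv(variant_path, sep=None, engine="python")
        return cls(pheno, dosages, variants)

    def to_files(self, phenotype_path, dosage_path, variant_path=None) -> None:
        self.phenotypes.to_csv(phenotype_path, sep="\t")
        self.dosages.T.to_csv(dosage_path, sep="\t")
        if variant_path is not None and self.variants is not None:
            self.variants.to_csv(variant_path, sep="\t", index=False)


@dataclass
class GRSVector:
    """Raw and standardized (mean 0, SD 1) genetic risk scores."""

    raw: pd.Series
    standardized: pd.Series

    def __len__(self) -> int:
        return len(self.raw)


def compute_grs(cohort: Cohort, weights: pd.Series) -> GRSVector:
    """Weighted additive genetic risk score from imputed dosages.

    ``weights`` is indexed by variant id, aligned to the cohort's dosage
    columns and harmonized effect alleles: raw_i = Σ_j dosage_ij · w_j. Scores
    are standardized within the cohort (population SD).
    """
    missing = [v for v in cohort.dosages.columns if v not in weights.index]
    if missing:
        raise ValueError(f"weights missing for {len(missing)} variants "
                         f"(e.g. {missing[:3]})")
    w = weights.loc[cohort.dosages.columns].to_numpy(dtype=float)
    raw = pd.Series(cohort.dosages.to_numpy() @ w, index=cohort.dosages.index,
                    name="grs_raw")
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("raw GRS has zero variance; cannot standardize")
    z = (raw - raw.mean()) / sd
    z.name = "grs"
    return GRSVector(raw=raw, standardized=z)


@dataclass
class TwoStageResults:
    """Two-stage MR results: OR per 1 SD of the exposure with robust CI."""

    model_label: str
    beta_per_sd: float
    se_per_sd: float
    pvalue: float
    n: int
    n_excluded: int
    stage1_r2: float
    height_sd: float
    stage1: object = field(repr=False, default=None)
    stage2: object = field(repr=False, default=None)
    metadata: dict = field(default_factory=dict)

    @property
    def or_per_sd(self) -> float:
        return float(np.exp(self.beta_per_sd))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta_per_sd - 1.959964 * self.se_per_sd))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta_per_sd + 1.959964 * self.se_per_sd))

    def or_per_units(self, target_units: float = 10.0) -> tuple[float, float, float]:
        """OR and CI per ``target_units`` of raw exposure (e.g. per 10 cm)."""
        f = target_units / self.height_sd
        b, s = self.beta_per_sd * f, self.se_per_sd * f
        return (float(np.exp(b)), float(np.exp(b - 1.959964 * s)),
                float(np.exp(b + 1.959964 * s)))

    def summary(self) -> str:
        return (
            f"Two-stage MR ({self.model_label}, n={self.n}, "
            f"{self.n_excluded} excluded for missing covariates)\n"
            f"  OR per 1-SD height  {self.or_per_sd:.3f} "
            f"[{self.ci_low:.3f}, {self.ci_high:.3f}] (p {self.pvalue:.3g})\n"
            f"  stage-1 R²          {self.stage1_r2:.3f}\n"
            f"  robust SE           HC1; height SD {self.height_sd:.2f}"
        )


class TwoStageMR:
    """Two-stage instrumental-variable model for a binary outcome.

    Stage 1: linear regression of height on the standardized GRS plus age,
    sex, principal components and the model's clinical covariates, fitted only
    on individuals without the outcome. Stage 2: logistic regression of the
    outcome on stage-1 predicted height (computed for all individuals) plus
    the same covariates, with HC1 sandwich standard errors. The coefficient is
    rescaled to per-SD-of-height using the whole-cohort height SD.
    """

    def __init__(self, cohort: Cohort, grs: GRSVector,
                 model: str = "base", n_pcs: int = 6,
                 covariates: list[str] | None = None):
        if model not in MODEL_COVARIATES and covariates is None:
            raise ValueError(f"unknown model {model!r}; expected one of "
                             f"{sorted(MODEL_COVARIATES)}")
        self.cohort = cohort
        self.grs = grs
        self.model_label = model
        self.n_pcs = n_pcs
        self.covariates = (covariates if covariates is not None
                           else MODEL_COVARIATES[model])

    def fit(self) -> TwoStageResults:
        pheno = self.cohort.phenotypes
        pcs = self.cohort.pc_columns(self.n_pcs)
        covar_cols = ["age", "sex"] + pcs + self.covariates
        df = pheno[["height", "outcome"] + covar_cols].copy()
        df["grs"] = self.grs.standardized

        complete = df[covar_cols + ["height", "outcome"]].notna().all(axis=1)
        n_excluded = int((~complete).sum())
        if n_excluded:
            logger.info("%s: %d rows excluded for missing covariates",
                        self.model_label, n_excluded)
        df = df[complete]
        # constant covariates (e.g. sex within a sex stratum) make the design
        # singular; drop them with a log entry
        constant = [c for c in covar_cols if df[c].nunique() <= 1]
        if constant:
            logger.info("%s: dropping constant covariate(s) %s",
                        self.model_label, constant)
            covar_cols = [c for c in covar_cols if c not in constant]
        controls = df[df["outcome"] == 0]
        if controls.empty:
            raise ValueError("no outcome-negative individuals for stage 1")

        x1 = sm.add_constant(controls[["grs"] + covar_cols])
        stage1 = sm.OLS(controls["height"], x1).fit()
        if self.grs.standardized.loc[df.index].std(ddof=0) == 0:
            raise ValueError("GRS has zero variance on the analysis rows")
        x_all = sm.add_constant(df[["grs"] + covar_cols])
        df = df.assign(height_hat=stage1.predict(x_all))

        x2 = sm.add_constant(df[["height_hat"] + covar_cols])
        try:
            stage2 = sm.Logit(df["outcome"], x2).fit(disp=False,
                                                     cov_type="HC1")
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise ValueError(
                f"stage-2 logistic fit failed ({exc}); check for separation "
                f"in model {self.model_label!r}") from exc
        if not np.isfinite(stage2.bse["height_hat"]):
            raise ValueError("stage-2 fit produced a non-finite robust SE "
                             "(likely separation)")

        height_sd = float(self.cohort.phenotypes["height"].std(ddof=0))
        beta = float(stage2.params["height_hat"]) * height_sd
        se = float(stage2.bse["height_hat"]) * height_sd
        p = float(stage2.pvalues["height_hat"])
        # stage-1 partial R² of the GRS (incremental over the covariates)
        x0 = sm.add_constant(controls[covar_cols])
        base_fit = sm.OLS(controls["height"], x0).fit()
        partial_r2 = float(1.0 - stage1.ssr / base_fit.ssr)
        return TwoStageResults(
            model_label=self.model_label, beta_per_sd=beta, se_per_sd=se,
            pvalue=p, n=len(df), n_excluded=n_excluded,
            stage1_r2=partial_r2, height_sd=height_sd,
            stage1=stage1, stage2=stage2,
            metadata={"robust_se": "HC1", "n_pcs": self.n_pcs,
                      "height_sd_scope": "whole cohort"},
        )


def two_stage_mr(cohort: Cohort, grs: GRSVector, model_label: str = "base",
                 covariate_set: list[str] | None = None,
                 n_pcs: int = 6) -> TwoStageResults:
    """Functional wrapper around :class:`TwoStageMR`."""
    return TwoStageMR(cohort, grs, model=model_label, n_pcs=n_pcs,
                      covariates=covariate_set).fit()


def select_n_pcs(explained_variance_share: np.ndarray,
                 threshold: float = 0.7) -> int:
    """Scree rule: smallest k whose cumulative variance share ≥ threshold."""
    cum = np.cumsum(np.asarray(explained_variance_share, dtype=float))
    if cum[-1] < threshold:
        return len(cum)
    return int(np.searchsorted(cum, threshold) + 1)


# ---------------------------------------------------------------------------
# Descriptive statistics (demographics table)
# ---------------------------------------------------------------------------

def format_percent(count: int, total: int) -> str:
    """Within-stratum percentage, one decimal below 3%, integer otherwise."""
    pct = 100.0 * count / total
    return f"{pct:.1f}%" if pct < 3 else f"{pct:.0f}%"


def summarize_cohort(cohort_or_frame,
                     continuous: list[str] | None = None,
                     binary: list[str] | None = None) -> pd.DataFrame:
    """Demographics stratified by outcome status.

    Continuous characteristics are summarized as mean (SD) with a Wilcoxon
    rank-sum p-value; binary ones as n (%) within stratum with a Fisher's
    exact p-value. Returns a frame with columns characteristic, statistic,
    controls, cases, pvalue (plus raw numeric columns for downstream use).
    """
    pheno = (cohort_or_frame.phenotypes
             if isinstance(cohort_or_frame, Cohort) else cohort_or_frame)
    if pheno["outcome"].isna().any():
        raise ValueError("outcome must be defined for all rows")
    cases = pheno[pheno["outcome"] == 1]
    controls = pheno[pheno["outcome"] == 0]
    if cases.empty or controls.empty:
        raise ValueError("both cases and controls are required")

    if continuous is None:
        continuous = [c for c in ("age", "height", "weight",
                                  "left_atrial_diameter")
                      if c in pheno.columns]
    if binary is None:
        binary = [c for c in ["sex"] + BINARY_COVARIATES if c in pheno.columns]

    rows = []
    for col in continuous:
        a = controls[col].dropna()
        b = cases[col].dropna()
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({
            "characteristic": col, "statistic": "mean (SD)",
            "controls": f"{a.mean():.4g} ({a.std(ddof=1):.3g})",
            "cases": f"{b.mean():.4g} ({b.std(ddof=1):.3g})",
            "pvalue": float(p),
            "controls_mean": a.mean(), "cases_mean": b.mean(),
        })
    for col in binary:
        a = int(controls[col].sum())
        b = int(cases[col].sum())
        table = [[b, len(cases) - b], [a, len(controls) - a]]
        p = stats.fisher_exact(table)[1]
        rows.append({
            "characteristic": col, "statistic": "n (%)",
            "controls": f"{a} ({format_percent(a, len(controls))})",
            "cases": f"{b} ({format_percent(b, len(cases))})",
            "pvalue": float(p),
            "controls_pct": 100.0 * a / len(controls),
            "cases_pct": 100.0 * b / len(cases),
        })
    out = pd.DataFrame(rows)
    out.attrs["n_controls"] = len(controls)
    out.attrs["n_cases"] = len(cases)
    return out


def format_table(table: pd.DataFrame) -> str:
    """Render the demographics frame as fixed-width text."""
    n0, n1 = table.attrs.get("n_controls", "?"), table.attrs.get("n_cases", "?")
    lines = [f"{'Characteristic':<26s}{'Statistic':<12s}"
             f"{'Controls (N=' + str(n0) + ')':<22s}"
             f"{'Cases (N=' + str(n1) + ')':<22s}p-value"]
    for _, r in table.iterrows():
        p = r["pvalue"]
        ptxt = "<0.001" if p < 0.001 else f"{p:.2g}"
        lines.append(f"{r['characteristic']:<26s}{r['statistic']:<12s}"
                     f"{r['controls']:<22s}{r['cases']:<22s}{ptxt}")
    return "\n".join(lines)
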