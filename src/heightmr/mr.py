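"""Two-sample Mendelian-randomization estimators and sensitivity analyses.

Given a harmonized instrument (per-variant exposure effects βx ± se_x and
outcome effects βy ± se_y on a shared effect allele), the causal effect of the
exposure on the outcome is estimated by

* the per-variant Wald ratio βy/βx,
* inverse-variance-weighted (IVW) meta-analysis of the ratios, the primary
  estimator, with a fixed- or multiplicative-random-effects standard error,
* MR-Egger regression, whose intercept estimates average directional
  pleiotropy,
* the weighted median of the ratios, consistent when valid instruments carry
  at least half the weight, and
* MR-PRESSO, a simulation-based residual-sum-of-squares test with per-variant
  outlier detection and an outlier-corrected estimate.

Multivariable MR regresses outcome effects jointly on several exposures'
effects to estimate direct effects. All estimates are carried as log-odds (for
a binary outcome) per 1-SD exposure; odds ratios are produced only at the
reporting boundary.

The model-style entry point is :class:`TwoSampleMR`, a statsmodels-flavoured
object built from the harmonized instrument whose ``fit(method=...)`` returns
an :class:`MREstimate` results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet, build_instrument
from .sumstats import LDPanel

logger = logging.getLogger(__name__)

Z95 = 1.959964  # normal 97.5% quantile used for all reported 95% CIs


def _as_frame(inst) -> pd.DataFrame:
    if isinstance(inst, InstrumentSet):
        return inst.harmonized
    return inst


def _bx_by(inst):
    df = _as_frame(inst)
    return (df["beta_exposure"].to_numpy(dtype=float),
            df["se_exposure"].to_numpy(dtype=float),
            df["beta_outcome"].to_numpy(dtype=float),
            df["se_outcome"].to_numpy(dtype=float))


@dataclass
class MREstimate:
    """One MR method's causal-effect estimate (a results object).

    ``beta`` is the log-odds of the outcome per 1-SD increase in the exposure;
    the 95% CI is the normal approximation beta ± 1.96·se. ``summary()``
    renders a one-method report including the odds-ratio scale.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    q_stat: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_ci_high(self) -> float:
        return float(np.exp(self.ci_high))

    def summary(self) -> str:
        lines = [
            f"MR estimate ({self.method}, {self.n_snps} SNPs)",
            f"  beta (log-odds/SD)  {self.beta: .4f} (se {self.se:.4f})",
            f"  OR [95% CI]         {self.odds_ratio:.3f} "
            f"[{self.or_ci_low:.3f}, {self.or_ci_high:.3f}]",
            f"  p-value             {self.pvalue:.3g}",
        ]
        if self.q_stat is not None:
            lines.append(f"  Cochran Q           {self.q_stat:.2f} "
                         f"(p {self.q_pvalue:.3g})")
        if self.egger_intercept is not None:
            lines.append(f"  Egger intercept     {self.egger_intercept: .4f} "
                         f"(p {self.egger_intercept_p:.3g})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method, "n_snps": self.n_snps,
            "beta": self.beta, "se": self.se,
            "or": self.odds_ratio, "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "pvalue": self.pvalue,
            "q_stat": self.q_stat, "q_pvalue": self.q_pvalue,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
        }


def wald_ratio(beta_x: float, se_x: float, beta_y: float,
               se_y: float) -> MREstimate:
    """Single-variant causal estimate βy/βx with first-order delta-method SE."""
    if beta_x == 0:
        raise ValueError("wald ratio undefined for beta_x = 0")
    beta = beta_y / beta_x
    se = abs(se_y / beta_x)
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
    return MREstimate(method="wald", beta=float(beta), se=float(se),
                      pvalue=float(p), n_snps=1)


def cochran_q(inst, beta: float) -> float:
    """Heterogeneity statistic Q = Σ wj (ratio_j − beta)², wj = (βx_j/se_y_j)²."""
    bx, _, by, sy = _bx_by(inst)
    if len(bx) < 2:
        raise ValueError("Cochran's Q requires at least 2 variants")
    w = np.square(bx / sy)
    ratios = by / bx
    return float(np.sum(w * np.square(ratios - beta)))


def ivw(inst, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate, the primary MR analysis.

    beta = Σ(βx βy / se_y²) / Σ(βx² / se_y²); the fixed-effects SE is
    1/sqrt(Σ βx²/se_y²) and the multiplicative-random-effects SE (the default)
    inflates it by max(1, sqrt(Q/(k−1))). A single-variant instrument reduces
    to the Wald ratio with a warning.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, sx, by, sy = _bx_by(inst)
    k = len(bx)
    if k == 0:
        raise ValueError("empty instrument")
    if k == 1:
        logger.warning("single-variant instrument: IVW reduces to the Wald ratio")
        est = wald_ratio(bx[0], sx[0], by[0], sy[0])
        return replace(est, method="ivw", metadata={"model": "wald_reduction"})
    w = np.square(bx / sy)
    beta = float(np.sum(bx * by / np.square(sy)) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    q = cochran_q(inst, beta)
    q_p = float(stats.chi2.sf(q, k - 1))
    se = se_fixed
    if model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return MREstimate(method="ivw", beta=beta, se=float(se), pvalue=float(p),
                      n_snps=k, q_stat=q, q_pvalue=q_p,
                      metadata={"model": model,
                                "weights": "second-order-free (beta_x/se_y)^2"})


def egger(inst) -> MREstimate:
    """MR-Egger regression: WLS of βy on βx with an intercept.

    Variants are oriented so βx ≥ 0 (flipping βy in step); weights are
    1/se_y². The slope estimates the causal effect; the intercept estimates
    average directional pleiotropy. SEs carry a multiplicative overdispersion
    factor max(1, sqrt(RSS/(k−2))) and p-values use t(k−2).
    """
    bx, _, by, sy = _bx_by(inst)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / np.square(sy)
    # weighted least squares with intercept, closed form
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * np.square(x - xbar))
    if sxx == 0:
        raise ValueError("no variation in exposure effects; Egger undefined")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    rss = float(np.sum(w * np.square(resid)))
    phi = max(1.0, np.sqrt(rss / (k - 2)))
    se_slope = float(np.sqrt(1.0 / sxx) * phi)
    se_intercept = float(np.sqrt(1.0 / sw + np.square(xbar) / sxx) * phi)
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), k - 2)
    p_intercept = 2.0 * stats.t.sf(abs(intercept / se_intercept), k - 2)
    return MREstimate(
        method="egger", beta=slope, se=se_slope, pvalue=float(p_slope),
        n_snps=k, q_stat=rss, q_pvalue=float(stats.chi2.sf(rss, k - 2)),
        egger_intercept=intercept, egger_intercept_se=se_intercept,
        egger_intercept_p=float(p_intercept),
    )


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray):
    """Interpolated weighted median (vectorized over leading axes).

    ``ratios``/``weights`` of shape (..., k); returns shape (...,). Uses the
    convention p_j = (cumsum(w) − w/2)/Σw on the sorted ratios with linear
    interpolation at 0.5.
    """
    order = np.argsort(ratios, axis=-1)
    r = np.take_along_axis(ratios, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    total = w.sum(axis=-1, keepdims=True)
    p = (np.cumsum(w, axis=-1) - 0.5 * w) / total
    # linear interpolation of r against p at 0.5, per row
    flat_p = p.reshape(-1, p.shape[-1])
    flat_r = r.reshape(-1, r.shape[-1])
    out = np.empty(flat_p.shape[0])
    for i in range(flat_p.shape[0]):
        out[i] = np.interp(0.5, flat_p[i], flat_r[i])
    return out.reshape(p.shape[:-1])


def weighted_median(inst, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with a parametric-bootstrap standard error.

    Per-variant ratios βy/βx are weighted by wj = (βx_j/se_y_j)² (normalized);
    the estimate interpolates the weighted empirical CDF at 0.5. The SE is the
    standard deviation of the estimate over ``n_boot`` parametric resamples of
    (βx, βy) from their stated SEs.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    bx, sx, by, sy = _bx_by(inst)
    k = len(bx)
    if k < 3:
        raise ValueError("weighted median requires at least 3 variants")
    w = np.square(bx / sy)
    if not np.any(w > 0):
        raise ValueError("all weights are zero")
    ratios = by / bx
    beta = float(_weighted_median_estimate(ratios, w))
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios_b = by_b / bx_b
        w_b = np.square(bx_b / sy)
    boot = _weighted_median_estimate(ratios_b, w_b)
    se = float(np.std(boot, ddof=1))
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
    return MREstimate(method="weighted_median", beta=beta, se=se,
                      pvalue=float(p), n_snps=k,
                      metadata={"n_boot": n_boot, "seed": seed,
                                "weights": "second-order-free (beta_x/se_y)^2"})


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    """MR-PRESSO results: global pleiotropy test, outliers, corrected estimate."""

    global_rss_observed: float
    global_p: float
    outlier_indices: list[int]
    per_snp_outlier_p: np.ndarray
    raw: MREstimate
    corrected: MREstimate | None = None
    distortion_p: float | None = None
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"MR-PRESSO ({self.raw.n_snps} SNPs, "
            f"{self.metadata.get('n_sim', '?')} simulations)",
            f"  global RSS          {self.global_rss_observed:.3f} "
            f"(p {self.global_p:.3g})",
            f"  outliers            {self.outlier_indices or 'none'}",
        ]
        if self.corrected is not None:
            lines.append(f"  corrected beta      {self.corrected.beta: .4f} "
                         f"(raw {self.raw.beta: .4f})")
            if self.distortion_p is not None:
                lines.append(f"  distortion p        {self.distortion_p:.3g}")
        return "\n".join(lines)


def _loo_ivw_slopes(bx, by, w):
    """Leave-one-out fixed-effect IVW slopes, vectorized over leading axes."""
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * np.square(bx), axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * np.square(bx))


def mr_presso(inst, n_sim: int = 5000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    The observed residual sum of squares from leave-one-out IVW predictions is
    compared to its distribution over ``n_sim`` parametric simulations under
    the fitted no-pleiotropy model (empirical p, lower bound 1/(n_sim+1)).
    Per-variant squared residuals are compared to their simulated distributions
    with Bonferroni correction at ``outlier_alpha``. When outliers are found,
    an outlier-corrected IVW estimate and a distortion test (observed shift of
    the estimate vs the shift from removing random variant subsets of the same
    size) are reported.
    """
    bx, sx, by, sy = _bx_by(inst)
    k = len(bx)
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 variants")
    if n_sim < 1000:
        logger.warning("n_sim=%d gives empirical-p resolution of only %.2g",
                       n_sim, 1.0 / (n_sim + 1))
    rng = np.random.default_rng(seed)
    w = 1.0 / np.square(sy)

    beta_loo = _loo_ivw_slopes(bx, by, w)
    resid2_obs = w * np.square(by - beta_loo * bx)
    rss_obs = float(resid2_obs.sum())

    # parametric simulation under the no-pleiotropy model fitted leave-one-out
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, k))
    beta_loo_sim = _loo_ivw_slopes(bx_sim, by_sim, w)
    resid2_sim = w * np.square(by_sim - beta_loo_sim * bx_sim)
    rss_sim = resid2_sim.sum(axis=-1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    per_snp_p = (1 + np.sum(resid2_sim >= resid2_obs, axis=0)) / (n_sim + 1)
    outliers = np.flatnonzero(per_snp_p < outlier_alpha / k)

    raw = ivw(inst)
    corrected = None
    distortion_p = None
    if len(outliers) and len(outliers) < k - 1:
        frame = _as_frame(inst)
        kept = frame.drop(frame.index[outliers]).reset_index(drop=True)
        corrected = ivw(kept)
        corrected = replace(corrected, method="presso_outlier_corrected")
        if raw.beta != 0:
            obs_distortion = (corrected.beta - raw.beta) / abs(raw.beta)
            n_out = len(outliers)
            n_rand = min(n_sim, 2000)
            dist_null = np.empty(n_rand)
            sxy_all = np.sum(w * bx * by)
            sxx_all = np.sum(w * np.square(bx))
            for i in range(n_rand):
                drop = rng.choice(k, size=n_out, replace=False)
                sxy = sxy_all - np.sum(w[drop] * bx[drop] * by[drop])
                sxx = sxx_all - np.sum(w[drop] * np.square(bx[drop]))
                dist_null[i] = (sxy / sxx - raw.beta) / abs(raw.beta)
            distortion_p = float(
                (1 + np.sum(np.abs(dist_null) >= abs(obs_distortion)))
                / (n_rand + 1))
    raw = replace(raw, method="presso_raw")
    return PressoResult(
        global_rss_observed=rss_obs, global_p=global_p,
        outlier_indices=[int(i) for i in outliers],
        per_snp_outlier_p=per_snp_p, raw=raw, corrected=corrected,
        distortion_p=distortion_p,
        metadata={"n_sim": n_sim, "seed": seed, "outlier_alpha": outlier_alpha},
    )


# ---------------------------------------------------------------------------
# Multivariable MR
# ---------------------------------------------------------------------------

@dataclass
class MVMRResult:
    """Direct effects of several exposures on the outcome (one row each)."""

    table: pd.DataFrame  # columns: exposure, beta, se, pvalue
    n_snps: int

    def estimate(self, exposure: str) -> MREstimate:
        row = self.table.set_index("exposure").loc[exposure]
        return MREstimate(method="mvmr", beta=float(row["beta"]),
                          se=float(row["se"]), pvalue=float(row["pvalue"]),
                          n_snps=self.n_snps)

    def summary(self) -> str:
        lines = [f"Multivariable MR ({self.n_snps} SNPs)"]
        for _, r in self.table.iterrows():
            lines.append(f"  {r['exposure']:<20s} beta {r['beta']: .4f} "
                         f"(se {r['se']:.4f}, p {r['pvalue']:.3g}, "
                         f"OR {np.exp(r['beta']):.3f})")
        return "\n".join(lines)


def mvmr(exposures: dict[str, pd.DataFrame], outcome: pd.DataFrame) -> MVMRResult:
    """Multivariable MR: weighted regression of βy on the exposure-beta matrix.

    Each exposure frame must provide variant_id/beta (se optional); the outcome
    frame variant_id/beta/se. The variant intersection across all inputs is
    taken (and logged). Fit is no-intercept WLS with weights 1/se_y².
    """
    names = list(exposures)
    if not names:
        raise ValueError("at least one exposure required")
    common = set(outcome["variant_id"])
    for df in exposures.values():
        common &= set(df["variant_id"])
    common = sorted(common)
    k, p = len(common), len(names)
    if k < p + 1:
        raise ValueError(f"need ≥ {p + 1} shared variants, found {k}")
    logger.info("multivariable MR: %d shared variants across %d exposures", k, p)

    X = np.column_stack([
        exposures[name].set_index("variant_id").loc[common, "beta"].to_numpy(dtype=float)
        for name in names])
    yframe = outcome.set_index("variant_id").loc[common]
    y = yframe["beta"].to_numpy(dtype=float)
    sy = yframe["se"].to_numpy(dtype=float)
    w = 1.0 / np.square(sy)

    xtwx = X.T @ (w[:, None] * X)
    if np.linalg.matrix_rank(xtwx) < p:
        corr = np.corrcoef(X, rowvar=False)
        raise ValueError("rank-deficient exposure matrix; collinear exposures "
                         f"among {names} (correlations:\n{corr})")
    xtwy = X.T @ (w * y)
    beta = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ beta
    dof = k - p
    phi = max(1.0, float(np.sum(w * np.square(resid)) / dof)) if dof > 0 else 1.0
    cov = np.linalg.inv(xtwx) * phi
    se = np.sqrt(np.diag(cov))
    pvals = 2.0 * stats.t.sf(np.abs(beta / se), dof)
    table = pd.DataFrame({"exposure": names, "beta": beta, "se": se,
                          "pvalue": pvals})
    return MVMRResult(table=table, n_snps=k)


# ---------------------------------------------------------------------------
# Scale conversion and orchestration
# ---------------------------------------------------------------------------

def scale_per_unit(estimate: MREstimate, sd_units: float,
                   target_units: float) -> MREstimate:
    """Rescale a per-SD estimate to a per-``target_units`` estimate.

    E.g. an OR per 1-SD of height with SD 9.28 cm becomes an OR per 10 cm by
    multiplying the log-odds (and its SE, hence the CI bounds) by 10/9.28.
    """
    if sd_units <= 0 or target_units <= 0:
        raise ValueError("scale units must be positive")
    factor = target_units / sd_units
    return replace(estimate, beta=estimate.beta * factor,
                   se=estimate.se * factor,
                   metadata={**estimate.metadata,
                             "scaled": f"per {target_units} units "
                                       f"(SD = {sd_units})"})


class TwoSampleMR:
    """Two-sample MR model over a harmonized instrument.

    Parameters
    ----------
    instrument
        An :class:`~heightmr.instruments.InstrumentSet` or a harmonized frame
        with beta/se columns for both studies.

    ``fit(method=...)`` dispatches to the individual estimators and returns an
    :class:`MREstimate`; ``fit_all()`` runs the primary IVW analysis together
    with the weighted-median, Egger, and MR-PRESSO sensitivity analyses.
    """

    METHODS = ("ivw", "egger", "weighted_median")

    def __init__(self, instrument):
        self.instrument = instrument
        self.data = _as_frame(instrument)

    def fit(self, method: str = "ivw", **kwargs) -> MREstimate:
        if method == "ivw":
            return ivw(self.data, **kwargs)
        if method == "egger":
            return egger(self.data, **kwargs)
        if method == "weighted_median":
            return weighted_median(self.data, **kwargs)
        raise ValueError(f"unknown method {method!r}")

    def fit_presso(self, **kwargs) -> PressoResult:
        return mr_presso(self.data, **kwargs)

    def fit_all(self, n_boot: int = 1000, n_sim: int = 5000,
                seed: int = 0, ivw_model: str = "multiplicative_random",
                ) -> dict[str, MREstimate | PressoResult]:
        results: dict = {
            "ivw": self.fit("ivw", model=ivw_model),
            "weighted_median": self.fit("weighted_median", n_boot=n_boot,
                                        seed=seed),
            "egger": self.fit("egger"),
        }
        if len(self.data) >= 4:
            results["mr_presso"] = self.fit_presso(n_sim=n_sim, seed=seed)
        return results

    def results_table(self, results: dict | None = None, **kwargs) -> pd.DataFrame:
        results = results or self.fit_all(**kwargs)
        rows = []
        for name, res in results.items():
            if isinstance(res, PressoResult):
                rows.append(res.raw.to_dict())
                if res.corrected is not None:
                    rows.append(res.corrected.to_dict())
            else:
                rows.append(res.to_dict())
        return pd.DataFrame(rows)


def bidirectional_mr(study_a: pd.DataFrame, study_b: pd.DataFrame,
                     ld: LDPanel, p_threshold: float = 5e-8,
                     window_kb: int = 10_000, r2_threshold: float = 0.001,
                     n_boot: int = 1000, seed: int = 0) -> dict[str, dict]:
    """Run MR in both directions to probe reverse causation.

    Forward: instrument from A-significant variants, A → B. Reverse:
    instrument from B-significant variants, B → A. Each direction reports IVW,
    weighted-median, and Egger estimates plus the instrument.
    """
    out = {}
    for label, exp, outc in (("forward", study_a, study_b),
                             ("reverse", study_b, study_a)):
        inst = build_instrument(exp, outc, ld, p_threshold=p_threshold,
                                window_kb=window_kb, r2_threshold=r2_threshold)
        model = TwoSampleMR(inst)
        out[label] = {
            "instrument": inst,
            "ivw": model.fit("ivw"),
            "weighted_median": model.fit("weighted_median", n_boot=n_boot,
                                         seed=seed),
            "egger": model.fit("egger") if inst.n_variants >= 3 else None,
        }
    return out
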