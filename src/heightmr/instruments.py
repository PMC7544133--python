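"""Genetic-instrument construction and strength diagnostics.

The instrument for a quantitative exposure is the set of independent,
genome-wide-significant variants, harmonized to the outcome study. Strength is
quantified per variant by the variance explained

    R² = 2 · MAF · (1 − MAF) · β²

(β the per-allele effect on the standardized exposure, MAF = min(eaf, 1−eaf))
and the F-statistic

    F = R² (N − 2) / (1 − R²),

with the total R² and the mean/min/max F summarizing the whole instrument.
Bias from exposure/outcome sample overlap is approximated to first order as
(overlap fraction) × (confounded observational effect) / (mean F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDPanel, clump, harmonize

logger = logging.getLogger(__name__)


def variance_explained(eaf, beta):
    """Per-variant exposure variance explained: 2·maf·(1−maf)·β².

    ``beta`` is the per-allele effect on the standardized exposure; ``maf`` is
    folded from the effect-allele frequency. Vectorized over array inputs.
    """
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf < 0) | (eaf > 1)):
        raise ValueError("eaf outside [0, 1]")
    maf = np.minimum(eaf, 1.0 - eaf)
    out = 2.0 * maf * (1.0 - maf) * np.square(np.asarray(beta, dtype=float))
    return out if out.ndim else float(out)


def f_statistic(r2, n):
    """Instrument-strength F-statistic: R²(N−2)/(1−R²). Vectorized."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ValueError("r2 must lie in [0, 1)")
    if np.any(n <= 2):
        raise ValueError("n must exceed 2")
    out = r2 * (n - 2.0) / (1.0 - r2)
    return out if out.ndim else float(out)


@dataclass
class InstrumentSet:
    """A harmonized instrument with per-variant and aggregate strength metrics."""

    harmonized: pd.DataFrame  # includes r2_explained and f_stat columns

    @property
    def n_variants(self) -> int:
        return len(self.harmonized)

    @property
    def r2_explained(self) -> np.ndarray:
        return self.harmonized["r2_explained"].to_numpy()

    @property
    def f_stat(self) -> np.ndarray:
        return self.harmonized["f_stat"].to_numpy()

    @property
    def total_r2(self) -> float:
        return float(self.r2_explained.sum())

    @property
    def mean_f(self) -> float:
        return float(self.f_stat.mean())

    @property
    def min_f(self) -> float:
        return float(self.f_stat.min())

    @property
    def max_f(self) -> float:
        return float(self.f_stat.max())

    @property
    def n_exposure(self) -> int:
        return int(self.harmonized["n_exposure"].max())

    def summary(self) -> str:
        return (
            f"InstrumentSet: {self.n_variants} variants\n"
            f"  total R² = {self.total_r2:.4f}\n"
            f"  F-statistic mean {self.mean_f:.1f} "
            f"(range {self.min_f:.1f}–{self.max_f:.1f})\n"
            f"  exposure N = {self.n_exposure}"
        )


def _with_strength(harmonized: pd.DataFrame) -> pd.DataFrame:
    df = harmonized.copy()
    df["r2_explained"] = variance_explained(df["eaf_exposure"], df["beta_exposure"])
    df["f_stat"] = f_statistic(df["r2_explained"], df["n_exposure"])
    return df


def build_instrument(exposure: pd.DataFrame, outcome: pd.DataFrame,
                     ld: LDPanel, p_threshold: float = 5e-8,
                     window_kb: int = 10_000, r2_threshold: float = 0.001,
                     palindrome_eaf_limit: float = 0.42) -> InstrumentSet:
    """Threshold → clump → harmonize → strength metrics.

    Exposure variants at p < ``p_threshold`` are LD-clumped to an independent
    set, harmonized with the outcome study, and annotated with per-variant R²
    and F computed from the exposure eaf/beta/N.
    """
    clumped = clump(exposure, ld, window_kb=window_kb,
                    r2_threshold=r2_threshold, p_threshold=p_threshold)
    if clumped.empty:
        raise ValueError("no variants pass the significance threshold")
    harmonized = harmonize(clumped, outcome,
                           palindrome_eaf_limit=palindrome_eaf_limit)
    return InstrumentSet(_with_strength(harmonized))


def restrict_instrument(inst: InstrumentSet,
                        confounder_studies: dict[str, pd.DataFrame],
                        nominal_p: float = 0.05) -> tuple[InstrumentSet, pd.DataFrame]:
    """Drop instrument variants nominally associated with any confounder trait.

    ``confounder_studies`` maps trait name → summary-statistics frame. A
    variant is excluded when its p-value in ANY confounder study is below
    ``nominal_p``; variants absent from a study are retained for that trait.
    Returns the restricted instrument (strength metrics recomputed) and an
    exclusion log (variant_id, trait, pvalue).
    """
    exclusions = []
    excluded_ids: set[str] = set()
    for trait, study in confounder_studies.items():
        pmap = study.set_index("variant_id")["pvalue"]
        hits = inst.harmonized["variant_id"].map(pmap)
        mask = hits < nominal_p
        for vid, p in zip(inst.harmonized.loc[mask, "variant_id"], hits[mask]):
            exclusions.append({"variant_id": vid, "trait": trait, "pvalue": p})
            excluded_ids.add(vid)
    log = pd.DataFrame(exclusions, columns=["variant_id", "trait", "pvalue"])
    kept = inst.harmonized[~inst.harmonized["variant_id"].isin(excluded_ids)]
    restricted = InstrumentSet(_with_strength(kept.reset_index(drop=True)))
    logger.info("restrictive instrument: %d of %d variants retained",
                restricted.n_variants, inst.n_variants)
    return restricted, log


@dataclass
class OverlapBiasReport:
    """First-order bias from exposure/outcome sample overlap.

    expected_bias = overlap_fraction × confounded effect / mean F; the type-I
    error is the rejection rate of the nominal 5% test under the shifted
    estimator, by normal approximation at the supplied IVW standard error.
    """

    overlap_fraction: float
    assumed_confounded_effect: float
    mean_f: float
    expected_bias: float
    expected_type1_error: float
    se: float

    def summary(self) -> str:
        return (
            f"Sample-overlap bias (overlap {self.overlap_fraction:.0%}, "
            f"confounded effect {self.assumed_confounded_effect}, "
            f"mean F {self.mean_f:.1f}):\n"
            f"  expected bias        {self.expected_bias:.3g}\n"
            f"  type-I error at 5%   {self.expected_type1_error:.3f}"
        )


def overlap_bias(overlap_fraction: float, mean_f: float,
                 assumed_confounded_effect: float = 0.2,
                 se: float = 0.05, alpha: float = 0.05) -> OverlapBiasReport:
    """Approximate the null bias of two-sample MR under sample overlap.

    With full overlap the estimator shifts toward the confounded observational
    association, attenuated by instrument strength; the shift is
    overlap_fraction · effect / mean_f. ``se`` is the IVW standard error scale
    at which the inflated type-I error of the nominal test is evaluated.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction outside [0, 1]")
    if mean_f <= 0:
        raise ValueError("mean_f must be positive")
    if se <= 0:
        raise ValueError("se must be positive")
    bias = overlap_fraction * assumed_confounded_effect / mean_f
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = bias / se
    type1 = float(stats.norm.sf(z - shift) + stats.norm.cdf(-z - shift))
    return OverlapBiasReport(
        overlap_fraction=overlap_fraction,
        assumed_confounded_effect=assumed_confounded_effect,
        mean_f=mean_f, expected_bias=bias,
        expected_type1_error=type1, se=se,
    )
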