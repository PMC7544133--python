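"""Phenome-wide association of a quantitative predictor against phecodes.

ICD-like diagnosis codes are mapped to phecodes; per phecode, individuals are
assigned case status (≥ ``min_code_count`` occurrences), excluded from the
control pool when they carry a code in the phecode's exclusion range, or kept
as controls. Each phenotype with enough cases is tested by logistic regression
of case status on the standardized predictor (measured height or the height
genetic risk score) adjusted for age, age², sex, and genetic principal
components, with Bonferroni control over the number of phenotypes tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


class PhecodeMap:
    """Source code → phecode mapping with exclusion ranges and labels.

    Construct from a frame with columns code, phecode, label,
    exclusion_range_start, exclusion_range_end, and optional sex_flag
    ("female"/"male" restricting the phenotype to one sex).
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.empty:
            raise ValueError("empty phecode map")
        self.frame = frame.copy()
        self.frame["phecode"] = self.frame["phecode"].astype(str)
        self.code_to_phecode = dict(zip(self.frame["code"].astype(str),
                                        self.frame["phecode"]))
        grouped = self.frame.drop_duplicates("phecode").set_index("phecode")
        self.labels = grouped["label"].to_dict()
        self.exclusion_ranges = {
            ph: (float(r["exclusion_range_start"]),
                 float(r["exclusion_range_end"]))
            for ph, r in grouped.iterrows()}
        self.sex_flags = (grouped["sex_flag"].dropna().to_dict()
                          if "sex_flag" in grouped.columns else {})
        for ph, (lo, hi) in self.exclusion_ranges.items():
            if not (lo <= float(ph) <= hi):
                # range excludes neighbours only; the phecode itself is the case
                # definition, so it must still fall inside its declared range
                raise ValueError(f"phecode {ph} outside its exclusion range "
                                 f"[{lo}, {hi}]")

    @classmethod
    def from_csv(cls, path) -> "PhecodeMap":
        return cls(pd.read_csv(path, dtype={"code": str, "phecode": str}))

    @property
    def phecodes(self) -> list[str]:
        return sorted(self.labels, key=float)

    def in_exclusion_range(self, phecode: str, other: str) -> bool:
        lo, hi = self.exclusion_ranges[phecode]
        return lo <= float(other) <= hi and other != phecode


def assign_case_control(code_records: dict, pmap: PhecodeMap,
                        min_code_count: int = 2,
                        sex: pd.Series | None = None) -> pd.DataFrame:
    """Per-phenotype case/control/excluded assignment.

    ``code_records`` maps individual id → list of source codes (with
    repetitions carrying the occurrence counts). Returns a frame indexed by
    individual with one column per phecode: 1 = case, 0 = control,
    NaN = excluded (a code in the exclusion range without reaching the case
    threshold). Unmapped codes are counted and logged. When ``sex`` is given
    (1 = female), individuals of the non-applicable sex are excluded from
    phenotypes the map flags as sex-specific.
    """
    phecodes = pmap.phecodes
    ids = list(code_records)
    counts = pd.DataFrame(0, index=ids, columns=phecodes, dtype=int)
    n_unmapped = 0
    for ind, codes in code_records.items():
        for code in codes:
            ph = pmap.code_to_phecode.get(str(code))
            if ph is None:
                n_unmapped += 1
                continue
            counts.loc[ind, ph] += 1
    if n_unmapped:
        logger.info("%d code occurrence(s) did not map to any phecode",
                    n_unmapped)

    out = pd.DataFrame(0.0, index=ids, columns=phecodes)
    carried = counts > 0
    for ph in phecodes:
        case = counts[ph] >= min_code_count
        # excluded: any code whose phecode falls in this phenotype's range
        in_range = [q for q in phecodes if pmap.in_exclusion_range(ph, q)]
        excl = carried[in_range].any(axis=1) | (carried[ph] & ~case)
        col = np.where(case, 1.0, np.where(excl, np.nan, 0.0))
        flag = pmap.sex_flags.get(ph)
        if flag is not None and sex is not None:
            wrong_sex = (sex.loc[ids] == 0).to_numpy() if flag == "female" \
                else (sex.loc[ids] == 1).to_numpy()
            col = np.where(wrong_sex, np.nan, col)
        out[ph] = col
    return out


@dataclass
class PhewasResults:
    """Per-phenotype association results with Bonferroni flags."""

    table: pd.DataFrame
    n_tested: int
    alpha: float
    bonferroni_threshold: float
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant_bonferroni"]]

    def summary(self, top: int = 10) -> str:
        lines = [
            f"PheWAS: {self.n_tested} phenotypes tested, Bonferroni "
            f"threshold {self.bonferroni_threshold:.3g} "
            f"(alpha {self.alpha})",
            f"  {len(self.significant())} phenotype(s) significant",
        ]
        shown = self.table.nsmallest(top, "pvalue")
        for _, r in shown.iterrows():
            star = "*" if r["significant_bonferroni"] else " "
            lines.append(
                f"  {star} {r['phecode']:>7s} {r['label'][:32]:<32s} "
                f"OR {r['odds_ratio']:.3f} p {r['pvalue']:.2e} "
                f"({int(r['n_cases'])}/{int(r['n_controls'])})")
        return "\n".join(lines)


class PheWAS:
    """Phenome-wide logistic-regression model.

    Parameters
    ----------
    covariates
        Frame with age, sex and principal-component columns, indexed by
        individual.
    predictor
        Standardized predictor series (measured height or GRS), same index.
    assignments
        Case/control/excluded frame from :func:`assign_case_control` (or any
        per-phenotype 1/0/NaN frame; column names are phenotype identifiers).
    """

    def __init__(self, covariates: pd.DataFrame, predictor: pd.Series,
                 assignments: pd.DataFrame, n_pcs: int = 10,
                 min_cases: int = 20, labels: dict | None = None):
        z = predictor.std(ddof=0)
        if not np.isclose(predictor.mean(), 0.0, atol=1e-6) or \
                not np.isclose(z, 1.0, atol=1e-6):
            predictor = (predictor - predictor.mean()) / z
        self.predictor = predictor
        self.covariates = covariates
        self.assignments = assignments
        self.n_pcs = n_pcs
        self.min_cases = min_cases
        self.labels = labels or {}

    def _design(self) -> pd.DataFrame:
        cov = self.covariates
        pcs = [f"PC{i}" for i in range(1, self.n_pcs + 1)]
        missing = [c for c in pcs if c not in cov.columns]
        if missing:
            raise ValueError(f"covariates lack principal components {missing}")
        x = pd.DataFrame({
            "predictor": self.predictor,
            "age": cov["age"], "age2": cov["age"] ** 2, "sex": cov["sex"],
        }, index=cov.index)
        for c in pcs:
            x[c] = cov[c]
        return sm.add_constant(x)

    def fit(self, alpha: float = 0.05) -> PhewasResults:
        x_full = self._design()
        rows, skipped = [], []
        for ph in self.assignments.columns:
            status = self.assignments[ph]
            mask = status.notna()
            n_cases = int((status == 1).sum())
            n_controls = int((status == 0).sum())
            if n_cases < self.min_cases:
                skipped.append({"phecode": ph, "reason":
                                f"n_cases {n_cases} < {self.min_cases}"})
                continue
            y = status[mask]
            x = x_full.loc[y.index]
            try:
                with np.errstate(over="ignore"):
                    fit = sm.Logit(y, x).fit(disp=False, maxiter=100)
                if not fit.mle_retvals.get("converged", True) or \
                        not np.isfinite(fit.bse["predictor"]):
                    raise ValueError("non-convergent fit")
            except Exception as exc:  # noqa: BLE001 - any fit failure is skipped
                skipped.append({"phecode": ph, "reason": str(exc)})
                logger.warning("phecode %s skipped: %s", ph, exc)
                continue
            beta = float(fit.params["predictor"])
            se = float(fit.bse["predictor"])
            rows.append({
                "phecode": ph,
                "label": self.labels.get(ph, ph),
                "n_cases": n_cases, "n_controls": n_controls,
                "beta": beta, "se": se,
                "odds_ratio": float(np.exp(beta)),
                "pvalue": float(fit.pvalues["predictor"]),
            })
        table = pd.DataFrame(rows)
        n_tested = len(table)
        threshold = alpha / n_tested if n_tested else np.nan
        if n_tested:
            table["significant_bonferroni"] = table["pvalue"] < threshold
        return PhewasResults(table=table, n_tested=n_tested, alpha=alpha,
                             bonferroni_threshold=threshold,
                             skipped=pd.DataFrame(skipped,
                                                  columns=["phecode", "reason"]))


def run_phewas(covariates: pd.DataFrame, predictor: pd.Series,
               assignments: pd.DataFrame, n_pcs: int = 10,
               min_cases: int = 20, alpha: float = 0.05,
               labels: dict | None = None) -> PhewasResults:
    """Functional wrapper around :class:`PheWAS`."""
    return PheWAS(covariates, predictor, assignments, n_pcs=n_pcs,
                  min_cases=min_cases, labels=labels).fit(alpha=alpha)


def bonferroni_threshold(alpha: float, n_phenotypes: int) -> float:
    """Family-wise threshold alpha / number of tested phenotypes."""
    if n_phenotypes <= 0:
        raise ValueError("n_phenotypes must be positive")
    return alpha / n_phenotypes
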