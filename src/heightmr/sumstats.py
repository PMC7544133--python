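"""GWAS summary statistics: reading, validation, allele harmonization, LD clumping.

Summary statistics are carried as pandas DataFrames with the canonical columns

    variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pvalue, n

(one row per biallelic SNP). ``read_summary_stats`` validates rows against the
record invariants and rejects malformed ones with a logged warning; indels and
multi-allelic sites are rejected at read time because the instruments used
downstream are SNP-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for a summary-statistics frame
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization actions recorded per variant
ACTION_UNCHANGED = "unchanged"
ACTION_FLIPPED = "flipped"
ACTION_INFERRED_PALINDROMIC = "inferred_palindromic"
ACTION_DROPPED_PALINDROMIC = "dropped_palindromic"
ACTION_DROPPED_INCOMPATIBLE = "dropped_incompatible"


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association estimate in one GWAS."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.effect_allele not in _NUCLEOTIDES or self.other_allele not in _NUCLEOTIDES:
            problems.append("alleles must be single uppercase nucleotides (SNPs only)")
        elif self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if not np.isfinite(self.se) or self.se <= 0:
            problems.append("se must be positive and finite")
        if not (0.0 <= self.eaf <= 1.0):
            problems.append("eaf outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append("pvalue outside (0, 1]")
        if self.n <= 0:
            problems.append("n must be positive")
        if not np.isfinite(self.beta):
            problems.append("beta must be finite")
        return problems


def _pvalue_consistency_warning(df: pd.DataFrame) -> int:
    """Warn when p is inconsistent with |beta/se| by > 2 orders of magnitude."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
        expected = 2.0 * stats.norm.sf(z)
    # compare on log10 scale; guard the p = 0 underflow of the normal tail
    expected = np.clip(expected, 1e-300, 1.0)
    observed = np.clip(df["pvalue"].to_numpy(), 1e-300, 1.0)
    off = np.abs(np.log10(expected) - np.log10(observed)) > 2.0
    n_off = int(off.sum())
    if n_off:
        ids = df.loc[off, "variant_id"].head(5).tolist()
        logger.warning(
            "%d variant(s) have p-values inconsistent with beta/se by >2 orders "
            "of magnitude (e.g. %s)", n_off, ids)
    return n_off


def validate_summary_stats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw frame into (valid rows, rejected rows with a 'reason' column)."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal reasons
        mask = mask.fillna(True) if mask.isna().any() else mask
        reasons[mask & (reasons == "")] = reason

    allele_ok = (
        df["effect_allele"].isin(_NUCLEOTIDES)
        & df["other_allele"].isin(_NUCLEOTIDES)
        & (df["effect_allele"] != df["other_allele"])
    )
    flag(~allele_ok, "invalid or non-SNP alleles")
    for col in ("eaf", "beta", "se", "pvalue", "n", "pos"):
        flag(~np.isfinite(df[col].astype(float)), f"unparseable {col}")
    flag(~(df["se"] > 0), "se must be > 0")
    flag(~df["eaf"].between(0.0, 1.0), "eaf outside [0, 1]")
    flag(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue outside (0, 1]")
    flag(~(df["n"] > 0), "n must be > 0")

    bad = reasons != ""
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    valid = df[~bad].copy()
    valid["pos"] = valid["pos"].astype(np.int64)
    valid["n"] = valid["n"].astype(np.int64)
    for col in ("eaf", "beta", "se", "pvalue"):
        valid[col] = valid[col].astype(float)
    if len(valid):
        _pvalue_consistency_warning(valid)
    return valid, rejected


def sniff_delimiter(path) -> str:
    """Detect tab vs comma delimiting from the header line (gzip-aware)."""
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty summary-statistics file: {path}")
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_summary_stats(path, column_map: Mapping[str, str] | None = None,
                       sep: str | None = None) -> pd.DataFrame:
    """Read a delimited summary-statistics file into the canonical frame.

    Parameters
    ----------
    path
        Tab- or comma-delimited text, optionally gzip-compressed, with header.
    column_map
        Mapping from canonical name to the file's column name, e.g.
        ``{"variant_id": "SNP", "pvalue": "P"}``. Unmapped canonical names are
        assumed to appear verbatim.
    sep
        Field delimiter; sniffed when ``None``.

    Malformed rows are dropped with a logged warning carrying their (1-based,
    header-inclusive) line numbers. Missing required columns or an empty file
    raise ``ValueError``.
    """
    if sep is None:
        sep = sniff_delimiter(path)
    try:
        # round_trip parsing keeps write -> read bit-identical
        raw = pd.read_csv(path, sep=sep, dtype={"chrom": str},
                          float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty summary-statistics file: {path}") from exc
    if raw.empty:
        raise ValueError(f"summary-statistics file has no data rows: {path}")

    column_map = dict(column_map or {})
    rename = {}
    for canonical in COLUMNS:
        source = column_map.get(canonical, canonical)
        if source not in raw.columns:
            raise ValueError(f"required column {source!r} (for {canonical!r}) "
                             f"missing from {path}")
        rename[source] = canonical
    df = raw.rename(columns=rename)[COLUMNS].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for allele_col in ("effect_allele", "other_allele"):
        df[allele_col] = df[allele_col].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    valid, rejected = validate_summary_stats(df)
    if len(rejected):
        for idx, row in rejected.iterrows():
            logger.warning("rejected row at line %d (%s): %s",
                           idx + 2, row.get("variant_id", "?"), row["reason"])
    valid = valid.reset_index(drop=True)
    valid.attrs["n_rejected"] = len(rejected)
    return valid


def write_summary_stats(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write the canonical frame as delimited text (gzip if path ends in .gz).

    Floats use repr-round-trip formatting so read_summary_stats reproduces the
    values bit-identically.
    """
    df[COLUMNS].to_csv(path, sep=sep, index=False, float_format="%.17g")


def records_to_frame(records: Iterable[SummaryStatRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    return [SummaryStatRecord(**{k: row[k] for k in COLUMNS})
            for _, row in df.iterrows()]


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    return _COMPLEMENT.get(a1) == a2


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------

class LDPanel:
    """Pairwise r² lookup over a set of variants.

    r²(a, a) = 1, r² is symmetric, and pairs on different chromosomes are 0 by
    definition. Variants absent from the panel are treated as unlinked (r² = 0)
    with a one-time logged warning, so clumping never silently drops data.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float],
                 chrom: Mapping[str, str] | None = None):
        self._r2: dict[tuple[str, str], float] = {}
        for (a, b), val in pairs.items():
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"r² outside [0, 1] for pair ({a}, {b}): {val}")
            self._r2[(a, b) if a <= b else (b, a)] = float(val)
        self._chrom = dict(chrom or {})
        self._known = set(self._chrom)
        for a, b in self._r2:
            self._known.update((a, b))
        self._warned_missing: set[str] = set()

    @classmethod
    def from_pair_frame(cls, df: pd.DataFrame,
                        chrom: Mapping[str, str] | None = None) -> "LDPanel":
        """Build from a 3-column frame (id1, id2, r2)."""
        id1, id2, r2 = df.columns[:3]
        pairs = {(a, b): v for a, b, v in zip(df[id1], df[id2], df[r2])}
        return cls(pairs, chrom=chrom)

    @classmethod
    def from_dosages(cls, dosages: pd.DataFrame,
                     chrom: Mapping[str, str] | None = None) -> "LDPanel":
        """Compute r² as the squared Pearson correlation of dosage columns.

        ``dosages``: individuals × variants. Zero-variance variants get r² = 0
        against everything, with a warning.
        """
        ids = list(dosages.columns)
        x = dosages.to_numpy(dtype=float)
        sd = x.std(axis=0)
        degenerate = sd == 0
        if degenerate.any():
            logger.warning("LD panel: %d zero-variance variant(s); their pairs "
                           "are defined as r²=0", int(degenerate.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(x, rowvar=False)
        corr = np.atleast_2d(corr)
        r2 = np.square(np.nan_to_num(corr, nan=0.0))
        pairs = {}
        for i in range(len(ids)):
            for j in range(i, len(ids)):
                if degenerate[i] or degenerate[j]:
                    val = 0.0
                elif i == j:
                    val = 1.0
                else:
                    val = float(r2[i, j])
                pairs[(ids[i], ids[j])] = val
        panel = cls(pairs, chrom=chrom)
        return panel

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        ca, cb = self._chrom.get(a), self._chrom.get(b)
        if ca is not None and cb is not None and ca != cb:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in self._r2:
            return self._r2[key]
        for v in (a, b):
            if v not in self._known and v not in self._warned_missing:
                logger.warning("variant %s absent from LD panel; treated as "
                               "unlinked (r²=0)", v)
                self._warned_missing.add(v)
        return 0.0

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._known


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _check_unique(df: pd.DataFrame, label: str) -> None:
    dup = df["variant_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate variant_id in {label} study: "
                         f"{sorted(df.loc[dup, 'variant_id'].unique())[:5]}")


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindrome_eaf_limit: float = 0.42) -> pd.DataFrame:
    """Align exposure and outcome effects to the exposure's effect allele.

    For each variant present in both studies the outcome's allele pair is
    matched to the exposure's, directly or on the opposite strand. A reversed
    pair has its beta negated and eaf complemented. Palindromic variants (A/T,
    C/G) are orientation-ambiguous: the strand is inferred from allele-frequency
    agreement when both eafs lie outside [limit, 1-limit], otherwise the
    variant is dropped. Irreconcilable allele pairs are dropped and logged.

    Returns the harmonized instrument frame (retained variants only) with
    columns variant_id, chrom, pos, effect_allele, other_allele,
    beta_exposure, se_exposure, pvalue_exposure, eaf_exposure, n_exposure,
    beta_outcome, se_outcome, pvalue_outcome, eaf_outcome, n_outcome, action.
    Dropped variants are recorded in ``result.attrs["dropped"]``.
    """
    if not (0.0 < palindrome_eaf_limit < 0.5):
        raise ValueError("palindrome_eaf_limit must lie in (0, 0.5)")
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")

    merged = exposure.merge(outcome, on="variant_id", suffixes=("_exp", "_out"),
                            how="inner")
    if merged.empty:
        raise ValueError("no overlapping variants between exposure and outcome")

    rows, dropped = [], []
    for _, r in merged.iterrows():
        e1, e2 = r["effect_allele_exp"], r["other_allele_exp"]
        o1, o2 = r["effect_allele_out"], r["other_allele_out"]
        beta_o, eaf_o = r["beta_out"], r["eaf_out"]
        action = None
        if is_palindromic(e1, e2):
            if {o1, o2} != {e1, e2}:
                action = ACTION_DROPPED_INCOMPATIBLE
            else:
                lo, hi = palindrome_eaf_limit, 1.0 - palindrome_eaf_limit
                eaf_o_aligned = eaf_o if o1 == e1 else 1.0 - eaf_o
                eaf_e = r["eaf_exp"]
                if (lo <= eaf_e <= hi) or (lo <= eaf_o_aligned <= hi):
                    action = ACTION_DROPPED_PALINDROMIC
                else:
                    # frequencies on the same side of 0.5 => same strand
                    if (eaf_e < 0.5) != (eaf_o_aligned < 0.5):
                        beta_o, eaf_o_aligned = -beta_o, 1.0 - eaf_o_aligned
                    eaf_o = eaf_o_aligned
                    action = ACTION_INFERRED_PALINDROMIC
        else:
            c1, c2 = _COMPLEMENT.get(o1, "?"), _COMPLEMENT.get(o2, "?")
            if (o1, o2) == (e1, e2) or (c1, c2) == (e1, e2):
                action = ACTION_UNCHANGED
            elif (o2, o1) == (e1, e2) or (c2, c1) == (e1, e2):
                beta_o, eaf_o = -beta_o, 1.0 - eaf_o
                action = ACTION_FLIPPED
            else:
                action = ACTION_DROPPED_INCOMPATIBLE
        if action in (ACTION_DROPPED_PALINDROMIC, ACTION_DROPPED_INCOMPATIBLE):
            dropped.append({"variant_id": r["variant_id"], "action": action})
            if action == ACTION_DROPPED_INCOMPATIBLE:
                logger.warning("variant %s: allele pair %s/%s vs %s/%s cannot "
                               "be reconciled; dropped", r["variant_id"],
                               e1, e2, o1, o2)
            continue
        rows.append({
            "variant_id": r["variant_id"],
            "chrom": r["chrom_exp"], "pos": r["pos_exp"],
            "effect_allele": e1, "other_allele": e2,
            "beta_exposure": r["beta_exp"], "se_exposure": r["se_exp"],
            "pvalue_exposure": r["pvalue_exp"], "eaf_exposure": r["eaf_exp"],
            "n_exposure": r["n_exp"],
            "beta_outcome": beta_o, "se_outcome": r["se_out"],
            "pvalue_outcome": r["pvalue_out"], "eaf_outcome": eaf_o,
            "n_outcome": r["n_out"],
            "action": action,
        })
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = pd.DataFrame(dropped, columns=["variant_id", "action"])
    if out.empty:
        raise ValueError("harmonization retained zero variants")
    return out.reset_index(drop=True)


def harmonized_to_outcome_frame(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Re-express a harmonized instrument's outcome side as a summary frame.

    Used to verify idempotence: harmonizing the exposure side against this
    frame reproduces the harmonized instrument.
    """
    return pd.DataFrame({
        "variant_id": harmonized["variant_id"],
        "chrom": harmonized["chrom"], "pos": harmonized["pos"],
        "effect_allele": harmonized["effect_allele"],
        "other_allele": harmonized["other_allele"],
        "eaf": harmonized["eaf_outcome"], "beta": harmonized["beta_outcome"],
        "se": harmonized["se_outcome"], "pvalue": harmonized["pvalue_outcome"],
        "n": harmonized["n_outcome"],
    })


def harmonized_to_exposure_frame(harmonized: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "variant_id": harmonized["variant_id"],
        "chrom": harmonized["chrom"], "pos": harmonized["pos"],
        "effect_allele": harmonized["effect_allele"],
        "other_allele": harmonized["other_allele"],
        "eaf": harmonized["eaf_exposure"], "beta": harmonized["beta_exposure"],
        "se": harmonized["se_exposure"], "pvalue": harmonized["pvalue_exposure"],
        "n": harmonized["n_exposure"],
    })


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def clump(records: pd.DataFrame, ld: LDPanel, window_kb: int = 10_000,
          r2_threshold: float = 0.001, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Greedy LD clumping of a summary-statistics frame.

    Only variants with p < ``p_threshold`` enter. Variants are visited in order
    of ascending p (ties broken by chrom, pos, variant_id for determinism);
    each retained index variant discards every remaining variant on the same
    chromosome within ±``window_kb`` kb (inclusive) with r² > ``r2_threshold``.
    The retained set is returned sorted by (chrom, pos).
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    sig = records[records["pvalue"] < p_threshold].copy()
    if sig.empty:
        logger.warning("no variants pass p < %g; clumped set is empty", p_threshold)
        return sig.reset_index(drop=True)

    sig = sig.sort_values(["pvalue", "chrom", "pos", "variant_id"],
                          kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1000
    alive = np.ones(len(sig), dtype=bool)
    keep = []
    chroms = sig["chrom"].to_numpy()
    positions = sig["pos"].to_numpy()
    ids = sig["variant_id"].to_numpy()
    for i in range(len(sig)):
        if not alive[i]:
            continue
        keep.append(i)
        near = (alive & (chroms == chroms[i])
                & (np.abs(positions - positions[i]) <= window_bp))
        near[i] = False
        for j in np.flatnonzero(near):
            if ld.r2(ids[i], ids[j]) > r2_threshold:
                alive[j] = False
    out = sig.iloc[keep].sort_values(["chrom", "pos", "variant_id"],
                                     kind="mergesort").reset_index(drop=True)
    return out
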