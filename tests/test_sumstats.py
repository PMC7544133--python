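"""Summary-statistics IO, allele harmonization, and LD clumping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heightmr.sumstats import (
    ACTION_DROPPED_PALINDROMIC, ACTION_FLIPPED, ACTION_INFERRED_PALINDROMIC,
    ACTION_UNCHANGED, COLUMNS, LDPanel, SummaryStatRecord, clump, harmonize,
    harmonized_to_exposure_frame, harmonized_to_outcome_frame,
    read_summary_stats, write_summary_stats)

from conftest import make_sumstats


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

class TestReadWrite:
    def test_well_formed_file_round_trips_bit_identically(self, tmp_path):
        rng = np.random.default_rng(5)
        df = make_sumstats([
            {"eaf": float(rng.uniform(0.01, 0.99)),
             "beta": float(rng.normal(0, 0.1)),
             "se": float(rng.uniform(1e-4, 0.05)),
             "pvalue": float(rng.uniform(1e-12, 1.0)),
             "n": int(rng.integers(1_000, 700_000))}
            for _ in range(20)])
        path = tmp_path / "stats.tsv"
        write_summary_stats(df, path)
        back = read_summary_stats(path)
        pd.testing.assert_frame_equal(back, df, check_exact=True)

    def test_gzip_transparent(self, tmp_path):
        df = make_sumstats([{}, {}])
        path = tmp_path / "stats.tsv.gz"
        write_summary_stats(df, path)
        back = read_summary_stats(path)
        pd.testing.assert_frame_equal(back, df)

    def test_invalid_rows_rejected_with_count(self, tmp_path):
        df = make_sumstats([{}, {"se": 0.0}, {}])
        path = tmp_path / "stats.tsv"
        write_summary_stats(df, path)
        back = read_summary_stats(path)
        assert len(back) == 2
        assert back.attrs["n_rejected"] == 1

    def test_indels_rejected(self, tmp_path):
        df = make_sumstats([{}, {"effect_allele": "AT"}])
        path = tmp_path / "stats.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_summary_stats(path)
        assert len(back) == 1

    def test_missing_column_is_hard_error(self, tmp_path):
        df = make_sumstats([{}]).drop(columns=["se"])
        path = tmp_path / "stats.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="se"):
            read_summary_stats(path)

    def test_column_map_resolves_names(self, tmp_path):
        df = make_sumstats([{}]).rename(columns={"variant_id": "SNP",
                                                 "pvalue": "P"})
        path = tmp_path / "stats.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = read_summary_stats(path, column_map={"variant_id": "SNP",
                                                    "pvalue": "P"})
        assert list(back.columns) == COLUMNS

    def test_empty_file_is_hard_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            read_summary_stats(path)

    def test_record_validation_reports_violations(self):
        good = SummaryStatRecord("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.01,
                                 1e-8, 1000)
        assert good.validate() == []
        bad = SummaryStatRecord("rs1", "1", 100, "A", "A", 1.3, 0.1, -1.0,
                                2.0, 0)
        assert len(bad.validate()) >= 4


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

class TestHarmonize:
    def _pair(self, exp_alleles, out_alleles, out_beta=0.05, out_eaf=0.7,
              exp_eaf=0.30):
        exposure = make_sumstats([{
            "effect_allele": exp_alleles[0], "other_allele": exp_alleles[1],
            "beta": 0.02, "eaf": exp_eaf}])
        outcome = make_sumstats([{
            "effect_allele": out_alleles[0], "other_allele": out_alleles[1],
            "beta": out_beta, "eaf": out_eaf}])
        return exposure, outcome

    def test_matching_alleles_unchanged(self):
        h = harmonize(*self._pair(("A", "G"), ("A", "G")))
        assert h.loc[0, "action"] == ACTION_UNCHANGED
        assert h.loc[0, "beta_outcome"] == 0.05

    def test_swapped_alleles_flip_beta_and_eaf(self):
        h = harmonize(*self._pair(("A", "G"), ("G", "A")))
        assert h.loc[0, "action"] == ACTION_FLIPPED
        assert h.loc[0, "beta_outcome"] == -0.05
        assert h.loc[0, "eaf_outcome"] == pytest.approx(0.3)

    def test_opposite_strand_same_order_unchanged(self):
        h = harmonize(*self._pair(("A", "G"), ("T", "C")))
        assert h.loc[0, "action"] == ACTION_UNCHANGED
        assert h.loc[0, "beta_outcome"] == 0.05

    def test_opposite_strand_swapped_flips(self):
        h = harmonize(*self._pair(("A", "G"), ("C", "T")))
        assert h.loc[0, "action"] == ACTION_FLIPPED
        assert h.loc[0, "beta_outcome"] == -0.05

    def test_irreconcilable_alleles_dropped(self):
        exposure, outcome = self._pair(("A", "G"), ("A", "C"))
        extra = make_sumstats([{}])
        extra["variant_id"] = ["rs99"]
        with pytest.raises(ValueError, match="zero variants"):
            harmonize(exposure, outcome)

    def test_palindromic_resolution_matches_strand_enumeration(self):
        """Frequency inference must agree with exhaustive strand enumeration.

        For an A/T variant the outcome may be reported on either strand; the
        only evidence is eaf agreement. The oracle enumerates both strand
        configurations, keeps those consistent with the frequencies, and
        expects a unique answer exactly when both eafs sit outside the
        ambiguity band.
        """
        limit = 0.42
        for exp_eaf, out_eaf in itertools.product(
                [0.05, 0.10, 0.30, 0.44, 0.56, 0.88, 0.95], repeat=2):
            exposure, outcome = self._pair(("A", "T"), ("A", "T"),
                                           out_eaf=out_eaf, exp_eaf=exp_eaf)
            # oracle: candidate orientations (same strand, flipped strand)
            candidates = []
            for flip in (False, True):
                eaf = 1.0 - out_eaf if flip else out_eaf
                if (eaf < 0.5) == (exp_eaf < 0.5):
                    candidates.append(flip)
            ambiguous = (limit <= exp_eaf <= 1 - limit) or \
                        (limit <= out_eaf <= 1 - limit)
            if ambiguous or len(candidates) != 1:
                with pytest.raises(ValueError):
                    harmonize(exposure, outcome, palindrome_eaf_limit=limit)
                continue
            h = harmonize(exposure, outcome, palindrome_eaf_limit=limit)
            assert h.loc[0, "action"] == ACTION_INFERRED_PALINDROMIC
            expected_beta = -0.05 if candidates[0] else 0.05
            assert h.loc[0, "beta_outcome"] == pytest.approx(expected_beta)

    def test_palindromic_discordant_frequencies_infer_flip(self):
        exposure, outcome = self._pair(("A", "T"), ("A", "T"),
                                       out_eaf=0.88, exp_eaf=0.10)
        h = harmonize(exposure, outcome, palindrome_eaf_limit=0.42)
        assert h.loc[0, "action"] == ACTION_INFERRED_PALINDROMIC
        assert h.loc[0, "beta_outcome"] == pytest.approx(-0.05)
        # eaf near 0.5 on the outcome side: no inference possible
        exposure, outcome = self._pair(("A", "T"), ("A", "T"),
                                       out_eaf=0.48, exp_eaf=0.10)
        with pytest.raises(ValueError):
            # single-variant study: the drop empties the instrument
            harmonize(exposure, outcome, palindrome_eaf_limit=0.42)

    def test_palindromic_drop_recorded(self):
        exposure = make_sumstats([
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.45},
            {"effect_allele": "A", "other_allele": "G"}])
        outcome = exposure.copy()
        outcome["beta"] = 0.05
        h = harmonize(exposure, outcome)
        assert len(h) == 1
        dropped = h.attrs["dropped"]
        assert list(dropped["action"]) == [ACTION_DROPPED_PALINDROMIC]

    def test_duplicate_variant_id_is_hard_error(self):
        exposure = make_sumstats([{}, {}])
        exposure["variant_id"] = ["rs1", "rs1"]
        with pytest.raises(ValueError, match="duplicate"):
            harmonize(exposure, make_sumstats([{}]))

    def test_harmonize_idempotent_on_own_output(self, study_bundle):
        h1 = harmonize(study_bundle.exposure_stats, study_bundle.outcome_stats)
        h2 = harmonize(harmonized_to_exposure_frame(h1),
                       harmonized_to_outcome_frame(h1))
        pd.testing.assert_frame_equal(
            h1.reset_index(drop=True), h2.reset_index(drop=True),
            check_exact=False)
        assert (h2["action"] == ACTION_UNCHANGED).all()

    def test_flipping_all_outcome_alleles_gives_identical_result(
            self, study_bundle):
        outcome = study_bundle.outcome_stats
        flipped = outcome.copy()
        flipped["effect_allele"] = outcome["other_allele"]
        flipped["other_allele"] = outcome["effect_allele"]
        flipped["beta"] = -outcome["beta"]
        flipped["eaf"] = 1.0 - outcome["eaf"]
        h1 = harmonize(study_bundle.exposure_stats, outcome)
        h2 = harmonize(study_bundle.exposure_stats, flipped)
        for col in ("beta_outcome", "eaf_outcome", "se_outcome"):
            np.testing.assert_allclose(h1[col], h2[col], atol=1e-12)


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------

class TestLDPanel:
    def test_identity_symmetry_and_cross_chromosome(self):
        panel = LDPanel({("rs1", "rs2"): 0.5},
                        chrom={"rs1": "1", "rs2": "1", "rs3": "2"})
        assert panel.r2("rs1", "rs1") == 1.0
        assert panel.r2("rs1", "rs2") == panel.r2("rs2", "rs1") == 0.5
        assert panel.r2("rs1", "rs3") == 0.0

    def test_missing_variant_treated_unlinked(self):
        panel = LDPanel({("rs1", "rs2"): 0.5})
        assert panel.r2("rs1", "rs_unknown") == 0.0

    def test_out_of_range_r2_rejected(self):
        with pytest.raises(ValueError):
            LDPanel({("rs1", "rs2"): 1.5})

    def test_from_dosages_duplicate_column_r2_one(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, size=200).astype(float)
        dosages = pd.DataFrame({"rs1": g, "rs2": g,
                                "rs3": rng.binomial(2, 0.4, 200)})
        panel = LDPanel.from_dosages(dosages)
        assert panel.r2("rs1", "rs2") == pytest.approx(1.0)
        assert panel.r2("rs1", "rs3") < 0.05

    def test_zero_variance_column_defined_as_zero(self):
        dosages = pd.DataFrame({"rs1": np.zeros(50),
                                "rs2": np.random.default_rng(1).binomial(
                                    2, 0.5, 50).astype(float)})
        panel = LDPanel.from_dosages(dosages)
        assert panel.r2("rs1", "rs2") == 0.0


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def _verify_clump(sig, ld, kept_df, window_kb, r2_threshold):
    """Exhaustively verify the greedy-clump definition on a small instance.

    Every retained pair must be unlinked-or-distant; every discarded variant
    must be linked and near a retained variant with better (p, chrom, pos, id)
    rank.
    """
    kept = set(kept_df["variant_id"])
    rank = {r.variant_id: (r.pvalue, r.chrom, r.pos, r.variant_id)
            for r in sig.itertuples()}
    meta = {r.variant_id: (r.chrom, r.pos) for r in sig.itertuples()}
    for a, b in itertools.combinations(kept, 2):
        ca, pa = meta[a]
        cb, pb = meta[b]
        assert (ca != cb or abs(pa - pb) > window_kb * 1000
                or ld.r2(a, b) <= r2_threshold)
    for v in set(sig["variant_id"]) - kept:
        cv, pv = meta[v]
        culprits = [u for u in kept
                    if meta[u][0] == cv
                    and abs(meta[u][1] - pv) <= window_kb * 1000
                    and ld.r2(u, v) > r2_threshold
                    and rank[u] < rank[v]]
        assert culprits, f"{v} was discarded but no retained variant explains it"


class TestClump:
    def test_single_significant_variant_retained(self):
        df = make_sumstats([{"pvalue": 1e-9}])
        out = clump(df, LDPanel({}))
        assert list(out["variant_id"]) == ["rs1"]

    def test_unlinked_chromosomes_both_retained(self):
        df = make_sumstats([{"chrom": "1"}, {"chrom": "2"}])
        out = clump(df, LDPanel({}))
        assert len(out) == 2

    def test_fully_linked_window_keeps_minimum_p(self):
        rows = [{"pos": 1_000_000 + 10_000 * i, "pvalue": 10 ** (-9 - i)}
                for i in range(5)]
        df = make_sumstats(rows)
        pairs = {(a, b): 0.5 for a, b in
                 itertools.combinations(df["variant_id"], 2)}
        out = clump(df, LDPanel(pairs))
        assert list(out["variant_id"]) == ["rs5"]  # smallest p

    def test_subthreshold_variants_never_enter(self):
        df = make_sumstats([{"pvalue": 1e-9}, {"pvalue": 1e-4}])
        out = clump(df, LDPanel({}), p_threshold=5e-8)
        assert list(out["variant_id"]) == ["rs1"]

    def test_empty_post_threshold_is_empty_not_error(self):
        df = make_sumstats([{"pvalue": 0.5}])
        out = clump(df, LDPanel({}))
        assert out.empty

    def test_nonpositive_window_is_hard_error(self):
        with pytest.raises(ValueError):
            clump(make_sumstats([{}]), LDPanel({}), window_kb=0)

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_exhaustive_verification(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))
        rows = [{"chrom": str(rng.integers(1, 3)),
                 "pos": int(rng.integers(1, 30_000_000)),
                 "pvalue": float(rng.uniform(1e-12, 1e-8))}
                for _ in range(k)]
        df = make_sumstats(rows)
        pairs = {}
        for a, b in itertools.combinations(range(k), 2):
            if df.loc[a, "chrom"] == df.loc[b, "chrom"]:
                pairs[(df.loc[a, "variant_id"], df.loc[b, "variant_id"])] = \
                    float(rng.uniform(0, 1))
        ld = LDPanel(pairs, chrom=dict(zip(df["variant_id"], df["chrom"])))
        out = clump(df, ld, window_kb=10_000, r2_threshold=0.1)
        _verify_clump(df, ld, out, window_kb=10_000, r2_threshold=0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(order_seed=st.integers(0, 10_000))
    def test_output_invariant_to_row_order(self, order_seed):
        rng = np.random.default_rng(3)
        rows = [{"chrom": "1", "pos": 1_000_000 + 5_000_000 * i,
                 "pvalue": float(rng.uniform(1e-12, 1e-8))}
                for i in range(6)]
        df = make_sumstats(rows)
        pairs = {(a, b): float(rng.uniform(0, 0.8)) for a, b in
                 itertools.combinations(df["variant_id"], 2)}
        ld = LDPanel(pairs)
        base = clump(df, ld, r2_threshold=0.2)
        shuffled = df.sample(frac=1.0, random_state=order_seed) \
            .reset_index(drop=True)
        out = clump(shuffled, ld, r2_threshold=0.2)
        pd.testing.assert_frame_equal(base, out)

    def test_retained_pair_property_on_simulated_panel(self, study_bundle):
        out = clump(study_bundle.exposure_stats, study_bundle.ld_panel,
                    p_threshold=5e-8)
        _verify_clump(
            study_bundle.exposure_stats[
                study_bundle.exposure_stats["pvalue"] < 5e-8],
            study_bundle.ld_panel, out, 10_000, 0.001)
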