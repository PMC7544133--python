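import numpy as np
import pandas as pd
import pytest

from heightmr.simulate import SimConfig, simulate_study
from heightmr.sumstats import COLUMNS


def make_sumstats(rows):
    """Build a canonical summary-statistics frame from row dicts.

    Missing fields get sensible defaults so tests only specify what matters.
    """
    defaults = {"chrom": "1", "effect_allele": "A", "other_allele": "G",
                "eaf": 0.3, "beta": 0.1, "se": 0.01, "pvalue": 1e-9,
                "n": 10_000}
    out = []
    for i, row in enumerate(rows):
        full = {"variant_id": f"rs{i + 1}", "pos": 1_000_000 * (i + 1),
                **defaults, **row}
        out.append(full)
    return pd.DataFrame(out)[COLUMNS]


@pytest.fixture
def sumstats_factory():
    return make_sumstats


@pytest.fixture(scope="session")
def study_bundle():
    """A moderately sized end-to-end synthetic study, shared across tests.

    Per-variant effects are strong enough (mean F ≈ 110) that variants
    genuinely clear genome-wide significance at the reduced sample size.
    """
    config = SimConfig(seed=11, n_variants=80, h2_instrument=0.45,
                       n_exposure_sample=20_000, n_outcome_cases=1_500,
                       n_outcome_controls=6_000, n_cohort=2_000)
    return simulate_study(config)


@pytest.fixture(scope="session")
def cohort_truth():
    """A cohort with the desk-scale defaults and a planted OR 1.75 per SD."""
    from heightmr.simulate import simulate_cohort
    config = SimConfig(seed=13, causal_log_or=float(np.log(1.75)),
                       n_cohort=4_000)
    return simulate_cohort(config)


@pytest.fixture
def phecode_map_frame():
    """Miniature phecode map (synthetic stand-in for the proprietary table)."""
    rows = [
        ("427.31", "427.2", "Atrial fibrillation and flutter", 427.0, 428.0, None),
        ("I48.0", "427.2", "Atrial fibrillation and flutter", 427.0, 428.0, None),
        ("I48.91", "427.2", "Atrial fibrillation and flutter", 427.0, 428.0, None),
        ("427.0", "427.1", "Paroxysmal tachycardia", 427.0, 428.0, None),
        ("414.01", "411.4", "Coronary atherosclerosis", 410.0, 414.99, None),
        ("I25.10", "411.4", "Coronary atherosclerosis", 410.0, 414.99, None),
        ("250.00", "250.2", "Type 2 diabetes", 249.0, 251.0, None),
        ("E11.9", "250.2", "Type 2 diabetes", 249.0, 251.0, None),
        ("185", "185.0", "Prostate cancer", 185.0, 187.0, "male"),
        ("C61", "185.0", "Prostate cancer", 185.0, 187.0, "male"),
        ("174.9", "174.1", "Breast cancer", 174.0, 175.99, "female"),
    ]
    return pd.DataFrame(rows, columns=[
        "code", "phecode", "label", "exclusion_range_start",
        "exclusion_range_end", "sex_flag"])
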