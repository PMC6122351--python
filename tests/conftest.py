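"""Shared fixtures: seeded synthetic cohorts and published report rows."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import normref as nr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


#: Published drug-report rows: (gene, log2FC, CV, ASG, TLV, variability).
#: The first four are the group-level tumor report, the rest the
#: personalized single-patient report.
PUBLISHED_REPORT_ROWS = [
    ("TUBB3", 3.4, 0.92, False, True, "high"),
    ("TOP2A", 3.1, 1.84, False, True, "high"),
    ("RET", 2.7, 1.72, False, False, "high"),
    ("ROS1", 2.2, 3.21, False, True, "high"),
    ("RAD51", 5.0, 0.56, True, False, "high"),
    ("TOP2A", 4.9, 0.50, False, True, "high"),
    ("AURKB", 4.5, 1.32, False, True, "high"),
    ("AURKA", 4.3, 0.59, False, False, "high"),
    ("CHEK1", 3.6, 0.49, False, False, "high"),
    ("CHEK2", 2.0, 0.27, False, True, "high"),
    ("NOTCH1", 2.0, 0.27, True, False, "high"),
    ("PARP1", 1.9, 0.13, False, False, "low"),
    ("PIK3R2", 1.9, 0.28, False, False, "low"),
    ("RRM1", 1.8, 0.14, True, False, "high"),
    ("SYK", 1.7, 0.35, True, False, "high"),
    ("CDK4", 1.6, 0.17, False, False, "low"),
    ("AKT1", 1.5, 0.16, True, False, "high"),
    ("MAP2K1", 1.4, 0.23, True, False, "high"),
    ("ALK", 1.3, 0.93, False, True, "high"),
    ("ERBB3", 1.1, 0.58, False, False, "high"),
]


@pytest.fixture(scope="session")
def cohort():
    """Default-design synthetic cohort (counts, metadata, truth)."""
    return nr.generate_cohort(nr.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def cohort_cpm(cohort):
    counts, meta, truth = cohort
    return nr.compute_cpm(counts)


@pytest.fixture(scope="session")
def cohort_meta_frame(cohort):
    _, meta, _ = cohort
    return nr.metadata_frame(meta)


@pytest.fixture(scope="session")
def ffpe_total_samples(cohort_meta_frame):
    f = cohort_meta_frame
    sel = (f.tissue == "breast_normal") & (f.asservation == "FFPE") & (f.kit == "total")
    return list(f.index[sel])


@pytest.fixture(scope="session")
def ffpe_total_pairs(cohort_cpm, cohort_meta_frame):
    """(left, right) CPM column pairs of the FFPE/total normal group."""
    f = cohort_meta_frame
    grp = f[(f.tissue == "breast_normal") & (f.asservation == "FFPE") & (f.kit == "total")]
    pairs, pair_ids = [], []
    for pair_id, members in grp[grp.pair_id.notna()].groupby("pair_id"):
        left = members.index[members.side == "L"][0]
        right = members.index[members.side == "R"][0]
        pairs.append((cohort_cpm.cpm[left], cohort_cpm.cpm[right]))
        pair_ids.append(pair_id)
    return pairs, pair_ids


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_count_matrix(rng, n_genes=50, n_samples=10, lam=30.0) -> nr.CountMatrix:
    counts = rng.poisson(lam, size=(n_genes, n_samples))
    counts[0, :] += 1  # guard against an all-zero library
    return nr.CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"G{i:03d}" for i in range(n_genes)],
            columns=[f"S{j:02d}" for j in range(n_samples)],
        )
    )
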