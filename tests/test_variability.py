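"""Coefficient-of-variation reference panels and the CV <-> fold-change map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import normref as nr


# ---------------------------------------------------------------------------
# gene_cv
# ---------------------------------------------------------------------------

def test_cv_constant_row_is_zero():
    df = pd.DataFrame([[5.0, 5.0, 5.0]], index=["G"])
    assert nr.gene_cv(df)["G"] == 0.0


def test_cv_small_example_sample_sd():
    """Row (100, 200, 300): mean 200, sample sd 100 (n-1 denominator)."""
    df = pd.DataFrame([[100.0, 200.0, 300.0]], index=["G"])
    assert nr.gene_cv(df)["G"] == pytest.approx(0.5, rel=1e-12)


def test_cv_zero_mean_is_undefined():
    df = pd.DataFrame([[0.0, 0.0], [1.0, 3.0]], index=["A", "B"])
    cv = nr.gene_cv(df)
    assert np.isnan(cv["A"]) and not np.isnan(cv["B"])


def test_cv_single_sample_group_rejected():
    with pytest.raises(nr.ValidationError):
        nr.gene_cv(pd.DataFrame([[1.0]], index=["G"]))


def test_cv_matches_per_gene_recomputation(rng):
    df = pd.DataFrame(rng.uniform(1, 100, size=(50, 9)))
    cv = nr.gene_cv(df)
    for g in df.index:
        row = df.loc[g].to_numpy()
        mean = row.sum() / len(row)
        sd = np.sqrt(((row - mean) ** 2).sum() / (len(row) - 1))
        assert cv[g] == pytest.approx(sd / mean, rel=1e-12)


@given(scale=st.floats(0.01, 1e4))
def test_cv_scale_invariance(scale):
    row = np.array([3.0, 8.0, 5.0, 11.0])
    base = nr.gene_cv(pd.DataFrame([row], index=["G"]))["G"]
    scaled = nr.gene_cv(pd.DataFrame([row * scale], index=["G"]))["G"]
    assert scaled == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# CV <-> maximal fold change
# ---------------------------------------------------------------------------

def test_cv_zero_maps_to_zero_fold_change():
    assert nr.cv_to_max_log2fc(0.0) == 0.0
    assert nr.cv_to_max_log2fc(0.0, z=2.58) == 0.0


def test_cv_030_stays_within_twofold_log2():
    """CV 0.30 at z=1.96 implies a maximal log2 fold change of about 1.95,
    i.e. the conventional threshold is (slightly conservatively) within
    the 2.0 budget."""
    value = nr.cv_to_max_log2fc(0.30, 1.96)
    assert value == pytest.approx(np.log2(1.588 / 0.412), rel=1e-12)
    assert value <= 2.0


def test_inverse_solves_fold_change_two():
    """The CV at which the 95% interval spans exactly 4-fold:
    (1 + 1.96 c) = 4 (1 - 1.96 c)  =>  c = 3 / 9.8."""
    assert nr.max_log2fc_to_cv(2.0, 1.96) == pytest.approx(3 / 9.8, rel=1e-12)


@given(cv=st.floats(0.0, 0.5))
def test_cv_fold_change_roundtrip(cv):
    fc = nr.cv_to_max_log2fc(cv, 1.96)
    assert nr.max_log2fc_to_cv(fc, 1.96) == pytest.approx(cv, abs=1e-9)


def test_cv_to_fold_change_strictly_increasing():
    grid = np.linspace(0, 0.5, 200)
    values = nr.cv_to_max_log2fc(grid, 1.96)
    assert np.all(np.diff(values) > 0)


def test_cv_out_of_domain_rejected():
    with pytest.raises(nr.ValidationError):
        nr.cv_to_max_log2fc(0.52, 1.96)  # lower bound would be nonpositive
    with pytest.raises(nr.ValidationError):
        nr.cv_to_max_log2fc(-0.1, 1.96)


# ---------------------------------------------------------------------------
# matched-pair fold change and the TLV set
# ---------------------------------------------------------------------------

def test_pair_log2fc_equal_columns_zero():
    col = pd.Series([1.0, 5.0, 9.0], index=list("abc"))
    assert (nr.matched_pair_log2fc(col, col, 0.5) == 0).all()


def test_pair_log2fc_exact_value_without_pseudocount():
    left = pd.Series([400.0], index=["G"])
    right = pd.Series([100.0], index=["G"])
    assert nr.matched_pair_log2fc(left, right, 0.0)["G"] == 2.0


def test_pair_log2fc_matches_per_gene_recomputation(rng):
    left = pd.Series(rng.uniform(0, 50, 40))
    right = pd.Series(rng.uniform(0, 50, 40))
    fc = nr.matched_pair_log2fc(left, right, 0.5)
    for g in left.index:
        assert fc[g] == pytest.approx(np.log2((left[g] + 0.5) / (right[g] + 0.5)), rel=1e-12)


def test_tlv_identical_pairs_empty():
    col = pd.Series([10.0, 20.0], index=["A", "B"])
    assert nr.tlv_gene_set([(col, col), (col, col)]) == set()


def test_tlv_boundary_is_strict():
    """A gene at exactly the threshold fold change is not flagged: the rule
    requires a change of *more than* the threshold."""
    left = pd.Series([40.0], index=["G"])
    right = pd.Series([10.0], index=["G"])
    config = nr.VariabilityConfig(pair_pseudocount=0.0)
    assert nr.matched_pair_log2fc(left, right, 0.0)["G"] == 2.0
    assert nr.tlv_gene_set([(left, right)], config) == set()


def test_tlv_recovers_planted_discordant_genes(cohort, ffpe_total_pairs):
    """Genes planted with a >2.5 log2 left/right discordance are all
    recovered; any extra flagged genes are low-expression cases where shot
    noise interacts with the pseudocount."""
    _, _, truth = cohort
    pairs, pair_ids = ffpe_total_pairs
    tlv = nr.tlv_gene_set(pairs)
    planted = {
        g for g, (pid, _, _) in truth.pair_discordant.items() if pid in set(pair_ids)
    }
    assert planted <= tlv
    for extra in tlv - planted:
        assert truth.baseline_cpm[extra] < 20.0


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def _tiny_panel_inputs():
    genes = ["A", "B", "C"]
    samples = [f"S{i}" for i in range(4)]
    cpm = pd.DataFrame(7.0, index=genes, columns=samples)
    meta = [
        nr.SampleMeta(s, "breast_normal", "FFPE", "total", f"P{i}")
        for i, s in enumerate(samples)
    ]
    return cpm, meta


def test_panel_all_constant_genes_low_variability():
    cpm, meta = _tiny_panel_inputs()
    panel = nr.build_reference_panel(cpm, meta, "FFPE", "total")
    assert panel.low_variability_genes == {"A", "B", "C"}
    assert panel.n_samples == 4


def test_panel_tlv_flag_overrides_low_cv():
    """A gene with CV below threshold but carrying the left/right
    discordance flag is not a trustworthy reference."""
    cpm, meta = _tiny_panel_inputs()
    panel = nr.build_reference_panel(cpm, meta, "FFPE", "total", tlv_set={"B"})
    assert panel.table.at["B", "cv"] < 0.30
    assert not panel.table.at["B", "low_variability"]
    assert panel.low_variability_genes == {"A", "C"}


def test_panel_rule_matches_brute_force(cohort, cohort_cpm):
    counts, meta, truth = cohort
    tlv = set(list(truth.pair_discordant)[:20])
    asg = set(list(truth.fat_signature)[:30])
    config = nr.VariabilityConfig()
    panel = nr.build_reference_panel(
        cohort_cpm, meta, "FFPE", "total", tlv_set=tlv, asg_set=asg, config=config
    )
    frame = nr.metadata_frame(meta)
    cols = [
        s
        for s in frame.index[
            (frame.tissue == "breast_normal")
            & (frame.asservation == "FFPE")
            & (frame.kit == "total")
        ]
    ]
    sub = cohort_cpm.cpm[cols]
    for g in panel.table.index:
        row = sub.loc[g].to_numpy()
        mean = row.mean()
        cv = row.std(ddof=1) / mean if mean > 0 else np.nan
        expected = (
            (not np.isnan(cv))
            and cv < config.cv_threshold
            and g not in tlv
            and g not in asg
        )
        assert bool(panel.table.at[g, "low_variability"]) == expected


def test_panel_monotone_in_exclusion_sets(cohort, cohort_cpm):
    counts, meta, truth = cohort
    base = nr.build_reference_panel(cohort_cpm, meta, "FFPE", "total")
    larger = nr.build_reference_panel(
        cohort_cpm, meta, "FFPE", "total",
        tlv_set=set(list(truth.pair_discordant)[:10]),
        asg_set=set(truth.fat_signature),
    )
    assert len(larger.low_variability_genes) <= len(base.low_variability_genes)
    assert larger.low_variability_genes <= base.low_variability_genes


def test_panel_requires_group_samples():
    cpm, meta = _tiny_panel_inputs()
    with pytest.raises(nr.ValidationError):
        nr.build_reference_panel(cpm, meta, "FF", "targeted")


# ---------------------------------------------------------------------------
# category counts
# ---------------------------------------------------------------------------

def _panel_with_low(n_low, n_total):
    genes = [f"G{i}" for i in range(n_total)]
    table = pd.DataFrame(
        {
            "mean_cpm": 10.0,
            "cv": 0.1,
            "tlv": False,
            "asg": False,
            "low_variability": [i < n_low for i in range(n_total)],
        },
        index=genes,
    )
    return nr.ReferencePanel("FFPE", "total", table, n_samples=19)


def test_category_counts_universe_percentages():
    """Half-up integer percentages of the whole-universe category."""
    panel = _panel_with_low(10259, 23686)
    out = nr.category_counts(panel, [], universe_size=23686)
    assert out.at["All genes", "percent"] == 43
    panel = _panel_with_low(3038, 23686)
    out = nr.category_counts(panel, [], universe_size=23686)
    assert out.at["All genes", "percent"] == 13


def test_category_counts_annotation_denominator():
    panel = _panel_with_low(4, 100)
    ann = nr.GeneAnnotation("markers", frozenset({"G0", "G1", "G50", "G60"}))
    out = nr.category_counts(panel, [ann])
    assert out.at["markers", "n_category"] == 4
    assert out.at["markers", "n_low"] == 2  # G0, G1 are low; G50, G60 not
    assert out.at["markers", "percent"] == 50


def test_category_counts_empty_panel_and_empty_annotation():
    panel = _panel_with_low(0, 10)
    ann = nr.GeneAnnotation("empty", frozenset())
    out = nr.category_counts(panel, [ann])
    assert out.at["All genes", "n_low"] == 0
    assert out.at["empty", "n_low"] == 0
    assert pd.isna(out.at["empty", "percent"])


# ---------------------------------------------------------------------------
# classification against generator truth
# ---------------------------------------------------------------------------

def test_low_variability_classification_recovers_truth(cohort, cohort_cpm):
    """At n=19 samples, genes simulated with biological CV <= 0.2 are
    flagged low-variability and genes with CV >= 0.5 high-variability, each
    with at least 90% accuracy (after the standard low-count filter)."""
    counts, meta, truth = cohort
    kept = nr.filter_low_counts(cohort_cpm)
    panel = nr.build_reference_panel(cohort_cpm, meta, "FFPE", "total")
    table = panel.table.loc[sorted(kept)]
    tc = truth.true_cv.loc[table.index]
    low_true = table.index[tc <= 0.2]
    high_true = table.index[tc >= 0.5]
    sensitivity = table.loc[low_true, "low_variability"].mean()
    specificity = 1.0 - table.loc[high_true, "low_variability"].mean()
    assert sensitivity >= 0.9
    assert specificity >= 0.9


def test_config_rejects_inconsistent_thresholds():
    with pytest.raises(nr.ValidationError):
        nr.VariabilityConfig(cv_threshold=0.6, z_95=1.96)
    with pytest.raises(nr.ValidationError):
        nr.VariabilityConfig(pair_log2fc_threshold=0.0)
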