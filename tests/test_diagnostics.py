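"""L/D diagnostics: concentrations, classification, replicability,
peripheral categories and digestion recommendations."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from diatomtest import (
    DiagnosticClass,
    MediumMeasurement,
    TissueMeasurement,
    analyze_case,
    analyze_synthetic_case,
    categorize_peripheral,
    classify_ld,
    ld_ratio,
    per_gram,
    per_ml,
    recommend_digestion,
    replicability,
    round_ld,
    simulate_case,
)
from diatomtest.datasets import study_cases


def test_per_gram_arithmetic():
    assert per_gram(57, 0.5) == pytest.approx(114.0)
    assert per_gram(0, 1.0) == 0.0
    assert per_gram(207, 1.0) == pytest.approx(207.0)
    with pytest.raises(ValueError):
        per_gram(10, 0.0)
    assert per_ml(24148, 1.0) == pytest.approx(24148.0)


def test_published_ld_ratios_reproduce_at_one_decimal():
    """All five validation cases: the per-gram/per-ml concentration
    pairs reproduce the published one-decimal L/D ratios."""
    for rec in study_cases().itertuples(index=False):
        ld = ld_ratio(rec.lung_per_gram, rec.medium_per_ml)
        assert round_ld(ld) == pytest.approx(rec.published_ld)


def test_drowning_cases_partition():
    """Cases 1-4 exceed L/D = 2 (strong evidence for drowning); case 5
    falls below 1 (compatible with post-mortal immersion)."""
    df = study_cases()
    for rec in df.itertuples(index=False):
        ld = ld_ratio(rec.lung_per_gram, rec.medium_per_ml)
        if rec.case_id == "5":
            assert ld < 1
            assert classify_ld(ld) is DiagnosticClass.IMMERSION_COMPATIBLE
        else:
            assert ld > 2
            assert classify_ld(ld) is DiagnosticClass.STRONG_DROWNING


def test_classification_boundaries():
    assert classify_ld(10.9) is DiagnosticClass.STRONG_DROWNING
    assert classify_ld(2.0) is DiagnosticClass.DROWNING_SUPPORTIVE
    assert classify_ld(1.5) is DiagnosticClass.DROWNING_SUPPORTIVE
    assert classify_ld(1.0) is DiagnosticClass.IMMERSION_COMPATIBLE
    assert classify_ld(0.1) is DiagnosticClass.IMMERSION_COMPATIBLE
    with pytest.raises(ValueError):
        classify_ld(-0.1)


_STRENGTH = {
    DiagnosticClass.IMMERSION_COMPATIBLE: 0,
    DiagnosticClass.DROWNING_SUPPORTIVE: 1,
    DiagnosticClass.STRONG_DROWNING: 2,
}


@settings(deadline=None, max_examples=200, derandomize=True)
@given(ld1=st.floats(0, 20), ld2=st.floats(0, 20))
def test_classification_monotone(ld1, ld2):
    lo, hi = sorted((ld1, ld2))
    assert _STRENGTH[classify_ld(lo)] <= _STRENGTH[classify_ld(hi)]


@settings(deadline=None, max_examples=100, derandomize=True)
@given(count=st.integers(0, 10_000))
def test_peripheral_categories_partition_integers(count):
    cat = categorize_peripheral(count)
    expected = "-" if count == 0 else "+" if count <= 4 else "++" if count <= 9 else "+++"
    assert cat == expected


def test_peripheral_category_boundaries():
    assert categorize_peripheral(0) == "-"
    assert categorize_peripheral(1) == "+"
    assert categorize_peripheral(4) == "+"
    assert categorize_peripheral(5) == "++"
    assert categorize_peripheral(9) == "++"
    assert categorize_peripheral(10) == "+++"
    with pytest.raises(ValueError):
        categorize_peripheral(-1)


def _lung(mass, count):
    return TissueMeasurement(tissue="lung", mass_g=mass, diatom_count=count)


def test_replicability_identical_values():
    rep = replicability([_lung(0.5, 50), _lung(1.0, 100), _lung(2.0, 200)])
    assert rep.max_rel_deviation_pct == 0.0
    assert rep.spearman_r == pytest.approx(1.0)


def test_replicability_control_case_a_arithmetic():
    """Control case A (masses 0.5/1.1/1.5 g, counts 57/108/155):
    per-gram values and range/mean deviation from independent arithmetic."""
    samples = [_lung(0.5, 57), _lung(1.1, 108), _lung(1.5, 155)]
    rep = replicability(samples)
    expected_pg = (57 / 0.5, 108 / 1.1, 155 / 1.5)
    assert rep.per_gram_values == pytest.approx(expected_pg)
    mean_pg = sum(expected_pg) / 3
    expected_dev = 100.0 * (max(expected_pg) - min(expected_pg)) / mean_pg
    assert rep.max_rel_deviation_pct == pytest.approx(expected_dev)
    assert rep.spearman_r == pytest.approx(1.0)  # both strictly increasing
    assert math.isnan(rep.kruskal_p)


def test_replicability_with_per_field_groups():
    samples = [_lung(0.5, 6), _lung(1.0, 9)]
    rep = replicability(samples, per_field_counts=[[1, 2, 3], [2, 3, 4]])
    assert 0.0 <= rep.kruskal_p <= 1.0


def test_replicability_validation():
    with pytest.raises(ValueError):
        replicability([_lung(1.0, 10)])
    with pytest.raises(ValueError):
        replicability([_lung(1.0, 10),
                       TissueMeasurement("liver", 1.0, 5)])


@pytest.mark.parametrize(
    "mass,total,hno3,h2o2",
    [(0.3, 5.0, 4.0, 1.0), (0.5, 5.0, 4.0, 1.0), (0.8, 10.0, 8.0, 2.0),
     (1.0, 10.0, 8.0, 2.0), (1.5, 15.0, 12.0, 3.0), (2.0, 15.0, 12.0, 3.0)],
)
def test_digestion_volume_rules(mass, total, hno3, h2o2):
    rec = recommend_digestion(mass)
    assert rec.total_volume_ml == total
    assert rec.hno3_ml == pytest.approx(hno3)
    assert rec.h2o2_ml == pytest.approx(h2o2)
    assert rec.hno3_ml / rec.h2o2_ml == pytest.approx(4.0)
    assert rec.warnings == ()


def test_digestion_override_warnings():
    # oversized batch on a light sample risks frustule disintegration
    rec = recommend_digestion(0.5, volume_ml=10.0)
    assert any("disintegration" in w for w in rec.warnings)
    rec = recommend_digestion(1.0, volume_ml=15.0)
    assert any("disintegration" in w for w in rec.warnings)
    # undersized batch digests incompletely
    rec = recommend_digestion(1.0, volume_ml=5.0)
    assert any("partial" in w for w in rec.warnings)


def test_digestion_mass_range_validated():
    with pytest.raises(ValueError):
        recommend_digestion(0.0)
    with pytest.raises(ValueError):
        recommend_digestion(2.5)


def test_analyze_case_published_examples():
    rec = analyze_case(
        "4", _lung(1.0, 4521), MediumMeasurement(volume_ml=1.0, diatom_count=675)
    )
    assert rec.ld_reported == pytest.approx(6.7)
    assert rec.diagnostic_class is DiagnosticClass.STRONG_DROWNING

    rec2 = analyze_case(
        "2", _lung(1.0, 410), MediumMeasurement(volume_ml=1.0, diatom_count=175)
    )
    assert rec2.ld_reported == pytest.approx(2.3)


def test_analyze_case_zero_lung_count():
    rec = analyze_case(
        "x", _lung(1.0, 0), MediumMeasurement(volume_ml=1.0, diatom_count=100)
    )
    assert rec.ld == 0.0
    assert rec.diagnostic_class is DiagnosticClass.IMMERSION_COMPATIBLE


def test_analyze_case_peripheral_and_debris_flag():
    rec = analyze_case(
        "5",
        _lung(1.0, 2567),
        MediumMeasurement(volume_ml=1.0, diatom_count=24148),
        peripheral_counts={"liver": 3, "kidney": 12},
        flags=("debris",),
    )
    assert rec.peripheral == {"liver": "+", "kidney": "+++"}
    assert any("debris" in f for f in rec.flags)
    assert rec.diagnostic_class is DiagnosticClass.IMMERSION_COMPATIBLE


def test_analyze_case_requires_lung_numerator():
    with pytest.raises(ValueError):
        analyze_case(
            "x",
            TissueMeasurement("liver", 1.0, 10),
            MediumMeasurement(volume_ml=1.0, diatom_count=5),
        )


def test_ld_ratio_requires_positive_medium():
    with pytest.raises(ValueError):
        ld_ratio(100.0, 0.0)


def test_analyze_synthetic_case_pools_aliquots():
    case = simulate_case(400.0, 100.0, [0.5, 1.0], [10.0], seed=7)
    rec = analyze_synthetic_case(case)
    mass = sum(m for m, _ in case.tissue_samples)
    count = sum(c for _, c in case.tissue_samples)
    vol = sum(v for v, _ in case.medium_samples)
    mcount = sum(c for _, c in case.medium_samples)
    assert rec.ld == pytest.approx((count / mass) / (mcount / vol))
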