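"""Field counting, area-proportional extrapolation and accuracy scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diatomtest import (
    AcquisitionPlan,
    FieldCounts,
    FieldOfView,
    MembraneSpec,
    accuracy_pct,
    count_fields,
    extrapolate_total,
    make_grid_plan,
    make_scatter_plan,
    make_transect_plan,
    simulate_membrane,
)
from diatomtest.synthetic import PointPattern


def test_count_fields_matches_brute_force_oracle(spec):
    """Vectorised counting agrees with a point-by-point membership loop."""
    pattern = simulate_membrane(spec, "homogeneous", intensity=15, seed=5)
    for plan in (make_scatter_plan(spec, "half"), make_transect_plan(spec, "full")):
        counts = count_fields(pattern, plan).counts
        oracle = [
            sum(f.contains(x, y) for x, y in pattern.coordinates)
            for f in plan.fields
        ]
        assert list(counts) == oracle


def test_empty_pattern_gives_zero_counts(spec):
    pattern = simulate_membrane(spec, "homogeneous", intensity=0, seed=0)
    counts = count_fields(pattern, make_scatter_plan(spec, "full"))
    assert counts.total == 0
    est = extrapolate_total(counts)
    assert est.estimated_total == 0.0


def test_disjoint_plan_counts_bounded_by_total(spec):
    pattern = simulate_membrane(spec, "clustered", seed=9)
    counts = count_fields(pattern, make_scatter_plan(spec, "full"))
    assert counts.total <= pattern.true_total


def test_full_coverage_extrapolation_is_exact(spec):
    """Over the exhaustive grid plan the extrapolated total equals the
    true total (no sampling error left)."""
    pattern = simulate_membrane(spec, "clustered", seed=21)
    grid = make_grid_plan(spec)
    counts = count_fields(pattern, grid)
    assert counts.total == pattern.true_total  # every point falls in a field
    est = extrapolate_total(counts)
    assert est.estimated_total == pytest.approx(pattern.true_total, rel=1e-6)


def test_spec_mismatch_rejected(spec):
    other = MembraneSpec(diameter_mm=8.0, fields_per_diameter=40)
    pattern = simulate_membrane(other, "homogeneous", intensity=5, seed=0)
    with pytest.raises(ValueError):
        count_fields(pattern, make_scatter_plan(spec, "eighth"))


def test_zero_sampled_area_is_unusable(spec):
    outside = FieldOfView(0, (spec.radius_mm + 1.0, 0.0), spec.field_width_mm, 0.0)
    plan = AcquisitionPlan("scatter", "custom", spec, (outside,))
    with pytest.raises(ValueError):
        extrapolate_total(FieldCounts(plan=plan, counts=np.array([0])))


def test_accuracy_pct_examples():
    assert accuracy_pct(100, 100) == 100.0
    assert accuracy_pct(0, 100) == 0.0
    assert accuracy_pct(110, 100) == pytest.approx(90.0)
    assert accuracy_pct(300, 100) == 0.0  # floored
    with pytest.raises(ValueError):
        accuracy_pct(10, 0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    est=st.floats(0, 1e6),
    ref=st.floats(1e-3, 1e6),
    k=st.floats(1e-3, 1e3),
)
def test_accuracy_pct_scale_invariant(est, ref, k):
    assert accuracy_pct(k * est, k * ref) == pytest.approx(
        accuracy_pct(est, ref), abs=1e-9
    )


def test_csr_estimator_matches_binomial_sampling_oracle(spec):
    """Under complete spatial randomness the sampled count is Binomial
    given the total, so the geometric pipeline's mean accuracy must agree
    with a geometry-free Poisson/Binomial resampling oracle."""
    plan = make_scatter_plan(spec, "full")
    frac = plan.sampled_area_mm2 / spec.area_mm2
    intensity = 20.0
    lam = intensity * spec.area_mm2

    n_geo = 300
    acc_geo = []
    for s in range(n_geo):
        pat = simulate_membrane(spec, "homogeneous", intensity=intensity, seed=s)
        est = extrapolate_total(count_fields(pat, plan))
        acc_geo.append(accuracy_pct(est.estimated_total, pat.true_total))

    rng = np.random.default_rng(999)
    n_orc = 3000
    totals = rng.poisson(lam, n_orc)
    ks = rng.binomial(totals, frac)
    est_tot = ks / frac
    acc_orc = np.maximum(0.0, 100.0 * (1.0 - np.abs(est_tot - totals) / totals))

    se = math.sqrt(np.var(acc_geo) / n_geo + np.var(acc_orc) / n_orc)
    assert abs(np.mean(acc_geo) - np.mean(acc_orc)) < 3 * se


def test_counts_validation(spec):
    plan = make_scatter_plan(spec, "eighth")
    with pytest.raises(ValueError):
        FieldCounts(plan=plan, counts=np.array([1, 2]))  # wrong length
    with pytest.raises(ValueError):
        FieldCounts(plan=plan, counts=-np.ones(8, dtype=int))
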