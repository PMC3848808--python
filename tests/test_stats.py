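"""Hotelling T-squared maps and LGE segment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_null_model
from lvatlas.cohort import (FRAMES, default_population_model,
                            generate_unpaired_cohorts, generate_paired_cohort)
from lvatlas.correction import fit_transform_variant
from lvatlas.stats import (hotelling_t2, pointwise_map,
                           segment_pvalue_distribution, select_lge_segments)


def test_identical_groups_zero_statistic():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(30, 3))
    t2, p = hotelling_t2(a, a.copy())
    assert t2 == 0.0 and p == 1.0


def test_univariate_reduction_equals_welch():
    """In 1-D the statistic is the squared Welch t, p-values agree."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = rng.normal(size=(rng.integers(6, 40), 1))
        b = rng.normal(0.3, 1.7, size=(rng.integers(6, 40), 1))
        t2, p = hotelling_t2(a, b)
        w = sps.ttest_ind(a.ravel(), b.ravel(), equal_var=False)
        assert t2 == pytest.approx(w.statistic**2, abs=1e-10)
        assert p == pytest.approx(w.pvalue, abs=1e-10)


def test_invariance_under_common_linear_map():
    """T2 is invariant to a shared nonsingular linear transform."""
    rng = np.random.default_rng(2)
    a = rng.normal(size=(40, 3))
    b = rng.normal(0.2, 1.0, size=(25, 3))
    t2, _ = hotelling_t2(a, b)
    for _ in range(5):
        M = rng.normal(size=(3, 3)) + 3.0 * np.eye(3)
        shift = rng.normal(size=3)
        t2m, _ = hotelling_t2(a @ M.T + shift, b @ M.T + shift)
        assert t2m == pytest.approx(t2, rel=1e-8)


def test_small_groups_rejected():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError):
        hotelling_t2(rng.normal(size=(4, 3)), rng.normal(size=(20, 3)))


# ---------------------------------------------------------------------------
# pointwise maps on cohorts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def null_cohorts():
    pop = default_population_model()
    null = make_null_model(pop, noise_sd=0.004)
    return generate_unpaired_cohorts(null, 60, 60, remodeling=None, seed=21)


def test_null_pvalues_uniform(null_cohorts):
    """Exchangeable cohorts: pointwise p-values are uniform (KS at 1%)."""
    ctrl, dis = null_cohorts
    m = pointwise_map(ctrl, dis, frame="ED", n_u=20, n_v=10, surface="endo")
    assert len(m.p) == 200
    ks = sps.kstest(m.p, "uniform")
    assert ks.pvalue > 0.01


def test_map_determinism(null_cohorts):
    ctrl, dis = null_cohorts
    m1 = pointwise_map(ctrl, dis, frame="ED", n_u=8, n_v=6, surface="endo")
    m2 = pointwise_map(ctrl, dis, frame="ED", n_u=8, n_v=6, surface="endo")
    np.testing.assert_array_equal(m1.t2, m2.t2)
    np.testing.assert_array_equal(m1.p, m2.p)


def test_disease_effect_localizes_to_remodeled_segments():
    """A large infero-lateral effect puts the maximal T2 in those segments."""
    pop = default_population_model()
    null = make_null_model(pop, noise_sd=0.004)
    target = {4: 0.08, 5: 0.08, 10: 0.08, 11: 0.08}
    ctrl, dis = generate_unpaired_cohorts(null, 60, 60, remodeling=target,
                                          seed=31)
    m = pointwise_map(ctrl, dis, frame="ED", n_u=24, n_v=24, surface="endo")
    assert m.segment_id[np.argmax(m.t2)] in target


def test_rigid_rotation_of_both_cohorts_preserves_t2():
    """A common rigid motion of every case leaves the map unchanged."""
    from dataclasses import replace
    from scipy.spatial.transform import Rotation

    from lvatlas.prolate import ProlateFrame

    pop = default_population_model()
    null = make_null_model(pop, noise_sd=0.004)
    ctrl, dis = generate_unpaired_cohorts(null, 30, 30, remodeling={4: 0.05},
                                          seed=41)
    m0 = pointwise_map(ctrl, dis, frame="ED", n_u=6, n_v=6, surface="endo")
    R = Rotation.from_euler("xyz", [0.3, -1.0, 2.2]).as_matrix()
    frame2 = ProlateFrame(focal_length=pop.prolate.focal_length,
                          origin=np.array([10.0, -5.0, 30.0]),
                          axes=R)
    ctrl2, dis2 = replace(ctrl, prolate=frame2), replace(dis, prolate=frame2)
    m1 = pointwise_map(ctrl2, dis2, frame="ED", n_u=6, n_v=6, surface="endo")
    np.testing.assert_allclose(m1.t2, m0.t2, rtol=1e-9, atol=1e-9)


def test_monotone_power_in_effect_amplitude():
    """Median T2 in the affected segment grows with the effect size."""
    pop = default_population_model()
    null = make_null_model(pop, noise_sd=0.004)
    medians = []
    for amp in (0.0, 0.02, 0.05, 0.1):
        ctrl, dis = generate_unpaired_cohorts(null, 40, 40,
                                              remodeling={10: amp}, seed=51)
        m = pointwise_map(ctrl, dis, frame="ED", n_u=24, n_v=24,
                          surface="endo")
        medians.append(np.median(m.t2[m.segment_id == 10]))
    assert np.all(np.diff(medians) > 0)


# ---------------------------------------------------------------------------
# LGE selection and segment p-value distributions
# ---------------------------------------------------------------------------

TOY_LGE = pd.DataFrame(
    [("a", s, g) for s, g in zip(range(1, 18), [0] * 14 + [3, 4, 2])]
    + [("b", s, g) for s, g in zip(range(1, 18), [0] * 15 + [3, 3])]
    + [("c", s, g) for s, g in zip(range(1, 18), [1] * 16 + [3])],
    columns=["case_id", "segment", "grade"],
)


def test_lge_selection_counts_on_toy_table():
    sel3 = select_lge_segments(TOY_LGE, min_grade=3)
    assert len(sel3) == 5
    assert set(map(tuple, sel3.values)) == {
        ("a", 15), ("a", 16), ("b", 16), ("b", 17), ("c", 17)}


def test_lge_selection_monotone_in_grade():
    sel2 = set(map(tuple, select_lge_segments(TOY_LGE, 2).values))
    sel3 = set(map(tuple, select_lge_segments(TOY_LGE, 3).values))
    assert sel3 <= sel2


def test_lge_selection_empty_and_invalid():
    zeros = pd.DataFrame({"case_id": ["x"] * 17, "segment": range(1, 18),
                          "grade": [0] * 17})
    assert select_lge_segments(zeros, 2).empty
    bad = zeros.assign(grade=[5] + [0] * 16)
    with pytest.raises(ValueError):
        select_lge_segments(bad, 2)
    with pytest.raises(ValueError):
        select_lge_segments(zeros, 0)


def test_segment_pvalue_distribution_self_consistent():
    pop = default_population_model()
    ctrl, dis = generate_unpaired_cohorts(pop, 40, 40,
                                          remodeling={10: 0.05, 11: 0.05},
                                          seed=61)
    paired = generate_paired_cohort(pop, 30, seed=62)
    t = fit_transform_variant(paired, "mle_zscore", "ED")
    res = segment_pvalue_distribution(ctrl, dis, t, min_grade=3, frame="ED",
                                      points_per_segment=50)
    for tag in ("before", "after"):
        p = res[tag]["p_values"]
        logp = np.log10(p)
        assert res[tag]["log10_p_median"] == pytest.approx(np.median(logp))
        assert res[tag]["log10_p_q25"] == pytest.approx(np.percentile(logp, 25))
    assert res["median_shift"] == pytest.approx(
        res["after"]["log10_p_median"] - res["before"]["log10_p_median"])


def test_correction_strengthens_separation_when_bias_opposes_effect():
    """Protocol bias opposing the disease effect masks it; correcting the
    controls restores (strengthens) the separation."""
    pop = default_population_model()
    # disease effect pushes endo outward in segments 10, 11; the default
    # protocol bias makes SSFP cavities larger, so the raw GRE controls
    # (smaller cavities) exaggerate agreement... construct opposing bias by
    # comparing patients (SSFP, effect) with *uncorrected* GRE controls.
    ctrl, dis = generate_unpaired_cohorts(pop, 60, 60,
                                          remodeling={13: -0.05, 15: -0.05},
                                          seed=71)
    paired = generate_paired_cohort(pop, 46, seed=72)
    t = fit_transform_variant(paired, "mle_zscore", "ED")
    res = segment_pvalue_distribution(ctrl, dis, t, min_grade=3, frame="ED",
                                      points_per_segment=50)
    assert res["after"]["log10_p_median"] <= res["before"]["log10_p_median"]


def test_segment_distribution_requires_selection():
    pop = default_population_model()
    ctrl, dis = generate_unpaired_cohorts(pop, 20, 20, remodeling=None, seed=81)
    paired = generate_paired_cohort(pop, 20, seed=82)
    t = fit_transform_variant(paired, "mle_zscore", "ED")
    with pytest.raises(ValueError, match="no segments"):
        segment_pvalue_distribution(ctrl, dis, t, min_grade=2)
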