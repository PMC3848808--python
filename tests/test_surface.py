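"""Tensor-spline surface evaluation and sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvatlas.prolate import ProlateFrame
from lvatlas.surface import (LVShape, SplineSurface, evaluate_surface,
                             greville_uv, sample_surface)

F = np.sqrt(50.0**2 - 25.0**2)
LAM0 = np.arccosh(50.0 / F)


def constant_shape(lam=LAM0, wall=0.2, mu_max=np.pi / 2, grid=(8, 8)):
    frame = ProlateFrame(focal_length=F)
    g = np.full(grid, lam)
    return LVShape("ED", frame, g, g + wall, mu_max=mu_max)


# ---------------------------------------------------------------------------
# independent oracle: Cox-de Boor recursion, written from the textbook
# definition and independent of the scipy evaluation path
# ---------------------------------------------------------------------------

def _basis(t, k, i, x):
    if k == 0:
        return 1.0 if t[i] <= x < t[i + 1] else 0.0
    out = 0.0
    if t[i + k] > t[i]:
        out += (x - t[i]) / (t[i + k] - t[i]) * _basis(t, k - 1, i, x)
    if t[i + k + 1] > t[i + 1]:
        out += (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * _basis(t, k - 1, i + 1, x)
    return out


def oracle_eval(grid, u, v):
    nc, nl = grid.shape
    tu = np.arange(-3, nc + 4) / nc
    tv = np.r_[np.zeros(3), np.linspace(0.0, 1.0, nl - 2), np.ones(3)]
    c_ext = np.vstack([grid, grid[:3]])
    vv = min(v, 1.0 - 1e-12)  # half-open convention at the right edge
    val = 0.0
    for i in range(nc + 3):
        bu = _basis(tu, 3, i, u % 1.0)
        if bu == 0.0:
            continue
        for j in range(nl):
            bv = _basis(tv, 3, j, vv)
            if bv:
                val += bu * bv * c_ext[i, j]
    return val


def test_spline_matches_de_boor_oracle_fixed_grid():
    """A fixed non-uniform 8x8 grid evaluated at 25 sites matches the oracle."""
    rng = np.random.default_rng(42)
    grid = rng.uniform(0.4, 1.0, (8, 8))
    sp = SplineSurface(grid)
    uv = rng.random((25, 2))
    for u, v in uv:
        assert abs(sp(u, v) - oracle_eval(grid, u, v)) < 1e-9


def test_spline_matches_oracle_many_random_grids():
    """Property: basis-summation oracle equality on >= 100 random grids."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        nc = int(rng.integers(4, 10))
        nl = int(rng.integers(4, 10))
        grid = rng.uniform(0.2, 1.5, (nc, nl))
        sp = SplineSurface(grid)
        for _ in range(3):
            u, v = rng.random(), rng.random()
            assert abs(sp(u, v) - oracle_eval(grid, u, v)) < 1e-9


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_spline_partition_of_unity(seed):
    """Constant control grids evaluate to the constant everywhere."""
    rng = np.random.default_rng(seed)
    c = rng.uniform(0.1, 2.0)
    sp = SplineSurface(np.full((rng.integers(4, 9), rng.integers(4, 9)), c))
    uv = rng.random((20, 2))
    np.testing.assert_allclose(sp(uv[:, 0], uv[:, 1]), c, atol=1e-12)


# ---------------------------------------------------------------------------
# surface evaluation
# ---------------------------------------------------------------------------

def test_constant_grid_lies_on_analytic_prolate_shell():
    """A constant lambda grid is exactly the analytic coordinate surface."""
    sh = constant_shape()
    rng = np.random.default_rng(3)
    for u, v in rng.random((50, 2)):
        p = evaluate_surface(sh, "endo", u, v)
        mu = v * sh.mu_max
        theta = 2.0 * np.pi * u
        expected = np.array([
            F * np.cosh(LAM0) * np.cos(mu),
            F * np.sinh(LAM0) * np.sin(mu) * np.cos(theta),
            F * np.sinh(LAM0) * np.sin(mu) * np.sin(theta),
        ])
        np.testing.assert_allclose(p, expected, atol=1e-9)


def test_circumferential_periodicity():
    rng = np.random.default_rng(11)
    g = rng.uniform(0.5, 0.9, (8, 8))
    sh = LVShape("ED", ProlateFrame(focal_length=F), g, g + 0.3)
    for v in (0.0, 0.3, 0.77, 1.0):
        p0 = evaluate_surface(sh, "endo", 0.0, v)
        p1 = evaluate_surface(sh, "endo", 1.0 - 1e-12, v)
        np.testing.assert_allclose(p0, p1, atol=1e-9)


def test_out_of_range_and_nonfinite_rejected():
    sh = constant_shape()
    with pytest.raises(ValueError):
        evaluate_surface(sh, "endo", 0.5, 1.5)
    with pytest.raises(ValueError):
        evaluate_surface(sh, "endo", np.nan, 0.5)
    with pytest.raises(ValueError):
        LVShape("ED", ProlateFrame(), np.full((8, 8), np.nan), np.ones((8, 8)))
    with pytest.raises(ValueError):
        LVShape("ED", ProlateFrame(), np.full((8, 8), -0.1), np.ones((8, 8)))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_default_sampling_is_1089_points():
    s = sample_surface(constant_shape(), "endo")
    assert len(s) == 1089
    assert np.unique(s.segment_id).size == 17


def test_minimum_grid_sampling():
    s = sample_surface(constant_shape(), "endo", 4, 4)
    assert len(s) == 16
    assert np.all(np.isfinite(s.points))
    with pytest.raises(ValueError):
        sample_surface(constant_shape(), "endo", 3, 5)


def test_sampling_round_trip_invariant():
    """Re-evaluating at parametric_uv reproduces the stored points."""
    rng = np.random.default_rng(5)
    g = rng.uniform(0.5, 0.9, (8, 8))
    sh = LVShape("ED", ProlateFrame(focal_length=F), g, g + 0.3)
    s = sample_surface(sh, "epi", 17, 13)
    again = evaluate_surface(sh, "epi", s.parametric_uv[:, 0],
                             s.parametric_uv[:, 1])
    np.testing.assert_allclose(again, s.points, atol=1e-9)


def test_constant_shell_focal_distance_sum():
    """On a lambda shell, distances to the two foci sum to 2 f cosh(lam)."""
    sh = constant_shape()
    s = sample_surface(sh, "endo")
    foci = np.array([[F, 0.0, 0.0], [-F, 0.0, 0.0]])
    d = (np.linalg.norm(s.points[:, None] - foci[None], axis=2)).sum(axis=1)
    np.testing.assert_allclose(d, 2.0 * F * np.cosh(LAM0), rtol=1e-12)


# ---------------------------------------------------------------------------
# shape invariants
# ---------------------------------------------------------------------------

def test_wall_thickness_enforced_on_construction():
    g = np.full((8, 8), 0.7)
    with pytest.raises(ValueError, match="wall-thickness"):
        LVShape("ED", ProlateFrame(), g, g - 0.05)


def test_wall_violation_flagged_when_not_enforced():
    g = np.full((8, 8), 0.7)
    with pytest.warns(RuntimeWarning):
        sh = LVShape("ED", ProlateFrame(), g, g - 0.05, enforce_wall=False)
    assert sh.wall_violation


def test_parameter_vector_round_trip():
    rng = np.random.default_rng(9)
    g = rng.uniform(0.5, 0.8, (8, 8))
    sh = LVShape("ED", ProlateFrame(), g, g + 0.2, case_id="a")
    params = sh.parameters
    assert params.shape == (128,)
    sh2 = sh.with_parameters(params + 0.01)
    np.testing.assert_allclose(sh2.endo_grid, g + 0.01)
    np.testing.assert_allclose(sh2.epi_grid, g + 0.21)


def test_greville_nodes_cover_unit_interval():
    u, v = greville_uv((8, 8))
    assert v[0] == 0.0 and v[-1] == 1.0
    assert len(np.unique(u)) == 8
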