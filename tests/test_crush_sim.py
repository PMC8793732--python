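"""Ellipse crushing geometry and the synthetic-column generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neckmetrics import (
    CrushIntensity,
    CrushParams,
    TrueColumnModel,
    crush_column,
    crush_section,
    discrimination_experiment,
    generate_true_column,
    summarize,
)
from neckmetrics.crush_sim import crush_matrix
from neckmetrics.errors import ValidationError
from neckmetrics.serial_metrics import series_ratios


def boundary_oracle(height, width, params, n=40000):
    """Brute-force extents: map densely sampled boundary points directly."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.stack([width / 2 * np.cos(phi), height / 2 * np.sin(phi)])
    mapped = crush_matrix(params.theta, params.k, params.gamma) @ pts
    return (
        mapped[1].max() - mapped[1].min(),  # height
        mapped[0].max() - mapped[0].min(),  # width
    )


def test_identity_when_k_is_one():
    for theta in (0.0, 30.0, 117.5):
        for gamma in (0.0, 0.5, 1.0):
            h, w = crush_section(9.0, 4.0, CrushParams(theta, 1.0, gamma))
            assert (h, w) == pytest.approx((9.0, 4.0), rel=1e-12)


def test_axis_aligned_compression_scales_height_only():
    assert crush_section(10, 6, CrushParams(theta=0, k=0.5, gamma=0)) == \
        pytest.approx((5.0, 6.0), rel=1e-12)


def test_oblique_area_preserving_crush_inflates_both_extents():
    """At 45 degrees with area-preserving flow, a circle grows in BOTH axes."""
    h, w = crush_section(2, 2, CrushParams(theta=45, k=0.5, gamma=1))
    assert h == pytest.approx(2.9155, abs=5e-4)
    assert w == pytest.approx(2.9155, abs=5e-4)
    assert h > 2 and w > 2


@given(
    st.floats(min_value=0.5, max_value=20),
    st.floats(min_value=0.5, max_value=20),
    st.floats(min_value=0, max_value=180),
    st.floats(min_value=0.05, max_value=1),
    st.floats(min_value=0, max_value=1),
)
def test_support_function_matches_boundary_oracle(h, w, theta, k, gamma):
    params = CrushParams(theta, k, gamma)
    exact = crush_section(h, w, params)
    sampled = boundary_oracle(h, w, params)
    assert exact == pytest.approx(sampled, rel=1e-6)


@given(
    st.floats(min_value=0.5, max_value=20),
    st.floats(min_value=0.5, max_value=20),
    st.floats(min_value=0, max_value=180),
    st.floats(min_value=0.05, max_value=1),
    st.floats(min_value=0, max_value=1),
)
def test_theta_periodicity(h, w, theta, k, gamma):
    a = crush_section(h, w, CrushParams(theta, k, gamma))
    b = crush_section(h, w, CrushParams(theta + 180.0, k, gamma))
    assert a == pytest.approx(b, rel=1e-9)


def test_area_scaling():
    """Mapped-ellipse area is pi*(h/2)(w/2)*k^(1-gamma); conserved at gamma=1."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        h, w = rng.uniform(0.5, 20, 2)
        theta, k, gamma = rng.uniform(0, 180), rng.uniform(0.05, 1), rng.uniform(0, 1)
        det = abs(np.linalg.det(crush_matrix(theta, k, gamma)))
        assert det == pytest.approx(k ** (1 - gamma), rel=1e-9)
    # gamma = 1 conserves area exactly (to 1e-9) for any theta, k
    for theta, k in [(0, 0.3), (45, 0.5), (133, 0.07)]:
        det = abs(np.linalg.det(crush_matrix(theta, k, 1.0)))
        assert det == pytest.approx(1.0, abs=1e-9)
    # and the Monte-Carlo area of mapped interior points agrees at low resolution
    rng = np.random.default_rng(5)
    pts = rng.uniform(-1, 1, size=(2, 200_000))
    inside = (pts**2).sum(axis=0) <= 1.0
    m = crush_matrix(60.0, 0.5, 1.0)
    h, w = 6.0, 4.0
    mapped = m @ (np.diag([w / 2, h / 2]) @ pts[:, inside])
    # area via the determinant of the overall map applied to the unit disc
    box = 4.0 * (w / 2) * (h / 2)
    mc_area_original = box * inside.mean()
    expected = np.pi * (h / 2) * (w / 2)
    assert mc_area_original == pytest.approx(expected, rel=0.01)
    assert mapped.shape[1] == inside.sum()  # area-preserving map keeps every point


def test_volume_loss_regime_is_contraction_in_realistic_range():
    """With gamma=0, k >= 0.5 and facet ratios in [0.5, 2], extents never grow."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        h = rng.uniform(1, 10)
        w = h / rng.uniform(0.5, 2.0)
        params = CrushParams(rng.uniform(0, 180), rng.uniform(0.5, 1.0), 0.0)
        ah, aw = crush_section(h, w, params)
        assert ah <= h + 1e-12 and aw <= w + 1e-12


def test_volume_loss_regime_never_grows_diameter():
    """Unconditionally (any aspect ratio, any k), gamma=0 shrinks the diameter."""
    rng = np.random.default_rng(43)
    for _ in range(1000):
        h, w = rng.uniform(0.2, 20, 2)
        params = CrushParams(rng.uniform(0, 180), rng.uniform(0.01, 1.0), 0.0)
        ah, aw = crush_section(h, w, params)
        assert max(ah, aw) <= max(h, w) + 1e-12


def test_generate_true_column_flat_and_linear_trends():
    flat = generate_true_column(TrueColumnModel(n=5, vh_start=0.8, vh_end=0.8,
                                                noise_sd=0.0))
    summ = summarize(flat)
    assert summ.metric_diff_x100 == pytest.approx(0, abs=1e-12)
    assert summ.metric_ratio_x100 == pytest.approx(0, abs=1e-12)

    ramp = generate_true_column(TrueColumnModel(n=5, vh_start=0.7, vh_end=0.9,
                                                noise_sd=0.0))
    diffs = summarize(ramp).first_diffs
    assert list(diffs) == pytest.approx([0.05] * 4, abs=1e-12)


def test_generate_true_column_deterministic():
    model = TrueColumnModel(seed=99)
    assert generate_true_column(model) == generate_true_column(model)


def test_generator_rejects_invalid_model():
    with pytest.raises(ValidationError):
        TrueColumnModel(n=1)
    with pytest.raises(ValidationError):
        TrueColumnModel(noise_sd=-0.1)
    with pytest.raises(ValidationError):
        CrushIntensity(k_min=0.9, k_max=0.5)


def test_crush_column_identity_and_determinism():
    col = generate_true_column(TrueColumnModel(seed=3))
    unchanged = crush_column(col, CrushIntensity(k_min=1.0, k_max=1.0, seed=5))
    assert series_ratios(unchanged).vh == pytest.approx(series_ratios(col).vh,
                                                        rel=1e-12)
    a = crush_column(col, CrushIntensity(seed=7))
    b = crush_column(col, CrushIntensity(seed=7))
    assert a == b
    assert len(a.meta["crush_params"]) == len(col)
    assert {"theta", "k", "gamma"} <= set(a.meta["crush_params"][0])


def test_crush_column_contracts_at_gamma_zero():
    col = generate_true_column(TrueColumnModel(seed=13))
    for seed in range(5):
        crushed = crush_column(col, CrushIntensity(gamma=0.0, seed=seed))
        for before, after in zip(col.measurements, crushed.measurements):
            assert after.vertical <= before.vertical + 1e-12
            assert after.horizontal <= before.horizontal + 1e-12


def test_discrimination_experiment_shapes_and_null_case():
    null = discrimination_experiment(
        TrueColumnModel(), CrushIntensity(k_min=1.0, k_max=1.0), replicates=20
    )
    assert null.exceed_fraction_diff == 0.0
    single = discrimination_experiment(TrueColumnModel(), CrushIntensity(), 1)
    assert len(single.table) == 1
    with pytest.raises(ValidationError):
        discrimination_experiment(TrueColumnModel(), CrushIntensity(), 0)


def test_stronger_crushing_inflates_metric_monotonically():
    """Mean crushed difference metric rises as the compression bound k_min drops."""
    means = []
    for k_min in (0.9, 0.7, 0.5, 0.3):
        res = discrimination_experiment(
            TrueColumnModel(seed=1), CrushIntensity(k_min=k_min, seed=2), replicates=50
        )
        means.append(res.table["crushed_diff_x100"].mean())
    assert means == sorted(means)
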