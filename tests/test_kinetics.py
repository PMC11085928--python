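"""Conversion curves, kinetic fits, proliferation rates, migration activity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from infiltra import (
    ConversionCurve,
    CountProfile,
    activity_share,
    conversion_curve,
    fit_conversion_model,
    generate_count_scenario,
    migration_activity_curve,
    proliferation_rate,
    select_conversion_model,
)
from infiltra.kinetics import ALPHA_STEPS, MigrationActivity, read_profiles_csv, write_profiles_csv


def _hill(z, n, K):
    return z**n / (K**n + z**n)


Z14 = (np.arange(14) + 0.5) * 7.0


# ---------------------------------------------------------------------------
# conversion curves


def test_all_cells_first_layer():
    curve = conversion_curve(CountProfile([3, 0, 0, 0]))
    assert curve.alpha.tolist() == [1.0, 1.0, 1.0, 1.0]


def test_uniform_counts():
    curve = conversion_curve(CountProfile([1, 1, 1, 1]))
    np.testing.assert_allclose(curve.alpha, [0.25, 0.5, 0.75, 1.0])


def test_empty_profile_rejected():
    with pytest.raises(ValueError, match="empty profile"):
        conversion_curve(CountProfile([0, 0, 0]))


@settings(derandomize=True, deadline=None, max_examples=100)
@given(
    counts=st.lists(st.integers(0, 1000), min_size=2, max_size=20).filter(lambda c: sum(c) > 0),
    scale=st.integers(2, 7),
)
def test_alpha_monotone_final_one_scale_invariant(counts, scale):
    """alpha is non-decreasing, ends at 1, and ignores uniform count scaling."""
    c1 = conversion_curve(CountProfile(counts))
    assert np.all(np.diff(c1.alpha) >= -1e-12)
    assert c1.alpha[-1] == 1.0
    c2 = conversion_curve(CountProfile([c * scale for c in counts]))
    np.testing.assert_allclose(c1.alpha, c2.alpha, atol=1e-12)


# ---------------------------------------------------------------------------
# model fitting


def test_hill_fit_noiseless_recovery():
    curve = ConversionCurve(Z14, _hill(Z14, 3.0, 40.0))
    fit = fit_conversion_model(curve, "hill")
    assert fit.converged
    assert fit.params["n"] == pytest.approx(3.0, rel=0.01)
    assert fit.params["K"] == pytest.approx(40.0, rel=0.01)


def test_hill_fit_stochastic_recovery():
    rng = np.random.default_rng(7)
    ns, Ks = [], []
    for _ in range(40):
        alpha = np.clip(np.maximum.accumulate(
            _hill(Z14, 3.0, 40.0) + rng.normal(0, 0.02, Z14.size)), 0, 1)
        fit = fit_conversion_model(ConversionCurve(Z14, alpha), "hill")
        ns.append(fit.params["n"])
        Ks.append(fit.params["K"])
    assert np.median(ns) == pytest.approx(3.0, rel=0.10)
    assert np.median(Ks) == pytest.approx(40.0, rel=0.10)


def test_hill_fit_midpoint_identity():
    """For the fitted Hill curve, alpha(K) = 0.5 exactly."""
    curve = ConversionCurve(Z14, _hill(Z14, 2.5, 35.0))
    fit = fit_conversion_model(curve, "hill")
    assert fit.predict(np.array([fit.params["K"]]))[0] == pytest.approx(0.5)


def test_surface_selected_over_hill_on_surface_data():
    profile = generate_count_scenario("surface", {"k_per_um": 0.5}, 14, 4000, 0.0, 0)
    curve = conversion_curve(profile)
    s = fit_conversion_model(curve, "surface_exponential")
    h = fit_conversion_model(curve, "hill")
    assert s.residual < h.residual
    assert select_conversion_model(curve).model != "hill"


def test_unknown_model_rejected():
    curve = ConversionCurve(Z14, _hill(Z14, 3, 40))
    with pytest.raises(ValueError, match="unknown kinetic model"):
        fit_conversion_model(curve, "gompertz")


def test_too_few_points_rejected():
    with pytest.raises(ValueError, match="4 points"):
        fit_conversion_model(ConversionCurve([1.0, 2, 3], [0.1, 0.2, 0.3]), "hill")


# ---------------------------------------------------------------------------
# proliferation rate


def test_rate_arithmetic():
    profiles = [
        CountProfile([100, 0], day=1),
        CountProfile([300, 100], day=4),
        CountProfile([500, 300], day=7),
    ]
    rates = proliferation_rate(profiles)
    assert rates["t_1"] == pytest.approx(100.0)
    assert rates["t_2"] == pytest.approx(400 / 3)
    assert rates["t_3"] == pytest.approx(800 / 3)


def test_rate_scales_inverse_duration():
    profiles = [CountProfile([60], day=d) for d in (1, 4, 7)]
    rates = proliferation_rate(profiles, {"a": 1.0, "b": 2.0, "c": 4.0})
    assert rates["a"] == 2 * rates["b"] == 4 * rates["c"]


def test_rate_missing_day_rejected():
    with pytest.raises(ValueError, match="t_3"):
        proliferation_rate([CountProfile([5], day=1), CountProfile([9], day=4)])


# ---------------------------------------------------------------------------
# migration activity


def test_activity_closed_form_linear_curve():
    """alpha(z) = z/Z → activity(alpha) = r/(alpha Z^2), slope negative."""
    Z, r = 98.0, 50.0
    curve = ConversionCurve(Z14, Z14 / Z)
    act = migration_activity_curve(curve, r)
    np.testing.assert_allclose(act.activity, r / (act.alpha_steps * Z**2), rtol=1e-6)
    assert act.slope < 0
    np.testing.assert_allclose(act.z_at_alpha_um, act.alpha_steps * Z, rtol=1e-9)


def test_activity_homogeneous_in_rate():
    curve = ConversionCurve(Z14, _hill(Z14, 3, 40))
    a1 = migration_activity_curve(curve, 50.0)
    a2 = migration_activity_curve(curve, 100.0)
    np.testing.assert_allclose(a2.activity, 2 * a1.activity)
    assert a2.slope == pytest.approx(2 * a1.slope)


def test_deep_curve_has_lower_activity_everywhere():
    """Cells that only convert deep in the scaffold score less activity."""
    shallow = conversion_curve(generate_count_scenario("surface", {"k_per_um": 0.3}, 14, 3000, 0.0, 1))
    deep = conversion_curve(generate_count_scenario("hill", {"n": 4, "K_um": 60}, 14, 3000, 0.0, 1))
    act_s = migration_activity_curve(shallow, 100.0)
    act_d = migration_activity_curve(deep, 100.0)
    assert np.all(act_d.activity < act_s.activity)


def test_flat_segment_flagged():
    alpha = np.array([0.05, 0.4, 0.4, 0.4, 0.9, 1.0])
    z = np.arange(1, 7, dtype=float) * 10
    act = migration_activity_curve(ConversionCurve(z, alpha), 10.0)
    # alpha = 0.4 is spanned by a flat run: resolved at midpoint, flagged
    i = np.argmin(np.abs(act.alpha_steps - 0.4))
    assert act.flagged[i]
    assert act.z_at_alpha_um[i] == pytest.approx(0.5 * (20 + 40))


def test_activity_share_uniform():
    act = MigrationActivity(ALPHA_STEPS, ALPHA_STEPS * 98, 1.0,
                            np.ones(9), 0.0, 0.0, np.zeros(9, bool))
    assert activity_share(act, 0.5) == pytest.approx(0.5)
    assert activity_share(act, 0.9) == pytest.approx(1.0)


def test_activity_share_shallow_mass_exceeds_half():
    """A surface-settling culture concentrates activity in the first half."""
    curve = conversion_curve(generate_count_scenario("surface", {"k_per_um": 0.2}, 14, 3000, 0.0, 2))
    act = migration_activity_curve(curve, 100.0)
    assert activity_share(act, 0.5) > 0.6


def test_activity_share_rejects_bad_fraction():
    act = MigrationActivity(ALPHA_STEPS, ALPHA_STEPS * 98, 1.0,
                            np.ones(9), 0.0, 0.0, np.zeros(9, bool))
    with pytest.raises(ValueError):
        activity_share(act, 0.0)


# ---------------------------------------------------------------------------
# CSV round trip


def test_profile_csv_round_trip(tmp_path):
    profiles = [
        CountProfile([5, 3, 1, 0], day=1),
        CountProfile([9, 6, 4, 2], day=4),
    ]
    path = write_profiles_csv(profiles, tmp_path / "profiles.csv")
    back = read_profiles_csv(path)
    assert len(back) == 2
    for orig, rt in zip(profiles, back):
        assert rt.day == orig.day
        np.testing.assert_array_equal(rt.counts, orig.counts)
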