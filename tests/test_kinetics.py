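import numpy as np
import pytest

from germkin import (
    CubicSplineModel,
    NormalizedMassSeries,
    fick_mass,
    fit_spline,
    kinetics_curves,
    time_average,
)
from tests.conftest import make_series


def random_norm_series(rng, n=12):
    s = make_series(rng, n=n)
    return NormalizedMassSeries("x", s.times, s.masses / s.M0)


def test_spline_interpolates_knots_exactly(rng):
    s = random_norm_series(rng)
    spl = fit_spline(s)
    assert np.allclose(spl(s.times), s.m, rtol=0, atol=1e-14)


def test_linear_data_gives_line_and_zero_curvature():
    t = np.arange(8.0)
    spl = CubicSplineModel(t, 2.0 * t + 1.0)
    assert np.allclose(spl.second_derivs, 0.0, atol=1e-10)
    g = np.linspace(0, 7, 113)
    assert np.allclose(spl(g), 2.0 * g + 1.0, atol=1e-12)
    cur = kinetics_curves(spl)
    assert np.allclose(cur.v, 2.0, atol=1e-10)
    assert np.allclose(cur.a, 0.0, atol=1e-10)


def test_sine_oracle_fourth_order():
    # natural closure is exact for sin on [0, pi] (curvature vanishes at ends),
    # so interpolation error obeys the classical O(h^4) bound
    t = np.linspace(0.0, np.pi, 21)
    spl = CubicSplineModel(t, np.sin(t))
    g = np.linspace(0.0, np.pi, 1000)
    h = t[1] - t[0]
    bound = (5.0 / 384.0) * h**4  # |f''''| <= 1 for sin
    assert np.max(np.abs(spl(g) - np.sin(g))) < bound * 1.5


def test_quadratic_velocity_against_finite_differences():
    t = np.linspace(0.0, 10.0, 11)
    spl = CubicSplineModel(t, t**2)
    interior = t[3:-3]
    v = spl(interior, 1)
    # central differences of the raw data as an independent oracle
    fd = (spl.values[4:-2] - spl.values[2:-4]) / (t[4:-2] - t[2:-4])
    assert np.allclose(fd, 2.0 * interior, rtol=1e-12)
    assert np.allclose(v, fd, rtol=0.01)


def test_needs_at_least_four_knots():
    with pytest.raises(ValueError, match="4"):
        CubicSplineModel([0.0, 1.0, 2.0], [1.0, 1.1, 1.2])


def test_fundamental_theorem_identities(rng):
    for _ in range(20):
        s = random_norm_series(rng)
        spl = fit_spline(s)
        cur = kinetics_curves(spl)
        tau = cur.tau
        dv = spl.derivative(1)
        assert np.isclose(
            dv.integrate(0.0, tau), spl(tau) - spl(0.0), rtol=0, atol=1e-9
        )
        da = spl.derivative(2)
        assert np.isclose(
            da.integrate(0.0, tau), spl(tau, 1) - spl(0.0, 1), rtol=0, atol=1e-9
        )
        assert np.isclose(cur.v_mean, (spl(tau) - spl(0.0)) / tau, atol=1e-9)


def test_value_shift_leaves_derivatives_unchanged(rng):
    s = random_norm_series(rng)
    spl = CubicSplineModel(s.times, s.m)
    shifted = CubicSplineModel(s.times, s.m + 5.0)
    g = np.linspace(s.times[0], s.times[-1], 333)
    assert np.allclose(shifted(g) - spl(g), 5.0, atol=1e-12)
    assert np.allclose(shifted(g, 1), spl(g, 1), atol=1e-12)
    assert np.allclose(shifted(g, 2), spl(g, 2), atol=1e-12)


def test_derivative_continuity_at_knots(rng):
    s = random_norm_series(rng)
    spl = fit_spline(s)
    eps = 1e-7
    interior = s.times[1:-1]
    for nu in (0, 1, 2):
        jump = np.abs(spl(interior + eps, nu) - spl(interior - eps, nu))
        assert np.max(jump) < 1e-5  # continuous up to second derivative


def test_fick_curve_velocity_monotone_acceleration_negative():
    # imbibition mass from the one-term diffusion series: uptake decelerates,
    # so velocity falls and acceleration is negative (away from the natural
    # boundary closure at the record ends)
    t = np.arange(0.0, 31.0, 1.0)
    m = fick_mass(t, 5e-3, 2.55, 1)
    spl = CubicSplineModel(t, m)
    g = np.linspace(t[2], t[-3], 400)
    v = spl(g, 1)
    a = spl(g, 2)
    assert np.all(v > 0)
    assert np.all(np.diff(v) < 0)
    assert np.all(a < 0)


def test_time_average_constant_and_linear():
    t = np.linspace(0.0, 2.0, 9)
    const = CubicSplineModel(t, np.full(t.size, 3.5))
    assert time_average(const) == pytest.approx(3.5, abs=1e-12)
    line = CubicSplineModel(t, t.copy())
    assert time_average(line) == pytest.approx(1.0, abs=1e-12)


def test_time_average_matches_simpson(rng):
    s = random_norm_series(rng)
    spl = fit_spline(s)
    tau = s.times[-1]
    v = spl.derivative(1)
    exact = time_average(spl, deriv=1)
    from scipy.integrate import simpson

    g = np.linspace(0.0, tau, 10001)
    assert np.isclose(exact, simpson(v(g), x=g) / tau, atol=1e-8)


def test_time_average_rejects_degenerate_window():
    t = np.linspace(0.0, 2.0, 9)
    spl = CubicSplineModel(t, t.copy())
    with pytest.raises(ValueError):
        time_average(spl, tau=0.0)


def test_mass_scale_converts_units(rng):
    s = random_norm_series(rng)
    spl = fit_spline(s)
    cur_n = kinetics_curves(spl)
    cur_g = kinetics_curves(spl, mass_scale=0.25)
    assert np.allclose(cur_g.v, 0.25 * cur_n.v)
    assert cur_g.v_mean == pytest.approx(0.25 * cur_n.v_mean)
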