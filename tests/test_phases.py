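import dataclasses
import warnings

import numpy as np
import pytest

from germkin import (
    KineticsCurves,
    PhaseSegmenter,
    detect_phase_boundaries,
    find_extrema,
    fit_phase_regressions,
    fit_spline,
    generate_cohort,
    kinetics_curves,
    random_ground_truth,
    true_kinetics_curves,
    true_segmentation,
)
from germkin.resampling import BootstrapEnsemble


def curve_from(grid, v, m=None, a=None):
    grid = np.asarray(grid, dtype=float)
    v = np.asarray(v, dtype=float)
    m = np.zeros_like(grid) if m is None else m
    a = np.zeros_like(grid) if a is None else a
    tau = float(grid[-1])
    return KineticsCurves(grid=grid, m=m, v=v, a=a, v_mean=0.0, a_mean=0.0, tau=tau)


# ---------------------------------------------------------------------------
# extrema
# ---------------------------------------------------------------------------


def test_monotone_velocity_has_no_extrema():
    g = np.linspace(0, 10, 300)
    ext = find_extrema(curve_from(g, np.exp(-g)), 0.05)
    assert len(ext) == 0


def test_sine_extrema_counts_and_alternation():
    g = np.linspace(0.0, 3 * np.pi, 800)
    ext = find_extrema(curve_from(g, np.sin(g)), 0.1)
    assert ext.peak_times.size == 2
    assert ext.valley_times.size == 1
    assert np.all(np.diff(ext.kinds) != 0)  # alternating
    assert np.allclose(ext.peak_times, [np.pi / 2, 5 * np.pi / 2], atol=0.05)
    assert np.allclose(ext.valley_times, [3 * np.pi / 2], atol=0.05)


def test_small_jitter_filtered_to_same_extrema():
    g = np.linspace(0.0, 3 * np.pi, 800)
    clean = find_extrema(curve_from(g, np.sin(g)), 0.1)
    rng = np.random.default_rng(0)
    jitter = 0.01 * np.sin(37.0 * g) + 0.005 * rng.standard_normal(g.size)
    noisy = find_extrema(curve_from(g, np.sin(g) + jitter), 0.1)
    assert noisy.kinds.tolist() == clean.kinds.tolist()
    assert np.allclose(noisy.times, clean.times, atol=0.1)


def test_flat_velocity_single_phase_with_warning():
    g = np.linspace(0, 10, 200)
    with pytest.warns(UserWarning, match="single-phase"):
        seg = detect_phase_boundaries(curve_from(g, np.zeros_like(g)))
    assert seg.n_phases == 1
    assert seg.boundaries.size == 0


def test_single_peak_then_decay_two_phases():
    g = np.linspace(0.0, 10.0, 600)
    v = np.where(g < 2.0, 0.05 * g / 2.0, 0.05 * np.exp(-(g - 2.0)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = detect_phase_boundaries(curve_from(g, v))
    assert seg.n_phases == 2
    assert seg.boundaries[0] == pytest.approx(2.0, abs=0.1)


def test_segmentation_scale_invariance(cohort):
    cur = kinetics_curves(fit_spline(cohort.mean_normalized()))
    big = dataclasses.replace(cur, v=10.0 * cur.v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s1 = detect_phase_boundaries(cur)
        s2 = detect_phase_boundaries(big)
    assert np.array_equal(s1.boundaries, s2.boundaries)


def test_threshold_factor_monotone(cohort):
    cur = kinetics_curves(fit_spline(cohort.mean_normalized()))
    counts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tf in (1.0, 1.2, 1.5, 2.0, 5.0):
            counts.append(detect_phase_boundaries(cur, threshold_factor=tf).n_phases)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_phases_partition_window(cohort):
    cur = kinetics_curves(fit_spline(cohort.mean_normalized()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = detect_phase_boundaries(cur)
    edges = [seg.phases[0][1]] + [p[2] for p in seg.phases]
    assert edges[0] == cur.grid[0]
    assert edges[-1] == cur.tau
    assert np.all(np.diff(edges) > 0)
    for (_, a0, b0), (_, a1, _) in zip(seg.phases, seg.phases[1:]):
        assert b0 == a1  # half-open, contiguous


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------


def test_exact_line_regression_is_perfect():
    g = np.linspace(0.0, 10.0, 400)
    v = 0.1 - 0.01 * g
    cur = curve_from(g, v)
    from germkin.phases import PhaseSegmentation

    seg = PhaseSegmentation(
        boundaries=np.array([]), phases=((0, 0.0, 10.0),), threshold_factor=1.2
    )
    (reg,) = fit_phase_regressions(cur, seg)
    assert reg.beta0 == pytest.approx(0.1, abs=1e-12)
    assert reg.beta == pytest.approx(-0.01, abs=1e-12)
    assert reg.chi2 == pytest.approx(0.0, abs=1e-12)


def test_constant_velocity_slope_not_significant():
    from germkin.phases import PhaseSegmentation

    g = np.linspace(0.0, 8.0, 200)
    c = 0.05
    cur = curve_from(g, np.full_like(g, c))
    seg = PhaseSegmentation(np.array([]), ((0, 0.0, 8.0),), 1.2)
    rng = np.random.default_rng(0)
    reps = c + 1e-4 * rng.standard_normal((500, g.size))
    ens = BootstrapEnsemble(reps, 500, 0, "velocity_curve", grid=g)
    (reg,) = fit_phase_regressions(cur, seg, ens=ens, alpha=0.05)
    assert reg.beta0 == pytest.approx(c, abs=1e-12)
    assert reg.beta == pytest.approx(0.0, abs=1e-12)
    assert reg.significant_beta0 is True
    assert reg.significant_beta is False


def test_short_phase_merged_with_warning():
    from germkin.phases import PhaseSegmentation

    g = np.linspace(0.0, 10.0, 101)
    cur = curve_from(g, 0.01 * g)
    seg = PhaseSegmentation(
        np.array([9.85]), ((0, 0.0, 9.85), (1, 9.85, 10.0)), 1.2
    )
    with pytest.warns(UserWarning, match="merged"):
        regs = fit_phase_regressions(cur, seg)
    assert len(regs) == 1


def test_ensemble_grid_mismatch_rejected(cohort):
    cur = kinetics_curves(fit_spline(cohort.mean_normalized()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = detect_phase_boundaries(cur)
    bad = BootstrapEnsemble(
        np.zeros((10, 5)), 10, 0, "velocity_curve", grid=np.arange(5.0)
    )
    with pytest.raises(ValueError, match="same grid"):
        fit_phase_regressions(cur, seg, ens=bad)


def test_noiseless_four_phase_exact_beta_recovery(noiseless_gt):
    cur = true_kinetics_curves(noiseless_gt, n_grid=801)
    regs = fit_phase_regressions(cur, true_segmentation(noiseless_gt))
    assert len(regs) == noiseless_gt.n_phases
    for reg, (b0, b1) in list(zip(regs, noiseless_gt.betas))[1:]:
        assert abs(reg.beta0 - b0) <= 1e-8
        assert abs(reg.beta - b1) <= 1e-8
        assert reg.chi2 <= 1e-12


def test_five_phase_cohort_boundary_recovery():
    # excursions at the true boundaries are built ~2x the curve's mean
    # peak-valley difference, the regime the 1.2x rule targets
    gt = random_ground_truth(3, n_phases=5)
    sample, _ = generate_cohort(gt)
    cur = kinetics_curves(fit_spline(sample.mean_normalized()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = detect_phase_boundaries(cur)
    assert seg.n_phases == 5
    assert np.all(
        np.abs(seg.boundaries - np.array(gt.phase_boundaries))
        <= gt.record_interval
    )


def test_segmenter_estimator(cohort):
    cur = kinetics_curves(fit_spline(cohort.mean_normalized()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = PhaseSegmenter().fit(cur)
        labels = PhaseSegmenter().fit_predict(cur)
    assert est.n_phases_ == est.segmentation_.n_phases
    assert labels.size == cur.grid.size
    assert labels.max() == est.n_phases_ - 1
    assert np.all(np.diff(labels) >= 0)
    params = est.get_params()
    assert params["threshold_factor"] == 1.2
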