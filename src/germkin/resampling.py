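"""Diaspore-level bootstrap and percentile Monte-Carlo confidence intervals.

The resampling unit is the whole diaspore curve, never the time point:
resampling time points would destroy the within-series dependence the
splines encode.  Each replicate draws ``n`` diaspores with replacement from
the cohort and evaluates the requested statistic (a mean weighted-mass
curve, a mean velocity/acceleration scalar, or a dense velocity or
acceleration curve of the replicate mean).  1000 resamples is the default;
replicate summaries change negligibly above that.

Confidence statements are plain percentile Monte-Carlo intervals: the
pointwise empirical alpha/2 and 1-alpha/2 quantiles of the replicate
distribution, with linear interpolation between order statistics.  All
randomness flows through one named, seedable generator so ensembles are
bit-reproducible given (seed, B, input).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data_io import SampleSet
from .kinetics import CubicSplineModel, POINTS_PER_INTERVAL

__all__ = [
    "BootstrapEnsemble",
    "ConfidenceBand",
    "bootstrap",
    "bootstrap_statistic",
    "percentile_ci",
]

STATISTIC_KINDS = (
    "mean_curve",
    "mean_velocity",
    "mean_acceleration",
    "velocity_curve",
    "acceleration_curve",
)


@dataclass(frozen=True, eq=False)
class BootstrapEnsemble:
    """B replicate statistic values on a shared grid (curves) or scalars."""

    replicates: np.ndarray  # shape (B,) or (B, grid)
    B: int
    seed: int | None
    statistic_kind: str
    grid: np.ndarray | None = None


@dataclass(frozen=True, eq=False)
class ConfidenceBand:
    """Percentile band: lower <= point_estimate <= upper (pointwise)."""

    alpha: float
    lower: np.ndarray | float
    upper: np.ndarray | float
    point_estimate: np.ndarray | float


def bootstrap(
    data: np.ndarray,
    statistic: Callable[[np.ndarray], np.ndarray | float],
    B: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Generic with-replacement bootstrap along the first axis of ``data``.

    Returns the (B, ...) array of replicate statistic values.  Deterministic
    under a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    data = np.asarray(data)
    n = data.shape[0]
    if n == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    first = np.asarray(statistic(data[idx[0]]))
    reps = np.empty((B,) + first.shape, dtype=float)
    reps[0] = first
    for b in range(1, B):
        reps[b] = statistic(data[idx[b]])
    return reps


def _per_diaspore_scalar(sample: SampleSet, kind: str) -> np.ndarray:
    """Exact per-diaspore time-averaged velocity or acceleration.

    Both are endpoint differences of the spline (fundamental theorem of
    calculus), so the per-diaspore mean commutes with cohort averaging.
    """
    vals = np.empty(sample.n_diaspores)
    for i, s in enumerate(sample.normalized()):
        spl = CubicSplineModel(s.times, s.m)
        t0, tau = spl.domain
        span = tau - t0
        if kind == "mean_velocity":
            vals[i] = (spl(tau) - spl(t0)) / span
        else:
            vals[i] = (spl(tau, 1) - spl(t0, 1)) / span
    return vals


def bootstrap_statistic(
    sample: SampleSet,
    statistic: str | Callable = "mean_curve",
    B: int = 1000,
    seed: int | None = None,
    n_grid: int | None = None,
) -> BootstrapEnsemble:
    """Bootstrap a named cohort summary over diaspore resamples.

    Parameters
    ----------
    statistic : str or callable
        One of ``mean_curve`` (pointwise mean weighted mass on the recording
        grid), ``mean_velocity`` / ``mean_acceleration`` (scalar time
        averages), ``velocity_curve`` / ``acceleration_curve`` (dense
        analytic derivative of the replicate-mean spline), or a callable
        mapping the (n, T) normalized-mass matrix of a resample to a
        statistic.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    m = sample.normalized_matrix()
    grid_out: np.ndarray | None = None
    kind = statistic if isinstance(statistic, str) else getattr(
        statistic, "__name__", "custom"
    )

    if callable(statistic):
        reps = bootstrap(m, statistic, B=B, seed=seed)
    elif statistic == "mean_curve":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, m.shape[0], size=(B, m.shape[0]))
        reps = m[idx].mean(axis=1)
        grid_out = sample.time_grid
    elif statistic in ("mean_velocity", "mean_acceleration"):
        vals = _per_diaspore_scalar(sample, statistic)
        reps = bootstrap(vals, lambda x: x.mean(), B=B, seed=seed)
    elif statistic in ("velocity_curve", "acceleration_curve"):
        knots = sample.time_grid
        if n_grid is None:
            n_grid = POINTS_PER_INTERVAL * (knots.size - 1) + 1
        grid_out = np.linspace(knots[0], knots[-1], int(n_grid))
        nu = 1 if statistic == "velocity_curve" else 2

        def stat(rows: np.ndarray) -> np.ndarray:
            return CubicSplineModel(knots, rows.mean(axis=0))(grid_out, nu)

        reps = bootstrap(m, stat, B=B, seed=seed)
    else:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {STATISTIC_KINDS}"
        )
    return BootstrapEnsemble(
        replicates=reps, B=int(B), seed=seed, statistic_kind=kind, grid=grid_out
    )


def percentile_ci(ens: BootstrapEnsemble, alpha: float = 0.05) -> ConfidenceBand:
    """Pointwise percentile confidence band of a bootstrap ensemble.

    Empirical alpha/2 and 1-alpha/2 quantiles with linear interpolation
    between order statistics; the point estimate is the replicate mean.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie strictly between 0 and 1")
    reps = ens.replicates
    lower = np.quantile(reps, alpha / 2.0, axis=0, method="linear")
    upper = np.quantile(reps, 1.0 - alpha / 2.0, axis=0, method="linear")
    point = reps.mean(axis=0)
    if np.ndim(lower) == 0:
        lower, upper, point = float(lower), float(upper), float(point)
    return ConfidenceBand(alpha=float(alpha), lower=lower, upper=upper,
                          point_estimate=point)
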