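"""Fick-series imbibition model and diffusion-coefficient estimation.

Imbibition (Phase I) is treated as purely physical water uptake by a
spherical diaspore, described by the series solution of Fick's second law:

    M(t)/M_inf = 1 - (6/pi^2) * sum_{k=1..n} (1/k^2) exp(-D k^2 pi^2 t / rho^2)

with ``M_inf`` the saturation mass and ``D/rho^2`` the diffusion coefficient
per squared diaspore radius (1/h).  Only the ratio D/rho^2 is identifiable
from mass records, and it is the comparable quantity across species with
different diaspore sizes; D and rho are never separated.

The fit is nonlinear least squares by Levenberg-Marquardt on the *total*
(not normalized) mass, restricted to the imbibition window, estimating
(D/rho^2, M_inf) jointly.  The series is truncated at ``n_terms = 1`` by
default; with one term the bracket at t = 0 equals 1 - 6/pi^2 (about
0.3921), and with many terms it vanishes as sum(1/k^2) -> pi^2/6.

A scikit-learn style estimator, :class:`FickDiffusionModel`, wraps the same
fit with ``fit``/``predict`` and trailing-underscore fitted attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .data_io import MassSeries, SampleSet

__all__ = [
    "fick_mass",
    "fit_fick",
    "fit_fick_cohort",
    "FickFit",
    "FickFitError",
    "FickDiffusionModel",
]

_PI2 = np.pi**2


def fick_mass(t, d_over_rho2, m_inf, n_terms: int = 1):
    """Evaluate the truncated Fick series mass M(t).

    Vectorised over ``t``.  Non-decreasing in both t and D/rho^2.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if d_over_rho2 <= 0 or m_inf <= 0:
        raise ValueError("d_over_rho2 and m_inf must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    k = np.arange(1, int(n_terms) + 1, dtype=float)
    # (..., n_terms) broadcast; exponent clipped only by exp underflow, safe
    expo = np.exp(-d_over_rho2 * _PI2 * np.multiply.outer(t, k**2))
    series = (expo / k**2).sum(axis=-1)
    out = m_inf * (1.0 - (6.0 / _PI2) * series)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class FickFit:
    """Result of a Levenberg-Marquardt Fick-series fit on a Phase-I window."""

    d_over_rho2: float
    m_inf: float
    n_terms: int
    window_end: float
    sse: float
    n_points: int
    converged: bool


class FickFitError(RuntimeError):
    """Fit failed (non-convergence or non-identifiable dynamics).

    Carries the best iterate reached, when one exists, as ``best``.
    """

    def __init__(self, message: str, best: FickFit | None = None):
        super().__init__(message)
        self.best = best


def _initial_guess(t: np.ndarray, M: np.ndarray) -> tuple[float, float]:
    """Heuristic start removing LM sensitivity to starting values.

    M_inf0 = 1.05 x max observed mass; D0 from the slope of
    -ln(1 - M/M_inf0) against t (for one term that transform is linear in t
    with slope D pi^2 / rho^2).
    """
    m_inf0 = 1.05 * float(np.max(M))
    ratio = np.clip(M / m_inf0, None, 1.0 - 1e-12)
    y = -np.log1p(-ratio)
    slope = float(np.polyfit(t, y, 1)[0]) if t.size > 1 else 0.0
    d0 = slope / _PI2
    if not np.isfinite(d0) or d0 <= 0:
        d0 = 1e-3
    return d0, m_inf0


def fit_fick(
    series,
    t_phase1_end: float | None = None,
    n_terms: int = 1,
    xtol: float = 1e-10,
    max_iter: int = 200,
) -> FickFit:
    """Fit (D/rho^2, M_inf) to the imbibition window of one mass series.

    Parameters
    ----------
    series : MassSeries or (times, masses) pair
        Total mass in grams against time in hours.
    t_phase1_end : float, optional
        End of the imbibition window (h); points with t <= t_phase1_end are
        used.  ``None`` uses the whole record.  In the full pipeline this
        comes from the phase segmentation (first velocity peak); pass it
        explicitly to override.
    n_terms : int
        Series truncation (1 by default; the one-term fit is the
        conventional choice, the full series remains available).

    Raises
    ------
    FickFitError
        On non-convergence (carrying the best iterate) or when the window
        shows no mass dynamics (non-identifiable).
    """
    if isinstance(series, MassSeries):
        t_all, M_all = series.times, series.masses
    else:
        t_all = np.asarray(series[0], dtype=float)
        M_all = np.asarray(series[1], dtype=float)
    if t_phase1_end is None:
        t_phase1_end = float(t_all[-1])
    mask = t_all <= t_phase1_end + 1e-12
    t, M = t_all[mask], M_all[mask]
    if t.size < 3:
        raise FickFitError(
            f"need at least 3 points in the imbibition window [0, {t_phase1_end}]; "
            f"got {t.size}"
        )
    rng_rel = (np.max(M) - np.min(M)) / np.max(M)
    if rng_rel < 1e-12:
        raise FickFitError(
            "constant mass in the imbibition window: diffusion coefficient is "
            "non-identifiable (no dynamics)"
        )

    d0, m_inf0 = _initial_guess(t, M)

    def resid(theta):
        d, m_inf = theta
        # keep the model evaluable for the trial steps LM may take
        d = abs(d) + 1e-300
        m_inf = abs(m_inf) + 1e-300
        return fick_mass(t, d, m_inf, n_terms) - M

    res = least_squares(
        resid,
        x0=[d0, m_inf0],
        method="lm",
        xtol=xtol,
        ftol=xtol,
        gtol=xtol,
        max_nfev=max_iter * 3,
    )
    d_hat, m_inf_hat = abs(res.x[0]), abs(res.x[1])
    fit = FickFit(
        d_over_rho2=float(d_hat),
        m_inf=float(m_inf_hat),
        n_terms=int(n_terms),
        window_end=float(t_phase1_end),
        sse=float(np.sum(res.fun**2)),
        n_points=int(t.size),
        converged=bool(res.success),
    )
    if not res.success:
        raise FickFitError("Levenberg-Marquardt did not converge", best=fit)
    if d_hat <= 1e-12:
        raise FickFitError("fitted D/rho^2 collapsed to zero: non-identifiable",
                           best=fit)
    return fit


def fit_fick_cohort(
    sample: SampleSet,
    t_phase1_end: float | None = None,
    n_terms: int = 1,
    per_diaspore: bool = True,
) -> list[tuple[str, FickFit]]:
    """Fit the Fick model per diaspore (default) or on the cohort mean curve."""
    out: list[tuple[str, FickFit]] = []
    if per_diaspore:
        for s in sample.series:
            out.append((s.diaspore_id, fit_fick(s, t_phase1_end, n_terms)))
    else:
        mean_mass = sample.mass_matrix().mean(axis=0)
        out.append(
            (f"{sample.label}:mean",
             fit_fick((sample.time_grid, mean_mass), t_phase1_end, n_terms))
        )
    return out


class FickDiffusionModel(RegressorMixin, BaseEstimator):
    """Fick-series imbibition regressor (scikit-learn estimator interface).

    Parameters
    ----------
    n_terms : int, default 1
        Series truncation.
    window_end : float, optional
        Imbibition window end in hours (``None``: use all supplied points).
    xtol : float
        Levenberg-Marquardt relative-change stopping tolerance.
    max_iter : int
        Iteration budget.

    Attributes
    ----------
    d_over_rho2_ : float
        Fitted diffusion coefficient per squared radius (1/h).
    m_inf_ : float
        Fitted saturation mass (g).
    sse_ : float
        Residual sum of squares (g^2).
    converged_ : bool
    """

    def __init__(self, n_terms: int = 1, window_end: float | None = None,
                 xtol: float = 1e-10, max_iter: int = 200):
        self.n_terms = n_terms
        self.window_end = window_end
        self.xtol = xtol
        self.max_iter = max_iter

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        M = np.asarray(y, dtype=float).reshape(-1)
        if t.size != M.size:
            raise ValueError("X (times) and y (masses) must have equal length")
        fit = fit_fick((t, M), self.window_end, self.n_terms,
                       xtol=self.xtol, max_iter=self.max_iter)
        self.fit_ = fit
        self.d_over_rho2_ = fit.d_over_rho2
        self.m_inf_ = fit.m_inf
        self.sse_ = fit.sse
        self.n_points_ = fit.n_points
        self.converged_ = fit.converged
        return self

    def predict(self, X):
        if not hasattr(self, "d_over_rho2_"):
            raise RuntimeError("FickDiffusionModel is not fitted yet")
        t = np.asarray(X, dtype=float).reshape(-1)
        return fick_mass(t, self.d_over_rho2_, self.m_inf_, self.n_terms)
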