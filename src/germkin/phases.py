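"""Germination-phase segmentation from velocity-curve inflections.

Germination sensu stricto is polyphasic: between imbibition and embryo
protrusion the water-uptake velocity shows pronounced inflections that mark
metabolically distinct phases (three to six in practice).  Segmentation uses
two rules on the velocity curve, normalised by its maximum absolute value so
that the decision is invariant to rescaling:

1. the first qualifying velocity *peak* closes Phase I (imbibition per se,
   the only window where a Fick description applies);
2. a later extremum opens a new phase when its adjacent peak-valley
   excursion exceeds ``threshold_factor`` (default 1.2) times the average
   peak-valley excursion of the curve — i.e. it is an abrupt change, not an
   ordinary oscillation.

Small oscillations (measurement noise, minor metabolic fluctuation) are
removed by a prominence filter before an extremum may become a boundary
candidate; the excursion *average* is taken over all discrete extrema of
the curve so ordinary fluctuation drags it down and only abrupt changes
clear the 1.2x bar.  The Phase-I peak's own excursions are excluded from
that average by default (they would otherwise dominate it).  Records from
the final two hours (post-protrusion by experimental design) are kept
inside the last phase and never open a new one.

Each phase is then summarised by an ordinary least-squares line
``v_hat = beta0 + beta * t`` (initial velocity and velocity increment or
decrement), with bootstrap percentile confidence intervals, CI-based
significance at alpha, and a chi-squared goodness-of-fit statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .kinetics import KineticsCurves
from .resampling import BootstrapEnsemble

__all__ = [
    "ExtremaSet",
    "PhaseSegmentation",
    "PhaseRegression",
    "find_extrema",
    "detect_phase_boundaries",
    "fit_phase_regressions",
    "PhaseSegmenter",
]

#: divisor floor for the chi-squared statistic, keeps near-zero predictions
#: from blowing the sum up
CHI2_FLOOR = 1e-6


@dataclass(frozen=True, eq=False)
class ExtremaSet:
    """Alternating local maxima/minima of a velocity curve.

    ``times``/``values``/``kinds`` hold the merged alternating chain
    (kind +1 = peak, -1 = valley); ``excursions[i]`` is the absolute
    velocity difference between chain members i and i+1.
    """

    times: np.ndarray
    values: np.ndarray
    kinds: np.ndarray
    excursions: np.ndarray
    mean_excursion: float

    @property
    def peak_times(self) -> np.ndarray:
        return self.times[self.kinds > 0]

    @property
    def valley_times(self) -> np.ndarray:
        return self.times[self.kinds < 0]

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True, eq=False)
class PhaseSegmentation:
    """Ordered interior boundaries and the phases they delimit.

    Phases partition [t0, tau] with the half-open convention
    [t_start, t_end), the last phase closed at tau.
    """

    boundaries: np.ndarray
    phases: tuple[tuple[int, float, float], ...]
    threshold_factor: float

    @property
    def n_phases(self) -> int:
        return len(self.phases)


@dataclass(frozen=True, eq=False)
class PhaseRegression:
    """OLS line v_hat = beta0 + beta*t for one phase, with CIs and chi2."""

    phase_index: int
    beta0: float
    beta: float
    ci_beta0: tuple[float, float] | None
    ci_beta: tuple[float, float] | None
    significant_beta0: bool | None
    significant_beta: bool | None
    chi2: float
    n_points: int


def _discrete_extrema(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All interior local maxima/minima indices, plateaus to earliest point."""
    d = np.diff(v)
    s = np.sign(d)
    # carry the previous non-zero slope sign through flat runs
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    peaks, valleys = [], []
    for i in range(1, s.size):
        if s[i - 1] > 0 and s[i] < 0:
            peaks.append(i)
        elif s[i - 1] < 0 and s[i] > 0:
            valleys.append(i)
    return np.asarray(peaks, dtype=int), np.asarray(valleys, dtype=int)


def _alternating_chain(v, peaks, valleys):
    """Merge peak/valley indices enforcing alternation.

    Within a run of same-kind extrema, the most extreme value is kept
    (earliest index on ties).
    """
    items = [(int(i), +1) for i in peaks] + [(int(i), -1) for i in valleys]
    items.sort()
    chain: list[tuple[int, int]] = []
    for idx, kind in items:
        if chain and chain[-1][1] == kind:
            prev_idx = chain[-1][0]
            better = v[idx] > v[prev_idx] if kind > 0 else v[idx] < v[prev_idx]
            if better:
                chain[-1] = (idx, kind)
        else:
            chain.append((idx, kind))
    return chain


def find_extrema(curve: KineticsCurves, min_prominence: float = 0.05) -> ExtremaSet:
    """Locate alternating velocity extrema above a prominence threshold.

    ``min_prominence`` is a fraction of ``max |v|`` (the normalisation by
    the absolute value of the derivative); 0 keeps every discrete local
    extremum.  Excursions are reported in the curve's own velocity units.
    """
    v = np.asarray(curve.v, dtype=float)
    vmax = float(np.max(np.abs(v))) if v.size else 0.0
    if v.size == 0 or vmax == 0.0:
        empty = np.array([])
        return ExtremaSet(empty, empty, empty.astype(int), empty, 0.0)
    vn = v / vmax
    if min_prominence > 0:
        peaks, _ = find_peaks(vn, prominence=min_prominence)
        valleys, _ = find_peaks(-vn, prominence=min_prominence)
    else:
        peaks, valleys = _discrete_extrema(vn)
    chain = _alternating_chain(vn, peaks, valleys)
    idx = np.array([i for i, _ in chain], dtype=int)
    kinds = np.array([k for _, k in chain], dtype=int)
    times = curve.grid[idx] if idx.size else np.array([])
    values = v[idx] if idx.size else np.array([])
    exc = np.abs(np.diff(values)) if idx.size > 1 else np.array([])
    mean_exc = float(exc.mean()) if exc.size else 0.0
    return ExtremaSet(times=times, values=values, kinds=kinds,
                      excursions=exc, mean_excursion=mean_exc)


def detect_phase_boundaries(
    curve: KineticsCurves,
    threshold_factor: float = 1.2,
    min_prominence: float = 0.05,
    tail_exclude: float = 2.0,
    include_first_peak_excursions: bool = False,
    min_separation: float | None = None,
) -> PhaseSegmentation:
    """Segment the record into germination phases from the velocity curve.

    Parameters
    ----------
    threshold_factor : float
        An extremum beyond Phase I opens a phase when its adjacent
        excursion exceeds this multiple of the curve's mean peak-valley
        excursion.
    min_prominence : float
        Small-oscillation filter, as a fraction of max |v|, applied to
        boundary candidates.
    tail_exclude : float
        Width (h) of the terminal window whose extrema never open a phase;
        2 h matches recording up to two hours past embryo protrusion.
    include_first_peak_excursions : bool
        Include the Phase-I peak's adjacent excursions in the mean (they
        otherwise dominate it); off by default.
    min_separation : float, optional
        Minimum spacing (h) between accepted boundaries; ``None`` disables.

    Returns a single-phase segmentation with a warning when no qualifying
    first peak exists.
    """
    grid = np.asarray(curve.grid, dtype=float)
    t0, tau = float(grid[0]), float(grid[-1])
    tail_cut = tau - float(tail_exclude)

    candidates = find_extrema(curve, min_prominence)
    all_ext = find_extrema(curve, 0.0)

    def _single_phase(msg: str) -> PhaseSegmentation:
        warnings.warn(msg, stacklevel=2)
        return PhaseSegmentation(
            boundaries=np.array([]),
            phases=((0, t0, tau),),
            threshold_factor=float(threshold_factor),
        )

    peak_mask = (candidates.kinds > 0) & (candidates.times > t0) & (
        candidates.times < tail_cut
    )
    if not np.any(peak_mask):
        return _single_phase(
            "no qualifying velocity peak: cannot close Phase I, "
            "returning a single-phase segmentation"
        )
    first_peak_pos = int(np.flatnonzero(peak_mask)[0])
    b1 = float(candidates.times[first_peak_pos])

    # mean excursion over every discrete extremum of the curve (ordinary
    # oscillations included), restricted to the pre-tail window
    chain_mask = (all_ext.times > t0) & (all_ext.times < tail_cut)
    chain_idx = np.flatnonzero(chain_mask)
    exclude_pairs: set[int] = set()
    if not include_first_peak_excursions and chain_idx.size:
        # the Phase-I peak and its whole descent (down to the next filtered
        # extremum) would dominate the average; leave them out
        after = candidates.times[candidates.times > b1]
        descent_end = float(after[0]) if after.size else tail_cut
        j = int(np.argmin(np.abs(all_ext.times - b1)))
        exclude_pairs.add(j - 1)
        for jj in range(j, len(all_ext) - 1):
            if all_ext.times[jj] <= descent_end:
                exclude_pairs.add(jj)
            else:
                break
    excs = []
    for j in range(len(all_ext) - 1):
        if j in exclude_pairs:
            continue
        if chain_mask[j] and chain_mask[j + 1]:
            excs.append(all_ext.excursions[j])
    # with no ordinary-oscillation reference left, every prominent extremum
    # is an abrupt change by definition
    mean_exc = float(np.mean(excs)) if len(excs) >= 2 else 0.0

    # candidate adjacent excursions within the filtered chain
    cand_exc = np.zeros(len(candidates))
    for j in range(len(candidates)):
        left = candidates.excursions[j - 1] if j > 0 else 0.0
        right = candidates.excursions[j] if j < len(candidates) - 1 else 0.0
        cand_exc[j] = max(left, right)

    boundaries = [b1]
    for j in range(len(candidates)):
        tj = float(candidates.times[j])
        if tj <= b1 or tj >= tail_cut:
            continue
        if cand_exc[j] > threshold_factor * mean_exc:
            boundaries.append(tj)
    boundaries = sorted(set(boundaries))
    if min_separation is not None:
        kept: list[float] = []
        for b in boundaries:
            if not kept or b - kept[-1] >= min_separation:
                kept.append(b)
        boundaries = kept

    bounds = np.asarray(boundaries, dtype=float)
    edges = [t0, *bounds, tau]
    phases = tuple(
        (k, float(edges[k]), float(edges[k + 1])) for k in range(len(edges) - 1)
    )
    return PhaseSegmentation(
        boundaries=bounds, phases=phases, threshold_factor=float(threshold_factor)
    )


def _phase_masks(grid: np.ndarray, seg: PhaseSegmentation, min_points: int = 3):
    """Half-open membership masks, merging underpopulated phases leftward."""
    masks = []
    for k, (idx, a, b) in enumerate(seg.phases):
        last = k == len(seg.phases) - 1
        m = (grid >= a) & ((grid <= b) if last else (grid < b))
        masks.append(m)
    merged_any = False
    k = 0
    while k < len(masks):
        if masks[k].sum() < min_points and len(masks) > 1:
            target = k - 1 if k > 0 else k + 1
            masks[target] = masks[target] | masks[k]
            del masks[k]
            merged_any = True
        else:
            k += 1
    if merged_any:
        warnings.warn(
            "phase with fewer than 3 grid points merged into its neighbour",
            stacklevel=3,
        )
    return masks


def fit_phase_regressions(
    curve: KineticsCurves,
    seg: PhaseSegmentation,
    ens: BootstrapEnsemble | None = None,
    alpha: float = 0.05,
) -> list[PhaseRegression]:
    """Per-phase OLS velocity lines with bootstrap CIs and chi-squared fit.

    ``ens`` must hold replicate *velocity curves* on the same grid as
    ``curve`` (statistic ``velocity_curve``); when omitted, confidence
    intervals and significance flags are left unset.

    chi2 = sum (v_obs - v_hat)^2 / max(|v_hat|, 1e-6) over the phase's grid
    points — a fixed, documented convention so printed magnitudes are
    comparable across analyses.
    """
    grid = np.asarray(curve.grid, dtype=float)
    v = np.asarray(curve.v, dtype=float)
    if ens is not None:
        if ens.grid is None or ens.replicates.ndim != 2 or not np.array_equal(
            np.asarray(ens.grid), grid
        ):
            raise ValueError(
                "bootstrap ensemble must hold velocity curves on the same grid "
                "as the kinetics curve (statistic='velocity_curve')"
            )
    masks = _phase_masks(grid, seg)
    out: list[PhaseRegression] = []
    for k, mask in enumerate(masks):
        t = grid[mask]
        vv = v[mask]
        beta, beta0 = np.polyfit(t, vv, 1)
        vhat = beta0 + beta * t
        chi2 = float(np.sum((vv - vhat) ** 2 / np.maximum(np.abs(vhat), CHI2_FLOOR)))
        ci0 = ci1 = None
        sig0 = sig1 = None
        if ens is not None:
            A = np.column_stack([np.ones(t.size), t])
            # one least-squares solve for every replicate at once
            coef, *_ = np.linalg.lstsq(A, ens.replicates[:, mask].T, rcond=None)
            b0s, b1s = coef[0], coef[1]
            lo0, hi0 = np.quantile(b0s, [alpha / 2, 1 - alpha / 2])
            lo1, hi1 = np.quantile(b1s, [alpha / 2, 1 - alpha / 2])
            ci0, ci1 = (float(lo0), float(hi0)), (float(lo1), float(hi1))
            sig0 = not (ci0[0] <= 0.0 <= ci0[1])
            sig1 = not (ci1[0] <= 0.0 <= ci1[1])
        out.append(
            PhaseRegression(
                phase_index=k,
                beta0=float(beta0),
                beta=float(beta),
                ci_beta0=ci0,
                ci_beta=ci1,
                significant_beta0=sig0,
                significant_beta=sig1,
                chi2=chi2,
                n_points=int(t.size),
            )
        )
    return out


class PhaseSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around the phase-boundary detector.

    ``fit`` takes a :class:`~germkin.kinetics.KineticsCurves` and exposes
    ``boundaries_``, ``segmentation_`` and ``extrema_``; ``fit_predict``
    returns the phase index of every grid point.
    """

    def __init__(self, threshold_factor: float = 1.2, min_prominence: float = 0.05,
                 tail_exclude: float = 2.0, min_separation: float | None = None):
        self.threshold_factor = threshold_factor
        self.min_prominence = min_prominence
        self.tail_exclude = tail_exclude
        self.min_separation = min_separation

    def fit(self, X: KineticsCurves, y=None):
        seg = detect_phase_boundaries(
            X,
            threshold_factor=self.threshold_factor,
            min_prominence=self.min_prominence,
            tail_exclude=self.tail_exclude,
            min_separation=self.min_separation,
        )
        self.segmentation_ = seg
        self.boundaries_ = seg.boundaries
        self.extrema_ = find_extrema(X, self.min_prominence)
        self.n_phases_ = seg.n_phases
        return self

    def fit_predict(self, X: KineticsCurves, y=None) -> np.ndarray:
        self.fit(X)
        grid = np.asarray(X.grid, dtype=float)
        labels = np.zeros(grid.size, dtype=int)
        for k, (idx, a, b) in enumerate(self.segmentation_.phases):
            last = k == len(self.segmentation_.phases) - 1
            m = (grid >= a) & ((grid <= b) if last else (grid < b))
            labels[m] = idx
        return labels
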