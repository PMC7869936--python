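"""Seeded synthetic cohorts of germinating-diaspore mass curves.

The generator emulates the experimental design behind the whole pipeline:
50 diaspores weighed individually every hour (balance precision 0.0001 g)
from sowing until two hours after embryo protrusion, with germination sensu
stricto unfolding in one to six velocity phases.

Ground truth is specified on the *normalized* mass scale (so the truth lives
in the same units the pipeline estimates) and converted per diaspore by its
initial mass:

* Phase I (imbibition): by default the velocity rises linearly from a small
  initial value to its maximum exactly at the first boundary — the
  morphology observed on real germinating diaspores, whose water-uptake
  velocity peaks one to a few hours after sowing before dropping sharply.
  The peak magnitude is Fick-consistent: v_peak = (M_inf/M0) * 6 * (D/rho^2)
  * exp(-(D/rho^2) pi^2 b1).  With ``imbibition="fick"`` Phase-I masses are
  instead *exactly* the truncated Fick series (monotonically decreasing
  velocity); that mode feeds the diffusion-fit tests.
* Later phases: mass integrates a piecewise-linear velocity
  v(t) = beta0_k + beta_k t, continuous across boundaries by construction
  (integration), plus a small smooth metabolic fluctuation (velocity and
  acceleration of real diaspores "float" between abrupt changes).
* Protrusion: a brief sharp negative velocity pulse inside the final two
  hours, the signature of embryo protrusion.
* Noise: additive Gaussian mass noise, default the balance precision.

Everything is deterministic given (seed, index); ``random_ground_truth``
draws a full truth (phase count, boundaries, velocity anchors) from one
seed so recovery studies can sweep hundreds of cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .data_io import MassSeries, SampleSet
from .diffusion import fick_mass
from .kinetics import KineticsCurves
from .phases import PhaseSegmentation

__all__ = [
    "SyntheticGroundTruth",
    "generate_diaspore_series",
    "generate_cohort",
    "random_ground_truth",
    "true_velocity",
    "true_kinetics_curves",
    "true_segmentation",
    "write_truth",
    "read_truth",
    "PRESETS",
]

_PI2 = np.pi**2


def _fick0_frac(n_terms: int) -> float:
    """Fraction M(0)/M_inf of the truncated series (0.3921 for one term)."""
    k = np.arange(1, n_terms + 1, dtype=float)
    return 1.0 - (6.0 / _PI2) * float(np.sum(1.0 / k**2))


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Complete, JSON-serialisable truth for one synthetic cohort.

    Velocity phase lines (``betas``, one ``(beta0, beta)`` pair per phase)
    are on normalized mass, units 1/h and 1/h^2.  ``m_inf`` defaults to
    ``m0_mean`` divided by the Fick series' t=0 fraction so the generated
    initial mass matches ``m0_mean``.
    """

    seed: int = 0
    n_diaspores: int = 50
    m0_mean: float = 0.2
    m0_cv: float = 0.05
    d_over_rho2: float = 2.0e-3
    n_terms: int = 1
    m_inf: float | None = None
    phase_boundaries: tuple[float, ...] = (2.0, 7.0, 12.0)
    t_end: float = 16.0
    betas: tuple[tuple[float, float], ...] | None = None
    imbibition: str = "linear"
    noise_sd: float = 1.0e-4
    protrusion_time: float | None = None
    record_interval: float = 1.0
    fluctuation_amplitude: float = 0.0008
    fluctuation_period: float = 2.0
    ripple_amplitude: float = 0.0
    spike_amplitude: float = 0.03
    spike_width: float = 0.2

    def __post_init__(self):
        bounds = tuple(float(b) for b in self.phase_boundaries)
        if any(np.diff(bounds) <= 0):
            raise ValueError("phase boundaries must be strictly increasing")
        if bounds and not (0.0 < bounds[0] and bounds[-1] < self.t_end):
            raise ValueError("phase boundaries must lie inside (0, t_end)")
        n_phases = len(bounds) + 1
        if not (1 <= n_phases <= 6):
            raise ValueError("phase count must lie in [1, 6]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.record_interval <= 0:
            raise ValueError("record_interval must be > 0")
        if self.imbibition not in ("linear", "fick"):
            raise ValueError("imbibition must be 'linear' or 'fick'")
        object.__setattr__(self, "phase_boundaries", bounds)
        if self.m_inf is None:
            object.__setattr__(
                self, "m_inf", self.m0_mean / _fick0_frac(self.n_terms)
            )
        if self.protrusion_time is None:
            object.__setattr__(self, "protrusion_time", self.t_end - 2.0)
        if not (0.0 <= self.protrusion_time <= self.t_end):
            raise ValueError("protrusion_time must lie within [0, t_end]")
        if self.betas is None:
            object.__setattr__(self, "betas", self._default_betas())
        else:
            bb = tuple((float(b0), float(b1)) for b0, b1 in self.betas)
            if len(bb) != n_phases:
                raise ValueError(
                    f"betas must give one (beta0, beta) pair per phase "
                    f"({n_phases} phases, got {len(bb)})"
                )
            object.__setattr__(self, "betas", bb)

    # -- derived quantities -------------------------------------------------

    @property
    def n_phases(self) -> int:
        return len(self.phase_boundaries) + 1

    @property
    def m_inf_normalized(self) -> float:
        return self.m_inf / self.m0_mean

    @property
    def v_peak(self) -> float:
        """Fick-consistent normalized velocity magnitude at the Phase-I end."""
        b1 = self.phase_boundaries[0] if self.phase_boundaries else self.t_end
        return (
            self.m_inf_normalized
            * 6.0
            * self.d_over_rho2
            * float(np.exp(-self.d_over_rho2 * _PI2 * b1))
        )

    @property
    def edges(self) -> tuple[float, ...]:
        return (0.0, *self.phase_boundaries, self.t_end)

    def _default_betas(self) -> tuple[tuple[float, float], ...]:
        """Canonical anchors: rise to the peak, then alternating valleys/peaks."""
        vp = self.v_peak
        edges = self.edges
        fr = [0.2, 1.0]
        for k in range(2, len(edges) - 1):
            fr.append(0.1 if k % 2 == 0 else 0.5)
        fr.append(0.15 if (len(edges) - 1) % 2 == 0 else 0.45)
        anchors = [f * vp for f in fr]
        return _betas_from_anchors(edges, anchors)


def _betas_from_anchors(edges, anchors) -> tuple[tuple[float, float], ...]:
    """Phase lines (beta0, beta) through consecutive (edge, velocity) anchors."""
    out = []
    for k in range(len(edges) - 1):
        t0, t1 = edges[k], edges[k + 1]
        v0, v1 = anchors[k], anchors[k + 1]
        beta = (v1 - v0) / (t1 - t0)
        out.append((v0 - beta * t0, beta))
    return tuple(out)


# ---------------------------------------------------------------------------
# truth curves
# ---------------------------------------------------------------------------


def _base_velocity(gt: SyntheticGroundTruth, t: np.ndarray) -> np.ndarray:
    """Piecewise phase velocity without fluctuation or protrusion spike."""
    t = np.asarray(t, dtype=float)
    v = np.empty_like(t)
    edges = gt.edges
    for k, (b0, b1) in enumerate(gt.betas):
        lo, hi = edges[k], edges[k + 1]
        mask = (t >= lo) & (t <= hi) if k == len(gt.betas) - 1 else (t >= lo) & (t < hi)
        v[mask] = b0 + b1 * t[mask]
    if gt.imbibition == "fick" and gt.phase_boundaries:
        b = gt.phase_boundaries[0]
        mask = t < b
        kk = np.arange(1, gt.n_terms + 1, dtype=float)
        expo = np.exp(-gt.d_over_rho2 * _PI2 * np.multiply.outer(t[mask], kk**2))
        v[mask] = gt.m_inf_normalized * 6.0 * gt.d_over_rho2 * expo.sum(axis=-1)
    return v


def _fluct_velocity(gt: SyntheticGroundTruth, t: np.ndarray) -> np.ndarray:
    if gt.fluctuation_amplitude == 0 or not gt.phase_boundaries:
        return np.zeros_like(t)
    b1 = gt.phase_boundaries[0]
    w = np.zeros_like(t)
    mask = t > b1
    w[mask] = gt.fluctuation_amplitude * np.sin(
        2.0 * np.pi * (t[mask] - b1) / gt.fluctuation_period
    )
    return w


def _ripple_ramp(gt, t):
    """Smooth 2-h onset of the recording-cadence ripple after Phase I."""
    b1 = gt.phase_boundaries[0]
    return np.clip((t - b1) / 2.0, 0.0, 1.0)


def _ripple_mass(gt: SyntheticGroundTruth, t: np.ndarray) -> np.ndarray:
    """Knot-scale mass ripple: the hourly weighing/re-watering cycle leaves a
    small alternating-sign mass artifact at successive records."""
    if gt.ripple_amplitude == 0 or not gt.phase_boundaries:
        return np.zeros_like(t)
    b1 = gt.phase_boundaries[0]
    ph = np.pi * (t - b1) / gt.record_interval
    return gt.ripple_amplitude * np.cos(ph) * _ripple_ramp(gt, t)


def _ripple_velocity(gt: SyntheticGroundTruth, t: np.ndarray) -> np.ndarray:
    if gt.ripple_amplitude == 0 or not gt.phase_boundaries:
        return np.zeros_like(t)
    b1 = gt.phase_boundaries[0]
    dt = gt.record_interval
    ph = np.pi * (t - b1) / dt
    ramp = _ripple_ramp(gt, t)
    dramp = np.where((t > b1) & (t < b1 + 2.0), 0.5, 0.0)
    return gt.ripple_amplitude * (
        -(np.pi / dt) * np.sin(ph) * ramp + np.cos(ph) * dramp
    )


def _spike_velocity(gt: SyntheticGroundTruth, t: np.ndarray) -> np.ndarray:
    if gt.spike_amplitude == 0:
        return np.zeros_like(t)
    tc = gt.protrusion_time + 1.6
    return -gt.spike_amplitude * np.exp(-(((t - tc) / gt.spike_width) ** 2))


def true_velocity(gt: SyntheticGroundTruth, t) -> np.ndarray:
    """Ground-truth normalized velocity v(t) = dm/dt, all components."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return (
        _base_velocity(gt, t)
        + _fluct_velocity(gt, t)
        + _ripple_velocity(gt, t)
        + _spike_velocity(gt, t)
    )


def _true_mass_normalized(gt: SyntheticGroundTruth, t: np.ndarray) -> np.ndarray:
    """m(t) = 1 + int_0^t v, by exact piecewise closed forms."""
    t = np.asarray(t, dtype=float)
    edges = gt.edges
    m = np.empty_like(t)

    def seg_integral(k: int, lo: float, up):
        """Integral of the phase-k base line from lo to up (array-friendly)."""
        b0, b1 = gt.betas[k]
        up = np.asarray(up, dtype=float)
        return b0 * (up - lo) + 0.5 * b1 * (up**2 - lo**2)

    # cumulative mass at the phase edges
    edge_m = [1.0]
    if gt.imbibition == "fick" and gt.phase_boundaries:
        frac0 = _fick0_frac(gt.n_terms)
        k1 = np.arange(1, gt.n_terms + 1, dtype=float)

        def fick_norm(tt):
            tt = np.asarray(tt, dtype=float)
            expo = np.exp(-gt.d_over_rho2 * _PI2 * np.multiply.outer(tt, k1**2))
            series = (expo / k1**2).sum(axis=-1)
            return gt.m_inf_normalized * (1.0 - (6.0 / _PI2) * series) - (
                gt.m_inf_normalized * frac0 - 1.0
            )

        edge_m.append(float(fick_norm(gt.phase_boundaries[0])))
        phase1_mass = fick_norm
    else:
        edge_m.append(1.0 + float(seg_integral(0, 0.0, edges[1])))

        def phase1_mass(tt):
            return 1.0 + seg_integral(0, 0.0, tt)

    for k in range(1, len(gt.betas)):
        edge_m.append(edge_m[-1] + float(seg_integral(k, edges[k], edges[k + 1])))

    for k in range(len(gt.betas)):
        lo, hi = edges[k], edges[k + 1]
        last = k == len(gt.betas) - 1
        mask = (t >= lo) & (t <= hi) if last else (t >= lo) & (t < hi)
        if k == 0:
            m[mask] = phase1_mass(t[mask])
        else:
            m[mask] = edge_m[k] + seg_integral(k, lo, t[mask])

    # fluctuation integral: A*P/(2*pi) * (1 - cos(2*pi*(t-b1)/P)) for t > b1
    if gt.fluctuation_amplitude != 0 and gt.phase_boundaries:
        b1 = gt.phase_boundaries[0]
        mask = t > b1
        P = gt.fluctuation_period
        m[mask] += (
            gt.fluctuation_amplitude * P / (2.0 * np.pi)
            * (1.0 - np.cos(2.0 * np.pi * (t[mask] - b1) / P))
        )
    m += _ripple_mass(gt, t)
    # spike integral (Gaussian pulse antiderivative)
    if gt.spike_amplitude != 0:
        tc = gt.protrusion_time + 1.6
        w = gt.spike_width
        m += (
            -gt.spike_amplitude * w * np.sqrt(np.pi) / 2.0
            * (erf((t - tc) / w) - erf((0.0 - tc) / w))
        )
    return m


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_diaspore_series(gt: SyntheticGroundTruth, index: int) -> MassSeries:
    """One diaspore's mass record; bit-identical under the same (seed, index)."""
    rng = np.random.default_rng((int(gt.seed), int(index)))
    z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    m0 = gt.m0_mean * (1.0 + gt.m0_cv * z)
    times = np.arange(0.0, gt.t_end + 1e-9, gt.record_interval)

    if gt.imbibition == "fick" and gt.phase_boundaries:
        b1 = gt.phase_boundaries[0]
        m_inf_i = m0 * gt.m_inf_normalized
        masses = np.empty_like(times)
        head = times < b1
        masses[head] = fick_mass(times[head], gt.d_over_rho2, m_inf_i, gt.n_terms)
        masses[~head] = m0 * _true_mass_normalized(gt, times[~head])
    else:
        masses = m0 * _true_mass_normalized(gt, times)
    if np.any(masses <= 0):
        raise ValueError(
            "inconsistent phase parameters: noiseless mass becomes non-positive"
        )
    if gt.noise_sd > 0:
        masses = masses + gt.noise_sd * rng.standard_normal(times.size)
        masses = np.maximum(masses, 1e-9)
    return MassSeries(
        diaspore_id=f"d{index:03d}",
        times=times,
        masses=masses,
        protrusion_time=gt.protrusion_time,
    )


def generate_cohort(
    gt: SyntheticGroundTruth, label: str = "synthetic"
) -> tuple[SampleSet, dict]:
    """A full cohort plus a machine-readable ground-truth report."""
    if gt.n_diaspores < 1:
        raise ValueError("n_diaspores must be >= 1")
    series = tuple(
        generate_diaspore_series(gt, i) for i in range(gt.n_diaspores)
    )
    sample = SampleSet(label=label, series=series, species="synthetic",
                       quality_class="unknown")
    report = dataclasses.asdict(gt)
    report["v_peak"] = gt.v_peak
    report["n_phases"] = gt.n_phases
    return sample, report


def true_kinetics_curves(gt: SyntheticGroundTruth, n_grid: int = 481) -> KineticsCurves:
    """Exact truth as a KineticsCurves object (bypassing the spline).

    Used by recovery tests that check the regression machinery against the
    generator's phase lines without interpolation error.
    """
    grid = np.linspace(0.0, gt.t_end, int(n_grid))
    v = true_velocity(gt, grid)
    m = _true_mass_normalized(gt, grid)
    # analytic acceleration of every component
    a = np.empty_like(grid)
    edges = gt.edges
    for k, (_, b1) in enumerate(gt.betas):
        lo, hi = edges[k], edges[k + 1]
        last = k == len(gt.betas) - 1
        mask = (grid >= lo) & ((grid <= hi) if last else (grid < hi))
        a[mask] = b1
    if gt.fluctuation_amplitude != 0 and gt.phase_boundaries:
        b1e = gt.phase_boundaries[0]
        mask = grid > b1e
        P = gt.fluctuation_period
        a[mask] += gt.fluctuation_amplitude * (2 * np.pi / P) * np.cos(
            2 * np.pi * (grid[mask] - b1e) / P
        )
    if gt.ripple_amplitude != 0 and gt.phase_boundaries:
        b1r = gt.phase_boundaries[0]
        dt = gt.record_interval
        ph = np.pi * (grid - b1r) / dt
        ramp = _ripple_ramp(gt, grid)
        dramp = np.where((grid > b1r) & (grid < b1r + 2.0), 0.5, 0.0)
        a += gt.ripple_amplitude * (
            -((np.pi / dt) ** 2) * np.cos(ph) * ramp
            - 2.0 * (np.pi / dt) * np.sin(ph) * dramp
        )
    if gt.spike_amplitude != 0:
        tc = gt.protrusion_time + 1.6
        w = gt.spike_width
        a += (
            gt.spike_amplitude * 2.0 * (grid - tc) / w**2
            * np.exp(-(((grid - tc) / w) ** 2))
        )
    tau = float(grid[-1])
    return KineticsCurves(
        grid=grid, m=m, v=v, a=a,
        v_mean=float((m[-1] - m[0]) / tau),
        a_mean=float((v[-1] - v[0]) / tau),
        tau=tau,
    )


def true_segmentation(gt: SyntheticGroundTruth) -> PhaseSegmentation:
    edges = gt.edges
    phases = tuple(
        (k, float(edges[k]), float(edges[k + 1])) for k in range(len(edges) - 1)
    )
    return PhaseSegmentation(
        boundaries=np.asarray(gt.phase_boundaries, dtype=float),
        phases=phases,
        threshold_factor=1.2,
    )


def random_ground_truth(
    seed: int,
    n_phases: int | None = None,
    n_diaspores: int = 50,
    noise_sd: float = 1.0e-4,
    imbibition: str = "linear",
    d_over_rho2: float | None = None,
    m0_mean: float = 0.2,
) -> SyntheticGroundTruth:
    """Draw a full cohort truth with 3-6 pronounced velocity phases.

    Boundaries sit on the hourly grid; boundary velocity anchors alternate
    between high peaks and low valleys so every true boundary is an abrupt
    velocity change well separated from the background fluctuation, as on
    real velocity curves.
    """
    rng = np.random.default_rng(seed)
    K = int(n_phases) if n_phases is not None else int(rng.integers(3, 7))
    if not (2 <= K <= 6):
        raise ValueError("n_phases must lie in [2, 6]")
    b1 = float(rng.integers(2, 4))
    bounds = [b1]
    for _ in range(K - 2):
        bounds.append(bounds[-1] + float(rng.integers(3, 6)))
    t_end = bounds[-1] + float(rng.integers(4, 6))
    d = 10.0 ** rng.uniform(-3.0, -2.1) if d_over_rho2 is None else float(d_over_rho2)

    # Fick-consistent peak magnitude at the Phase-I boundary
    m_inf_n = 1.0 / _fick0_frac(1)
    vp = m_inf_n * 6.0 * d * float(np.exp(-d * _PI2 * b1))

    anchors = [float(rng.uniform(0.10, 0.30)) * vp, vp]
    for k in range(2, K):
        if k % 2 == 0:  # valley
            anchors.append(float(rng.uniform(0.04, 0.08)) * vp)
        else:  # peak
            anchors.append(float(rng.uniform(0.55, 0.65)) * vp)
    # endpoint anchor continues the alternation without being an extremum
    if K % 2 == 0:
        anchors.append(float(rng.uniform(0.04, 0.10)) * vp)
    else:
        anchors.append(float(rng.uniform(0.45, 0.55)) * vp)

    edges = (0.0, *bounds, t_end)
    betas = _betas_from_anchors(edges, anchors)
    return SyntheticGroundTruth(
        seed=int(seed),
        n_diaspores=n_diaspores,
        m0_mean=float(m0_mean),
        d_over_rho2=float(d),
        phase_boundaries=tuple(bounds),
        t_end=float(t_end),
        betas=betas,
        imbibition=imbibition,
        noise_sd=noise_sd,
        fluctuation_amplitude=float(rng.uniform(0.02, 0.03)) * vp,
        fluctuation_period=float(rng.uniform(2.5, 3.5)),
        ripple_amplitude=float(rng.uniform(0.010, 0.015)) * vp,
        spike_amplitude=float(rng.uniform(0.18, 0.25)) * vp,
        spike_width=0.2,
    )


# ---------------------------------------------------------------------------
# truth serialisation and presets
# ---------------------------------------------------------------------------


def write_truth(gt: SyntheticGroundTruth, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(gt), fh, indent=2)


def read_truth(path: str | os.PathLike) -> SyntheticGroundTruth:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    d["phase_boundaries"] = tuple(d["phase_boundaries"])
    if d.get("betas") is not None:
        d["betas"] = tuple(tuple(b) for b in d["betas"])
    return SyntheticGroundTruth(**d)


def _flat_preset(seed: int) -> SyntheticGroundTruth:
    return SyntheticGroundTruth(
        seed=seed,
        phase_boundaries=(),
        t_end=12.0,
        betas=((0.0, 0.0),),
        noise_sd=1.0e-4,
        fluctuation_amplitude=0.0,
        spike_amplitude=0.0,
    )


PRESETS = {
    # slow imbibition, high later metabolism (oilseed-like)
    "soybean-like": lambda seed: random_ground_truth(
        seed, n_phases=4, d_over_rho2=1.6e-3, m0_mean=0.15
    ),
    # fast imbibition, shallow later metabolism (starchy caryopsis-like)
    "maize-like": lambda seed: random_ground_truth(
        seed, n_phases=5, d_over_rho2=8.5e-3, m0_mean=0.30
    ),
    # no dynamics at all: degenerate paths
    "flat": _flat_preset,
}
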