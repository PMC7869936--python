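"""Reading, validation and writing of diaspore mass-recording tables.

The raw observable of the whole pipeline is the mass of a single diaspore
(seed, caryopsis or cypsela) recorded at successive times after sowing, in
grams, on a fixed time grid in hours.  A cohort of diaspores weighed on the
same grid forms a :class:`SampleSet`.  Normalisation divides each record by
the diaspore's initial mass, giving the dimensionless "weighted mass"
``m(t) = M(t)/M0`` with ``m(0) = 1``; all kinetic quantities downstream are
derivatives of ``m``.

Notes on units and conventions:

* time is always hours, mass always grams; readers never auto-convert.
* ``M0`` is the first recorded mass.  Diaspores are assumed standardised to
  their pre-imbibition moisture before t = 0, so "initial (dry) mass" means
  pre-imbibition mass, not oven-dry mass.
* the long CSV format (``diaspore_id,time_h,mass_g[,protrusion_h]``) is
  canonical; the wide format (one ``time_h`` column plus one column per
  diaspore) is supported read-only.
* missing values are rejected: the spline/bootstrap machinery needs a
  complete shared grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "MassSeries",
    "NormalizedMassSeries",
    "SampleSet",
    "normalize_series",
    "read_mass_table",
    "write_mass_table",
    "write_normalized_mass",
    "write_kinetics",
    "write_fick_fits",
    "write_phases",
    "write_ci_bands",
]

QUALITY_CLASSES = ("low", "intermediate", "high", "unknown")


class ValidationError(ValueError):
    """Raised when an input table or series violates the data contract."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains missing or non-finite values")
    return arr


@dataclass(frozen=True, eq=False)
class MassSeries:
    """One diaspore's (time, mass) record.

    Attributes
    ----------
    diaspore_id : str
        Identifier of the individual diaspore.
    times : ndarray
        Recording times in hours, strictly increasing.
    masses : ndarray
        Total mass ``M(t)`` in grams, all positive.
    protrusion_time : float, optional
        Time of visible embryo protrusion (h); must lie inside the
        recording window when present.
    """

    diaspore_id: str
    times: np.ndarray
    masses: np.ndarray
    protrusion_time: float | None = None

    def __post_init__(self):
        times = _as_float_array(self.times, f"diaspore '{self.diaspore_id}': times")
        masses = _as_float_array(self.masses, f"diaspore '{self.diaspore_id}': masses")
        if times.size != masses.size:
            raise ValidationError(
                f"diaspore '{self.diaspore_id}': times and masses differ in length"
            )
        if times.size == 0:
            raise ValidationError(f"diaspore '{self.diaspore_id}': empty series")
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"diaspore '{self.diaspore_id}': times must be strictly increasing "
                "(duplicated or out-of-order recording time)"
            )
        if np.any(masses <= 0):
            raise ValidationError(
                f"diaspore '{self.diaspore_id}': non-positive mass recorded"
            )
        if self.protrusion_time is not None:
            pt = float(self.protrusion_time)
            if not (times[0] <= pt <= times[-1]):
                raise ValidationError(
                    f"diaspore '{self.diaspore_id}': protrusion time {pt} outside "
                    f"recording window [{times[0]}, {times[-1]}]"
                )
            object.__setattr__(self, "protrusion_time", pt)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "masses", masses)

    @property
    def M0(self) -> float:
        """Initial (pre-imbibition) mass in grams: the first recorded mass."""
        return float(self.masses[0])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True, eq=False)
class NormalizedMassSeries:
    """Dimensionless weighted mass ``m(t) = M(t)/M0`` with ``m[0] == 1``."""

    diaspore_id: str
    times: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        times = _as_float_array(self.times, f"diaspore '{self.diaspore_id}': times")
        m = _as_float_array(self.m, f"diaspore '{self.diaspore_id}': m")
        if times.size != m.size:
            raise ValidationError(
                f"diaspore '{self.diaspore_id}': times and m differ in length"
            )
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"diaspore '{self.diaspore_id}': times must be strictly increasing"
            )
        if np.any(m <= 0):
            raise ValidationError(
                f"diaspore '{self.diaspore_id}': normalized mass must stay positive"
            )
        if m[0] != 1.0:
            raise ValidationError(
                f"diaspore '{self.diaspore_id}': normalized mass must start at 1 "
                f"(got {m[0]!r})"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "m", m)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True, eq=False)
class SampleSet:
    """A cohort of diaspores weighed on one shared time grid.

    The shared grid is required by the curve-wise bootstrap: resampling
    whole diaspores only produces comparable replicate curves when every
    series is tabulated at identical times.
    """

    label: str
    series: tuple[MassSeries, ...]
    species: str = ""
    quality_class: str = "unknown"

    def __post_init__(self):
        series = tuple(self.series)
        if not series:
            raise ValidationError(f"sample '{self.label}': no diaspore series")
        if self.quality_class not in QUALITY_CLASSES:
            raise ValidationError(
                f"sample '{self.label}': quality_class must be one of {QUALITY_CLASSES}"
            )
        grid = series[0].times
        for s in series[1:]:
            if s.times.size != grid.size or not np.array_equal(s.times, grid):
                raise ValidationError(
                    f"sample '{self.label}': diaspore '{s.diaspore_id}' is on a "
                    "different time grid; ragged grids are not supported — analyse "
                    "such diaspores one series at a time (per-series mode)"
                )
        object.__setattr__(self, "series", series)

    @property
    def time_grid(self) -> np.ndarray:
        return self.series[0].times

    @property
    def n_diaspores(self) -> int:
        return len(self.series)

    def mass_matrix(self) -> np.ndarray:
        """(n_diaspores, n_times) matrix of raw masses in grams."""
        return np.vstack([s.masses for s in self.series])

    def normalized_matrix(self) -> np.ndarray:
        """(n_diaspores, n_times) matrix of weighted mass ``m(t)``."""
        return np.vstack([s.masses / s.M0 for s in self.series])

    def normalized(self) -> tuple[NormalizedMassSeries, ...]:
        return tuple(normalize_series(s) for s in self.series)

    def mean_normalized(self) -> NormalizedMassSeries:
        """Pointwise cohort mean of the weighted mass (still ``m[0] = 1``)."""
        m = self.normalized_matrix().mean(axis=0)
        return NormalizedMassSeries(
            diaspore_id=f"{self.label}:mean", times=self.time_grid, m=m
        )


def normalize_series(s: MassSeries) -> NormalizedMassSeries:
    """Weighted (normalized) mass: divide every record by the initial mass.

    ``m[0]`` is exactly 1 in floating point (x/x == 1 for finite positive x).
    Scale-invariant: multiplying all masses by a positive constant leaves
    the result unchanged.
    """
    if s.M0 <= 0:
        raise ValidationError(
            f"diaspore '{s.diaspore_id}': cannot normalize, initial mass <= 0"
        )
    return NormalizedMassSeries(
        diaspore_id=s.diaspore_id, times=s.times, m=s.masses / s.M0
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ("diaspore_id", "time_h", "mass_g")


def read_mass_table(
    path: str | os.PathLike,
    format: str = "long",
    label: str | None = None,
    species: str = "",
    quality_class: str = "unknown",
) -> SampleSet:
    """Read a mass-recording CSV into a validated :class:`SampleSet`.

    Parameters
    ----------
    path : path
        CSV file, UTF-8, "." decimal separator.
    format : {"long", "wide"}
        Long: columns ``diaspore_id, time_h, mass_g`` and optional
        ``protrusion_h``.  Wide: a ``time_h`` column plus one mass column
        per diaspore (read-only convenience, no protrusion support).
    """
    if format not in ("long", "wide"):
        raise ValueError(f"format must be 'long' or 'wide', got {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if label is None:
        label = os.path.splitext(os.path.basename(os.fspath(path)))[0]

    series: list[MassSeries] = []
    if format == "long":
        missing = [c for c in _LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"long-format table lacks columns: {missing}")
        if df[list(_LONG_COLUMNS)].isna().any().any():
            raise ValidationError("table contains missing values; imputation is not supported")
        has_prot = "protrusion_h" in df.columns
        # row order is immaterial: sort within each diaspore by time
        for did, grp in df.groupby("diaspore_id", sort=True):
            grp = grp.sort_values("time_h")
            prot = None
            if has_prot:
                pvals = grp["protrusion_h"].dropna().unique()
                if pvals.size > 1:
                    raise ValidationError(
                        f"diaspore '{did}': inconsistent protrusion_h values"
                    )
                if pvals.size == 1:
                    prot = float(pvals[0])
            series.append(
                MassSeries(
                    diaspore_id=str(did),
                    times=grp["time_h"].to_numpy(float),
                    masses=grp["mass_g"].to_numpy(float),
                    protrusion_time=prot,
                )
            )
    else:  # wide
        if "time_h" not in df.columns:
            raise ValidationError("wide-format table needs a 'time_h' column")
        if df.isna().any().any():
            raise ValidationError("table contains missing values; imputation is not supported")
        times = df["time_h"].to_numpy(float)
        for col in df.columns:
            if col == "time_h":
                continue
            series.append(
                MassSeries(diaspore_id=str(col), times=times,
                           masses=df[col].to_numpy(float))
            )
    return SampleSet(label=label, series=tuple(series), species=species,
                     quality_class=quality_class)


def write_mass_table(sample: SampleSet, path: str | os.PathLike) -> None:
    """Write a SampleSet as the canonical long-format CSV (full precision)."""
    rows = []
    for s in sample.series:
        for t, M in zip(s.times, s.masses):
            row = {"diaspore_id": s.diaspore_id, "time_h": t, "mass_g": M}
            if s.protrusion_time is not None:
                row["protrusion_h"] = s.protrusion_time
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_normalized_mass(sample: SampleSet, path: str | os.PathLike) -> None:
    rows = []
    for s in sample.normalized():
        for t, m in zip(s.times, s.m):
            rows.append({"diaspore_id": s.diaspore_id, "time_h": t, "m": m})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_kinetics(curves, path: str | os.PathLike) -> None:
    """Write a KineticsCurves object (t, v, a columns) to CSV."""
    pd.DataFrame({"t": curves.grid, "v": curves.v, "a": curves.a}).to_csv(
        path, index=False, float_format="%.10g"
    )


def write_fick_fits(fits, path: str | os.PathLike) -> None:
    """Write an iterable of (diaspore_id, FickFit) pairs to CSV."""
    rows = [
        {
            "diaspore_id": did,
            "D_over_rho2": f.d_over_rho2,
            "M_inf": f.m_inf,
            "n_terms": f.n_terms,
            "window_end_h": f.window_end,
            "sse": f.sse,
            "converged": f.converged,
        }
        for did, f in fits
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_phases(regressions, segmentation, path: str | os.PathLike) -> None:
    """Write per-phase regression results shaped like the printed phase tables."""
    rows = []
    for reg in regressions:
        idx, t0, t1 = segmentation.phases[reg.phase_index]
        rows.append(
            {
                "phase": idx + 1,
                "t_start": t0,
                "t_end": t1,
                "beta0": reg.beta0,
                "beta": reg.beta,
                "beta0_lo": reg.ci_beta0[0] if reg.ci_beta0 else np.nan,
                "beta0_hi": reg.ci_beta0[1] if reg.ci_beta0 else np.nan,
                "beta_lo": reg.ci_beta[0] if reg.ci_beta else np.nan,
                "beta_hi": reg.ci_beta[1] if reg.ci_beta else np.nan,
                "chi2": reg.chi2,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_ci_bands(band, ens, grid, path: str | os.PathLike) -> None:
    """Write a pointwise confidence band with its bootstrap provenance."""
    lower = np.atleast_1d(band.lower)
    upper = np.atleast_1d(band.upper)
    point = np.atleast_1d(band.point_estimate)
    grid = np.atleast_1d(grid)
    pd.DataFrame(
        {
            "grid": grid,
            "mean": point,
            "lower": lower,
            "upper": upper,
            "statistic_kind": ens.statistic_kind,
            "B": ens.B,
            "seed": ens.seed,
            "alpha": band.alpha,
        }
    ).to_csv(path, index=False, float_format="%.10g")
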