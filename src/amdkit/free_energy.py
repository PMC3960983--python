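"""Potential-of-mean-force estimation and energetic reweighting.

A PMF (free-energy profile) over a reaction coordinate ξ is estimated from a
frame series as F_i = −k_BT·ln P_i, with P_i the (optionally weighted)
fraction of frames in bin i and the minimum over defined bins shifted to
zero.  Empty bins are left undefined (NaN), never clipped to a cap.

Binning conventions
-------------------
* Distance-like coordinates: uniform bins anchored at coordinate 0, so
  profiles at different bin sizes share an origin.
* Periodic coordinates (dihedrals): bins tile exactly one period on
  (−180°, 180°]; bin sizes that do not divide the period are rejected.
  3, 5, 6, 9, 10, 12 and 15° all divide 360°.

Reweighting
-----------
Boosted-ensemble frames are reweighted to the canonical ensemble by the
Boltzmann factor of the boost, w_i ∝ e^{ΔV_i/k_BT} (computed with
max-shifted exponentials for overflow safety), or approximately through a
cumulant expansion of the log-average per bin:

    F_i(rw) = F_i − [⟨ΔV⟩_i + (β/2)·Var(ΔV)_i·1{order=2}]

The order-2 form is exact for Gaussian per-bin ΔV; for broad or heavy-tailed
boost distributions the two estimators diverge, which is the known noise
failure mode of exponential reweighting at large system size.

The multi-bin-size precision sweep re-estimates the profile at several bin
sizes and reports the maximum pairwise deviation on well-sampled common
support: poorly sampled series show large variations across bin sizes,
converged ones do not.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .amd_core import ThermodynamicState
from .errors import (
    ComparisonError,
    InputError,
    NumericalError,
    ParameterError,
)
from .geometry_rc import RCSeries, wrap_periodic

__all__ = [
    "PMFProfile",
    "WeightSeries",
    "SweepReport",
    "exponential_weights",
    "pmf_1d",
    "pmf_2d",
    "bin_size_sweep",
    "cumulant_reweight",
    "compare_profiles",
    "group_delta_v_by_bin",
    "reweight_series",
    "find_minima",
    "DISTANCE_BIN_SIZES",
    "DIHEDRAL_BIN_SIZES",
    "DIHEDRAL_2D_BIN_SIZE",
]

#: Standard five-bin-size precision sweeps: 0.1–0.5 Å for distances and
#: 3–15° for side-chain dihedrals; 2D dihedral surfaces use 6°.
DISTANCE_BIN_SIZES = (0.1, 0.2, 0.3, 0.4, 0.5)
DIHEDRAL_BIN_SIZES = (3.0, 6.0, 9.0, 12.0, 15.0)
DIHEDRAL_2D_BIN_SIZE = 6.0


@dataclass(frozen=True)
class WeightSeries:
    """Per-frame statistical weights, normalised to sum 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise InputError("weights must be a non-empty 1D array")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise InputError("weights must be finite and non-negative")
        total = w.sum()
        if not (total > 0):
            raise InputError("weights must not all be zero")
        object.__setattr__(self, "weights", w / total)

    def __len__(self) -> int:
        return self.weights.size


def exponential_weights(delta_v: np.ndarray, state: ThermodynamicState) -> WeightSeries:
    """Normalised Boltzmann reweighting factors w_i ∝ e^{ΔV_i/k_BT}.

    Uses max-shifted exponentials so arbitrarily large boost energies cannot
    overflow.  Negative ΔV violates the boost-potential non-negativity and is
    rejected.
    """
    dv = np.asarray(delta_v, dtype=float)
    if dv.ndim != 1 or dv.size == 0:
        raise InputError("delta_v must be a non-empty 1D array")
    if not np.all(np.isfinite(dv)):
        raise InputError("delta_v must be finite")
    if np.any(dv < 0):
        raise InputError("delta_v must be non-negative (boost energies)")
    x = state.beta * dv
    w = np.exp(x - x.max())
    return WeightSeries(weights=w)


@dataclass
class PMFProfile:
    """A 1D or 2D free-energy profile in kcal/mol, minimum shifted to zero.

    ``free_energy`` is NaN on empty bins.  For 2D profiles ``bin_edges``,
    ``bin_size`` and ``periodic`` are per-axis tuples and ``free_energy`` /
    ``counts`` are (nx, ny) arrays.
    """

    bin_edges: np.ndarray | tuple
    free_energy: np.ndarray
    counts: np.ndarray
    bin_size: float | tuple
    weighted: bool
    state: ThermodynamicState
    periodic: bool | tuple = False
    metadata: dict = field(default_factory=dict)

    @property
    def is_2d(self) -> bool:
        return isinstance(self.bin_edges, tuple)

    @property
    def centers(self) -> np.ndarray | tuple:
        if self.is_2d:
            ex, ey = self.bin_edges
            return (0.5 * (ex[:-1] + ex[1:]), 0.5 * (ey[:-1] + ey[1:]))
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def defined_at(self, x) -> np.ndarray:
        """Whether each coordinate falls in a defined (occupied) bin."""
        if self.is_2d:
            raise InputError("defined_at supports 1D profiles")
        edges = self.bin_edges
        idx = np.clip(
            np.searchsorted(edges, np.asarray(x, dtype=float), side="right") - 1,
            0, edges.size - 2,
        )
        return self.defined[idx]

    def value_at(self, x) -> np.ndarray:
        """Linear interpolation of the 1D profile between defined bin centers."""
        if self.is_2d:
            raise InputError("value_at supports 1D profiles")
        c = self.centers[self.defined]
        f = self.free_energy[self.defined]
        if c.size == 0:
            raise NumericalError("profile has no defined bins")
        return np.interp(np.asarray(x, dtype=float), c, f)

    def min_location(self):
        """Coordinate(s) of the global free-energy minimum (bin center)."""
        if self.is_2d:
            idx = np.unravel_index(np.nanargmin(self.free_energy), self.free_energy.shape)
            cx, cy = self.centers
            return (float(cx[idx[0]]), float(cy[idx[1]]))
        return float(self.centers[np.nanargmin(self.free_energy)])

    # -- serialisation ------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        if self.is_2d:
            raise InputError("use to_matrix_text for 2D profiles")
        with open(path, "w") as fh:
            fh.write("# amdkit pmf-profile\n")
            fh.write(f"# bin_size: {self.bin_size:.17g}\n")
            fh.write(f"# temperature: {self.state.temperature:.17g}\n")
            fh.write(f"# weighted: {str(self.weighted).lower()}\n")
            fh.write(f"# periodic: {str(bool(self.periodic)).lower()}\n")
            fh.write("# zero_convention: global-defined-minimum\n")
            for key, val in sorted(self.metadata.items()):
                fh.write(f"# meta:{key}: {val}\n")
            fh.write("# columns: bin_center\tfree_energy_kcal_mol\tcount\n")
            centers = self.centers
            for i in range(centers.size):
                f = self.free_energy[i]
                fstr = "nan" if not np.isfinite(f) else f"{f:.17g}"
                c = self.counts[i]
                cstr = "nan" if not np.isfinite(c) else f"{c:.17g}"
                fh.write(f"{centers[i]:.17g}\t{fstr}\t{cstr}\n")

    def to_json(self, path: str | Path | None = None) -> str:
        def arr(a):
            return [None if not np.isfinite(v) else float(v) for v in np.ravel(a)]

        d = {
            "dimensions": 2 if self.is_2d else 1,
            "bin_size": list(self.bin_size) if self.is_2d else self.bin_size,
            "temperature_K": self.state.temperature,
            "boltzmann_constant": self.state.boltzmann_constant,
            "weighted": self.weighted,
            "periodic": list(self.periodic) if self.is_2d else bool(self.periodic),
            "zero_convention": "global-defined-minimum",
            "metadata": {k: str(v) for k, v in self.metadata.items()},
        }
        if self.is_2d:
            d["bin_edges_x"] = list(map(float, self.bin_edges[0]))
            d["bin_edges_y"] = list(map(float, self.bin_edges[1]))
            d["shape"] = list(self.free_energy.shape)
        else:
            d["bin_edges"] = list(map(float, self.bin_edges))
        d["free_energy_kcal_mol"] = arr(self.free_energy)
        d["counts"] = arr(self.counts)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_matrix_text(self, path: str | Path) -> None:
        """Dense 2D matrix with axis headers; rows are x bins, columns y bins."""
        if not self.is_2d:
            raise InputError("to_matrix_text supports 2D profiles")
        cx, cy = self.centers
        with open(path, "w") as fh:
            fh.write("# amdkit pmf-2d free energy (kcal/mol), rows=x columns=y\n")
            fh.write(f"# bin_size: {self.bin_size[0]:.17g} {self.bin_size[1]:.17g}\n")
            fh.write(f"# temperature: {self.state.temperature:.17g}\n")
            fh.write("x\\y\t" + "\t".join(f"{c:.17g}" for c in cy) + "\n")
            for i in range(cx.size):
                row = "\t".join(
                    "nan" if not np.isfinite(v) else f"{v:.17g}"
                    for v in self.free_energy[i]
                )
                fh.write(f"{cx[i]:.17g}\t{row}\n")


def _edges_1d(values: np.ndarray, bin_size: float, periodic: bool, period: float = 360.0):
    if not (bin_size > 0):
        raise ParameterError(f"bin_size must be > 0, got {bin_size}")
    if periodic:
        n = round(period / bin_size)
        if n < 1 or abs(n * bin_size - period) > 1e-9:
            raise ParameterError(
                f"bin_size {bin_size} does not divide the period {period}"
            )
        return -period / 2.0 + bin_size * np.arange(n + 1)
    lo = math.floor(values.min() / bin_size)
    hi = math.ceil(values.max() / bin_size)
    if hi <= lo:
        hi = lo + 1
    return bin_size * np.arange(lo, hi + 1)


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-closed bins with the last bin closed on the right (histogram
    convention); assumes edges cover all values."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def _profile_from_hist(counts, prob, edges, bin_size, state, weighted, periodic, meta):
    with np.errstate(divide="ignore"):
        f = -state.kt * np.log(prob)
    f = np.where(prob > 0, f, np.nan)
    if not np.any(np.isfinite(f)):
        raise NumericalError("no occupied bins; cannot define a profile")
    f = f - np.nanmin(f)
    return PMFProfile(
        bin_edges=edges,
        free_energy=f,
        counts=counts.astype(float),
        bin_size=bin_size,
        weighted=weighted,
        state=state,
        periodic=periodic,
        metadata=meta,
    )


def pmf_1d(
    series: RCSeries,
    bin_size: float,
    state: ThermodynamicState = ThermodynamicState(),
    weights: WeightSeries | None = None,
) -> PMFProfile:
    """Histogram PMF over one reaction coordinate.

    F_i = −k_BT·ln P_i with P_i the (weighted) fraction of frames in bin i;
    empty bins are NaN and the defined minimum is shifted to zero.
    """
    values = np.asarray(series.values, dtype=float)
    if values.size == 0:
        raise InputError("series is empty")
    if series.periodic:
        values = wrap_periodic(values, series.period)
    edges = _edges_1d(values, bin_size, series.periodic, series.period)
    idx = _bin_indices(values, edges)
    counts = np.bincount(idx, minlength=edges.size - 1).astype(float)
    if weights is not None:
        if len(weights) != values.size:
            raise InputError("weights length must match series length")
        # bincount accumulates in frame order, so the weighted mass is
        # reproducible by a naive sequential loop
        prob = np.bincount(idx, weights=weights.weights, minlength=edges.size - 1)
    else:
        prob = counts / values.size
    meta = {"series": series.name, "unit": series.unit}
    return _profile_from_hist(
        counts, prob, edges, float(bin_size), state, weights is not None,
        series.periodic, meta,
    )


def pmf_2d(
    series_x: RCSeries,
    series_y: RCSeries,
    bin_size: float | tuple,
    state: ThermodynamicState = ThermodynamicState(),
    weights: WeightSeries | None = None,
) -> PMFProfile:
    """2D histogram PMF (e.g. over the toggle-switch χ1/χ2 rotamer plane)."""
    vx = np.asarray(series_x.values, dtype=float)
    vy = np.asarray(series_y.values, dtype=float)
    if vx.size != vy.size:
        raise InputError(
            f"series lengths differ: {vx.size} vs {vy.size}"
        )
    if np.isscalar(bin_size):
        bin_size = (float(bin_size), float(bin_size))
    bx, by = (float(b) for b in bin_size)
    if series_x.periodic:
        vx = wrap_periodic(vx, series_x.period)
    if series_y.periodic:
        vy = wrap_periodic(vy, series_y.period)
    ex = _edges_1d(vx, bx, series_x.periodic, series_x.period)
    ey = _edges_1d(vy, by, series_y.periodic, series_y.period)
    counts, _, _ = np.histogram2d(vx, vy, bins=(ex, ey))
    if weights is not None:
        if len(weights) != vx.size:
            raise InputError("weights length must match series length")
        prob, _, _ = np.histogram2d(vx, vy, bins=(ex, ey), weights=weights.weights)
    else:
        prob = counts / vx.size
    meta = {"series_x": series_x.name, "series_y": series_y.name}
    return _profile_from_hist(
        counts, prob, (ex, ey), (bx, by), state, weights is not None,
        (series_x.periodic, series_y.periodic), meta,
    )


@dataclass
class SweepReport:
    """Bin-size precision sweep: one profile per size plus their spread.

    ``max_deviation`` is the maximum pairwise free-energy difference between
    profiles, linearly interpolated at the finest profile's bin centers,
    restricted to well-sampled common support (finest-profile count >=
    ``min_count``) with each profile re-zeroed on that support.
    """

    bin_sizes: tuple
    profiles: list
    max_deviation: float
    min_count: int
    n_eval_points: int

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "bin_sizes": list(self.bin_sizes),
            "max_deviation_kcal_mol": self.max_deviation,
            "min_count": self.min_count,
            "n_eval_points": self.n_eval_points,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def bin_size_sweep(
    series: RCSeries,
    sizes: Sequence[float],
    state: ThermodynamicState = ThermodynamicState(),
    weights: WeightSeries | None = None,
    min_count: int | None = None,
) -> SweepReport:
    """Estimate PMF precision by re-binning at several bin sizes.

    All profiles share the common bin origin (0 for distances, −period/2 for
    periodic coordinates), so differences reflect sampling precision and
    resolution only.  Converged series show small deviation; undersampled
    series show large deviation.

    ``min_count`` sets the well-sampled threshold on finest-profile bins;
    by default it scales with the series as 0.2% of the frames (at least 1),
    i.e. 200 frames at the 10⁵-frame reference scale.
    """
    sizes = tuple(float(s) for s in sizes)
    if len(sizes) < 2:
        raise ParameterError("bin-size sweep needs at least two sizes")
    if any(s <= 0 for s in sizes):
        raise ParameterError("bin sizes must be positive")
    if min_count is None:
        min_count = max(1, int(round(0.002 * len(series))))
    profiles = [pmf_1d(series, s, state, weights) for s in sizes]
    finest = profiles[int(np.argmin(sizes))]
    pts = finest.centers[finest.defined & (finest.counts >= min_count)]
    # keep points strictly inside every profile's defined-center range so
    # interpolation never extrapolates
    for p in profiles:
        c = p.centers[p.defined]
        pts = pts[(pts >= c.min()) & (pts <= c.max())]
    if pts.size == 0:
        raise NumericalError(
            f"no common well-sampled support at min_count={min_count}; "
            "series too short for this sweep"
        )
    evaluated = []
    for p in profiles:
        v = p.value_at(pts)
        evaluated.append(v - v.min())
    dev = 0.0
    for i in range(len(evaluated)):
        for j in range(i + 1, len(evaluated)):
            dev = max(dev, float(np.max(np.abs(evaluated[i] - evaluated[j]))))
    return SweepReport(
        bin_sizes=sizes,
        profiles=profiles,
        max_deviation=dev,
        min_count=min_count,
        n_eval_points=int(pts.size),
    )


def group_delta_v_by_bin(series: RCSeries, profile: PMFProfile) -> list[np.ndarray]:
    """Per-bin boost-energy samples aligned with a 1D profile's bins."""
    if series.delta_v is None:
        raise InputError("series carries no per-frame delta_v")
    if profile.is_2d:
        raise InputError("group_delta_v_by_bin supports 1D profiles")
    values = np.asarray(series.values, dtype=float)
    if series.periodic:
        values = wrap_periodic(values, series.period)
    edges = profile.bin_edges
    idx = _bin_indices(values, edges)
    return [series.delta_v[idx == i] for i in range(edges.size - 1)]


def cumulant_reweight(
    profile: PMFProfile,
    delta_v_by_bin: Sequence[np.ndarray],
    order: int,
    state: ThermodynamicState | None = None,
) -> PMFProfile:
    """Cumulant-expansion reweighting of an unweighted boosted-run profile.

    F_i(rw) = F_i − [⟨ΔV⟩_i + (β/2)·Var(ΔV)_i·1{order=2}], re-zeroed.  Exact
    for per-bin Gaussian ΔV at order 2.  Defined bins without enough ΔV
    samples (>= 1 for order 1, >= 2 for order 2) are left undefined and
    listed in ``metadata['skipped_bins']``.
    """
    if order not in (1, 2):
        raise ParameterError(
            f"unsupported cumulant order {order}: higher cumulants amplify "
            "noise and are not provided"
        )
    if profile.is_2d:
        raise InputError("cumulant_reweight supports 1D profiles")
    state = state or profile.state
    if len(delta_v_by_bin) != profile.free_energy.size:
        raise InputError("delta_v_by_bin length must match the number of bins")
    f = profile.free_energy.copy()
    skipped: list[int] = []
    need = 1 if order == 1 else 2
    for i in range(f.size):
        if not np.isfinite(f[i]):
            continue
        dv = np.asarray(delta_v_by_bin[i], dtype=float)
        if dv.size < need:
            f[i] = np.nan
            skipped.append(i)
            continue
        corr = float(dv.mean())
        if order == 2:
            corr += 0.5 * state.beta * float(dv.var(ddof=1))
        f[i] -= corr
    if not np.any(np.isfinite(f)):
        raise NumericalError("all bins skipped in cumulant reweighting")
    f = f - np.nanmin(f)
    meta = dict(profile.metadata)
    meta["reweighting"] = f"cumulant-order-{order}"
    if skipped:
        meta["skipped_bins"] = ",".join(map(str, skipped))
    return PMFProfile(
        bin_edges=profile.bin_edges,
        free_energy=f,
        counts=profile.counts.copy(),
        bin_size=profile.bin_size,
        weighted=True,
        state=state,
        periodic=profile.periodic,
        metadata=meta,
    )


def reweight_series(
    series: RCSeries,
    bin_size: float,
    state: ThermodynamicState = ThermodynamicState(),
    method: str = "exponential",
) -> PMFProfile:
    """One-call reweighted PMF from a series carrying per-frame ΔV.

    ``method`` is ``"exponential"`` (Boltzmann-factor weights) or
    ``"cumulant1"`` / ``"cumulant2"`` (cumulant expansion of the per-bin
    log-average).
    """
    if series.delta_v is None:
        raise InputError("reweighting requested but series has no delta_v")
    if method == "exponential":
        w = exponential_weights(series.delta_v, state)
        prof = pmf_1d(series, bin_size, state, weights=w)
        prof.metadata["reweighting"] = "exponential"
        return prof
    if method in ("cumulant1", "cumulant2"):
        base = pmf_1d(series, bin_size, state)
        grouped = group_delta_v_by_bin(series, base)
        return cumulant_reweight(base, grouped, order=int(method[-1]), state=state)
    raise ParameterError(f"unknown reweighting method {method!r}")


def compare_profiles(a: PMFProfile, b: PMFProfile) -> float:
    """Maximum absolute free-energy deviation on common defined support.

    Both profiles are re-zeroed at their minimum over the shared support
    before differencing (profiles are defined only up to an additive
    constant).  Profiles on different grids are compared by linear
    interpolation at the finer profile's bin centers.
    """
    if a.is_2d != b.is_2d:
        raise ComparisonError("cannot compare 1D and 2D profiles")
    if a.is_2d:
        ex_a, ey_a = a.bin_edges
        ex_b, ey_b = b.bin_edges
        if ex_a.shape != ex_b.shape or not (
            np.allclose(ex_a, ex_b) and np.allclose(ey_a, ey_b)
        ):
            raise ComparisonError("2D comparison requires identical bin grids")
        mask = a.defined & b.defined
        if not np.any(mask):
            raise ComparisonError("profiles share no defined bins")
        fa = a.free_energy[mask] - a.free_energy[mask].min()
        fb = b.free_energy[mask] - b.free_energy[mask].min()
        return float(np.max(np.abs(fa - fb)))

    if a.bin_edges.size == b.bin_edges.size and np.allclose(a.bin_edges, b.bin_edges):
        mask = a.defined & b.defined
        if not np.any(mask):
            raise ComparisonError("profiles share no defined bins")
        fa = a.free_energy[mask] - a.free_energy[mask].min()
        fb = b.free_energy[mask] - b.free_energy[mask].min()
        return float(np.max(np.abs(fa - fb)))

    ca = a.centers[a.defined]
    cb = b.centers[b.defined]
    lo = max(ca.min(), cb.min())
    hi = min(ca.max(), cb.max())
    if lo > hi:
        raise ComparisonError("profiles share no overlapping support")
    fine = a if a.bin_size <= b.bin_size else b
    pts = fine.centers[fine.defined]
    pts = pts[(pts >= lo) & (pts <= hi)]
    pts = pts[a.defined_at(pts) & b.defined_at(pts)]
    if pts.size == 0:
        raise ComparisonError("no evaluation points on shared support")
    va = a.value_at(pts)
    vb = b.value_at(pts)
    va = va - va.min()
    vb = vb - vb.min()
    return float(np.max(np.abs(va - vb)))


def find_minima(
    profile: PMFProfile, prominence: float = 0.08, min_count: float = 0
) -> list[float]:
    """Locations (bin centers) of local free-energy minima of a 1D profile.

    Uses peak detection on −F over defined bins with a prominence threshold
    (kcal/mol, several times the per-bin statistical noise) to suppress
    bin-noise minima; ``min_count`` additionally excludes sparsely occupied
    bins.  Returned in coordinate order.
    """
    from scipy.signal import find_peaks

    if profile.is_2d:
        raise InputError("find_minima supports 1D profiles")
    mask = profile.defined
    if min_count > 0:  # counts may be NaN for analytic profiles
        mask = mask & (profile.counts >= min_count)
    c = profile.centers[mask]
    f = profile.free_energy[mask]
    if f.size < 3:
        return [float(c[np.argmin(f)])]
    peaks, _ = find_peaks(-f, prominence=prominence)
    if peaks.size == 0:
        return [float(c[np.argmin(f)])]
    # the global minimum is always a well, even if it sits on the array edge
    gmin = int(np.argmin(f))
    locs = sorted(set(peaks.tolist()) | {gmin})
    return [float(c[i]) for i in locs]


def refine_minimum(
    profile: PMFProfile, near: float, window_bins: int = 3
) -> float:
    """Sub-bin minimum location by a least-squares parabola fit.

    Fits F(x) = a(x−x0)² + c over the defined bins within ``window_bins`` of
    the bin nearest ``near`` and returns the vertex x0, clamped to the fit
    window.  Averaging over the window suppresses the bin-level noise that
    makes a raw argmin wander on flat well bottoms.
    """
    if profile.is_2d:
        raise InputError("refine_minimum supports 1D profiles")
    c = profile.centers[profile.defined]
    f = profile.free_energy[profile.defined]
    if c.size < 3:
        return float(c[np.argmin(f)])
    i0 = int(np.argmin(np.abs(c - near)))
    lo, hi = max(0, i0 - window_bins), min(c.size, i0 + window_bins + 1)
    cs, fs = c[lo:hi], f[lo:hi]
    if cs.size < 3:
        return float(c[i0])
    coef = np.polyfit(cs, fs, 2)
    if coef[0] <= 0:  # not convex in the window; fall back to the bin center
        return float(cs[np.argmin(fs)])
    vertex = -coef[1] / (2.0 * coef[0])
    return float(np.clip(vertex, cs.min(), cs.max()))
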