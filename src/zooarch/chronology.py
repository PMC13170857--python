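"""Radiocarbon calibration, site medians, and chronological grouping.

A radiocarbon determination (a 14C age BP with a 1σ lab error) is mapped
onto the calendar axis through a calibration curve. The posterior over
calendar years t is

    prob(t) ∝ Normal(age_bp; c14_bp(t), sqrt(sigma² + curve_sigma(t)²))

evaluated as integrated probability mass per 1-year bin, truncated where
the density falls below 1e-12 of its maximum and renormalized to sum 1.
Sites are then placed in time by the median of their dates' medians, and
partitioned into chronological groups by exact one-dimensional k-means.

Internal unit is cal BP (years before 1950 CE). A year y cal BCE
corresponds to 1949 + y cal BP; conversion helpers are provided so all
user-facing output can stay in cal BCE/CE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RadiocarbonDate",
    "CalibrationCurve",
    "CalibratedDensity",
    "ChronoGrouping",
    "CurveFormatError",
    "CoverageError",
    "TIME_SLICES",
    "bce_to_bp",
    "bp_to_bce",
    "read_calibration_curve",
    "write_calibration_curve",
    "read_radiocarbon_dates",
    "calibrate_date",
    "density_median",
    "site_median",
    "kmeans_1d",
    "assign_time_slice",
]


class CurveFormatError(ValueError):
    """Calibration-curve file is malformed (e.g., non-monotone grid)."""


class CoverageError(ValueError):
    """A date falls outside the calibration curve's support."""


def bce_to_bp(year_bce: float) -> float:
    """Convert a year in cal BCE to cal BP (1 BCE = 1950 cal BP)."""
    return 1949.0 + year_bce


def bp_to_bce(cal_bp: float) -> float:
    """Convert cal BP to cal BCE (negative results mean CE years)."""
    return cal_bp - 1949.0


@dataclass(frozen=True)
class RadiocarbonDate:
    """One laboratory determination: uncalibrated 14C age ± 1σ."""

    lab_id: str
    site_id: str
    age_bp: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.age_bp > 0:
            raise ValueError("age_bp must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass
class CalibrationCurve:
    """Tabulated curve: calendar grid, 14C age at each point, curve 1σ."""

    cal_bp: np.ndarray
    c14_bp: np.ndarray
    curve_sigma: np.ndarray

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_bp = np.asarray(self.c14_bp, dtype=float)
        self.curve_sigma = np.asarray(self.curve_sigma, dtype=float)
        if not (len(self.cal_bp) == len(self.c14_bp) == len(self.curve_sigma)):
            raise CurveFormatError("curve columns differ in length")
        d = np.diff(self.cal_bp)
        if np.all(d < 0):  # IntCal files run old → young; store ascending
            self.cal_bp = self.cal_bp[::-1]
            self.c14_bp = self.c14_bp[::-1]
            self.curve_sigma = self.curve_sigma[::-1]
        elif not np.all(d > 0):
            raise CurveFormatError("cal_bp grid is not strictly monotone")

    def interp(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (c14_bp, curve_sigma) at calendar ages t."""
        return (
            np.interp(t, self.cal_bp, self.c14_bp),
            np.interp(t, self.cal_bp, self.curve_sigma),
        )


def read_calibration_curve(path: str | Path) -> CalibrationCurve:
    """Read a curve in the standard IntCal tabular layout.

    Comma- or whitespace-separated numeric columns (cal BP, 14C BP, 1σ, …);
    lines starting with '#' are comments. Extra columns are ignored.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append([float(x) for x in parts[:3]])
        except ValueError as exc:
            raise CurveFormatError(f"unparseable curve line: {line!r}") from exc
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")
    arr = np.array(rows)
    if arr.shape[1] < 3:
        raise CurveFormatError("curve needs ≥3 numeric columns (cal BP, 14C BP, sigma)")
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2])


def write_calibration_curve(curve: CalibrationCurve, path: str | Path, header: str = "cal BP, 14C BP, sigma") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for t, c, s in zip(curve.cal_bp[::-1], curve.c14_bp[::-1], curve.curve_sigma[::-1]):
            fh.write(f"{t:.1f},{c:.2f},{s:.2f}\n")


def read_radiocarbon_dates(path: str | Path) -> list[RadiocarbonDate]:
    """Read determinations from CSV with columns lab_id, site_id, age_bp, sigma."""
    df = pd.read_csv(path)
    required = ["lab_id", "site_id", "age_bp", "sigma"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        RadiocarbonDate(str(r.lab_id), str(r.site_id), float(r.age_bp), float(r.sigma))
        for r in df.itertuples()
    ]


@dataclass
class CalibratedDensity:
    """Probability mass over calendar years (1-year bins, cal BP)."""

    cal_grid: np.ndarray  # integer years, ascending cal BP (young → old)
    prob: np.ndarray
    median_cal: float = field(init=False)

    def __post_init__(self) -> None:
        self.cal_grid = np.asarray(self.cal_grid, dtype=float)
        self.prob = np.asarray(self.prob, dtype=float)
        self.median_cal = density_median(self)


def density_median(d: CalibratedDensity | tuple[np.ndarray, np.ndarray]) -> float:
    """Median calendar age: oldest grid year whose old-to-young CDF ≥ 0.5.

    Accumulation runs from the old end of the grid so that a 50/50
    two-point density resolves to the earlier (older) year.
    """
    if isinstance(d, CalibratedDensity):
        grid, prob = d.cal_grid, d.prob
    else:
        grid, prob = np.asarray(d[0], float), np.asarray(d[1], float)
    order = np.argsort(grid)[::-1]  # oldest first
    cdf = np.cumsum(prob[order])
    idx = int(np.searchsorted(cdf, 0.5 - 1e-15))
    return float(grid[order][min(idx, len(grid) - 1)])


_SUBSTEPS = 10  # midpoint sub-quadrature per 1-year bin (0.1-year spacing)


def calibrate_date(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    truncate: float = 1e-12,
) -> CalibratedDensity:
    """Calibrate one determination against a curve.

    Per-year mass is the 0.1-year midpoint-rule integral of the Gaussian
    likelihood with linearly interpolated curve mean and error, truncated
    below ``truncate`` × the peak and renormalized. Grid-extension beyond
    the truncation bounds cannot change the result.
    """
    lo, hi = float(np.ceil(curve.cal_bp.min())), float(np.floor(curve.cal_bp.max()))
    if hi - lo < 1:
        raise CoverageError("curve support shorter than one year")
    grid = np.arange(lo, hi + 1.0)
    fine = grid[:, None] + (np.arange(_SUBSTEPS) + 0.5) / _SUBSTEPS - 0.5
    mu, sg = curve.interp(fine.ravel())
    tot = np.sqrt(date.sigma**2 + sg**2)
    dens = np.exp(-0.5 * ((date.age_bp - mu) / tot) ** 2) / tot
    mass = dens.reshape(len(grid), _SUBSTEPS).mean(axis=1)

    peak = mass.max()
    if peak <= 0 or not np.isfinite(peak):
        raise CoverageError(
            f"date {date.age_bp}±{date.sigma} BP outside curve support "
            f"[{curve.c14_bp.min():.0f}, {curve.c14_bp.max():.0f}] 14C BP"
        )
    # date must genuinely intersect the curve, not just leave float dust
    span = np.abs(date.age_bp - curve.c14_bp) / np.sqrt(date.sigma**2 + curve.curve_sigma**2)
    if span.min() > 8:
        raise CoverageError(f"date {date.age_bp}±{date.sigma} BP beyond 8σ of the curve")

    keep = np.flatnonzero(mass >= truncate * peak)
    sl = slice(keep.min(), keep.max() + 1)
    grid, mass = grid[sl], mass[sl]
    return CalibratedDensity(grid, mass / mass.sum())


def site_median(densities: Sequence[CalibratedDensity]) -> float:
    """Site age: the median of the per-date median calendar ages.

    Deliberately *not* the median of the pooled density — a site occupied
    in two pulses should land between them, weighting each date equally
    regardless of its precision.
    """
    if len(densities) == 0:
        raise ValueError("site_median needs at least one calibrated date")
    meds = sorted(d.median_cal for d in densities)
    n = len(meds)
    mid = n // 2
    return float(meds[mid]) if n % 2 else float((meds[mid - 1] + meds[mid]) / 2)


@dataclass
class ChronoGrouping:
    """Assignment of sites to temporally ordered groups."""

    site_medians: dict[str, float]
    labels: dict[str, int]  # group 0 = oldest
    k: int
    boundaries: list[tuple[float, float]]  # (min, max) age per group
    wcss: float


def kmeans_1d(values: Mapping[str, float] | Sequence[float], k: int, seed: int = 0) -> ChronoGrouping:
    """Optimal 1-D k-means of site ages.

    In one dimension the optimal clustering is contiguous in sorted order,
    so the global optimum is found exactly by dynamic programming over
    contiguous partitions (O(n²k)); the result is deterministic and the
    ``seed`` argument is accepted only for interface symmetry with
    stochastic callers. Groups are relabelled oldest-first (descending age).
    """
    if isinstance(values, Mapping):
        names = list(values)
        x = np.array([values[s] for s in names], dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        names = [str(i) for i in range(len(x))]
    n = len(x)
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of sites n={n}")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    pre = np.concatenate([[0.0], np.cumsum(xs)])
    pre2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(i: int, j: int) -> float:  # [i, j) within-cluster SS
        m = j - i
        if m == 1:
            return 0.0
        s, s2 = pre[j] - pre[i], pre2[j] - pre2[i]
        return max(s2 - s * s / m, 0.0)

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            for i in range(g - 1, j):
                c = cost[g - 1, i] + seg_cost(i, j)
                if c < cost[g, j] - 1e-12:
                    cost[g, j], back[g, j] = c, i
    cuts = [n]
    for g in range(k, 0, -1):
        cuts.append(back[g, cuts[-1]])
    cuts = cuts[::-1]  # ascending segment boundaries

    sorted_labels = np.empty(n, dtype=int)
    seg_ranges = []
    for g in range(k):
        lo_i, hi_i = cuts[g], cuts[g + 1]
        sorted_labels[lo_i:hi_i] = g
        seg_ranges.append((float(xs[lo_i]), float(xs[hi_i - 1])))
    # ascending value order = youngest first; relabel oldest-first
    remap = {g: k - 1 - g for g in range(k)}
    labels_arr = np.empty(n, dtype=int)
    labels_arr[order] = [remap[g] for g in sorted_labels]
    boundaries = [seg_ranges[k - 1 - g] for g in range(k)]

    return ChronoGrouping(
        site_medians={s: float(v) for s, v in zip(names, x)},
        labels={s: int(l) for s, l in zip(names, labels_arr)},
        k=k,
        boundaries=boundaries,
        wcss=float(cost[k, n]),
    )


#: Named chronological slices in cal BCE, oldest first. Each slice owns its
#: younger boundary: an age on the shared bound goes to the *later* slice.
TIME_SLICES: tuple[tuple[str, float, float], ...] = (
    ("Early Neolithic", 4500.0, 3500.0),
    ("Middle Neolithic", 3500.0, 2800.0),
    ("Late Neolithic", 2800.0, 1800.0),
    ("Bronze Age", 1800.0, 800.0),
)


def assign_time_slice(
    median_bce: float,
    slices: Sequence[tuple[str, float, float]] = TIME_SLICES,
) -> str:
    """Map a median age in cal BCE to its named slice, or "outside".

    Slices are half-open toward the past — (younger, older] in BCE years —
    so a median exactly on a shared boundary belongs to the later slice.
    The overall endpoints are inclusive.
    """
    for i, (name, older, younger) in enumerate(slices):
        if younger < median_bce <= older:
            return name
        if i == len(slices) - 1 and median_bce == younger:
            return name  # youngest endpoint inclusive
    return "outside"
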