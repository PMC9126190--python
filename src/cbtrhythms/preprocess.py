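"""Cleaning and phase segmentation of minute-binned core body temperature.

Implanted telemeters occasionally emit transmission spikes, near-instantaneous
jumps and short dropouts.  The cleaning rules here are the standard ones for
such records: replace gross outliers (|x - mean| > k.SD) and jump artifacts by
the median of the preceding hour, linearly interpolate short gaps, and leave
long gaps explicitly missing.  The adolescent record is then split into three
equal-length phases (early-to-mid puberty, mid-to-late puberty, late puberty
to early adulthood) for phase-wise trend statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TemperatureSeries",
    "PreprocessParams",
    "PhaseSegments",
    "CleaningReport",
    "clean_series",
    "segment_phases",
]


@dataclass
class TemperatureSeries:
    """Per-animal core body temperature on a uniform 1-minute grid.

    Parameters
    ----------
    animal_id : str
        Unique animal identifier.
    age_min : ndarray of int
        Postnatal age of each sample in minutes, strictly increasing with a
        constant 1-minute step.
    temp_c : ndarray of float
        Temperature in degrees Celsius; NaN marks missing samples (missingness
        is explicit, never silently dropped).
    """

    animal_id: str
    age_min: np.ndarray
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        self.age_min = np.asarray(self.age_min, dtype=np.int64)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.age_min.shape != self.temp_c.shape:
            raise ValueError("age_min and temp_c must have the same length")
        if self.age_min.size == 0:
            raise ValueError("empty temperature series")
        d = np.diff(self.age_min)
        if self.age_min.size > 1 and not np.all(d == 1):
            bad = int(np.flatnonzero(d != 1)[0])
            raise ValueError(
                f"age grid not uniform 1-min: step of {d[bad]} min after "
                f"sample {bad} (age {self.age_min[bad]} min)"
            )

    @property
    def age_days(self) -> np.ndarray:
        """Postnatal age in (fractional) days."""
        return self.age_min / 1440.0

    @property
    def n(self) -> int:
        return int(self.age_min.size)

    def copy(self) -> "TemperatureSeries":
        return TemperatureSeries(self.animal_id, self.age_min.copy(), self.temp_c.copy())

    def view_days(self, start_day: float, stop_day: float) -> "TemperatureSeries":
        """Half-open age window [start_day, stop_day) in postnatal days."""
        lo = int(math.ceil(start_day * 1440))
        hi = int(math.ceil(stop_day * 1440))
        m = (self.age_min >= lo) & (self.age_min < hi)
        if not m.any():
            raise ValueError(
                f"no samples of animal {self.animal_id!r} in [p{start_day}, p{stop_day})"
            )
        return TemperatureSeries(self.animal_id, self.age_min[m], self.temp_c[m])


@dataclass(frozen=True)
class PreprocessParams:
    """Cleaning thresholds.

    outlier_sd : outliers are samples more than this many whole-record SDs from
        the whole-record mean (default 4).
    jump_cutoff : |first difference| per 1-min step above which the later
        sample is treated as a transmission jump.  The default 1e5 is an
        intentionally inert arbitrary cutoff for temperature data in deg C; it
        is exposed because logger units differ.
    max_gap_min : missing runs up to this length (minutes) are linearly
        interpolated; longer runs stay missing (default 10).
    replace_window_min : width of the preceding window whose median replaces a
        flagged sample (default 60, i.e. the prior hour).
    """

    outlier_sd: float = 4.0
    jump_cutoff: float = 1e5
    max_gap_min: int = 10
    replace_window_min: int = 60

    def __post_init__(self) -> None:
        for name in ("outlier_sd", "jump_cutoff", "max_gap_min", "replace_window_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class CleaningReport:
    outliers_replaced: int = 0
    jumps_replaced: int = 0
    gaps_interpolated: int = 0
    gap_samples_filled: int = 0
    long_gaps_left: int = 0
    long_gap_samples: int = 0
    warnings: list = field(default_factory=list)

    @property
    def total_replaced(self) -> int:
        return self.outliers_replaced + self.jumps_replaced


# three equal-length adolescent phases; half-open day intervals
@dataclass(frozen=True)
class PhaseSegments:
    pre_mid: tuple = (26.0, 42.0)
    mid_late: tuple = (42.0, 59.0)
    late_adult: tuple = (59.0, 75.0)

    def items(self):
        return (
            ("pre_mid", self.pre_mid),
            ("mid_late", self.mid_late),
            ("late_adult", self.late_adult),
        )


def _prior_window_median(x: np.ndarray, i: int, window: int, report: CleaningReport) -> float:
    """Median of non-missing samples in the `window` minutes preceding i.

    Falls back to the nearest preceding non-missing value, then (loudly) to the
    median of whatever precedes i, when the window is empty or absent.
    """
    lo = max(0, i - window)
    prior = x[lo:i]
    prior = prior[~np.isnan(prior)]
    if prior.size:
        if i < window:
            report.warnings.append(
                f"sample {i}: only {prior.size} samples available before first "
                f"replacement target; used median of available prefix"
            )
        return float(np.median(prior))
    pre = x[:i]
    pre = pre[~np.isnan(pre)]
    if pre.size:
        report.warnings.append(
            f"sample {i}: empty prior {window}-min window; used nearest preceding value"
        )
        return float(pre[-1])
    report.warnings.append(
        f"sample {i}: nothing precedes the replacement target; used overall median"
    )
    allv = x[~np.isnan(x)]
    return float(np.median(allv))


def clean_series(
    series: TemperatureSeries, params: PreprocessParams | None = None
) -> tuple[TemperatureSeries, CleaningReport]:
    """Apply the canonical cleaning pass: outliers, jumps, then gap filling.

    Reference mean/SD for the outlier rule are computed once over the whole
    raw record (not rolling).  Flagged samples are replaced, in time order, by
    the median of the preceding ``replace_window_min`` non-missing samples of
    the working series.  Missing runs of at most ``max_gap_min`` samples are
    linearly interpolated between their bounding observations; longer runs are
    left missing and counted.
    """
    params = params or PreprocessParams()
    x = series.temp_c.copy()
    report = CleaningReport()

    finite = ~np.isnan(x)
    if not finite.any():
        raise ValueError(f"animal {series.animal_id!r}: all samples missing")
    mean = float(np.mean(x[finite]))
    sd = float(np.std(x[finite]))

    # rule 1: +/- k SD outliers -> prior-hour median
    if sd > 0:
        out_idx = np.flatnonzero(finite & (np.abs(x - mean) > params.outlier_sd * sd))
        for i in out_idx:
            x[i] = _prior_window_median(x, int(i), params.replace_window_min, report)
            report.outliers_replaced += 1

    # rule 2: near-instantaneous jumps -> prior-hour median (later sample replaced)
    dx = np.abs(np.diff(x))
    with np.errstate(invalid="ignore"):
        jump_idx = np.flatnonzero(dx > params.jump_cutoff) + 1
    for i in jump_idx:
        x[i] = _prior_window_median(x, int(i), params.replace_window_min, report)
        report.jumps_replaced += 1

    # rule 3: linear interpolation of short gaps
    isnan = np.isnan(x)
    if isnan.any():
        # run-length encode missing stretches
        idx = np.flatnonzero(isnan)
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            a, b = int(run[0]), int(run[-1])
            length = b - a + 1
            if length > params.max_gap_min or a == 0 or b == x.size - 1:
                # unbounded runs cannot be interpolated either
                report.long_gaps_left += 1
                report.long_gap_samples += length
                continue
            x0, x1 = x[a - 1], x[b + 1]
            t = np.arange(1, length + 1) / (length + 1)
            x[a : b + 1] = x0 + t * (x1 - x0)
            report.gaps_interpolated += 1
            report.gap_samples_filled += length

    out = TemperatureSeries(series.animal_id, series.age_min.copy(), x)
    assert out.n == series.n  # length conservation
    return out, report


def segment_phases(
    series: TemperatureSeries, segments: PhaseSegments | None = None
) -> dict[str, TemperatureSeries]:
    """Partition the analysis span into the three adolescent phases.

    Postnatal day d spans ages [d, d+1) days; the phases are half-open so no
    sample lands in two of them.  Raises if the record does not cover the full
    analysis window, naming the missing span.
    """
    segments = segments or PhaseSegments()
    start = segments.pre_mid[0]
    stop = segments.late_adult[1]
    lo_min, hi_min = int(start * 1440), int(stop * 1440) - 1
    have_lo, have_hi = int(series.age_min[0]), int(series.age_min[-1])
    if have_lo > lo_min or have_hi < hi_min:
        raise ValueError(
            f"animal {series.animal_id!r}: record covers p{have_lo / 1440:.2f}-"
            f"p{have_hi / 1440:.2f} but analysis needs p{start:g}-p{stop:g} "
            f"(missing span at the {'start' if have_lo > lo_min else 'end'})"
        )
    return {name: series.view_days(*iv) for name, iv in segments.items()}
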