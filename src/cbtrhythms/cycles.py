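"""Estrous-cycle detection, alignment and ovulatory-rhythm metrics.

Puberty onset is read from daily fecal estradiol (fE2): the first day the
level rises more than 2 SDs above its pre-pubertal baseline.  From that day
the record is divided into consecutive 4-day blocks whose anchor is shifted so
the within-block fE2 maximum sits on day 3 (fE2 rises for three days and falls
on the fourth).  Ovulatory modulation of temperature is then quantified by a
combined daily metric z(CBT) - z(UR power) — elevated when temperature is high
and ultradian power low, the signature of the peri-ovulatory day — tested
across day-of-cycle bins with Friedman + Dunn, and by the 4-5 day band area of
the FFT magnitude spectrum of daily temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ComparisonResult, omnibus_with_dunn

__all__ = [
    "HormoneSeries",
    "RiseDetection",
    "CycleAlignment",
    "OvulatoryMetric",
    "detect_rise",
    "align_cycles",
    "combined_metric",
    "day_of_cycle_test",
    "fft_band_auc",
    "fft_dominant_period",
    "fe2_cycle_auc",
]


@dataclass
class HormoneSeries:
    """Per-animal daily fecal estradiol (pg/ml); days strictly increasing.

    Collection may be non-contiguous (separate pre-, mid- and late-pubertal
    windows); gaps between windows are simply absent days.
    """

    animal_id: str
    day: np.ndarray
    fe2: np.ndarray

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=np.int64)
        self.fe2 = np.asarray(self.fe2, dtype=float)
        if self.day.shape != self.fe2.shape:
            raise ValueError("day and fe2 must have the same length")
        if self.day.size and np.any(np.diff(self.day) <= 0):
            raise ValueError(f"days not strictly increasing for {self.animal_id!r}")
        if np.any(self.fe2 < 0):
            raise ValueError("fE2 concentrations must be >= 0")


@dataclass
class RiseDetection:
    """Result of the 2-SD pubertal fE2 rise rule."""

    baseline_window: tuple = (25, 30)
    sd_multiple: float = 2.0
    baseline_mean: float | None = None
    baseline_sd: float | None = None
    threshold: float | None = None
    rise_day: int | None = None
    undefined_threshold: bool = False


@dataclass
class CycleAlignment:
    """Day-of-cycle labelling anchored so the fE2 peak sits on day 3."""

    animal_id: str
    block_len: int
    anchor_day: int
    labels: pd.DataFrame  # columns: day, cycle_index, day_of_cycle
    complete_blocks: list = field(default_factory=list)  # list of day arrays
    peak_day_index: int | None = None

    def day_of_cycle(self, day) -> np.ndarray:
        """Arithmetic day-of-cycle label (1..block_len) for arbitrary days."""
        day = np.asarray(day, dtype=np.int64)
        return ((day - self.anchor_day) % self.block_len) + 1


@dataclass
class OvulatoryMetric:
    """Daily combined ovulatory metric z(CBT) - z(UR power) per animal."""

    animal_id: str
    day: np.ndarray
    z_cbt: np.ndarray
    z_ur: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.z_cbt - self.z_ur


def detect_rise(
    h: HormoneSeries,
    baseline_window: tuple = (25, 30),
    sd_multiple: float = 2.0,
) -> RiseDetection:
    """First day fE2 exceeds baseline mean + ``sd_multiple`` * baseline SD.

    The baseline window (inclusive days, default p25-p30, before vaginal
    opening) must be fully observed.  A zero baseline SD with no qualifying
    day is reported as an undefined threshold rather than "no rise".
    """
    det = RiseDetection(baseline_window=tuple(baseline_window), sd_multiple=sd_multiple)
    lo, hi = baseline_window
    want = np.arange(lo, hi + 1)
    mask = np.isin(h.day, want)
    if mask.sum() != want.size:
        missing = sorted(set(want) - set(h.day.tolist()))
        raise ValueError(
            f"animal {h.animal_id!r}: baseline days {missing} not observed"
        )
    base = h.fe2[mask]
    det.baseline_mean = float(np.mean(base))
    det.baseline_sd = float(np.std(base, ddof=1))
    det.threshold = det.baseline_mean + sd_multiple * det.baseline_sd

    after = h.day > hi
    exceed = after & (h.fe2 > det.threshold)
    if exceed.any():
        det.rise_day = int(h.day[np.flatnonzero(exceed)[0]])
    elif det.baseline_sd == 0.0:
        det.undefined_threshold = True
    return det


def align_cycles(h: HormoneSeries, rise: RiseDetection, block_len: int = 4) -> CycleAlignment:
    """Anchor consecutive ``block_len``-day blocks so the fE2 peak is day 3.

    The anchor starts at the detected rise day and is shifted (by at most
    block_len-1 days) so that the maximum of the first complete block falls at
    within-block index 3 (index block_len - 1 for 5-day sensitivity blocks).
    Labels propagate arithmetically through unobserved spans.  Blocks with any
    unobserved day are flagged incomplete and excluded from per-block metrics;
    ties among equal within-block maxima go to the earliest day.
    """
    if rise.rise_day is None:
        raise ValueError(f"animal {h.animal_id!r}: no detected rise to align from")
    peak_slot = 3 if block_len == 4 else block_len - 1  # 0-based: slot index 2
    peak_pos0 = peak_slot - 1

    observed = set(h.day.tolist())
    post = h.day >= rise.rise_day
    if post.sum() < block_len:
        raise ValueError(
            f"animal {h.animal_id!r}: only {int(post.sum())} observed days after "
            f"rise; need >= {block_len}"
        )

    # first fully observed window of block_len consecutive days from the rise
    first_days = None
    for start in range(rise.rise_day, int(h.day[-1]) - block_len + 2):
        window = list(range(start, start + block_len))
        if all(d in observed for d in window):
            first_days = np.array(window)
            break
    if first_days is None:
        raise ValueError(
            f"animal {h.animal_id!r}: no complete {block_len}-day window after rise"
        )
    vals = h.fe2[np.isin(h.day, first_days)]
    peak_day = int(first_days[int(np.argmax(vals))])  # argmax: earliest tie wins
    anchor = peak_day - peak_pos0
    # keep the anchor within one block of the rise day
    while anchor > rise.rise_day:
        anchor -= block_len

    day_of_cycle = ((h.day - anchor) % block_len) + 1
    cycle_index = (h.day - anchor) // block_len
    labels = pd.DataFrame(
        {"day": h.day, "cycle_index": cycle_index, "day_of_cycle": day_of_cycle}
    )

    complete, peak_indices = [], []
    for start in range(anchor, int(h.day[-1]) - block_len + 2, block_len):
        window = np.arange(start, start + block_len)
        if all(d in observed for d in window):
            complete.append(window)
            v = h.fe2[np.isin(h.day, window)]
            peak_indices.append(int(np.argmax(v)) + 1)
    peak_day_index = None
    if peak_indices:
        vals_u, counts = np.unique(peak_indices, return_counts=True)
        peak_day_index = int(vals_u[np.argmax(counts)])

    return CycleAlignment(h.animal_id, block_len, anchor, labels, complete, peak_day_index)


def combined_metric(
    daily: pd.DataFrame,
    cbt_col: str = "cbt_mean",
    ur_col: str = "ur_power",
    animal_col: str = "animal_id",
    day_col: str = "day",
) -> list[OvulatoryMetric]:
    """Daily z(CBT) - z(UR power), z-scored per animal over the supplied span.

    Both inputs must be on the same day grid; the combined value exists only
    where both are present.  By construction the metric is invariant to affine
    rescaling of either input.
    """
    out = []
    for aid, sub in daily.groupby(animal_col, sort=True):
        sub = sub.dropna(subset=[cbt_col, ur_col]).sort_values(day_col)
        if len(sub) < 3:
            raise ValueError(f"animal {aid!r}: fewer than 3 paired days")
        for col in (cbt_col, ur_col):
            if float(sub[col].std(ddof=0)) == 0.0:
                raise ValueError(f"animal {aid!r}: zero variance in {col}")
        z = lambda v: (v - v.mean()) / v.std(ddof=0)
        out.append(
            OvulatoryMetric(
                str(aid),
                sub[day_col].to_numpy(dtype=np.int64),
                z(sub[cbt_col].to_numpy(dtype=float)),
                z(sub[ur_col].to_numpy(dtype=float)),
            )
        )
    return out


def day_of_cycle_test(
    values: pd.DataFrame,
    alignments: dict,
    value_col: str = "combined",
    animal_col: str = "animal_id",
    day_col: str = "day",
    alpha: float = 0.05,
    always_pairwise: bool = False,
) -> ComparisonResult:
    """Friedman + Dunn test of day-of-cycle structure, cycles as replicates.

    Each complete block (one estrous cycle of one animal) becomes one Friedman
    block with ``block_len`` conditions, matching the treatment of cycles as
    independent replicates.  Blocks with a missing daily value are dropped and
    counted via the result's group_ns.
    """
    rows = []
    for aid, sub in values.groupby(animal_col):
        align = alignments[aid]
        per_day = sub.set_index(day_col)[value_col]
        k = align.block_len
        start0 = align.anchor_day
        last = int(per_day.index.max())
        for start in range(start0, last - k + 2, k):
            window = np.arange(start, start + k)
            vals = per_day.reindex(window).to_numpy(dtype=float)
            if np.isnan(vals).any():
                continue
            rows.append(vals)
    if len(rows) < 2:
        raise ValueError("fewer than 2 complete blocks; cannot test day-of-cycle")
    table = np.vstack(rows)
    k = table.shape[1]
    return omnibus_with_dunn(
        table,
        design="repeated",
        labels=[f"day{i}" for i in range(1, k + 1)],
        alpha=alpha,
        always_pairwise=always_pairwise,
    )


def _magnitude_spectrum(day: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT magnitude of a linearly detrended daily series."""
    day = np.asarray(day, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        keep = ~np.isnan(v)
        day, v = day[keep], v[keep]
    if v.size < 4:
        raise ValueError("daily series too short for a spectrum")
    if np.any(np.diff(day) != 1):
        # interpolate interior holes onto the uniform daily grid
        grid = np.arange(day[0], day[-1] + 1)
        v = np.interp(grid, day, v)
        day = grid
    coeffs = np.polyfit(day, v, 1)
    v = v - np.polyval(coeffs, day)
    mag = np.abs(np.fft.rfft(v)) * 2.0 / v.size
    freq = np.fft.rfftfreq(v.size, d=1.0)  # cycles per day
    return freq, mag


def fft_band_auc(day, values, band_days: tuple = (4.0, 5.0)) -> float:
    """Trapezoidal area of the FFT magnitude spectrum between two periods.

    The spectrum is of daily (or daily-summarised) temperature, linearly
    detrended, and integrated over frequency between 1/hi and 1/lo cycles/day
    with linearly interpolated band endpoints, making the area exactly
    additive over disjoint period sub-bands.
    """
    lo_d, hi_d = band_days
    day = np.asarray(day, dtype=float)
    if (day.max() - day.min() + 1) < 3 * hi_d:
        raise ValueError(f"span too short to resolve a {hi_d:g}-day period")
    freq, mag = _magnitude_spectrum(day, values)
    f_lo, f_hi = 1.0 / hi_d, 1.0 / lo_d
    if f_hi > freq[-1]:
        raise ValueError("band extends beyond the resolvable frequency range")
    inner = (freq > f_lo) & (freq < f_hi)
    fs = np.concatenate([[f_lo], freq[inner], [f_hi]])
    ms = np.concatenate([[np.interp(f_lo, freq, mag)], mag[inner], [np.interp(f_hi, freq, mag)]])
    return float(np.trapezoid(ms, fs))


def fft_dominant_period(day, values, period_range_days: tuple = (3.0, 6.0)) -> float:
    """Period (days) of the largest spectral magnitude within a period range."""
    freq, mag = _magnitude_spectrum(day, values)
    lo_d, hi_d = period_range_days
    sel = (freq > 0) & (freq >= 1.0 / hi_d) & (freq <= 1.0 / lo_d)
    if not sel.any():
        raise ValueError("no non-DC frequency bins inside the period range")
    f = freq[sel][np.argmax(mag[sel])]
    return float(1.0 / f)


def fe2_cycle_auc(h: HormoneSeries, align: CycleAlignment) -> pd.DataFrame:
    """Trapezoidal fE2 area over each complete aligned block (day spacing 1)."""
    rows = []
    for window in align.complete_blocks:
        vals = h.fe2[np.isin(h.day, window)]
        rows.append((int(window[0]), float(np.trapezoid(vals))))
    return pd.DataFrame(rows, columns=["block_start_day", "auc"])
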