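"""End-to-end analysis pipeline and its configuration.

``run_pipeline`` strings the stages together per animal — cleaning, Morse
transform, circadian/ultradian band power, 24 h smoothing, daily summaries,
fE2 rise detection and cycle alignment — and then runs the group-level
statistics: Mann-Kendall trends per adolescent phase, day-of-cycle Friedman +
Dunn tests of the combined ovulatory metric, 2-SD circadian power crossing
times, 4-5 day FFT band areas, per-cycle fE2 AUC comparisons, and the mixed
model of circadian power on fE2.  Everything is written under an output
directory with a deterministic manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cycles as cyc
from . import io as cio
from . import stats as st
from . import synth
from .preprocess import PhaseSegments, PreprocessParams, clean_series
from .wavelet import (
    CIRCADIAN_BAND,
    ULTRADIAN_BAND,
    CrossingCriterion,
    WaveletParams,
    band_max_power,
    crossing_time,
    morse_transform,
    smooth_power,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "daily_summary", "analyze_cohort"]


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the protocol's standard values."""

    temperature_csv: str | None = None
    hormone_csv: str | None = None
    design_csv: str | None = None
    synthetic: bool = True
    n_animals_per_group: int = 8
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    circadian_band: tuple = CIRCADIAN_BAND
    ultradian_band: tuple = ULTRADIAN_BAND
    smoothing_window_h: float = 24.0
    analysis_window: tuple = (26.0, 75.0)       # p26 through p74 inclusive
    phases: PhaseSegments = field(default_factory=PhaseSegments)
    block_len: int = 4
    fallback_anchor_day: int = 32               # acyclic groups: midpoint of onset range
    fft_band_days: tuple = (4.0, 5.0)
    fft_span_split_day: int = 50                # rise->p50 and p50->p74 spans
    crossing: CrossingCriterion = field(default_factory=CrossingCriterion)
    rise_baseline_window: tuple = (25, 30)
    rise_sd_multiple: float = 2.0
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "cbtrhythms_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["preprocess"] = PreprocessParams(**raw["preprocess"])
        raw["wavelet"] = WaveletParams(**{k: (tuple(v) if isinstance(v, list) else v)
                                          for k, v in raw["wavelet"].items()})
        ph = raw["phases"]
        raw["phases"] = PhaseSegments(**{k: tuple(v) for k, v in ph.items()})
        raw["crossing"] = CrossingCriterion(**{k: (tuple(v) if isinstance(v, list) else v)
                                               for k, v in raw["crossing"].items()})
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class RunReport:
    config: RunConfig
    daily: pd.DataFrame
    rises: pd.DataFrame
    trends: pd.DataFrame
    day_of_cycle: dict
    crossings: pd.DataFrame
    fft_auc: pd.DataFrame
    stats_table: pd.DataFrame
    mixed_models: dict
    manifest: dict


def daily_summary(ts, cr_bp, ur_bp, analysis_window) -> pd.DataFrame:
    """Per-day mean CBT and median smoothed band powers over the analysis span."""
    lo, hi = analysis_window
    days = ts.age_min // 1440
    keep = (days >= lo) & (days < hi)
    df = pd.DataFrame({
        "day": days[keep],
        "cbt": ts.temp_c[keep],
        "cr": np.where(cr_bp.valid, cr_bp.values, np.nan)[keep],
        "ur": np.where(ur_bp.valid, ur_bp.values, np.nan)[keep],
    })
    agg = df.groupby("day").agg(
        cbt_mean=("cbt", "mean"),
        cr_power_median=("cr", "median"),
        ur_power_median=("ur", "median"),
    ).reset_index()
    agg.insert(0, "animal_id", ts.animal_id)
    return agg


def _per_animal_tables(animals, config: RunConfig):
    """Clean, transform and summarise every animal; returns daily table + rises."""
    daily_frames, rise_rows, crossing_rows = [], [], {}
    alignments, cleaning = {}, {}
    lo, hi = config.analysis_window
    for a in animals:
        cleaned, report = clean_series(a.temperature, config.preprocess)
        cleaning[a.temperature.animal_id] = report
        spec = morse_transform(cleaned, config.wavelet)
        cr = smooth_power(band_max_power(spec, config.circadian_band),
                          config.smoothing_window_h)
        # ultradian daily medians stay day-local (raw, unsmoothed): the
        # 24 h-centred smoother would leak power across day-of-cycle block
        # boundaries and cycles are treated as independent replicates
        ur = band_max_power(spec, config.ultradian_band)
        daily_frames.append(daily_summary(cleaned, cr, ur, (lo, hi)))

        det = cyc.detect_rise(a.hormones, config.rise_baseline_window,
                              config.rise_sd_multiple)
        align = None
        if det.rise_day is not None:
            try:
                align = cyc.align_cycles(a.hormones, det, config.block_len)
            except ValueError:
                align = None  # rise too close to the record end to anchor on
        if align is None:
            align = cyc.CycleAlignment(
                a.hormones.animal_id, config.block_len,
                config.fallback_anchor_day, pd.DataFrame(), [], None,
            )
        alignments[a.hormones.animal_id] = align
        rise_rows.append({
            "animal_id": a.hormones.animal_id,
            "group": a.design.group_label,
            "rise_day": det.rise_day,
            "threshold": det.threshold,
            "anchor_day": align.anchor_day,
            "peak_day_index": align.peak_day_index,
        })

        # first crossing of the 2-SD circadian power criterion (daily medians)
        days_d, vals_d = st.downsample_for_stats(
            cr.times_min, np.where(cr.valid, cr.values, np.nan))
        from .wavelet import BandPowerSeries
        daily_bp = BandPowerSeries(
            cr.animal_id, cr.band, (days_d * 1440).astype(np.int64), vals_d,
            np.ones(vals_d.size, dtype=bool), smoothed=True)
        try:
            crossing_rows[a.hormones.animal_id] = crossing_time(daily_bp, config.crossing)
        except ValueError:
            crossing_rows[a.hormones.animal_id] = None

    daily = pd.concat(daily_frames, ignore_index=True)
    rises = pd.DataFrame(rise_rows)
    crossings = rises[["animal_id", "group"]].copy()
    crossings["crossing_day"] = crossings["animal_id"].map(crossing_rows)
    return daily, rises, crossings, alignments, cleaning


def analyze_cohort(animals, config: RunConfig) -> RunReport:
    """Run the full statistical analysis on simulated or loaded animals."""
    daily, rises, crossings, alignments, cleaning = _per_animal_tables(animals, config)
    groups = sorted({a.design.group_label for a in animals})
    group_of = {a.temperature.animal_id: a.design.group_label for a in animals}
    daily["group"] = daily["animal_id"].map(group_of)

    # Mann-Kendall trends of daily CR power and daily CBT per group and phase
    trend_rows = []
    for (grp, aid), sub in daily.groupby(["group", "animal_id"]):
        for phase_name, (plo, phi_) in config.phases.items():
            w = sub[(sub["day"] >= plo) & (sub["day"] < phi_)]
            for col, label in (("cr_power_median", "cr_power"), ("cbt_mean", "cbt")):
                v = w[col].dropna().to_numpy()
                if v.size < 4:
                    continue
                tr = st.mann_kendall(v)
                trend_rows.append({
                    "group": grp, "animal_id": aid, "phase": phase_name,
                    "series": label, "S": tr.S, "tau": tr.tau, "p": tr.p_value,
                })
    trends = pd.DataFrame(trend_rows)

    # combined ovulatory metric + day-of-cycle tests per group
    day_of_cycle = {}
    metrics_frames = []
    for grp in groups:
        aids = [a.temperature.animal_id for a in animals
                if a.design.group_label == grp]
        sub = daily[daily["animal_id"].isin(aids)].rename(
            columns={"ur_power_median": "ur_power"})
        # post-anchor span per animal
        frames = []
        for aid in aids:
            anchor = alignments[aid].anchor_day
            frames.append(sub[(sub["animal_id"] == aid) & (sub["day"] >= anchor)])
        sub = pd.concat(frames, ignore_index=True)
        try:
            mets = cyc.combined_metric(sub)
        except ValueError:
            continue
        met_df = pd.concat(
            [pd.DataFrame({"animal_id": m.animal_id, "day": m.day,
                           "combined": m.combined}) for m in mets],
            ignore_index=True)
        met_df["group"] = grp
        metrics_frames.append(met_df)
        try:
            day_of_cycle[grp] = cyc.day_of_cycle_test(
                met_df, alignments, alpha=config.alpha)
        except ValueError:
            pass
    metrics = (pd.concat(metrics_frames, ignore_index=True)
               if metrics_frames else pd.DataFrame())

    # 4-5 day FFT band AUC per animal, pre/post the contraceptive split day
    auc_rows = []
    for a in animals:
        aid = a.temperature.animal_id
        sub = daily[daily["animal_id"] == aid]
        rise = rises.set_index("animal_id").loc[aid, "rise_day"]
        start = int(rise) if pd.notna(rise) else config.fallback_anchor_day
        for span_name, (s0, s1) in (
            ("rise_to_split", (start, config.fft_span_split_day)),
            ("split_to_end", (config.fft_span_split_day, int(config.analysis_window[1]))),
        ):
            w = sub[(sub["day"] >= s0) & (sub["day"] < s1)]
            try:
                auc = cyc.fft_band_auc(w["day"].to_numpy(),
                                       w["cbt_mean"].to_numpy(),
                                       config.fft_band_days)
            except ValueError:
                auc = np.nan
            auc_rows.append({"animal_id": aid, "group": group_of[aid],
                             "span": span_name, "auc": auc})
    fft_auc = pd.DataFrame(auc_rows)

    # group-level comparisons
    stats_rows = []

    def record(test_name, context, result):
        stats_rows.append({
            "test": result.test, "context": context,
            "statistic": result.statistic, "p": result.p_value,
            "ns": str(result.group_ns),
        })

    post = fft_auc[fft_auc["span"] == "split_to_end"].dropna(subset=["auc"])
    if {"Intact", "IntactC"} <= set(post["group"]):
        a_ = post[post["group"] == "Intact"]["auc"].to_numpy()
        b_ = post[post["group"] == "IntactC"]["auc"].to_numpy()
        if a_.size >= 3 and b_.size >= 3:
            record("mw", "fft_auc_post_split_Intact_vs_IntactC",
                   st.rank_test_two(a_, b_, alternative="greater"))

    cross_ok = crossings.dropna(subset=["crossing_day"])
    if {"Intact", "OVX_E2"} <= set(cross_ok["group"]):
        a_ = cross_ok[cross_ok["group"] == "OVX_E2"]["crossing_day"].to_numpy(dtype=float)
        b_ = cross_ok[cross_ok["group"] == "Intact"]["crossing_day"].to_numpy(dtype=float)
        if a_.size >= 3 and b_.size >= 3:
            record("mw", "crossing_day_OVX_E2_earlier_than_Intact",
                   st.rank_test_two(a_, b_, alternative="less"))

    if len(groups) >= 3:
        for phase_name, (plo, phi_) in config.phases.items():
            samples, labels = [], []
            for grp in groups:
                w = daily[(daily["group"] == grp) & (daily["day"] >= plo)
                          & (daily["day"] < phi_)]
                v = w["cr_power_median"].dropna().to_numpy()
                if v.size:
                    samples.append(v)
                    labels.append(grp)
            if len(samples) >= 3:
                record("kw", f"cr_power_{phase_name}",
                       st.omnibus_with_dunn(samples, "independent", labels,
                                            alpha=config.alpha))

    # mixed model: normalized daily CR power ~ fE2, per group
    mixed_models = {}
    horm = {a.hormones.animal_id: a.hormones for a in animals}
    for grp in groups:
        frames = []
        for a in animals:
            if a.design.group_label != grp:
                continue
            aid = a.temperature.animal_id
            sub = daily[daily["animal_id"] == aid][["animal_id", "day", "cr_power_median"]]
            sub = sub.dropna()
            mu = sub["cr_power_median"].mean()
            sd = sub["cr_power_median"].std(ddof=0)
            if not sd > 0:
                continue
            sub = sub.assign(cr_power=(sub["cr_power_median"] - mu) / sd)
            h = horm[aid]
            fe2 = pd.DataFrame({"day": h.day, "fe2": h.fe2})
            frames.append(sub.merge(fe2, on="day"))
        if not frames:
            continue
        dat = pd.concat(frames, ignore_index=True)
        try:
            mixed_models[grp] = st.mixed_cr_fe2(dat)
        except (ValueError, np.linalg.LinAlgError):
            pass

    stats_table = pd.DataFrame(stats_rows)
    return RunReport(config, daily, rises, trends, day_of_cycle, crossings,
                     fft_auc, stats_table, mixed_models, manifest={})


def run_pipeline(config: RunConfig) -> RunReport:
    """Simulate (or load) the cohort, analyse it, and write all artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.temperature_csv and config.hormone_csv:
        temp = cio.read_temperature_csv(config.temperature_csv)
        horm = {h.animal_id: h for h in cio.read_hormone_csv(config.hormone_csv)}
        designs = (cio.read_design_csv(config.design_csv)
                   if config.design_csv else synth.default_designs())
        by_group = {d.group_label: d for d in designs}
        animals = []
        for ts in temp:
            grp = ts.animal_id.rsplit("_", 1)[0]
            design = by_group.get(grp)
            if design is None:
                raise ValueError(
                    f"animal {ts.animal_id!r}: cannot map id prefix {grp!r} to a "
                    "design group")
            if ts.animal_id not in horm:
                raise ValueError(f"no hormone series for animal {ts.animal_id!r}")
            animals.append(synth.SimulatedAnimal(ts, horm[ts.animal_id], None, design))
    elif config.synthetic:
        designs = synth.default_designs(config.n_animals_per_group)
        bundle = synth.simulate_cohort(designs, seed=config.seed)
        animals = bundle.animals
        cio.write_temperature_csv(outdir / "temperature.csv",
                                  [a.temperature for a in animals])
        cio.write_hormone_csv(outdir / "fe2.csv", [a.hormones for a in animals])
        cio.write_design_csv(outdir / "design.csv", designs)
        cio.write_ground_truth_json(outdir / "ground_truth.json", animals)
    else:
        raise ValueError("config provides neither input CSVs nor a synthetic cohort")

    report = analyze_cohort(animals, config)

    report.daily.to_csv(outdir / "daily_summaries.csv", index=False,
                        float_format="%.10g")
    report.rises.to_csv(outdir / "rise_alignment.csv", index=False,
                        float_format="%.10g")
    report.trends.to_csv(outdir / "mk_trends.csv", index=False, float_format="%.10g")
    report.crossings.to_csv(outdir / "crossing_days.csv", index=False,
                            float_format="%.10g")
    report.fft_auc.to_csv(outdir / "fft_band_auc.csv", index=False,
                          float_format="%.10g")
    report.stats_table.to_csv(outdir / "group_stats.csv", index=False,
                              float_format="%.10g")
    doc = {grp: {"statistic": r.statistic, "p": r.p_value, "ns": list(r.group_ns)}
           for grp, r in report.day_of_cycle.items()}
    mm = {grp: dataclasses.asdict(m) for grp, m in report.mixed_models.items()}
    (outdir / "day_of_cycle.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
    (outdir / "mixed_models.json").write_text(json.dumps(mm, indent=1, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")

    manifest = {"config_seed": config.seed, "files": {}}
    for f in sorted(outdir.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest["files"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    report.manifest = manifest
    return report
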