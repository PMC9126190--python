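"""CSV readers/writers for temperature, hormone and design tables.

Temperature CSV: columns ``animal_id, age_days, temp_c``; one row per minute,
fractional postnatal days, empty temp_c for missing samples.
Hormone CSV: ``animal_id, day, fe2_pg_ml``; one row per collected day.
Design CSV: one row per group with the intervention days.
Ground truth is serialised as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cycles import HormoneSeries
from .preprocess import TemperatureSeries
from .synth import GroupDesign

__all__ = [
    "read_temperature_csv",
    "write_temperature_csv",
    "read_hormone_csv",
    "write_hormone_csv",
    "read_design_csv",
    "write_design_csv",
    "write_ground_truth_json",
]


def write_temperature_csv(path, series_list) -> None:
    frames = []
    for ts in series_list:
        frames.append(pd.DataFrame({
            "animal_id": ts.animal_id,
            "age_min": ts.age_min,
            "temp_c": ts.temp_c,
        }))
    df = pd.concat(frames, ignore_index=True)
    df["age_days"] = df.pop("age_min") / 1440.0
    df[["animal_id", "age_days", "temp_c"]].to_csv(
        path, index=False, float_format="%.10g"
    )


def read_temperature_csv(path) -> list[TemperatureSeries]:
    """Read and validate per-animal minute-binned temperature series."""
    df = pd.read_csv(path)
    required = {"animal_id", "age_days", "temp_c"}
    if not required.issubset(df.columns):
        raise ValueError(f"temperature CSV needs columns {sorted(required)}")
    out = []
    for aid, sub in df.groupby("animal_id", sort=True):
        age_min = np.round(sub["age_days"].to_numpy(dtype=float) * 1440.0).astype(np.int64)
        dup = pd.Series(age_min).duplicated()
        if dup.any():
            row = sub.index[dup.to_numpy()][0]
            raise ValueError(f"duplicate (animal, time) at CSV row {row + 2} for {aid!r}")
        order = np.argsort(age_min)
        if not np.all(order == np.arange(age_min.size)):
            raise ValueError(f"non-monotone timestamps for animal {aid!r}")
        temps = sub["temp_c"].to_numpy(dtype=float)
        steps = np.diff(age_min)
        if np.any(steps != 1):
            # absent rows become explicit missing samples on the full grid
            full = np.arange(age_min[0], age_min[-1] + 1)
            filled = np.full(full.size, np.nan)
            filled[age_min - age_min[0]] = temps
            age_min, temps = full, filled
        out.append(TemperatureSeries(str(aid), age_min, temps))
    return out


def write_hormone_csv(path, series_list) -> None:
    df = pd.concat(
        [pd.DataFrame({"animal_id": h.animal_id, "day": h.day, "fe2_pg_ml": h.fe2})
         for h in series_list],
        ignore_index=True,
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_hormone_csv(path) -> list[HormoneSeries]:
    df = pd.read_csv(path)
    required = {"animal_id", "day", "fe2_pg_ml"}
    if not required.issubset(df.columns):
        raise ValueError(f"hormone CSV needs columns {sorted(required)}")
    out = []
    for aid, sub in df.groupby("animal_id", sort=True):
        days = sub["day"].to_numpy(dtype=np.int64)
        if pd.Series(days).duplicated().any():
            raise ValueError(f"duplicate day for animal {aid!r}")
        order = np.argsort(days)
        out.append(HormoneSeries(str(aid), days[order],
                                 sub["fe2_pg_ml"].to_numpy(dtype=float)[order]))
    return out


def write_design_csv(path, designs) -> None:
    rows = []
    for d in designs:
        rows.append({
            "group": d.group_label,
            "n_animals": d.n_animals,
            "ovx_day": d.ovx_day if d.ovx_day is not None else "",
            "capsule_day": d.capsule_day if d.capsule_day is not None else "",
            "contraceptive_start": d.contraceptive_window[0] if d.contraceptive_window else "",
            "contraceptive_end": d.contraceptive_window[1] if d.contraceptive_window else "",
            "record_start": d.record_window[0],
            "record_end": d.record_window[1],
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design_csv(path) -> list[GroupDesign]:
    df = pd.read_csv(path)
    designs = []
    for _, r in df.iterrows():
        def opt(key):
            v = r.get(key)
            return None if pd.isna(v) or v == "" else int(v)
        cw = (opt("contraceptive_start"), opt("contraceptive_end"))
        designs.append(GroupDesign(
            group_label=str(r["group"]),
            n_animals=int(r["n_animals"]),
            ovx_day=opt("ovx_day"),
            capsule_day=opt("capsule_day"),
            contraceptive_window=cw if cw[0] is not None else None,
            record_window=(int(r["record_start"]), int(r["record_end"])),
        ))
    return designs


def write_ground_truth_json(path, animals) -> None:
    payload = {a.truth.animal_id: a.truth.to_dict() for a in animals}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
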