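"""Synthetic adolescent cohorts: temperature and fecal estradiol generators.

The generator emulates the structure the analysis pipeline assumes in female
rats recorded continuously from weaning through early adulthood:

* minute-binned core body temperature (CBT) with a baseline that ramps across
  early puberty, a light-entrained circadian component whose amplitude rises
  from the pubertal fE2 onset (p31) to p41 and then plateaus, an ultradian
  (~2 h) component, and AR(1) physiological noise with additional
  day-to-day level variability;
* daily fecal estradiol (fE2) that is flat pre-pubertally and, from an
  individually drawn onset day, repeats a 4-day estrous profile (three days
  rising, one falling);
* 4-day ovulatory modulation of CBT (elevation the day after the fE2 peak)
  and of ultradian amplitude (suppression trough in the same window);
* four hormonal-group templates: Intact, Intact + pubertal contraceptives
  (cycling abolished from p50, temperature and circadian amplitude
  depressed), OVX (no cycles, low circadian amplitude, late temperature
  decline) and OVX + E2 (no cycles, faster circadian amplitude rise,
  temperature maintained).

A ground-truth record of every drawn quantity accompanies each animal so
downstream detectors can be scored against what was actually generated.
Artifact injection (spikes, short and long gaps) is separate so the cleaning
rules can be stress-tested positionally.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.signal import lfilter

from .cycles import HormoneSeries
from .preprocess import TemperatureSeries

__all__ = [
    "GroupDesign",
    "SimulationParams",
    "ArtifactSpec",
    "GroundTruth",
    "CohortBundle",
    "simulate_animal",
    "simulate_cohort",
    "inject_artifacts",
    "default_designs",
]

GROUPS = ("Intact", "IntactC", "OVX", "OVX_E2")


@dataclass(frozen=True)
class GroupDesign:
    """One hormonal group of the cohort design."""

    group_label: str
    n_animals: int = 8
    ovx_day: int | None = None            # p21 for OVX / OVX_E2
    capsule_day: int | None = None        # p29 silastic capsule (oil or E2)
    contraceptive_window: tuple | None = None  # (50, 58) for IntactC
    record_window: tuple = (25, 75)

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValueError(f"unknown group {self.group_label!r}; expected one of {GROUPS}")
        if self.contraceptive_window is not None and self.group_label != "IntactC":
            raise ValueError("contraceptive_window is only valid for IntactC")
        if self.capsule_day is not None and self.group_label not in ("OVX", "OVX_E2"):
            raise ValueError("capsule_day is only valid for OVX / OVX_E2")
        if not self.record_window[0] < self.record_window[1]:
            raise ValueError("record_window start must precede end")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


def default_designs(n_animals: int = 8, record_window: tuple = (25, 75)) -> list[GroupDesign]:
    """The four-group study design (n=8/group by default)."""
    return [
        GroupDesign("Intact", n_animals, record_window=record_window),
        GroupDesign("IntactC", n_animals, contraceptive_window=(50, 58),
                    record_window=record_window),
        GroupDesign("OVX", n_animals, ovx_day=21, capsule_day=29,
                    record_window=record_window),
        GroupDesign("OVX_E2", n_animals, ovx_day=21, capsule_day=29,
                    record_window=record_window),
    ]


@dataclass(frozen=True)
class SimulationParams:
    """Generative counterparts of the observed quantities.

    Temperatures in deg C, periods in hours, ages in postnatal days, fE2 in
    pg/ml.  The circadian component is a sinusoid phase-locked to the light
    cycle (peak mid-scotophase; lights on 01:00, off 13:00), with amplitude
    ramping linearly over ``circadian_ramp_window`` and constant thereafter.
    The ramp begins at p31, where the pubertal fE2 rise that the circadian
    elevation follows typically starts; OVX+E2 animals instead ramp (more
    steeply) from capsule implantation at p29, so p26-p29 is a pre-rise
    circadian baseline in every group.  The estrous (ovulatory) cycle repeats ``fe2_cycle_profile`` — relative
    levels rising for three days with a fall on the fourth, scaled by
    ``fe2_cycle_amp`` — from an onset day drawn uniformly in
    ``onset_day_range``; temperature is elevated and ultradian amplitude
    suppressed on the day after the profile peak.  Noise is AR(1) (stationary
    SD ``noise_sd``) at 1-min resolution.
    """

    baseline_cbt: float = 37.0
    pubertal_cbt_slope: float = 0.02          # deg C/day over p26-p41
    circadian_period: float = 24.0
    circadian_amp_initial: float = 0.15
    circadian_amp_plateau: float = 0.5
    circadian_ramp_window: tuple = (31.0, 41.0)
    ultradian_period: float = 2.0
    ultradian_amp: float = 0.15
    estrous_cycle_len: int = 4
    estrous_cbt_effect: float = 0.25          # deg C on the day after the fE2 peak
    estrous_ur_suppression: float = 0.4       # fractional UR amplitude trough
    fe2_baseline: float = 10.0
    fe2_baseline_sd: float = 1.0
    fe2_cycle_profile: tuple = (1.0, 2.0, 3.0, 0.5)
    fe2_cycle_amp: float = 8.0                # pg/ml per unit of profile
    onset_day_range: tuple = (31, 36)
    noise_sd: float = 0.1
    ar1_coef: float = 0.9
    daily_level_sd: float = 0.08        # day-to-day CBT level variability
    ultradian_daily_jitter: float = 0.2  # fractional daily UR amplitude jitter
    lights_on_hour: float = 1.0
    lights_off_hour: float = 13.0
    # group-template effect sizes (free parameters; no quantitative values
    # are reported for the contraceptive temperature depression)
    contraceptive_cbt_drop: float = 0.2
    contraceptive_cr_amp_drop: float = 0.15
    ovx_cr_amp_plateau: float = 0.3
    ovx_late_decline_slope: float = -0.03     # deg C/day from p59, OVX only
    ovx_e2_ramp_window: tuple = (29.0, 36.0)  # steeper rise from capsule implantation

    def __post_init__(self) -> None:
        for name in ("circadian_amp_initial", "circadian_amp_plateau",
                     "ultradian_amp", "estrous_cbt_effect", "noise_sd",
                     "fe2_baseline_sd", "fe2_cycle_amp", "daily_level_sd",
                     "ultradian_daily_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.estrous_cycle_len not in (4, 5):
            raise ValueError("estrous_cycle_len must be 4 or 5")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if not 0 <= self.estrous_ur_suppression <= 1:
            raise ValueError("estrous_ur_suppression must be in [0, 1]")
        prof = np.asarray(self.fe2_cycle_profile)
        if prof.size != self.estrous_cycle_len or int(np.argmax(prof)) != 2:
            raise ValueError("fe2_cycle_profile must peak at position 3 (index 2)")
        if not (1.0 <= self.ultradian_period <= 3.0):
            raise ValueError("ultradian_period must lie in [1, 3] h")


@dataclass(frozen=True)
class ArtifactSpec:
    """Spike and gap injection rates for stress-testing the cleaning rules."""

    spike_rate: float = 0.0          # events/day
    spike_magnitude_sd: float = 6.0  # multiples of series SD; must exceed 4
    gap_rate: float = 0.0            # events/day, short gaps
    gap_length_min: int = 5          # < 10 by default
    long_gap_rate: float = 0.0       # events/study, length > 10 min
    long_gap_length_min: int = 30

    def __post_init__(self) -> None:
        for name in ("spike_rate", "gap_rate", "long_gap_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spike_rate > 0 and self.spike_magnitude_sd <= 4:
            raise ValueError(
                "spike_magnitude_sd must exceed 4 (smaller spikes are invisible "
                "to the 4-SD despiking rule by construction)"
            )


@dataclass
class GroundTruth:
    """What the generator actually drew for one animal."""

    animal_id: str
    group_label: str
    onset_day: int | None
    days: np.ndarray                 # postnatal days with fE2 samples
    cycle_phase: np.ndarray          # 0 = acyclic, else 1..cycle_len
    circadian_amp_by_day: np.ndarray
    ur_amp_by_day: np.ndarray
    cbt_level_by_day: np.ndarray
    fe2_clean: np.ndarray            # fE2 before measurement noise
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    def fe2_peak_days(self) -> np.ndarray:
        """Days whose generated cycle phase is the profile peak (day 3)."""
        return self.days[self.cycle_phase == 3]


@dataclass
class SimulatedAnimal:
    temperature: TemperatureSeries
    hormones: HormoneSeries
    truth: GroundTruth
    design: GroupDesign


@dataclass
class CohortBundle:
    animals: list
    designs: list
    master_seed: int

    def by_group(self, label: str) -> list:
        return [a for a in self.animals if a.design.group_label == label]


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    w = rng.normal(0.0, innov_sd, n)
    x = lfilter([1.0], [1.0, -phi], w)
    return x


def _cycle_phase_for_days(days, onset, cycle_len, cutoff=None):
    """1..cycle_len from onset (onset day is day 1); 0 before onset / after cutoff."""
    phase = np.zeros(days.size, dtype=np.int64)
    if onset is not None:
        post = days >= onset
        phase[post] = ((days[post] - onset) % cycle_len) + 1
        if cutoff is not None:
            phase[days >= cutoff] = 0
    return phase


def simulate_animal(
    design: GroupDesign,
    params: SimulationParams | None = None,
    seed: int = 0,
    animal_id: str | None = None,
) -> SimulatedAnimal:
    """Generate one animal's (TemperatureSeries, HormoneSeries, GroundTruth).

    Identical (design, params, seed) reproduce identical output.  The record
    window must span at least 10 days.
    """
    params = params or SimulationParams()
    d0, d1 = design.record_window
    if d1 - d0 < 10:
        raise ValueError("record_window must span >= 10 days")
    rng = np.random.default_rng(seed)
    aid = animal_id or f"{design.group_label}_{seed}"
    cyc = params.estrous_cycle_len
    profile = np.asarray(params.fe2_cycle_profile, dtype=float)

    cycling = design.group_label in ("Intact", "IntactC")
    onset = None
    if cycling:
        onset = int(rng.integers(params.onset_day_range[0], params.onset_day_range[1] + 1))
    cutoff = None
    if design.group_label == "IntactC" and design.contraceptive_window is not None:
        cutoff = design.contraceptive_window[0]

    days = np.arange(d0, d1)
    phase = _cycle_phase_for_days(days, onset, cyc, cutoff)

    # --- daily fE2 ---
    fe2_clean = np.full(days.size, params.fe2_baseline)
    mod = phase > 0
    fe2_clean[mod] += profile[phase[mod] - 1] * params.fe2_cycle_amp
    if cutoff is not None and onset is not None:
        # tonic level preserved after contraceptives; patterning removed
        post_c = days >= cutoff
        fe2_clean[post_c] = params.fe2_baseline + profile.mean() * params.fe2_cycle_amp
    fe2 = np.clip(fe2_clean + rng.normal(0.0, params.fe2_baseline_sd, days.size), 0.0, None)

    # --- per-day component amplitudes and levels ---
    ramp_lo, ramp_hi = params.circadian_ramp_window
    amp_plateau = params.circadian_amp_plateau
    if design.group_label == "OVX":
        amp_plateau = params.ovx_cr_amp_plateau
    elif design.group_label == "OVX_E2":
        ramp_lo, ramp_hi = params.ovx_e2_ramp_window

    def circ_amp(age_days):
        frac = np.clip((age_days - ramp_lo) / (ramp_hi - ramp_lo), 0.0, 1.0)
        amp = params.circadian_amp_initial + frac * (amp_plateau - params.circadian_amp_initial)
        if design.group_label == "IntactC" and cutoff is not None:
            amp = np.where(age_days >= cutoff,
                           np.maximum(amp - params.contraceptive_cr_amp_drop, 0.0), amp)
        return amp

    def cbt_level(age_days):
        lvl = params.baseline_cbt + params.pubertal_cbt_slope * np.clip(
            age_days - 26.0, 0.0, 41.0 - 26.0
        )
        if design.group_label == "OVX":
            lvl = lvl + params.ovx_late_decline_slope * np.clip(age_days - 59.0, 0.0, None)
        if design.group_label == "IntactC" and cutoff is not None:
            lvl = np.where(age_days >= cutoff, lvl - params.contraceptive_cbt_drop, lvl)
        return lvl

    # --- minute-resolution temperature ---
    t_min = np.arange(d0 * 1440, d1 * 1440, dtype=np.int64)
    age = t_min / 1440.0
    day_idx = (t_min // 1440) - d0
    phase_min = phase[day_idx]

    level = cbt_level(age)
    level = level + np.where(phase_min == cyc, params.estrous_cbt_effect, 0.0)
    # day-to-day physiological level variability (metabolic/behavioural state)
    if params.daily_level_sd > 0:
        level = level + rng.normal(0.0, params.daily_level_sd, days.size)[day_idx]

    peak_hour = (params.lights_off_hour + params.lights_on_hour + 24.0) / 2.0 % 24.0
    hour = (age % 1.0) * 24.0
    circadian = circ_amp(age) * np.cos(
        2.0 * np.pi * (hour - peak_hour) / params.circadian_period
    )

    ur_amp = np.full(age.size, params.ultradian_amp)
    ur_amp[phase_min == cyc] *= 1.0 - params.estrous_ur_suppression
    if params.ultradian_daily_jitter > 0:
        jitter = np.clip(
            rng.normal(1.0, params.ultradian_daily_jitter, days.size), 0.0, None)
        ur_amp = ur_amp * jitter[day_idx]
    if design.group_label == "IntactC" and cutoff is not None:
        pass  # modulation already removed via phase cutoff; mean UR amp unchanged
    ultradian = ur_amp * np.cos(2.0 * np.pi * age * 24.0 / params.ultradian_period)

    temp = level + circadian + ultradian + _ar1_noise(
        rng, age.size, params.noise_sd, params.ar1_coef
    )

    truth = GroundTruth(
        animal_id=aid,
        group_label=design.group_label,
        onset_day=onset,
        days=days,
        cycle_phase=phase,
        circadian_amp_by_day=circ_amp(days.astype(float)),
        ur_amp_by_day=np.where(phase == cyc,
                               params.ultradian_amp * (1 - params.estrous_ur_suppression),
                               params.ultradian_amp),
        cbt_level_by_day=cbt_level(days.astype(float))
        + np.where(phase == cyc, params.estrous_cbt_effect, 0.0),
        fe2_clean=fe2_clean,
        seed=int(seed),
    )
    return SimulatedAnimal(
        TemperatureSeries(aid, t_min, temp),
        HormoneSeries(aid, days, fe2),
        truth,
        design,
    )


def simulate_cohort(
    designs: list,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> CohortBundle:
    """Simulate every animal of every design with per-animal derived seeds."""
    if not designs:
        raise ValueError("need at least one group design")
    params = params or SimulationParams()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(sum(d.n_animals for d in designs))
    animals, ids = [], set()
    k = 0
    for design in designs:
        for i in range(design.n_animals):
            aid = f"{design.group_label}_{i + 1:02d}"
            if aid in ids:
                raise ValueError(f"duplicate animal id {aid!r}")
            ids.add(aid)
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            animals.append(simulate_animal(design, params, child_seed, animal_id=aid))
            k += 1
    return CohortBundle(animals, list(designs), int(seed))


@dataclass
class ArtifactRecord:
    spike_indices: np.ndarray
    gap_slices: list
    long_gap_slices: list


def inject_artifacts(
    series: TemperatureSeries, spec: ArtifactSpec, seed: int = 0
) -> tuple[TemperatureSeries, ArtifactRecord]:
    """Insert spikes and missing runs into a copy of ``series``.

    Event counts are deterministic (rate x record length, rounded) so exact
    counts can be asserted; positions are drawn from ``seed``.  Spike
    magnitude is ``spike_magnitude_sd`` series SDs (alternating sign), which
    must exceed the 4-SD despiking threshold.
    """
    if series.n == 0:
        raise ValueError("empty series")
    rng = np.random.default_rng(seed)
    out = series.copy()
    n = out.n
    days = n / 1440.0
    sd = float(np.nanstd(out.temp_c))

    n_spikes = int(round(spec.spike_rate * days))
    spike_idx = np.sort(rng.choice(n, size=min(n_spikes, n), replace=False)) if n_spikes else \
        np.array([], dtype=int)
    for k, i in enumerate(spike_idx):
        out.temp_c[i] += (1 if k % 2 == 0 else -1) * spec.spike_magnitude_sd * max(sd, 0.5)

    def _draw_gaps(count: int, length: int) -> list:
        slices = []
        for _ in range(count):
            start = int(rng.integers(1, max(2, n - length - 1)))
            slices.append(slice(start, start + length))
            out.temp_c[start : start + length] = np.nan
        return slices

    gap_slices = _draw_gaps(int(round(spec.gap_rate * days)), spec.gap_length_min)
    long_slices = _draw_gaps(int(round(spec.long_gap_rate)), spec.long_gap_length_min)
    return out, ArtifactRecord(spike_idx, gap_slices, long_slices)
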