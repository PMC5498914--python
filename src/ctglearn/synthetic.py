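"""Synthetic FHR cohort generator.

Emulates the statistical structure of an intrapartum CTG cohort so that
the full pipeline (preprocessing, feature extraction, resampling,
selection, classification, evaluation) runs without any external data:
two classes at 4 Hz, up to 90-minute records, zero-run signal dropouts,
cases with reduced short/long-term variability and more/deeper
decelerations, controls with regular accelerations.

A record is composed additively:

    baseline + AR(1) wander + band-limited variability
             + Poisson-placed trapezoidal accel/decel events
             + white observation noise

with Poisson-placed dropouts marked missing (NaN). Every inserted event
is returned as ground truth so detector recovery can be tested. One
cohort seed fans out to independent per-record streams via
``numpy.random.SeedSequence`` spawning, so cohorts are reproducible
element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import FHRRecord, ValidationError

__all__ = ["GeneratorParams", "CohortSpec", "GroundTruthEvent", "generate_record", "generate_cohort"]


@dataclass(frozen=True)
class GroundTruthEvent:
    kind: str          # "acc" or "dec"
    start_s: float
    duration_s: float  # plateau duration (time fully at amplitude)
    amplitude_bpm: float


@dataclass(frozen=True)
class GeneratorParams:
    """Per-class signal composition parameters.

    Defaults below are the control-class settings; :func:`case_params`
    returns the case-class counterpart (reduced variability, fewer
    accelerations, more and deeper decelerations) chosen so the two
    classes separate strongly but with overlap. Because the analysis
    low-passes signals at 0.034 Hz, the class contrast in short/long-term
    variability is carried mainly by the slow in-band baseline wander
    (``baseline_drift_sd``): a healthy trace wanders, a compromised one
    is flat.
    """

    baseline_bpm: float = 140.0
    baseline_drift_sd: float = 8.0     # bpm, slow AR(1) wander amplitude
    wander_tau_s: float = 120.0        # s, wander correlation time (healthy cycling)
    stv_level: float = 2.0             # bpm, band-limited high-frequency variability
    accel_rate: float = 8.0            # events / hour
    decel_rate: float = 1.5            # events / hour
    accel_amp: float = 20.0            # bpm above baseline
    decel_amp: float = 20.0            # bpm below baseline
    event_duration_s: float = 40.0     # mean plateau duration
    gap_rate: float = 4.0              # dropouts / hour
    gap_duration_s: float = 10.0       # mean dropout duration
    noise_sd: float = 1.0              # bpm, white observation noise
    between_record_sd: float = 0.8     # lognormal sigma of per-record scaling

    def validate(self) -> None:
        if not (50.0 <= self.baseline_bpm <= 210.0):
            raise ValidationError(f"baseline {self.baseline_bpm} outside [50, 210] bpm")
        for name in ("accel_rate", "decel_rate", "gap_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("accel_amp", "decel_amp"):
            if getattr(self, name) < 15.0:
                raise ValidationError(f"{name} must be >= 15 bpm to be detectable")


def case_params() -> GeneratorParams:
    """Default case-class parameters: flattened variability, sparse
    accelerations, frequent deep decelerations."""
    return GeneratorParams(
        baseline_bpm=138.0,
        baseline_drift_sd=4.0,
        wander_tau_s=240.0,  # sluggish: flatter, slowly-moving baseline
        stv_level=0.8,
        accel_rate=3.0,
        decel_rate=6.0,
        accel_amp=18.0,
        decel_amp=25.0,
        event_duration_s=50.0,
        gap_rate=4.0,
        gap_duration_s=10.0,
        noise_sd=1.0,
        between_record_sd=0.8,
    )


def well_separated_params() -> tuple[GeneratorParams, GeneratorParams]:
    """A (control, case) pair with pronounced contrast and low
    between-record heterogeneity — classes that any competent classifier
    should separate almost perfectly. Used for parameter-recovery checks
    and demos rather than as the default cohort, whose classes overlap."""
    control = GeneratorParams(between_record_sd=0.2)
    case = GeneratorParams(
        baseline_bpm=138.0,
        baseline_drift_sd=2.0,
        wander_tau_s=300.0,
        stv_level=0.5,
        accel_rate=2.0,
        decel_rate=10.0,
        accel_amp=18.0,
        decel_amp=28.0,
        event_duration_s=50.0,
        between_record_sd=0.2,
    )
    return control, case


@dataclass(frozen=True)
class CohortSpec:
    """Cohort shape: 506 controls / 46 cases by default (8.33% case prior),
    matching the class skew of the reference intrapartum database."""

    n_controls: int = 506
    n_cases: int = 46
    duration_min: float = 90.0
    fs: float = 4.0
    seed: int = 0
    control_params: GeneratorParams = field(default_factory=GeneratorParams)
    case_params: GeneratorParams = field(default_factory=case_params)
    case_group_fractions: tuple = (18 / 46, 4 / 46, 24 / 46)

    def validate(self) -> None:
        if self.n_controls < 0 or self.n_cases < 0:
            raise ValidationError("cohort counts must be >= 0")
        if not (0 < self.duration_min <= 90.0):
            raise ValidationError("duration must be in (0, 90] minutes")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")


def _ar1_wander(n: int, fs: float, sd: float, tau_s: float,
                rng: np.random.Generator) -> np.ndarray:
    """Slow baseline wander: AR(1) with correlation time ``tau_s``,
    scaled to stationary SD ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / (tau_s * fs))
    innov_sd = np.sqrt(1.0 - phi ** 2)
    w = sps.lfilter([innov_sd], [1.0, -phi], rng.standard_normal(n))
    return sd * w


def _band_limited_variability(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """High-frequency variability: white noise band-passed to 0.03-1 Hz
    (the HRV band below the 2 Hz Nyquist), rescaled to SD ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = sps.butter(2, [0.03, 1.0], btype="band", fs=fs, output="sos")
    band = sps.sosfilt(sos, white)
    scale = np.std(band)
    return sd * band / scale if scale > 0 else np.zeros(n)


def _trapezoid(n_ramp: int, n_plateau: int) -> np.ndarray:
    up = np.linspace(0.0, 1.0, n_ramp + 2)[1:-1]
    return np.concatenate([up, np.ones(n_plateau), up[::-1]])


def _place_events(
    signal: np.ndarray,
    fs: float,
    rate_per_hour: float,
    amp: float,
    mean_plateau_s: float,
    kind: str,
    rng: np.random.Generator,
    occupied: np.ndarray,
) -> list[GroundTruthEvent]:
    """Poisson-placed trapezoidal events (5-s ramps). Events that would
    overlap an earlier one (of either kind — ``occupied`` is shared) or
    run off the record are skipped, so the ground-truth list contains
    exactly the inserted events."""
    events: list[GroundTruthEvent] = []
    n = signal.size
    duration_h = n / fs / 3600.0
    n_events = rng.poisson(rate_per_hour * duration_h)
    n_ramp = int(5.0 * fs)
    starts = np.sort(rng.uniform(0.0, n / fs, size=n_events))
    for start_s in starts:
        plateau_s = max(20.0, rng.exponential(mean_plateau_s))
        n_plateau = int(round(plateau_s * fs))
        shape = _trapezoid(n_ramp, n_plateau)
        i0 = int(round(start_s * fs))
        i1 = i0 + shape.size
        if i1 > n or occupied[i0:i1].any():
            continue
        signal[i0:i1] += amp * shape if kind == "acc" else -amp * shape
        occupied[i0:i1] = True
        events.append(GroundTruthEvent(kind, start_s=i0 / fs,
                                       duration_s=n_plateau / fs, amplitude_bpm=amp))
    return events


def _place_gaps(signal: np.ndarray, fs: float, rate_per_hour: float,
                mean_duration_s: float, rng: np.random.Generator) -> None:
    n = signal.size
    n_gaps = rng.poisson(rate_per_hour * n / fs / 3600.0)
    for _ in range(n_gaps):
        dur = max(1.0 / fs, rng.exponential(mean_duration_s))
        i0 = int(rng.uniform(0, n))
        i1 = min(n, i0 + int(round(dur * fs)))
        signal[i0:i1] = np.nan


def generate_record(
    params: GeneratorParams,
    duration_min: float = 90.0,
    fs: float = 4.0,
    seed: int | np.random.SeedSequence = 0,
    record_id: str = "synthetic",
    label: str = "unknown",
) -> tuple[FHRRecord, list[GroundTruthEvent]]:
    """One synthetic record plus its ground-truth event list.

    Deterministic given the seed. With all stochastic amplitudes zero and
    zero event rates the output is a constant at ``baseline_bpm``.

    Between-subject heterogeneity: the record's variability amplitudes and
    event/gap rates are scaled by per-record lognormal factors (sigma =
    ``between_record_sd``, normalised to mean 1), so records of one class
    differ from each other the way real cohort members do and the two
    classes overlap rather than forming disjoint clusters. Event
    amplitudes are deliberately not scaled, keeping inserted events
    detector-recoverable.
    """
    params.validate()
    if duration_min <= 0:
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(seed)

    def draw_scale() -> float:
        s = params.between_record_sd
        return float(np.exp(rng.normal(-0.5 * s * s, s))) if s > 0 else 1.0

    drift_sd = params.baseline_drift_sd * draw_scale()
    stv_level = params.stv_level * draw_scale()
    accel_rate = params.accel_rate * draw_scale()
    decel_rate = params.decel_rate * draw_scale()
    event_dur = params.event_duration_s * draw_scale()
    gap_rate = params.gap_rate * draw_scale()

    n = int(round(duration_min * 60.0 * fs))
    x = np.full(n, params.baseline_bpm)
    x += _ar1_wander(n, fs, drift_sd, params.wander_tau_s, rng)
    x += _band_limited_variability(n, fs, stv_level, rng)
    occupied = np.zeros(n, dtype=bool)
    events = _place_events(x, fs, accel_rate, params.accel_amp,
                           event_dur, "acc", rng, occupied)
    events += _place_events(x, fs, decel_rate, params.decel_amp,
                            event_dur, "dec", rng, occupied)
    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, size=n)
    np.clip(x, 30.0, 240.0, out=x)
    _place_gaps(x, fs, gap_rate, params.gap_duration_s, rng)
    events.sort(key=lambda e: e.start_s)
    return FHRRecord(record_id=record_id, signal=x, fs=fs, label=label), events


def _case_ph_values(n_cases: int, fractions: tuple, rng: np.random.Generator) -> np.ndarray:
    """pH draws for case outcomes so that configurable fractions fall in
    the acidosis (<=7.20), deterioration ((7.20, 7.25]) and
    clinical-decision (>7.25) bands. Band counts use largest-remainder
    rounding so they are exact for the default 18/4/24 split at n=46."""
    raw = np.array(fractions) * n_cases
    counts = np.floor(raw).astype(int)
    remainder = n_cases - counts.sum()
    order = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[order[i % 3]] += 1
    bands = [(6.85, 7.20), (7.205, 7.25), (7.26, 7.45)]
    ph = np.concatenate([rng.uniform(lo, hi, size=c) for (lo, hi), c in zip(bands, counts)])
    return np.round(ph, 2)


def generate_cohort(spec: CohortSpec):
    """Generate a labelled cohort.

    Returns ``(records, truths, outcomes_df)``: the FHR records (controls
    first), the per-record ground-truth event lists, and a pandas frame of
    synthetic outcome rows for the cases (pH banded per the case-group
    fractions; blood-gas fields derived from pH with noise; marked
    synthetic by construction).
    """
    import pandas as pd

    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_controls + spec.n_cases
    child_seeds = root.spawn(n_total + 1)
    records, truths = [], []
    for i in range(spec.n_controls):
        rec, ev = generate_record(
            spec.control_params, spec.duration_min, spec.fs, child_seeds[i],
            record_id=f"ctrl{i + 1:04d}", label="control",
        )
        records.append(rec)
        truths.append(ev)
    for j in range(spec.n_cases):
        rec, ev = generate_record(
            spec.case_params, spec.duration_min, spec.fs, child_seeds[spec.n_controls + j],
            record_id=f"case{j + 1:04d}", label="case",
        )
        records.append(rec)
        truths.append(ev)

    rng = np.random.default_rng(child_seeds[-1])
    ph = _case_ph_values(spec.n_cases, spec.case_group_fractions, rng)
    rng.shuffle(ph)
    # blood gas panel loosely consistent with pH: BDecf rises ~60 mmol/l
    # per pH unit below 7.35, BE ~ -BDecf, Apgar lower in acidosis
    bdecf = np.round(np.maximum(-1.0, (7.35 - ph) * 60.0 + rng.normal(0, 2, spec.n_cases)), 2)
    outcomes = pd.DataFrame(
        {
            "id": np.arange(2001, 2001 + spec.n_cases),
            "age": rng.integers(18, 43, spec.n_cases),
            "pH": ph,
            "BDecf": bdecf,
            "pCO2": np.round(rng.uniform(4.8, 12.0, spec.n_cases), 1),
            "BE": np.round(-bdecf + rng.normal(0, 1, spec.n_cases), 1),
            "apgar1": np.clip(np.round(10 - bdecf / 4 + rng.normal(0, 1, spec.n_cases)), 0, 10).astype(int),
            "apgar5": np.clip(np.round(10 - bdecf / 6 + rng.normal(0, 1, spec.n_cases)), 0, 10).astype(int),
            "dev_type": 2,
        }
    )
    return records, truths, outcomes
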