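"""Synthetic multi-visit 12-lead ECG cohorts.

Emulates the structure patient-contrastive pre-training relies on: each
patient has a stable morphological signature (a parametric P-QRS-T beat
template) while individual visits vary in heart rate, baseline wander,
muscle-artifact noise and, for susceptible patients, an intermittent
atrial-fibrillation-like rhythm (irregular RR intervals, absent P wave).

The beat template is a sum of Gaussians — one per P, Q, R, S, T wave — on
a 3-component "dipole", projected to 12 correlated leads through a fixed
full-rank mixing matrix. Amplitudes are emitted as 16-bit integers in
microvolts, 10 s per record at 250 or 500 Hz.

Labels of both kinds used by downstream probes are attached:
patient-stable (``sex_like``, ``hypertrophy_like`` — the latter a
deterministic threshold on the per-patient R-amplitude scale) and
per-record (``age``, ``af_active``, ``heart_rate``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .errors import CohortFormatError, InvalidSamplingRateError

LEAD_NAMES = ("I", "II", "III", "AVR", "AVL", "AVF",
              "V1", "V2", "V3", "V4", "V5", "V6")
WAVES = ("P", "Q", "R", "S", "T")
SUPPORTED_RATES = (250, 500)
RECORD_SECONDS = 10.0

# Canonical single-beat wave parameters: amplitude (mV), Gaussian width
# sigma (s), centre time relative to the R peak (s).
BASE_AMP = {"P": 0.12, "Q": -0.12, "R": 1.0, "S": -0.25, "T": 0.35}
BASE_SIGMA = {"P": 0.020, "Q": 0.012, "R": 0.018, "S": 0.014, "T": 0.060}
WAVE_TIME = {"P": -0.16, "Q": -0.035, "R": 0.0, "S": 0.035, "T": 0.30}

# Direction of each wave's dipole contribution (3-vector, unnormalised).
WAVE_DIR = {
    "P": np.array([0.4, 0.8, 0.2]),
    "Q": np.array([0.7, 0.5, 0.4]),
    "R": np.array([0.8, 0.5, 0.3]),
    "S": np.array([0.6, 0.4, 0.6]),
    "T": np.array([0.6, 0.6, 0.2]),
}

# Fixed 12 x 3 lead-mixing matrix (full rank). Limb leads follow the
# Einthoven/Goldberger relations on the frontal (x, y) components; the
# precordial leads rotate from the anterior (z-heavy) to the lateral
# (x-heavy) direction.
_I = np.array([1.0, 0.0, 0.0])
_II = np.array([0.5, 0.87, 0.0])
_III = _II - _I
LEAD_MATRIX = np.stack([
    _I, _II, _III,
    -(_I + _II) / 2.0,          # AVR
    (_I - _III) / 2.0,          # AVL
    (_II + _III) / 2.0,         # AVF
    np.array([-0.4, -0.10, 0.90]),   # V1
    np.array([-0.2, 0.00, 1.00]),    # V2
    np.array([0.2, 0.10, 0.90]),     # V3
    np.array([0.6, 0.20, 0.70]),     # V4
    np.array([0.9, 0.20, 0.40]),     # V5
    np.array([1.0, 0.15, 0.10]),     # V6
])

# Per-lead baseline-wander gain: wander is a body-surface artifact, so it
# is applied after lead projection with lead-specific magnitude.
LEAD_WANDER_GAIN = np.array(
    [1.0, 0.8, 0.9, 0.7, 0.85, 0.75, 1.1, 1.2, 1.0, 0.9, 0.8, 0.7])

HYPERTROPHY_THRESHOLD = 1.25   # on amplitude_scale; deterministic label
INT16_MIN, INT16_MAX = -32768, 32767


@dataclass(frozen=True)
class PatientSignature:
    """Patient-stable morphology parameters, drawn once per patient."""

    patient_id: str
    sex_like: int                  # binary; shifts T amplitude and HR
    baseline_age: float            # years at first visit
    amplitude_scale: float         # R-wave scaling, > 0
    wave_amp_offset: dict          # additive mV offset per wave
    wave_sigma_mult: dict          # multiplicative width factor per wave
    wave_time_jitter: dict         # additive centre shift (s) per wave
    hypertrophy_like: bool         # amplitude_scale > HYPERTROPHY_THRESHOLD
    af_propensity: float           # visit-level probability of AF rhythm
    hr_baseline: float             # beats/min

    def __post_init__(self):
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if not 0.0 <= self.af_propensity <= 1.0:
            raise ValueError("af_propensity must lie in [0, 1]")


@dataclass(frozen=True)
class VisitSpec:
    """Per-visit acquisition parameters."""

    record_id: str
    days_since_first: float
    heart_rate: float
    noise_level: float             # white-noise sigma, mV
    baseline_wander_amp: float     # wander amplitude, mV
    af_active: bool
    age_at_visit: float
    sampling_rate: int

    def __post_init__(self):
        if self.sampling_rate not in SUPPORTED_RATES:
            raise InvalidSamplingRateError(
                f"sampling rate {self.sampling_rate} Hz not in "
                f"{SUPPORTED_RATES}")

    @property
    def n_samples(self) -> int:
        return int(round(RECORD_SECONDS * self.sampling_rate))


@dataclass
class RawECG:
    """One acquisition: integer microvolt amplitudes per lead."""

    record_id: str
    patient_id: str
    sampling_rate: int
    leads: dict                    # lead name -> int16 array, microvolts
    acquisition_day: float = 0.0
    labels: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


@dataclass
class PatientGroup:
    """A patient identifier with its ordered visits."""

    patient_id: str
    records: list
    signature: PatientSignature | None = None


@dataclass
class Cohort:
    """An ordered collection of patient groups."""

    groups: list

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)

    @property
    def n_records(self) -> int:
        return sum(len(g.records) for g in self.groups)

    def all_records(self):
        for g in self.groups:
            yield from g.records

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for r in g.records:
                rows.append({
                    "patient_id": r.patient_id,
                    "record_id": r.record_id,
                    "acquisition_day": r.acquisition_day,
                    "age": r.labels.get("age"),
                    "sex_like": r.labels.get("sex_like"),
                    "hypertrophy_like": r.labels.get("hypertrophy_like"),
                    "af_active": r.labels.get("af_active"),
                    "heart_rate": r.labels.get("heart_rate"),
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortParams:
    """Generator defaults: the stated world of the synthetic cohort.

    Visit gaps are uniform in [30, 500] days (mean 265, matching a
    real-world mean inter-ECG gap on the order of 260 days). Noise and
    wander levels span clean to moderately artifacted routine recordings.
    """

    min_visits: int = 2
    max_visits: int = 4
    visit_gap_days: tuple = (30.0, 500.0)
    age_range: tuple = (25.0, 80.0)
    amplitude_scale_sigma: float = 0.3    # lognormal sigma
    amp_offset_frac: float = 0.15         # per-wave amplitude offset scale
    sigma_mult_sigma: float = 0.08        # lognormal width-multiplier sigma
    time_jitter_sd: float = 0.006         # s
    af_carrier_fraction: float = 0.2
    af_propensity_range: tuple = (0.3, 1.0)
    hr_baseline_range: tuple = (60.0, 85.0)
    hr_visit_jitter_sd: float = 5.0
    sex_hr_offset: float = 3.0            # beats/min added when sex_like=1
    hr_limits: tuple = (45.0, 110.0)
    noise_level_range: tuple = (0.05, 0.25)      # mV
    wander_amp_range: tuple = (0.05, 0.40)       # mV
    wander_freq_range: tuple = (0.15, 0.35)      # Hz
    sampling_rates: tuple = SUPPORTED_RATES
    af_rr_cv: float = 0.25                # lognormal CV of RR in AF
    min_af_rr_cv: float = 0.15            # enforced in-sample

    def __post_init__(self):
        for r in self.sampling_rates:
            if r not in SUPPORTED_RATES:
                raise InvalidSamplingRateError(
                    f"sampling rate {r} Hz not in {SUPPORTED_RATES}")


def wave_params(signature: PatientSignature, af_active: bool = False) -> dict:
    """Resolved per-wave (amplitude mV, sigma s, centre s) for a patient.

    The R amplitude carries the patient's ``amplitude_scale`` (the
    hypertrophy-like criterion); ``sex_like`` modulates T amplitude and
    QRS width; an active AF rhythm zeroes the P wave.
    """
    t_mult = 0.85 if signature.sex_like else 1.15
    qrs_w = 0.97 if signature.sex_like else 1.03
    params = {}
    for w in WAVES:
        amp = BASE_AMP[w] + signature.wave_amp_offset[w]
        if w == "R":
            amp *= signature.amplitude_scale
        if w == "T":
            amp *= t_mult
        sigma = BASE_SIGMA[w] * signature.wave_sigma_mult[w]
        if w in ("Q", "R", "S"):
            sigma *= qrs_w
        if w == "P" and af_active:
            amp = 0.0
        centre = WAVE_TIME[w] + signature.wave_time_jitter[w]
        params[w] = (amp, sigma, centre)
    return params


def _dipole_at(phase: np.ndarray, params: dict, period: float | None) -> np.ndarray:
    """Dipole (n, 3) at times ``phase`` (s, relative to an R peak).

    With ``period`` set, Gaussians are evaluated on the wrapped distance so
    the beat is exactly periodic (noiseless records repeat circularly).
    """
    out = np.zeros((phase.size, 3))
    for w in WAVES:
        amp, sigma, centre = params[w]
        if amp == 0.0:
            continue
        d = phase - centre
        if period is not None:
            d = (d + period / 2.0) % period - period / 2.0
        out += amp * np.exp(-0.5 * (d / sigma) ** 2)[:, None] * WAVE_DIR[w]
    return out


def _draw_signature(pid: str, rng: np.random.Generator,
                    params: CohortParams) -> PatientSignature:
    sex_like = int(rng.integers(0, 2))
    baseline_age = float(rng.uniform(*params.age_range))
    amplitude_scale = float(np.exp(rng.normal(0.0, params.amplitude_scale_sigma)))
    amp_off = {w: float(rng.normal(0.0, params.amp_offset_frac * abs(BASE_AMP[w])))
               for w in WAVES}
    sig_mult = {w: float(np.exp(rng.normal(0.0, params.sigma_mult_sigma)))
                for w in WAVES}
    jitter = {w: (0.0 if w == "R"
                  else float(rng.normal(0.0, params.time_jitter_sd)))
              for w in WAVES}
    if rng.random() < params.af_carrier_fraction:
        af_propensity = float(rng.uniform(*params.af_propensity_range))
    else:
        af_propensity = 0.0
    hr_baseline = float(rng.uniform(*params.hr_baseline_range))
    if sex_like:
        hr_baseline += params.sex_hr_offset
    return PatientSignature(
        patient_id=pid, sex_like=sex_like, baseline_age=baseline_age,
        amplitude_scale=amplitude_scale, wave_amp_offset=amp_off,
        wave_sigma_mult=sig_mult, wave_time_jitter=jitter,
        hypertrophy_like=bool(amplitude_scale > HYPERTROPHY_THRESHOLD),
        af_propensity=af_propensity, hr_baseline=hr_baseline)


def _af_beat_times(rng: np.random.Generator, mean_rr: float, duration: float,
                   cv: float, min_cv: float) -> np.ndarray:
    """Irregular R-peak times covering [-1, duration + 1] s.

    Lognormal RR intervals; redrawn until the realised coefficient of
    variation reaches ``min_cv`` so the AF contract holds per record.
    """
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    mu = np.log(mean_rr) - sigma ** 2 / 2.0
    n = int(np.ceil((duration + 2.0) / mean_rr)) + 4
    for _ in range(1000):
        rr = rng.lognormal(mu, sigma, size=n)
        if rr.std() / rr.mean() >= min_cv:
            break
    start = -rng.uniform(0.0, rr[0])
    beats = start + np.concatenate([[0.0], np.cumsum(rr)])
    return beats[beats < duration + 1.0], rr


def _render_record(signature: PatientSignature, visit: VisitSpec,
                   rng: np.random.Generator, params: CohortParams) -> RawECG:
    n = visit.n_samples
    t = np.arange(n) / visit.sampling_rate
    period = 60.0 / visit.heart_rate
    wp = wave_params(signature, af_active=visit.af_active)
    meta = {}
    if visit.af_active:
        beats, rr = _af_beat_times(rng, period, RECORD_SECONDS,
                                   params.af_rr_cv, params.min_af_rr_cv)
        dipole = np.zeros((n, 3))
        for b in beats:
            dipole += _dipole_at(t - b, wp, period=None)
        meta["rr_intervals"] = rr
    else:
        phase0 = rng.uniform(0.0, period)
        dipole = _dipole_at((t + phase0) % period, wp, period=period)
    sig_mv = dipole @ LEAD_MATRIX.T        # (n, 12), millivolts

    if visit.baseline_wander_amp > 0:
        f = rng.uniform(*params.wander_freq_range)
        phi = rng.uniform(0.0, 2 * np.pi)
        wander = visit.baseline_wander_amp * np.sin(2 * np.pi * f * t + phi)
        sig_mv = sig_mv + wander[:, None] * LEAD_WANDER_GAIN[None, :]
    if visit.noise_level > 0:
        sig_mv = sig_mv + rng.normal(0.0, visit.noise_level, size=sig_mv.shape)

    uv = np.clip(np.rint(sig_mv * 1000.0), INT16_MIN, INT16_MAX).astype(np.int16)
    leads = {name: uv[:, j].copy() for j, name in enumerate(LEAD_NAMES)}
    labels = {
        "age": visit.age_at_visit,
        "sex_like": signature.sex_like,
        "hypertrophy_like": int(signature.hypertrophy_like),
        "af_active": int(visit.af_active),
        "heart_rate": visit.heart_rate,
    }
    return RawECG(record_id=visit.record_id, patient_id=signature.patient_id,
                  sampling_rate=visit.sampling_rate, leads=leads,
                  acquisition_day=visit.days_since_first, labels=labels,
                  meta=meta)


def visit_template(signature: PatientSignature, heart_rate: float = 60.0,
                   n_samples: int = 256, af_active: bool = False) -> np.ndarray:
    """Clean single-beat 12-lead template (n_samples, 12) in mV.

    One beat period at the given heart rate, noiseless; patient-stable
    morphology only, so two visits of one patient differ solely via heart
    rate. Useful for separability and label-realizability checks.
    """
    period = 60.0 / heart_rate
    phase = np.linspace(0.0, period, n_samples, endpoint=False)
    wp = wave_params(signature, af_active=af_active)
    return _dipole_at(phase, wp, period=period) @ LEAD_MATRIX.T


def generate_cohort(n_patients: int, visits_per_patient=None, seed: int = 0,
                    params: CohortParams | None = None) -> Cohort:
    """Generate a seeded multi-visit cohort.

    ``visits_per_patient`` is an int (constant), an (lo, hi) inclusive
    tuple drawn uniformly, or None for the params' default range.
    The same seed reproduces the cohort bit-exactly.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params = params or CohortParams()
    if visits_per_patient is None:
        lo, hi = params.min_visits, params.max_visits
    elif isinstance(visits_per_patient, int):
        lo = hi = visits_per_patient
    else:
        lo, hi = visits_per_patient
    if lo < 1:
        raise ValueError("visit counts must be >= 1")

    ss = np.random.SeedSequence(seed)
    groups = []
    for i, child in enumerate(ss.spawn(n_patients)):
        rng = np.random.default_rng(child)
        pid = f"P{i:05d}"
        sig = _draw_signature(pid, rng, params)
        n_visits = int(rng.integers(lo, hi + 1))
        records, day = [], 0.0
        for v in range(n_visits):
            if v > 0:
                day += float(rng.uniform(*params.visit_gap_days))
            hr = float(np.clip(
                sig.hr_baseline + rng.normal(0.0, params.hr_visit_jitter_sd),
                *params.hr_limits))
            visit = VisitSpec(
                record_id=f"{pid}R{v:02d}",
                days_since_first=day,
                heart_rate=hr,
                noise_level=float(rng.uniform(*params.noise_level_range)),
                baseline_wander_amp=float(rng.uniform(*params.wander_amp_range)),
                af_active=bool(rng.random() < sig.af_propensity),
                age_at_visit=sig.baseline_age + day / 365.25,
                sampling_rate=int(rng.choice(params.sampling_rates)),
            )
            records.append(_render_record(sig, visit, rng, params))
        groups.append(PatientGroup(patient_id=pid, records=records,
                                   signature=sig))
    return Cohort(groups)


# ---------------------------------------------------------------------------
# Storage: HDF5 amplitude store + metadata CSV, one directory per cohort.

H5_NAME = "cohort.h5"
CSV_NAME = "metadata.csv"


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write a cohort to ``path`` (directory): cohort.h5 + metadata.csv.

    HDF5 layout: one group per record named by record_id, one int16
    dataset per lead named by the lead label; group attributes
    patient_id, record_id, sampling_rate_hz.
    """
    os.makedirs(path, exist_ok=True)
    with h5py.File(os.path.join(path, H5_NAME), "w") as f:
        for rec in cohort.all_records():
            g = f.create_group(rec.record_id)
            g.attrs["patient_id"] = rec.patient_id
            g.attrs["record_id"] = rec.record_id
            g.attrs["sampling_rate_hz"] = rec.sampling_rate
            for lead, arr in rec.leads.items():
                g.create_dataset(lead, data=arr)
    cohort.metadata_frame().to_csv(os.path.join(path, CSV_NAME), index=False)


def read_cohort(path: str) -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    Raises :class:`CohortFormatError` naming the offending record for a
    missing lead, a metadata row without an amplitude group, or a
    patient-id mismatch between the metadata table and the HDF5 store.
    """
    csv_path = os.path.join(path, CSV_NAME)
    h5_path = os.path.join(path, H5_NAME)
    if not (os.path.exists(csv_path) and os.path.exists(h5_path)):
        raise CohortFormatError(f"no cohort at {path!r}")
    meta = pd.read_csv(csv_path)
    groups: dict[str, PatientGroup] = {}
    with h5py.File(h5_path, "r") as f:
        for row in meta.itertuples(index=False):
            rid, pid = str(row.record_id), str(row.patient_id)
            if rid not in f:
                raise CohortFormatError(
                    f"metadata row for record {rid!r} has no amplitude group")
            g = f[rid]
            if str(g.attrs["patient_id"]) != pid:
                raise CohortFormatError(
                    f"record {rid!r}: metadata patient_id {pid!r} does not "
                    f"match stored patient_id {g.attrs['patient_id']!r}")
            leads = {}
            for lead in LEAD_NAMES:
                if lead not in g:
                    raise CohortFormatError(
                        f"record {rid!r} is missing lead {lead!r}")
                leads[lead] = g[lead][:]
            rec = RawECG(
                record_id=rid, patient_id=pid,
                sampling_rate=int(g.attrs["sampling_rate_hz"]), leads=leads,
                acquisition_day=float(row.acquisition_day),
                labels={
                    "age": float(row.age),
                    "sex_like": int(row.sex_like),
                    "hypertrophy_like": int(row.hypertrophy_like),
                    "af_active": int(row.af_active),
                    "heart_rate": float(row.heart_rate),
                })
            groups.setdefault(pid, PatientGroup(pid, [])).records.append(rec)
    return Cohort(list(groups.values()))
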