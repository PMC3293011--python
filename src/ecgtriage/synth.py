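"""Seeded generation of labeled synthetic 12-lead ECG cohorts.

Each record is built from a sum-of-five-Gaussians beat template (P, Q, R, S, T
deflections) repeated at the configured heart rate on the eight independent
leads (I, II, V1..V6); the four remaining limb leads are derived through the
Einthoven/Goldberger relations, so the standard linear lead identities hold
exactly on every generated record. ST-elevation cases add a raised-cosine
tapered offset from the J point through the end of the T wave in a coronary
territory's leads, with per-lead magnitudes at or above the clinical
criterion thresholds (0.2 mV in V1-V3, 0.1 mV elsewhere, at standard
calibration 1 mm = 0.1 mV). Ground-truth labels (STEMI yes/no, needs acute
PCI yes/no) are assigned by the generator and never depend on any
downstream classifier.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)
#: The eight electrically independent leads; III, aVR, aVL, aVF are derived.
BASE_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

TERRITORIES: tuple[str, ...] = ("anterior", "inferior", "lateral")

#: Leads conventionally read for each infarct territory.
TERRITORY_LEADS: dict[str, tuple[str, ...]] = {
    "anterior": ("V1", "V2", "V3", "V4"),
    "inferior": ("II", "III", "aVF"),
    "lateral": ("I", "aVL", "V5", "V6"),
}

#: ST criterion threshold per lead, mV (2 mm in V1-V3, 1 mm elsewhere).
def criterion_threshold(lead: str) -> float:
    return 0.2 if lead in ("V1", "V2", "V3") else 0.1


WAVES: tuple[str, ...] = ("P", "Q", "R", "S", "T")

#: Shared Gaussian centers (s within the beat) and widths (s).
DEFAULT_WAVE_CENTERS: dict[str, float] = {
    "P": 0.18, "Q": 0.355, "R": 0.38, "S": 0.405, "T": 0.60,
}
DEFAULT_WAVE_WIDTHS: dict[str, float] = {
    "P": 0.025, "Q": 0.010, "R": 0.015, "S": 0.010, "T": 0.055,
}

#: Typical adult amplitudes (mV) per independent lead.
DEFAULT_WAVE_AMPLITUDES: dict[str, dict[str, float]] = {
    "I":  {"P": 0.08, "Q": -0.05, "R": 0.70, "S": -0.12, "T": 0.25},
    "II": {"P": 0.12, "Q": -0.08, "R": 1.05, "S": -0.15, "T": 0.35},
    "V1": {"P": 0.05, "Q": 0.00, "R": 0.30, "S": -0.80, "T": 0.10},
    "V2": {"P": 0.06, "Q": 0.00, "R": 0.55, "S": -0.70, "T": 0.40},
    "V3": {"P": 0.07, "Q": -0.03, "R": 0.90, "S": -0.45, "T": 0.45},
    "V4": {"P": 0.08, "Q": -0.06, "R": 1.40, "S": -0.30, "T": 0.40},
    "V5": {"P": 0.08, "Q": -0.08, "R": 1.25, "S": -0.20, "T": 0.35},
    "V6": {"P": 0.07, "Q": -0.07, "R": 1.00, "S": -0.15, "T": 0.30},
}


class InvalidParameterError(ValueError):
    """A generator or configuration parameter is out of its valid range."""


class ParseError(ValueError):
    """A record file could not be parsed."""


@dataclass(frozen=True)
class ECGRecord:
    """One 12-lead ECG: voltages in mV, rows ordered as :data:`LEAD_NAMES`."""

    samples: np.ndarray          # (12, n_samples), mV
    sampling_rate: float         # Hz
    record_id: str = ""
    lead_names: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if self.lead_names != LEAD_NAMES or s.shape[0] != 12:
            raise InvalidParameterError("record must have the 12 standard leads in order")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be positive")
        if s.shape[1] < 2 * self.sampling_rate:
            raise InvalidParameterError("record must be at least 2 s long")
        if not np.all(np.isfinite(s)):
            raise InvalidParameterError("voltages must be finite")

    def lead(self, name: str) -> np.ndarray:
        return self.samples[LEAD_NAMES.index(name)]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class CaseLabel:
    """Generator-assigned ground truth for one case."""

    stemi: bool
    needs_acute_pci: bool
    territory: str                      # anterior | inferior | lateral | none
    st_offsets: Mapping[str, float]     # lead -> injected peak ST shift, mV

    def __post_init__(self):
        if self.territory not in TERRITORIES + ("none",):
            raise InvalidParameterError(f"unknown territory {self.territory!r}")
        # NaN marks an unknown (deserialized) nonzero offset.
        any_offset = any(v != 0 for v in self.st_offsets.values())
        if (self.territory == "none") == any_offset:
            raise InvalidParameterError("territory 'none' iff all ST offsets are zero")
        if self.territory == "none" and self.stemi:
            raise InvalidParameterError("no-territory case cannot be STEMI")


@dataclass(frozen=True)
class BeatGeometry:
    """Timing hints for ST injection: beat period and in-beat phases (s)."""

    period: float
    j_point: float
    t_end: float


@dataclass
class SynthConfig:
    """Cohort-level generator settings.

    Defaults emulate an ambulance chest-pain cohort: n=560 with STEMI
    prevalence 38/560 (~7%) and an acute-PCI prevalence near 6% via the
    conditional probabilities, 10 s records at 500 Hz and 60 bpm.
    """

    n_cases: int = 560
    stemi_prevalence: float = 38 / 560
    p_pci_given_stemi: float = 0.9
    p_pci_given_nonstemi: float = 0.01
    heart_rate: float = 60.0
    sampling_rate: float = 500.0
    duration: float = 10.0
    wave_amplitudes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_WAVE_AMPLITUDES.items()})
    wave_centers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WAVE_CENTERS))
    wave_widths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WAVE_WIDTHS))
    st_magnitude_range: tuple[float, float] = (0.15, 0.40)
    st_margin: float = 0.05              # headroom above criterion threshold, mV
    noise_sd: float = 0.02               # white noise, mV
    baseline_wander: tuple[float, float] = (0.05, 0.33)  # amplitude mV, freq Hz
    amplitude_jitter_sd: float = 0.10    # relative, per wave per lead per record
    heart_rate_jitter_sd: float = 0.03   # relative, per record
    limb_gain: float = 1.0               # proximal-placement emulation, test cohorts
    limb_offset: float = 0.0             # additive limb perturbation, mV
    seed: int = 0

    def validate(self) -> None:
        for name in ("stemi_prevalence", "p_pci_given_stemi", "p_pci_given_nonstemi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_cases < 1:
            raise InvalidParameterError("n_cases must be >= 1")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        lo, hi = self.st_magnitude_range
        if lo > hi:
            raise InvalidParameterError("st_magnitude_range min must be <= max")
        if self.sampling_rate <= 0 or self.heart_rate <= 0 or self.duration < 2.0:
            raise InvalidParameterError("sampling_rate/heart_rate positive, duration >= 2 s")

    def beat_geometry(self, heart_rate: float | None = None) -> BeatGeometry:
        """Analytic J point and T end of the noise-free template."""
        hr = self.heart_rate if heart_rate is None else heart_rate
        j = self.wave_centers["S"] + 3.0 * self.wave_widths["S"]
        t_end = self.wave_centers["T"] + 3.0 * self.wave_widths["T"]
        return BeatGeometry(period=60.0 / hr, j_point=j, t_end=t_end)


def synth_beat_template(wave_params: Mapping[str, tuple[float, float, float]],
                        sampling_rate: float, beat_duration: float) -> np.ndarray:
    """Sum of Gaussian deflections evaluated on a uniform time grid.

    ``wave_params`` maps wave name to (amplitude mV, center s, width s).
    """
    if sampling_rate <= 0:
        raise InvalidParameterError("sampling_rate must be positive")
    n = int(round(beat_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    out = np.zeros(n)
    for name, (amp, center, width) in wave_params.items():
        if width <= 0:
            raise InvalidParameterError(f"width of wave {name!r} must be positive")
        if not 0.0 <= center <= beat_duration:
            raise InvalidParameterError(f"center of wave {name!r} outside the beat")
        out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return out


def derive_limb_leads(lead_i: np.ndarray, lead_ii: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Einthoven/Goldberger derivations: (III, aVR, aVL, aVF) from I and II."""
    lead_i = np.asarray(lead_i, dtype=float)
    lead_ii = np.asarray(lead_ii, dtype=float)
    if lead_i.shape != lead_ii.shape:
        raise ValueError(f"lead length mismatch: {lead_i.shape} vs {lead_ii.shape}")
    iii = lead_ii - lead_i
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return iii, avr, avl, avf


def _assemble_record(base: dict[str, np.ndarray], sampling_rate: float,
                     record_id: str) -> ECGRecord:
    iii, avr, avl, avf = derive_limb_leads(base["I"], base["II"])
    rows = {"III": iii, "aVR": avr, "aVL": avl, "aVF": avf, **base}
    samples = np.vstack([rows[name] for name in LEAD_NAMES])
    return ECGRecord(samples=samples, sampling_rate=sampling_rate, record_id=record_id)


def _st_pulse(geometry: BeatGeometry, sampling_rate: float, n_samples: int,
              taper: float = 0.020) -> np.ndarray:
    """Unit-height ST offset train: plateau J..T-end with raised-cosine ramps."""
    n_beat = int(round(geometry.period * sampling_rate))
    t = np.arange(n_beat) / sampling_rate
    start, stop = geometry.j_point - taper, geometry.t_end + taper
    pulse = np.zeros(n_beat)
    plateau = (t >= geometry.j_point) & (t <= geometry.t_end)
    pulse[plateau] = 1.0
    rise = (t >= start) & (t < geometry.j_point)
    pulse[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - start) / taper))
    fall = (t > geometry.t_end) & (t <= stop)
    pulse[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - geometry.t_end) / taper))
    reps = math.ceil(n_samples / n_beat)
    return np.tile(pulse, reps)[:n_samples]


#: Injection coefficients on the independent leads realising each territory.
#: Inferior elevation is produced through the limb derivations: dI=-m, dII=+m
#: gives III=+2m and aVF=+1.5m with reciprocal aVL depression.
_TERRITORY_BASE_COEFF: dict[str, dict[str, float]] = {
    "anterior": {"V1": 1.0, "V2": 1.0, "V3": 1.0, "V4": 1.0},
    "inferior": {"I": -1.0, "II": 1.0},
    "lateral": {"I": 1.0, "V5": 1.0, "V6": 1.0},
}


def territory_st_offsets(territory: str, magnitudes: Mapping[str, float]
                         ) -> dict[str, float]:
    """Realised peak ST offset on all 12 leads for base-lead ``magnitudes``."""
    base = {lead: 0.0 for lead in BASE_LEADS}
    for lead, coeff in _TERRITORY_BASE_COEFF[territory].items():
        base[lead] = coeff * magnitudes.get(lead, 0.0)
    d_iii = base["II"] - base["I"]
    d_avr = -(base["I"] + base["II"]) / 2.0
    d_avl = base["I"] - base["II"] / 2.0
    d_avf = base["II"] - base["I"] / 2.0
    return {**base, "III": d_iii, "aVR": d_avr, "aVL": d_avl, "aVF": d_avf}


def inject_st_elevation(record: ECGRecord, territory: str,
                        magnitude: float | Mapping[str, float],
                        geometry: BeatGeometry) -> ECGRecord:
    """Add a tapered ST offset in a territory's leads of every beat.

    ``magnitude`` is either one peak offset (mV) applied to every base lead
    of the territory, or a map base-lead -> magnitude. Limb-lead identities
    are re-established by recomputing III/aVR/aVL/aVF from the perturbed
    I and II.
    """
    if territory not in _TERRITORY_BASE_COEFF:
        raise InvalidParameterError(f"unknown territory {territory!r}")
    coeffs = _TERRITORY_BASE_COEFF[territory]
    if isinstance(magnitude, Mapping):
        mags = dict(magnitude)
    else:
        if magnitude < 0:
            raise InvalidParameterError("magnitude must be >= 0")
        mags = {lead: float(magnitude) for lead in coeffs}
    pulse = _st_pulse(geometry, record.sampling_rate, record.n_samples)
    base = {lead: record.lead(lead).copy() for lead in BASE_LEADS}
    for lead, coeff in coeffs.items():
        base[lead] += coeff * mags.get(lead, 0.0) * pulse
    return _assemble_record(base, record.sampling_rate, record.record_id)


def _case_rng(config_seed: int, case_seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed & 0x7FFFFFFF,
                                                         case_seed & 0x7FFFFFFF]))


def generate_case(config: SynthConfig, case_seed: int) -> tuple[ECGRecord, CaseLabel]:
    """One reproducible labeled case; identical output for fixed seeds."""
    config.validate()
    rng = _case_rng(config.seed, case_seed)

    stemi = bool(rng.random() < config.stemi_prevalence)
    territory = str(rng.choice(TERRITORIES)) if stemi else "none"
    p_pci = config.p_pci_given_stemi if stemi else config.p_pci_given_nonstemi
    pci = bool(rng.random() < p_pci)

    hr = config.heart_rate * float(1.0 + rng.normal(0.0, config.heart_rate_jitter_sd))
    hr = float(np.clip(hr, 0.8 * config.heart_rate, 1.2 * config.heart_rate))
    geometry = config.beat_geometry(hr)
    n_beat = int(round(geometry.period * config.sampling_rate))
    n_samples = int(round(config.duration * config.sampling_rate))
    reps = math.ceil(n_samples / n_beat)

    base: dict[str, np.ndarray] = {}
    for lead in BASE_LEADS:
        amps = config.wave_amplitudes[lead]
        jitter = 1.0 + rng.normal(0.0, config.amplitude_jitter_sd, size=len(WAVES))
        params = {w: (amps[w] * jitter[i], config.wave_centers[w], config.wave_widths[w])
                  for i, w in enumerate(WAVES)}
        beat = synth_beat_template(params, config.sampling_rate, geometry.period)
        base[lead] = np.tile(beat, reps)[:n_samples]

    st_offsets = {lead: 0.0 for lead in LEAD_NAMES}
    if stemi:
        m_base = float(rng.uniform(*config.st_magnitude_range))
        mags: dict[str, float] = {}
        for lead in _TERRITORY_BASE_COEFF[territory]:
            floor = criterion_threshold(lead) + config.st_margin
            mags[lead] = max(m_base * float(rng.uniform(0.9, 1.1)), floor)
        pulse = _st_pulse(geometry, config.sampling_rate, n_samples)
        for lead, coeff in _TERRITORY_BASE_COEFF[territory].items():
            base[lead] += coeff * mags[lead] * pulse
        st_offsets = territory_st_offsets(territory, mags)

    # Wander and noise go on the independent leads only, so the Einthoven/
    # Goldberger identities survive derivation.
    amp_w, freq_w = config.baseline_wander
    t = np.arange(n_samples) / config.sampling_rate
    for lead in BASE_LEADS:
        if amp_w > 0:
            phase = rng.uniform(0, 2 * np.pi)
            base[lead] += amp_w * np.sin(2 * np.pi * freq_w * t + phase)
        if config.noise_sd > 0:
            base[lead] += rng.normal(0.0, config.noise_sd, size=n_samples)

    record = _assemble_record(base, config.sampling_rate, f"rec{case_seed:05d}")
    if config.limb_gain != 1.0 or config.limb_offset != 0.0:
        # Proximal limb placement emulation: perturb I and II, re-derive.
        pert = {lead: record.lead(lead).copy() for lead in BASE_LEADS}
        for lead in ("I", "II"):
            pert[lead] = config.limb_gain * pert[lead] + config.limb_offset
        record = _assemble_record(pert, config.sampling_rate, record.record_id)

    label = CaseLabel(stemi=stemi, needs_acute_pci=pci, territory=territory,
                      st_offsets=st_offsets)
    return record, label


def generate_cohort(config: SynthConfig) -> list[tuple[ECGRecord, CaseLabel]]:
    """``n_cases`` independent cases; fully reproducible under a fixed seed."""
    config.validate()
    return [generate_case(config, i) for i in range(config.n_cases)]


# ---------------------------------------------------------------------------
# CSV record dialect: one file per record, header "lead,t0,dt,unit=mV", one
# row per lead with 6-decimal voltages; labels in a sidecar labels.csv.
# ---------------------------------------------------------------------------

_LABELS_FILE = "labels.csv"


def write_records(cohort: Sequence[tuple[ECGRecord, CaseLabel]], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for record, _ in cohort:
        dt = 1.0 / record.sampling_rate
        with open(path / f"{record.record_id}.csv", "w") as fh:
            fh.write("lead,t0,dt,unit=mV\n")
            for i, lead in enumerate(record.lead_names):
                volts = ",".join(f"{v:.6f}" for v in record.samples[i])
                fh.write(f"{lead},0.0,{dt:.9f},{volts}\n")
    with open(path / _LABELS_FILE, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "stemi", "needs_acute_pci", "territory"])
        for record, label in cohort:
            writer.writerow([record.record_id, int(label.stemi),
                             int(label.needs_acute_pci), label.territory])


def _read_record_file(fpath: Path) -> ECGRecord:
    with open(fpath) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("lead,t0,dt"):
        raise ParseError(f"{fpath.name}: line 1: missing record header")
    rows: dict[str, np.ndarray] = {}
    dt = None
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) < 4:
            raise ParseError(f"{fpath.name}: line {lineno}: too few fields")
        lead = parts[0]
        if lead not in LEAD_NAMES:
            raise ParseError(f"{fpath.name}: line {lineno}: unknown lead {lead!r}")
        try:
            dt = float(parts[2])
            rows[lead] = np.array([float(v) for v in parts[3:]])
        except ValueError as exc:
            raise ParseError(f"{fpath.name}: line {lineno}: {exc}") from exc
    missing = [lead for lead in LEAD_NAMES if lead not in rows]
    if missing:
        raise ParseError(f"{fpath.name}: missing lead rows {missing}")
    samples = np.vstack([rows[lead] for lead in LEAD_NAMES])
    return ECGRecord(samples=samples, sampling_rate=1.0 / dt,
                     record_id=fpath.stem)


def read_records(path: str | Path) -> list[tuple[ECGRecord, CaseLabel]]:
    """Read a cohort written by :func:`write_records`; inverse within 1e-6 mV."""
    path = Path(path)
    labels: dict[str, CaseLabel] = {}
    labels_path = path / _LABELS_FILE
    if labels_path.exists():
        with open(labels_path, newline="") as fh:
            for row in csv.DictReader(fh):
                stemi = bool(int(row["stemi"]))
                territory = row["territory"]
                offsets = ({lead: float("nan") for lead in LEAD_NAMES}
                           if territory != "none" else {lead: 0.0 for lead in LEAD_NAMES})
                # Offsets are not serialized; mark unknown for STEMI reads.
                labels[row["record_id"]] = CaseLabel(
                    stemi=stemi, needs_acute_pci=bool(int(row["needs_acute_pci"])),
                    territory=territory, st_offsets=offsets)
    cohort = []
    for fpath in sorted(path.glob("*.csv")):
        if fpath.name == _LABELS_FILE:
            continue
        record = _read_record_file(fpath)
        label = labels.get(record.record_id)
        if label is None:
            label = CaseLabel(stemi=False, needs_acute_pci=False, territory="none",
                              st_offsets={lead: 0.0 for lead in LEAD_NAMES})
        cohort.append((record, label))
    if not cohort:
        warnings.warn(f"no records found in {path}", stacklevel=2)
        logger.warning("no records found in %s", path)
    return cohort
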