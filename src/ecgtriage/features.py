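"""Fiducial detection and the 13-measurement-per-lead ECG feature vector.

Fiducial points (QRS onset, R peak, QRS offset / J point, T end) are found
once per record on the cross-lead root-mean-square signal, which is robust
to single noisy leads, then thirteen baseline-relative measurements are
taken per lead and averaged over beats: Q, R and S amplitudes, QRS area and
duration, positive and negative T amplitudes, and the ST amplitude at six
positions J + {0, 16, 32, 48, 64, 80} ms. Twelve leads times thirteen
measures give the 156-variable raw feature vector with a fixed ordering
contract. The rule-based ST-elevation criterion (>= 0.2 mV in V1-V3,
>= 0.1 mV in other leads, in at least two adjacent leads) operates on
J-point amplitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synth import LEAD_NAMES, ECGRecord, CaseLabel, criterion_threshold

logger = logging.getLogger(__name__)

#: Per-lead measurement names, in the fixed feature-vector order.
MEASURE_NAMES: tuple[str, ...] = (
    "q_amp", "r_amp", "s_amp", "qrs_area", "qrs_duration",
    "t_pos", "t_neg", "st1", "st2", "st3", "st4", "st5", "st6",
)

#: ST sampling offsets after the J point, seconds.
ST_OFFSETS_S: tuple[float, ...] = (0.0, 0.016, 0.032, 0.048, 0.064, 0.080)

N_FEATURES = len(LEAD_NAMES) * len(MEASURE_NAMES)  # 156


class FiducialError(RuntimeError):
    """Fiducial points could not be located."""


class DetectionError(FiducialError):
    """No QRS complex found in the record."""


@dataclass(frozen=True)
class FiducialPoints:
    """Global per-beat time fiducials (sample indices into the record)."""

    qrs_on: np.ndarray
    r_peak: np.ndarray
    qrs_off: np.ndarray     # the J point
    t_end: np.ndarray
    rms_baseline: float     # baseline of the cross-lead RMS signal, mV

    @property
    def n_beats(self) -> int:
        return len(self.r_peak)

    @property
    def beat_windows(self) -> list[tuple[int, int, int]]:
        return [(int(a), int(r), int(t))
                for a, r, t in zip(self.qrs_on, self.r_peak, self.t_end)]


@dataclass(frozen=True)
class LeadMeasurement:
    """The 13 baseline-relative measures of one lead (amplitudes mV,
    area mV*ms, duration ms, all beat-averaged)."""

    q_amp: float
    r_amp: float
    s_amp: float
    qrs_area: float
    qrs_duration: float
    t_pos: float
    t_neg: float
    st: tuple[float, ...]   # six signed values

    def as_array(self) -> np.ndarray:
        vals = np.array([self.q_amp, self.r_amp, self.s_amp, self.qrs_area,
                         self.qrs_duration, self.t_pos, self.t_neg, *self.st])
        assert vals.shape == (13,)
        return vals


def feature_names() -> list[str]:
    """The 156 names, e.g. ``V2_st1``, in the fixed ordering contract."""
    return [f"{lead}_{m}" for lead in LEAD_NAMES for m in MEASURE_NAMES]


def _smooth(x: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_fiducials(record: ECGRecord,
                     min_rms_peak: float = 0.2) -> FiducialPoints:
    """Locate QRS onset/offset, R peak and T end on the cross-lead RMS.

    R peaks are RMS maxima; QRS bounds are found by scanning outward from
    each R peak until the RMS slope magnitude stays below 10% of its beat
    maximum for at least 8 ms; T end is the return of the RMS to within
    0.05 mV of baseline after the T peak. Beats without a complete
    PR window or T wave inside the record are dropped.
    """
    sr = record.sampling_rate
    rms = _smooth(np.sqrt(np.mean(record.samples ** 2, axis=0)))
    peaks, _ = find_peaks(rms, height=min_rms_peak, distance=int(0.4 * sr))
    if len(peaks) == 0:
        raise DetectionError(
            f"record {record.record_id!r}: no QRS complex (RMS max "
            f"{rms.max():.3f} mV < {min_rms_peak} mV)")

    slope = np.gradient(rms) * sr
    run = max(1, int(round(0.008 * sr)))       # 8 ms of quiet slope
    half = int(round(0.12 * sr))               # QRS search half-window

    qrs_on, r_peak, qrs_off, t_end = [], [], [], []
    pr_len, pr_gap = int(round(0.040 * sr)), int(round(0.010 * sr))
    for b, pk in enumerate(peaks):
        lo, hi = max(0, pk - half), min(len(rms), pk + half)
        thresh = 0.10 * np.max(np.abs(slope[lo:hi]))

        quiet = np.abs(slope) < thresh
        on = None
        count = 0
        for i in range(pk, lo - 1, -1):
            count = count + 1 if quiet[i] else 0
            if count >= run:
                on = i + run - 1
                break
        off = None
        count = 0
        for i in range(pk, hi):
            count = count + 1 if quiet[i] else 0
            if count >= run:
                off = i - run + 1
                break
        if on is None or off is None:
            continue
        if on - pr_len - pr_gap < 0:
            continue                                    # no PR window: drop beat
        # T end: after the T peak, RMS returns to near its baseline level.
        next_on = peaks[b + 1] - half if b + 1 < len(peaks) else len(rms)
        t_hi = min(len(rms), next_on)
        if t_hi - off < int(0.08 * sr):
            continue
        base = float(np.mean(rms[on - pr_len - pr_gap: on - pr_gap]))
        seg = rms[off:t_hi]
        t_pk = off + int(np.argmax(np.abs(seg - base)))
        after = np.nonzero(np.abs(rms[t_pk:t_hi] - base) < 0.05)[0]
        if len(after) == 0:
            continue                                    # T wave runs off the record
        qrs_on.append(on)
        r_peak.append(int(pk))
        qrs_off.append(off)
        t_end.append(t_pk + int(after[0]))

    if not r_peak:
        raise DetectionError(f"record {record.record_id!r}: no complete beat")
    base_all = [float(np.mean(rms[a - pr_len - pr_gap: a - pr_gap])) for a in qrs_on]
    return FiducialPoints(qrs_on=np.array(qrs_on), r_peak=np.array(r_peak),
                          qrs_off=np.array(qrs_off), t_end=np.array(t_end),
                          rms_baseline=float(np.mean(base_all)))


def estimate_baseline(lead: np.ndarray, fiducials: FiducialPoints,
                      sampling_rate: float) -> float:
    """Mean voltage over the PR windows (40 ms ending 10 ms before QRS onset),
    averaged across beats."""
    pr_len = int(round(0.040 * sampling_rate))
    pr_gap = int(round(0.010 * sampling_rate))
    vals = []
    for on in fiducials.qrs_on:
        lo = on - pr_len - pr_gap
        if lo < 0:
            raise FiducialError("PR window extends before record start")
        vals.append(np.mean(lead[lo: on - pr_gap]))
    return float(np.mean(vals))


def measure_lead(lead: np.ndarray, fiducials: FiducialPoints,
                 sampling_rate: float) -> LeadMeasurement:
    """The 13 baseline-relative measures of one lead, averaged over beats."""
    lead = np.asarray(lead, dtype=float)
    baseline = estimate_baseline(lead, fiducials, sampling_rate)
    dt_ms = 1000.0 / sampling_rate
    n = len(lead)

    per_beat = []
    clipped = 0
    for on, pk, off, tend in zip(fiducials.qrs_on, fiducials.r_peak,
                                 fiducials.qrs_off, fiducials.t_end):
        v = lead - baseline
        qrs = v[on: off + 1]
        q_seg = v[on: pk] if pk > on else v[on:on + 1]
        s_seg = v[pk + 1: off + 1] if off > pk else v[off:off + 1]
        q_amp = max(0.0, -float(np.min(q_seg)))
        r_amp = max(0.0, float(np.max(qrs)))
        s_amp = max(0.0, -float(np.min(s_seg)))
        qrs_area = float(np.sum(np.abs(qrs))) * dt_ms
        qrs_duration = (off - on) * dt_ms
        t_seg = v[off + 1: tend + 1]
        t_pos = max(0.0, float(np.max(t_seg))) if len(t_seg) else 0.0
        t_neg = max(0.0, -float(np.min(t_seg))) if len(t_seg) else 0.0
        st = []
        for offset in ST_OFFSETS_S:
            idx = off + int(round(offset * sampling_rate))
            if idx >= n or idx > tend:
                idx = min(tend, n - 1)
                clipped += 1
            st.append(float(v[idx]))
        per_beat.append([q_amp, r_amp, s_amp, qrs_area, qrs_duration,
                         t_pos, t_neg, *st])

    if clipped:
        logger.warning("%d ST sample(s) clipped to the last valid index", clipped)
    mean = np.mean(np.asarray(per_beat), axis=0)
    return LeadMeasurement(q_amp=mean[0], r_amp=mean[1], s_amp=mean[2],
                           qrs_area=mean[3], qrs_duration=mean[4],
                           t_pos=mean[5], t_neg=mean[6],
                           st=tuple(mean[7:13]))


def extract_features(record: ECGRecord) -> np.ndarray:
    """The 156-vector: 12 leads in standard order, 13 measures per lead."""
    try:
        fiducials = detect_fiducials(record)
    except FiducialError as exc:
        raise type(exc)(f"record {record.record_id!r}: {exc}") from exc
    blocks = [measure_lead(record.samples[i], fiducials, record.sampling_rate).as_array()
              for i in range(12)]
    vec = np.concatenate(blocks)
    assert vec.shape == (N_FEATURES,)
    return vec


#: Adjacent-lead pairs for the ST-elevation criterion: consecutive precordial
#: pairs plus any pair within the inferior group {II, III, aVF} and the
#: lateral groups {I, aVL} and {V5, V6, I, aVL}.
def _group_pairs(group: tuple[str, ...]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(group) for b in group[i + 1:]]


ADJACENT_PAIRS: list[tuple[str, str]] = sorted(set(
    [("V1", "V2"), ("V2", "V3"), ("V3", "V4"), ("V4", "V5"), ("V5", "V6")]
    + _group_pairs(("II", "III", "aVF"))
    + _group_pairs(("I", "aVL"))
    + _group_pairs(("V5", "V6", "I", "aVL"))
))


def stemi_criteria(st_by_lead: Mapping[str, float]) -> bool:
    """True iff two adjacent leads both meet their ST-elevation threshold
    (0.2 mV in V1-V3, 0.1 mV elsewhere), evaluated on J-point amplitudes."""
    missing = [lead for lead in LEAD_NAMES if lead not in st_by_lead]
    if missing:
        raise ValueError(f"missing leads: {missing}")
    meets = {lead: st_by_lead[lead] >= criterion_threshold(lead)
             for lead in LEAD_NAMES}
    return any(meets[a] and meets[b] for a, b in ADJACENT_PAIRS)


def st_values(vector: np.ndarray) -> dict[str, float]:
    """J-point (st1) amplitude per lead from a 156-feature vector."""
    names = feature_names()
    return {lead: float(vector[names.index(f"{lead}_st1")]) for lead in LEAD_NAMES}


def extract_cohort_features(cohort: Sequence[tuple[ECGRecord, CaseLabel]]
                            ) -> pd.DataFrame:
    """Feature matrix for a cohort: record_id index, 156 named columns, plus
    the ground-truth label columns ``stemi`` and ``needs_acute_pci``."""
    rows, ids, stemi, pci = [], [], [], []
    for record, label in cohort:
        rows.append(extract_features(record))
        ids.append(record.record_id)
        stemi.append(label.stemi)
        pci.append(label.needs_acute_pci)
    df = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="record_id"),
                      columns=feature_names())
    df["stemi"] = np.asarray(stemi, dtype=bool)
    df["needs_acute_pci"] = np.asarray(pci, dtype=bool)
    return df


def features_to_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def features_from_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="record_id")
    for col in ("stemi", "needs_acute_pci"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
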