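"""Diagnostic-test evaluation: ROC/AUROC, exact binomial intervals,
sensitivity-anchored operating points, serial testing and triage yield.

A case is called positive when its score is at or above the operating
threshold. The threshold is anchored to a target sensitivity (95% for
STEMI screening by default): among all cut-offs whose sensitivity meets
the target, the largest — hence most specific — is chosen. Proportions
carry exact Clopper-Pearson intervals (inverted binomial tails via beta
quantiles); AUROC is the Mann-Whitney pair-ordering statistic with a
stratified-bootstrap percentile interval. Serial testing models the
screening workflow in which only screen-positive ECGs reach the
confirmatory reader, and the transmission reduction is the fraction of
ECGs the screen withholds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import beta, rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ProportionEstimate:
    """A proportion with its exact 95% (by default) confidence interval."""

    value: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0 <= self.lower <= self.value <= self.upper <= 1):
            raise ValueError("interval must contain the estimate within [0, 1]")


def _check_cohort(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    return s, y


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("cohort must contain both classes")


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """(threshold, sensitivity, specificity) per distinct cut-off.

    Positive prediction at score >= threshold; thresholds run from +inf
    (nothing called positive) down through every distinct score, so
    sensitivity is non-decreasing down the list.
    """
    s, y = _check_cohort(scores, labels)
    _check_two_classes(y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    points = [(np.inf, 0.0, 1.0)]
    for thr in np.unique(s)[::-1]:
        called = s >= thr
        sens = float((called & y).sum()) / n_pos
        spec = float((~called & ~y).sum()) / n_neg
        points.append((float(thr), sens, spec))
    return points


def auroc(scores, labels) -> float:
    """Mann-Whitney pair statistic: P(random positive scores above a random
    negative), ties counted half — identical to the ROC trapezoid area."""
    s, y = _check_cohort(scores, labels)
    _check_two_classes(y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
             level: float = 0.95) -> tuple[float, float]:
    """Stratified bootstrap percentile interval; always contains the
    point estimate."""
    s, y = _check_cohort(scores, labels)
    _check_two_classes(y)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    pos, neg = s[y], s[~y]
    rng = np.random.default_rng(seed)
    # Vectorized Mann-Whitney over replicates via a comparison tensor.
    bp = pos[rng.integers(0, len(pos), size=(n_boot, len(pos)))]
    bn = neg[rng.integers(0, len(neg), size=(n_boot, len(neg)))]
    stats = np.empty(n_boot)
    chunk = max(1, int(5e7 // (len(pos) * len(neg) + 1)))
    for i in range(0, n_boot, chunk):
        diff = bp[i:i + chunk, :, None] - bn[i:i + chunk, None, :]
        stats[i:i + chunk] = ((diff > 0).mean(axis=(1, 2))
                              + 0.5 * (diff == 0).mean(axis=(1, 2)))
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    point = auroc(s, y)
    return float(min(lo, point)), float(max(hi, point))


def threshold_at_sensitivity(scores, labels, target_sens: float
                             ) -> tuple[float, float]:
    """Largest threshold whose sensitivity meets the target (maximizing
    specificity under the constraint); returns (threshold, achieved)."""
    if not 0.0 < target_sens <= 1.0:
        raise ValueError("target sensitivity must be in (0, 1]")
    s, y = _check_cohort(scores, labels)
    if not y.any():
        raise ValueError("no positive cases to anchor sensitivity on")
    pos = np.sort(s[y])[::-1]
    n_pos = len(pos)
    k = int(np.ceil(target_sens * n_pos))
    thr = float(pos[k - 1])
    achieved = float((s[y] >= thr).sum()) / n_pos
    return thr, achieved


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    s, y = _check_cohort(scores, labels)
    called = s >= threshold
    return ConfusionCounts(tp=int((called & y).sum()), fp=int((called & ~y).sum()),
                           tn=int((~called & ~y).sum()), fn=int((~called & y).sum()))


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval by beta-quantile inversion of the tails."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def _proportion(k: int, n: int, level: float) -> ProportionEstimate | None:
    if n == 0:
        warnings.warn("zero denominator; metric undefined", stacklevel=3)
        return None
    lo, hi = clopper_pearson(k, n, level)
    return ProportionEstimate(value=k / n, lower=lo, upper=hi)


def metrics(counts: ConfusionCounts, level: float = 0.95
            ) -> dict[str, ProportionEstimate | None]:
    """Sensitivity, specificity, PPV and NPV, each with an exact interval."""
    return {
        "sens": _proportion(counts.tp, counts.tp + counts.fn, level),
        "spec": _proportion(counts.tn, counts.tn + counts.fp, level),
        "ppv": _proportion(counts.tp, counts.tp + counts.fp, level),
        "npv": _proportion(counts.tn, counts.tn + counts.fn, level),
    }


def serial_combine(screen_flags, confirm_flags) -> np.ndarray:
    """Two-stage positive call: positive iff the screen AND the confirmatory
    reader are positive (screen-negatives are never transmitted)."""
    a = np.asarray(screen_flags, dtype=bool)
    b = np.asarray(confirm_flags, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag arrays must have equal length")
    return a & b


def transmission_reduction(screen_flags) -> float:
    """Fraction of ECGs withheld from transmission by the screen."""
    a = np.asarray(screen_flags, dtype=bool)
    if a.size == 0:
        raise ValueError("empty screen flags")
    return float(1.0 - a.mean())


@dataclass
class DiagnosticReport:
    """Operating-point performance of a scored cohort."""

    counts: ConfusionCounts
    sens: ProportionEstimate | None
    spec: ProportionEstimate | None
    ppv: ProportionEstimate | None
    npv: ProportionEstimate | None
    auroc: float
    auroc_ci: tuple[float, float]
    threshold: float
    achieved_sensitivity: float
    reduction: float
    outcome: str = "stemi"
    level: float = 0.95

    def to_dict(self) -> dict:
        def prop(p):
            return None if p is None else {"value": round(p.value, 6),
                                           "lower": round(p.lower, 6),
                                           "upper": round(p.upper, 6)}
        return {
            "outcome": self.outcome,
            "n": self.counts.n,
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
            "sens": prop(self.sens), "spec": prop(self.spec),
            "ppv": prop(self.ppv), "npv": prop(self.npv),
            "auroc": round(self.auroc, 6),
            "auroc_ci": [round(v, 6) for v in self.auroc_ci],
            "threshold": round(self.threshold, 9),
            "achieved_sensitivity": round(self.achieved_sensitivity, 6),
            "reduction": round(self.reduction, 6),
            "reduction_percent": int(round(100 * self.reduction)),
            "level": self.level,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))

    def summary(self) -> str:
        def fmt(p):
            return ("   n/a    " if p is None
                    else f"{p.value:.2f} ({p.lower:.2f}-{p.upper:.2f})")
        lines = [
            f"Diagnostic report — outcome: {self.outcome}, n={self.counts.n}",
            f"  operating threshold: {self.threshold:.4f} "
            f"(achieved sensitivity {self.achieved_sensitivity:.3f})",
            f"  counts: TP={self.counts.tp} FP={self.counts.fp} "
            f"TN={self.counts.tn} FN={self.counts.fn}",
            f"  Sens {fmt(self.sens)}   Spec {fmt(self.spec)}",
            f"  PPV  {fmt(self.ppv)}   NPV  {fmt(self.npv)}",
            f"  AUROC {self.auroc:.2f} "
            f"({self.auroc_ci[0]:.2f}-{self.auroc_ci[1]:.2f})",
            f"  transmission reduction: {100 * self.reduction:.0f}%",
        ]
        return "\n".join(lines)


def evaluate_cohort(scores, labels, target_sensitivity: float = 0.95,
                    threshold: float | None = None, level: float = 0.95,
                    n_boot: int = 2000, seed: int = 0,
                    outcome: str = "stemi") -> DiagnosticReport:
    """Full operating-point report; the threshold is anchored on this cohort
    unless one calibrated elsewhere is supplied."""
    s, y = _check_cohort(scores, labels)
    if threshold is None:
        threshold, _ = threshold_at_sensitivity(s, y, target_sensitivity)
    counts = confusion(s, y, threshold)
    achieved = (counts.tp / (counts.tp + counts.fn)
                if counts.tp + counts.fn else float("nan"))
    m = metrics(counts, level)
    return DiagnosticReport(
        counts=counts, sens=m["sens"], spec=m["spec"], ppv=m["ppv"], npv=m["npv"],
        auroc=auroc(s, y), auroc_ci=auroc_ci(s, y, n_boot=n_boot, seed=seed, level=level),
        threshold=float(threshold), achieved_sensitivity=float(achieved),
        reduction=transmission_reduction(s >= threshold),
        outcome=outcome, level=level)
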