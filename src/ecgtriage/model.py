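"""Model/Results interface over the screening pipeline.

`EcgTriageModel` holds a training cohort's 156-column raw feature matrix and
binary outcome; `fit()` standardizes, projects to 20 principal components,
Z-scores, optionally tunes (lambda, hidden nodes) by cross-validation, and
trains the bagged network ensemble. The returned `EcgTriageResults` scores
new ECGs, anchors an operating threshold to a target sensitivity, and
produces a `DiagnosticReport` on an independent test cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ann, evaluate, features as feat, reduction
from .synth import CaseLabel, ECGRecord


class EcgTriageModel:
    """Screening classifier specification bound to training data.

    Parameters
    ----------
    endog : array-like of bool, shape (n,)
        Outcome labels (STEMI or needs-acute-PCI).
    exog : array-like, shape (n, 156)
        Raw ECG feature matrix in the fixed 156-column ordering.
    n_components : int
        Number of principal components retained (default 20).
    train_config : ann.TrainConfig, optional
        Ensemble training settings; defaults mirror the study classifier
        (25 members, 15 hidden nodes).
    """

    def __init__(self, endog, exog, n_components: int = 20,
                 train_config: ann.TrainConfig | None = None):
        self.endog = np.asarray(endog, dtype=bool)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        self.n_components = n_components
        self.train_config = train_config or ann.TrainConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "stemi",
                       **kwargs) -> "EcgTriageModel":
        """Build from an `extract_cohort_features` frame (labels + features)."""
        X = df[feat.feature_names()].to_numpy(dtype=float)
        return cls(df[outcome].to_numpy(dtype=bool), X, **kwargs)

    @classmethod
    def from_cohort(cls, cohort: Sequence[tuple[ECGRecord, CaseLabel]],
                    outcome: str = "stemi", **kwargs) -> "EcgTriageModel":
        return cls.from_dataframe(feat.extract_cohort_features(cohort),
                                  outcome=outcome, **kwargs)

    def fit(self, select_hyperparams: bool = False) -> "EcgTriageResults":
        """Fit reducer and ensemble on the training data only."""
        reducer = reduction.fit_reducer(self.exog, self.n_components)
        scores = reduction.apply_reducer(reducer, self.exog)
        config = self.train_config
        cv_selection = None
        if select_hyperparams:
            lam, n_hidden = ann.cross_validate(scores, self.endog, config)
            cv_selection = (lam, n_hidden)
            config = replace(config, lam=lam, n_hidden=n_hidden)
        ensemble = ann.train_ensemble(scores, self.endog, config,
                                      reducer_ref="fitted-with-model")
        return EcgTriageResults(self, reducer, ensemble, cv_selection)


@dataclass
class EcgTriageResults:
    """Fitted reducer + ensemble with prediction and evaluation methods."""

    model: EcgTriageModel
    reducer: reduction.Reducer
    ensemble: ann.Ensemble
    cv_selection: tuple[float, int] | None = None

    def predict(self, exog: np.ndarray) -> np.ndarray:
        """Ensemble scores in (0, 1) for raw 156-column feature rows."""
        scores = reduction.apply_reducer(self.reducer, np.atleast_2d(exog))
        return ann.predict(self.ensemble, scores)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    def calibrate_threshold(self, target_sensitivity: float = 0.95,
                            exog: np.ndarray | None = None,
                            labels: np.ndarray | None = None
                            ) -> tuple[float, float]:
        """Sensitivity-anchored threshold; defaults to the training cohort."""
        if exog is None:
            s, y = self.fittedvalues, self.model.endog
        else:
            s, y = self.predict(exog), np.asarray(labels, dtype=bool)
        return evaluate.threshold_at_sensitivity(s, y, target_sensitivity)

    def evaluate(self, exog: np.ndarray, labels: np.ndarray,
                 target_sensitivity: float = 0.95,
                 threshold: float | None = None, level: float = 0.95,
                 n_boot: int = 2000, seed: int = 0,
                 outcome: str = "stemi") -> evaluate.DiagnosticReport:
        """Diagnostic report on a (typically independent) cohort."""
        return evaluate.evaluate_cohort(
            self.predict(exog), np.asarray(labels, dtype=bool),
            target_sensitivity=target_sensitivity, threshold=threshold,
            level=level, n_boot=n_boot, seed=seed, outcome=outcome)

    def save(self, reducer_path: str | Path, ensemble_path: str | Path) -> None:
        self.reducer.to_json(reducer_path)
        self.ensemble.to_json(ensemble_path)

    def summary(self) -> str:
        cfg = self.ensemble.config
        train_auc = evaluate.auroc(self.fittedvalues, self.model.endog)
        lines = [
            "ECG triage ensemble results",
            "===========================",
            f"training cases:        {self.model.exog.shape[0]} "
            f"({int(self.model.endog.sum())} positive)",
            f"features -> components: {self.model.exog.shape[1]} -> "
            f"{self.reducer.n_components}",
            f"explained variance:    "
            f"{self.reducer.explained_variance_ratio.sum():.3f}",
            f"ensemble members:      {len(self.ensemble.members)}",
            f"hidden nodes:          {cfg.n_hidden}",
            f"weight elimination:    lambda={cfg.lam}, w0={cfg.w0}",
        ]
        if self.cv_selection is not None:
            lines.append(f"cross-validation pick: lambda={self.cv_selection[0]}, "
                         f"hidden={self.cv_selection[1]}")
        lines.append(f"training AUROC:        {train_auc:.3f} (resubstitution)")
        return "\n".join(lines)
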