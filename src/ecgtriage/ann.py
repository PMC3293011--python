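"""Bagged ensemble of single-hidden-layer perceptrons with weight elimination.

Each member is a fully connected feed-forward network — tanh hidden layer
(15 nodes by default), logistic output — trained by full-batch gradient
descent on the cross-entropy error plus a weight-elimination penalty

    lambda * sum_w (w^2 / w0^2) / (1 + w^2 / w0^2)

over the connection weights (biases excluded). The penalty behaves like
ridge shrinkage for |w| << w0 but saturates at lambda per weight, so large
weights that earn their keep are not pulled down further; lambda tunes
network complexity and is chosen, together with the hidden-layer size, by
stratified cross-validation on held-out AUROC. The ensemble is built by
bagging: 25 members by default, each trained on its own bootstrap resample,
and the ensemble score is the arithmetic mean of the member outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class NetworkParams:
    W1: np.ndarray   # (n_in, n_hidden)
    b1: np.ndarray   # (n_hidden,)
    W2: np.ndarray   # (n_hidden,)
    b2: float

    def __post_init__(self):
        for arr in (self.W1, self.b1, self.W2, np.asarray(self.b2)):
            if not np.all(np.isfinite(arr)):
                raise ValueError("network parameters must be finite")


@dataclass
class TrainConfig:
    lam: float = 1.0             # weight-elimination coefficient, >= 0
    w0: float = 1.0              # weight-elimination scale (natural on Z-scored inputs)
    n_hidden: int = 15
    n_members: int = 25
    learning_rate: float = 0.5   # step on the per-sample mean objective
    n_epochs: int = 400
    cv_folds: int = 5
    lambda_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    hidden_grid: tuple[int, ...] = (15,)
    seed: int = 0

    def validate(self) -> None:
        if self.lam < 0 or self.w0 <= 0:
            raise ValueError("lam must be >= 0 and w0 > 0")
        if self.n_members < 1 or self.n_hidden < 1:
            raise ValueError("n_members and n_hidden must be >= 1")
        if not self.lambda_grid or not self.hidden_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.learning_rate <= 0 or self.n_epochs < 1:
            raise ValueError("learning_rate > 0 and n_epochs >= 1 required")


@dataclass
class Ensemble:
    members: list[NetworkParams]
    member_seeds: list[int]
    bootstrap_indices: list[np.ndarray]
    config: TrainConfig
    reducer_ref: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "members": [{"W1": m.W1.tolist(), "b1": m.b1.tolist(),
                         "W2": m.W2.tolist(), "b2": m.b2} for m in self.members],
            "member_seeds": self.member_seeds,
            "bootstrap_indices": [idx.tolist() for idx in self.bootstrap_indices],
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "reducer_ref": self.reducer_ref,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Ensemble":
        payload = json.loads(Path(path).read_text())
        cfg = dict(payload["config"])
        cfg["lambda_grid"] = tuple(cfg["lambda_grid"])
        cfg["hidden_grid"] = tuple(cfg["hidden_grid"])
        members = [NetworkParams(W1=np.asarray(m["W1"]), b1=np.asarray(m["b1"]),
                                 W2=np.asarray(m["W2"]), b2=float(m["b2"]))
                   for m in payload["members"]]
        return cls(members=members, member_seeds=list(payload["member_seeds"]),
                   bootstrap_indices=[np.asarray(i) for i in payload["bootstrap_indices"]],
                   config=TrainConfig(**cfg), reducer_ref=payload["reducer_ref"])


_CLIP = 1e-12


def forward(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    """Network output in (0, 1); accepts a single vector or an (m, d) batch."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("inputs must be finite")
    single = x.ndim == 1
    X = np.atleast_2d(x)
    h = np.tanh(X @ params.W1 + params.b1)
    y = expit(h @ params.W2 + params.b2)
    return float(y[0]) if single else y


def _penalty(params: NetworkParams, w0: float) -> float:
    total = 0.0
    for w in (params.W1, params.W2):
        r = (w / w0) ** 2
        total += float(np.sum(r / (1.0 + r)))
    return total


def loss(params: NetworkParams, inputs: np.ndarray, targets: np.ndarray,
         lam: float, w0: float = 1.0) -> float:
    """Summed cross-entropy plus the weight-elimination penalty."""
    t = np.asarray(targets, dtype=float)
    if not np.all((t == 0) | (t == 1)):
        raise ValueError("targets must be binary")
    y = np.clip(np.atleast_1d(forward(params, inputs)), _CLIP, 1.0 - _CLIP)
    ce = -float(np.sum(t * np.log(y) + (1.0 - t) * np.log(1.0 - y)))
    return ce + lam * _penalty(params, w0)


def gradient(params: NetworkParams, inputs: np.ndarray, targets: np.ndarray,
             lam: float, w0: float = 1.0) -> NetworkParams:
    """Analytic gradient of :func:`loss` (backpropagation), parameter-shaped."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    t = np.asarray(targets, dtype=float)
    h = np.tanh(X @ params.W1 + params.b1)
    y = expit(h @ params.W2 + params.b2)
    # d(ce)/dz for the logistic output with clipped-log cross-entropy.
    delta = y - t
    gW2 = h.T @ delta
    gb2 = float(np.sum(delta))
    dh = np.outer(delta, params.W2) * (1.0 - h ** 2)
    gW1 = X.T @ dh
    gb1 = dh.sum(axis=0)

    def pen_grad(w: np.ndarray) -> np.ndarray:
        return lam * 2.0 * w * w0 ** 2 / (w0 ** 2 + w ** 2) ** 2

    return NetworkParams(W1=gW1 + pen_grad(params.W1), b1=gb1,
                         W2=gW2 + pen_grad(params.W2), b2=gb2)


def init_params(n_in: int, n_hidden: int, seed: int) -> NetworkParams:
    rng = np.random.default_rng(seed)
    return NetworkParams(W1=rng.uniform(-0.1, 0.1, size=(n_in, n_hidden)),
                         b1=rng.uniform(-0.1, 0.1, size=n_hidden),
                         W2=rng.uniform(-0.1, 0.1, size=n_hidden),
                         b2=float(rng.uniform(-0.1, 0.1)))


def train_member(train_scores: np.ndarray, targets: np.ndarray,
                 config: TrainConfig, member_seed: int) -> NetworkParams:
    """Full-batch gradient descent from a seeded uniform initialization.

    The update direction is the gradient of the per-sample mean objective,
    so the default learning rate is independent of the batch size. A
    warning is raised if the monitored loss ever increases materially.
    """
    config.validate()
    X = np.atleast_2d(np.asarray(train_scores, dtype=float))
    t = np.asarray(targets, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 training rows, got {n}")
    if len(np.unique(t)) < 2:
        raise ValueError("training set must contain both classes")

    params = init_params(X.shape[1], config.n_hidden, member_seed)
    prev = loss(params, X, t, config.lam, config.w0) / n
    warned = False
    for _ in range(config.n_epochs):
        g = gradient(params, X, t, config.lam, config.w0)
        lr = config.learning_rate / n
        params = NetworkParams(W1=params.W1 - lr * g.W1, b1=params.b1 - lr * g.b1,
                               W2=params.W2 - lr * g.W2, b2=params.b2 - lr * g.b2)
        cur = loss(params, X, t, config.lam, config.w0) / n
        if cur > prev + 1e-9 and not warned:
            warnings.warn("training loss increased; consider lowering the "
                          "learning rate", stacklevel=2)
            warned = True
        prev = cur
    return params


def bootstrap_sample(n: int, seed: int) -> np.ndarray:
    """n draws with replacement from 0..n-1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).integers(0, n, size=n)


def _derived_seed(seed: int, stream: int) -> int:
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, stream])
    return int(np.random.default_rng(ss).integers(0, 2 ** 31 - 1))


def train_ensemble(train_scores: np.ndarray, targets: np.ndarray,
                   config: TrainConfig, reducer_ref: str = "") -> Ensemble:
    """Bag ``n_members`` networks, each on its own bootstrap resample."""
    config.validate()
    X = np.atleast_2d(np.asarray(train_scores, dtype=float))
    t = np.asarray(targets, dtype=float)
    n = X.shape[0]
    members, seeds, indices = [], [], []
    for m in range(config.n_members):
        member_seed = _derived_seed(config.seed, 2 * m)
        boot_seed = _derived_seed(config.seed, 2 * m + 1)
        idx = bootstrap_sample(n, boot_seed)
        attempt = 0
        while len(np.unique(t[idx])) < 2:      # resample must carry both classes
            attempt += 1
            idx = bootstrap_sample(n, _derived_seed(boot_seed, attempt))
        members.append(train_member(X[idx], t[idx], config, member_seed))
        seeds.append(member_seed)
        indices.append(idx)
    return Ensemble(members=members, member_seeds=seeds,
                    bootstrap_indices=indices, config=config,
                    reducer_ref=reducer_ref)


def predict(ensemble: Ensemble, scores: np.ndarray) -> np.ndarray:
    """Ensemble score: arithmetic mean of member outputs, in (0, 1)."""
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] != ensemble.members[0].W1.shape[0]:
        raise ValueError(f"expected {ensemble.members[0].W1.shape[0]} input "
                         f"columns, got {X.shape[1]}")
    outs = np.stack([forward(m, X) for m in ensemble.members])
    return outs.mean(axis=0)


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .evaluate import auroc
    return auroc(scores, labels)


def cross_validate(train_scores: np.ndarray, targets: np.ndarray,
                   config: TrainConfig, full_output: bool = False):
    """Select (lambda, n_hidden) by mean held-out AUROC over stratified folds.

    One network per fold is trained per grid point; ties break toward
    larger lambda, then fewer hidden nodes (prefer simpler models).
    """
    config.validate()
    if config.cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    X = np.atleast_2d(np.asarray(train_scores, dtype=float))
    t = np.asarray(targets, dtype=float)
    n_pos = int(t.sum())
    if min(n_pos, len(t) - n_pos) < config.cv_folds:
        raise ValueError("too few members of the minority class to stratify")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed & 0x7FFFFFFF)
    folds = list(skf.split(X, t))

    best: tuple[float, float, float, int] | None = None  # (auc, lam, -h, h)
    table: dict[tuple[float, int], float] = {}
    for lam, h in product(config.lambda_grid, config.hidden_grid):
        cand = replace(config, lam=lam, n_hidden=h)
        aucs = []
        for k, (tr, va) in enumerate(folds):
            params = train_member(X[tr], t[tr], cand,
                                  _derived_seed(config.seed, 1000 + k))
            aucs.append(_auroc(np.atleast_1d(forward(params, X[va])), t[va]))
        table[(lam, h)] = float(np.mean(aucs))
        key = (table[(lam, h)], lam, -h)
        if best is None or key > best[:3]:
            best = (*key, h)
    if full_output:
        return best[1], best[3], table
    return best[1], best[3]
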