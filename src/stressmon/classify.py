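"""Linear and MLP classifiers over selected feature vectors.

Both classifiers regress one-hot class targets with squared error and
decide by the arg-max output (ties broken toward the lowest class index).
The linear classifier is the cheap surrogate used to rank feature subsets
during selection; the deployed classifier is a single-hidden-layer
perceptron with 10 tan-sigmoid units and linear outputs, trained by
Levenberg-Marquardt with early stopping on a by-subject validation split.

Features are standardized to train-set mean/variance before either
classifier: batch second-order training on raw beats-per-minute scales is
badly conditioned otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Standardizer",
    "LinearClassifier",
    "linear_fit",
    "MLPConfig",
    "MLPModel",
    "mlp_train",
    "one_hot",
]


def one_hot(labels, classes) -> np.ndarray:
    classes = list(classes)
    idx = np.array([classes.index(l) for l in labels])
    t = np.zeros((len(idx), len(classes)))
    t[np.arange(len(idx)), idx] = 1.0
    return t


@dataclass
class Standardizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


@dataclass
class LinearClassifier:
    """Least-squares one-hot regression with bias; arg-max decision."""

    weights: np.ndarray          # (n_features + 1, n_classes); last row = bias
    classes: list = field(default_factory=list)
    standardizer: Standardizer | None = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.standardizer is not None:
            X = self.standardizer.transform(X)
        Xb = np.column_stack([X, np.ones(len(X))])
        return Xb @ self.weights

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.scores(X), axis=1)

    def mse(self, X: np.ndarray, T: np.ndarray) -> float:
        """Mean over samples and outputs of the squared target error."""
        return float(np.mean((self.scores(X) - T) ** 2))


def linear_fit(X: np.ndarray, T: np.ndarray, classes=None,
               ridge: float = 1e-8, standardize: bool = False) -> LinearClassifier:
    """Fit the least-squares linear classifier.

    ``T`` is the one-hot target matrix.  A tiny ridge term scaled by the
    trace of the Gram matrix keeps rank-deficient designs solvable without
    measurably biasing well-posed ones.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if T.ndim != 2:
        raise ValueError("targets must be one-hot encoded (2-D)")
    if len(X) < T.shape[1]:
        raise ValueError("need at least as many samples as classes")
    std = Standardizer.fit(X) if standardize else None
    Xs = std.transform(X) if std is not None else X
    Xb = np.column_stack([Xs, np.ones(len(Xs))])
    G = Xb.T @ Xb
    lam = ridge * np.trace(G) / G.shape[0]
    W = np.linalg.solve(G + lam * np.eye(G.shape[0]), Xb.T @ T)
    return LinearClassifier(weights=W, classes=list(classes or []),
                            standardizer=std)


@dataclass
class MLPConfig:
    """Training protocol for the 10-unit tan-sigmoid perceptron."""

    hidden_units: int = 10
    restarts: int = 5
    max_epochs: int = 200
    patience: int = 6
    validation_fraction: float = 0.10   # fraction of *subjects* held out
    init_scale: float = 0.5
    mu0: float = 1e-3                   # initial Levenberg-Marquardt damping
    mu_factor: float = 10.0
    mu_max: float = 1e10
    seed: int = 0


@dataclass
class MLPModel:
    W1: np.ndarray  # (hidden, n_features)
    b1: np.ndarray
    W2: np.ndarray  # (n_classes, hidden)
    b2: np.ndarray
    classes: list
    standardizer: Standardizer
    train_trace: list = field(default_factory=list)
    val_trace: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.W1.shape[1]

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        Z = np.tanh(X @ self.W1.T + self.b1)
        return Z @ self.W2.T + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.standardizer.transform(X)
        return np.argmax(self.scores(Xs), axis=1)

    def mse(self, X: np.ndarray, T: np.ndarray) -> float:
        Xs = self.standardizer.transform(X)
        return float(np.mean((self.scores(Xs) - T) ** 2))

    def to_json(self) -> str:
        return json.dumps({
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "classes": list(self.classes),
            "standardizer": {"mean": self.standardizer.mean.tolist(),
                             "scale": self.standardizer.scale.tolist()},
        })

    @classmethod
    def from_json(cls, s: str) -> "MLPModel":
        d = json.loads(s)
        return cls(W1=np.array(d["W1"]), b1=np.array(d["b1"]),
                   W2=np.array(d["W2"]), b2=np.array(d["b2"]),
                   classes=d["classes"],
                   standardizer=Standardizer(np.array(d["standardizer"]["mean"]),
                                             np.array(d["standardizer"]["scale"])))


def _pack(W1, b1, W2, b2):
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(p, n_in, h, m):
    i = 0
    W1 = p[i : i + h * n_in].reshape(h, n_in); i += h * n_in
    b1 = p[i : i + h]; i += h
    W2 = p[i : i + m * h].reshape(m, h); i += m * h
    b2 = p[i : i + m]
    return W1, b1, W2, b2


def _forward(p, X, n_in, h, m):
    W1, b1, W2, b2 = _unpack(p, n_in, h, m)
    Z = np.tanh(X @ W1.T + b1)
    Y = Z @ W2.T + b2
    return Y, Z, (W1, b1, W2, b2)


def _jacobian(p, X, Z, n_in, h, m):
    """Jacobian of the flattened residuals (sample-major, output-minor)
    with respect to the packed parameters."""
    W1, b1, W2, b2 = _unpack(p, n_in, h, m)
    S = len(X)
    P = len(p)
    J = np.zeros((S * m, P))
    dZ = 1.0 - Z ** 2                                # (S, h)
    for out in range(m):
        rows = np.arange(S) * m + out
        # dY/dW2[out, :] = Z ; dY/db2[out] = 1
        J[rows, h * n_in + h + out * h : h * n_in + h + (out + 1) * h] = Z
        J[rows, h * n_in + h + m * h + out] = 1.0
        # dY/dW1[i, j] = W2[out, i] * (1 - z_i^2) * x_j
        coef = W2[out] * dZ                          # (S, h)
        J[rows, : h * n_in] = (coef[:, :, None] * X[:, None, :]).reshape(S, h * n_in)
        J[rows, h * n_in : h * n_in + h] = coef
    return J


def _train_once(X, T, Xv, Tv, cfg: MLPConfig, rng) -> tuple[np.ndarray, list, list]:
    S, n_in = X.shape
    m = T.shape[1]
    h = cfg.hidden_units
    p = cfg.init_scale * rng.standard_normal(h * n_in + h + m * h + m)
    mu = cfg.mu0

    def sse(params, A, B):
        Y, _, _ = _forward(params, A, n_in, h, m)
        return float(np.sum((Y - B) ** 2))

    best_val = np.inf
    best_p = p.copy()
    stall = 0
    train_trace, val_trace = [], []
    cur_sse = sse(p, X, T)
    for _ in range(cfg.max_epochs):
        Y, Z, _ = _forward(p, X, n_in, h, m)
        r = (Y - T).ravel()
        J = _jacobian(p, X, Z, n_in, h, m)
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        while mu <= cfg.mu_max:
            try:
                step = np.linalg.solve(JtJ + mu * np.eye(len(p)), -g)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_factor
                continue
            new_sse = sse(p + step, X, T)
            if new_sse < cur_sse:
                p = p + step
                cur_sse = new_sse
                mu = max(mu / cfg.mu_factor, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_factor
        train_trace.append(cur_sse / (S * m))
        val_mse = sse(p, Xv, Tv) / (len(Xv) * m) if len(Xv) else cur_sse / (S * m)
        val_trace.append(val_mse)
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_p = p.copy()
            stall = 0
        else:
            stall += 1
        if not accepted or stall >= cfg.patience:
            break
    return best_p, train_trace, val_trace


def mlp_train(X: np.ndarray, labels, subjects, classes,
              config: MLPConfig | None = None, seed: int | None = None) -> MLPModel:
    """Train the MLP with restarts, by-subject validation split, early stop.

    The validation set holds out ``validation_fraction`` of the *subjects*
    (at least one), so early stopping measures generalisation to unseen
    individuals.  Of ``restarts`` runs from random initialisations the one
    with the lowest error over the full design set wins.
    """
    cfg = config or MLPConfig()
    if seed is not None:
        cfg = MLPConfig(**{**cfg.__dict__, "seed": seed})
    X = np.asarray(X, dtype=float)
    classes = list(classes)
    T = one_hot(labels, classes)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("need at least 2 subjects for a by-subject validation split")

    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.validation_fraction * len(uniq))))
    val_subjects = rng.choice(uniq, size=n_val, replace=False)
    val_mask = np.isin(subjects, val_subjects)

    std = Standardizer.fit(X[~val_mask])
    Xs = std.transform(X)
    Xt, Tt = Xs[~val_mask], T[~val_mask]
    Xv, Tv = Xs[val_mask], T[val_mask]

    n_in, h, m = X.shape[1], cfg.hidden_units, T.shape[1]
    best = None
    best_design = np.inf
    for _ in range(cfg.restarts):
        p, tr, vl = _train_once(Xt, Tt, Xv, Tv, cfg, rng)
        Y, _, _ = _forward(p, Xs, n_in, h, m)
        design_mse = float(np.mean((Y - T) ** 2))
        if design_mse < best_design:
            best_design = design_mse
            best = (p, tr, vl)
    p, tr, vl = best
    W1, b1, W2, b2 = _unpack(p, n_in, h, m)
    return MLPModel(W1=W1, b1=b1, W2=W2, b2=b2, classes=classes,
                    standardizer=std, train_trace=tr, val_trace=vl)
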