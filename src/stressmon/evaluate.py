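"""Leave-one-subject-out evaluation and error-probability metrics.

Each fold holds out every window of exactly one subject; feature selection
and classifier training see only the remaining subjects, so the reported
error reflects generalisation to unseen individuals.  Confusion matrices
are pooled over folds; the per-class error probability is the off-diagonal
row mass of the pooled matrix and the average error is the unweighted mean
over classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import MLPConfig, mlp_train
from .costs import CostModel
from .ga import GAConfig, evolve

__all__ = ["loso_split", "error_metrics", "CVResult", "run_analysis",
           "nmax_sweep"]

_META_COLS = ("subject_id", "label", "t_start")


def loso_split(subjects) -> list[tuple[np.ndarray, np.ndarray]]:
    """(design indices, test indices) pairs, one per subject with windows."""
    subjects = np.asarray(subjects)
    uniq = [s for s in np.unique(subjects)]
    if len(uniq) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for s in uniq:
        mask = subjects == s
        if not mask.any():
            continue
        folds.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    return folds


def error_metrics(confusion: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class error probabilities (%) and their unweighted mean.

    Row ``i`` of ``confusion`` counts true-class-``i`` windows by predicted
    class; the class error is the off-diagonal row mass over the row sum.
    Classes with empty rows are excluded from the average with a warning.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0):
        raise ValueError("confusion counts must be non-negative")
    row_sums = C.sum(axis=1)
    per_class = np.full(C.shape[0], np.nan)
    ok = row_sums > 0
    if not ok.all():
        import warnings

        warnings.warn("confusion matrix has empty true-class rows; "
                      "their error is undefined and excluded from the average")
    per_class[ok] = (row_sums[ok] - np.diag(C)[ok]) / row_sums[ok] * 100.0
    average = float(np.mean(per_class[ok]))
    return per_class, average


@dataclass
class CVResult:
    confusion: np.ndarray
    classes: list
    per_class_error: np.ndarray
    average_error: float
    selected_features: list = field(default_factory=list)  # per fold
    nop: list = field(default_factory=list)                # per fold
    fold_confusions: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "per_class_error": [round(float(e), 2) for e in self.per_class_error],
            "average_error": round(float(self.average_error), 2),
            "selected_features": [sorted(f) for f in self.selected_features],
            "nop": self.nop,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def run_analysis(feature_table: pd.DataFrame,
                 ga_config: GAConfig,
                 mlp_config: MLPConfig | None = None,
                 cost_model: CostModel | None = None,
                 seed: int = 0,
                 progress=None) -> CVResult:
    """Full LOSO evaluation: per fold, GA selection on the design set, MLP
    training on the design set, testing on the held-out subject.

    ``feature_table`` must carry ``subject_id`` and ``label`` columns next
    to the feature columns.  Every fold's selected subset satisfies the
    GA's budget by construction.
    """
    cm = cost_model or CostModel()
    mlp_cfg = mlp_config or MLPConfig()
    subjects = np.asarray(feature_table["subject_id"])
    labels = np.asarray(feature_table["label"])
    classes = sorted(set(labels.tolist()))
    m = len(classes)
    feat_cols = [c for c in feature_table.columns if c not in _META_COLS]

    rng = np.random.default_rng(seed)
    confusion = np.zeros((m, m), dtype=int)
    result_folds = []
    selected, nops = [], []
    for fold_i, (design_idx, test_idx) in enumerate(loso_split(subjects)):
        design = feature_table.iloc[design_idx]
        ga_seed = int(rng.integers(0, 2**31 - 1))
        ga_res = evolve(design, labels[design_idx], subjects[design_idx],
                        GAConfig(**{**ga_config.__dict__, "seed": ga_seed}),
                        cost_model=cm, catalog_names=feat_cols)
        names = sorted(ga_res.best.feature_set)
        selected.append(names)
        nops.append(float(ga_res.best.nop))

        Xd = np.asarray(design[names], dtype=float)
        model = mlp_train(Xd, labels[design_idx], subjects[design_idx], classes,
                          mlp_cfg, seed=int(rng.integers(0, 2**31 - 1)))
        Xt = np.asarray(feature_table.iloc[test_idx][names], dtype=float)
        pred = model.predict(Xt)
        fold_conf = np.zeros((m, m), dtype=int)
        for true_lbl, p in zip(labels[test_idx], pred):
            fold_conf[classes.index(true_lbl), p] += 1
        confusion += fold_conf
        result_folds.append(fold_conf)
        if progress is not None:
            progress(fold_i, names, fold_conf)

    per_class, average = error_metrics(confusion)
    return CVResult(confusion=confusion, classes=classes,
                    per_class_error=per_class, average_error=average,
                    selected_features=selected, nop=nops,
                    fold_confusions=result_folds)


def nmax_sweep(feature_table: pd.DataFrame, nmax_values,
               ga_config: GAConfig, mlp_config: MLPConfig | None = None,
               repetitions: int = 1, seed: int = 0) -> pd.DataFrame:
    """Average error distribution across a grid of operation budgets.

    Returns one row per (nmax, repetition) with the achieved average error
    and median Nop, suitable for box-plot style summaries.
    """
    if repetitions < 1:
        raise ValueError("need at least one repetition")
    rng = np.random.default_rng(seed)
    rows = []
    for nmax in nmax_values:
        for rep in range(repetitions):
            cfg = GAConfig(**{**ga_config.__dict__, "nmax": float(nmax)})
            res = run_analysis(feature_table, cfg, mlp_config,
                               seed=int(rng.integers(0, 2**31 - 1)))
            rows.append({"nmax": float(nmax), "repetition": rep,
                         "average_error": res.average_error,
                         "median_nop": float(np.median(res.nop))})
    return pd.DataFrame(rows)


def sweep_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Quantiles of the average error per budget (box-plot summary)."""
    return (sweep.groupby("nmax")["average_error"]
            .quantile([0.0, 0.25, 0.5, 0.75, 1.0]).unstack()
            .rename(columns={0.0: "min", 0.25: "q25", 0.5: "median",
                             0.75: "q75", 1.0: "max"}))
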