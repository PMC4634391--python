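"""The 112-feature catalog: 14 window statistics per IF signal.

Each feature is a (measurement, signal, parameter) triple: 2 measurements
(ECG, TEB) x 4 signals each x 14 parameters = 112.  Features are computed
over 60 s sliding windows advancing every 10 s on the 50 Hz IF traces.

Parameter conventions (fixed, documented for reproducibility):

* kurtosis is non-excess (a normal distribution scores 3);
* the 25% trimmed mean discards 12.5% of the sorted samples at each end;
* percentiles interpolate linearly between order statistics;
* geometric and harmonic means are defined only for positive windows and
  propagate as NaN otherwise (windows with any missing selected feature
  are excluded from training);
* ``baseline`` is the long-term mean tracked by a first-order low-pass
  IIR filter over the whole trace, sampled at the window's end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

from .rates import IFSignalSet, IF_SIGNAL_NAMES

__all__ = [
    "PARAMETERS",
    "FeatureDescriptor",
    "catalog",
    "compute_parameter",
    "baseline_tracker",
    "extract_features",
    "WINDOW_S",
    "STRIDE_S",
    "BASELINE_ALPHA",
]

WINDOW_S = 60.0
STRIDE_S = 10.0

#: time constant of the baseline IIR: ~300 s at the 50 Hz IF rate, matching
#: the scale of the resting intervals between recording stages
BASELINE_ALPHA = 1.0 / (300.0 * 50.0)

PARAMETERS = (
    "mean",
    "std",
    "trimmed_mean_25",
    "median",
    "skewness",
    "kurtosis",
    "max",
    "min",
    "p25",
    "p75",
    "geometric_mean",
    "harmonic_mean",
    "mean_abs_dev",
    "baseline",
)

_ECG_SIGNALS = ("ecf", "ert", "erd", "eppm")
_TEB_SIGNALS = ("zcf", "zrt", "zrd", "zppm")


@dataclass(frozen=True)
class FeatureDescriptor:
    """One catalog entry, named ``ECG.ECF.mean`` style."""

    measurement: str  # "ECG" | "TEB"
    signal: str       # one of the 8 IF signal names (lowercase)
    parameter: str

    def __post_init__(self) -> None:
        if self.measurement not in ("ECG", "TEB"):
            raise ValueError(f"unknown measurement {self.measurement!r}")
        expected = _ECG_SIGNALS if self.measurement == "ECG" else _TEB_SIGNALS
        if self.signal not in expected:
            raise ValueError(f"signal {self.signal!r} does not belong to "
                             f"{self.measurement}")
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")

    @property
    def name(self) -> str:
        return f"{self.measurement}.{self.signal.upper()}.{self.parameter}"

    @classmethod
    def from_name(cls, name: str) -> "FeatureDescriptor":
        try:
            meas, sig, param = name.split(".")
        except ValueError:
            raise ValueError(f"malformed feature name {name!r}") from None
        return cls(measurement=meas, signal=sig.lower(), parameter=param)


def catalog() -> list[FeatureDescriptor]:
    """All 112 descriptors in canonical (measurement, signal, parameter) order."""
    out = []
    for meas, signals in (("ECG", _ECG_SIGNALS), ("TEB", _TEB_SIGNALS)):
        for sig in signals:
            for param in PARAMETERS:
                out.append(FeatureDescriptor(meas, sig, param))
    return out


def compute_parameter(x: np.ndarray, parameter: str) -> float:
    """One window statistic by its standard definition (see module docs)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        return float("nan")
    if parameter == "mean":
        return float(np.mean(x))
    if parameter == "std":
        return float(np.std(x, ddof=0))
    if parameter == "trimmed_mean_25":
        # explicit full sort: matches the shared-sort cost accounting
        k = int(0.125 * x.size)
        return float(np.mean(np.sort(x)[k : x.size - k]))
    if parameter == "median":
        return float(np.median(x))
    if parameter == "skewness":
        s = float(np.std(x, ddof=0))
        if s == 0.0:
            return 0.0
        return float(sst.skew(x, bias=True))
    if parameter == "kurtosis":
        s = float(np.std(x, ddof=0))
        if s == 0.0:
            return 0.0
        return float(sst.kurtosis(x, fisher=False, bias=True))
    if parameter == "max":
        return float(np.max(x))
    if parameter == "min":
        return float(np.min(x))
    if parameter == "p25":
        return float(np.percentile(x, 25.0))
    if parameter == "p75":
        return float(np.percentile(x, 75.0))
    if parameter == "geometric_mean":
        if np.any(x <= 0):
            return float("nan")
        return float(sst.gmean(x))
    if parameter == "harmonic_mean":
        if np.any(x <= 0):
            return float("nan")
        return float(sst.hmean(x))
    if parameter == "mean_abs_dev":
        return float(np.mean(np.abs(x - np.mean(x))))
    raise ValueError(f"unknown parameter {parameter!r}")


def baseline_tracker(x: np.ndarray, alpha: float = BASELINE_ALPHA) -> np.ndarray:
    """First-order IIR long-term mean: b[n] = (1-a) b[n-1] + a x[n], b[0]=x[0]."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    from scipy.signal import lfilter

    b, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x,
                   zi=np.array([(1.0 - alpha) * x[0]]))
    return b


def window_count(duration_s: float, window_s: float = WINDOW_S,
                 stride_s: float = STRIDE_S) -> int:
    """Number of complete sliding windows in a span of ``duration_s``."""
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / stride_s)) + 1


def _window_label(labels: list[tuple[float, float, str]], t0: float, t1: float,
                  majority: float) -> str | None:
    """Majority label of [t0, t1); None if below the majority threshold."""
    cover: dict[str, float] = {}
    for start, end, lbl in labels:
        ov = min(end, t1) - max(start, t0)
        if ov > 0:
            cover[lbl] = cover.get(lbl, 0.0) + ov
    if not cover:
        return None
    best, span = max(cover.items(), key=lambda kv: kv[1])
    return best if span >= majority * (t1 - t0) else None


def extract_features(if_signals: IFSignalSet,
                     selection: list[FeatureDescriptor] | None = None,
                     label_intervals: list[tuple[float, float, str]] | None = None,
                     subject_id: str = "",
                     window_s: float = WINDOW_S, stride_s: float = STRIDE_S,
                     majority: float = 0.9,
                     baseline_alpha: float = BASELINE_ALPHA) -> pd.DataFrame:
    """Feature matrix over sliding windows of one recording.

    Returns a DataFrame with one row per retained window: the selected
    feature columns (named ``ECG.ECF.mean`` style) plus ``subject_id``,
    ``label`` and ``t_start``.  Windows whose majority label covers less
    than ``majority`` of the span are dropped (they straddle a class
    boundary), as are windows overlapping an invalid detector span.
    """
    if selection is None:
        selection = catalog()
    fs = if_signals.if_rate
    n = if_signals.n_samples
    w = int(round(window_s * fs))
    s = int(round(stride_s * fs))
    if n < w:
        return pd.DataFrame(columns=[d.name for d in selection]
                            + ["subject_id", "label", "t_start"])

    baselines = {}
    needed_signals = {d.signal for d in selection}
    for sig in needed_signals:
        trace = if_signals[sig]
        if np.all(np.isfinite(trace)):
            baselines[sig] = baseline_tracker(trace, baseline_alpha)
        else:
            baselines[sig] = np.full(n, np.nan)

    rows = []
    for i0 in range(0, n - w + 1, s):
        t0, t1 = i0 / fs, (i0 + w) / fs
        label = None
        if label_intervals is not None:
            label = _window_label(label_intervals, t0, t1, majority)
            if label is None:
                continue
        row = {}
        for d in selection:
            seg = if_signals[d.signal][i0 : i0 + w]
            if d.parameter == "baseline":
                row[d.name] = float(baselines[d.signal][i0 + w - 1])
            else:
                row[d.name] = compute_parameter(seg, d.parameter)
        row["subject_id"] = subject_id
        row["label"] = label
        row["t_start"] = t0
        rows.append(row)
    return pd.DataFrame(rows)


def extract_cohort_features(recordings, selection=None, **kwargs) -> pd.DataFrame:
    """Concatenate per-recording feature matrices for a cohort.

    ``recordings`` yields (RawRecording, IFSignalSet) pairs or
    RawRecording objects (in which case the IF signals are computed here).
    """
    from .rates import assemble_if_signals

    frames = []
    for item in recordings:
        if isinstance(item, tuple):
            rec, sig = item
        else:
            rec, sig = item, assemble_if_signals(item.ecg, item.teb,
                                                 item.ecg_fs, item.teb_fs)
        frames.append(extract_features(sig, selection,
                                       label_intervals=rec.label_intervals,
                                       subject_id=rec.subject_id, **kwargs))
    df = pd.concat(frames, ignore_index=True)
    feat_cols = [c for c in df.columns if c not in ("subject_id", "label", "t_start")]
    return df.dropna(subset=feat_cols).reset_index(drop=True)


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
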