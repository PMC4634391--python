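"""Cycle detectors and the eight intermediate-frequency (IF) signals.

Two detectors turn band-limited oscillations into per-cycle events:

* the BPM block assumes a roughly sine-shaped input and tracks alternating
  minima/maxima with an adaptive hysteresis, yielding a rate (60 / period
  between successive maxima) and a per-cycle amplitude (max - min);
* the PPM block marks heart beats where the five-sample differentiation of
  the pulse-bearing signal crosses an adaptive threshold upward, subject to
  a refractory period.

A zero-order-hold interpolator then turns the sparse events into uniform
50 Hz traces, giving the eight IF signals: ECF, ERT, ERD and EPPM from the
ECG chain and ZCF, ZRT, ZRD and ZPPM from the bioimpedance chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filterbank import (
    IF_RATE,
    decimate_to_if,
    ecg_filter_chain,
    teb_filter_chain,
)

__all__ = [
    "CycleEvents",
    "IFSignalSet",
    "bpm_block",
    "ppm_block",
    "zoh_interpolate",
    "assemble_if_signals",
    "IF_SIGNAL_NAMES",
]

IF_SIGNAL_NAMES = ("ecf", "ert", "erd", "eppm", "zcf", "zrt", "zrd", "zppm")


class EmptyEventsError(ValueError):
    """Raised when an event stream is required but no cycles were found."""


@dataclass
class CycleEvents:
    """Per-cycle detections: times (s), rates (per minute) and, for the
    BPM block, peak-to-trough amplitudes."""

    times: np.ndarray
    rates: np.ndarray
    amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if np.any(self.rates <= 0):
                raise ValueError("rates must be positive")

    def __len__(self) -> int:
        return len(self.times)


def _block_quantile(x: np.ndarray, fs: float, block_s: float, trail_blocks: int,
                    q: float, reducer=None) -> np.ndarray:
    """Per-sample trailing quantile, updated once per ``block_s`` seconds."""
    n = len(x)
    bs = max(1, int(round(block_s * fs)))
    n_blocks = int(np.ceil(n / bs))
    out = np.empty(n)
    vals = []
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, n)
        window = x[max(0, (b - trail_blocks + 1)) * bs : hi]
        if reducer is not None:
            v = reducer(window)
        else:
            v = np.quantile(window, q) if window.size else 0.0
        out[lo:hi] = v
        vals.append(v)
    return out


def bpm_block(x: np.ndarray, fs: float, hysteresis: float = 0.20,
              p2p_window_s: float = 10.0, min_cycle_s: float = 0.0) -> CycleEvents:
    """Detect alternating extrema of a sine-shaped signal.

    An extremum is confirmed once the signal retreats from the running
    candidate by ``hysteresis`` times a trailing peak-to-peak estimate
    (updated blockwise over ``p2p_window_s``), which makes the detector
    invariant to amplitude scaling and robust to in-band noise.  Rates are
    derived from maxima-to-maxima intervals; the amplitude of a cycle is
    the confirmed maximum minus the minimum seen within that cycle.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return CycleEvents(np.empty(0), np.empty(0), np.empty(0))

    p2p = _block_quantile(x, fs, 1.0, int(p2p_window_s),
                          0.0, reducer=lambda w: np.ptp(w) if w.size else 0.0)
    maxima_t: list[float] = []
    maxima_v: list[float] = []
    minima_v: list[float] = []
    rising = True
    cand_v, cand_i = x[0], 0
    last_min = x[0]
    for i in range(1, len(x)):
        h = hysteresis * p2p[i]
        if h <= 0:
            continue
        v = x[i]
        if rising:
            if v > cand_v:
                cand_v, cand_i = v, i
            elif cand_v - v > h:
                t_cand = cand_i / fs
                if maxima_t and t_cand - maxima_t[-1] < min_cycle_s:
                    # refractory: merge into the previous maximum
                    if cand_v > maxima_v[-1]:
                        maxima_t[-1], maxima_v[-1] = t_cand, cand_v
                else:
                    maxima_t.append(t_cand)
                    maxima_v.append(cand_v)
                    minima_v.append(last_min)
                rising = False
                cand_v, cand_i = v, i
        else:
            if v < cand_v:
                cand_v, cand_i = v, i
            elif v - cand_v > h:
                last_min = cand_v
                rising = True
                cand_v, cand_i = v, i

    if len(maxima_t) < 2:
        return CycleEvents(np.empty(0), np.empty(0), np.empty(0))

    mt = np.asarray(maxima_t)
    mv = np.asarray(maxima_v)
    # minima_v[k] is the minimum preceding maximum k; the cycle ending at
    # maximum k spans (max k-1, max k) and its trough is minima_v[k]
    lows = np.asarray(minima_v)
    periods = np.diff(mt)
    rates = 60.0 / periods
    amps = mv[1:] - lows[1:]
    return CycleEvents(times=mt[1:], rates=rates, amplitudes=amps)


def ppm_block(x: np.ndarray, fs: float, diff_lag: int = 5,
              threshold_frac: float = 0.5, percentile: float = 99.0,
              trailing_s: float = 5.0, refractory_s: float = 0.25) -> CycleEvents:
    """Detect heart beats by thresholding the ``diff_lag``-sample difference.

    The threshold adapts as ``threshold_frac`` times the trailing
    ``percentile`` of the positive differences (updated every second over
    the last ``trailing_s`` seconds), so detection is independent of the
    absolute signal scale.  Beats closer than ``refractory_s`` to the
    previous one are rejected.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= diff_lag:
        return CycleEvents(np.empty(0), np.empty(0))
    d = np.empty_like(x)
    d[:diff_lag] = 0.0
    d[diff_lag:] = x[diff_lag:] - x[:-diff_lag]

    pos = np.where(d > 0, d, 0.0)
    thr = threshold_frac * _block_quantile(pos, fs, 1.0, int(max(1, trailing_s)),
                                           percentile / 100.0)
    thr = np.maximum(thr, 1e-12)
    above = d > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1

    refractory = int(round(refractory_s * fs))
    beats: list[int] = []
    last = -refractory - 1
    for i in crossings:
        if i - last > refractory:
            beats.append(i)
            last = i
    if len(beats) < 2:
        return CycleEvents(np.empty(0), np.empty(0))
    bt = np.asarray(beats, dtype=float) / fs
    rates = 60.0 / np.diff(bt)
    return CycleEvents(times=bt[1:], rates=rates)


def zoh_interpolate(events: CycleEvents, duration_s: float,
                    if_rate: float = IF_RATE) -> tuple[np.ndarray, np.ndarray | None]:
    """Piecewise-constant (hold-last-value) interpolation onto the IF grid.

    Samples before the first event take the first event's value; a sample
    coinciding exactly with an event time takes the new value.  Returns the
    rate trace and, when the events carry amplitudes, the amplitude trace.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    if len(events) == 0:
        raise EmptyEventsError("cannot interpolate an empty event stream")
    n = int(round(duration_s * if_rate))
    t = np.arange(n) / if_rate
    idx = np.searchsorted(events.times, t, side="right") - 1
    idx = np.clip(idx, 0, None)
    rate_trace = events.rates[idx]
    amp_trace = events.amplitudes[idx] if events.amplitudes is not None else None
    return rate_trace, amp_trace


@dataclass
class IFSignalSet:
    """The eight derived signals on the common 50 Hz grid.

    ERT/ZRT are in breaths/min, EPPM/ZPPM in beats/min, ERD/ZRD in the
    input's amplitude units.  Traces whose detector found no cycles are
    filled with NaN and flagged in ``invalid``; feature windows touching
    them are dropped downstream.
    """

    ecf: np.ndarray
    ert: np.ndarray
    erd: np.ndarray
    eppm: np.ndarray
    zcf: np.ndarray
    zrt: np.ndarray
    zrd: np.ndarray
    zppm: np.ndarray
    if_rate: float = IF_RATE
    invalid: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lengths = {len(getattr(self, k)) for k in IF_SIGNAL_NAMES}
        if len(lengths) != 1:
            raise ValueError(f"IF traces have unequal lengths: {sorted(lengths)}")

    def __getitem__(self, name: str) -> np.ndarray:
        if name.lower() not in IF_SIGNAL_NAMES:
            raise KeyError(name)
        return getattr(self, name.lower())

    @property
    def n_samples(self) -> int:
        return len(self.ecf)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.if_rate

    def as_array(self) -> np.ndarray:
        """(n_samples, 8) array in canonical signal order."""
        return np.column_stack([getattr(self, k) for k in IF_SIGNAL_NAMES])


def _hold_or_nan(events: CycleEvents, duration_s: float, if_rate: float,
                 want_amp: bool, invalid: list[str], names: tuple[str, ...]):
    n = int(round(duration_s * if_rate))
    if len(events) == 0:
        invalid.extend(names)
        nan = np.full(n, np.nan)
        return (nan, nan.copy()) if want_amp else (nan, None)
    return zoh_interpolate(events, duration_s, if_rate)


def assemble_if_signals(ecg: np.ndarray, teb: np.ndarray,
                        ecg_fs: float = 250.0, teb_fs: float = 100.0,
                        if_rate: float = IF_RATE,
                        zppm_hysteresis: float = 0.30,
                        bpm_hysteresis: float = 0.20) -> IFSignalSet:
    """Run both filter chains and the cycle detectors; return the 8 traces.

    ECF/ZCF are the decimated continuous-frequency outputs; ERT/ERD (and
    ZRT/ZRD) hold the respiration rate and depth from the BPM block on the
    respiration band; EPPM holds the PPM-block heart rate from the ECG
    pulse branch; ZPPM reuses the BPM block, with a wider hysteresis, on
    the bioimpedance pulse band whose cardiac component is oscillatory
    rather than spiky.
    """
    ecg_f = ecg_filter_chain(ecg)
    teb_f = teb_filter_chain(teb)

    duration = min(len(ecg) / ecg_fs, len(teb) / teb_fs)
    n_if = int(duration * if_rate)
    duration = n_if / if_rate
    invalid: list[str] = []

    ecf = decimate_to_if(ecg_f.fe1, ecg_fs, if_rate)[:n_if]
    zcf = decimate_to_if(teb_f.fe1, teb_fs, if_rate)[:n_if]

    e_resp = bpm_block(ecg_f.fe2, ecg_fs, hysteresis=bpm_hysteresis)
    ert, erd = _hold_or_nan(e_resp, duration, if_rate, True, invalid, ("ert", "erd"))

    e_beat = ppm_block(ecg_f.fe3, ecg_fs)
    eppm, _ = _hold_or_nan(e_beat, duration, if_rate, False, invalid, ("eppm",))

    z_resp = bpm_block(teb_f.fe2, teb_fs, hysteresis=bpm_hysteresis)
    zrt, zrd = _hold_or_nan(z_resp, duration, if_rate, True, invalid, ("zrt", "zrd"))

    z_beat = bpm_block(teb_f.fe3, teb_fs, hysteresis=zppm_hysteresis,
                       min_cycle_s=0.3)
    zppm, _ = _hold_or_nan(z_beat, duration, if_rate, False, invalid, ("zppm",))

    traces = dict(ecf=ecf, ert=ert, erd=erd, eppm=eppm,
                  zcf=zcf, zrt=zrt, zrd=zrd, zppm=zppm)
    for k, v in traces.items():
        if len(v) != n_if:
            traces[k] = v[:n_if]
    return IFSignalSet(**traces, if_rate=if_rate, invalid=tuple(invalid))


def export_if_signals(signals: IFSignalSet, path) -> None:
    """Write the eight traces as a delimited text table (one row per sample)."""
    header = "time_s\t" + "\t".join(n.upper() for n in IF_SIGNAL_NAMES)
    t = np.arange(signals.n_samples) / signals.if_rate
    data = np.column_stack([t, signals.as_array()])
    np.savetxt(path, data, delimiter="\t", header=header, comments="")
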