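"""FIR/IFIR filterbank front end.

Both measurement chains start with the same structure: a short FIR
anti-aliasing low-pass (the LF block), a pair of very-narrow-band filters
realised as interpolated FIR (IFIR) structures — a continuous-frequency
low-pass (CF, <= 0.1 Hz) and a respiration band-pass (RF, 0.1-0.5 Hz) —
and a wider branch carrying the pulse information (the MF block for ECG,
a pulse band-pass for bioimpedance).  All filtered signals are then
decimated to a common intermediate frequency (IF, 50 Hz).

An IFIR filter of total order ``N`` with stretch factor ``SF`` stores only
``N/SF + 1`` non-zero coefficients: the prototype is designed against the
band edges scaled up by ``SF`` and its impulse response is zero-stuffed,
which compresses the frequency axis by ``SF``.  The spectral images this
creates (at multiples of ``fs/SF``) are removed by the preceding LF
anti-aliasing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "FilteredSignals",
    "design_filter",
    "frequency_response",
    "apply_filter",
    "ecg_filter_chain",
    "teb_filter_chain",
    "decimate_to_if",
    "ECG_FS",
    "TEB_FS",
    "IF_RATE",
]

ECG_FS = 250.0
TEB_FS = 100.0
IF_RATE = 50.0

_KINDS = ("fir_lowpass", "ifir_lowpass", "ifir_bandpass")


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filter block.

    ``order`` is the total order of the realised filter (number of taps
    minus one); for IFIR kinds it must be divisible by ``stretch`` and the
    stored prototype has ``order/stretch + 1`` taps.  ``cutoffs`` are the
    band edges in Hz at the operating rate ``fs``.
    """

    kind: str
    order: int
    cutoffs: tuple[float, ...]
    fs: float
    stretch: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order <= 0:
            raise ValueError("filter order must be positive")
        if self.stretch < 1:
            raise ValueError("stretch factor must be >= 1")
        if self.kind.startswith("ifir") and self.order % self.stretch:
            raise ValueError("IFIR order must be a multiple of the stretch factor")
        nyq = self.fs / 2.0
        cuts = tuple(float(c) for c in self.cutoffs)
        if not cuts:
            raise ValueError("at least one cutoff frequency is required")
        for c in cuts:
            if not 0.0 < c < nyq:
                raise ValueError(f"cutoff {c} Hz outside (0, {nyq}) Hz")
        if self.kind == "ifir_bandpass" and len(cuts) != 2:
            raise ValueError("band-pass needs two cutoffs")
        object.__setattr__(self, "cutoffs", cuts)

    @property
    def n_taps(self) -> int:
        return self.order + 1

    @property
    def group_delay(self) -> int:
        """Delay of the linear-phase response, in samples (order/2)."""
        return self.order // 2

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "order": self.order,
            "cutoffs": list(self.cutoffs),
            "fs": self.fs,
            "stretch": self.stretch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(
            kind=d["kind"],
            order=int(d["order"]),
            cutoffs=tuple(d["cutoffs"]),
            fs=float(d["fs"]),
            stretch=int(d.get("stretch", 1)),
        )


def design_filter(spec: FilterSpec) -> np.ndarray:
    """Return the impulse response (taps) for a :class:`FilterSpec`.

    Plain FIR low-passes use a Hamming-windowed sinc.  IFIR prototypes are
    least-squares designs against the stretched band edges: the pass/stop
    edges are placed at half and a few multiples of the nominal cutoff so
    that the modest prototype order is spent on stop-band rejection rather
    than on an unattainably sharp transition.  All responses are linear
    phase with unit pass-band gain.
    """
    nyq = spec.fs / 2.0
    if spec.kind == "fir_lowpass":
        taps = sps.firwin(spec.n_taps, spec.cutoffs[0], fs=spec.fs, window="hamming")
        return taps

    p_order = spec.order // spec.stretch
    if p_order % 2:  # firls needs an odd tap count (type-I linear phase)
        raise ValueError("IFIR prototype order must be even")
    s = float(spec.stretch)
    # least-squares designs leave transition bands unconstrained, so keep
    # every transition no wider than the prototype's frequency resolution
    res = 3.5 * spec.fs / (p_order + 1)

    if spec.kind == "ifir_lowpass":
        fc = spec.cutoffs[0] * s  # stretched-domain cutoff
        stop = min(2.0 * fc, 0.5 * fc + res, 0.95 * nyq)
        bands = [0.0, 0.5 * fc, stop, nyq]
        desired = [1.0, 1.0, 0.0, 0.0]
        weights = [1.0, 10.0]
    else:  # ifir_bandpass
        f1, f2 = spec.cutoffs[0] * s, spec.cutoffs[1] * s
        lo_stop = 0.4 * f1
        lo_pass = min(1.5 * f1, 0.6 * (f1 + f2))
        hi_pass = 0.9 * f2
        hi_stop = min(1.45 * hi_pass, hi_pass + res, 0.95 * nyq)
        if hi_stop <= hi_pass:
            raise ValueError("band-pass upper edge too close to Nyquist")
        bands = [0.0, lo_stop, lo_pass, hi_pass, hi_stop, nyq]
        desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
        weights = [10.0, 1.0, 10.0]

    proto = sps.firls(p_order + 1, bands, desired, weight=weights, fs=spec.fs)
    taps = np.zeros(spec.order + 1)
    taps[:: spec.stretch] = proto

    # normalise pass-band gain to unity
    if spec.kind == "ifir_lowpass":
        taps /= taps.sum()
    else:
        f_ref = np.sqrt(spec.cutoffs[0] * spec.cutoffs[1])
        w, h = sps.freqz(taps, worN=[f_ref], fs=spec.fs)
        taps /= np.abs(h[0])
    return taps


def frequency_response(spec: FilterSpec, freqs_hz) -> np.ndarray:
    """Complex frequency response of the designed filter at ``freqs_hz``."""
    taps = design_filter(spec)
    _, h = sps.freqz(taps, worN=np.atleast_1d(np.asarray(freqs_hz, dtype=float)), fs=spec.fs)
    return h


def apply_filter(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Zero-phase application of a linear-phase FIR.

    The input is extended by reflection over half the filter length at each
    end and the central ``len(x)`` samples of the convolution are returned,
    so the output is time-aligned with the input (group delay compensated).
    """
    x = np.asarray(x, dtype=float)
    half = (len(taps) - 1) // 2
    if half == 0:
        return sps.fftconvolve(x, taps, mode="same")
    pad = min(half, len(x) - 1)
    left = x[1 : pad + 1][::-1]
    right = x[-pad - 1 : -1][::-1]
    ext = np.concatenate([left, x, right])
    y = sps.fftconvolve(ext, taps, mode="same")
    return y[pad : pad + len(x)]


@dataclass
class FilteredSignals:
    """Outputs of step 1 for one measurement channel, at the native rate.

    ``fe1`` carries the continuous (near-DC) component, ``fe2`` the
    respiration band, ``fe3`` the pulse-bearing branch.  ``warmup`` is the
    number of leading/trailing samples inside the longest filter's half
    length, where edge extension makes the outputs only approximately valid.
    """

    fe1: np.ndarray
    fe2: np.ndarray
    fe3: np.ndarray
    fs: float
    warmup: int = 0
    specs: dict = field(default_factory=dict)


def ecg_specs() -> dict[str, FilterSpec]:
    """The four ECG filter blocks (250 Hz chain)."""
    return {
        "lf": FilterSpec("fir_lowpass", 100, (0.5,), ECG_FS),
        "mf": FilterSpec("fir_lowpass", 100, (30.0,), ECG_FS),
        "cf": FilterSpec("ifir_lowpass", 1150, (0.1,), ECG_FS, stretch=25),
        "rf": FilterSpec("ifir_bandpass", 1150, (0.1, 0.5), ECG_FS, stretch=25),
    }


def teb_specs() -> dict[str, FilterSpec]:
    """The four bioimpedance filter blocks (100 Hz chain).

    The pulse branch is a 0.5-5 Hz band-pass bracketing the physiological
    pulse range (30-300 beats/min); it runs on the raw signal since the
    anti-aliasing low-pass would destroy the cardiac component.
    """
    return {
        "lf": FilterSpec("fir_lowpass", 100, (0.5,), TEB_FS),
        "cf": FilterSpec("ifir_lowpass", 400, (0.1,), TEB_FS, stretch=10),
        "rf": FilterSpec("ifir_bandpass", 400, (0.1, 0.5), TEB_FS, stretch=10),
        "pulse": FilterSpec("ifir_bandpass", 400, (0.5, 5.0), TEB_FS, stretch=2),
    }


def _chain(x: np.ndarray, specs: dict[str, FilterSpec], pulse_key: str) -> FilteredSignals:
    designs = {k: design_filter(s) for k, s in specs.items()}
    lf_out = apply_filter(designs["lf"], x)
    fe1 = apply_filter(designs["cf"], lf_out)
    fe2 = apply_filter(designs["rf"], lf_out)
    fe3 = apply_filter(designs[pulse_key], x)
    warmup = max(s.group_delay for s in specs.values()) + specs["lf"].group_delay
    return FilteredSignals(
        fe1=fe1, fe2=fe2, fe3=fe3, fs=specs["lf"].fs, warmup=warmup,
        specs={k: s.to_dict() for k, s in specs.items()},
    )


def ecg_filter_chain(ecg: np.ndarray) -> FilteredSignals:
    """Filter a raw 250 Hz ECG into FE1 (CF), FE2 (RF) and FE3 (MF) signals.

    LF and MF run in parallel on the raw input; the IFIR pair runs on the
    LF output, which doubles as the image suppressor for the zero-stuffed
    prototypes.
    """
    ecg = np.asarray(ecg, dtype=float)
    specs = ecg_specs()
    min_len = specs["cf"].n_taps
    if len(ecg) < min_len:
        raise ValueError(f"need at least {min_len} samples (one CF filter length)")
    return _chain(ecg, specs, "mf")


def teb_filter_chain(teb: np.ndarray) -> FilteredSignals:
    """Filter a raw 100 Hz bioimpedance signal; FE3 is the pulse band."""
    teb = np.asarray(teb, dtype=float)
    specs = teb_specs()
    min_len = specs["cf"].n_taps
    if len(teb) < min_len:
        raise ValueError(f"need at least {min_len} samples (one CF filter length)")
    return _chain(teb, specs, "pulse")


def decimate_to_if(x: np.ndarray, fs: float, target_if: float = IF_RATE) -> np.ndarray:
    """Keep every ``fs/target_if``-th sample (phase 0).

    The caller is responsible for the signal being band-limited below
    ``target_if/2``.  Output length is ``floor(n * target_if / fs)``.
    """
    ratio = fs / target_if
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(f"sampling rate {fs} is not an integer multiple of {target_if}")
    x = np.asarray(x)
    n_out = len(x) // factor
    return x[: n_out * factor : factor].copy()
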