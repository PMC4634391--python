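"""Synthetic multi-subject ECG + bioimpedance recordings.

The generator emulates the statistical structure of the study conditions:
each class (activity type, emotional state or mental-load level) has
class-conditional means for the eight IF signals — continuous level,
respiration rate and depth, and heart rate — and each subject carries a
multiplicative offset drawn once per subject, so that subject identity is
a confounder that leave-one-subject-out evaluation must respect.

The ECG channel is a quasi-periodic train of narrow raised-cosine pulses
(the pulse detector thresholds a differentiated signal, so beat morphology
beyond a sharp rise is irrelevant) plus respiration-coupled baseline
wander below 0.5 Hz, a constant class-dependent level and white noise.
The bioimpedance channel is a respiration oscillation plus a smaller
cardiac-frequency oscillation, a level and noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ECG_FS = 250.0
TEB_FS = 100.0

#: Class-conditional mean values of the eight IF signals used as generator
#: defaults (rows: continuous level, respiration rate/depth, heart rate for
#: each measurement).  Activity classes come from the activity analysis,
#: sad/disgust from the emotional-state analysis and low/high mental load
#: from the mental-activity analysis.
CLASS_TABLE: dict[str, dict[str, float]] = {
    "neutral":     dict(ecf=4.92, ert=28.17, erd=0.32, eppm=72.07,
                        zcf=5.61, zrt=19.44, zrd=0.09, zppm=74.36),
    "emotional":   dict(ecf=4.93, ert=29.62, erd=0.40, eppm=70.99,
                        zcf=6.33, zrt=20.10, zrd=0.16, zppm=71.99),
    "mental":      dict(ecf=4.92, ert=27.69, erd=0.45, eppm=74.62,
                        zcf=5.74, zrt=20.50, zrd=0.27, zppm=74.30),
    "physical":    dict(ecf=5.36, ert=24.75, erd=1.20, eppm=130.43,
                        zcf=7.89, zrt=27.17, zrd=0.67, zppm=93.86),
    "sad":         dict(ecf=4.93, ert=29.53, erd=0.43, eppm=70.21,
                        zcf=5.74, zrt=19.85, zrd=0.09, zppm=72.62),
    "disgust":     dict(ecf=4.92, ert=28.46, erd=0.43, eppm=71.12,
                        zcf=6.89, zrt=20.27, zrd=0.23, zppm=71.80),
    "low_mental":  dict(ecf=4.92, ert=28.76, erd=0.44, eppm=74.37,
                        zcf=5.75, zrt=20.97, zrd=0.19, zppm=74.34),
    "high_mental": dict(ecf=4.92, ert=27.59, erd=0.45, eppm=74.77,
                        zcf=5.72, zrt=20.46, zrd=0.25, zppm=74.35),
}

CLASS_GROUPS = {
    "activity": ("neutral", "emotional", "mental", "physical"),
    "emotion": ("neutral", "sad", "disgust"),
    "mental": ("low_mental", "high_mental"),
}


@dataclass(frozen=True)
class ClassCondition:
    """Target physiology for one class: heart rate (beats/min), respiration
    rate (breaths/min) and respiration depth (amplitude units), plus the
    continuous levels and the bioimpedance-side counterparts."""

    class_label: str
    hr_mean: float
    rr_mean: float
    resp_depth_mean: float
    ecf_level: float = 4.92
    teb_level: float = 5.61
    teb_rr_mean: float | None = None
    teb_resp_depth: float | None = None
    teb_cardiac_amp: float = 0.10

    def __post_init__(self) -> None:
        if not 30.0 < self.hr_mean < 220.0:
            raise ValueError(f"heart rate {self.hr_mean} outside (30, 220)")
        if not 4.0 < self.rr_mean < 60.0:
            raise ValueError(f"respiration rate {self.rr_mean} outside (4, 60)")

    @classmethod
    def from_label(cls, label: str) -> "ClassCondition":
        try:
            row = CLASS_TABLE[label]
        except KeyError:
            raise ValueError(f"unknown class label {label!r}") from None
        return cls(
            class_label=label,
            hr_mean=row["eppm"], rr_mean=row["ert"], resp_depth_mean=row["erd"],
            ecf_level=row["ecf"], teb_level=row["zcf"],
            teb_rr_mean=row["zrt"], teb_resp_depth=row["zrd"],
        )


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject state: baseline physiology and the multiplicative
    offsets (drawn once from ``seed``) applied to every class mean."""

    subject_id: str
    baseline_hr: float = 72.0
    baseline_rr: float = 20.0
    baseline_resp_depth: float = 0.3
    inter_subject_jitter: float = 0.05
    seed: int = 0
    hr_factor: float = field(init=False, default=1.0)
    rr_factor: float = field(init=False, default=1.0)
    depth_factor: float = field(init=False, default=1.0)

    def __post_init__(self) -> None:
        if not 30.0 < self.baseline_hr < 220.0:
            raise ValueError("baseline_hr outside (30, 220)")
        if not 4.0 < self.baseline_rr < 60.0:
            raise ValueError("baseline_rr outside (4, 60)")
        rng = np.random.default_rng(self.seed)
        j = self.inter_subject_jitter
        f = 1.0 + j * rng.standard_normal(3)
        f = np.clip(f, 1.0 - 3.0 * j, 1.0 + 3.0 * j) if j > 0 else np.ones(3)
        object.__setattr__(self, "hr_factor", float(f[0]))
        object.__setattr__(self, "rr_factor", float(f[1]))
        object.__setattr__(self, "depth_factor", float(f[2]))


@dataclass
class RawRecording:
    """Two-channel labelled recording with generator ground truth.

    ``truth`` holds, per schedule segment, the effective (subject-adjusted)
    heart rate, respiration rate and depth actually programmed.
    """

    ecg: np.ndarray
    teb: np.ndarray
    subject_id: str
    label_intervals: list[tuple[float, float, str]]
    ecg_fs: float = ECG_FS
    teb_fs: float = TEB_FS
    truth: list[dict] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.ecg_fs

    def __post_init__(self) -> None:
        d_ecg = len(self.ecg) / self.ecg_fs
        d_teb = len(self.teb) / self.teb_fs
        if abs(d_ecg - d_teb) > 1.0 / min(self.ecg_fs, self.teb_fs) + 1e-9:
            raise ValueError("channel durations differ by more than one sample")
        prev_end = 0.0
        for start, end, _ in self.label_intervals:
            if start < prev_end - 1e-9 or end > d_ecg + 1e-6:
                raise ValueError("label intervals overlap or exceed duration")
            prev_end = end


def _raised_cosine_train(beat_times: np.ndarray, n: int, fs: float,
                         width_s: float = 0.08, amplitude: float = 1.0) -> np.ndarray:
    x = np.zeros(n)
    w = int(round(width_s * fs))
    tpl = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(w) / w))
    for bt in beat_times:
        i0 = int(round(bt * fs))
        i1 = min(i0 + w, n)
        if i0 < n:
            x[i0:i1] += tpl[: i1 - i0]
    return x


def _beat_times(rate_bpm: np.ndarray, fs: float, phase0: float) -> np.ndarray:
    """Integrate an instantaneous rate (beats/min per sample) into event times."""
    phase = phase0 + np.cumsum(rate_bpm / 60.0) / fs
    k = np.arange(np.floor(phase[0]) + 1, np.floor(phase[-1]) + 1)
    return np.interp(k, phase, np.arange(len(phase)) / fs)


def generate_recording(profile: SubjectProfile,
                       schedule: list[tuple[float, ClassCondition]],
                       noise_ecg: float = 0.02, noise_teb: float = 0.01,
                       rate_wobble: float = 0.01) -> RawRecording:
    """Synthesise one subject recording for a (duration, class) schedule.

    ``rate_wobble`` adds slow fractional variation to the instantaneous
    rates so that cycles are not perfectly metronomic.  All randomness is
    driven by ``profile.seed``, so identical inputs give bit-identical
    output.
    """
    if not schedule:
        raise ValueError("schedule is empty")
    durations = [d for d, _ in schedule]
    if any(d <= 0 for d in durations):
        raise ValueError("segment durations must be positive")
    total = float(sum(durations))
    if total < 60.0:
        raise ValueError("total duration must be at least 60 s (one window)")

    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 2718]))
    n_ecg = int(round(total * ECG_FS))
    n_teb = int(round(total * TEB_FS))

    def segment_trace(n: int, fs: float, values: list[float]) -> np.ndarray:
        out = np.empty(n)
        pos = 0.0
        for (dur, _), v in zip(schedule, values):
            i0, i1 = int(round(pos * fs)), int(round((pos + dur) * fs))
            out[i0:min(i1, n)] = v
            pos += dur
        return out

    hr_vals, rr_vals, depth_vals, ecf_vals = [], [], [], []
    zrr_vals, zdepth_vals, zlev_vals, zcard_vals = [], [], [], []
    truth, intervals = [], []
    pos = 0.0
    for dur, cond in schedule:
        hr = cond.hr_mean * profile.hr_factor
        rr = cond.rr_mean * profile.rr_factor
        depth = cond.resp_depth_mean * profile.depth_factor
        zrr = (cond.teb_rr_mean or cond.rr_mean) * profile.rr_factor
        zdepth = (cond.teb_resp_depth if cond.teb_resp_depth is not None
                  else cond.resp_depth_mean) * profile.depth_factor
        hr_vals.append(hr); rr_vals.append(rr); depth_vals.append(depth)
        ecf_vals.append(cond.ecf_level)
        zrr_vals.append(zrr); zdepth_vals.append(zdepth)
        zlev_vals.append(cond.teb_level); zcard_vals.append(cond.teb_cardiac_amp)
        truth.append(dict(start=pos, end=pos + dur, label=cond.class_label,
                          hr=hr, rr=rr, depth=depth, teb_rr=zrr, teb_depth=zdepth))
        intervals.append((pos, pos + dur, cond.class_label))
        pos += dur

    # ECG channel -------------------------------------------------------
    hr_trace = segment_trace(n_ecg, ECG_FS, hr_vals)
    if rate_wobble > 0:
        slow = np.interp(np.arange(n_ecg), np.arange(0, n_ecg, int(5 * ECG_FS)),
                         rng.standard_normal(len(range(0, n_ecg, int(5 * ECG_FS)))))
        hr_trace = hr_trace * (1.0 + rate_wobble * slow)
    beats = _beat_times(hr_trace, ECG_FS, phase0=rng.uniform(0, 1))
    ecg = _raised_cosine_train(beats, n_ecg, ECG_FS)

    rr_trace = segment_trace(n_ecg, ECG_FS, rr_vals)
    resp_phase = rng.uniform(0, 1) + np.cumsum(rr_trace / 60.0) / ECG_FS
    depth_trace = segment_trace(n_ecg, ECG_FS, depth_vals)
    ecg += 0.5 * depth_trace * np.sin(2.0 * np.pi * resp_phase)
    ecg += segment_trace(n_ecg, ECG_FS, ecf_vals)
    ecg += noise_ecg * rng.standard_normal(n_ecg)

    # bioimpedance channel ---------------------------------------------
    zrr_trace = segment_trace(n_teb, TEB_FS, zrr_vals)
    z_resp_phase = rng.uniform(0, 1) + np.cumsum(zrr_trace / 60.0) / TEB_FS
    zdepth_trace = segment_trace(n_teb, TEB_FS, zdepth_vals)
    teb = 0.5 * zdepth_trace * np.sin(2.0 * np.pi * z_resp_phase)

    hr_trace_z = segment_trace(n_teb, TEB_FS, hr_vals)
    card_phase = rng.uniform(0, 1) + np.cumsum(hr_trace_z / 60.0) / TEB_FS
    teb += 0.5 * segment_trace(n_teb, TEB_FS, zcard_vals) * np.sin(2.0 * np.pi * card_phase)
    teb += segment_trace(n_teb, TEB_FS, zlev_vals)
    teb += noise_teb * rng.standard_normal(n_teb)

    return RawRecording(ecg=ecg, teb=teb, subject_id=profile.subject_id,
                        label_intervals=intervals, truth=truth)


def generate_cohort(n_subjects: int, classes: list[ClassCondition], seed: int,
                    duration_per_class: float = 120.0,
                    inter_subject_jitter: float = 0.05,
                    noise_ecg: float = 0.02, noise_teb: float = 0.01,
                    shuffle_order: bool = True) -> list[RawRecording]:
    """One recording per subject with balanced time per class.

    Per-subject offsets are drawn once per subject (from a seed derived
    from ``seed`` and the subject index); the class order within each
    recording is shuffled per subject unless ``shuffle_order`` is False.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not classes:
        raise ValueError("class list is empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31415]))
    recordings = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        profile = SubjectProfile(subject_id=f"S{i:03d}", seed=sub_seed,
                                 inter_subject_jitter=inter_subject_jitter)
        order = list(classes)
        if shuffle_order:
            order = [order[j] for j in rng.permutation(len(order))]
        schedule = [(duration_per_class, c) for c in order]
        recordings.append(generate_recording(profile, schedule,
                                             noise_ecg=noise_ecg,
                                             noise_teb=noise_teb))
    return recordings


def conditions_for(analysis: str) -> list[ClassCondition]:
    """The class conditions for one of the three analyses
    (``activity`` M=4, ``emotion`` M=3, ``mental`` M=2)."""
    try:
        labels = CLASS_GROUPS[analysis]
    except KeyError:
        raise ValueError(f"unknown analysis {analysis!r}; "
                         f"choose from {sorted(CLASS_GROUPS)}") from None
    return [ClassCondition.from_label(lbl) for lbl in labels]


def write_recording(rec: RawRecording, out_dir) -> None:
    """Write a recording as two two-column text files plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, x, fs in (("ecg", rec.ecg, rec.ecg_fs), ("teb", rec.teb, rec.teb_fs)):
        t = np.arange(len(x)) / fs
        np.savetxt(out / f"{rec.subject_id}_{name}.txt",
                   np.column_stack([t, x]), fmt="%.6f",
                   header="time_s\tvalue", comments="", delimiter="\t")
    sidecar = {
        "subject_id": rec.subject_id,
        "ecg_fs": rec.ecg_fs,
        "teb_fs": rec.teb_fs,
        "label_intervals": [list(iv) for iv in rec.label_intervals],
    }
    (out / f"{rec.subject_id}_labels.json").write_text(json.dumps(sidecar, indent=1))


def read_recording(out_dir, subject_id: str) -> RawRecording:
    """Read back a recording written by :func:`write_recording`."""
    out = Path(out_dir)
    sidecar = json.loads((out / f"{subject_id}_labels.json").read_text())
    ecg = np.loadtxt(out / f"{subject_id}_ecg.txt", skiprows=1)[:, 1]
    teb = np.loadtxt(out / f"{subject_id}_teb.txt", skiprows=1)[:, 1]
    return RawRecording(
        ecg=ecg, teb=teb, subject_id=sidecar["subject_id"],
        label_intervals=[tuple(iv) for iv in sidecar["label_intervals"]],
        ecg_fs=sidecar["ecg_fs"], teb_fs=sidecar["teb_fs"],
    )
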