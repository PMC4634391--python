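"""Operations-per-second cost model for feature subsets.

The budget the feature-selection search enforces is the total number of
simple operations per second, Nop, of the processing chain a feature
subset requires.  Filter stage costs follow from their structure:

* a plain FIR of order N at rate fs costs ``N * fs`` operations/s;
* an IFIR of order N with stretch factor SF costs ``N * fs / SF``
  (only every SF-th coefficient is non-zero).

The remaining per-block constants (decimation, cycle detectors) and the
per-parameter costs are adopted as printed constants — their internal
op-counting conventions are not derivable from the block structure.
Stages shared between features are counted once per evaluated subset, and
rank-based parameters (trimmed mean, median, percentiles) of the same
signal share a single sort whose cost dominates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .features import FeatureDescriptor, PARAMETERS, catalog
from .filterbank import FilterSpec

__all__ = [
    "stage_cost",
    "CostModel",
    "PARAMETER_COSTS",
    "SORT_COST",
    "SORT_INCREMENTS",
]

#: per-parameter operations/s; rank-based entries include the shared sort
PARAMETER_COSTS: dict[str, int] = {
    "mean": 300,
    "std": 1201,
    "trimmed_mean_25": 27_805,
    "median": 27_580,
    "skewness": 2101,
    "kurtosis": 2710,
    "max": 300,
    "min": 300,
    "p25": 27_580,
    "p75": 27_580,
    "geometric_mean": 3901,
    "harmonic_mean": 3301,
    "mean_abs_dev": 1200,
    "baseline": 550,
}
assert set(PARAMETER_COSTS) == set(PARAMETERS)

SORT_COST = 27_580
RANK_PARAMS = ("trimmed_mean_25", "median", "p25", "p75")
#: cost on top of the shared sort for each rank-based parameter
SORT_INCREMENTS = {p: PARAMETER_COSTS[p] - SORT_COST for p in RANK_PARAMS}


def stage_cost(spec: FilterSpec) -> float:
    """Operations/s of one filter stage from its structure.

    FIR: order x fs.  IFIR: order x fs / stretch.
    """
    if spec.kind == "fir_lowpass" or spec.stretch == 1:
        return spec.order * spec.fs
    return spec.order * spec.fs / spec.stretch


def _default_stage_table() -> dict[str, float]:
    """Per-second cost of every processing stage.

    Filter stages are computed from their specs; the decimation and
    detector blocks are printed constants.  TEB stage-1 filters are all of
    the IFIR class, including the pulse branch.
    """
    ecg_fir = FilterSpec("fir_lowpass", 100, (0.5,), 250.0)
    ecg_ifir = FilterSpec("ifir_lowpass", 1150, (0.1,), 250.0, stretch=25)
    teb_fir = FilterSpec("fir_lowpass", 100, (0.5,), 100.0)
    teb_ifir = FilterSpec("ifir_lowpass", 400, (0.1,), 100.0, stretch=10)
    c1 = stage_cost(ecg_fir)
    c2 = stage_cost(ecg_ifir)
    d1 = stage_cost(teb_fir)
    d2 = stage_cost(teb_ifir)
    return {
        # ECG chain
        "ecg.lf": c1, "ecg.mf": c1,
        "ecg.cf": c2, "ecg.rf": c2,
        "ecg.decim": 3750.0,      # decimation of FE1 to the IF rate
        "ecg.bpm": 9050.0,        # BPM detector + ZOH interpolation
        "ecg.ppm": 8800.0,        # PPM detector
        # bioimpedance chain
        "teb.lf": d1,
        "teb.cf": d2, "teb.rf": d2, "teb.pulse": d2,
        "teb.decim": 900.0,
        "teb.bpm": 2116.0,        # BPM detector + ZOH (also reused for ZPPM)
        "teb.ppm": 2116.0,
    }


#: stages each IF signal's chain requires
_SIGNAL_STAGES: dict[str, tuple[str, ...]] = {
    "ecf": ("ecg.lf", "ecg.cf", "ecg.decim"),
    "ert": ("ecg.lf", "ecg.rf", "ecg.bpm"),
    "erd": ("ecg.lf", "ecg.rf", "ecg.bpm"),
    "eppm": ("ecg.mf", "ecg.ppm"),
    "zcf": ("teb.lf", "teb.cf", "teb.decim"),
    "zrt": ("teb.lf", "teb.rf", "teb.bpm"),
    "zrd": ("teb.lf", "teb.rf", "teb.bpm"),
    "zppm": ("teb.pulse", "teb.ppm"),
}


@dataclass
class CostModel:
    """Maps feature subsets to total operations/s with shared accounting."""

    stage_table: dict[str, float] = field(default_factory=_default_stage_table)
    parameter_costs: dict[str, int] = field(default_factory=lambda: dict(PARAMETER_COSTS))
    sort_cost: float = SORT_COST

    def _descriptors(self, selection) -> list[FeatureDescriptor]:
        out = []
        for item in selection:
            if isinstance(item, FeatureDescriptor):
                out.append(item)
            else:
                out.append(FeatureDescriptor.from_name(str(item)))
        return out

    def itemize(self, selection) -> dict:
        """Stage-by-stage and parameter-by-parameter breakdown of Nop."""
        descs = self._descriptors(selection)
        stages: set[str] = set()
        params: list[tuple[str, float]] = []
        sorted_signals: set[str] = set()
        for d in descs:
            stages.update(_SIGNAL_STAGES[d.signal])
            if d.parameter in SORT_INCREMENTS:
                key = f"{d.measurement}.{d.signal}"
                if key not in sorted_signals:
                    sorted_signals.add(key)
                    params.append((f"{key}.sort", self.sort_cost))
                params.append((d.name, float(SORT_INCREMENTS[d.parameter])))
            else:
                params.append((d.name, float(self.parameter_costs[d.parameter])))
        stage_items = {s: self.stage_table[s] for s in sorted(stages)}
        total = sum(stage_items.values()) + sum(c for _, c in params)
        return {
            "stages": stage_items,
            "parameters": dict(params),
            "total": total,
        }

    def total_nop(self, selection) -> float:
        """Total operations/s for a feature subset (empty subset costs 0)."""
        if not selection:
            return 0.0
        return self.itemize(selection)["total"]

    def check_budget(self, selection, nmax: float) -> bool:
        """Strict budget test: Nop < Nmax."""
        return self.total_nop(selection) < nmax

    def cheapest_single(self) -> tuple[str, float]:
        """The least expensive single-feature subset (name, Nop)."""
        best_name, best_cost = None, float("inf")
        for d in catalog():
            c = self.total_nop([d])
            if c < best_cost:
                best_name, best_cost = d.name, c
        return best_name, best_cost
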