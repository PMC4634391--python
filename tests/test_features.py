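"""Window statistics against brute-force oracles; windowing arithmetic."""

import math

import numpy as np
import pytest

from stressmon.features import (
    FeatureDescriptor,
    PARAMETERS,
    baseline_tracker,
    catalog,
    compute_parameter,
    extract_features,
    window_count,
)
from stressmon.rates import IFSignalSet


def oracle(x, parameter):
    """Straightforward-definition oracle, independent of the implementation."""
    x = list(x)
    n = len(x)
    mean = sum(x) / n
    if parameter == "mean":
        return mean
    if parameter == "std":
        return math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if parameter == "trimmed_mean_25":
        k = int(0.125 * n)
        xs = sorted(x)[k : n - k]
        return sum(xs) / len(xs)
    if parameter == "median":
        xs = sorted(x)
        return xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2
    if parameter in ("p25", "p75"):
        q = 0.25 if parameter == "p25" else 0.75
        xs = sorted(x)
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[min(lo + 1, n - 1)] * frac
    if parameter == "skewness":
        s = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
        return sum((v - mean) ** 3 for v in x) / n / s**3
    if parameter == "kurtosis":
        s2 = sum((v - mean) ** 2 for v in x) / n
        return sum((v - mean) ** 4 for v in x) / n / s2**2
    if parameter == "max":
        return max(x)
    if parameter == "min":
        return min(x)
    if parameter == "geometric_mean":
        return math.exp(sum(math.log(v) for v in x) / n)
    if parameter == "harmonic_mean":
        return n / sum(1.0 / v for v in x)
    if parameter == "mean_abs_dev":
        return sum(abs(v - mean) for v in x) / n
    raise ValueError(parameter)


STAT_PARAMS = [p for p in PARAMETERS if p != "baseline"]


class TestParameters:
    @pytest.mark.parametrize("parameter", STAT_PARAMS)
    def test_matches_definition_oracle(self, parameter, rng):
        for _ in range(20):
            x = np.exp(rng.standard_normal(rng.integers(10, 400)))  # positive
            got = compute_parameter(x, parameter)
            want = oracle(x, parameter)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_constant_window_degenerate_values(self):
        x = np.full(100, 5.0)
        for p in ("mean", "median", "max", "min", "geometric_mean",
                  "harmonic_mean", "trimmed_mean_25", "p25", "p75"):
            assert compute_parameter(x, p) == pytest.approx(5.0)
        for p in ("std", "mean_abs_dev", "skewness", "kurtosis"):
            assert compute_parameter(x, p) == pytest.approx(0.0)

    def test_symmetric_window_zero_skewness(self):
        x = np.concatenate([np.arange(100.0), -np.arange(100.0)])
        assert compute_parameter(x, "skewness") == pytest.approx(0.0, abs=1e-9)

    def test_normal_kurtosis_is_three(self, rng):
        x = rng.standard_normal(200_000)
        assert compute_parameter(x, "kurtosis") == pytest.approx(3.0, abs=0.1)

    def test_nonpositive_window_flags_ratio_means(self):
        x = np.linspace(-1, 1, 50)
        assert math.isnan(compute_parameter(x, "geometric_mean"))
        assert math.isnan(compute_parameter(x, "harmonic_mean"))

    def test_affine_equivariance(self, rng):
        x = rng.standard_normal(500)
        a, b = 3.0, -7.0
        for p in ("mean", "median", "p25", "p75", "max", "min", "trimmed_mean_25"):
            assert compute_parameter(a * x + b, p) == pytest.approx(
                a * compute_parameter(x, p) + b, rel=1e-9, abs=1e-9)
        for p in ("std", "mean_abs_dev"):
            assert compute_parameter(a * x + b, p) == pytest.approx(
                a * compute_parameter(x, p), rel=1e-9)
        for p in ("skewness", "kurtosis"):
            assert compute_parameter(a * x + b, p) == pytest.approx(
                compute_parameter(x, p), rel=1e-9)


class TestBaseline:
    def test_constant_is_fixed_point(self):
        b = baseline_tracker(np.full(1000, 4.2), alpha=0.01)
        assert np.allclose(b, 4.2)

    def test_unit_step_matches_geometric_closed_form(self):
        alpha = 0.05
        n = 200
        b = baseline_tracker(np.ones(n), alpha=alpha)
        # with b[0] = x[0] = 1 the tracker stays at the fixed point
        assert np.allclose(b, 1.0)
        # step from a zero history: closed form 1 - (1-a)^(n+1)
        b2 = baseline_tracker(np.concatenate([[0.0], np.ones(n)]), alpha=alpha)
        expected = 1.0 - (1.0 - alpha) ** (np.arange(n + 1))
        assert np.allclose(b2, expected, atol=1e-12)

    def test_alpha_one_tracks_current_sample(self, rng):
        x = rng.standard_normal(100)
        assert np.allclose(baseline_tracker(x, alpha=1.0), x)


class TestCatalogAndWindows:
    def test_catalog_cardinality(self):
        cat = catalog()
        assert len(cat) == 112
        assert sum(1 for d in cat if d.measurement == "ECG") == 56
        assert len({d.name for d in cat}) == 112

    def test_descriptor_name_roundtrip(self):
        d = FeatureDescriptor("TEB", "zrd", "kurtosis")
        assert d.name == "TEB.ZRD.kurtosis"
        assert FeatureDescriptor.from_name(d.name) == d

    def test_descriptor_validation(self):
        with pytest.raises(ValueError):
            FeatureDescriptor("ECG", "zcf", "mean")  # TEB signal on ECG
        with pytest.raises(ValueError):
            FeatureDescriptor("ECG", "ecf", "variance")

    @pytest.mark.parametrize("duration,expected", [
        (280.0, 23), (60.0, 1), (59.9, 0), (69.9, 1), (70.0, 2), (600.0, 55),
    ])
    def test_window_count_formula(self, duration, expected):
        assert window_count(duration) == expected

    def test_extract_features_counts_and_labels(self, rng):
        n = 50 * 280  # 280 s at the IF rate
        base = 10.0 + rng.standard_normal(n) * 0.1
        sig = IFSignalSet(**{k: base.copy() for k in
                             ("ecf", "ert", "erd", "eppm", "zcf", "zrt", "zrd", "zppm")})
        sel = [FeatureDescriptor("ECG", "ecf", "mean"),
               FeatureDescriptor("ECG", "ecf", "baseline")]
        df = extract_features(sig, sel, label_intervals=[(0.0, 280.0, "neutral")],
                              subject_id="S1")
        assert len(df) == 23
        assert set(df["label"]) == {"neutral"}
        assert df["ECG.ECF.mean"].iloc[0] == pytest.approx(10.0, abs=0.1)

    def test_boundary_straddling_windows_dropped(self, rng):
        n = 50 * 120
        base = np.full(n, 5.0) + rng.standard_normal(n) * 0.01
        sig = IFSignalSet(**{k: base.copy() for k in
                             ("ecf", "ert", "erd", "eppm", "zcf", "zrt", "zrd", "zppm")})
        sel = [FeatureDescriptor("ECG", "ecf", "mean")]
        df = extract_features(sig, sel,
                              label_intervals=[(0.0, 60.0, "a"), (60.0, 120.0, "b")],
                              subject_id="S1")
        # only the two fully-covered windows survive the 90% majority rule
        assert list(df["label"]) == ["a", "b"]
        assert list(df["t_start"]) == [0.0, 60.0]
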