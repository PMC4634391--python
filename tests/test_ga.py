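"""Genetic-algorithm selection: repair, dedupe, fitness, evolution contract."""

import numpy as np
import pandas as pd
import pytest

from stressmon.costs import CostModel
from stressmon.features import catalog
from stressmon.ga import (
    BudgetError,
    GAConfig,
    dedupe,
    evolve,
    repair,
    subset_fitness,
    _make_folds,
)

NAMES = [d.name for d in catalog()]


@pytest.fixture(scope="module")
def cm():
    return CostModel()


def planted_table(rng, n_subjects=8, per_subject=25,
                  informative=("ECG.ECF.mean", "TEB.ZRD.kurtosis", "ECG.EPPM.std")):
    """112-column table where only ``informative`` columns carry the label."""
    n = n_subjects * per_subject
    subjects = np.repeat([f"S{i}" for i in range(n_subjects)], per_subject)
    y = rng.integers(0, 2, n)
    cols = {}
    for nm in NAMES:
        if nm in informative:
            cols[nm] = y + 0.3 * rng.standard_normal(n)
        else:
            cols[nm] = rng.standard_normal(n)
    return pd.DataFrame(cols), y, subjects, list(informative)


class TestRepair:
    def test_under_budget_untouched(self, cm):
        fs = frozenset(["ECG.ECF.mean"])
        rng = np.random.default_rng(0)
        assert repair(fs, cm, 100_000, NAMES, rng) == fs

    @pytest.mark.parametrize("seed", range(20))
    def test_full_catalog_repaired_under_budget(self, cm, seed):
        rng = np.random.default_rng(seed)
        fixed = repair(frozenset(NAMES), cm, 80_000, NAMES, rng)
        assert len(fixed) >= 1
        assert cm.total_nop(fixed) < 80_000

    def test_unsatisfiable_budget_raises_with_cheapest(self, cm):
        rng = np.random.default_rng(0)
        with pytest.raises(BudgetError, match="cheapest"):
            repair(frozenset(["ECG.ECF.mean"]), cm, 1_000, NAMES, rng)


class TestDedupe:
    def test_duplicates_perturbed_by_single_swap(self):
        rng = np.random.default_rng(1)
        a = frozenset(["ECG.ECF.mean", "ECG.ERT.std"])
        out = dedupe([a, a], NAMES, rng)
        assert out[0] == a
        assert out[1] != a
        assert len(out[1]) == len(a)
        assert len(a & out[1]) == len(a) - 1  # exactly one feature swapped

    def test_distinct_population_unchanged(self):
        rng = np.random.default_rng(1)
        pop = [frozenset(["ECG.ECF.mean"]), frozenset(["ECG.ERT.std"])]
        assert dedupe(pop, NAMES, rng) == pop


class TestFitness:
    def test_perfectly_predictable_targets_near_zero(self, rng):
        n = 200
        subjects = np.repeat([f"S{i}" for i in range(4)], n // 4)
        y = rng.integers(0, 2, n)
        X_cols = {"f": y.astype(float)}
        folds = _make_folds(subjects)
        mse = subset_fitness(["f"], X_cols, y, subjects, [0, 1], folds)
        assert mse < 1e-6

    def test_pure_noise_matches_no_information_baseline(self, rng):
        """With useless features the held-out MSE approaches the one-hot
        target variance: mean over M outputs of (1/M)(1-1/M)."""
        n, m = 2000, 4
        subjects = np.repeat([f"S{i}" for i in range(8)], n // 8)
        y = np.tile(np.arange(m), n // m)
        X_cols = {"f1": rng.standard_normal(n), "f2": rng.standard_normal(n)}
        folds = _make_folds(subjects)
        mse = subset_fitness(["f1", "f2"], X_cols, y, subjects, list(range(m)), folds)
        baseline = (1 / m) * (1 - 1 / m)
        assert mse == pytest.approx(baseline, rel=0.05)


@pytest.fixture(scope="module")
def planted():
    return planted_table(np.random.default_rng(42))


class TestEvolve:
    def test_recovers_planted_features_and_respects_contract(self, planted, cm):
        df, y, subjects, informative = planted
        cfg = GAConfig(population_size=60, survivors=12, generations=25,
                       restarts=1, nmax=500_000, seed=5)
        res = evolve(df, y, subjects, cfg, cost_model=cm)
        assert all(f in res.best.feature_set for f in informative)
        assert res.budget_violations == 0
        assert res.best.nop < cfg.nmax
        for trace in res.fitness_trace:
            assert all(trace[i + 1] <= trace[i] + 1e-12
                       for i in range(len(trace) - 1))  # elitism

    def test_seeded_end_to_end_determinism(self, planted, cm):
        df, y, subjects, _ = planted
        cfg = GAConfig(population_size=30, survivors=6, generations=5,
                       restarts=2, nmax=200_000, seed=9)
        a = evolve(df, y, subjects, cfg, cost_model=cm)
        b = evolve(df, y, subjects, cfg, cost_model=cm)
        assert a.best.feature_set == b.best.feature_set
        assert a.fitness_trace == b.fitness_trace

    def test_tight_budget_always_respected(self, planted, cm):
        df, y, subjects, _ = planted
        cfg = GAConfig(population_size=30, survivors=6, generations=8,
                       restarts=1, nmax=15_000, seed=2)
        res = evolve(df, y, subjects, cfg, cost_model=cm)
        assert res.budget_violations == 0
        assert res.best.nop < 15_000

    def test_generous_budget_no_worse_than_tight(self, planted, cm):
        """More computational room cannot hurt the best achievable fitness
        (checked on matched seeds)."""
        df, y, subjects, _ = planted
        fits = {}
        for nmax in (15_000, 500_000):
            cfg = GAConfig(population_size=40, survivors=8, generations=15,
                           restarts=2, nmax=nmax, seed=7)
            fits[nmax] = evolve(df, y, subjects, cfg, cost_model=cm).best.fitness
        assert fits[500_000] <= fits[15_000] + 1e-9
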