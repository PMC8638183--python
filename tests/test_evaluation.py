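import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fourquad.errors import EvaluationError
from fourquad.evaluation import (
    bootstrap_real_protocol,
    factor_tables,
    q_statistic,
    roc_auc,
)
from fourquad.sbp import SbpSimSpec, generate_sbp_like
from fourquad.simulation import SimulationConfig, run_simulation


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.9, 0.1, 0.1], [True, True, False, False])
        assert res.auc == 1.0

    def test_null_case_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_hand_enumerated_thresholds(self):
        """Scores 0.2-,0.4-,0.6+,0.8+: AUC=1; the smallest maximizing cutoff
        is 0.6 (any threshold in (0.4, 0.6] separates perfectly)."""
        res = roc_auc([0.2, 0.4, 0.6, 0.8], [False, False, True, True])
        assert res.auc == 1.0
        assert 0.4 < res.cutoff <= 0.6
        assert res.cutoff == pytest.approx(0.6)

    def test_ties_counted_half(self):
        # one tied pair out of 1x1 comparisons -> AUC 0.5
        assert roc_auc([0.5, 0.5], [True, False]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.9], [True, True])

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(50)
        labels = np.r_[np.ones(25, bool), np.zeros(25, bool)]
        base = roc_auc(scores, labels).auc
        warped = roc_auc(np.expm1(3 * scores), labels).auc
        assert warped == pytest.approx(base)


class TestQStatistic:
    def test_all_correct(self):
        res = q_statistic([0.9, 0.8, 0.1], [True, True, False], cutoff=0.5)
        assert res.q == 1.0 and res.n_star == 3

    def test_all_flipped(self):
        assert q_statistic([0.1, 0.9], [True, False], cutoff=0.5).q == 0.0

    def test_mixed_counting(self):
        scores = [0.9] * 7 + [0.1] * 3
        labels = [True] * 7 + [True] * 3  # the three low scores are misses
        assert q_statistic(scores, labels, 0.5).q == pytest.approx(0.7)

    def test_positive_boundary_counts_as_called(self):
        assert q_statistic([0.5], [True], cutoff=0.5).q == 1.0
        assert q_statistic([0.5], [False], cutoff=0.5).q == 0.0

    def test_youden_cutoff_maximizes_q_on_balanced_data(self, rng):
        scores = np.r_[rng.normal(0.7, 0.1, 300), rng.normal(0.4, 0.1, 300)]
        labels = np.r_[np.ones(300, bool), np.zeros(300, bool)]
        res = roc_auc(scores, labels)
        q_best = q_statistic(scores, labels, res.cutoff).q
        for c in np.quantile(scores, np.linspace(0.05, 0.95, 19)):
            assert q_best >= q_statistic(scores, labels, float(c)).q - 1e-12


@pytest.fixture(scope="module")
def small_run():
    grid = [
        SimulationConfig(p, rho, 0.0, 0.5, 15, m, n_replicates=4)
        for p in (1, 5, 15, 23)
        for rho in (0.0, 1 / 3)
        for m in (1, 2)
    ]
    return run_simulation(grid)


@pytest.fixture(scope="module")
def triple():
    methods = generate_sbp_like(SbpSimSpec(seed=4))
    return methods["J"], methods["R"], methods["S"]


class TestFactorTables:
    def test_table_shapes(self, small_run):
        tables = factor_tables(small_run)
        assert set(tables["overall"]["method"]) == {
            "proposal", "ccr", "control1", "control2"
        }
        assert len(tables["overall"]) == 3 + 4  # m=1 and m=2 rows
        assert sorted(tables["rho"]["rho"].unique()) == [0.0, 1 / 3]
        assert set(tables["pattern_q"]["pattern"]) == {1, 5, 15, 23}

    def test_identical_scores_give_identical_auc(self, small_run):
        df = small_run.copy()
        clone = df[df["method"] == "control1"].assign(method="proposal")
        df = pd.concat([df[df["method"] != "proposal"], clone], ignore_index=True)
        tables = factor_tables(df)
        overall = tables["overall"].set_index(["m", "method"])["auc"]
        for m in (1, 2):
            assert overall[(m, "proposal")] == overall[(m, "control1")]

    def test_missing_cell_raises(self, small_run):
        broken = small_run[small_run["method"] != "ccr"]
        with pytest.raises(EvaluationError):
            factor_tables(broken)


class TestBootstrapProtocol:
    def test_synthetic_contrast_is_detected(self, triple):
        table, rocs, undefined = bootstrap_real_protocol(
            *triple, n_iterations=120, subjects_per_draw=10, seed=2
        )
        assert rocs["proposal"].auc > 0.9
        assert rocs["proposal"].auc >= rocs["ccr"].auc
        # 120 iterations x 3 pairs x 4 methods rows
        assert len(table) == 120 * 3 * 4

    def test_fixed_seed_reproducible(self, triple):
        _, rocs_a, _ = bootstrap_real_protocol(
            *triple, n_iterations=30, subjects_per_draw=10, seed=6
        )
        _, rocs_b, _ = bootstrap_real_protocol(
            *triple, n_iterations=30, subjects_per_draw=10, seed=6
        )
        assert rocs_a["proposal"].auc == rocs_b["proposal"].auc

    def test_single_iteration_is_rejected(self, triple):
        # one draw yields one rate per pair per method: no meaningful ROC
        with pytest.raises(EvaluationError):
            bootstrap_real_protocol(
                *triple, n_iterations=1, subjects_per_draw=5, seed=0
            )

    def test_misaligned_series_rejected(self, triple):
        j, r, s = triple
        short = type(s)(
            subject_ids=s.subject_ids[:10],
            times=s.times,
            reference_values=s.reference_values[:10],
            test_values=s.test_values[:10],
        )
        with pytest.raises(EvaluationError):
            bootstrap_real_protocol(j, r, short, n_iterations=5, seed=0)
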