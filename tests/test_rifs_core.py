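import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rifs import (
    RIFSConfig,
    SynergyPairSpec,
    SyntheticSpec,
    generate,
    make_subset_evaluator,
    rank_ttest,
    rifs,
    sample_start_ranks,
    seed_sweep,
    sifs,
)
from rifs.ranking import RankedFeatures

FAST = dict(classifiers=("LDA",))


def dummy_ranking(n: int) -> RankedFeatures:
    return RankedFeatures(
        order=np.arange(n), pvalues=np.linspace(0.0, 1.0, n), method="ttest"
    )


def sequence_eval(seq):
    """Mocked evaluator: accuracy depends only on the prefix length."""
    return lambda subset: seq[len(subset) - 1]


def reference_stop(seq, depth, cap):
    """Independent 10-line simulator of the stopping rule."""
    n_evals, streak, best_acc, best_len = 0, 0, -1.0, 0
    for i, acc in enumerate(seq[:cap]):
        n_evals += 1
        streak = streak + 1 if i > 0 and acc < seq[i - 1] else 0
        if acc > best_acc:
            best_acc, best_len = acc, i + 1
        if streak >= depth:
            break
    return n_evals, best_len, best_acc


class TestSifs:
    def test_hand_simulated_depth4(self):
        seq = [0.80, 0.90, 0.88, 0.87, 0.86, 0.85, 0.99]
        trace = sifs(dummy_ranking(20), 1, 4, sequence_eval(seq))
        assert trace.n_evaluations == 6  # 4 consecutive decreases
        assert trace.best_prefix_len == 2
        assert trace.best_accuracy == 0.90
        assert trace.stopped_reason == "depth_exhausted"

    def test_immediate_single_decrease(self):
        trace = sifs(dummy_ranking(20), 1, 1, sequence_eval([0.70, 0.65]))
        assert trace.n_evaluations == 2
        assert trace.best_prefix_len == 1
        assert trace.best_accuracy == 0.70

    def test_drop_then_larger_rise(self):
        # rise, rise, drop at the 4th feature, rise above pre-drop at
        # the 5th: tolerated only when depth >= 2
        seq = [0.750, 0.770, 0.790, 0.775, 0.804, 0.5, 0.4, 0.3, 0.2]
        tolerant = sifs(dummy_ranking(20), 1, 2, sequence_eval(seq))
        assert tolerant.best_prefix_len == 5
        assert tolerant.best_accuracy == 0.804
        greedy = sifs(dummy_ranking(20), 1, 1, sequence_eval(seq))
        assert greedy.best_prefix_len == 3
        assert greedy.best_accuracy == 0.790

    def test_tie_resets_counter(self):
        # equal accuracy is not a decrease: the streak resets
        seq = [0.8, 0.7, 0.7, 0.6, 0.6, 0.5, 0.5]
        trace = sifs(dummy_ranking(7), 1, 2, sequence_eval(seq))
        assert trace.n_evaluations == 7
        assert trace.stopped_reason == "rank_exhausted"

    def test_rank_exhaustion(self):
        trace = sifs(dummy_ranking(3), 2, 5, sequence_eval([0.5, 0.6, 0.7]))
        assert trace.n_evaluations == 2  # only ranks 2..3 available
        assert trace.stopped_reason == "rank_exhausted"

    def test_cap(self):
        trace = sifs(dummy_ranking(100), 1, 5,
                     sequence_eval([0.5] * 100), cap=7)
        assert trace.n_evaluations == 7
        assert trace.stopped_reason == "cap_reached"

    def test_start_rank_out_of_range(self):
        with pytest.raises(IndexError):
            sifs(dummy_ranking(5), 6, 1, sequence_eval([1.0]))
        with pytest.raises(IndexError):
            sifs(dummy_ranking(5), 0, 1, sequence_eval([1.0]))

    def test_eval_failure_carries_context(self):
        def bad(subset):
            raise ValueError("nope")

        with pytest.raises(RuntimeError, match="start_rank=3"):
            sifs(dummy_ranking(5), 3, 1, bad)

    @given(
        seq=st.lists(st.sampled_from([round(x * 0.05, 2) for x in range(21)]),
                     min_size=1, max_size=40),
        depth=st.integers(1, 5),
    )
    @settings(max_examples=300, deadline=None)
    def test_stopping_rule_matches_reference(self, seq, depth):
        cap = 100
        trace = sifs(dummy_ranking(len(seq)), 1, depth,
                     sequence_eval(seq), cap=cap)
        n_evals, best_len, best_acc = reference_stop(seq, depth, cap)
        assert trace.n_evaluations == n_evals
        assert trace.best_prefix_len == best_len
        assert trace.best_accuracy == best_acc

    @given(
        seq=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1,
                     max_size=30),
        depth=st.integers(1, 4),
    )
    @settings(max_examples=200, deadline=None)
    def test_depth_monotonicity(self, seq, depth):
        shallow = sifs(dummy_ranking(len(seq)), 1, depth, sequence_eval(seq))
        deep = sifs(dummy_ranking(len(seq)), 1, depth + 1, sequence_eval(seq))
        assert deep.best_accuracy >= shallow.best_accuracy


class TestSampleStartRanks:
    def test_cardinality_and_forced_rank_one(self):
        ranks = sample_start_ranks(100, 0.45, master_seed=0)
        assert len(ranks) == 45
        assert len(set(ranks)) == 45
        assert all(1 <= r <= 100 for r in ranks)
        assert ranks[0] == 1

    def test_full_budget_is_exhaustive(self):
        ranks = sample_start_ranks(37, 1.0, master_seed=5)
        assert sorted(ranks) == list(range(1, 38))

    def test_nested_across_budgets(self):
        big = sample_start_ranks(500, 0.6, master_seed=9)
        small = sample_start_ranks(500, 0.2, master_seed=9)
        assert big[: len(small)] == small

    def test_seed_overlap_matches_hypergeometric(self):
        a = set(sample_start_ranks(10000, 0.45, master_seed=0))
        b = set(sample_start_ranks(10000, 0.45, master_seed=1))
        assert a != b
        overlap = len(a & b) / len(a)
        assert 0.40 <= overlap <= 0.50

    def test_ceil_budget(self):
        assert len(sample_start_ranks(10, 0.05, master_seed=0)) == 1
        assert sample_start_ranks(10, 0.05, master_seed=0) == [1]


class TestRifs:
    def test_degenerate_config_equals_classical(self, synergy_dataset):
        ds, _ = synergy_dataset
        cfg = RIFSConfig(start_pct=1e-9, depth=1, report_seeds=(0,), **FAST)
        result = rifs(ds, cfg)
        assert result.all_start_ranks == (1,)
        ranked = rank_ttest(ds)
        ev = make_subset_evaluator(ds, **FAST)
        classical = sifs(ranked, 1, 1, ev, cap=cfg.max_subset_size)
        assert result.winning_trace == classical
        assert result.selected_features == tuple(
            int(i) for i in ranked.window(1, classical.best_prefix_len)
        )

    def test_brute_force_restart_equivalence(self, synergy_dataset):
        # independent loop over the same start set, no shared state
        ds, _ = synergy_dataset
        cfg = RIFSConfig(start_pct=0.05, depth=4, max_subset_size=20,
                         report_seeds=(0,), **FAST)
        result = rifs(ds, cfg)
        ranked = rank_ttest(ds)
        best = -1.0
        for rank in sample_start_ranks(ds.n_features, 0.05, 0):
            ev = make_subset_evaluator(ds, **FAST)  # fresh evaluator
            trace = sifs(ranked, rank, 4, ev, cap=20)
            best = max(best, trace.best_accuracy)
        assert result.search_mAcc == best

    def test_full_determinism(self, synergy_dataset):
        ds, _ = synergy_dataset
        cfg = RIFSConfig(start_pct=0.03, max_subset_size=15,
                         report_seeds=(0, 1), **FAST)
        assert rifs(ds, cfg) == rifs(ds, cfg)

    def test_budget_monotonicity(self, synergy_dataset):
        ds, _ = synergy_dataset
        accs = []
        for pct in (0.02, 0.10, 0.25):
            cfg = RIFSConfig(start_pct=pct, max_subset_size=15,
                             report_seeds=(0,), **FAST)
            accs.append(rifs(ds, cfg).search_mAcc)
        assert accs == sorted(accs)

    def test_selected_features_are_consecutive_ranks(self, synergy_dataset):
        ds, _ = synergy_dataset
        cfg = RIFSConfig(start_pct=0.05, max_subset_size=15,
                         report_seeds=(0,), **FAST)
        result = rifs(ds, cfg)
        ranked = rank_ttest(ds)
        start = result.winning_start_rank
        expected = ranked.window(start, len(result.selected_features))
        np.testing.assert_array_equal(result.selected_features, expected)
        assert result.search_mAcc == result.winning_trace.best_accuracy

    def test_restart_patience_early_exit(self, synergy_dataset):
        ds, _ = synergy_dataset
        cfg = RIFSConfig(start_pct=0.10, max_subset_size=10,
                         report_seeds=(0,), restart_patience=3, **FAST)
        result = rifs(ds, cfg)
        full = rifs(ds, RIFSConfig(start_pct=0.10, max_subset_size=10,
                                   report_seeds=(0,), **FAST))
        assert len(result.traces) <= len(full.traces)

    def test_small_exhaustive_window_oracle(self):
        # pct = 1.0 and depth = n reduces to exhaustive search over all
        # consecutive-rank windows (tiny-n oracle)
        ds, _ = generate(SyntheticSpec(n_features=8, m_pos=10, m_neg=10,
                                       n_strong=1, seed=4))
        n = ds.n_features
        cfg = RIFSConfig(start_pct=1.0, depth=n, max_subset_size=n,
                         report_seeds=(0,), folds=5, **FAST)
        result = rifs(ds, cfg)
        ranked = rank_ttest(ds)
        ev = make_subset_evaluator(ds, k=5, **FAST)
        best_key, best_subset = None, None
        for start in range(1, n + 1):
            for length in range(1, n - start + 2):
                acc = ev(ranked.window(start, length))
                key = (-acc, length, start)
                if best_key is None or key < best_key:
                    best_key = key
                    best_subset = tuple(int(i) for i in ranked.window(start, length))
        assert result.search_mAcc == -best_key[0]
        assert result.selected_features == best_subset


class TestSeedSweep:
    def test_same_seed_identical_rows(self, synergy_dataset):
        ds, _ = synergy_dataset
        cfg = RIFSConfig(start_pct=0.03, max_subset_size=10,
                         report_seeds=(0,), **FAST)
        rows = seed_sweep(ds, cfg, seeds=[7, 7])
        assert rows[0]["selected_features"] == rows[1]["selected_features"]
        assert rows[0]["subset_group"] == rows[1]["subset_group"] == 0

    def test_exhaustive_budget_is_seed_independent(self):
        ds, _ = generate(SyntheticSpec(n_features=10, m_pos=8, m_neg=8,
                                       n_strong=1, seed=2))
        cfg = RIFSConfig(start_pct=1.0, max_subset_size=10, folds=4,
                         report_seeds=(0,), **FAST)
        rows = seed_sweep(ds, cfg, seeds=[0, 1, 2])
        assert len({tuple(r["selected_features"]) for r in rows}) == 1

    def test_empty_seed_list_rejected(self, synergy_dataset):
        ds, _ = synergy_dataset
        with pytest.raises(ValueError):
            seed_sweep(ds, RIFSConfig(**FAST), seeds=[])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"start_pct": 0.0},
            {"start_pct": 1.5},
            {"depth": 0},
            {"max_subset_size": 0},
            {"restart_patience": 0},
        ],
    )
    def test_bad_config(self, kwargs):
        with pytest.raises(ValueError):
            RIFSConfig(**kwargs)
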