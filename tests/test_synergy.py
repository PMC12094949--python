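"""NMF, VAF, the significant-difference synergy-count criterion, matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from musclenet.synergy import (
    build_weight_observations,
    compute_vaf,
    dunn_posthoc,
    kruskal_wallis,
    match_synergies,
    nmf,
    select_synergy_count,
    vaf_curve,
)
from oracles import best_permutation_cosine, dunn_z_by_hand, kruskal_by_hand


class TestVaf:
    def test_perfect_reconstruction(self):
        M = np.abs(np.random.default_rng(0).standard_normal((4, 10)))
        assert compute_vaf(M, M, np.eye(10)) == pytest.approx(1.0)

    def test_zero_fit_gives_zero(self):
        M = np.ones((3, 5))
        assert compute_vaf(M, np.zeros((3, 2)), np.zeros((2, 5))) == 0.0

    def test_hand_worked_example(self):
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        W = np.array([[1.0], [3.0]])
        C = np.array([[1.0, 2.0]])  # WC = [[1,2],[3,6]]; e = [[0,0],[0,-2]]
        assert compute_vaf(M, W, C) == pytest.approx(1.0 - 4.0 / 30.0)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_vaf(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros((1, 2)))


class TestNmf:
    def test_rank_one_matrix_fit_exactly(self):
        rng = np.random.default_rng(1)
        M = np.outer(rng.uniform(0.1, 1, 6), rng.uniform(0.1, 1, 40))
        d = nmf(M, 1, seed=1)
        assert d.vaf >= 0.999

    def test_planted_three_synergies_recovered(self):
        """Noiseless 3-synergy matrix: matched cosines >= 0.99."""
        rng = np.random.default_rng(2)
        W0 = rng.uniform(0.0, 1.0, (8, 3))
        C0 = np.abs(rng.standard_normal((3, 101)))
        M = W0 @ C0
        d = nmf(M, 3, seed=2)
        assert d.vaf >= 0.999
        perm, _ = best_permutation_cosine(W0, d.W)
        for c in range(3):
            w = d.W[:, perm[c]]
            cos = W0[:, c] @ w / (np.linalg.norm(W0[:, c]) * np.linalg.norm(w))
            assert cos >= 0.99

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(3)
        M = np.abs(rng.standard_normal((8, 101)))
        d = nmf(M, 3, seed=5, n_restarts=1)
        assert np.all(np.diff(d.objective_history) <= 1e-10)

    def test_determinism_and_internal_consistency(self):
        rng = np.random.default_rng(4)
        M = np.abs(rng.standard_normal((6, 50)))
        d1, d2 = nmf(M, 2, seed=9), nmf(M, 2, seed=9)
        assert np.array_equal(d1.W, d2.W) and np.array_equal(d1.C, d2.C)
        assert d1.vaf == pytest.approx(compute_vaf(M, d1.W, d1.C), abs=1e-12)

    def test_scale_convention_c_rows_unit_max(self):
        rng = np.random.default_rng(5)
        M = np.abs(rng.standard_normal((6, 50)))
        d = nmf(M, 3, seed=1)
        assert np.allclose(d.C.max(axis=1), 1.0)
        assert np.all(d.W >= 0) and np.all(d.C >= 0)

    def test_matches_sklearn_objective(self):
        """Independent solver cross-check: equal reconstruction error (1%)."""
        from sklearn.decomposition import NMF as SkNMF

        rng = np.random.default_rng(6)
        M = np.abs(rng.standard_normal((8, 101)))
        mine = np.linalg.norm(M - nmf(M, 3, seed=0).reconstruction())
        best = np.inf
        for rs in range(5):
            sk = SkNMF(
                n_components=3, init="random", solver="mu", max_iter=2000,
                tol=1e-9, random_state=rs,
            )
            Wk = sk.fit_transform(M)
            best = min(best, np.linalg.norm(M - Wk @ sk.components_))
        assert mine <= best * 1.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nmf(np.array([[1.0, -0.1], [0.2, 0.3]]), 1)
        with pytest.raises(ValueError):
            nmf(np.ones((3, 4)), 5)


class TestVafCurve:
    def test_values_and_monotonicity(self, processed_k2):
        table = vaf_curve(processed_k2[:6], k_range=range(1, 5), seed=0)
        vals = table.to_numpy()
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(np.diff(vals, axis=1) >= -1e-3)

    def test_needs_two_trials(self, processed_k2):
        with pytest.raises(ValueError):
            vaf_curve(processed_k2[:1])


class TestKruskalWallis:
    def test_identical_groups(self):
        H, p = kruskal_wallis([np.ones(5), np.ones(5), np.ones(5)])
        assert H == 0.0 and p == 1.0

    def test_matches_hand_rank_arithmetic(self):
        groups = [
            np.array([1.0, 2.0, 3.0]),
            np.array([10.0, 11.0, 12.0]),
            np.array([20.0, 21.0, 22.0]),
        ]
        H, p = kruskal_wallis(groups)
        assert H == pytest.approx(kruskal_by_hand(groups), abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(H, 2), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.ones(3), np.array([])])

    def test_label_permutation_symmetry(self):
        """Shuffling pooled identical-distribution data leaves H small."""
        rng = np.random.default_rng(7)
        pooled = rng.standard_normal(30)
        stats_h = []
        for _ in range(200):
            rng.shuffle(pooled)
            H, _ = kruskal_wallis([pooled[:10], pooled[10:20], pooled[20:]])
            stats_h.append(H)
        # H ~ chi2(2) under exchangeability: median near 1.39
        assert 0.5 < np.median(stats_h) < 3.0


class TestDunn:
    def test_identical_groups_not_significant(self):
        out = dunn_posthoc([np.arange(6.0), np.arange(6.0)])
        assert abs(out["z"].iloc[0]) < 1e-9
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_hand_formula_with_ties(self):
        groups = [
            np.array([1.0, 2.0, 2.0, 5.0]),
            np.array([2.0, 6.0, 7.0]),
            np.array([8.0, 9.0, 9.0, 10.0]),
        ]
        out = dunn_posthoc(groups)
        for _, row in out.iterrows():
            z_hand = dunn_z_by_hand(groups, int(row.group_i), int(row.group_j))
            assert row.z == pytest.approx(z_hand, abs=1e-9)

    def test_p_monotone_in_abs_z(self):
        rng = np.random.default_rng(8)
        groups = [rng.standard_normal(8) + m for m in (0.0, 0.5, 3.0)]
        out = dunn_posthoc(groups).sort_values("z", key=np.abs)
        assert np.all(np.diff(out["p"].to_numpy()) <= 1e-12)

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([np.ones(3), np.ones(3)], comparisons=[(0, 5)])

    def test_holm_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(9)
        groups = [rng.standard_normal(10) + m for m in (0, 1, 2)]
        raw = dunn_posthoc(groups)
        adj = dunn_posthoc(groups, p_adjust="holm")
        assert np.all(adj["p"].to_numpy() >= raw["p"].to_numpy() - 1e-12)


class TestSelectSynergyCount:
    @staticmethod
    def _table(cols: dict[int, tuple[float, float]], n=30, seed=0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        data = {
            k: np.clip(mu + sd * rng.standard_normal(n), 0, 1)
            for k, (mu, sd) in cols.items()
        }
        return pd.DataFrame(data)

    def test_strong_gap_after_first_column_selects_two(self):
        """Self-STS pattern: k=1 low, k>=2 clustered high -> 2."""
        cols = {1: (0.80, 0.01)} | {k: (0.97, 0.01) for k in range(2, 8)}
        k, report = select_synergy_count(self._table(cols))
        assert k == 2 and not report.fallback

    def test_intermediate_second_column_selects_three(self):
        """Robot-STS pattern: k=2 sits between k=1 and the high block -> 3."""
        cols = {1: (0.80, 0.005), 2: (0.90, 0.005)}
        cols |= {k: (0.98, 0.005) for k in range(3, 8)}
        k, report = select_synergy_count(self._table(cols))
        assert k == 3

    def test_identical_columns_fall_back_to_one(self):
        table = pd.DataFrame({k: np.full(20, 0.95) for k in range(1, 8)})
        k, report = select_synergy_count(table)
        assert k == 1 and report.fallback


class TestMatchSynergies:
    def test_identity_and_swap(self):
        rng = np.random.default_rng(10)
        W = rng.uniform(0.1, 1.0, (8, 3))
        assert np.array_equal(match_synergies(W, W), [0, 1, 2])
        swapped = W[:, [2, 0, 1]]
        perm = match_synergies(W, swapped)
        assert np.allclose(swapped[:, perm], W)

    def test_noisy_permutations_recovered(self):
        """sigma = 0.05 noise: correct assignment in >= 95% of 200 seeds."""
        rng = np.random.default_rng(11)
        hits = 0
        for s in range(200):
            W = rng.uniform(0.1, 1.0, (8, 3))
            true_perm = rng.permutation(3)
            noisy = W[:, true_perm] + 0.05 * rng.standard_normal((8, 3))
            trial = np.clip(noisy, 0, None)
            perm = match_synergies(W, trial)
            oracle_perm, _ = best_permutation_cosine(W, trial)
            assert np.array_equal(perm, oracle_perm)
            if np.array_equal(perm, np.argsort(true_perm)):
                hits += 1
        assert hits >= 190

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_synergies(np.ones((8, 2)), np.ones((8, 3)))


class TestBuildWeightObservations:
    def test_study_layout_and_ground_truth_correlation(
        self, processed_k2, dataset_k2
    ):
        _, truths = dataset_k2
        obs = build_weight_observations(processed_k2, "self", 2, seed=0)
        assert len(obs) == 2
        for o in obs:
            assert o.matrix.shape == (30, 8)
            assert np.all(o.matrix >= 0)
        W_true = truths["self"].W_true
        means = np.stack([o.matrix.mean(axis=0) for o in obs], axis=1)
        perm, _ = best_permutation_cosine(W_true, means)
        rs = [
            np.corrcoef(W_true[:, c], means[:, perm[c]])[0, 1] for c in range(2)
        ]
        assert min(rs) >= 0.9

    def test_unknown_condition_rejected(self, processed_k2):
        with pytest.raises(ValueError):
            build_weight_observations(processed_k2, "nope", 2)
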