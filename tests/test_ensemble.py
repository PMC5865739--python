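import math
from collections import Counter

import numpy as np
import pytest

import svmcluster as sc
from svmcluster.ensemble import (
    HARD_MARGIN_COST,
    NEGATIVE,
    POSITIVE,
    SvmParams,
    default_d,
    member_votes,
    proportion_correct,
)


class TestSvmParams:
    def test_width_convention_maps_to_solver_gamma(self):
        p = SvmParams(gamma=3.0)
        assert p.effective_gamma == pytest.approx(1.0 / 18.0)
        assert SvmParams(gamma=3.0, gamma_convention="libsvm").effective_gamma == 3.0

    def test_infinite_cost_maps_to_hard_margin_surrogate(self):
        assert SvmParams().effective_cost == HARD_MARGIN_COST
        assert SvmParams(cost=10.0).effective_cost == 10.0

    @pytest.mark.parametrize("kwargs", [{"gamma": 0}, {"cost": -1}, {"gamma_convention": "x"}])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SvmParams(**kwargs)

    def test_default_d_follows_sqrt_rule_with_pinned_4005(self):
        assert default_d(4005) == 62
        assert default_d(100) == 10
        assert default_d(66) == 8


class TestSplitDataset:
    def test_replication_sizes(self, rng):
        feats = rng.standard_normal((60, 10))
        labels = np.array([POSITIVE] * 25 + [NEGATIVE] * 35)
        ds = sc.Dataset(feats, labels)
        split = sc.split_dataset(ds, (40, 2, 18), seed=0)
        assert (len(split.train_idx), len(split.test_idx), len(split.validation_idx)) == (40, 2, 18)
        both = set(split.train_idx) | set(split.test_idx) | set(split.validation_idx)
        assert both == set(range(60))

    def test_all_train_split(self, small_ds):
        split = sc.split_dataset(small_ds, (small_ds.n_subjects, 0, 0), seed=1)
        assert len(split.train_idx) == small_ds.n_subjects

    def test_same_seed_same_split(self, small_ds):
        a = sc.split_dataset(small_ds, (12, 2, 4), seed=9)
        b = sc.split_dataset(small_ds, (12, 2, 4), seed=9)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.validation_idx, b.validation_idx)

    def test_inconsistent_sizes_rejected(self, small_ds):
        with pytest.raises(ValueError):
            sc.split_dataset(small_ds, (10, 2, 4), seed=0)

    def test_train_and_validation_cover_both_classes(self, small_ds):
        for seed in range(10):
            split = sc.split_dataset(small_ds, (12, 2, 4), seed=seed)
            assert len(set(small_ds.labels[split.train_idx])) == 2
            assert len(set(small_ds.labels[split.validation_idx])) == 2


class TestBuildCluster:
    def test_same_seed_identical_member_subsets(self, small_ds, small_split):
        a = sc.build_cluster(small_ds, small_split, n=12, d=8, k=10, seed=3)
        b = sc.build_cluster(small_ds, small_split, n=12, d=8, k=10, seed=3)
        for ma, mb in zip(a.members, b.members):
            assert np.array_equal(ma.sample_idx, mb.sample_idx)
            assert np.array_equal(ma.feature_idx, mb.feature_idx)

    def test_member_subsets_well_formed(self, small_cluster, small_split, small_ds):
        for m in small_cluster.members:
            assert len(m.feature_idx) == 8
            assert len(set(m.feature_idx.tolist())) == 8
            assert np.array_equal(m.feature_idx, np.sort(m.feature_idx))
            assert set(m.sample_idx) <= set(small_split.train_idx)
            assert len(set(small_ds.labels[m.sample_idx])) == 2

    def test_single_member_full_data_equals_plain_svm(self, small_ds, small_split):
        from sklearn.svm import SVC

        p = small_ds.n_features
        cluster = sc.build_cluster(
            small_ds, small_split, n=len(small_split.train_idx), d=p, k=1,
            seed=0, sample_with_replacement=False,
        )
        params = cluster.params
        ref = SVC(kernel="rbf", gamma=params.effective_gamma, C=params.effective_cost)
        tr = np.sort(cluster.members[0].sample_idx)
        assert np.array_equal(tr, np.sort(small_split.train_idx))
        ref.fit(small_ds.features[cluster.members[0].sample_idx], small_ds.labels[cluster.members[0].sample_idx])
        pred, _ = sc.vote_predict(cluster, small_ds.features)
        assert np.array_equal(pred, ref.predict(small_ds.features))

    def test_invalid_shapes_rejected(self, small_ds, small_split):
        with pytest.raises(ValueError):
            sc.build_cluster(small_ds, small_split, n=12, d=small_ds.n_features + 1, k=3)
        with pytest.raises(ValueError):
            sc.build_cluster(
                small_ds, small_split, n=len(small_split.train_idx) + 1, d=5, k=3,
                sample_with_replacement=False,
            )


class TestMajorityVote:
    def test_vote_equals_brute_force_mode(self, small_cluster, small_ds):
        votes = member_votes(small_cluster, small_ds.features)
        pred, counts = sc.vote_predict(small_cluster, small_ds.features)
        for s in range(small_ds.n_subjects):
            mode, n_mode = Counter(votes[:, s].tolist()).most_common(1)[0]
            assert pred[s] == mode  # k=31 is odd: no ties possible
            assert counts[s, 0] + counts[s, 1] == small_cluster.k
            assert counts[s, 0] == int((votes[:, s] == POSITIVE).sum())

    def test_single_sample_interface(self, small_cluster, small_ds):
        label, counts = sc.majority_vote(small_cluster, small_ds.features[0])
        assert label in (POSITIVE, NEGATIVE)
        assert counts[POSITIVE] + counts[NEGATIVE] == small_cluster.k

    def test_unanimity(self, small_cluster, small_ds):
        votes = member_votes(small_cluster, small_ds.features)
        pred, _ = sc.vote_predict(small_cluster, small_ds.features)
        unanimous = np.flatnonzero(np.abs(votes.sum(axis=0)) == small_cluster.k)
        for s in unanimous:
            assert pred[s] == votes[0, s]

    def test_tie_break_is_deterministic(self, small_ds, small_split):
        # even k can produce ties; the decision-value rule must be reproducible
        cluster = sc.build_cluster(small_ds, small_split, n=12, d=8, k=2, seed=1)
        p1, _ = sc.vote_predict(cluster, small_ds.features)
        p2, _ = sc.vote_predict(cluster, small_ds.features)
        assert np.array_equal(p1, p2)
        assert set(p1.tolist()) <= {POSITIVE, NEGATIVE}


class TestAccuracy:
    def test_nc_over_n3_worked_values(self):
        assert proportion_correct(17, 18) == pytest.approx(0.9444, abs=5e-5)
        assert proportion_correct(0, 18) == 0.0
        assert proportion_correct(18, 18) == 1.0
        with pytest.raises(ValueError):
            proportion_correct(1, 0)

    def test_cluster_accuracy_matches_manual_count(self, small_cluster, small_ds, small_split):
        idx = small_split.validation_idx
        pred, _ = sc.vote_predict(small_cluster, small_ds.features[idx])
        manual = (pred == small_ds.labels[idx]).sum() / len(idx)
        assert sc.cluster_accuracy(small_cluster, small_ds, idx) == manual

    def test_member_accuracy_granularity(self, small_cluster, small_ds, small_split):
        accs = sc.member_accuracies(small_cluster, small_ds, small_split.validation_idx)
        n3 = len(small_split.validation_idx)
        assert np.allclose(accs * n3, np.round(accs * n3))
        assert np.all((accs >= 0) & (accs <= 1))

    def test_empty_eval_set_rejected(self, small_cluster, small_ds):
        with pytest.raises(ValueError):
            sc.cluster_accuracy(small_cluster, small_ds, [])


class TestSweepK:
    def test_single_point_equals_cluster_accuracy(self, small_ds, small_split):
        curve = sc.sweep_k(small_ds, small_split, n=12, d=8, k_values=[7], seed=5)
        child = int(np.random.default_rng(5).integers(2**31, size=1)[0])
        cluster = sc.build_cluster(small_ds, small_split, n=12, d=8, k=7, seed=child)
        expected = sc.cluster_accuracy(cluster, small_ds, small_split.validation_idx)
        assert len(curve) == 1
        assert curve.loc[0, "accuracy"] == expected

    def test_curve_shape_and_determinism(self, small_ds, small_split):
        a = sc.sweep_k(small_ds, small_split, n=12, d=8, k_values=[3, 9, 15], seed=2)
        b = sc.sweep_k(small_ds, small_split, n=12, d=8, k_values=[3, 9, 15], seed=2)
        assert a["k"].tolist() == [3, 9, 15]
        assert a["accuracy"].tolist() == b["accuracy"].tolist()

    def test_non_ascending_grid_rejected(self, small_ds, small_split):
        with pytest.raises(ValueError):
            sc.sweep_k(small_ds, small_split, n=12, d=8, k_values=[9, 3])


class TestTuneParams:
    def test_single_point_grid_returned(self, small_ds, small_split):
        params = sc.tune_params(small_ds, small_split, [2.0], [5.0], k=9, seed=0)
        assert (params.gamma, params.cost) == (2.0, 5.0)

    def test_chosen_point_beats_grid_exhaustively(self, small_ds, small_split):
        gamma_grid, cost_grid = [0.5, 3.0], [1.0, math.inf]
        chosen = sc.tune_params(small_ds, small_split, gamma_grid, cost_grid, n=12, d=8, k=15, seed=4)
        assert chosen.gamma in gamma_grid and chosen.cost in cost_grid

        def acc(gamma, cost):
            cl = sc.build_cluster(
                small_ds, small_split, n=12, d=8, k=15,
                params=SvmParams(gamma=gamma, cost=cost), seed=4,
            )
            return sc.cluster_accuracy(cl, small_ds, small_split.test_idx)

        best = acc(chosen.gamma, chosen.cost)
        assert all(acc(g, c) <= best for g in gamma_grid for c in cost_grid)


class TestManifestRoundtrip:
    def test_retrained_cluster_predicts_identically(self, tmp_path, small_cluster, small_ds):
        path = sc.save_cluster(small_cluster, tmp_path)
        back = sc.load_cluster(path, small_ds)
        assert back.k == small_cluster.k
        p1, c1 = sc.vote_predict(small_cluster, small_ds.features)
        p2, c2 = sc.vote_predict(back, small_ds.features)
        assert np.array_equal(p1, p2)
        assert np.array_equal(c1, c2)
        assert [m.accuracy for m in back.members] == [m.accuracy for m in small_cluster.members]


class TestEnsembleBeatsMembersSmall:
    def test_vote_aggregation_helps_on_planted_cohort(self, small_ds, small_split):
        # light version of the study-scale property: average over a few seeds
        ens_accs, mem_accs = [], []
        for seed in range(5):
            cl = sc.build_cluster(small_ds, small_split, n=12, d=8, k=51, seed=seed)
            mem_accs.append(sc.member_accuracies(cl, small_ds, small_split.validation_idx).mean())
            ens_accs.append(sc.cluster_accuracy(cl, small_ds, small_split.validation_idx))
        assert np.mean(ens_accs) > np.mean(mem_accs)
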