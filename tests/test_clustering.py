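"""Binomial-mixture clonal clustering, merge/prune rules, fishplot tables."""

from collections import Counter

import numpy as np
import pytest

from subclonepulse import clustering as cl


def simulate_matrix(rng, truth, per_cluster=30, depth=150):
    X, D, labels = [], [], []
    for k, row in enumerate(truth):
        for _ in range(per_cluster):
            d = rng.poisson(depth, len(row)).clip(min=1)
            X.append(rng.binomial(d, row) / d)
            D.append(d)
            labels.append(k)
    return np.array(X), np.array(D), np.array(labels)


def make_model(X, D, labels, prevalence):
    return cl.ClusterModel(
        mutation_ids=[f"m{i}" for i in range(len(X))],
        labels=np.asarray(labels),
        prevalence=np.asarray(prevalence, dtype=float),
        timepoints=tuple(f"t{j}" for j in range(X.shape[1])),
        X=np.asarray(X, dtype=float),
        depths=np.asarray(D, dtype=float),
        fit_score=0.0,
    )


class TestModelSelection:
    def test_identical_prevalence_vectors_give_one_cluster(self):
        X = np.full((25, 3), 0.5)
        D = np.full((25, 3), 150.0)
        model = cl.cluster_mutations(X, D, seed=0)
        assert model.n_clusters == 1

    def test_two_group_recovery(self, rng):
        truth = np.array([[1.0, 1.0, 1.0], [0.6, 0.1, 0.4]])
        ks = []
        for seed in range(5):
            X, D, _ = simulate_matrix(np.random.default_rng(100 + seed), truth)
            m = cl.cluster_mutations(X, D, seed=seed)
            ks.append(m.n_clusters)
            if m.n_clusters == 2:
                for row in truth:
                    err = np.abs(m.prevalence - row).mean(axis=1).min()
                    assert err <= 0.05
        assert Counter(ks).most_common(1)[0][0] == 2

    def test_bic_recovers_true_k_on_well_separated_noiseless_data(self):
        centers = np.array([[0.95, 0.95], [0.65, 0.6], [0.35, 0.3], [0.08, 0.1]])
        for true_k in (1, 2, 3, 4):
            X = np.repeat(centers[:true_k], 20, axis=0)
            D = np.full_like(X, 150.0)
            model = cl.cluster_mutations(X, D, seed=3)
            assert model.n_clusters == true_k

    def test_permutation_invariance_up_to_relabeling(self, rng):
        truth = np.array([[1.0, 1.0, 1.0], [0.5, 0.1, 0.3]])
        X, D, _ = simulate_matrix(np.random.default_rng(5), truth, per_cluster=20)
        base = cl.cluster_mutations(X, D, seed=9)
        perm = np.random.default_rng(1).permutation(len(X))
        permuted = cl.cluster_mutations(X[perm], D[perm], seed=9)
        # same partition: co-membership matrices agree after unpermuting
        def partition(labels):
            return {
                frozenset(np.flatnonzero(labels == k).tolist())
                for k in np.unique(labels)
            }
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert partition(base.labels) == partition(permuted.labels[inv])

    def test_all_zero_depths_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            cl.cluster_mutations(np.full((4, 2), 0.5), np.zeros((4, 2)), seed=0)


class TestMergeSingletons:
    def test_no_singletons_is_identity(self):
        X = np.vstack([np.full((3, 2), 0.9), np.full((3, 2), 0.3)])
        D = np.full_like(X, 150.0)
        model = make_model(X, D, [0] * 3 + [1] * 3, [[0.9, 0.9], [0.3, 0.3]])
        merged = cl.merge_singletons(model)
        assert merged.n_clusters == 2
        assert np.array_equal(merged.labels, model.labels)

    def test_singleton_at_cluster_mean_is_merged(self):
        X = np.vstack([np.full((4, 2), 0.8), [[0.8, 0.8]]])
        D = np.full_like(X, 150.0)
        model = make_model(X, D, [0, 0, 0, 0, 1], [[0.8, 0.8], [0.8, 0.8]])
        merged = cl.merge_singletons(model)
        assert merged.n_clusters == 1
        assert merged.cluster_sizes().tolist() == [5]

    def test_distant_singleton_is_retained_and_flagged(self):
        X = np.vstack([np.full((4, 2), 0.8), [[0.1, 0.1]]])
        D = np.full_like(X, 150.0)
        model = make_model(X, D, [0, 0, 0, 0, 1], [[0.8, 0.8], [0.1, 0.1]])
        merged = cl.merge_singletons(model)
        assert merged.n_clusters == 2
        assert merged.flagged_singletons == ["m4"]

    def test_random_configurations_match_brute_force_search(self, rng):
        for trial in range(50):
            r = np.random.default_rng(trial)
            n_hosts = int(r.integers(2, 4))
            T = int(r.integers(2, 4))
            centers = r.uniform(0.1, 0.9, size=(n_hosts, T))
            rows, labels = [], []
            for k in range(n_hosts):
                for _ in range(3):
                    rows.append(np.clip(centers[k] + r.normal(0, 0.01, T), 0, 1))
                    labels.append(k)
            x_single = r.uniform(0.05, 0.95, T)
            rows.append(x_single)
            labels.append(n_hosts)
            X = np.array(rows)
            D = np.full_like(X, 200.0)
            prevalence = np.vstack([centers, x_single[None, :]])
            model = make_model(X, D, labels, prevalence)
            merged = cl.merge_singletons(model)
            # oracle: exhaustive nearest-host search under the same z-window
            best, best_norm = None, np.inf
            for k in range(n_hosts):
                se = np.sqrt(np.clip(centers[k], 1e-6, 1 - 1e-6)
                             * (1 - np.clip(centers[k], 1e-6, 1 - 1e-6)) / 200.0)
                z = (x_single - centers[k]) / se
                if np.all(np.abs(z) <= 1) and np.linalg.norm(z) < best_norm:
                    best, best_norm = k, np.linalg.norm(z)
            if best is None:
                assert merged.n_clusters == n_hosts + 1
                assert merged.flagged_singletons == [f"m{len(X) - 1}"]
            else:
                assert merged.n_clusters == n_hosts
                assert merged.labels[-1] == best

    def test_merging_never_increases_cluster_count(self, rng):
        for trial in range(20):
            r = np.random.default_rng(500 + trial)
            n = int(r.integers(4, 12))
            X = r.uniform(0, 1, size=(n, 3))
            D = np.full_like(X, 150.0)
            model = cl.cluster_mutations(X, D, k_max=6, seed=trial)
            merged = cl.merge_singletons(model)
            assert merged.n_clusters <= model.n_clusters


class TestPrune:
    def build(self):
        X = np.vstack([np.full((5, 2), 0.9), np.full((2, 2), 0.4)])
        D = np.full_like(X, 150.0)
        return make_model(X, D, [0] * 5 + [1] * 2, [[0.9, 0.9], [0.4, 0.4]])

    def test_small_cluster_moves_to_removed_list(self):
        display, removed = cl.prune_small_clusters(self.build(), min_size=3)
        assert display.n_clusters == 1
        assert removed == [(1, ["m5", "m6"])]

    def test_all_large_clusters_removed_list_empty(self):
        display, removed = cl.prune_small_clusters(self.build(), min_size=2)
        assert removed == []
        assert display.n_clusters == 2

    def test_mutation_count_conserved_and_prevalences_untouched(self):
        model = self.build()
        display, removed = cl.prune_small_clusters(model, min_size=3)
        total = len(display.mutation_ids) + sum(len(m) for _, m in removed)
        assert total == len(model.mutation_ids)
        assert np.allclose(display.prevalence[0], model.prevalence[0])


class TestFishplot:
    def test_single_cluster_is_root(self):
        X = np.full((4, 3), 0.9)
        D = np.full_like(X, 150.0)
        model = make_model(X, D, [0] * 4, [[0.9, 0.9, 0.9]])
        table = cl.build_fishplot_table(model)
        assert set(table["parent"]) == {"root"}

    def test_contained_subclone_parented_to_truncal(self):
        X = np.vstack([np.full((3, 3), 1.0), np.full((3, 3), 0.4)])
        D = np.full_like(X, 150.0)
        model = make_model(X, D, [0] * 3 + [1] * 3, [[1.0, 1.0, 1.0], [0.4, 0.4, 0.4]])
        table = cl.build_fishplot_table(model)
        sub = table[table["cluster"] == 1]
        assert set(sub["parent"]) == {0}

    def test_random_nested_sets_match_containment_oracle(self, rng):
        for trial in range(30):
            r = np.random.default_rng(trial)
            K, T = int(r.integers(2, 6)), 3
            prev = np.sort(r.uniform(0, 1, size=(K, T)), axis=0)[::-1].copy()
            X = np.repeat(prev, 3, axis=0)
            D = np.full_like(X, 150.0)
            model = make_model(X, D, np.repeat(np.arange(K), 3), prev)
            table = cl.build_fishplot_table(model)
            parents = {
                c: table.loc[table["cluster"] == c, "parent"].iloc[0]
                for c in range(K)
            }
            for b in range(K):
                # oracle: tightest strictly-containing cluster
                candidates = [
                    a for a in range(K)
                    if a != b and np.all(prev[a] >= prev[b] - 1e-9)
                    and (np.any(prev[a] > prev[b] + 1e-9) or a < b)
                ]
                if candidates:
                    want = min(candidates, key=lambda a: prev[a].sum())
                    assert parents[b] == want
                else:
                    assert parents[b] == "root"
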