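"""Ground-truth simulator: tree dynamics, copy number, read emission, I/O."""

import numpy as np
import pandas as pd
import pytest

from subclonepulse import genotype as gt
from subclonepulse import simdata as sd


def small_config(**kw):
    defaults = dict(n_patients=2, n_subclones_range=(2, 4),
                    mutations_per_clone_range=(3, 6), seed=5)
    defaults.update(kw)
    return sd.SimConfig(**defaults)


class TestClonalTree:
    def test_no_dynamics_limit_freezes_prevalences(self):
        cfg = small_config(extinction_prob_small_clone=0.0, expansion_sd=0.0)
        tree = sd.simulate_clonal_tree(cfg, np.random.default_rng(1))
        for s in tree.subclones:
            vals = [s.prevalence[tp] for tp in sd.TIMEPOINTS]
            assert vals == pytest.approx([vals[0]] * 3)

    def test_truncal_prevalence_is_one_everywhere(self):
        cfg = small_config()
        for seed in range(20):
            tree = sd.simulate_clonal_tree(cfg, np.random.default_rng(seed))
            assert all(tree.root.prevalence[tp] == 1.0 for tp in sd.TIMEPOINTS)

    def test_nesting_invariant_on_many_random_trees(self):
        # at every timepoint, each node's children sum to at most its value
        cfg = small_config(n_subclones_range=(2, 6), expansion_sd=0.7,
                           extinction_prob_small_clone=0.4)
        for seed in range(300):
            tree = sd.simulate_clonal_tree(cfg, np.random.default_rng(seed))
            for s in tree.subclones:
                kids = tree.children(s.subclone_id)
                for tp in sd.TIMEPOINTS:
                    assert all(c.prevalence[tp] >= 0 for c in kids)
                    total = sum(c.prevalence[tp] for c in kids)
                    assert total <= s.prevalence[tp] + 1e-9

    def test_extinct_clones_stay_extinct(self):
        cfg = small_config(extinction_prob_small_clone=1.0, expansion_sd=0.5)
        for seed in range(50):
            tree = sd.simulate_clonal_tree(cfg, np.random.default_rng(seed))
            for s in tree.subclones[1:]:
                if s.prevalence["post_a"] == 0.0:
                    assert s.prevalence["post_b"] == 0.0


def _oracle_tree_prevalences(cfg, rng):
    """Independent re-implementation of the perturbation loop (same seed protocol)."""
    lo, hi = cfg.n_subclones_range
    k = int(rng.integers(lo, hi + 1))
    parent = {0: None}
    for i in range(1, k + 1):
        parent[i] = int(rng.integers(0, i))
    prev = {0: {tp: 1.0 for tp in sd.TIMEPOINTS}}
    used = dict.fromkeys(range(k + 1), 0.0)
    for i in range(1, k + 1):
        share = (prev[parent[i]]["pre"] - used[parent[i]]) * rng.uniform(0.05, 0.8)
        used[parent[i]] += share
        prev[i] = {"pre": share}
    for t_from, t_to in (("pre", "post_a"), ("post_a", "post_b")):
        for i in range(1, k + 1):
            v = prev[i][t_from]
            if v > 0:
                v = min(v * rng.lognormal(0.0, cfg.expansion_sd), 1.0)
                if prev[i][t_from] < 0.1 and rng.random() < cfg.extinction_prob_small_clone:
                    v = 0.0
            prev[i][t_to] = v
        for node in range(k + 1):
            kids = [i for i in range(1, k + 1) if parent[i] == node]
            s = sum(prev[i][t_to] for i in kids)
            if s > prev[node][t_to] and s > 0:
                for i in kids:
                    prev[i][t_to] *= prev[node][t_to] / s
    return prev


class TestDetectionBoundaryCrossing:
    def test_crossing_fraction_matches_independent_resimulation(self):
        # fraction of trees with a subclone crossing the 5% VAF boundary
        cfg = small_config(expansion_sd=0.5, n_subclones_range=(2, 6))
        rho = 0.7
        ccf_limit = 0.05 / gt.expected_vaf(1, 2, rho)
        n_trees = 300

        def crossings(prevalences):
            hit = 0
            for prev in prevalences:
                crossed = False
                for i in prev:
                    if i == 0:
                        continue
                    vals = [prev[i][tp] for tp in sd.TIMEPOINTS]
                    for a, b in zip(vals, vals[1:]):
                        if (a < ccf_limit) != (b < ccf_limit):
                            crossed = True
                hit += crossed
            return hit / len(prevalences)

        package = []
        for seed in range(n_trees):
            tree = sd.simulate_clonal_tree(cfg, np.random.default_rng(seed))
            package.append(
                {s.subclone_id: s.prevalence for s in tree.subclones}
            )
        oracle = [
            _oracle_tree_prevalences(cfg, np.random.default_rng(seed))
            for seed in range(n_trees)
        ]
        for got, want in zip(package, oracle):
            for i in want:
                for tp in sd.TIMEPOINTS:
                    assert got[i][tp] == pytest.approx(want[i][tp])
        assert crossings(package) == pytest.approx(crossings(oracle))
        assert crossings(package) > 0  # dynamics actually cross the boundary


class TestCopyNumber:
    def test_no_events_is_diploid_everywhere(self):
        cfg = small_config()
        tree = sd.simulate_clonal_tree(cfg, np.random.default_rng(0))
        segs = sd.simulate_copy_number(tree, cfg, np.random.default_rng(0))
        assert ((segs["n_major"] == 1) & (segs["n_minor"] == 1)).all()

    def test_certain_loss_applies_to_all_patients(self):
        cfg = small_config(
            n_patients=10,
            directed_cna_events=(sd.CnaEvent("8q", "post_b", "loss", 1.0),),
        )
        cohort = sd.simulate_cohort(cfg)
        for p in cohort.patients:
            seg = p.segments.query("timepoint == 'post_b' and chrom == 'chr8'")
            q_arm = seg[seg["start"] == 50_000_000].iloc[0]
            assert q_arm["n_major"] + q_arm["n_minor"] == 1

    def test_event_probability_matches_binomial_oracle(self):
        prob, n = 0.3, 600
        cfg = small_config(
            n_patients=1,
            directed_cna_events=(sd.CnaEvent("3p", "post_a", "gain", prob),),
        )
        tree = sd.simulate_clonal_tree(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(n):
            segs = sd.simulate_copy_number(tree, cfg, rng)
            row = segs.query("timepoint == 'post_a' and bin == '3p'").iloc[0]
            hits += (row["n_major"] + row["n_minor"]) == 3
        se = np.sqrt(prob * (1 - prob) / n)
        assert abs(hits / n - prob) < 3 * se

    def test_unknown_bin_rejected(self):
        with pytest.raises(ValueError, match="unknown bin"):
            small_config(directed_cna_events=(sd.CnaEvent("nope", "pre", "loss", 1.0),))


class TestReadEmission:
    def test_zero_ccf_never_emits_alt_reads(self):
        rng = np.random.default_rng(0)
        assert all(
            sd.simulate_reads(0.0, 1, 2, 0.8, 150, rng)[0] == 0 for _ in range(200)
        )

    def test_diploid_het_pure_tumor_limit(self):
        rng = np.random.default_rng(1)
        alt, ref = sd.simulate_reads(1.0, 1, 2, 1.0, 1e6, rng)
        assert abs(alt / (alt + ref) - 0.5) < 0.002

    @pytest.mark.parametrize(
        "ccf, n_mut, n_tot, purity",
        [(1.0, 1, 2, 0.5), (1.0, 1, 2, 1.0), (0.5, 1, 2, 0.8), (1.0, 2, 4, 0.6)],
    )
    def test_mean_vaf_matches_analytic_emission(self, ccf, n_mut, n_tot, purity):
        rng = np.random.default_rng(7)
        n = 100_000
        p = ccf * gt.expected_vaf(n_mut, n_tot, purity)
        total_alt = total_depth = 0
        for _ in range(n):
            alt, ref = sd.simulate_reads(ccf, n_mut, n_tot, purity, 30, rng)
            total_alt += alt
            total_depth += alt + ref
        se = np.sqrt(p * (1 - p) / total_depth)
        assert abs(total_alt / total_depth - p) < 3 * se

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sd.simulate_reads(1.5, 1, 2, 0.5, 150, rng)
        with pytest.raises(ValueError):
            sd.simulate_reads(0.5, 1, 2, 0.5, -1, rng)


class TestCohortSerialization:
    def test_fixed_seed_reruns_are_byte_identical(self, tmp_path):
        cfg = small_config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.write_cohort(sd.simulate_cohort(cfg), d1)
        sd.write_cohort(sd.simulate_cohort(cfg), d2)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_truth_lists_every_mutation_exactly_once(self, tmp_path):
        cohort = sd.simulate_cohort(small_config())
        truth = cohort.truth()
        for record, patient in zip(truth["patients"], cohort.patients):
            from_tree = [m for c in record["tree"] for m in c["mutation_ids"]]
            assert len(from_tree) == len(set(from_tree))
            observed = set(patient.mutations["mutation_id"])
            assert set(from_tree) == observed
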