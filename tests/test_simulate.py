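"""Generators: determinism, constructed invariants, statistical calibration
against independent oracles, and ground-truth recovery."""

import dataclasses
import math
import random

import numpy as np
import pytest
from scipy.special import zeta

from cwrphylo import (
    ConfigurationError,
    Evidence,
    SimConfig,
    load_config,
    patristic_matrix,
    recovery_experiment,
    simulate_bundle,
    simulate_conservation,
    simulate_evidence,
    simulate_ploidy,
    simulate_tree,
    write_newick,
)
from cwrphylo.gaps import Establishment, endemic_flags, filter_native
from cwrphylo.simulate import _evolve_2n


class TestSimConfig:
    @pytest.mark.parametrize("kwargs", [
        {"evidence_missing_rate": 1.5},
        {"n_tips": 2},
        {"n_crops": 50, "n_tips": 50},
        {"birth_rate": 0.0},
        {"wgd_rate": -1},
        {"base_2n": 9},
        {"range_size_dispersion": 0.9},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)

    def test_yaml_round_trip_and_unknown_key(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("seed: 5\nn_tips: 30\nn_crops: 3\n", encoding="utf-8")
        config = load_config(path)
        assert (config.seed, config.n_tips, config.n_crops) == (5, 30, 3)
        path.write_text("sneed: 5\n", encoding="utf-8")
        with pytest.raises(ConfigurationError):
            load_config(path)


class TestSimulateTree:
    def test_seed_determinism_byte_identical(self):
        config = SimConfig(seed=42, n_tips=30, n_crops=3)
        assert write_newick(simulate_tree(config)) == write_newick(simulate_tree(config))

    def test_different_seeds_differ(self):
        a = write_newick(simulate_tree(SimConfig(seed=1, n_tips=30, n_crops=3)))
        b = write_newick(simulate_tree(SimConfig(seed=2, n_tips=30, n_crops=3)))
        assert a != b

    @pytest.mark.parametrize("seed", [0, 5, 11])
    def test_ultrametric_height_one_right_tip_count(self, seed):
        tree = simulate_tree(SimConfig(seed=seed, n_tips=40, n_crops=2))
        assert tree.n_tips == 40
        depths = np.array(list(tree.tip_depths().values()))
        assert np.max(np.abs(depths - 1.0)) <= 1e-8
        assert tree.is_ultrametric()

    @staticmethod
    def _straightforward_mean_pd(n_tips: int, rng: random.Random) -> float:
        """Independent re-simulation of the pure-birth process: no tree
        objects, just split times and pair counts.  On a height-T ultrametric
        tree d(i,j) = 2(T - t_mrca), so the pairwise-distance total is a sum
        over internal nodes of 2(T - t_v) * n_left * n_right."""
        left, right = [], []
        active = [left, right]
        birth = {id(left): 0.0, id(right): 0.0}
        t = 0.0
        while len(active) < n_tips:
            k = len(active)
            t += rng.expovariate(k)
            node = active.pop(rng.randrange(k))
            a, b = [], []
            node.extend([t, a, b])
            active += [a, b]
            birth[id(a)] = birth[id(b)] = t
        total_time = t + rng.expovariate(len(active))

        def agg(node):
            if not node:
                return 1, 0.0
            t_v, a, b = node
            na, sa = agg(a)
            nb, sb = agg(b)
            return na + nb, sa + sb + 2 * (total_time - t_v) * na * nb

        na, sa = agg(left)
        nb, sb = agg(right)
        total = sa + sb + 2 * total_time * na * nb
        n_pairs = n_tips * (n_tips - 1) / 2
        return total / total_time / n_pairs  # height-normalized mean

    def test_mean_pairwise_distance_matches_resimulation_oracle(self):
        n_reps, n_tips = 120, 20

        def mean_pd(tree):
            values = patristic_matrix(tree).values
            return values[np.triu_indices_from(values, k=1)].mean()

        ours = [mean_pd(simulate_tree(SimConfig(seed=s, n_tips=n_tips, n_crops=2)))
                for s in range(n_reps)]
        rng = random.Random(4242)
        theirs = [self._straightforward_mean_pd(n_tips, rng) for _ in range(n_reps)]
        se = math.hypot(np.std(ours, ddof=1) / math.sqrt(n_reps),
                        np.std(theirs, ddof=1) / math.sqrt(n_reps))
        assert abs(np.mean(ours) - np.mean(theirs)) <= 3 * se


class TestSimulateEvidence:
    def _run(self, **kwargs):
        config = SimConfig(seed=8, n_tips=50, n_crops=5, **kwargs)
        tree = simulate_tree(config)
        return config, tree, *simulate_evidence(tree, config)

    def test_noiseless_labels_partition_by_radius(self):
        config, tree, records, gt = self._run(evidence_missing_rate=0.0)
        matrix = patristic_matrix(tree)
        for r in records:
            d = matrix.distance(r.crop, r.relative)
            if d <= gt.radius[r.crop]:
                assert r.evidence in (Evidence.Y, Evidence.Y_STAR)
            else:
                assert r.evidence is Evidence.N

    def test_total_missingness_blanks_everything(self):
        _, _, records, _ = self._run(evidence_missing_rate=1.0)
        assert all(r.evidence is Evidence.NI for r in records)

    def test_ni_fraction_matches_missing_rate(self):
        rate = 0.3
        _, _, records, _ = self._run(evidence_missing_rate=rate)
        n = len(records)
        observed = sum(r.evidence is Evidence.NI for r in records) / n
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) <= 3 * se

    def test_anchors_subset_of_true_compatibles(self):
        _, _, _, gt = self._run(anchor_radius_scale=0.5)
        for crop in gt.crops:
            assert gt.anchors[crop] <= gt.compatible[crop]


class TestSimulatePloidy:
    def test_zero_rates_keep_base_count(self):
        config = SimConfig(seed=3, n_tips=20, n_crops=2,
                           wgd_rate=0.0, dysploidy_rate=0.0)
        tree = simulate_tree(config)
        ploidy = simulate_ploidy(tree, config)
        assert all(v == frozenset({16}) for v in ploidy.values())

    def test_single_forced_wgd_doubles(self):
        rng = np.random.default_rng(0)
        assert _evolve_2n(10, n_wgd=1, n_dysploidy=0, rng=rng) == 20

    def test_high_dysploidy_stays_even_and_floored(self):
        config = SimConfig(seed=9, n_tips=30, n_crops=2,
                           wgd_rate=0.0, dysploidy_rate=60.0, base_2n=4)
        tree = simulate_tree(config)
        for cytotypes in simulate_ploidy(tree, config).values():
            for v in cytotypes:
                assert v >= 4 and v % 2 == 0


class TestSimulateConservation:
    def test_degenerate_dispersion_all_endemic(self):
        config = SimConfig(seed=1, n_tips=10, n_crops=2,
                           range_size_dispersion=60.0, introduced_rate=0.0)
        occurrences, _ = simulate_conservation([f"t{i}" for i in range(200)], config)
        assert all(endemic_flags(occurrences).values())

    def test_full_zero_inflation_means_nothing_conserved(self):
        config = SimConfig(seed=1, n_tips=10, n_crops=2, exsitu_zero_inflation=1.0)
        _, conservation = simulate_conservation([f"t{i}" for i in range(100)], config)
        assert all(c.exsitu_accessions == 0 for c in conservation)

    def test_endemic_fraction_matches_zeta_tail(self):
        config = SimConfig(seed=17, n_tips=10, n_crops=2)
        n = 2000
        occurrences, _ = simulate_conservation([f"t{i}" for i in range(n)], config)
        flags = endemic_flags(filter_native(occurrences))
        p = 1.0 / zeta(config.range_size_dispersion)
        observed = sum(flags.values()) / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se

    def test_introduced_records_present_and_filterable(self):
        config = SimConfig(seed=2, n_tips=10, n_crops=2, introduced_rate=0.5)
        occurrences, _ = simulate_conservation([f"t{i}" for i in range(200)], config)
        intro = [o for o in occurrences if o.establishment is Establishment.INTRODUCED]
        assert intro and len(filter_native(occurrences)) == len(occurrences) - len(intro)


class TestRecoveryExperiment:
    CONFIG = SimConfig(seed=21, n_tips=40, n_crops=4, evidence_missing_rate=0.0)

    def test_noiseless_recovery_is_exact(self):
        df = recovery_experiment(self.CONFIG, n_replicates=10)
        defined = df.dropna(subset=["tau"])
        assert len(defined) > 0
        assert (defined.tau == defined.max_anchor_distance).all()
        assert (defined.tau <= defined.r + 1e-12).all()
        assert (defined.sensitivity == 1.0).all()
        assert (defined.specificity == 1.0).all()

    def test_half_radius_anchors_are_conservative(self):
        config = dataclasses.replace(self.CONFIG, anchor_radius_scale=0.5)
        df = recovery_experiment(config, n_replicates=10)
        defined = df.dropna(subset=["tau"])
        assert (defined.tau <= defined.r + 1e-12).all()
        assert (defined.specificity == 1.0).all()
        assert (defined.sensitivity <= 1.0).all()

    def test_metrics_deterministic_across_reruns(self):
        a = recovery_experiment(self.CONFIG, n_replicates=3)
        b = recovery_experiment(self.CONFIG, n_replicates=3)
        assert a.to_csv(index=False) == b.to_csv(index=False)


class TestSimulateBundle:
    def test_bundle_consistent_and_deterministic(self):
        config = SimConfig(seed=33, n_tips=30, n_crops=3)
        a, b = simulate_bundle(config), simulate_bundle(config)
        assert write_newick(a.tree) == write_newick(b.tree)
        assert a.crosses == b.crosses
        assert a.conservation == b.conservation
        tips = set(a.tree.tip_labels)
        assert set(a.ground_truth.two_n) == tips
        assert {t.name for t in a.taxa.values()} == tips
        assert sum(t.is_crop for t in a.taxa.values()) == 3
        for crop in a.ground_truth.crops:
            assert a.ground_truth.anchors[crop] <= a.ground_truth.compatible[crop]
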