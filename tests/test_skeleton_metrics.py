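"""Cable-length measurement, consistency filtering and decay-rate fitting."""

import numpy as np
import pytest

from edrnet.skeleton import SkeletonTree
from edrnet.skeleton_metrics import (
    ExponentialDecayModel,
    MeasurementError,
    arbor_consistency_filter,
    fit_edr,
    measure_cohort,
    measure_neuron,
    path_length_to_node,
    scaling_factor,
)
from edrnet.synthetic import SyntheticTruth, make_skeletons


def chain_tree(step_lengths, **kwargs):
    xyz = [[0.0, 0.0, 0.0]]
    for s in step_lengths:
        xyz.append([xyz[-1][0] + s, 0.0, 0.0])
    n = len(xyz)
    return SkeletonTree(
        node_ids=np.arange(n), parents=np.arange(-1, n - 1), xyz=np.array(xyz), **kwargs
    )


class TestPathLength:
    def test_chain_hand_sum(self):
        tree = chain_tree([0.1, 0.2])
        assert path_length_to_node(tree, 2) == pytest.approx(0.3)

    def test_soma_is_zero(self):
        tree = chain_tree([0.1, 0.2])
        assert path_length_to_node(tree, 0) == 0.0

    def test_unknown_node_rejected(self):
        with pytest.raises(KeyError):
            path_length_to_node(chain_tree([0.1]), 99)

    def test_random_tree_matches_floyd_warshall(self):
        # unique tree path must equal the general shortest path on the tree graph
        rng = np.random.default_rng(4)
        n = 50
        parents = np.concatenate([[-1], [int(rng.integers(0, k)) for k in range(1, n)]])
        xyz = rng.uniform(0, 1, (n, 3))
        tree = SkeletonTree(node_ids=np.arange(n), parents=parents, xyz=xyz)
        import math

        INF = math.inf
        d = [[0.0 if i == j else INF for j in range(n)] for i in range(n)]
        for k in range(1, n):
            e = float(np.linalg.norm(xyz[k] - xyz[parents[k]]))
            d[k][parents[k]] = d[parents[k]][k] = e
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    if d[i][k] + d[k][j] < d[i][j]:
                        d[i][j] = d[i][k] + d[k][j]
        for node in rng.integers(0, n, 12):
            assert tree.path_length_to_root(int(node)) == pytest.approx(d[0][int(node)])
        for u, v in rng.integers(0, n, (12, 2)):
            assert tree.path_length_between(int(u), int(v)) == pytest.approx(d[int(u)][int(v)])


class TestMeasureNeuron:
    def _toy(self):
        # soma(0) - branch(1) at 0.05; dendrite node(2) at path 0.08;
        # axon nodes 3,4 with path(4) = 0.30
        xyz = np.array([
            [0.0, 0.0, 0.0],
            [0.05, 0.0, 0.0],
            [0.05, 0.03, 0.0],
            [0.15, 0.0, 0.0],
            [0.15, 0.15, 0.0],
        ])
        return SkeletonTree(
            node_ids=np.arange(5),
            parents=np.array([-1, 0, 1, 1, 3]),
            xyz=xyz,
            presyn_nodes=frozenset({4}),
            postsyn_nodes=frozenset({2}),
        )

    def test_toy_tree_hand_computation(self):
        rec = measure_neuron(self._toy())
        assert rec.cable_mm == pytest.approx((0.08 - 0.05) + (0.30 - 0.05))
        assert rec.euclid_mm == pytest.approx(np.hypot(0.10, 0.12))
        assert rec.post_min_mm == pytest.approx(0.08)
        assert rec.pre_min_mm == pytest.approx(0.30)

    def test_coincident_pre_post_gives_zero(self):
        tree = chain_tree([0.1, 0.1], presyn_nodes={2}, postsyn_nodes={2})
        rec = measure_neuron(tree)
        assert rec.cable_mm == 0.0 and rec.euclid_mm == 0.0

    def test_missing_synapses_named_in_error(self):
        with pytest.raises(MeasurementError, match="presynaptic"):
            measure_neuron(chain_tree([0.1], postsyn_nodes={1}))
        with pytest.raises(MeasurementError, match="postsynaptic"):
            measure_neuron(chain_tree([0.1], presyn_nodes={1}))

    def test_synthetic_ground_truth_recovered(self, atlas75):
        truth = SyntheticTruth(33.0, 1.5, seed=17)
        skeletons, table = make_skeletons(atlas75, truth, 50)
        rec = measure_cohort(skeletons)
        assert np.allclose(rec["cable_mm"], table["cable_true_mm"], atol=1e-12)
        assert np.allclose(rec["euclid_mm"], table["euclid_true_mm"], atol=1e-12)

    def test_cable_at_least_euclid(self, atlas75):
        skeletons, _ = make_skeletons(atlas75, SyntheticTruth(seed=3), 100)
        rec = measure_cohort(skeletons)
        assert (rec["cable_mm"] >= rec["euclid_mm"] - 1e-12).all()


class TestConsistencyFilter:
    def test_threshold_discards_inconsistent(self):
        import pandas as pd

        rec = pd.DataFrame(
            dict(
                neuron_id=[0, 1],
                pre_min_mm=[0.1, 0.1],
                pre_mean_mm=[0.3, 0.2],  # diffs 0.2, 0.1
                post_min_mm=[0.1, 0.1],
                post_mean_mm=[0.1, 0.1],
                cable_mm=[1, 1],
                euclid_mm=[1, 1],
                hemi_class=["intra", "intra"],
                kept=[True, True],
            )
        )
        out, summary = arbor_consistency_filter(rec, 0.15)
        assert list(out["kept"]) == [False, True]
        assert summary["kept_fraction"] == 0.5

    def test_single_point_zero_difference_kept(self):
        import pandas as pd

        rec = pd.DataFrame(
            dict(neuron_id=[0], pre_min_mm=[0.4], pre_mean_mm=[0.4],
                 post_min_mm=[0.2], post_mean_mm=[0.2], cable_mm=[1], euclid_mm=[1],
                 hemi_class=["intra"], kept=[True])
        )
        out, _ = arbor_consistency_filter(rec, 0.15)
        assert out["kept"].all()

    def test_infinite_threshold_keeps_all(self, atlas75):
        skeletons, _ = make_skeletons(atlas75, SyntheticTruth(seed=9), 30)
        rec = measure_cohort(skeletons)
        out, summary = arbor_consistency_filter(rec, np.inf)
        assert summary["kept_fraction"] == 1.0

    def test_monotone_in_threshold(self, atlas75):
        skeletons, _ = make_skeletons(atlas75, SyntheticTruth(seed=9), 60, arbor_radius_mm=0.2)
        rec = measure_cohort(skeletons)
        kept_sets = []
        for t in (0.05, 0.1, 0.2, 0.5):
            out, _ = arbor_consistency_filter(rec, t)
            kept_sets.append(set(out.loc[out["kept"], "neuron_id"]))
        for small, large in zip(kept_sets, kept_sets[1:]):
            assert small <= large


class TestFitEdr:
    def test_exact_exponential_histogram_counts(self):
        # counts proportional to exp(-33 x) at bin centers -> slope 33 exactly
        bs = 0.01
        centers = bs * (np.arange(30) + 0.5)
        counts = np.round(1e7 * np.exp(-33.0 * centers)).astype(int)
        lengths = np.repeat(centers, counts)
        fit = fit_edr(lengths, bin_sizes_mm=(bs,))
        assert fit.lambda_per_mm == pytest.approx(33.0, rel=1e-4)

    def test_recovery_from_exponential_draws(self):
        # 50k draws at lambda=33, averaged over 10 seeds, within the +-10% band
        lams = []
        for s in range(10):
            rng = np.random.default_rng(1000 + s)
            x = rng.exponential(1 / 33.0, 50_000)
            lams.append(fit_edr(x).lambda_per_mm)
        assert 29.7 <= np.mean(lams) <= 36.3

    def test_interval_spans_per_bin_size_fits(self):
        rng = np.random.default_rng(5)
        fit = fit_edr(rng.exponential(1 / 25.0, 20_000))
        lo, hi = fit.lambda_interval
        for lam in fit.per_bin_size.values():
            assert lo <= lam <= hi

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_edr(np.full(100, 0.2))

    def test_mle_cross_check(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(1 / 40.0, 30_000)
        m = ExponentialDecayModel(x)
        assert m.mle_lambda() == pytest.approx(40.0, rel=0.05)
        assert m.fit().lambda_per_mm == pytest.approx(m.mle_lambda(), rel=0.15)

    def test_euclid_rate_exceeds_cable_rate_under_tortuosity(self, atlas75):
        truth = SyntheticTruth(33.0, tortuosity_a=1.5, seed=12)
        skeletons, _ = make_skeletons(atlas75, truth, 4000)
        rec = measure_cohort(skeletons)
        f_cable = fit_edr(rec["cable_mm"])
        f_euclid = fit_edr(rec["euclid_mm"])
        assert f_euclid.lambda_per_mm > f_cable.lambda_per_mm
        assert f_euclid.lambda_per_mm / f_cable.lambda_per_mm == pytest.approx(1.5, rel=0.12)


class TestScalingFactor:
    def test_exact_line(self):
        e = np.linspace(0.01, 0.5, 40)
        a, r = scaling_factor(1.5 * e, e)
        assert a == pytest.approx(1.5) and r == pytest.approx(1.0)

    def test_identity(self):
        e = np.linspace(0.01, 0.5, 40)
        a, r = scaling_factor(e, e)
        assert a == pytest.approx(1.0) and r == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            scaling_factor(np.ones(10), np.ones(10))

    def test_synthetic_cohort_recovers_tortuosity(self, atlas75):
        truth = SyntheticTruth(33.0, tortuosity_a=1.5, seed=13)
        skeletons, _ = make_skeletons(atlas75, truth, 2000, jitter=0.05)
        rec = measure_cohort(skeletons)
        a, r = scaling_factor(rec["cable_mm"].to_numpy(), rec["euclid_mm"].to_numpy())
        assert a == pytest.approx(1.5, abs=0.05)
        assert r > 0.9
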