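import numpy as np
import pytest

from dyntopo import (
    SignedGraph,
    TopologySeries,
    WindowPartitionSet,
    cartographic_profile,
    match_labels,
    module_degree_zscore,
    participation_coef,
    regional_flexibility,
)
from oracles import module_degree_z_oracle, participation_oracle


def _random_graph(n, seed):
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n, n))
    return SignedGraph(w + w.T)


class TestCartographyMeasures:
    @pytest.mark.parametrize("seed", range(10))
    def test_match_brute_force_oracles(self, seed):
        g = _random_graph(12, seed)
        part = np.random.default_rng(seed + 100).integers(1, 5, size=12)
        np.testing.assert_allclose(
            module_degree_zscore(g, part),
            module_degree_z_oracle(g.weights, part),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            participation_coef(g, part),
            participation_oracle(g.weights, part),
            atol=1e-12,
        )

    def test_all_within_node_has_zero_participation(self):
        w = np.zeros((8, 8))
        part = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        for j in range(1, 4):  # node 0 connects only inside its module
            w[0, j] = w[j, 0] = 0.7
        w[4, 5] = w[5, 4] = 1.0  # some structure elsewhere
        b = participation_coef(SignedGraph(w), part)
        assert b[0] == 0.0

    def test_uniform_spread_node(self):
        # equal positive strength to each of 4 modules -> B = 1 - 4*(1/4)^2
        w = np.zeros((9, 9))
        part = np.array([1, 1, 2, 2, 3, 3, 4, 4, 1])
        for j, target in enumerate([0, 2, 4, 6]):
            w[8, target] = w[target, 8] = 0.5
        b = participation_coef(SignedGraph(w), part)
        assert b[8] == pytest.approx(0.75)

    def test_zscore_properties(self):
        g = _random_graph(20, 3)
        part = np.repeat([1, 2, 3, 4], 5)
        z = module_degree_zscore(g, part)
        for m in range(1, 5):
            members = part == m
            assert abs(z[members].mean()) < 1e-9
        # member whose strength equals the module mean scores 0 exactly
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0  # symmetric triangle: all kappas equal
        z = module_degree_zscore(SignedGraph(w), np.array([1, 1, 1, 2, 2, 2]))
        np.testing.assert_array_equal(z[:3], 0.0)

    def test_participation_monotone_in_spreading(self):
        """Moving positive strength to a new module strictly increases B."""
        w = np.zeros((8, 8))
        part = np.array([1, 1, 1, 1, 2, 2, 3, 3])
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        b_before = participation_coef(SignedGraph(w), part)[0]
        w2 = w.copy()
        w2[0, 2] = w2[2, 0] = 0.0
        w2[0, 4] = w2[4, 0] = 1.0  # same total strength, now split across modules
        b_after = participation_coef(SignedGraph(w2), part)[0]
        assert b_after > b_before


class TestCartographicProfile:
    def test_point_mass_occupies_single_bin(self):
        topo = TopologySeries(W=np.zeros((5, 4)), B=np.full((5, 4), 0.5))
        prof = cartographic_profile(topo, n_bins_b=10, n_bins_w=10)
        assert prof.occupancy.max() == pytest.approx(1.0)
        assert prof.occupancy.sum() == pytest.approx(1.0)

    def test_occupancy_normalised_and_clipping_counted(self):
        rng = np.random.default_rng(0)
        topo = TopologySeries(
            W=rng.standard_normal((20, 10)) * 4, B=rng.uniform(0, 1, (20, 10))
        )
        prof = cartographic_profile(topo, n_bins_b=20, n_bins_w=20)
        assert prof.occupancy.sum() == pytest.approx(1.0, abs=1e-12)
        assert prof.n_clipped == np.sum(np.abs(topo.W) > 5)

    def test_integrated_state_shifts_mass_toward_high_b(self):
        from dyntopo import SyntheticSpec, generate_modular_bold, mtd_coupling
        from dyntopo.topology import topology_series

        profs = {}
        for name, between in (("seg", 0.05), ("int", 0.55)):
            spec = SyntheticSpec(
                n_regions=24, module_sizes=(6, 6, 6, 6), n_frames=160,
                within_coupling=0.7, between_coupling_by_state={"rest": between},
                seed=4,
            )
            ts, truth = generate_modular_bold(spec)
            tensor = mtd_coupling(ts, w=15)
            topo = topology_series(tensor, truth.planted_partition)
            profs[name] = cartographic_profile(topo, n_bins_b=20, n_bins_w=20)
        assert (
            profs["int"].b_center_of_mass() > profs["seg"].b_center_of_mass() + 0.05
        )

    def test_empty_topology_rejected(self):
        with pytest.raises(ValueError, match="W and B"):
            TopologySeries(W=np.zeros((2, 2)), B=np.zeros((0, 2)))


def _parts(assignments, gamma=1.0):
    a = np.asarray(assignments)
    return WindowPartitionSet(
        assignments=a, modularity=np.zeros(a.shape[0]), gamma=gamma
    )


class TestLabelMatching:
    def test_permuted_labels_become_identical(self):
        base = np.array([1, 1, 2, 2, 3, 3])
        perms = [{1: 2, 2: 3, 3: 1}, {1: 3, 2: 1, 3: 2}, {1: 1, 2: 2, 3: 3}]
        rows = [np.array([p[x] for x in base]) for p in perms]
        matched = match_labels(_parts(rows))
        for row in matched.assignments:
            np.testing.assert_array_equal(row, matched.assignments[0])

    def test_matching_preserves_modularity_and_grouping(self):
        rng = np.random.default_rng(2)
        a = rng.integers(1, 4, size=(6, 10))
        parts = _parts(a)
        matched = match_labels(parts)
        np.testing.assert_array_equal(matched.modularity, parts.modularity)
        for before, after in zip(parts.assignments, matched.assignments):
            # same grouping: co-membership matrices identical
            np.testing.assert_array_equal(
                before[:, None] == before[None, :],
                after[:, None] == after[None, :],
            )

    def test_single_migrating_region(self):
        w1 = np.array([1, 1, 1, 2, 2, 2])
        w2 = np.array([2, 2, 2, 1, 1, 1])  # permuted labels, same grouping
        w3 = np.array([2, 2, 1, 1, 1, 1])  # region 2 migrated (in w2's labels)
        matched = match_labels(_parts([w1, w2, w3]))
        np.testing.assert_array_equal(matched.assignments[0], matched.assignments[1])
        diff = matched.assignments[2] != matched.assignments[1]
        np.testing.assert_array_equal(diff, [False, False, True, False, False, False])


class TestFlexibility:
    def test_constant_partition_zero(self):
        matched = match_labels(_parts([[1, 2, 1], [1, 2, 1], [1, 2, 1]]))
        flex = regional_flexibility(matched)
        np.testing.assert_array_equal(flex.values, 0.0)

    def test_label_permuted_constant_partition_zero(self):
        rows = [[1, 1, 2, 2], [2, 2, 1, 1], [1, 1, 2, 2]]
        flex = regional_flexibility(match_labels(_parts(rows)))
        np.testing.assert_array_equal(flex.values, 0.0)

    def test_hand_built_migration_fixture(self):
        """Region 0 switches at 4 of 9 transitions; others are stable."""
        rows = []
        membership = 1
        switch_at = {2, 4, 6, 8}
        for t in range(10):
            if t in switch_at:
                membership = 3 - membership  # toggle 1 <-> 2
            row = [membership, 1, 1, 2, 2]
            rows.append(row)
        flex = regional_flexibility(match_labels(_parts(rows)))
        assert flex.values[0] == pytest.approx(4 / 9)
        np.testing.assert_array_equal(flex.values[1:], 0.0)

    def test_invariant_under_window_label_permutation(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(1, 4, size=(8, 6))
        flex_a = regional_flexibility(match_labels(_parts(rows)))
        permuted = rows.copy()
        mapping = {1: 3, 2: 1, 3: 2}
        permuted[4] = np.vectorize(mapping.get)(permuted[4])
        flex_b = regional_flexibility(match_labels(_parts(permuted)))
        np.testing.assert_allclose(flex_a.values, flex_b.values)

    def test_per_module_normalisation(self):
        rows = [[1, 2, 1, 2], [2, 1, 2, 1], [1, 2, 2, 1]]
        matched = match_labels(_parts(rows))
        sw = regional_flexibility(matched, normalization="switch_fraction")
        pm = regional_flexibility(matched, normalization="per_module")
        np.testing.assert_allclose(
            pm.values, sw.values / matched.n_modules.mean()
        )
        assert pm.normalization == "per_module"
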