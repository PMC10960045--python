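import numpy as np
import pytest

from braincontrol.controllability import InputSet
from braincontrol.lcc import input_distances
from braincontrol.placement import (hub_greedy_for_lcc, input_set_census,
                                    matched_size_hub_set, min_inputs_for_lcc)
from braincontrol.synthetic_data import rich_club_chain_fixture

from conftest import make_net, min_cover_brute, random_digraph


class TestMinInputs:
    def test_toy_exact_two_inputs_for_lcc2(self, toy):
        res = min_inputs_for_lcc(toy, 2, mode="exact")
        assert res.n_inputs == 2
        assert 0 in res.inputs  # node 1 has no in-links: always forced
        assert res.achieved_lcc <= 2

    def test_lcc_zero_forces_all_nodes(self, toy):
        res = min_inputs_for_lcc(toy, 0)
        assert res.inputs == tuple(range(5))
        assert res.achieved_lcc == 0

    def test_star_center_covers_at_distance_one(self, star4):
        res = min_inputs_for_lcc(star4, 1, mode="exact",
                                 verify_controllability=False)
        assert res.inputs == (0,)
        assert res.achieved_lcc == 1

    def test_star_cover_augmented_to_controllable_set(self, star4):
        # the three leaves hang off one node, so a lone center signal cannot
        # steer them independently: the Gramian safeguard adds unmatched nodes
        res = min_inputs_for_lcc(star4, 1, mode="exact")
        assert res.controllable
        assert res.augmented_nodes != ()
        assert 0 in res.inputs and res.n_inputs > 1

    def test_exact_matches_brute_force_on_random_digraphs(self):
        rng = np.random.default_rng(71)
        for _ in range(15):
            n = int(rng.integers(3, 8))
            net = random_digraph(rng, n, p=0.3)
            ell = int(rng.integers(1, 3))
            res = min_inputs_for_lcc(net, ell, mode="exact",
                                     verify_controllability=False)
            assert res.n_inputs == len(min_cover_brute(net, ell))

    def test_exact_le_greedy_le_hub(self):
        rng = np.random.default_rng(73)
        for _ in range(10):
            net = random_digraph(rng, int(rng.integers(4, 12)), p=0.3)
            ell = int(rng.integers(1, 3))
            kw = dict(verify_controllability=False)
            exact = min_inputs_for_lcc(net, ell, mode="exact", **kw)
            greedy = min_inputs_for_lcc(net, ell, mode="greedy", **kw)
            hub = hub_greedy_for_lcc(net, ell, **kw)
            assert exact.n_inputs <= greedy.n_inputs <= hub.n_inputs

    def test_monotone_in_ell(self):
        rng = np.random.default_rng(79)
        net = random_digraph(rng, 10, p=0.3)
        sizes = [min_inputs_for_lcc(net, ell,
                                    verify_controllability=False).n_inputs
                 for ell in range(4)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_returned_set_verified_by_lcc_module(self):
        rng = np.random.default_rng(83)
        for _ in range(10):
            net = random_digraph(rng, 9, p=0.35)
            res = min_inputs_for_lcc(net, 2, verify_controllability=False)
            prof = input_distances(net, InputSet(res.inputs))
            assert prof.lcc <= 2

    def test_negative_ell_rejected(self, toy):
        with pytest.raises(ValueError):
            min_inputs_for_lcc(toy, -1)


class TestHubGreedy:
    def test_star_hub_greedy_matches_optimal(self, star4):
        res = hub_greedy_for_lcc(star4, 1, verify_controllability=False)
        assert res.inputs == (0,) and res.method == "hub-greedy"

    def test_two_stars_need_both_centers(self):
        # centers 0 (degree 4) and 5 (degree 3), bidirected
        edges = [(0, v) for v in (1, 2, 3, 4)] + [(5, v) for v in (6, 7, 8)]
        edges += [(j, i) for i, j in edges]
        net = make_net(edges, 9)
        res = hub_greedy_for_lcc(net, 1, verify_controllability=False)
        assert res.inputs == (0, 5)

    def test_rich_club_fixture_hub_prefix_strictly_larger(self):
        net = rich_club_chain_fixture()
        greedy = min_inputs_for_lcc(net, 1, verify_controllability=False)
        hub = hub_greedy_for_lcc(net, 1, verify_controllability=False)
        assert hub.n_inputs > greedy.n_inputs


class TestMatchedHubSet:
    def test_hub_clique_dispersion_is_one_with_zero_std(self):
        net = rich_club_chain_fixture()  # top-4 degrees form the clique
        res = matched_size_hub_set(net, 4)
        assert res.mean_pairwise_input_distance == pytest.approx(1.0)
        assert res.pairwise_input_distance_std == pytest.approx(0.0)

    def test_singleton_reference_has_no_dispersion(self, star4):
        res = matched_size_hub_set(star4, 1)
        assert res.mean_pairwise_input_distance is None
        assert res.pairwise_input_distance_std is None

    def test_optimal_set_more_dispersed_than_hub_set(self):
        net = rich_club_chain_fixture()
        opt = min_inputs_for_lcc(net, 1, mode="exact",
                                 verify_controllability=False)
        hubs = matched_size_hub_set(net, opt)
        assert opt.mean_pairwise_input_distance \
            > hubs.mean_pairwise_input_distance


class TestCensus:
    def test_star_center_in_every_set(self, star4):
        res = input_set_census(star4, 1, n_sets=5, seed=0)
        assert 0 in res.primary_contributors
        assert res.counts[0] == res.n_sets

    def test_toy_root_forced_in_every_set(self, toy):
        res = input_set_census(toy, 2, n_sets=10, seed=1)
        assert 0 in res.primary_contributors

    def test_census_reproducible_under_seed(self, toy):
        a = input_set_census(toy, 2, n_sets=10, seed=7)
        b = input_set_census(toy, 2, n_sets=10, seed=7)
        assert a.sets == b.sets
        assert np.array_equal(a.counts, b.counts)

    def test_warns_when_fewer_distinct_sets_exist(self, star4):
        with pytest.warns(UserWarning, match="distinct"):
            res = input_set_census(star4, 1, n_sets=50, seed=0,
                                   max_attempts_factor=2)
        assert res.n_sets < 50
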