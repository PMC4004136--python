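import pytest

from disseminet.dissemination_metrics import (
    OrganizationProfile,
    activity_histogram,
    cdf_value,
    characterize,
    data_cleaning_report,
    dissemination_potential,
    follower_cdf,
    level2_follower_sum,
    multi_group_membership,
    overlap_percentage,
    profiles_from_graph,
    prune_inactive,
    unique_two_hop_reach,
)
from disseminet.network_model import (
    Account,
    FollowGraph,
    GraphDomainError,
    UnknownAccountError,
)


def org_with_followers(counts_and_tweets):
    """Graph with one org whose i-th follower has (declared count, tweets)."""
    g = FollowGraph([Account("org", is_organization=True)])
    ids = []
    for i, (declared, tweets) in enumerate(counts_and_tweets):
        fid = f"f{i}"
        g.add_account(Account(fid, declared_follower_count=declared, tweet_count=tweets))
        g.add_edge("org", fid)
        ids.append(fid)
    return g, OrganizationProfile("org", frozenset(ids))


class TestLevel2AndPotential:
    def test_zero_count_followers_contribute_nothing(self):
        g, org = org_with_followers([(0, 1)] * 4)
        assert level2_follower_sum(g, org) == 0
        assert dissemination_potential(g, org) == 4

    def test_sums_declared_counts_without_deduplication(self):
        g, org = org_with_followers([(10, 1), (20, 1), (30, 1)])
        assert level2_follower_sum(g, org) == 60
        assert dissemination_potential(g, org) == 63

    def test_no_followers_means_zero_potential(self):
        g = FollowGraph([Account("org")])
        org = OrganizationProfile("org", frozenset())
        assert dissemination_potential(g, org) == 0

    def test_unregistered_follower_raises(self):
        g = FollowGraph([Account("org")])
        org = OrganizationProfile("org", frozenset({"ghost"}))
        with pytest.raises(UnknownAccountError):
            level2_follower_sum(g, org)

    def test_structural_mode_uses_in_graph_degree(self):
        g, org = org_with_followers([(1000, 1), (1000, 1)])
        g.add_account(Account("x"))
        g.add_edge("f0", "x")
        assert level2_follower_sum(g, org, structural=True) == 1
        assert level2_follower_sum(g, org) == 2000

    def test_unique_two_hop_reach_deduplicates(self):
        g, org = org_with_followers([(5, 1), (5, 1)])
        g.add_account(Account("shared"))
        g.add_edge("f0", "shared")
        g.add_edge("f1", "shared")
        # followers {f0,f1} plus one shared level-2 account
        assert unique_two_hop_reach(g, org) == 3


class TestOverlapPercentage:
    def test_identical_sets_give_100(self):
        assert overlap_percentage({"a", "b"}, {"a", "b"}) == 100.0

    def test_disjoint_sets_give_0(self):
        assert overlap_percentage({"a"}, {"b"}) == 0.0

    def test_normalized_by_smaller_set(self):
        assert overlap_percentage({1, 2, 3}, {2, 3, 4, 5}) == pytest.approx(66.6667, abs=1e-3)

    def test_symmetric(self):
        a, b = {"a", "b", "c"}, {"b", "x"}
        assert overlap_percentage(a, b) == overlap_percentage(b, a)

    def test_containment_gives_100(self):
        assert overlap_percentage({"a", "b"}, {"a", "b", "c", "d"}) == 100.0

    def test_empty_set_rejected(self):
        with pytest.raises(GraphDomainError):
            overlap_percentage(set(), {"a"})


class TestMultiGroupMembership:
    @staticmethod
    def profile(org_id, members):
        return OrganizationProfile(org_id, frozenset(members))

    def test_disjoint_groups(self):
        result = multi_group_membership([self.profile("A", "ab"), self.profile("B", "cd")])
        assert result.counts_by_k == {1: 4}
        assert result.full_intersection == frozenset()

    def test_identical_groups(self):
        s = {"x", "y", "z"}
        result = multi_group_membership([self.profile(i, s) for i in "ABC"])
        assert result.counts_by_k == {3: 3}
        assert result.full_intersection == frozenset(s)

    def test_mixed_membership(self):
        result = multi_group_membership(
            [self.profile("A", {"1", "2"}), self.profile("B", {"2", "3"}), self.profile("C", {"2", "4"})]
        )
        assert result.counts_by_k == {1: 3, 3: 1}
        assert result.full_intersection == {"2"}

    def test_counts_sum_to_union(self):
        profiles = [self.profile("A", {"1", "2", "5"}), self.profile("B", {"2", "3"})]
        result = multi_group_membership(profiles)
        assert result.union_size == len({"1", "2", "3", "5"})

    def test_duplicate_org_ids_rejected(self):
        with pytest.raises(ValueError):
            multi_group_membership([self.profile("A", "ab"), self.profile("A", "cd")])


class TestFollowerCdf:
    def test_single_value_single_step(self):
        g, org = org_with_followers([(7, 0)] * 5)
        assert follower_cdf(g, org) == [(7, 1.0)]

    def test_distinct_counts_quartiles(self):
        g, org = org_with_followers([(0, 0), (10, 0), (100, 0), (1000, 0)])
        assert follower_cdf(g, org) == [(0, 0.25), (10, 0.5), (100, 0.75), (1000, 1.0)]

    def test_step_evaluation_is_right_continuous(self):
        g, org = org_with_followers([(0, 0), (10, 0), (100, 0), (1000, 0)])
        points = follower_cdf(g, org)
        assert cdf_value(points, 9) == 0.25
        assert cdf_value(points, 10) == 0.5
        assert cdf_value(points, 99999) == 1.0

    def test_matches_naive_recount(self):
        counts = [(c * 13 % 47, 0) for c in range(60)]
        g, org = org_with_followers(counts)
        points = follower_cdf(g, org)
        for threshold in (0, 5, 20, 46):
            naive = sum(1 for c, _ in counts if c <= threshold) / len(counts)
            assert cdf_value(points, threshold) == pytest.approx(naive)

    def test_no_followers_rejected(self):
        g = FollowGraph([Account("org")])
        with pytest.raises(GraphDomainError):
            follower_cdf(g, OrganizationProfile("org", frozenset()))


class TestActivityHistogram:
    def test_all_silent(self):
        g, org = org_with_followers([(0, 0)] * 3)
        assert activity_histogram(g, org) == {0: 1.0}

    def test_zero_bin_isolates_exact_zeros(self):
        g, org = org_with_followers([(0, 0), (0, 1), (0, 5), (0, 500)])
        hist = activity_histogram(g, org, log_bins=True)
        assert hist[0] == 0.25
        assert hist[1] == 0.5  # volumes 1 and 5 share the first decade
        assert hist[100] == 0.25

    def test_fractions_sum_to_one(self):
        g, org = org_with_followers([(0, t) for t in [0, 0, 3, 17, 17, 240]])
        for log_bins in (False, True):
            hist = activity_histogram(g, org, log_bins=log_bins)
            assert sum(hist.values()) == pytest.approx(1.0)

    def test_matches_brute_force_count(self):
        tweets = [0, 1, 1, 2, 9, 10, 33]
        g, org = org_with_followers([(0, t) for t in tweets])
        hist = activity_histogram(g, org)
        for volume in set(tweets):
            assert hist[volume] == pytest.approx(tweets.count(volume) / len(tweets))


class TestPruneInactive:
    def make(self):
        # follower tuples: (declared audience, tweets sent)
        return org_with_followers([(100, 0), (50, 5), (200, 12), (1000, 40)])

    def test_none_threshold_prunes_nothing(self):
        g, org = self.make()
        result = prune_inactive(g, org, None)
        assert result.percent_reduction == 0.0
        assert result.pruned_potential == dissemination_potential(g, org)

    def test_threshold_above_everyone_removes_everything(self):
        g, org = self.make()
        assert prune_inactive(g, org, 40).percent_reduction == 100.0

    def test_reduction_monotone_in_threshold(self):
        g, org = self.make()
        reductions = [prune_inactive(g, org, t).percent_reduction for t in (0, 5, 12, 40)]
        assert reductions == sorted(reductions)

    def test_two_route_equivalence_with_subgraph_recomputation(self):
        g, org = self.make()
        for t in (0, 5, 12):
            kept = frozenset(
                f for f in org.follower_ids if g.account(f).tweet_count > t
            )
            direct = prune_inactive(g, org, t).pruned_potential
            rerouted = dissemination_potential(g, OrganizationProfile("org", kept))
            assert direct == rerouted

    def test_quiet_followers_with_tiny_audiences_barely_reduce(self):
        followers = [(2, 0)] * 10 + [(10_000, 50)] * 10
        g, org = org_with_followers(followers)
        result = prune_inactive(g, org, 0)
        assert result.percent_reduction is not None and result.percent_reduction < 1.0

    def test_zero_potential_flagged_undefined(self):
        g = FollowGraph([Account("org")])
        result = prune_inactive(g, OrganizationProfile("org", frozenset()), 0)
        assert not result.defined

    def test_negative_threshold_rejected(self):
        g, org = self.make()
        with pytest.raises(GraphDomainError):
            prune_inactive(g, org, -1)


class TestCharacterizeAndCleaning:
    def test_report_invariants(self):
        g, org = org_with_followers([(10, 0), (20, 3), (30, 11)])
        report = characterize(g, org)
        assert report.potential == report.follower_count + report.level2_sum
        reductions = [
            report.pruned_potentials[t].percent_reduction for t in (None, 0, 10)
        ]
        assert reductions == sorted(reductions)

    def test_cleaning_no_ignored_rows(self):
        assert data_cleaning_report([False] * 10).ignored_percentage == 0.0

    def test_cleaning_matches_brute_force(self):
        flags = [i % 7 == 0 for i in range(200)]
        report = data_cleaning_report(flags)
        assert report.ignored == sum(flags)
        assert report.retained == 200 - sum(flags)
        assert report.ignored_percentage == pytest.approx(100 * sum(flags) / 200)

    def test_profiles_from_graph_uses_flag_and_edges(self):
        g, org = org_with_followers([(1, 0), (2, 0)])
        (derived,) = profiles_from_graph(g)
        assert derived.follower_ids == org.follower_ids
        assert derived.org_id == "org"
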