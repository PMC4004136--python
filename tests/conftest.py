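"""Shared fixtures: small hand-enumerable graphs and a four-organization
network shaped like the study population (printed totals used as inputs)."""

from __future__ import annotations

import pytest

from disseminet.cascade_propagation import RetweetRecord
from disseminet.dissemination_metrics import OrganizationProfile
from disseminet.network_model import Account, FollowGraph
from disseminet.synthetic_data import make_star, spread_total

# The four-organization study population, used as *input*: follower-set
# sizes, dissemination potentials, per-org zero-tweeter counts, top-tweet
# retweeter counts and their combined audiences, as printed in the source
# tables.  Order: AAFP, ACP, AAP, AMA.
STUDY_ORGS = [
    dict(org_id="AAFP", followers=7546, potential=6_959_092, zero_tweeters=522,
         retweeters=10, retweet_audience=9558, tweets=2788),
    dict(org_id="ACP", followers=5955, potential=11_228_160, zero_tweeters=430,
         retweeters=7, retweet_audience=489, tweets=2979),
    dict(org_id="AAP", followers=11_768, potential=14_496_559, zero_tweeters=962,
         retweeters=25, retweet_audience=25_482, tweets=1184),
    dict(org_id="AMA", followers=213_122, potential=122_066_397, zero_tweeters=39_275,
         retweeters=45, retweet_audience=200_778, tweets=7065,
         quiet_listeners=119_560),  # followers with fewer than 50 listeners
]


def build_study_network() -> tuple[FollowGraph, list[OrganizationProfile], list[RetweetRecord]]:
    """One graph holding all four organizations, with follower attributes
    arranged so every printed total is realized exactly:

    * declared follower counts per org sum to potential - followers,
    * the designated retweeters' counts sum to the printed retweet audience,
    * exactly the printed number of followers have tweet_count 0,
    * for the largest org, exactly the printed number of followers have
      declared counts below 50 and the rest at least 50.
    """
    graph = FollowGraph()
    profiles: list[OrganizationProfile] = []
    records: list[RetweetRecord] = []
    for org in STUDY_ORGS:
        org_id = org["org_id"]
        n = org["followers"]
        level2_total = org["potential"] - n
        quiet = org.get("quiet_listeners", 0)
        n_rt = org["retweeters"]

        declared = [0] * n
        # retweeters first: their counts must sum to the printed audience
        declared[:n_rt] = spread_total(org["retweet_audience"], n_rt)
        if quiet:
            # quiet followers get counts < 50; the rest absorb the remainder
            declared[n - quiet:] = [10] * quiet
            loud_rest = n - quiet - n_rt
            declared[n_rt:n - quiet] = spread_total(
                level2_total - org["retweet_audience"] - 10 * quiet, loud_rest
            )
        else:
            declared[n_rt:] = spread_total(level2_total - org["retweet_audience"], n - n_rt)
        # zero-tweeters at the tail (never the retweeters)
        tweet_counts = [1] * n
        tweet_counts[n - org["zero_tweeters"]:] = [0] * org["zero_tweeters"]

        graph.add_account(
            Account(org_id, declared_follower_count=n, tweet_count=org["tweets"],
                    is_organization=True)
        )
        follower_ids = []
        for i, (d, t) in enumerate(zip(declared, tweet_counts)):
            fid = f"{org_id}_f{i:06d}"
            graph.add_account(Account(fid, declared_follower_count=d, tweet_count=t))
            follower_ids.append(fid)
        for fid in follower_ids:
            graph.add_edge(org_id, fid)
        profiles.append(
            OrganizationProfile(org_id, frozenset(follower_ids), frozenset(), org["tweets"])
        )
        records.append(
            RetweetRecord(f"{org_id}_top_tweet", org_id, frozenset(follower_ids[:n_rt]))
        )
    return graph, profiles, records


@pytest.fixture(scope="session")
def study_network():
    return build_study_network()


@pytest.fixture
def star9() -> FollowGraph:
    return make_star(9)


@pytest.fixture
def path4() -> FollowGraph:
    g = FollowGraph(Account(i) for i in "abcd")
    for u, v in [("a", "b"), ("b", "c"), ("c", "d")]:
        g.add_edge(u, v)
    return g


@pytest.fixture
def triangle() -> FollowGraph:
    g = FollowGraph(Account(i) for i in "abc")
    for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
        g.add_edge(u, v)
    return g
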