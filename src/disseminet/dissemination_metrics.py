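"""Audience-size metrics, overlap analysis, distributions and activity pruning.

The central quantity is the *dissemination potential* of an organization:
its follower count plus the sum of its followers' declared follower counts
(the "Level-2" audience).  The metric is deliberately theoretical — it
assumes every follower retweets once and that no two followers share an
audience — so no deduplication is applied; an exact unique-reach variant
computed on the structural graph is exposed separately as
:func:`unique_two_hop_reach`.

Level-2 sums consume *declared* follower counts, never structural
out-degrees: the follower graph of a study is a sample while the counts the
platform reports are global.  A structural mode is available behind an
explicit flag.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

from .network_model import FollowGraph, GraphDomainError

__all__ = [
    "OrganizationProfile",
    "DisseminationReport",
    "PruneResult",
    "CleaningReport",
    "MembershipBreakdown",
    "level2_follower_sum",
    "dissemination_potential",
    "unique_two_hop_reach",
    "overlap_percentage",
    "multi_group_membership",
    "follower_cdf",
    "cdf_value",
    "activity_histogram",
    "prune_inactive",
    "characterize",
    "data_cleaning_report",
    "profiles_from_graph",
]


@dataclass(frozen=True)
class OrganizationProfile:
    """An organization account with its follower and following sets."""

    org_id: str
    follower_ids: frozenset[str]
    following_ids: frozenset[str] = frozenset()
    tweet_count: int = 0

    def __post_init__(self) -> None:
        if self.org_id in self.follower_ids:
            raise ValueError("an organization cannot follow itself")
        if self.tweet_count < 0:
            raise ValueError("tweet_count must be >= 0")

    @property
    def follower_count(self) -> int:
        return len(self.follower_ids)


@dataclass(frozen=True)
class PruneResult:
    """Outcome of removing low-activity followers from the potential."""

    threshold: int | None
    pruned_potential: int
    percent_reduction: float | None  # None when the original potential is 0
    removed_followers: int

    @property
    def defined(self) -> bool:
        return self.percent_reduction is not None


@dataclass(frozen=True)
class DisseminationReport:
    """Per-organization audience report, one row of a characterization table."""

    org_id: str
    follower_count: int
    level2_sum: int
    potential: int
    pruned_potentials: dict[int | None, PruneResult]


@dataclass(frozen=True)
class CleaningReport:
    """Tally of raw account rows retained vs ignored during ingestion."""

    retained: int
    ignored: int

    @property
    def total(self) -> int:
        return self.retained + self.ignored

    @property
    def ignored_percentage(self) -> float:
        if self.total == 0:
            return 0.0
        return 100.0 * self.ignored / self.total


@dataclass(frozen=True)
class MembershipBreakdown:
    """How many accounts follow exactly k of the organizations."""

    counts_by_k: dict[int, int]
    full_intersection: frozenset[str]

    @property
    def union_size(self) -> int:
        return sum(self.counts_by_k.values())


def level2_follower_sum(graph: FollowGraph, org: OrganizationProfile, *, structural: bool = False) -> int:
    """Total audience of the organization's followers.

    Sum over followers of their declared follower counts, with no
    deduplication across followers (the metric is defined under the
    assumption that followers' audiences are disjoint).  With
    ``structural=True`` the in-graph out-degree is summed instead.
    """
    if structural:
        return sum(graph.structural_follower_count(f) for f in org.follower_ids)
    return sum(graph.declared_follower_count(f) for f in org.follower_ids)


def dissemination_potential(graph: FollowGraph, org: OrganizationProfile, *, structural: bool = False) -> int:
    """Followers plus Level-2 followers: the audience if every follower
    retweeted once and no audiences overlapped."""
    return org.follower_count + level2_follower_sum(graph, org, structural=structural)


def unique_two_hop_reach(graph: FollowGraph, org: OrganizationProfile) -> int:
    """Exact de-duplicated two-hop audience on the structural graph.

    Size of the union of the followers and the followers-of-followers,
    excluding the organization itself.  Use this when the no-shared-audience
    assumption behind the potential must be dropped; it requires the
    Level-2 accounts to actually be present in the sampled graph.
    """
    reach: set[str] = set(org.follower_ids)
    for f in org.follower_ids:
        reach |= graph.followers_of(f)
    reach.discard(org.org_id)
    return len(reach)


def overlap_percentage(followers_a: Iterable[str], followers_b: Iterable[str]) -> float:
    """Follower overlap of two groups: |A ∩ B| / min(|A|, |B|) × 100."""
    a, b = set(followers_a), set(followers_b)
    if not a or not b:
        raise GraphDomainError("overlap percentage undefined for an empty follower set")
    return 100.0 * len(a & b) / min(len(a), len(b))


def multi_group_membership(profiles: Sequence[OrganizationProfile]) -> MembershipBreakdown:
    """Break the union of follower sets down by how many groups each
    account follows, plus the all-groups intersection."""
    if len(profiles) < 2:
        raise GraphDomainError("need at least 2 organization profiles")
    if len({p.org_id for p in profiles}) != len(profiles):
        raise ValueError("duplicate organization ids")
    membership: Counter[str] = Counter()
    for p in profiles:
        membership.update(p.follower_ids)
    counts = Counter(membership.values())
    intersection = frozenset.intersection(*(p.follower_ids for p in profiles))
    return MembershipBreakdown(dict(sorted(counts.items())), intersection)


def follower_cdf(graph: FollowGraph, org: OrganizationProfile) -> list[tuple[int, float]]:
    """Cumulative distribution of the followers' declared follower counts.

    Returns the right-continuous step function as (count threshold,
    cumulative fraction) pairs at each distinct count; the final fraction
    is 1.  Suitable for plotting on a log x-axis.
    """
    if not org.follower_ids:
        raise GraphDomainError("follower CDF undefined for an org with no followers")
    counts = sorted(graph.declared_follower_count(f) for f in org.follower_ids)
    n = len(counts)
    points: list[tuple[int, float]] = []
    seen = 0
    for value in counts:
        seen += 1
        if points and points[-1][0] == value:
            points[-1] = (value, seen / n)
        else:
            points.append((value, seen / n))
    return points


def cdf_value(points: Sequence[tuple[int, float]], threshold: int) -> float:
    """Evaluate a right-continuous step CDF: fraction with count <= threshold."""
    best = 0.0
    for value, frac in points:
        if value <= threshold:
            best = frac
        else:
            break
    return best


def activity_histogram(
    graph: FollowGraph, org: OrganizationProfile, log_bins: bool = False
) -> dict[int, float]:
    """Fraction of followers per tweet-volume bin; bin 0 isolates exactly
    the followers who have never tweeted.

    With ``log_bins`` positive volumes are grouped by decade (bin key =
    lower bound 1, 10, 100, ...); otherwise each distinct volume is its
    own bin.  Fractions sum to 1.
    """
    if not org.follower_ids:
        raise GraphDomainError("activity histogram undefined for an org with no followers")
    n = len(org.follower_ids)
    bins: Counter[int] = Counter()
    for f in org.follower_ids:
        volume = graph.account(f).tweet_count
        if volume == 0:
            bins[0] += 1
        elif log_bins:
            bins[10 ** len(str(volume)) // 10] += 1
        else:
            bins[volume] += 1
    return {key: bins[key] / n for key in sorted(bins)}


def prune_inactive(
    graph: FollowGraph, org: OrganizationProfile, max_tweets: int | None
) -> PruneResult:
    """Remove low-activity followers and their Level-2 mass from the potential.

    Followers with ``tweet_count <= max_tweets`` are dropped together with
    their declared audiences; ``max_tweets=None`` prunes nothing.  The
    reduction is reported as a percentage of the original potential
    (``None``-flagged when the original potential is 0).
    """
    original = dissemination_potential(graph, org)
    if max_tweets is None:
        kept = org.follower_ids
    else:
        if max_tweets < 0:
            raise GraphDomainError("max_tweets must be >= 0 or None")
        kept = frozenset(
            f for f in org.follower_ids if graph.account(f).tweet_count > max_tweets
        )
    pruned_org = OrganizationProfile(org.org_id, kept, org.following_ids, org.tweet_count)
    pruned = dissemination_potential(graph, pruned_org)
    removed = org.follower_count - len(kept)
    if original == 0:
        return PruneResult(max_tweets, pruned, None, removed)
    return PruneResult(max_tweets, pruned, 100.0 * (1.0 - pruned / original), removed)


def characterize(
    graph: FollowGraph,
    org: OrganizationProfile,
    thresholds: Sequence[int | None] = (None, 0, 10),
) -> DisseminationReport:
    """Full audience report for one organization, including a pruning sweep."""
    level2 = level2_follower_sum(graph, org)
    return DisseminationReport(
        org_id=org.org_id,
        follower_count=org.follower_count,
        level2_sum=level2,
        potential=org.follower_count + level2,
        pruned_potentials={t: prune_inactive(graph, org, t) for t in thresholds},
    )


def data_cleaning_report(ignored_flags: Iterable[bool]) -> CleaningReport:
    """Tally raw account rows: True marks a row that was ignored
    (disabled, private, or unrecognizable)."""
    ignored = 0
    retained = 0
    for flag in ignored_flags:
        if flag:
            ignored += 1
        else:
            retained += 1
    return CleaningReport(retained=retained, ignored=ignored)


def profiles_from_graph(graph: FollowGraph) -> list[OrganizationProfile]:
    """Derive OrganizationProfiles for every account flagged as an
    organization: followers are out-neighbors, following are in-neighbors."""
    profiles = []
    for account in graph.accounts():
        if account.is_organization:
            profiles.append(
                OrganizationProfile(
                    org_id=account.id,
                    follower_ids=graph.followers_of(account.id),
                    following_ids=graph.following_of(account.id),
                    tweet_count=account.tweet_count,
                )
            )
    return profiles
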