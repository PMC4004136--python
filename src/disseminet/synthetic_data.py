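"""Generators for reference topologies and Twitter-like multi-organization fixtures.

Three classic topology classes — star, Erdős–Rényi random, and power-law
(small-world-like) — plus :func:`make_twitter_fixture`, which emulates the
structure the downstream analysis assumes: a handful of organization
accounts, each with a follower set of configured size, configurable
pairwise follower overlap between organizations, heavy-tailed declared
follower counts among the followers, and zero-inflated heavy-tailed tweet
activity.

All randomness flows through one ``numpy`` generator seeded explicitly;
identical seed and config yield byte-identical edge lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_model import Account, FollowGraph, GraphDomainError
from .dissemination_metrics import OrganizationProfile

__all__ = [
    "FollowerDegreeLaw",
    "ActivityLaw",
    "FixtureConfig",
    "FixtureConfigError",
    "spread_total",
    "make_star",
    "make_random",
    "make_power_law",
    "make_twitter_fixture",
]


class FixtureConfigError(ValueError):
    """Raised when a fixture configuration is internally inconsistent."""


@dataclass(frozen=True)
class FollowerDegreeLaw:
    """Distribution of declared follower counts among an org's followers.

    ``power_law`` draws a continuous Pareto tail (exponent ``exponent``)
    and rounds; ``lognormal`` draws a discrete lognormal with shape
    ``sigma``.  When ``target_median`` is set the scale is solved so the
    population median lands there (Pareto median = xmin * 2^(1/(alpha-1))).
    """

    family: str = "power_law"
    exponent: float = 2.1
    minimum: int = 1
    target_median: int | None = 120
    sigma: float = 1.2

    def __post_init__(self) -> None:
        if self.family not in ("power_law", "lognormal"):
            raise FixtureConfigError(f"unknown degree-law family {self.family!r}")
        if self.family == "power_law" and self.exponent <= 1:
            raise FixtureConfigError("power-law exponent must exceed 1")
        if self.minimum < 0:
            raise FixtureConfigError("minimum must be >= 0")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "power_law":
            xmin = float(max(self.minimum, 1))
            if self.target_median is not None:
                xmin = max(xmin, self.target_median / 2.0 ** (1.0 / (self.exponent - 1.0)))
            u = rng.random(size)
            values = np.rint(xmin * (1.0 - u) ** (-1.0 / (self.exponent - 1.0)))
        else:
            median = float(self.target_median if self.target_median is not None else 100)
            values = np.rint(rng.lognormal(mean=np.log(max(median, 1.0)), sigma=self.sigma, size=size))
        return np.maximum(values, self.minimum).astype(np.int64)


@dataclass(frozen=True)
class ActivityLaw:
    """Zero-inflated discrete lognormal for per-follower tweet volume.

    A fraction ``zero_fraction`` of followers never tweeted; the rest draw
    a lognormal (median ``median``, shape ``sigma``) rounded up to >= 1.
    """

    zero_fraction: float = 0.07
    median: float = 50.0
    sigma: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise FixtureConfigError("zero_fraction must lie in [0, 1]")
        if self.median <= 0 or self.sigma <= 0:
            raise FixtureConfigError("median and sigma must be positive")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        zeros = rng.random(size) < self.zero_fraction
        positive = np.maximum(
            np.rint(rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=size)), 1
        )
        return np.where(zeros, 0, positive).astype(np.int64)


# Defaults mirror the four-organization study population: follower-set
# sizes and org tweet volumes from the characterization table (AAFP, ACP,
# AAP, AMA order), per-org zero-activity masses from the activity
# histograms, listener-count medians 120/165/81 for the three smaller
# groups and a sub-50 median for the largest (whose majority of followers
# have fewer than 50 listeners).
_DEFAULT_SIZES = (7546, 5955, 11768, 213122)
_DEFAULT_ZERO_FRACTIONS = (0.0692, 0.0722, 0.0817, 0.1843)
_DEFAULT_MEDIANS = (120, 165, 81, 35)
_DEFAULT_ORG_TWEETS = (2788, 2979, 1184, 7065)
_DEFAULT_OVERLAP = 0.25


def _default_degree_laws() -> tuple[FollowerDegreeLaw, ...]:
    return tuple(FollowerDegreeLaw(target_median=m) for m in _DEFAULT_MEDIANS)


def _default_activity_laws() -> tuple[ActivityLaw, ...]:
    return tuple(ActivityLaw(zero_fraction=z) for z in _DEFAULT_ZERO_FRACTIONS)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of a multi-organization follower-network fixture.

    ``pairwise_overlap_fraction`` may be a single float (applied to every
    org pair) or a full symmetric matrix; the realized intersection of
    groups i and j is ``round(f_ij * min(|F_i|, |F_j|))`` accounts shared
    exactly, so the requested overlap is met to rounding.
    """

    n_orgs: int = 4
    followers_per_org: tuple[int, ...] = _DEFAULT_SIZES
    pairwise_overlap_fraction: float | tuple[tuple[float, ...], ...] = _DEFAULT_OVERLAP
    follower_degree_laws: tuple[FollowerDegreeLaw, ...] = field(default_factory=_default_degree_laws)
    activity_laws: tuple[ActivityLaw, ...] = field(default_factory=_default_activity_laws)
    org_tweet_counts: tuple[int, ...] = _DEFAULT_ORG_TWEETS
    seed: int = 0

    def overlap_matrix(self) -> np.ndarray:
        k = self.n_orgs
        f = self.pairwise_overlap_fraction
        if isinstance(f, (int, float)):
            mat = np.full((k, k), float(f))
        else:
            mat = np.asarray(f, dtype=float)
        np.fill_diagonal(mat, 0.0)
        return mat

    def validate(self) -> None:
        k = self.n_orgs
        if k < 1:
            raise FixtureConfigError("n_orgs must be >= 1")
        for name, seq in (
            ("followers_per_org", self.followers_per_org),
            ("follower_degree_laws", self.follower_degree_laws),
            ("activity_laws", self.activity_laws),
            ("org_tweet_counts", self.org_tweet_counts),
        ):
            if len(seq) != k:
                raise FixtureConfigError(f"{name} must have length n_orgs={k}, got {len(seq)}")
        if any(n < 1 for n in self.followers_per_org):
            raise FixtureConfigError("every follower-set size must be >= 1")
        mat = self.overlap_matrix()
        if mat.shape != (k, k):
            raise FixtureConfigError(f"overlap matrix must be {k}x{k}")
        if not np.allclose(mat, mat.T):
            raise FixtureConfigError("overlap matrix must be symmetric")
        if ((mat < 0) | (mat > 1)).any():
            raise FixtureConfigError("overlap fractions must lie in [0, 1]")
        # pair-shared accounts must fit inside each group
        for i in range(k):
            demand = sum(
                round(mat[i, j] * min(self.followers_per_org[i], self.followers_per_org[j]))
                for j in range(k)
                if j != i
            )
            if demand > self.followers_per_org[i]:
                raise FixtureConfigError(
                    f"requested overlaps for org {i} demand {demand} shared followers, "
                    f"but the group only has {self.followers_per_org[i]}"
                )


def spread_total(total: int, n: int) -> list[int]:
    """Split ``total`` into ``n`` non-negative integers as evenly as
    possible (first ``total % n`` parts get the extra unit).  Handy for
    building follower populations whose counts must sum to an exact
    published total."""
    if n < 1:
        raise GraphDomainError("n must be >= 1")
    if total < 0:
        raise GraphDomainError("total must be >= 0")
    base, rem = divmod(total, n)
    return [base + 1] * rem + [base] * (n - rem)


def make_star(n: int) -> FollowGraph:
    """Star topology: node ``s0`` broadcasts to ``n - 1`` leaves.

    The center's message reaches everyone in one hop with no redundancy; a
    leaf's message reaches nobody.
    """
    if n < 2:
        raise GraphDomainError("a star needs at least 2 nodes")
    ids = [f"s{i}" for i in range(n)]
    graph = FollowGraph(Account(i) for i in ids)
    for leaf in ids[1:]:
        graph.add_edge(ids[0], leaf)
    return graph


def make_random(n: int, mean_degree: float, seed: int) -> FollowGraph:
    """Directed Erdős–Rényi graph G(n, p) with p = mean_degree / (n - 1).

    Out- (and in-) degrees are Binomial(n-1, p), i.e. approximately normal
    around the mean — no hubs, dissemination power concentrated at the
    mean.
    """
    if not 0 < mean_degree < n - 1:
        raise GraphDomainError("mean_degree must lie strictly between 0 and n-1")
    p = mean_degree / (n - 1)
    rng = np.random.default_rng(seed)
    ids = [f"r{i}" for i in range(n)]
    graph = FollowGraph(Account(i) for i in ids)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    for u, v in zip(*np.nonzero(mask)):
        graph.add_edge(ids[u], ids[v])
    return graph


def _power_law_degrees(n: int, exponent: float, min_degree: int, rng: np.random.Generator) -> np.ndarray:
    # exact inverse-CDF draw from the discrete power law P(k) ∝ k^-exponent,
    # truncated to the feasible degree range [min_degree, n-1]
    ks = np.arange(min_degree, n, dtype=np.float64)
    pmf = ks**-exponent
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    return (min_degree + np.searchsorted(cdf, rng.random(n), side="right")).astype(np.int64)


def make_power_law(n: int, exponent: float = 2.3, min_degree: int = 1, seed: int = 0) -> FollowGraph:
    """Scale-free graph: power-law out-degrees, uniformly chosen targets.

    Each node draws an audience size from a discrete power law
    (P(k) ∝ k^-exponent, k >= min_degree, capped at n-1) and is wired to
    that many distinct uniformly random targets, configuration-model
    style.  Out-degrees match the drawn sequence exactly, so a
    maximum-likelihood fit of the realized out-degrees recovers the
    exponent; in-degrees are approximately Poisson.  The undirected
    projection has the low, slowly growing diameter characteristic of
    small-world networks.
    """
    if n < 2:
        raise GraphDomainError("need at least 2 nodes")
    if exponent <= 1:
        raise GraphDomainError("exponent must exceed 1")
    if min_degree < 1:
        raise GraphDomainError("min_degree must be >= 1")
    rng = np.random.default_rng(seed)
    degrees = _power_law_degrees(n, exponent, min_degree, rng)
    ids = [f"p{i}" for i in range(n)]
    graph = FollowGraph(Account(i, declared_follower_count=int(d)) for i, d in zip(ids, degrees))
    all_idx = np.arange(n)
    for i, d in enumerate(degrees):
        if d == 0:
            continue
        targets = rng.choice(n - 1, size=int(d), replace=False)
        targets = np.where(targets >= i, targets + 1, targets)  # skip self
        for t in np.sort(targets):
            graph.add_edge(ids[i], ids[int(all_idx[t])])
    return graph


def make_twitter_fixture(config: FixtureConfig) -> tuple[FollowGraph, list[OrganizationProfile]]:
    """Build a multi-organization follower network per ``config``.

    Pairwise overlap is realized by minting a dedicated pool of shared
    followers for each org pair before filling each group with its own
    specific followers — simple and exactly auditable.  Every follower
    carries a declared follower count drawn from its (first-owning) org's
    degree law and a tweet count from that org's activity law; Level-2
    audiences exist only as declared counts, not as graph nodes, matching
    how the metrics consume them.
    """
    config.validate()
    k = config.n_orgs
    rng = np.random.default_rng(config.seed)
    mat = config.overlap_matrix()
    sizes = config.followers_per_org

    org_ids = [f"org{i}" for i in range(k)]
    member_sets: list[set[str]] = [set() for _ in range(k)]
    owner_of: dict[str, int] = {}  # first org that minted the follower
    serial = 0

    def mint(owner: int) -> str:
        nonlocal serial
        fid = f"u{serial:07d}"
        serial += 1
        owner_of[fid] = owner
        return fid

    for i in range(k):
        for j in range(i + 1, k):
            shared = round(mat[i, j] * min(sizes[i], sizes[j]))
            for _ in range(shared):
                fid = mint(i)
                member_sets[i].add(fid)
                member_sets[j].add(fid)
    for i in range(k):
        while len(member_sets[i]) < sizes[i]:
            member_sets[i].add(mint(i))

    follower_ids = sorted(owner_of)
    owners = np.array([owner_of[f] for f in follower_ids])
    declared = np.empty(len(follower_ids), dtype=np.int64)
    tweets = np.empty(len(follower_ids), dtype=np.int64)
    for i in range(k):
        idx = np.nonzero(owners == i)[0]
        declared[idx] = config.follower_degree_laws[i].sample(rng, idx.size)
        tweets[idx] = config.activity_laws[i].sample(rng, idx.size)

    graph = FollowGraph()
    for i, org_id in enumerate(org_ids):
        graph.add_account(
            Account(
                org_id,
                declared_follower_count=sizes[i],
                tweet_count=config.org_tweet_counts[i],
                is_organization=True,
            )
        )
    for fid, d, t in zip(follower_ids, declared, tweets):
        graph.add_account(Account(fid, declared_follower_count=int(d), tweet_count=int(t)))
    profiles = []
    for i, org_id in enumerate(org_ids):
        for fid in sorted(member_sets[i]):
            graph.add_edge(org_id, fid)
        profiles.append(
            OrganizationProfile(
                org_id=org_id,
                follower_ids=frozenset(member_sets[i]),
                following_ids=frozenset(),
                tweet_count=config.org_tweet_counts[i],
            )
        )
    return graph, profiles
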