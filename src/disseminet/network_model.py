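"""Directed follower-graph data model and structural statistics.

The graph convention throughout this package is *information flow*: an edge
``u -> v`` means v follows u, so a message posted by u is seen by v.  The
"follows" relation is the edge reversal.  Two follower counts coexist and are
never conflated: the *structural* count (out-degree inside the sampled graph)
and the *declared* count (the account's global follower total as reported by
the platform, which routinely exceeds what a sampled subgraph contains).
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Iterator
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "Account",
    "FollowGraph",
    "GroupCohesion",
    "UnknownAccountError",
    "GraphDomainError",
    "followers_of",
    "following_of",
    "degree_distribution",
    "diameter",
    "local_clustering",
    "group_cohesion",
    "pairwise_jaccard",
]


class UnknownAccountError(KeyError):
    """Raised when an operation references an account id not in the graph."""


class GraphDomainError(ValueError):
    """Raised when an operation's preconditions on the graph are violated."""


@dataclass(frozen=True)
class Account:
    """One account: opaque id plus the attributes the metrics consume.

    ``declared_follower_count`` is the platform-reported global follower
    total; it may exceed the account's out-degree in a sampled graph.
    """

    id: str
    declared_follower_count: int = 0
    tweet_count: int = 0
    is_organization: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.id, str) or not self.id:
            raise ValueError("account id must be a non-empty string")
        if self.declared_follower_count < 0:
            raise ValueError("declared_follower_count must be >= 0")
        if self.tweet_count < 0:
            raise ValueError("tweet_count must be >= 0")


@dataclass(frozen=True)
class GroupCohesion:
    """Cohesion of a set of accounts: shared audience over total audience.

    ``cohesion`` is ``common_neighbors / total_neighbors`` on the undirected
    projection, members excluded from their own neighbor sets.  When the
    group has no neighbors at all the ratio is undefined and ``cohesion``
    is ``None`` (exposed via :attr:`defined`).
    """

    member_ids: frozenset[str]
    common_neighbors: int
    total_neighbors: int
    cohesion: float | None

    @property
    def defined(self) -> bool:
        return self.cohesion is not None


class FollowGraph:
    """Directed graph of accounts; edges point along information flow.

    Thin wrapper over a :class:`networkx.DiGraph` that enforces account
    registration, forbids self-loops, and stores one :class:`Account`
    record per node.
    """

    def __init__(self, accounts: Iterable[Account] = (), edges: Iterable[tuple[str, str]] = ()):
        self._g = nx.DiGraph()
        self._accounts: dict[str, Account] = {}
        for account in accounts:
            self.add_account(account)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -----------------------------------------------------

    def add_account(self, account: Account) -> None:
        if account.id in self._accounts:
            raise ValueError(f"duplicate account id: {account.id!r}")
        self._accounts[account.id] = account
        self._g.add_node(account.id)

    def replace_account(self, account: Account) -> None:
        """Overwrite the attribute record of an already-registered account."""
        self._require(account.id)
        self._accounts[account.id] = account

    def add_edge(self, u: str, v: str) -> None:
        self._require(u)
        self._require(v)
        if u == v:
            raise GraphDomainError(f"self-loop forbidden: {u!r}")
        self._g.add_edge(u, v)

    # -- accessors --------------------------------------------------------

    def _require(self, account_id: str) -> None:
        if account_id not in self._accounts:
            raise UnknownAccountError(account_id)

    def account(self, account_id: str) -> Account:
        self._require(account_id)
        return self._accounts[account_id]

    def has_account(self, account_id: str) -> bool:
        return account_id in self._accounts

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def account_ids(self) -> list[str]:
        return sorted(self._accounts)

    def accounts(self) -> Iterator[Account]:
        for account_id in sorted(self._accounts):
            yield self._accounts[account_id]

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges())

    @property
    def n_accounts(self) -> int:
        return len(self._accounts)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def followers_of(self, account_id: str) -> frozenset[str]:
        """Accounts that receive ``account_id``'s messages (out-neighbors)."""
        self._require(account_id)
        return frozenset(self._g.successors(account_id))

    def following_of(self, account_id: str) -> frozenset[str]:
        """Accounts whose messages ``account_id`` receives (in-neighbors)."""
        self._require(account_id)
        return frozenset(self._g.predecessors(account_id))

    def structural_follower_count(self, account_id: str) -> int:
        """Follower count *inside this graph* (out-degree), as opposed to
        the account's declared global total."""
        self._require(account_id)
        return self._g.out_degree(account_id)

    def declared_follower_count(self, account_id: str) -> int:
        return self.account(account_id).declared_follower_count

    def out_degree(self, account_id: str) -> int:
        self._require(account_id)
        return self._g.out_degree(account_id)

    def in_degree(self, account_id: str) -> int:
        self._require(account_id)
        return self._g.in_degree(account_id)

    def undirected_neighbors(self, account_id: str) -> frozenset[str]:
        self._require(account_id)
        return frozenset(self._g.successors(account_id)) | frozenset(self._g.predecessors(account_id))

    def to_networkx(self) -> nx.DiGraph:
        """A copy of the underlying digraph (ids only, no attributes)."""
        return self._g.copy()

    def undirected_projection(self) -> nx.Graph:
        return self._g.to_undirected(as_view=False)

    def copy(self) -> "FollowGraph":
        return FollowGraph(self.accounts(), self._g.edges())


# -- operations -----------------------------------------------------------


def followers_of(graph: FollowGraph, account_id: str) -> frozenset[str]:
    """Out-neighbors of ``account_id`` under the information-flow convention."""
    return graph.followers_of(account_id)


def following_of(graph: FollowGraph, account_id: str) -> frozenset[str]:
    return graph.following_of(account_id)


def degree_distribution(graph: FollowGraph, mode: str = "out") -> dict[int, int]:
    """Histogram of node degrees.

    Parameters
    ----------
    mode:
        ``"out"`` (audience size), ``"in"`` (sources followed) or
        ``"total"``.

    The counts always sum to the number of accounts.
    """
    g = graph.to_networkx()
    if mode == "out":
        degrees = (d for _, d in g.out_degree())
    elif mode == "in":
        degrees = (d for _, d in g.in_degree())
    elif mode == "total":
        degrees = (d for _, d in g.degree())
    else:
        raise ValueError(f"mode must be 'in', 'out' or 'total', got {mode!r}")
    return dict(Counter(degrees))


def diameter(graph: FollowGraph, direction_respecting: bool = True, strict: bool = True) -> float:
    """Longest shortest-path length in the graph.

    In ``strict`` mode, any mutually unreachable pair yields ``math.inf``
    rather than being dropped; with ``strict=False`` the maximum is taken
    over finite distances only.  ``direction_respecting=False`` computes on
    the undirected projection.  Unweighted BFS throughout.
    """
    if graph.n_accounts == 0:
        raise GraphDomainError("diameter of an empty graph is undefined")
    g: nx.Graph | nx.DiGraph
    g = graph.to_networkx() if direction_respecting else graph.undirected_projection()
    if graph.n_accounts == 1:
        return 0
    if strict:
        connected = (
            nx.is_strongly_connected(g) if direction_respecting else nx.is_connected(g)
        )
        if not connected:
            return math.inf
        return nx.diameter(g)
    best = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        best = max(best, max(lengths.values()))
    return best


def local_clustering(graph: FollowGraph, account_id: str) -> float:
    """Triangle density around one node, on the undirected projection.

    Fraction of the node's neighbor pairs that are themselves connected;
    0 when the node has fewer than two neighbors.
    """
    graph.account(account_id)  # raises UnknownAccountError
    return nx.clustering(graph.undirected_projection(), account_id)


def _neighbor_sets(graph: FollowGraph, member_ids: frozenset[str]) -> list[frozenset[str]]:
    # members are excluded from their own neighbor sets to avoid
    # self-inflating the shared-audience count
    return [graph.undirected_neighbors(m) - member_ids for m in sorted(member_ids)]


def group_cohesion(graph: FollowGraph, member_ids: Iterable[str]) -> GroupCohesion:
    """Shared audience of a group divided by its total audience.

    ``common / total`` where *common* is the intersection and *total* the
    union of the members' undirected neighbor sets (members themselves
    excluded).  High cohesion means the group addresses one tightly shared
    audience; low cohesion means mostly disjoint audiences.
    """
    members = frozenset(member_ids)
    if len(members) < 2:
        raise GraphDomainError("group cohesion requires at least 2 members")
    sets = _neighbor_sets(graph, members)
    common = frozenset.intersection(*sets)
    total = frozenset.union(*sets)
    if not total:
        return GroupCohesion(members, 0, 0, None)
    return GroupCohesion(members, len(common), len(total), len(common) / len(total))


def pairwise_jaccard(graph: FollowGraph, u: str, v: str) -> float | None:
    """Jaccard index of two accounts' undirected neighbor sets (the
    alternative two-member reading of cohesion); ``None`` when both are
    isolated."""
    result = group_cohesion(graph, {u, v})
    return result.cohesion
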