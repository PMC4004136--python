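"""Per-tweet propagation measurement and diffusion simulation.

Two families of operations live here.  The measurement side turns retweet
records into *actual dissemination*: the combined declared audience of the
accounts that retweeted a message, compared against the theoretical
potential as a fraction.  The simulation side implements message flooding
(everyone forwards) and the independent cascade model: each newly informed
node forwards the message once, with one independent coin of fixed
probability p — the classic node-centric formulation.  Hop 1 is the
source's direct followers.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_model import FollowGraph, GraphDomainError

__all__ = [
    "RetweetRecord",
    "CascadeResult",
    "actual_dissemination",
    "unique_actual_dissemination",
    "fraction_of_potential",
    "retweet_distribution",
    "RetweetSummary",
    "flood_diffusion",
    "independent_cascade",
    "cascade_experiment",
]


@dataclass(frozen=True)
class RetweetRecord:
    """One tweet's propagation: origin organization and who retweeted it."""

    tweet_id: str
    org_id: str
    retweeter_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.org_id in self.retweeter_ids:
            raise ValueError("the origin organization cannot retweet its own tweet")

    @property
    def n_retweets(self) -> int:
        return len(self.retweeter_ids)


@dataclass(frozen=True)
class CascadeResult:
    """Outcome of one diffusion run from a single source.

    ``reached`` excludes the source; ``hop_of`` maps every reached node to
    its BFS level (direct followers are hop 1).  ``messages_sent`` counts
    one message per (sender, out-edge); ``redundant_receptions`` is the
    number of deliveries to reached nodes beyond each node's first.
    """

    source: str
    resend_probability: float
    reached: frozenset[str]
    hop_of: Mapping[str, int]
    messages_sent: int
    redundant_receptions: int
    seed: int | None = None

    @property
    def reach(self) -> int:
        return len(self.reached)

    @property
    def max_hop(self) -> int:
        return max(self.hop_of.values(), default=0)


@dataclass(frozen=True)
class RetweetSummary:
    """Descending retweet counts over a set of tweets, with summary fields."""

    sorted_counts: tuple[int, ...]
    max_retweets: int
    zero_retweet_tweets: int


def actual_dissemination(graph: FollowGraph, record: RetweetRecord) -> int:
    """Retweeter network size: sum of the retweeters' declared follower
    counts, without deduplicating audiences shared between retweeters.

    The origin organization's own first-hop audience and the retweeter
    count itself are not added; the metric measures the second-hop
    audience the retweets created.
    """
    return sum(graph.declared_follower_count(r) for r in record.retweeter_ids)


def unique_actual_dissemination(graph: FollowGraph, record: RetweetRecord) -> int:
    """De-duplicated variant on the structural graph: size of the union of
    the retweeters' follower sets (origin excluded)."""
    audience: set[str] = set()
    for r in record.retweeter_ids:
        audience |= graph.followers_of(r)
    audience.discard(record.org_id)
    return len(audience)


def fraction_of_potential(actual: int, potential: int) -> float:
    """How close actual dissemination came to the theoretical best."""
    if potential <= 0:
        raise GraphDomainError("potential must be positive")
    if actual < 0:
        raise ValueError("actual must be >= 0")
    return actual / potential


def retweet_distribution(records: Sequence[RetweetRecord]) -> RetweetSummary:
    """Per-tweet retweet counts sorted descending, with max and the number
    of tweets nobody retweeted."""
    counts = sorted((r.n_retweets for r in records), reverse=True)
    return RetweetSummary(
        sorted_counts=tuple(counts),
        max_retweets=counts[0] if counts else 0,
        zero_retweet_tweets=sum(1 for c in counts if c == 0),
    )


def _bfs_cascade(graph: FollowGraph, source: str, forwards) -> tuple[dict[str, int], int, int]:
    """Shared BFS core: ``forwards(node)`` decides whether a reached node
    resends.  Returns (hop_of, messages_sent, redundant_receptions)."""
    hop_of: dict[str, int] = {}
    messages_sent = graph.out_degree(source)
    receptions: dict[str, int] = {}
    queue: deque[str] = deque()
    for v in sorted(graph.followers_of(source)):
        hop_of[v] = 1
        receptions[v] = receptions.get(v, 0) + 1
        queue.append(v)
    while queue:
        node = queue.popleft()
        if not forwards(node):
            continue
        messages_sent += graph.out_degree(node)
        for v in sorted(graph.followers_of(node)):
            if v == source:
                continue
            receptions[v] = receptions.get(v, 0) + 1
            if v not in hop_of:
                hop_of[v] = hop_of[node] + 1
                queue.append(v)
    redundant = sum(c - 1 for c in receptions.values())
    return hop_of, messages_sent, redundant


def flood_diffusion(graph: FollowGraph, source: str) -> CascadeResult:
    """Deterministic flood: everyone who receives the message forwards it.

    Equivalent to the independent cascade at p = 1; hop_of is the BFS
    level from the source.
    """
    graph.account(source)
    hop_of, messages, redundant = _bfs_cascade(graph, source, lambda _: True)
    return CascadeResult(
        source=source,
        resend_probability=1.0,
        reached=frozenset(hop_of),
        hop_of=hop_of,
        messages_sent=messages,
        redundant_receptions=redundant,
    )


def independent_cascade(
    graph: FollowGraph,
    source: str,
    p: float,
    seed: int | None = None,
    node_uniforms: Mapping[str, float] | None = None,
) -> CascadeResult:
    """Independent cascade: each reached node forwards once with probability p.

    The source always sends.  Each other node holds a single uniform draw
    and forwards iff it falls below p, so runs sharing ``node_uniforms``
    (or a seed) are coupled across p: the reached set is monotone
    non-decreasing in p, and p = 1 reproduces :func:`flood_diffusion`
    exactly.  Either ``seed`` or an explicit ``node_uniforms`` map must
    make the run deterministic.
    """
    graph.account(source)
    if not 0.0 <= p <= 1.0:
        raise GraphDomainError("resend probability must lie in [0, 1]")
    if node_uniforms is None:
        rng = np.random.default_rng(seed)
        ids = [i for i in graph.account_ids() if i != source]
        node_uniforms = dict(zip(ids, rng.random(len(ids))))
    hop_of, messages, redundant = _bfs_cascade(
        graph, source, lambda node: node_uniforms.get(node, 1.0) < p or p == 1.0
    )
    return CascadeResult(
        source=source,
        resend_probability=p,
        reached=frozenset(hop_of),
        hop_of=hop_of,
        messages_sent=messages,
        redundant_receptions=redundant,
        seed=seed,
    )


def cascade_experiment(
    graph: FollowGraph,
    sources: Sequence[str],
    p_values: Sequence[float],
    reps: int,
    seed: int,
) -> pd.DataFrame:
    """Monte-Carlo grid of independent cascades.

    For each repetition one set of per-node uniforms is drawn and reused
    across the whole p grid (coupled coins), so mean reach is exactly
    monotone in p rep by rep.  Returns a tidy frame with columns
    source, p, mean_reach, sd_reach, mean_max_hop, sorted by (source, p).
    """
    if reps < 1:
        raise GraphDomainError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    ids = graph.account_ids()
    reach: dict[tuple[str, float], list[int]] = {
        (s, p): [] for s in sources for p in p_values
    }
    max_hop: dict[tuple[str, float], list[int]] = {
        (s, p): [] for s in sources for p in p_values
    }
    for _ in range(reps):
        uniforms = dict(zip(ids, rng.random(len(ids))))
        for s in sources:
            for p in p_values:
                result = independent_cascade(graph, s, p, node_uniforms=uniforms)
                reach[(s, p)].append(result.reach)
                max_hop[(s, p)].append(result.max_hop)
    rows = []
    for s in sorted(sources):
        for p in sorted(p_values):
            r = np.asarray(reach[(s, p)], dtype=float)
            rows.append(
                {
                    "source": s,
                    "p": p,
                    "mean_reach": r.mean(),
                    "sd_reach": r.std(ddof=1) if reps > 1 else 0.0,
                    "mean_max_hop": float(np.mean(max_hop[(s, p)])),
                }
            )
    return pd.DataFrame(rows, columns=["source", "p", "mean_reach", "sd_reach", "mean_max_hop"])
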