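"""Domain types and I/O for social graphs, messages, and retweet cascades.

The substrate of every analysis in this package is a directed follower
graph ``G = (V, E)`` together with per-user message timelines.  An edge
``(u, v)`` means *u follows v*: u perceives the messages that v posts or
retweets.  A *cascade* is the time-ordered set of users who adopted
(posted or retweeted) one root message; its *final size* ``n_inf`` is the
popularity the prediction models target, and its *observed prefix*
``C_m^t`` (adopters inside an observation window after the root post) is
what the models see as input.

File formats are deliberately plain text:

* edge list — ``follower<TAB>followee``, UTF-8, no header;
* messages — JSON lines with fields ``id, author, timestamp, text,
  retweet_of, covid_related``;
* cascades — ``root_id<TAB>user<TAB>timestamp``, grouped by root and
  sorted by timestamp within each root.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger("spillcast")

DEFAULT_MIN_CASCADE_SIZE = 3
DEFAULT_OBSERVATION_WINDOW = 3 * 3600.0  # seconds


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, reason: str):
        self.path, self.lineno = str(path), lineno
        super().__init__(f"{path}:{lineno}: {reason}")


# ---------------------------------------------------------------------------
# Social graph
# ---------------------------------------------------------------------------


class SocialGraph:
    """Directed follow relations, backed by a :class:`networkx.DiGraph`.

    Edge direction is follower → followee, so a user's *followees* are its
    out-neighbours and the messages it perceives come from them.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self._g = graph if graph is not None else nx.DiGraph()

    # construction ----------------------------------------------------------
    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> "SocialGraph":
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        n_self = 0
        for u, v in edges:
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
        if n_self:
            logger.warning("dropped %d self-loop edge(s)", n_self)
        return cls(g)

    def add_edge(self, follower: str, followee: str) -> None:
        if follower == followee:
            logger.warning("dropped self-loop edge %r", follower)
            return
        self._g.add_edge(follower, followee)

    # queries ---------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def followees(self, v: str) -> list[str]:
        """Out-neighbours of ``v`` — the users whose posts v perceives."""
        return list(self._g.successors(v))

    def followers(self, v: str) -> list[str]:
        return list(self._g.predecessors(v))

    def neighbors(self, v: str) -> list[str]:
        """N(v) for message passing: the followees of v (see module doc)."""
        return self.followees(v)

    def mutual_neighbors(self, v: str) -> list[str]:
        succ = set(self._g.successors(v))
        return [u for u in self._g.predecessors(v) if u in succ]

    def to_networkx(self) -> nx.DiGraph:
        return self._g


def read_social_graph(path: str | Path) -> SocialGraph:
    """Read a two-column tab-delimited edge list (follower first).

    Duplicate edges are deduplicated; self-loops are dropped with a
    warning.  A line with other than two fields raises :class:`ParseError`
    naming the line number.
    """
    g = nx.DiGraph()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ParseError(path, lineno, f"expected 'follower<TAB>followee', got {line!r}")
            u, v = parts
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
    if n_self:
        logger.warning("%s: dropped %d self-loop edge(s)", path, n_self)
    return SocialGraph(g)


def write_social_graph(graph: SocialGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Messages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Message:
    """One posted or retweeted message.

    ``retweet_of`` links a retweet to the id of the root message it
    relays; ``covid_related`` marks pandemic-related content, the split
    the feature builder keeps separate when summarising past messages.
    """

    id: str
    author: str
    timestamp: float
    text: str = ""
    retweet_of: str | None = None
    covid_related: bool = False

    def __post_init__(self):
        if not (self.timestamp == self.timestamp and abs(self.timestamp) != float("inf")):
            raise ValueError(f"message {self.id!r}: non-finite timestamp")


class MessageStore:
    """Messages indexed by id and by author, time-sorted per author."""

    def __init__(self, messages: Iterable[Message] = ()):
        self._by_id: dict[str, Message] = {}
        self._by_author: dict[str, list[Message]] = {}
        for m in messages:
            self.add(m)

    def add(self, m: Message) -> None:
        if m.id in self._by_id:
            raise ValueError(f"duplicate message id {m.id!r}")
        self._by_id[m.id] = m
        self._by_author.setdefault(m.author, []).append(m)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Message]:
        return iter(self._by_id.values())

    def __contains__(self, mid: str) -> bool:
        return mid in self._by_id

    def get(self, mid: str) -> Message:
        return self._by_id[mid]

    @property
    def authors(self) -> list[str]:
        return list(self._by_author)

    def by_author(self, author: str) -> list[Message]:
        """Messages of ``author`` sorted by timestamp (stable on ties)."""
        return sorted(self._by_author.get(author, []), key=lambda m: m.timestamp)

    def originals(self) -> list[Message]:
        return [m for m in self._by_id.values() if m.retweet_of is None]


def read_messages(path: str | Path) -> MessageStore:
    """Read JSON-lines message records."""
    store = MessageStore()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                rec = json.loads(raw)
                store.add(
                    Message(
                        id=str(rec["id"]),
                        author=str(rec["author"]),
                        timestamp=float(rec["timestamp"]),
                        text=rec.get("text", ""),
                        retweet_of=rec.get("retweet_of") or None,
                        covid_related=bool(int(rec.get("covid_related", 0))),
                    )
                )
            except (KeyError, ValueError, json.JSONDecodeError) as exc:
                raise ParseError(path, lineno, f"bad message record: {exc}") from exc
    return store


def write_messages(store: MessageStore, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in store:
            rec = {
                "id": m.id,
                "author": m.author,
                "timestamp": m.timestamp,
                "text": m.text,
                "retweet_of": m.retweet_of,
                "covid_related": int(m.covid_related),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Cascades
# ---------------------------------------------------------------------------


@dataclass
class Cascade:
    """Time-ordered adopters of one root message.

    The first adopter is the root author; every other entry is a user who
    retweeted the root.  ``final_size`` is the number of distinct
    adopters, the quantity popularity prediction targets.
    """

    root_message: str
    adopters: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        times = [t for _, t in self.adopters]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"cascade {self.root_message!r}: adopters not time-ordered")
        users = [u for u, _ in self.adopters]
        if len(set(users)) != len(users):
            raise ValueError(f"cascade {self.root_message!r}: duplicate adopters")

    @property
    def final_size(self) -> int:
        return len(self.adopters)

    @property
    def root_author(self) -> str:
        return self.adopters[0][0]

    @property
    def root_time(self) -> float:
        return self.adopters[0][1]

    def users(self) -> list[str]:
        return [u for u, _ in self.adopters]


@dataclass
class CascadeDiagnostics:
    """Bookkeeping from cascade construction."""

    n_roots: int = 0
    n_retweets: int = 0
    n_dangling: int = 0
    n_duplicate_adoptions: int = 0


def build_cascades(store: MessageStore) -> tuple[list[Cascade], CascadeDiagnostics]:
    """Group retweet records under their root messages.

    One cascade per original message; adopters are the root author plus
    every user with a retweet record of that root, ordered by timestamp.
    A user retweeting the same root twice is counted once at the earliest
    record.  Retweets whose root is missing from the store are skipped
    and counted in the diagnostics.
    """
    diag = CascadeDiagnostics()
    adoptions: dict[str, dict[str, float]] = {}
    roots: dict[str, Message] = {}
    for m in store:
        if m.retweet_of is None:
            roots[m.id] = m
            diag.n_roots += 1
    for m in store:
        if m.retweet_of is None:
            continue
        if m.retweet_of not in roots:
            diag.n_dangling += 1
            continue
        diag.n_retweets += 1
        slot = adoptions.setdefault(m.retweet_of, {})
        if m.author in slot:
            diag.n_duplicate_adoptions += 1
            slot[m.author] = min(slot[m.author], m.timestamp)
        else:
            slot[m.author] = m.timestamp
    if diag.n_dangling:
        logger.warning("build_cascades: skipped %d dangling retweet record(s)", diag.n_dangling)

    cascades = []
    for rid, root in roots.items():
        entries = [(root.author, root.timestamp)]
        extra = adoptions.get(rid, {})
        extra.pop(root.author, None)  # root author already adopted at post time
        entries.extend(sorted(extra.items(), key=lambda kv: (kv[1], kv[0])))
        cascades.append(Cascade(root_message=rid, adopters=entries))
    return cascades, diag


@dataclass
class FilterReport:
    """Retention bookkeeping of the minimum-size cascade filter."""

    n_input: int
    n_kept: int

    @property
    def retention(self) -> float:
        return self.n_kept / self.n_input if self.n_input else 1.0

    @property
    def retention_percent(self) -> float:
        return 100.0 * self.retention


def filter_min_size(
    cascades: Iterable[Cascade], min_size: int = DEFAULT_MIN_CASCADE_SIZE
) -> tuple[list[Cascade], FilterReport]:
    """Keep cascades with at least ``min_size`` adopters.

    Tiny cascades carry almost no signal for popularity prediction and
    are conventionally removed before training; the report records the
    retained fraction.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    cascades = list(cascades)
    kept = [c for c in cascades if c.final_size >= min_size]
    return kept, FilterReport(n_input=len(cascades), n_kept=len(kept))


def observe(cascade: Cascade, window: float = DEFAULT_OBSERVATION_WINDOW) -> Cascade:
    """Observed prefix C_m^t: adopters within ``window`` seconds of the root.

    The window is closed — an adoption at exactly root time + window is
    included.  ``window=0`` degenerates to the root author alone.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    cutoff = cascade.root_time + window
    prefix = [(u, t) for u, t in cascade.adopters if t <= cutoff]
    return Cascade(root_message=cascade.root_message, adopters=prefix)


def read_cascades(path: str | Path) -> list[Cascade]:
    """Read the tab-delimited cascade table (root_id, user, timestamp)."""
    groups: dict[str, list[tuple[str, float]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(path, lineno, f"expected 3 fields, got {len(parts)}")
            rid, user, ts = parts
            try:
                t = float(ts)
            except ValueError as exc:
                raise ParseError(path, lineno, f"bad timestamp {ts!r}") from exc
            if rid not in groups:
                groups[rid] = []
                order.append(rid)
            groups[rid].append((user, t))
    return [Cascade(root_message=rid, adopters=groups[rid]) for rid in order]


def write_cascades(cascades: Iterable[Cascade], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in cascades:
            for user, t in c.adopters:
                fh.write(f"{c.root_message}\t{user}\t{t!r}\n")
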