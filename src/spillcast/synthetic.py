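"""Synthetic social graphs, timelines, and spillover-driven cascades.

The generator emulates the kind of data the analysis modules expect —
a (mutualised) follower graph, per-user message timelines mixing
pandemic-related/unrelated and topical/background posts, and retweet
cascades — with a *planted* info-exposure spillover effect of known
size, so the whole pipeline can be validated end to end with ground
truth in hand.

Diffusion is a discrete-time independent-cascade process over follow
edges: when a followee of v adopts message m, v adopts with probability

    sigmoid(b0 + sum_T b1[T] * exposed_T(v))

for preventive-measure (PM) roots, and sigmoid(b0) for other roots.
``exposed_T(v)`` looks at the recent messages v perceives — its own and
each followee's last ``lambda_sim`` posts.  The logistic link is the
simplest mechanism that makes the spillover elasticity identifiable and
puts real signal into the message features the prediction models read:
topic keywords are observable in the text.

Topic vocabularies are drawn from the default lexicon and are disjoint
across topics, so keyword tagging is exact on synthetic data and model
behaviour is isolated from lexicon noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .graph_data import (
    Cascade,
    Message,
    MessageStore,
    SocialGraph,
    write_cascades,
    write_messages,
    write_social_graph,
)
from .spillover import (
    ANALYSIS_TOPICS,
    DEFAULT_LEXICON,
    TopicLexicon,
    classify_topics,
    compute_exposure,
    pm_adopters,
    spillover_report,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "simulate_graph",
    "simulate_timelines",
    "simulate_diffusion",
    "simulate",
    "recover_elasticity",
    "write_dataset",
]

BACKGROUND = "__background__"
COVID_TOPICS = ("PM", "U", "PB", "SC")  # pandemic-related message classes
SECONDS_PER_DAY = 86400.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic benchmark.

    Defaults define the standard benchmark: 2,000 users on a mutualised
    small-world substrate (near-constant degree, so exposure is close to
    exchangeable under the null and the planted effect is the only
    systematic signal), ~5 posts per user over a 30-day period with
    mostly background content, 3,000 cascades, and an exposure memory of
    the last 3 posts per perceived source.
    """

    n_users: int = 2000
    graph_model: str = "smallworld"  # smallworld | preferential | block
    graph_params: dict = field(default_factory=dict)
    mutual: bool = True
    topics: tuple[str, ...] = ANALYSIS_TOPICS
    rate: float = 5.0  # Poisson mean messages per user
    background_weight: float = 80.0  # prior mass of background vs 1 per topic
    pm_weight: float = 6.0  # prior mass of the PM category
    concentration: float = 3.0  # Dirichlet concentration of user preferences
    period_days: float = 30.0
    n_cascades: int = 3000
    pm_root_fraction: float = 0.2  # share of diffusion roots drawn from PM posts
    b0: float = -3.0  # base adoption logit (sigmoid ~ 0.05)
    b1: float | dict[str, float] = 1.0  # planted spillover coefficients
    lambda_sim: int = 3  # exposure memory per perceived source
    step_seconds: float = 3600.0  # diffusion time step
    seed: int = 0

    def b1_map(self) -> dict[str, float]:
        if isinstance(self.b1, dict):
            return {t: float(self.b1.get(t, 0.0)) for t in self.topics}
        return {t: float(self.b1) for t in self.topics}


@dataclass
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    b0: float
    b1: dict[str, float]
    message_topics: dict[str, str]  # message id -> category (incl. background)
    exposure: dict[str, set[str]]  # diffusion-time exposure sets per user
    final_sizes: dict[str, int]  # root id -> cascade final size


@dataclass
class SimData:
    """A complete simulated study: substrate, timelines, cascades, truth."""

    graph: SocialGraph
    store: MessageStore  # timeline posts only (no retweet records)
    cascades: list[Cascade]
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Graph
# ---------------------------------------------------------------------------


def _preferential_attachment(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Growth with preferential attachment; seed is a complete graph on m nodes.

    Bookkeeping: the seed contributes m(m-1)/2 edges and each of the
    n - m later nodes attaches m edges to distinct existing nodes.
    """
    if n < m + 1 or m < 1:
        raise ValueError("preferential attachment needs n > m >= 1")
    edges: list[tuple[int, int]] = [(i, j) for i in range(m) for j in range(i + 1, m)]
    repeated: list[int] = [v for e in edges for v in e] or list(range(m))
    for new in range(m, n):
        targets: set[int] = set()
        while len(targets) < m:
            pick = repeated[rng.integers(len(repeated))] if repeated else int(rng.integers(new))
            targets.add(pick)
        for t in targets:
            edges.append((new, t))
            repeated += [new, t]
    return edges


def simulate_graph(config: SimConfig) -> SocialGraph:
    """Directed follower graph from the configured generator.

    ``mutual=True`` (the default) emits both directions of every
    undirected edge, mirroring a mutual-follow crawl; otherwise each
    undirected edge gets a random orientation.
    """
    if config.n_users < 2:
        raise ValueError("need at least 2 users")
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    if config.graph_model == "preferential":
        m = int(config.graph_params.get("m", 2))
        und = _preferential_attachment(n, m, rng)
    elif config.graph_model == "smallworld":
        k = int(config.graph_params.get("k", 4))
        p = float(config.graph_params.get("p", 0.1))
        g = nx.watts_strogatz_graph(n, k, p, seed=int(rng.integers(2**31)))
        und = list(g.edges)
    elif config.graph_model == "block":
        sizes = config.graph_params.get("sizes", [n // 2, n - n // 2])
        probs = config.graph_params.get(
            "probs", [[0.01, 0.001], [0.001, 0.01]]
        )
        g = nx.stochastic_block_model(sizes, probs, seed=int(rng.integers(2**31)))
        und = list(g.edges)
    else:
        raise ValueError(f"unknown graph model {config.graph_model!r}")

    edges: list[tuple[str, str]] = []
    for a, b in und:
        u, v = f"u{a}", f"u{b}"
        if config.mutual:
            edges += [(u, v), (v, u)]
        else:
            edges.append((u, v) if rng.random() < 0.5 else (v, u))
    nodes = [f"u{i}" for i in range(n)]
    return SocialGraph.from_edges(edges, nodes=nodes)


# ---------------------------------------------------------------------------
# Timelines
# ---------------------------------------------------------------------------


def _topic_vocabularies(topics: tuple[str, ...]) -> dict[str, list[str]]:
    """Per-topic keyword vocabularies (disjoint across topics) + background.

    Background tokens contain digits, so they can never collide with the
    alphabetic lexicon keywords under substring matching.
    """
    vocab = {t: list(DEFAULT_LEXICON[t]) for t in ("PM",) + tuple(topics)}
    vocab[BACKGROUND] = [f"w{i}x{i % 7}" for i in range(50)]
    return vocab


def simulate_timelines(
    graph: SocialGraph,
    config: SimConfig,
    preferences: dict[str, np.ndarray] | None = None,
) -> tuple[MessageStore, dict[str, str]]:
    """Per-user message timelines with topical and background posts.

    Message counts are Poisson(``rate``); each message's category is
    drawn from the user's preference mixture (Dirichlet over PM, the
    analysis topics and a heavy background category, unless
    ``preferences`` overrides specific users); its text is sampled topic
    keywords plus background tokens; ``covid_related`` is set from the
    category.  Returns the store and the true per-message category.
    """
    rng = np.random.default_rng(config.seed + 1)
    cats = ("PM",) + tuple(config.topics) + (BACKGROUND,)
    vocab = _topic_vocabularies(config.topics)
    base = np.array(
        [config.pm_weight] + [1.0] * len(config.topics) + [config.background_weight]
    )
    alpha = config.concentration * base / base.sum()
    period = config.period_days * SECONDS_PER_DAY

    store = MessageStore()
    topics_true: dict[str, str] = {}
    for v in graph.nodes:
        pref = (preferences or {}).get(v)
        if pref is None:
            pref = rng.dirichlet(alpha)
        n_msgs = rng.poisson(config.rate)
        times = np.sort(rng.uniform(0, period, size=n_msgs))
        for j, t in enumerate(times):
            cat = cats[rng.choice(len(cats), p=pref)]
            words = []
            if cat != BACKGROUND:
                kws = vocab[cat]
                words += [kws[i] for i in rng.choice(len(kws), size=min(2, len(kws)), replace=False)]
            bg = vocab[BACKGROUND]
            words += [bg[i] for i in rng.choice(len(bg), size=3, replace=False)]
            mid = f"m-{v}-{j}"
            store.add(
                Message(
                    id=mid,
                    author=v,
                    timestamp=float(t),
                    text=" ".join(words),
                    covid_related=cat in COVID_TOPICS,
                )
            )
            topics_true[mid] = cat
    return store, topics_true


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------


def _diffusion_exposure(
    graph: SocialGraph,
    store: MessageStore,
    topics_true: dict[str, str],
    config: SimConfig,
) -> dict[str, set[str]]:
    """Topics among the last ``lambda_sim`` posts of each perceived source."""
    recent: dict[str, set[str]] = {}
    for v in graph.nodes:
        tl = store.by_author(v)[-config.lambda_sim :]
        recent[v] = {topics_true[m.id] for m in tl} & set(config.topics)
    out: dict[str, set[str]] = {}
    for v in graph.nodes:
        exposed = set(recent[v])
        for u in graph.followees(v):
            exposed |= recent[u]
        out[v] = exposed
    return out


def simulate_diffusion(
    graph: SocialGraph,
    store: MessageStore,
    topics_true: dict[str, str],
    config: SimConfig,
    adoption_prob: dict[str, float] | None = None,
) -> tuple[list[Cascade], SimTruth]:
    """Discrete-time independent-cascade diffusion with planted spillover.

    Roots are sampled from original posts, oversampling PM posts to
    ``pm_root_fraction``.  Each activation gives every follower of the
    adopter one independent chance to adopt, at probability
    sigmoid(b0 + sum_T b1[T] exposed_T(v)) for PM roots and sigmoid(b0)
    otherwise.  ``adoption_prob`` (user -> probability) overrides the
    logistic model entirely — used for calibration against exhaustive
    enumeration.
    """
    rng = np.random.default_rng(config.seed + 2)
    b1 = config.b1_map()
    exposure = _diffusion_exposure(graph, store, topics_true, config)

    sigm = lambda x: 1.0 / (1.0 + np.exp(-x))
    p_pm: dict[str, float] = {}
    p_base = float(sigm(config.b0))
    for v in graph.nodes:
        logit = config.b0 + sum(b1[t] for t in exposure[v])
        p_pm[v] = float(sigm(logit))

    originals = [m for m in store.originals() if m.author in graph]
    pm_roots = [m for m in originals if topics_true.get(m.id) == "PM"]
    other_roots = [m for m in originals if topics_true.get(m.id) != "PM"]
    n_pm = min(len(pm_roots), int(round(config.pm_root_fraction * config.n_cascades)))
    n_other = min(len(other_roots), config.n_cascades - n_pm)
    roots: list[Message] = []
    if n_pm:
        roots += [pm_roots[i] for i in rng.choice(len(pm_roots), size=n_pm, replace=False)]
    if n_other:
        roots += [other_roots[i] for i in rng.choice(len(other_roots), size=n_other, replace=False)]

    followers = {v: graph.followers(v) for v in graph.nodes}
    cascades: list[Cascade] = []
    final_sizes: dict[str, int] = {}
    for root in roots:
        is_pm = topics_true.get(root.id) == "PM"
        active = {root.author}
        adopters = [(root.author, root.timestamp)]
        frontier = [root.author]
        step = 0
        while frontier:
            step += 1
            t_step = root.timestamp + step * config.step_seconds
            new: list[str] = []
            for u in frontier:
                for v in followers[u]:
                    if v in active:
                        continue
                    if adoption_prob is not None:
                        p = adoption_prob.get(v, p_base)
                    else:
                        p = p_pm[v] if is_pm else p_base
                    if rng.random() < p:
                        active.add(v)
                        new.append(v)
            for j, v in enumerate(new):
                adopters.append((v, t_step + 1e-3 * j))
            frontier = new
        cascades.append(Cascade(root_message=root.id, adopters=adopters))
        final_sizes[root.id] = len(adopters)

    truth = SimTruth(
        b0=config.b0,
        b1=b1,
        message_topics=topics_true,
        exposure=exposure,
        final_sizes=final_sizes,
    )
    return cascades, truth


def simulate(config: SimConfig) -> SimData:
    """Full pipeline: graph, timelines, diffusion; deterministic per seed."""
    graph = simulate_graph(config)
    store, topics_true = simulate_timelines(graph, config)
    cascades, truth = simulate_diffusion(graph, store, topics_true, config)
    return SimData(graph=graph, store=store, cascades=cascades, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Closing the loop
# ---------------------------------------------------------------------------


def recover_elasticity(
    data: SimData,
    lexicon: TopicLexicon | None = None,
    n_boot: int = 0,
):
    """Run the spillover validation end-to-end on simulated output.

    Exposure is computed from the timeline store (the exogenous posts);
    PM roots are identified by keyword tagging of root texts, exactly as
    on real data.  Returns the per-topic validation table.
    """
    lexicon = lexicon or TopicLexicon()
    profile = compute_exposure(data.graph, data.store, lexicon)
    pm_roots = {
        c.root_message
        for c in data.cascades
        if c.root_message in data.store
        and "PM" in classify_topics(data.store.get(c.root_message).text, lexicon)
    }
    return spillover_report(
        profile,
        data.cascades,
        pm_roots,
        topics=tuple(data.config.topics),
        n_boot=n_boot,
        seed=data.config.seed,
    )


# ---------------------------------------------------------------------------
# Emission in the package's file formats
# ---------------------------------------------------------------------------


def write_dataset(data: SimData, outdir: str | Path) -> dict[str, Path]:
    """Write edge list, messages (timelines + retweet records), cascades, truth.

    The emitted message file appends one retweet record per non-root
    adopter, so reading it back and rebuilding cascades reproduces the
    simulated ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "messages": outdir / "messages.jsonl",
        "cascades": outdir / "cascades.tsv",
        "truth": outdir / "truth.json",
    }
    write_social_graph(data.graph, paths["edges"])

    full = MessageStore(list(data.store))
    for c in data.cascades:
        root = data.store.get(c.root_message)
        for user, t in c.adopters[1:]:
            full.add(
                Message(
                    id=f"rt-{c.root_message}-{user}",
                    author=user,
                    timestamp=t,
                    text=root.text,
                    retweet_of=c.root_message,
                    covid_related=root.covid_related,
                )
            )
    write_messages(full, paths["messages"])
    write_cascades(data.cascades, paths["cascades"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "b0": data.truth.b0,
                "b1": data.truth.b1,
                "final_sizes": data.truth.final_sizes,
                "exposure": {k: sorted(v) for k, v in data.truth.exposure.items()},
                "message_topics": data.truth.message_topics,
            },
            fh,
        )
    return paths
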