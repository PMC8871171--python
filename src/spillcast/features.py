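"""Initial node attributes for popularity prediction: h0 = s ∥ delta ∥ e.

Each user enters the GNN with the concatenation of

* ``s`` — activation status: 1 if the user is in the observed cascade
  prefix, 0 otherwise;
* ``delta`` — a summary of the user's recent posts, kept separate for
  pandemic-related and unrelated messages and blended with a weight
  ``rho`` (this is where the info-exposure spillover signal lives);
* ``e`` — a structural node embedding from truncated random walks.

Past messages are first encoded to fixed-length vectors.  The default
encoder is token feature-hashing (deterministic, dependency-free); a
pretrained multilingual transformer can be plugged in where available.
The last ``lam`` messages of each class are then integrated into one
vector per class by one of four temporal schemes: TE (fixed recency
weights), Mean, Hawkes (exponential decay in clock time), or GRU (a
recurrent gate over the sequence).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph_data import Message, MessageStore, SocialGraph

logger = logging.getLogger("spillcast")

DEFAULT_D_TEXT = 128
DEFAULT_D_STRUCT = 64
DEFAULT_LAMBDA = 3  # number of past messages per class

__all__ = [
    "TemporalWeights",
    "PastMessageSummary",
    "NodeAttributes",
    "encode_messages",
    "temporal_encode",
    "integrate_variant",
    "combine_rel_unrel",
    "structural_embed",
    "past_message_summaries",
    "build_node_attributes",
]


# ---------------------------------------------------------------------------
# Text encoding
# ---------------------------------------------------------------------------


def _tokenize(text: str) -> list[str]:
    out, cur = [], []
    for ch in text.lower():
        if ch.isalnum():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def _hash_vector(text: str, dim: int) -> np.ndarray:
    """Signed token feature-hashing into ``dim`` buckets, l2-normalised."""
    vec = np.zeros(dim)
    for tok in _tokenize(text):
        h = zlib.crc32(tok.encode("utf-8"))
        sign = 1.0 if (h >> 31) & 1 else -1.0
        vec[h % dim] += sign
    norm = np.linalg.norm(vec)
    return vec / norm if norm > 0 else vec


def encode_messages(
    texts: list[str],
    backend: str = "hashing",
    d_text: int = DEFAULT_D_TEXT,
    n_buckets: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Encode texts to a (len(texts), d_text) embedding matrix.

    ``backend='hashing'`` hashes tokens into ``n_buckets`` (default
    ``d_text``) and, if the bucket count differs from ``d_text``, applies
    a seeded random linear projection — mirroring the linear map that
    takes a high-dimensional sentence encoding down to the working
    dimension.  ``backend='transformer'`` requires the optional
    sentence-transformers stack at runtime.
    """
    if backend == "transformer":
        try:
            from sentence_transformers import SentenceTransformer  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional extra
            raise RuntimeError(
                "the transformer text-encoder backend requires the optional "
                "'sentence-transformers' package; use backend='hashing' for a "
                "dependency-free deterministic encoder"
            ) from exc
        model = SentenceTransformer("paraphrase-multilingual-MiniLM-L12-v2")  # pragma: no cover
        raw = np.asarray(model.encode(list(texts)))  # pragma: no cover
    elif backend == "hashing":
        n_buckets = n_buckets or d_text
        raw = np.stack([_hash_vector(t, n_buckets) for t in texts]) if texts else np.zeros((0, n_buckets))
    else:
        raise ValueError(f"unknown encoder backend {backend!r}")

    if raw.shape[1] != d_text:
        rng = np.random.default_rng(seed)
        proj = rng.standard_normal((raw.shape[1], d_text)) / np.sqrt(raw.shape[1])
        raw = raw @ proj
    return raw


# ---------------------------------------------------------------------------
# Temporal integration
# ---------------------------------------------------------------------------


@dataclass
class TemporalWeights:
    """Fixed per-position importance for the last ``lam`` messages.

    Position ``lam`` (the last entry) is the most recent message.  The
    default schedule decays geometrically with recency, ``a_i ∝ r^(lam-i)``
    with ratio ``r=0.5``, normalised to sum 1 — recent posts dominate but
    older ones still contribute.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("temporal weights must be non-negative")
        s = self.values.sum()
        if s <= 0:
            raise ValueError("temporal weights must not all be zero")
        self.values = self.values / s

    @property
    def lam(self) -> int:
        return len(self.values)

    @classmethod
    def recency(cls, lam: int = DEFAULT_LAMBDA, ratio: float = 0.5) -> "TemporalWeights":
        return cls(values=ratio ** np.arange(lam - 1, -1, -1, dtype=float))

    @classmethod
    def uniform(cls, lam: int = DEFAULT_LAMBDA) -> "TemporalWeights":
        return cls(values=np.ones(lam))


def temporal_encode(embeddings: list[np.ndarray], weights: TemporalWeights) -> np.ndarray:
    """TE integration: weighted sum of the last ``lam`` embeddings.

    ``embeddings`` are time-ordered oldest → newest and occupy the most
    recent positions; shorter lists are zero-padded at the oldest end and
    the weights renormalised over the present positions.  An empty list
    yields the zero vector (dimension unknown → length-0 handled by
    caller).
    """
    lam = weights.lam
    if len(embeddings) > lam:
        raise ValueError(f"got {len(embeddings)} embeddings for lambda={lam}")
    if not embeddings:
        raise ValueError("temporal_encode needs at least one embedding (pad upstream)")
    n = len(embeddings)
    w = weights.values[lam - n :]
    w = w / w.sum()
    E = np.stack(embeddings)
    return w @ E


def _gru_params(dim: int, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(dim)
    return {
        name: rng.uniform(-scale, scale, size=shape)
        for name, shape in [
            ("Wz", (dim, dim)), ("Uz", (dim, dim)), ("bz", (dim,)),
            ("Wr", (dim, dim)), ("Ur", (dim, dim)), ("br", (dim,)),
            ("Wh", (dim, dim)), ("Uh", (dim, dim)), ("bh", (dim,)),
        ]
    }


def _gru_last_hidden(E: np.ndarray, p: dict[str, np.ndarray]) -> np.ndarray:
    h = np.zeros(E.shape[1])
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))
    for x in E:
        z = sig(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
        r = sig(x @ p["Wr"] + h @ p["Ur"] + p["br"])
        h_tilde = np.tanh(x @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
        h = (1 - z) * h + z * h_tilde
    return h


def integrate_variant(
    embeddings: list[np.ndarray],
    variant: str = "TE",
    weights: TemporalWeights | None = None,
    timestamps: list[float] | None = None,
    kappa: float = np.log(2) / 3600.0,
    t_now: float | None = None,
    gru_params: dict[str, np.ndarray] | None = None,
    gru_seed: int = 0,
) -> np.ndarray:
    """Integrate a time-ordered embedding list into one vector.

    * ``TE`` — fixed recency weights (:func:`temporal_encode`);
    * ``Mean`` — unweighted average;
    * ``Hawkes`` — weights ∝ exp(-kappa · (t_now - t_i)), normalised
      (kappa defaults to a half-life of one hour); reduces to Mean as
      kappa → 0;
    * ``GRU`` — last hidden state of a single-layer recurrent gate
      (untrained seeded parameters unless supplied).
    """
    if not embeddings:
        raise ValueError("integrate_variant needs at least one embedding")
    E = np.stack(embeddings)
    if variant == "Mean":
        # the TE reduction with uniform weights, so the two variants agree
        # bitwise when TE is run with a flat schedule
        return temporal_encode(embeddings, TemporalWeights.uniform(len(embeddings)))
    if variant == "TE":
        return temporal_encode(embeddings, weights or TemporalWeights.recency(max(len(embeddings), DEFAULT_LAMBDA)))
    if variant == "Hawkes":
        if timestamps is None:
            raise ValueError("Hawkes integration requires timestamps")
        ts = np.asarray(timestamps, dtype=float)
        now = float(ts.max()) if t_now is None else t_now
        w = np.exp(-kappa * (now - ts))
        w = w / w.sum()
        return w @ E
    if variant == "GRU":
        p = gru_params or _gru_params(E.shape[1], gru_seed)
        return _gru_last_hidden(E, p)
    raise ValueError(f"unknown integration variant {variant!r}")


def combine_rel_unrel(phi_rel: np.ndarray, phi_unrel: np.ndarray, rho: float) -> np.ndarray:
    """delta = rho * phi_rel + (1 - rho) * phi_unrel, the class blend.

    ``rho`` weighs pandemic-related against unrelated message summaries;
    it is a convex combination, so delta lies between the two summaries
    coordinatewise.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    return rho * np.asarray(phi_rel, float) + (1.0 - rho) * np.asarray(phi_unrel, float)


# ---------------------------------------------------------------------------
# Past-message summaries per user
# ---------------------------------------------------------------------------


@dataclass
class PastMessageSummary:
    """Per-user integrated summaries and their blend.

    ``delta = rho*phi_rel + (1-rho)*phi_unrel`` holds exactly for the
    BOTH ablation mode; REL / UNREL / ALL replace delta with the single
    corresponding summary.
    """

    phi_rel: np.ndarray
    phi_unrel: np.ndarray
    delta: np.ndarray
    rho: float


def past_message_summaries(
    store: MessageStore,
    users: list[str],
    d_text: int = DEFAULT_D_TEXT,
    lam: int = DEFAULT_LAMBDA,
    variant: str = "TE",
    ablation: str = "BOTH",
    rho: float = 0.5,
    weights: TemporalWeights | None = None,
    before: float | None = None,
    backend: str = "hashing",
    encoder_seed: int = 0,
) -> dict[str, PastMessageSummary]:
    """Integrated past-message vector for every user.

    For each user the last ``lam`` pandemic-related and last ``lam``
    unrelated messages posted before ``before`` (default: all) are
    encoded and integrated by ``variant``; ``ablation`` picks what
    becomes delta: BOTH (the rho-blend), REL, UNREL, or ALL (a single
    undifferentiated last-``lam`` list).  Users with no qualifying
    messages get zero vectors.
    """
    if ablation not in {"BOTH", "REL", "UNREL", "ALL"}:
        raise ValueError(f"unknown ablation mode {ablation!r}")
    weights = weights or TemporalWeights.recency(lam)
    if weights.lam != lam:
        raise ValueError(f"weights length {weights.lam} != lambda {lam}")
    out: dict[str, PastMessageSummary] = {}
    zero = np.zeros(d_text)

    def integrate(msgs: list[Message]) -> np.ndarray:
        msgs = msgs[-lam:]
        if not msgs:
            return zero
        E = list(encode_messages([m.text for m in msgs], backend=backend, d_text=d_text, seed=encoder_seed))
        return integrate_variant(
            E, variant=variant, weights=weights, timestamps=[m.timestamp for m in msgs]
        )

    for v in users:
        timeline = store.by_author(v)
        if before is not None:
            timeline = [m for m in timeline if m.timestamp < before]
        rel = [m for m in timeline if m.covid_related]
        unrel = [m for m in timeline if not m.covid_related]
        phi_rel, phi_unrel = integrate(rel), integrate(unrel)
        if ablation == "BOTH":
            delta = combine_rel_unrel(phi_rel, phi_unrel, rho)
        elif ablation == "REL":
            delta = phi_rel
        elif ablation == "UNREL":
            delta = phi_unrel
        else:  # ALL — one undifferentiated list of the last lam messages
            delta = integrate(timeline)
        out[v] = PastMessageSummary(phi_rel=phi_rel, phi_unrel=phi_unrel, delta=delta, rho=rho)
    return out


# ---------------------------------------------------------------------------
# Structural embedding (truncated random walks + skip-gram)
# ---------------------------------------------------------------------------


def _random_walks(
    adj: sp.csr_matrix, n_walks: int, walk_length: int, rng: np.random.Generator
) -> np.ndarray:
    n = adj.shape[0]
    deg = np.diff(adj.indptr)
    starts = np.tile(np.arange(n), n_walks)
    walks = np.empty((len(starts), walk_length), dtype=np.int64)
    walks[:, 0] = starts
    cur = starts.copy()
    for step in range(1, walk_length):
        u = rng.random(len(cur))
        d = deg[cur]
        nxt = cur.copy()
        movable = d > 0
        offs = (u[movable] * d[movable]).astype(np.int64)
        nxt[movable] = adj.indices[adj.indptr[cur[movable]] + offs]
        walks[:, step] = nxt
        cur = nxt
    return walks


def structural_embed(
    graph: SocialGraph,
    d_struct: int = DEFAULT_D_STRUCT,
    n_walks: int = 10,
    walk_length: int = 40,
    window: int = 5,
    n_negative: int = 1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Structural node embeddings from truncated random walks.

    Uniform random walks over the undirected skeleton of the follow
    graph are summarised by window co-occurrence counts, and the
    embedding factorises the shifted positive PMI of those counts (the
    closed-form equivalent of skip-gram with ``n_negative`` negative
    samples) by truncated SVD.  Deterministic for a fixed seed.  Nodes
    with no edges get the zero vector with a warning.
    """
    nodes = graph.nodes
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return {}
    und = graph.to_networkx().to_undirected()
    rows, cols = [], []
    for u, v in und.edges:
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.diff(adj.indptr)
    isolated = deg == 0
    if isolated.any():
        logger.warning("structural_embed: %d isolated node(s) get zero embeddings", int(isolated.sum()))

    rng = np.random.default_rng(seed)
    walks = _random_walks(adj, n_walks, walk_length, rng)

    # window co-occurrence counts from the walks
    rows, cols = [], []
    for off in range(1, window + 1):
        rows += [walks[:, off:].ravel(), walks[:, :-off].ravel()]
        cols += [walks[:, :-off].ravel(), walks[:, off:].ravel()]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    keep = rows != cols
    C = sp.coo_matrix(
        (np.ones(keep.sum()), (rows[keep], cols[keep])), shape=(n, n)
    ).tocsr()

    # shifted positive PMI, the closed form of skip-gram with negative
    # sampling at shift n_negative
    total = C.sum()
    w_freq = np.asarray(C.sum(axis=1)).ravel()
    c_freq = np.asarray(C.sum(axis=0)).ravel()
    coo = C.tocoo()
    with np.errstate(divide="ignore"):
        pmi = np.log(coo.data * total / (w_freq[coo.row] * c_freq[coo.col])) - np.log(
            n_negative
        )
    pmi = np.maximum(pmi, 0.0)
    k = min(d_struct, n - 1) if n > 1 else 1
    if n <= 3000:
        M = np.zeros((n, n))
        M[coo.row, coo.col] = pmi
        U, S, _ = np.linalg.svd(M, full_matrices=False)
    else:  # large graphs: sparse truncated SVD with a seeded start vector
        Msp = sp.csr_matrix((pmi, (coo.row, coo.col)), shape=(n, n))
        U, S, _ = sp.linalg.svds(Msp, k=k, v0=rng.standard_normal(n))
        order = np.argsort(S)[::-1]
        U, S = U[:, order], S[order]
    emb = U[:, :k] * np.sqrt(S[:k])
    if k < d_struct:  # tiny graphs: pad to the requested dimension
        emb = np.hstack([emb, np.zeros((n, d_struct - k))])
    # fix a deterministic sign convention per component
    signs = np.sign(emb[np.abs(emb).argmax(axis=0), np.arange(d_struct)])
    signs[signs == 0] = 1.0
    emb = emb * signs

    emb[isolated] = 0.0
    return {v: emb[index[v]].copy() for v in nodes}


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class NodeAttributes:
    """Stacked initial representations h0 = s ∥ delta ∥ e for all nodes.

    ``matrix`` has one row per node in ``nodes`` order; column 0 is the
    activation status, the next ``d_text`` columns the past-message
    summary, the last ``d_struct`` columns the structural embedding.
    """

    nodes: list[str]
    matrix: np.ndarray
    d_text: int
    d_struct: int
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        if self.matrix.shape != (len(self.nodes), 1 + self.d_text + self.d_struct):
            raise ValueError("attribute matrix shape inconsistent with dimensions")
        self.index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def activation(self) -> np.ndarray:
        return self.matrix[:, 0]

    def h0(self, v: str) -> np.ndarray:
        return self.matrix[self.index[v]]


def build_node_attributes(
    prefix_users: set[str],
    summaries: dict[str, PastMessageSummary],
    embeddings: dict[str, np.ndarray],
    nodes: list[str],
) -> NodeAttributes:
    """Concatenate s, delta and e for every node (in ``nodes`` order)."""
    missing = [v for v in nodes if v not in summaries or v not in embeddings]
    if missing:
        raise KeyError(f"missing feature components for node(s) {missing[:5]!r}")
    d_text = len(next(iter(summaries.values())).delta)
    d_struct = len(next(iter(embeddings.values())))
    H = np.zeros((len(nodes), 1 + d_text + d_struct))
    for i, v in enumerate(nodes):
        H[i, 0] = 1.0 if v in prefix_users else 0.0
        H[i, 1 : 1 + d_text] = summaries[v].delta
        H[i, 1 + d_text :] = embeddings[v]
    return NodeAttributes(nodes=list(nodes), matrix=H, d_text=d_text, d_struct=d_struct)
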