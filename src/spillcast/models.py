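"""GNN popularity predictors with the info-exposure spillover extension.

Three message-passing families are implemented, each in a plain and a
spillover-extended (SE) form:

* **GCN** — closed-neighbourhood mean aggregation, linear combine with a
  leaky rectifier;
* **GAT** — the same combine, but attention-softmax weights over the
  closed neighbourhood;
* **CoupledGNN (CGNN)** — two coupled networks: a *state* network whose
  per-node activation s_v ∈ [0,1] simulates the cascading effect layer by
  layer, and an *influence* network whose vectors r_v weight each
  neighbour's contribution through a scalar influence gate.

The SE extension injects message content: node inputs carry the user's
past-message summary delta, and the diffused message's embedding z_m
enters the activation head (SE-GCN/SE-GAT) or the influence gate
(SE-CGNN).  Plain variants drop both, relying on network structure only.

The readout is the sum of predicted final activation statuses,
``n_pred = sum_v s_v``; observed cascade members are pinned to 1 at every
layer, so the prediction can never fall below the observed prefix size.

All layers run on sparse edge structure, so one layer costs O(|E|).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .autograd import Tensor, concat, gather, scatter_add, spmm
from .features import NodeAttributes
from .graph_data import SocialGraph

__all__ = [
    "GraphTensors",
    "ModelParams",
    "PopularityPrediction",
    "gcn_layer",
    "gat_layer",
    "se_head",
    "influ_gate",
    "coupled_step",
    "make_model",
    "SpilloverGNN",
    "predict_popularity",
    "save_checkpoint",
    "load_checkpoint",
    "VARIANTS",
]

VARIANTS = ("GCN", "GAT", "CGNN", "SE-GCN", "SE-GAT", "SE-CGNN")

LEAKY_SLOPE = 0.01


# ---------------------------------------------------------------------------
# Graph preprocessing
# ---------------------------------------------------------------------------


class GraphTensors:
    """Sparse structure of a social graph, precomputed once per graph.

    Message passing runs along *perception* direction: node v aggregates
    from its followees N(v) (out-neighbours of the follower→followee
    edge list).  ``A_mean`` is the row-normalised closed-neighbourhood
    operator for GCN; ``closed_src/closed_dst`` enumerate the closed
    neighbourhood as edges for GAT; ``src/dst`` enumerate the open
    neighbourhood for the coupled model.
    """

    def __init__(self, graph: SocialGraph):
        self.nodes = graph.nodes
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.n = len(self.nodes)
        src, dst = [], []  # influence source u (followee) -> target v (follower)
        for v, u in graph.edges:  # v follows u
            src.append(self.index[u])
            dst.append(self.index[v])
        self.src = np.asarray(src, dtype=np.intp)
        self.dst = np.asarray(dst, dtype=np.intp)
        loops = np.arange(self.n, dtype=np.intp)
        self.closed_src = np.concatenate([self.src, loops])
        self.closed_dst = np.concatenate([self.dst, loops])
        deg = np.bincount(self.closed_dst, minlength=self.n).astype(float)
        w = 1.0 / deg[self.closed_dst]
        self.A_mean = sp.csr_matrix(
            (w, (self.closed_dst, self.closed_src)), shape=(self.n, self.n)
        )
        # incidence maps for segment sums over edges (cached for reuse)
        self.S_closed = sp.csr_matrix(
            (np.ones(len(self.closed_dst)), (self.closed_dst, np.arange(len(self.closed_dst)))),
            shape=(self.n, len(self.closed_dst)),
        )
        self.S_open = sp.csr_matrix(
            (np.ones(len(self.dst)), (self.dst, np.arange(len(self.dst)))),
            shape=(self.n, len(self.dst)),
        )

    def mask(self, users: set[str]) -> np.ndarray:
        m = np.zeros(self.n)
        for u in users:
            if u in self.index:
                m[self.index[u]] = 1.0
        return m


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


class ModelParams(dict):
    """Named trainable tensors of one model variant."""

    def tensors(self) -> list[Tensor]:
        return list(self.values())

    def add(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self[name] = t
        return t

    def zero_grad(self) -> None:
        for t in self.values():
            t.zero_grad()

    def l2(self) -> Tensor:
        total = None
        for t in self.values():
            term = (t * t).sum()
            total = term if total is None else total + term
        return total


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan = sum(shape) if len(shape) > 1 else shape[0] + 1
    scale = np.sqrt(6.0 / fan)
    return rng.uniform(-scale, scale, size=shape)


# ---------------------------------------------------------------------------
# Functional layers
# ---------------------------------------------------------------------------


def gcn_layer(H: Tensor, gt: GraphTensors, W: Tensor) -> Tensor:
    """Mean over the closed neighbourhood, linear map, leaky rectifier."""
    return (spmm(gt.A_mean, H) @ W).leaky_relu(LEAKY_SLOPE)


def _segment_softmax(scores: Tensor, dst: np.ndarray, n: int) -> Tensor:
    """Softmax of per-edge scores within each destination segment."""
    shift = np.full(n, -np.inf)
    np.maximum.at(shift, dst, scores.data)
    shifted = scores - Tensor(shift[dst])  # constant shift, exact for softmax
    ex = shifted.exp()
    denom = scatter_add(ex, dst, n)
    return ex / gather(denom, dst)


def gat_layer(H: Tensor, gt: GraphTensors, W: Tensor, gamma: Tensor) -> Tensor:
    """Attention-weighted aggregation over the closed neighbourhood.

    Scores follow e_uv = LeakyReLU(gamma^T [W h_u ∥ W h_v]), softmax over
    each closed neighbourhood; the combine is shared with GCN.
    """
    d = W.shape[1]
    HW = H @ W
    g_u, g_v = gamma[np.arange(d)], gamma[np.arange(d, 2 * d)]
    scores = (gather(HW, gt.closed_src) @ g_u + gather(HW, gt.closed_dst) @ g_v).leaky_relu(
        LEAKY_SLOPE
    )
    coef = _segment_softmax(scores, gt.closed_dst, gt.n)
    msgs = coef.reshape(-1, 1) * gather(H, gt.closed_src)
    agg = scatter_add(msgs, gt.closed_dst, gt.n)
    return (agg @ W).leaky_relu(LEAKY_SLOPE)


def gat_coefficients(H: Tensor, gt: GraphTensors, W: Tensor, gamma: Tensor) -> np.ndarray:
    """Attention coefficients per closed-neighbourhood edge (for inspection)."""
    d = W.shape[1]
    HW = H @ W
    g_u, g_v = gamma[np.arange(d)], gamma[np.arange(d, 2 * d)]
    scores = (gather(HW, gt.closed_src) @ g_u + gather(HW, gt.closed_dst) @ g_v).leaky_relu(
        LEAKY_SLOPE
    )
    return _segment_softmax(scores, gt.closed_dst, gt.n).data


def _mlp3_logits(x: Tensor, params: ModelParams, prefix: str) -> Tensor:
    h = (x @ params[f"{prefix}_W1"] + params[f"{prefix}_b1"]).leaky_relu(LEAKY_SLOPE)
    h = (h @ params[f"{prefix}_W2"] + params[f"{prefix}_b2"]).leaky_relu(LEAKY_SLOPE)
    return (h @ params[f"{prefix}_W3"] + params[f"{prefix}_b3"]).reshape(-1)


def _mlp3(x: Tensor, params: ModelParams, prefix: str) -> Tensor:
    """The 3-layer activation head; squashing output in (0, 1)."""
    return _mlp3_logits(x, params, prefix).sigmoid()


def se_head(
    Hk: Tensor,
    zm: np.ndarray | None,
    mask: np.ndarray,
    params: ModelParams,
) -> Tensor:
    """Final activation statuses: members pinned to 1, others through the head.

    The head input is W_h h_v^k, with W_z z_m appended in SE mode, passed
    through a 3-layer network with a sigmoid output — so non-member
    statuses are strictly inside (0, 1).
    """
    hh = Hk @ params["W_h"]
    if zm is not None:
        zt = (Tensor(zm) @ params["W_z"]).reshape(1, -1)
        zrep = concat([zt] * hh.shape[0], axis=0)
        x = concat([hh, zrep], axis=1)
    else:
        x = hh
    s_open = _mlp3(x, params, "head")
    m = Tensor(mask)
    return m + (1.0 - m) * s_open


def influ_gate(
    r_src: Tensor,
    r_dst: Tensor,
    beta_u: Tensor,
    beta_v: Tensor,
    W: Tensor,
    beta_z: Tensor | None = None,
    Wz_zm: Tensor | None = None,
) -> Tensor:
    """Scalar influence gate per edge.

    Plain form: beta^T [W r_u ∥ W r_v].  SE form appends the diffused
    message's projected embedding, beta^T [W r_u ∥ W r_v ∥ W_z z_m].
    """
    g = (r_src @ W) @ beta_u + (r_dst @ W) @ beta_v
    if beta_z is not None:
        if Wz_zm is None:
            raise ValueError("SE influence gate requires the message embedding term")
        g = g + (Wz_zm @ beta_z)
    return g


def coupled_step(
    s: Tensor,
    r: Tensor,
    gt: GraphTensors,
    params: ModelParams,
    layer: int,
    mask: np.ndarray,
    Wz_zm: Tensor | None,
    se: bool,
    update_r: bool = True,
) -> tuple[Tensor, Tensor]:
    """One layer of the coupled state/influence update.

    State network: a_v = sum_{u in N(v)} gate(r_u, r_v) s_u + p_v, then
    s_v <- sigma(mu_s s_v + mu_a a_v) for non-members; members stay 1.
    Influence network: r_v <- LeakyReLU(W_self r_v +
    sum_u omega_uv s_u W_nb r_u) with attention-normalised omega — the
    one update the coupled-model description leaves to its original
    source, kept behind this function.
    """
    W = params[f"cg_W{layer}"]
    gate = influ_gate(
        gather(r, gt.src),
        gather(r, gt.dst),
        params[f"cg_bu{layer}"],
        params[f"cg_bv{layer}"],
        W,
        beta_z=params[f"cg_bz{layer}"] if se else None,
        Wz_zm=Wz_zm if se else None,
    )
    s_src = gather(s, gt.src)
    a = scatter_add(gate * s_src, gt.dst, gt.n) + params["p_v"]
    s_new_open = (params[f"mu_s{layer}"] * s + params[f"mu_a{layer}"] * a).sigmoid()
    m = Tensor(mask)
    s_new = m + (1.0 - m) * s_new_open
    if not update_r:
        return s_new, r

    # influence update
    d_prev = r.shape[1]
    gam = params[f"cg_gr{layer}"]
    g_u, g_v = gam[np.arange(d_prev)], gam[np.arange(d_prev, 2 * d_prev)]
    att = (gather(r, gt.src) @ g_u + gather(r, gt.dst) @ g_v).leaky_relu(LEAKY_SLOPE)
    omega = _segment_softmax(att, gt.dst, gt.n)
    msgs = (omega * s_src).reshape(-1, 1) * (gather(r, gt.src) @ params[f"cg_Wnb{layer}"])
    r_new = (r @ params[f"cg_Wself{layer}"] + scatter_add(msgs, gt.dst, gt.n)).leaky_relu(
        LEAKY_SLOPE
    )
    return s_new, r_new


# ---------------------------------------------------------------------------
# Batched execution
#
# Training evaluates many cascades on the same graph.  States are laid
# out as (n, B*d) blocks — sample b of node i occupies columns
# [b*d, (b+1)*d) of row i — so one sparse product serves the whole
# mini-batch and the Python op count is independent of batch size.
# The single-sample functional ops above remain the reference
# implementation; batched and per-sample paths agree to float precision.
# ---------------------------------------------------------------------------


def _bmm(X: Tensor, rows: int, B: int, d: int, W: Tensor) -> Tensor:
    """Per-block matmul: (rows, B*d) x (d, h) -> (rows, B*h)."""
    return (X.reshape(rows * B, d) @ W).reshape(rows, B * W.shape[1])


def _seg_softmax_b(scores: Tensor, dst: np.ndarray, S: sp.csr_matrix) -> Tensor:
    """Per-destination softmax of (E, B) scores, shared incidence map."""
    n = S.shape[0]
    shift = np.full((n, scores.shape[1]), -np.inf)
    np.maximum.at(shift, dst, scores.data)
    ex = (scores - Tensor(shift[dst])).exp()
    denom = spmm(S, ex)
    return ex / gather(denom, dst)


def _gcn_layer_b(H: Tensor, gt: GraphTensors, W: Tensor, B: int, d: int) -> Tensor:
    return _bmm(spmm(gt.A_mean, H), gt.n, B, d, W).leaky_relu(LEAKY_SLOPE)


def _gat_layer_b(
    H: Tensor, gt: GraphTensors, W: Tensor, gamma: Tensor, B: int, d: int
) -> Tensor:
    h = W.shape[1]
    E = len(gt.closed_dst)
    HW = _bmm(H, gt.n, B, d, W)
    g_u, g_v = gamma[np.arange(h)], gamma[np.arange(h, 2 * h)]
    sc = (
        gather(HW, gt.closed_src).reshape(E * B, h) @ g_u
        + gather(HW, gt.closed_dst).reshape(E * B, h) @ g_v
    ).leaky_relu(LEAKY_SLOPE).reshape(E, B)
    coef = _seg_softmax_b(sc, gt.closed_dst, gt.S_closed)
    msgs = coef.reshape(E, B, 1) * gather(H, gt.closed_src).reshape(E, B, d)
    agg = spmm(gt.S_closed, msgs.reshape(E, B * d))
    return _bmm(agg, gt.n, B, d, W).leaky_relu(LEAKY_SLOPE)


def _head_b(
    Hk: Tensor, Z: np.ndarray | None, masks: np.ndarray, params: ModelParams,
    B: int, d: int,
) -> tuple[Tensor, Tensor]:
    """Batched activation head; returns (statuses, open-node logits)."""
    n = masks.shape[0]
    hh = Hk.reshape(n * B, d) @ params["W_h"]
    if Z is not None:
        zproj = Tensor(Z) @ params["W_z"]  # (B, hd)
        x = concat([hh, gather(zproj, np.tile(np.arange(B), n))], axis=1)
    else:
        x = hh
    logits = _mlp3_logits(x, params, "head").reshape(n, B)
    m = Tensor(masks)
    return m + (1.0 - m) * logits.sigmoid(), logits


def _coupled_step_b(
    s: Tensor, r: Tensor, gt: GraphTensors, params: ModelParams, layer: int,
    masks: np.ndarray, Zp: Tensor | None, se: bool, B: int, d: int,
    update_r: bool,
) -> tuple[Tensor, Tensor]:
    E = len(gt.dst)
    W = params[f"cg_W{layer}"]
    r_src = gather(r, gt.src)
    r_dst = gather(r, gt.dst)
    gate = (
        r_src.reshape(E * B, d) @ (W @ params[f"cg_bu{layer}"])
        + r_dst.reshape(E * B, d) @ (W @ params[f"cg_bv{layer}"])
    ).reshape(E, B)
    if se:
        gate = gate + (Zp @ params[f"cg_bz{layer}"])  # (B,) broadcast over edges
    s_src = gather(s, gt.src)
    a = spmm(gt.S_open, gate * s_src) + params["p_v"]
    logits = params[f"mu_s{layer}"] * s + params[f"mu_a{layer}"] * a
    m = Tensor(masks)
    s_new = m + (1.0 - m) * logits.sigmoid()
    if not update_r:
        return s_new, r, logits

    gam = params[f"cg_gr{layer}"]
    g_u, g_v = gam[np.arange(d)], gam[np.arange(d, 2 * d)]
    att = (
        r_src.reshape(E * B, d) @ g_u + r_dst.reshape(E * B, d) @ g_v
    ).leaky_relu(LEAKY_SLOPE).reshape(E, B)
    omega = _seg_softmax_b(att, gt.dst, gt.S_open)
    h_out = params[f"cg_Wnb{layer}"].shape[1]
    msgs = (omega * s_src).reshape(E, B, 1) * (
        r_src.reshape(E * B, d) @ params[f"cg_Wnb{layer}"]
    ).reshape(E, B, h_out)
    agg = spmm(gt.S_open, msgs.reshape(E, B * h_out))
    r_new = (_bmm(r, gt.n, B, d, params[f"cg_Wself{layer}"]) + agg).leaky_relu(LEAKY_SLOPE)
    return s_new, r_new, logits


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class PopularityPrediction:
    """Per-node predicted final statuses and their sum, the predicted size."""

    statuses: np.ndarray
    size: float
    nodes: list[str]


class SpilloverGNN:
    """A popularity predictor: one of GCN/GAT/CGNN, plain or SE-extended.

    Parameters
    ----------
    variant:
        One of ``GCN, GAT, CGNN, SE-GCN, SE-GAT, SE-CGNN``.
    d_text, d_struct:
        Dimensions of the past-message summary and structural embedding
        blocks of the node attributes (needed to slice delta out for the
        plain variants).
    k:
        Number of message-passing layers (default 3).
    hidden:
        Width of GCN/GAT hidden layers and of the coupled influence
        vectors.
    head_dim:
        Width of the W_h / W_z projections feeding the activation head.
    """

    def __init__(
        self,
        variant: str,
        d_text: int,
        d_struct: int,
        k: int = 3,
        hidden: int = 16,
        head_dim: int = 16,
        head_hidden: tuple[int, int] = (64, 32),
        seed: int = 0,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.variant = variant
        self.se = variant.startswith("SE-")
        self.family = variant.removeprefix("SE-")
        self.d_text, self.d_struct = d_text, d_struct
        self.k, self.hidden, self.head_dim = k, hidden, head_dim
        self.head_hidden = tuple(head_hidden)
        self.seed = seed
        self.d_in = 1 + d_text + d_struct
        self.params = self._init_params(np.random.default_rng(seed))

    # -- parameter construction ----------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> ModelParams:
        p = ModelParams()
        d_in, hid, hd = self.d_in, self.hidden, self.head_dim
        if self.family in ("GCN", "GAT"):
            dims = [d_in] + [hid] * self.k
            for ell in range(self.k):
                p.add(f"W{ell}", _glorot(rng, (dims[ell], dims[ell + 1])))
                if self.family == "GAT":
                    p.add(f"gamma{ell}", _glorot(rng, (2 * dims[ell + 1],)) * 0.1)
            p.add("W_h", _glorot(rng, (hid, hd)))
            if self.se:
                p.add("W_z", _glorot(rng, (self.d_text, hd)))
        else:  # coupled
            dims = [d_in] + [hid] * self.k
            for ell in range(self.k):
                dp = dims[ell]
                p.add(f"cg_W{ell}", _glorot(rng, (dp, hd)))
                p.add(f"cg_bu{ell}", _glorot(rng, (hd,)) * 0.1)
                p.add(f"cg_bv{ell}", _glorot(rng, (hd,)) * 0.1)
                if self.se:
                    p.add(f"cg_bz{ell}", _glorot(rng, (hd,)) * 0.1)
                p.add(f"mu_s{ell}", np.array(1.0))
                p.add(f"mu_a{ell}", np.array(1.0))
                if ell < self.k - 1:  # influence vectors after the last layer are unused
                    p.add(f"cg_Wself{ell}", _glorot(rng, (dp, dims[ell + 1])))
                    p.add(f"cg_Wnb{ell}", _glorot(rng, (dp, dims[ell + 1])))
                    p.add(f"cg_gr{ell}", _glorot(rng, (2 * dp,)) * 0.1)
            # start the default activation low: a fresh model should predict
            # few additional adopters, not half the graph
            p.add("p_v", np.array(-4.0))
            if self.se:
                p.add("W_z", _glorot(rng, (self.d_text, hd)))
        if self.family in ("GCN", "GAT"):
            head_in = hd * (2 if self.se else 1)
            h1, h2 = self.head_hidden
            p.add("head_W1", _glorot(rng, (head_in, h1)))
            p.add("head_b1", np.zeros(h1))
            p.add("head_W2", _glorot(rng, (h1, h2)))
            p.add("head_b2", np.zeros(h2))
            p.add("head_W3", _glorot(rng, (h2, 1)))
            # low-rate output bias, same rationale as the coupled p_v
            p.add("head_b3", np.full(1, -4.0))
        return p

    # -- forward --------------------------------------------------------------
    def _input_matrix(self, attrs: NodeAttributes, mask: np.ndarray) -> np.ndarray:
        H0 = attrs.matrix.copy()
        H0[:, 0] = mask
        if not self.se:
            # plain variants drop the message-representation block
            H0[:, 1 : 1 + self.d_text] = 0.0
        return H0

    def forward(
        self,
        gt: GraphTensors,
        attrs: NodeAttributes,
        prefix_users: set[str],
        zm: np.ndarray | None = None,
    ) -> Tensor:
        """Predicted final activation statuses s_tilde for every node."""
        if self.se and zm is None:
            raise ValueError(f"{self.variant} requires the diffused message embedding z_m")
        if attrs.d_text != self.d_text or attrs.d_struct != self.d_struct:
            raise ValueError("node-attribute dimensions do not match the model")
        mask = gt.mask(prefix_users)
        H = Tensor(self._input_matrix(attrs, mask))
        if self.family in ("GCN", "GAT"):
            for ell in range(self.k):
                if self.family == "GCN":
                    H = gcn_layer(H, gt, self.params[f"W{ell}"])
                else:
                    H = gat_layer(H, gt, self.params[f"W{ell}"], self.params[f"gamma{ell}"])
            return se_head(H, zm if self.se else None, mask, self.params)
        # coupled
        s = Tensor(mask)
        r = H
        Wz_zm = (Tensor(zm) @ self.params["W_z"]) if self.se else None
        for ell in range(self.k):
            s, r = coupled_step(
                s, r, gt, self.params, ell, mask, Wz_zm, self.se,
                update_r=(ell < self.k - 1),
            )
        return s

    def forward_batch(
        self,
        gt: GraphTensors,
        attrs: NodeAttributes,
        prefix_sets: list[set[str]],
        zms: list[np.ndarray] | None = None,
        with_logits: bool = False,
    ) -> Tensor | tuple[Tensor, Tensor, np.ndarray]:
        """Batched statuses, shape (n, B) — one column per cascade.

        Same computation as :meth:`forward`, laid out in (n, B*d) blocks
        so the op count does not grow with the batch.  With
        ``with_logits=True`` also returns the open-node pre-squash logits
        and the member masks, for a numerically robust training loss.
        """
        B = len(prefix_sets)
        if self.se and (zms is None or any(z is None for z in zms)):
            raise ValueError(f"{self.variant} requires message embeddings z_m")
        masks = np.stack([gt.mask(p) for p in prefix_sets], axis=1)  # (n, B)
        base = attrs.matrix.copy()
        if not self.se:
            base[:, 1 : 1 + self.d_text] = 0.0
        H0 = np.repeat(base[:, None, :], B, axis=1)  # (n, B, d_in)
        H0[:, :, 0] = masks
        Z = np.stack(zms) if self.se else None  # (B, d_text)

        if self.family in ("GCN", "GAT"):
            H = Tensor(H0.reshape(gt.n, B * self.d_in))
            d = self.d_in
            for ell in range(self.k):
                W = self.params[f"W{ell}"]
                if self.family == "GCN":
                    H = _gcn_layer_b(H, gt, W, B, d)
                else:
                    H = _gat_layer_b(H, gt, W, self.params[f"gamma{ell}"], B, d)
                d = W.shape[1]
            s, logits = _head_b(H, Z if self.se else None, masks, self.params, B, d)
            return (s, logits, masks) if with_logits else s

        s = Tensor(masks)
        r = Tensor(H0.reshape(gt.n, B * self.d_in))
        d = self.d_in
        Zp = (Tensor(Z) @ self.params["W_z"]) if self.se else None
        logits = None
        for ell in range(self.k):
            update_r = ell < self.k - 1
            s, r, logits = _coupled_step_b(
                s, r, gt, self.params, ell, masks, Zp, self.se, B, d, update_r
            )
            if update_r:
                d = self.params[f"cg_Wself{ell}"].shape[1]
        return (s, logits, masks) if with_logits else s

    def predict(
        self,
        gt: GraphTensors,
        attrs: NodeAttributes,
        prefix_users: set[str],
        zm: np.ndarray | None = None,
    ) -> PopularityPrediction:
        s = self.forward(gt, attrs, prefix_users, zm)
        return PopularityPrediction(
            statuses=s.data.copy(), size=float(s.data.sum()), nodes=gt.nodes
        )

    # -- config ---------------------------------------------------------------
    def config(self) -> dict:
        return {
            "variant": self.variant,
            "d_text": self.d_text,
            "d_struct": self.d_struct,
            "k": self.k,
            "hidden": self.hidden,
            "head_dim": self.head_dim,
            "head_hidden": list(self.head_hidden),
            "seed": self.seed,
        }


def make_model(variant: str, d_text: int, d_struct: int, **kw) -> SpilloverGNN:
    return SpilloverGNN(variant, d_text, d_struct, **kw)


def predict_popularity(
    model: SpilloverGNN,
    graph: SocialGraph | GraphTensors,
    attrs: NodeAttributes,
    prefix_users: set[str],
    zm: np.ndarray | None = None,
) -> PopularityPrediction:
    """Run the chosen variant and sum final statuses into the size estimate."""
    gt = graph if isinstance(graph, GraphTensors) else GraphTensors(graph)
    return model.predict(gt, attrs, prefix_users, zm)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SpilloverGNN, directory: str | Path) -> None:
    """Serialise parameters (npz) plus structured config (json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "params.npz", **{k: t.data for k, t in model.params.items()})
    with open(directory / "config.json", "w", encoding="utf-8") as fh:
        json.dump(model.config(), fh, indent=2)


def load_checkpoint(directory: str | Path) -> SpilloverGNN:
    """Rebuild a model whose predictions match the saved one bitwise."""
    directory = Path(directory)
    with open(directory / "config.json", encoding="utf-8") as fh:
        cfg = json.load(fh)
    cfg["head_hidden"] = tuple(cfg["head_hidden"])
    model = SpilloverGNN(**cfg)
    with np.load(directory / "params.npz") as data:
        for k in model.params:
            model.params[k].data = data[k].astype(np.float64)
    return model
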