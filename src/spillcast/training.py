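"""Losses, data splitting, and the optimisation loop.

The objective is the regularised mean relative squared error over a set
of cascades:

    L = L_MRSE + theta * sum_p ||p||^2 + lambda_reg * L_user

where ``L_MRSE = mean(((n_pred - n_true)/n_true)^2)`` scores the size
prediction, the middle term is an L2 penalty over all trainable tensors,
and ``L_user`` is the per-node binary cross-entropy between predicted
and true final activation statuses (the printed form is a
log-likelihood; it is negated here so the whole objective is
minimised).  ``lambda_reg`` is the loss-side coefficient (default 0.5);
it is named apart from the past-message count ``lam`` used by the
feature builder, which shares its symbol in the source notation.

Optimisation is adaptive-moment gradient descent over mini-batches of
cascades, with early stopping on validation MRSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor, concat
from .features import NodeAttributes
from .graph_data import Cascade, observe, DEFAULT_OBSERVATION_WINDOW
from .metrics import evaluate
from .models import GraphTensors, ModelParams, SpilloverGNN

logger = logging.getLogger("spillcast")

__all__ = [
    "LossConfig",
    "SplitSpec",
    "CascadeSample",
    "Adam",
    "mrse_loss",
    "user_ce_loss",
    "user_ce_from_logits",
    "total_loss",
    "split_cascades",
    "make_samples",
    "predict_sizes",
    "train",
    "grid_search",
    "THETA_GRID",
    "LR_GRID",
    "BATCH_GRID",
    "K_GRID",
]

# canonical hyper-parameter grids for validation-based selection
THETA_GRID = (0.5, 0.1, 0.05, 0.01, 0.005, 0.001, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8)
LR_GRID = (0.1, 0.05, 0.01, 0.005, 0.001, 5e-4, 1e-4, 5e-5, 1e-5)
BATCH_GRID = (15, 10, 5)
K_GRID = (5, 4, 3, 2)

CE_CLAMP = 1e-7


@dataclass
class LossConfig:
    """Objective and optimisation settings."""

    theta: float = 1e-5
    lambda_reg: float = 0.5
    lr: float = 0.01
    batch_size: int = 10
    epochs: int = 100
    patience: int = 10

    def __post_init__(self):
        if self.theta < 0 or self.lambda_reg < 0:
            raise ValueError("theta and lambda_reg must be non-negative")


@dataclass
class SplitSpec:
    """Random train/validation/test split fractions."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be non-negative")


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def _stack_scalars(values: list[Tensor]) -> Tensor:
    return concat([v.reshape(1) for v in values], axis=0)


def mrse_loss(predictions: Tensor | list[Tensor], truths: np.ndarray) -> Tensor:
    """Mean squared relative size error, the primary objective term."""
    if isinstance(predictions, list):
        predictions = _stack_scalars(predictions)
    truths = np.asarray(truths, dtype=float)
    if np.any(truths < 1):
        raise ValueError("cascade sizes must be >= 1")
    rel = (predictions - Tensor(truths)) / Tensor(truths)
    return (rel * rel).mean()


def user_ce_loss(s_true: np.ndarray, s_pred: Tensor) -> Tensor:
    """Negative mean binary cross-entropy over node final statuses.

    Predicted statuses are clamped to [1e-7, 1-1e-7] inside the logs;
    the result is >= 0 and ~0 for a perfect prediction.
    """
    s_true = np.asarray(s_true, dtype=float)
    p = s_pred.clip(CE_CLAMP, 1.0 - CE_CLAMP)
    ll = Tensor(s_true) * p.log() + Tensor(1.0 - s_true) * (1.0 - p).log()
    return -ll.mean()


def user_ce_from_logits(logits: Tensor, s_true: np.ndarray, masks: np.ndarray) -> Tensor:
    """Cross-entropy on pre-squash logits (softplus form).

    Numerically robust: the gradient is sigmoid(x) - s, which never
    vanishes for a confidently wrong status — saturated nodes can
    recover.  Observed members (mask 1) are pinned to status 1 and
    contribute zero, matching the probability-space definition.
    """
    open_w = 1.0 - masks
    bce = logits.softplus() - logits * Tensor(s_true)
    return (bce * Tensor(open_w)).sum() * (1.0 / s_true.size)


def total_loss(
    predictions: list[Tensor],
    truths: np.ndarray,
    status_pairs: list[tuple[np.ndarray, Tensor]],
    params: ModelParams,
    config: LossConfig,
) -> Tensor:
    """L = L_MRSE + theta * sum ||p||^2 + lambda_reg * L_user."""
    loss = mrse_loss(predictions, truths)
    if config.theta > 0:
        loss = loss + config.theta * params.l2()
    if config.lambda_reg > 0 and status_pairs:
        ce = None
        for s_true, s_pred in status_pairs:
            term = user_ce_loss(s_true, s_pred)
            ce = term if ce is None else ce + term
        loss = loss + (config.lambda_reg / len(status_pairs)) * ce
    return loss


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_cascades(
    cascades: list[Cascade], spec: SplitSpec | None = None
) -> tuple[list[Cascade], list[Cascade], list[Cascade]]:
    """Seeded shuffle, then contiguous partition into train/val/test."""
    spec = spec or SplitSpec()
    if len(cascades) < 3:
        raise ValueError("need at least 3 cascades to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(cascades))
    n = len(cascades)
    b1 = int(round(spec.fractions[0] * n))
    b2 = int(round((spec.fractions[0] + spec.fractions[1]) * n))
    shuffled = [cascades[i] for i in order]
    return shuffled[:b1], shuffled[b1:b2], shuffled[b2:]


# ---------------------------------------------------------------------------
# Samples
# ---------------------------------------------------------------------------


@dataclass
class CascadeSample:
    """One training/evaluation instance: observed prefix vs final outcome."""

    cascade_id: str
    prefix_users: set[str]
    n_true: int
    s_final: np.ndarray  # final per-node activation in graph node order
    zm: np.ndarray | None  # diffused message's text embedding


def make_samples(
    gt: GraphTensors,
    cascades: list[Cascade],
    message_embeddings: dict[str, np.ndarray] | None = None,
    window: float = DEFAULT_OBSERVATION_WINDOW,
) -> list[CascadeSample]:
    """Build samples: 3-hour-window prefixes, final sizes, z_m vectors."""
    out = []
    for c in cascades:
        prefix = observe(c, window)
        zm = message_embeddings.get(c.root_message) if message_embeddings else None
        out.append(
            CascadeSample(
                cascade_id=c.root_message,
                prefix_users=set(prefix.users()),
                n_true=c.final_size,
                s_final=gt.mask(set(c.users())),
                zm=zm,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------


class Adam:
    """Adaptive moment estimation over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, clip_norm: float = 5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        if self.clip_norm:
            total = np.sqrt(sum(float((p.grad**2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def predict_sizes(model: SpilloverGNN, gt: GraphTensors, attrs: NodeAttributes,
                  samples: list[CascadeSample], chunk: int = 64) -> np.ndarray:
    """Predicted final sizes for a sample list (batched forward)."""
    out = []
    for lo in range(0, len(samples), chunk):
        part = samples[lo : lo + chunk]
        s = model.forward_batch(
            gt, attrs, [p.prefix_users for p in part],
            [p.zm for p in part] if model.se else None,
        )
        out.append(s.data.sum(axis=0))
    return np.concatenate(out)


def _eval_mrse(model: SpilloverGNN, gt: GraphTensors, attrs: NodeAttributes,
               samples: list[CascadeSample]) -> float:
    preds = predict_sizes(model, gt, attrs, samples)
    return evaluate(preds, [s.n_true for s in samples]).mrse


def train(
    model: SpilloverGNN,
    gt: GraphTensors,
    attrs: NodeAttributes,
    train_samples: list[CascadeSample],
    val_samples: list[CascadeSample] | None = None,
    config: LossConfig | None = None,
    seed: int = 0,
) -> list[dict]:
    """Minimise the total loss over mini-batches of cascades.

    Early-stops when validation MRSE has not improved for ``patience``
    epochs and restores the best parameters.  Returns the per-epoch
    history (train loss, validation MRSE).  A non-finite loss aborts
    with diagnostics.
    """
    config = config or LossConfig()
    rng = np.random.default_rng(seed)
    opt = Adam(model.params.tensors(), lr=config.lr)
    history: list[dict] = []
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        for lo in range(0, len(order), config.batch_size):
            batch = [train_samples[i] for i in order[lo : lo + config.batch_size]]
            opt.zero_grad()
            st, logits, masks = model.forward_batch(
                gt, attrs, [s.prefix_users for s in batch],
                [s.zm for s in batch] if model.se else None,
                with_logits=True,
            )
            preds = st.sum(axis=0)  # (B,)
            s_true = np.stack([s.s_final for s in batch], axis=1)
            loss = mrse_loss(preds, np.array([s.n_true for s in batch]))
            if config.theta > 0:
                loss = loss + config.theta * model.params.l2()
            if config.lambda_reg > 0:
                loss = loss + config.lambda_reg * user_ce_from_logits(logits, s_true, masks)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r} "
                    f"(lr={config.lr}, theta={config.theta})"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        rec = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_samples:
            val_mrse = _eval_mrse(model, gt, attrs, val_samples)
            rec["val_mrse"] = val_mrse
            if val_mrse < best_val - 1e-12:
                best_val, stale = val_mrse, 0
                best_state = {k: t.data.copy() for k, t in model.params.items()}
            else:
                stale += 1
        history.append(rec)
        logger.debug("epoch %d: %s", epoch, rec)
        if val_samples and stale >= config.patience:
            break

    if best_state is not None:
        for k, t in model.params.items():
            t.data = best_state[k]
    return history


#: Per-family optimisation settings for the benchmark comparison, fixed
#: after pilot runs on tuning seeds (10-12): the coupled models prefer a
#: livelier rate with light L2; the convolutional models a slower rate
#: with stronger L2.
BENCHMARK_LOSS_CONFIGS = {
    "coupled": LossConfig(lr=0.02, theta=1e-5, lambda_reg=0.5,
                          batch_size=10, epochs=30, patience=8),
    "convolutional": LossConfig(lr=0.01, theta=1e-3, lambda_reg=0.5,
                                batch_size=10, epochs=40, patience=10),
}


def run_prediction_experiment(
    seed: int,
    variants: tuple[str, ...] = ("CGNN", "SE-CGNN", "GCN", "SE-GCN"),
    sim_config=None,
    d_text: int = 16,
    d_struct: int = 8,
    k: int = 2,
    hidden: int = 12,
    head_dim: int = 8,
    loss_config: LossConfig | None = None,
    min_size: int = 3,
    n_inits: int = 2,
) -> dict[str, float]:
    """Train each variant on one synthetic benchmark; return test MRSE.

    The benchmark mixes preventive-measure cascades carrying a planted
    spillover effect (b1 = 1) with background cascades that spread at the
    base rate only, builds node attributes (TE-integrated past-message
    summaries + structural embeddings), trains every listed variant on
    the same 80/10/10 split, and scores the held-out test cascades.
    Each variant is trained ``n_inits`` times from different
    initialisations and the size predictions averaged, damping
    optimisation noise.  Unless overridden, the optimisation settings
    come from :data:`BENCHMARK_LOSS_CONFIGS` per model family.
    Everything derives from ``seed``, so comparisons between variants
    are paired like-for-like.
    """
    from .features import (
        build_node_attributes,
        encode_messages,
        past_message_summaries,
        structural_embed,
    )
    from .graph_data import filter_min_size
    from .synthetic import SimConfig, simulate

    cfg = sim_config or SimConfig(
        n_users=300,
        n_cascades=1000,
        pm_root_fraction=0.3,
        b0=-2.0,
        b1=1.0,
        background_weight=40.0,
        pm_weight=6.0,
        rate=5.0,
        step_seconds=3600.0,
        seed=seed,
    )
    data = simulate(cfg)
    cascades, _ = filter_min_size(data.cascades, min_size=min_size)
    if len(cascades) < 30:
        raise RuntimeError(f"benchmark produced only {len(cascades)} usable cascades")

    gt = GraphTensors(data.graph)
    summaries = past_message_summaries(
        data.store, gt.nodes, d_text=d_text, variant="TE"
    )
    embeddings = structural_embed(data.graph, d_struct=d_struct, seed=seed)
    attrs = build_node_attributes(set(), summaries, embeddings, gt.nodes)
    roots = [c.root_message for c in cascades]
    Z = encode_messages([data.store.get(r).text for r in roots], d_text=d_text)
    zs = dict(zip(roots, Z))

    tr_c, va_c, te_c = split_cascades(cascades, SplitSpec(seed=seed))
    mk = lambda cs: make_samples(gt, cs, zs)
    tr, va, te = mk(tr_c), mk(va_c), mk(te_c)
    results: dict[str, float] = {}
    for variant in variants:
        family = "coupled" if variant.endswith("CGNN") else "convolutional"
        lcfg = loss_config or BENCHMARK_LOSS_CONFIGS[family]
        preds = []
        for j in range(n_inits):
            init = seed + 1000 * j
            model = SpilloverGNN(variant, d_text, d_struct, k=k, hidden=hidden,
                                 head_dim=head_dim, seed=init)
            train(model, gt, attrs, tr, va, lcfg, seed=init)
            preds.append(predict_sizes(model, gt, attrs, te))
        results[variant] = evaluate(
            np.mean(preds, axis=0), [s.n_true for s in te]
        ).mrse
    return results


def grid_search(
    make_model,
    gt: GraphTensors,
    attrs: NodeAttributes,
    train_samples: list[CascadeSample],
    val_samples: list[CascadeSample],
    base_config: LossConfig | None = None,
    thetas: tuple = (1e-5,),
    lrs: tuple = (0.01,),
    batch_sizes: tuple = (10,),
    ks: tuple = (3,),
    seed: int = 0,
) -> tuple[SpilloverGNN, LossConfig, list[dict]]:
    """Validation-selected configuration over the supplied grids.

    ``make_model(k)`` must return a fresh model with ``k`` layers.  The
    canonical full grids are available as module constants; callers pass
    the subset they can afford.
    """
    base = base_config or LossConfig()
    best = (np.inf, None, None, None)
    for k in ks:
        for theta in thetas:
            for lr in lrs:
                for bs in batch_sizes:
                    cfg = replace(base, theta=theta, lr=lr, batch_size=bs)
                    model = make_model(k)
                    hist = train(model, gt, attrs, train_samples, val_samples, cfg, seed=seed)
                    val = _eval_mrse(model, gt, attrs, val_samples)
                    if val < best[0]:
                        best = (val, model, cfg, hist)
    _, model, cfg, hist = best
    return model, cfg, hist
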