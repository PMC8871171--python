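# spillcast

Spillover-aware analysis and prediction of information cascades on social
media, built for the epidemic-era ("infodemic") setting in which the content a
user has been *exposed to* changes whether they relay preventive-measure
messages — masks, lockdowns, social distancing — onward.

The package has two halves, for two audiences:

* **Validation** (computational social scientists): quantify the
  *info-exposure spillover effect*. A user is exposed to a message if they
  posted it or a followee did. For a user group `V_i` with control `V_c`, the
  *adoption likelihood* is `α(V_i) = |V_i ∩ PM| / |V_i|` — the fraction who
  ever participated in a preventive-measure (PM) cascade — and the *spillover
  elasticity* is

  ```
  ε = (α(V_i) − α(V_c)) / α(V_c)
  ```

  ε > 0 means the group's common exposure raises PM adoption. Groups are built
  from keyword-tagged exposure profiles: exposed/unexposed per topic, or
  exclusive topic pairs (for k topics: k(k−1)/2 pairs + k singles + 1
  control).

* **Prediction** (applied ML): estimate a cascade's final size `n_∞` from its
  observed 3-hour prefix `C_m^t`. Three GNN families — GCN, GAT and the
  coupled activation/influence model CGNN — are implemented in a plain,
  structure-only form and a spillover-extended (**SE-**) form whose node
  inputs carry `h⁰ = s ∥ δ ∥ e` (activation status, past-message summary,
  structural embedding) and whose activation head or influence gate also sees
  the diffused message's embedding `z_m`. The readout is `ñ_∞ = Σ_v s̃_v` with
  observed adopters pinned to 1. Training minimises

  ```
  L = MRSE + θ Σ‖p‖² + λ_reg · L_user,   MRSE = mean(((ñ−n)/n)²)
  ```

  with `L_user` a per-node cross-entropy on final activation statuses.
  Evaluation reports MRSE, MAPE and WroPerc (share of cascades with relative
  error ≥ 0.5).

A synthetic-data generator closes the loop: follower graphs, keyword-bearing
timelines, and independent-cascade diffusion whose adoption probability is
`sigmoid(b0 + Σ_T b1[T]·exposed_T(v))` for PM messages — a *planted*,
recoverable spillover effect.

Everything runs on numpy/scipy (a small reverse-mode autodiff core drives the
GNNs); no GPU or deep-learning framework is required.

## Worked example

Simulate the standard benchmark (2,000 users, 3,000 cascades, planted
spillover coefficient `b1 = 1`) and recover the per-topic elasticities
end-to-end — exposure tagging, group construction, adoption likelihoods:

```python
from spillcast import SimConfig, simulate, recover_elasticity

data = simulate(SimConfig(n_users=2000, b1=1.0, seed=7))
table = recover_elasticity(data)
print(table.round(3).to_string(index=False))
```

```
topic  n_exposed  n_unexposed  alpha_exposed  alpha_unexposed  elasticity
    U        292         1708          0.318            0.319      -0.002
   PB        359         1641          0.343            0.314       0.092
   SC        281         1719          0.367            0.311       0.178
  SAH        400         1600          0.432            0.291       0.488
  BLM        313         1687          0.482            0.289       0.671
    L        291         1709          0.388            0.307       0.264
```

Each row is one analysis topic (unemployment, panic buying, school closures,
stop-Asian-hate, black-lives-matter, loneliness). With a planted effect every
exposed group adopts PM messages more often than its unexposed control
(positive elasticities, mean 0.28 here); rerunning with `b1=0.0` drives them
to zero within sampling noise, and larger `b1` raises them monotonically.

The same machinery works from the shell on emitted files:

```bash
spillcast simulate --seed 7 --users 2000 --out data/
spillcast validate-spillover --data data/ --out table.tsv
spillcast featurize --data data/ --out feats/ --d-text 32 --d-struct 16
spillcast train --data data/ --features feats/ --variant SE-CGNN --out model/
spillcast evaluate --data data/ --features feats/ --checkpoint model/ --out eval.tsv
```

## Layout

| module | contents |
| --- | --- |
| `spillcast.graph_data` | graphs, messages, cascades; construction, filtering, observation windows, plain-text I/O |
| `spillcast.spillover` | topic lexicons, exposure profiles, group sets, adoption likelihood, elasticity |
| `spillcast.features` | text hashing encoder, TE/Mean/Hawkes/GRU temporal integration, rel/unrel blending, walk-based structural embeddings |
| `spillcast.models` | GCN/GAT/CGNN layers, SE activation head and influence gate, popularity readout, checkpoints |
| `spillcast.training` | losses, splits, Adam, training loop, benchmark experiment |
| `spillcast.metrics` | MRSE / MAPE / WroPerc evaluation reports |
| `spillcast.synthetic` | graph/timeline/diffusion generators with planted ground truth |
| `spillcast.cli` | `spillcast` command-line entry point |

See `docs/methods.md` for the model assumptions, parameter choices and known
limitations.
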