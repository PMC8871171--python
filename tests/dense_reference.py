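"""Dense, loop-based reference implementations of the GNN layers.

Deliberately naive (per-node Python loops over a dense adjacency view)
and written independently of the package's sparse message-passing code,
so the two can be compared on small fixtures.
"""

import numpy as np


def leaky(x, slope=0.01):
    return np.where(x > 0, x, slope * x)


def closed_neighbors(gt, v):
    """Indices aggregated by node v: its followees plus itself."""
    out = [u for u, d in zip(gt.closed_src, gt.closed_dst) if d == v]
    return sorted(out)


def dense_gcn_layer(gt, H, W):
    n = gt.n
    out = np.zeros((n, W.shape[1]))
    for v in range(n):
        nb = closed_neighbors(gt, v)
        agg = np.mean([H[u] for u in nb], axis=0)
        out[v] = leaky(W.T @ agg)
    return out


def dense_gat_layer(gt, H, W, gamma):
    n, h = gt.n, W.shape[1]
    g_u, g_v = gamma[:h], gamma[h:]
    out = np.zeros((n, h))
    for v in range(n):
        nb = closed_neighbors(gt, v)
        scores = np.array(
            [leaky(g_u @ (H[u] @ W) + g_v @ (H[v] @ W)) for u in nb]
        )
        w = np.exp(scores - scores.max())
        w = w / w.sum()
        agg = sum(wi * H[u] for wi, u in zip(w, nb))
        out[v] = leaky(W.T @ agg)
    return out


def dense_gat_coefficients(gt, H, W, gamma):
    """Per-(closed-edge) attention coefficients, in gt edge order."""
    n, h = gt.n, W.shape[1]
    g_u, g_v = gamma[:h], gamma[h:]
    denom = {}
    raw = np.zeros(len(gt.closed_src))
    for e, (u, v) in enumerate(zip(gt.closed_src, gt.closed_dst)):
        raw[e] = leaky(g_u @ (H[u] @ W) + g_v @ (H[v] @ W))
    shift = {v: max(raw[e] for e in range(len(raw)) if gt.closed_dst[e] == v) for v in range(n)}
    ex = np.array([np.exp(raw[e] - shift[gt.closed_dst[e]]) for e in range(len(raw))])
    for e, v in enumerate(gt.closed_dst):
        denom[v] = denom.get(v, 0.0) + ex[e]
    return np.array([ex[e] / denom[gt.closed_dst[e]] for e in range(len(ex))])


def dense_coupled_forward(gt, params, mask, H0, k, se=False, zm=None):
    """Per-node loop version of the coupled state/influence recursion."""
    sig = lambda x: 1.0 / (1.0 + np.exp(-x))
    n = gt.n
    s = mask.astype(float).copy()
    r = H0.copy()
    in_edges = {v: [] for v in range(n)}
    for u, v in zip(gt.src, gt.dst):
        in_edges[v].append(u)
    for ell in range(k):
        W = params[f"cg_W{ell}"].data
        bu, bv = params[f"cg_bu{ell}"].data, params[f"cg_bv{ell}"].data
        mu_s, mu_a = float(params[f"mu_s{ell}"].data), float(params[f"mu_a{ell}"].data)
        p_v = float(params["p_v"].data)
        zterm = 0.0
        if se:
            zterm = params[f"cg_bz{ell}"].data @ (zm @ params["W_z"].data)
        s_new = np.zeros(n)
        for v in range(n):
            a = p_v
            for u in in_edges[v]:
                gate = bu @ (r[u] @ W) + bv @ (r[v] @ W) + zterm
                a += gate * s[u]
            s_new[v] = 1.0 if mask[v] else sig(mu_s * s[v] + mu_a * a)
        if ell < k - 1:
            Wself = params[f"cg_Wself{ell}"].data
            Wnb = params[f"cg_Wnb{ell}"].data
            gam = params[f"cg_gr{ell}"].data
            d = r.shape[1]
            g_u, g_v = gam[:d], gam[d:]
            r_new = np.zeros((n, Wself.shape[1]))
            for v in range(n):
                acc = r[v] @ Wself
                if in_edges[v]:
                    att = np.array([leaky(g_u @ r[u] + g_v @ r[v]) for u in in_edges[v]])
                    w = np.exp(att - att.max())
                    w = w / w.sum()
                    for wi, u in zip(w, in_edges[v]):
                        acc = acc + wi * s[u] * (r[u] @ Wnb)
                r_new[v] = leaky(acc)
            r = r_new
        s = s_new
    return s
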