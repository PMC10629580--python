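"""Independent reference implementations used only to check the package.

Each oracle is written from the definitional formulas, not from the
package's code paths: the constant-rate likelihood is the classic
geometric-survival closed form, DCCA is the literal box-by-box sum,
branching times come from a plain root-to-tip traversal, and equal-splits
values from an explicit path walk.
"""

from __future__ import annotations

import math

import numpy as np

import chronodiv as cd


def nee_constant_rate_loglik(tree: cd.TimeTree, lam: float, mu: float) -> float:
    """Closed-form constant-rate reconstructed-tree log-likelihood with
    rho-sampling, conditioned on both crown lineages surviving."""
    f = tree.sampling_fraction
    r = lam - mu

    def p0(t: float) -> float:
        return 1.0 - f * r / (f * lam + (lam * (1 - f) - mu) * math.exp(-r * t))

    def p1(t: float) -> float:
        den = f * lam + (lam * (1 - f) - mu) * math.exp(-r * t)
        return f * r**2 * math.exp(-r * t) / den**2

    bt = cd.branching_times(tree)  # descending; bt[0] = crown age
    ll = 2.0 * math.log(p1(bt[0])) - 2.0 * math.log(1.0 - p0(bt[0]))
    for x in bt[1:]:
        ll += math.log(lam * p1(x))
    return ll


def brute_force_branching_times(tree: cd.TimeTree) -> np.ndarray:
    """Internal node ages recovered by independent root-to-tip traversal
    of the freshly re-parsed Newick string (via dendropy only)."""
    import dendropy

    t = dendropy.Tree.get(data=tree.write_newick(), schema="newick")
    t.calc_node_ages(ultrametricity_precision=1e-4)
    ages = [nd.age for nd in t.preorder_node_iter() if len(nd.child_nodes()) == 2]
    return np.sort(np.asarray(ages))[::-1]


def brute_force_ltt(tree: cd.TimeTree, grid: np.ndarray) -> np.ndarray:
    """Lineage counts by explicit edge-interval membership, evaluated an
    instant after each age (a split at age a has already happened at a):
    an edge with child age c and parent age p is extant iff c < a <= p.
    At the present every tip edge is extant."""
    edges = tree.edges(crown_only=True)
    out = []
    for a in grid:
        if a <= 0.0:
            out.append(tree.n_tips)
        else:
            out.append(int(np.sum((edges[:, 0] < a) & (a <= edges[:, 1]))))
    return np.asarray(out)


def brute_force_dcca(x: np.ndarray, y: np.ndarray, box: int) -> float:
    """Definitional DCCA: integrate, slide boxes, least-squares detrend
    each box with np.polyfit, average the residual moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.cumsum(x - x.mean())
    Y = np.cumsum(y - y.mean())
    t = np.arange(box, dtype=float)
    f2x, f2y, f2xy = [], [], []
    for i in range(len(x) - box + 1):
        xb, yb = X[i : i + box], Y[i : i + box]
        rx = xb - np.polyval(np.polyfit(t, xb, 1), t)
        ry = yb - np.polyval(np.polyfit(t, yb, 1), t)
        f2x.append(np.mean(rx * rx))
        f2y.append(np.mean(ry * ry))
        f2xy.append(np.mean(rx * ry))
    return float(np.mean(f2xy) / math.sqrt(np.mean(f2x) * np.mean(f2y)))


def path_walk_es(tree: cd.TimeTree) -> dict[str, float]:
    """Equal-splits by explicit tip-to-root path enumeration on the parsed
    Newick (independent of the package's array walk)."""
    import dendropy

    t = dendropy.Tree.get(data=tree.write_newick(), schema="newick",
                          preserve_underscores=True)
    out = {}
    for leaf in t.leaf_node_iter():
        val, w, nd = 0.0, 1.0, leaf
        while nd.parent_node is not None:
            val += nd.edge.length * w
            w *= 0.5
            nd = nd.parent_node
        out[leaf.taxon.label] = val
    return out
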