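"""Minimal random survival tree grower with log-rank splitting.

Grows binary survival trees in the style of randomForestSRC: at each node a
random subset of mtry candidate variables is tried, each with up to
``n_split`` random split points, and the split maximizing the standardized
log-rank statistic wins.  The grower exposes full tree topology (node depths
and split variables), which the minimal-depth selection rule needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurvivalTree", "grow_tree", "null_depth_distribution",
           "null_depth_mean"]


@dataclass
class _Node:
    depth: int
    n: int
    feature: int = -1  # -1 for terminal
    threshold: float = np.nan
    left: int = -1
    right: int = -1


@dataclass
class SurvivalTree:
    nodes: list = field(default_factory=list)

    @property
    def depth(self) -> int:
        """D(S): depth of the deepest node (root = 0)."""
        return max(nd.depth for nd in self.nodes)

    def nodes_at_depth(self) -> np.ndarray:
        """l_d for d = 0..D(S): number of nodes at each depth."""
        counts = np.zeros(self.depth + 1, dtype=int)
        for nd in self.nodes:
            counts[nd.depth] += 1
        return counts

    def minimal_depths(self, p: int) -> np.ndarray:
        """Per-variable minimal depth; D(S) for variables never split on."""
        out = np.full(p, float(self.depth))
        for nd in self.nodes:
            if nd.feature >= 0 and nd.depth < out[nd.feature]:
                out[nd.feature] = nd.depth
        return out


def _logrank_stats(time, event, groups):
    """Standardized log-rank statistics for column-wise group-1 indicators.

    ``time``/``event`` are node data sorted by ascending time; ``groups`` is
    an (n, m) boolean matrix, one candidate split per column.  Returns |Z|
    per column (0 where the variance is degenerate).
    """
    n, m = groups.shape
    # at-risk counts at each row's time: suffix sums over the sorted order
    ones = np.ones(n)
    Y = np.cumsum(ones[::-1])[::-1]
    Y1 = np.cumsum(groups[::-1].astype(float), axis=0)[::-1]
    # collapse tied times: use counts at the first index of each tie group
    first = np.empty(n, dtype=bool)
    first[0] = True
    first[1:] = time[1:] > time[:-1]
    gidx = np.maximum.accumulate(np.where(first, np.arange(n), 0))
    # aggregate events per distinct time (tie group), overall and in group 1
    d_rows = event.astype(float)
    uniq = np.flatnonzero(first)
    d = np.add.reduceat(d_rows, uniq)
    d1 = np.add.reduceat(d_rows[:, None] * groups, uniq, axis=0)
    y = Y[uniq]
    y1 = Y1[uniq]
    frac = y1 / y[:, None]
    num = (d1 - frac * d[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = (d * (y - d) / np.maximum(y - 1, 1))[:, None] * frac * (1 - frac)
    var = np.where(y[:, None] > 1, vterm, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, np.abs(num) / np.sqrt(var), 0.0)
    return z


def grow_tree(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    rng: np.random.Generator,
    mtry: int,
    n_split: int = 10,
    nodesize: int = 15,
    max_depth: int = 50,
) -> SurvivalTree:
    """Grow one survival tree on (already bootstrapped) data."""
    n, p = X.shape
    tree = SurvivalTree()

    def build(idx, depth):
        node_id = len(tree.nodes)
        tree.nodes.append(_Node(depth=depth, n=idx.size))
        node = tree.nodes[node_id]
        if (depth >= max_depth or idx.size < 2 * nodesize
                or event[idx].sum() == 0):
            return node_id
        order = idx[np.argsort(time[idx], kind="stable")]
        t_s, e_s = time[order], event[order]
        feats = rng.choice(p, size=min(mtry, p), replace=False)
        best = (0.0, -1, np.nan)
        for f in feats:
            xv = X[order, f]
            lo, hi = xv.min(), xv.max()
            if hi <= lo:
                continue
            thresholds = np.unique(rng.uniform(lo, hi, size=n_split))
            groups = xv[:, None] <= thresholds[None, :]
            # drop splits that put everything on one side
            sizes = groups.sum(axis=0)
            keep = (sizes > 0) & (sizes < idx.size)
            if not keep.any():
                continue
            z = _logrank_stats(t_s, e_s, groups[:, keep])
            k = int(np.argmax(z))
            if z[k] > best[0]:
                best = (float(z[k]), int(f), float(thresholds[keep][k]))
        if best[1] < 0:
            return node_id
        _, f, thr = best
        mask = X[idx, f] <= thr
        node.feature, node.threshold = f, thr
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node_id

    build(np.arange(n), 0)
    return tree


def null_depth_distribution(l_counts: np.ndarray, p: int) -> np.ndarray:
    """Null distribution of the minimal depth of a noise variable.

    Given tree topology (l_counts[d] = number of nodes at depth d,
    d = 0..D(S)) and p candidate variables, the probability that a noise
    variable's minimal depth equals d < D(S) is
    (1 - 1/p)^{L_d} (1 - (1 - 1/p)^{l_d}) with L_d = l_0 + ... + l_{d-1},
    and the remaining mass sits at D(S).
    """
    l_counts = np.asarray(l_counts, dtype=float)
    D = l_counts.size - 1
    q = 1.0 - 1.0 / p
    L = np.concatenate([[0.0], np.cumsum(l_counts[:-1])])
    probs = np.empty(D + 1)
    probs[:D] = q ** L[:D] * (1.0 - q ** l_counts[:D])
    probs[D] = 1.0 - probs[:D].sum()
    return probs


def null_depth_mean(l_counts: np.ndarray, p: int) -> float:
    probs = null_depth_distribution(l_counts, p)
    return float(np.arange(probs.size) @ probs)
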