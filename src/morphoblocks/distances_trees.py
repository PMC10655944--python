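"""Distance matrices, Mantel tests and neighbor-joining phenograms.

Morphometric divergence between groups is summarised by the Mahalanobis
distance between group means in the pooled within-group covariance metric,
with significance assessed by label permutation (group sizes per karyotype
can be as small as five, so a distribution-free test is the default).
Geographic separation uses great-circle distances between group centroid
coordinates.  The Mantel permutation test correlates the two matrices, and a
Saitou-Nei neighbor-joining tree turns the morphometric matrix into an
unrooted phenogram exportable as Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .shape_stats import SingularCovarianceError

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "other"

    def __post_init__(self) -> None:
        self.labels = tuple(map(str, self.labels))
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.labels)
        if self.values.shape != (m, m):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def m(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.m, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


def _group_stats(scores: np.ndarray, labels: np.ndarray):
    groups = sorted(map(str, np.unique(labels)))
    y = labels.astype(str)
    means, w, n = {}, np.zeros((scores.shape[1],) * 2), 0
    for g in groups:
        xg = scores[y == g]
        if xg.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        means[g] = xg.mean(axis=0)
        r = xg - means[g]
        w += r.T @ r
        n += xg.shape[0]
    pooled = w / (n - len(groups))
    return groups, means, pooled


def _pairwise_mahalanobis(groups, means, pooled) -> np.ndarray:
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(
            "singular pooled within-group covariance; reduce the number "
            "of PCs"
        ) from None
    m = len(groups)
    d = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        diff = means[groups[i]] - means[groups[j]]
        d2 = float(diff @ inv @ diff)
        d[i, j] = d[j, i] = np.sqrt(max(d2, 0.0))
    return d


def mahalanobis_matrix(scores: np.ndarray, labels: Sequence,
                       ) -> DistanceMatrix:
    """Mahalanobis distances between all group means.

    D(a, b) = sqrt((m_a - m_b)' S_pooled^-1 (m_a - m_b)) with S_pooled the
    pooled within-group covariance over *all* groups.  Affine-invariant:
    any common invertible linear map of the scores leaves D unchanged.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    groups, means, pooled = _group_stats(x, np.asarray(labels))
    return DistanceMatrix(tuple(groups),
                          _pairwise_mahalanobis(groups, means, pooled),
                          kind="mahalanobis")


def permutation_significance(scores: np.ndarray, labels: Sequence,
                             n_perm: int = 999,
                             seed: int | np.random.Generator | None = None,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Permutation p-values for each pairwise Mahalanobis distance.

    For every group pair the test statistic is the Mahalanobis distance
    computed from the pair's own specimens (pooled two-group covariance);
    labels are permuted within the pooled pair, and
    p = (1 + #{permuted D >= observed D}) / (n_perm + 1).  Significance
    flags apply the Bonferroni correction over all pairs.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(labels).astype(str)
    groups = sorted(np.unique(y))
    pairs = list(combinations(groups, 2))
    threshold = alpha / len(pairs)

    def pair_distance(xs: np.ndarray, ls: np.ndarray) -> float:
        gs, means, pooled = _group_stats(xs, ls)
        return float(_pairwise_mahalanobis(gs, means, pooled)[0, 1])

    rows = []
    for a, b in pairs:
        mask = np.isin(y, (a, b))
        xs, ls = x[mask], y[mask]
        n_a = int((ls == a).sum())
        observed = pair_distance(xs, ls)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(ls.size)
            pl = np.full(ls.size, b, dtype=ls.dtype)
            pl[perm[:n_a]] = a
            if pair_distance(xs, pl) >= observed:
                count += 1
        p = (1 + count) / (n_perm + 1)
        rows.append({"group_a": a, "group_b": b, "distance": observed,
                     "p": p, "significant": p < threshold})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_perm"] = n_perm
    return out


def haversine_km(lat1, lon1, lat2, lon2,
                 radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km on a spherical earth."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def geographic_matrix(labels: Sequence, lats: Sequence, lons: Sequence,
                      ) -> DistanceMatrix:
    """Great-circle distance matrix between group centroid coordinates.

    Multiple specimens sharing a label are reduced to their mean lat/lon.
    Missing coordinates raise, naming the offending positions.
    """
    y = np.asarray(labels).astype(str)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    missing = [str(lbl) for lbl, la, lo in zip(y, lats, lons)
               if not (np.isfinite(la) and np.isfinite(lo))]
    if missing:
        raise ValueError(f"missing coordinates for: {sorted(set(missing))}")
    groups = sorted(np.unique(y))
    cent = {g: (lats[y == g].mean(), lons[y == g].mean()) for g in groups}
    m = len(groups)
    d = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        d[i, j] = d[j, i] = haversine_km(*cent[groups[i]], *cent[groups[j]])
    return DistanceMatrix(tuple(groups), d, kind="geographic")


def mantel_test(m1: DistanceMatrix, m2: DistanceMatrix,
                n_perm: int = 999,
                seed: int | np.random.Generator | None = None,
                alternative: str = "greater") -> tuple[float, float]:
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation over the m(m-1)/2 upper-triangle entries;
    the null distribution comes from simultaneous row/column permutations of
    the second matrix.  The default one-tailed 'greater' alternative is the
    isolation-by-distance direction; 'less' and 'two-sided' are available.
    """
    if m1.labels != m2.labels:
        raise ValueError(
            f"label mismatch between matrices: {m1.labels} vs {m2.labels}"
        )
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    a = m1.upper_triangle()
    iu = np.triu_indices(m1.m, k=1)
    b = m2.values[iu]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a distance matrix triangle")
    az = (a - a.mean()) / a.std()

    def corr(bvec: np.ndarray) -> float:
        return float(np.mean(az * ((bvec - bvec.mean()) / bvec.std())))

    r_obs = corr(b)
    # epsilon guards the >= tie against round-off: a permutation equal to
    # the identity must count as at least as extreme
    eps = 1e-12
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m1.m)
        r_perm = corr(m2.values[np.ix_(perm, perm)][iu])
        if alternative == "greater":
            hit = r_perm >= r_obs - eps
        elif alternative == "less":
            hit = r_perm <= r_obs + eps
        elif alternative == "two-sided":
            hit = abs(r_perm) >= abs(r_obs) - eps
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        if hit:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


@dataclass
class TreeNode:
    """Node of an unrooted phenogram; ``length`` is the branch to the parent."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree produced by neighbor joining.

    Stored with an arbitrary internal node as root; the root has three
    children (unrooted resolution), every other internal node two.  Branch
    lengths may be negative (NJ can produce them); they are kept as-is so
    path distances remain faithful to the input matrix.
    """

    root: TreeNode

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(lf.name for lf in self.root.leaves())

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (sorted labels)."""
        dists: dict[str, dict[str, float]] = {}

        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                below = {node.name: 0.0}
            else:
                below = {}
                sub = [collect(c) for c in node.children]
                for s1, s2 in combinations(sub, 2):
                    for l1, d1 in s1.items():
                        for l2, d2 in s2.items():
                            dists.setdefault(l1, {})[l2] = d1 + d2
                            dists.setdefault(l2, {})[l1] = d1 + d2
                for s in sub:
                    below.update(s)
            if node.length is not None:
                below = {k: v + node.length for k, v in below.items()}
            return below

        collect(self.root)
        labels = tuple(sorted(self.leaf_labels))
        m = len(labels)
        vals = np.zeros((m, m))
        for i, j in combinations(range(m), 2):
            vals[i, j] = vals[j, i] = dists[labels[i]][labels[j]]
        # numerical guard: NJ trees on noisy input can yield tiny negatives
        vals[vals < 0] = np.where(vals[vals < 0] > -1e-9, 0.0,
                                  vals[vals < 0])
        return DistanceMatrix(labels, vals, kind="other")


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q criterion.

    At each step the pair (i, j) minimising
    Q_ij = (r - 2) d_ij - R_i - R_j (with R the row sums over the r active
    nodes) is joined; ties are broken by the lexicographically lowest label
    pair.  Branch lengths follow the standard two- and three-point formulas
    and are not clamped: negative lengths are emitted with a warning.
    """
    if dm.m < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    labels: list[str] = list(dm.labels)
    d = dm.values.astype(float).copy()

    def tie_key(i: int, j: int) -> tuple[str, str]:
        return tuple(sorted((labels[i], labels[j])))

    internal_count = 0
    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        best, best_q = None, np.inf
        for i, j in combinations(range(r), 2):
            q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and best is not None
                and tie_key(i, j) < tie_key(*best)
            ):
                best, best_q = (i, j), q
        i, j = best
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            warnings.warn("neighbor joining produced a negative branch "
                          "length", RuntimeWarning)
        nodes[i].length, nodes[j].length = float(li), float(lj)
        internal_count += 1
        new_node = TreeNode(name=None, children=[nodes[i], nodes[j]])
        new_dist = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(r) if x not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_dist[keep]
        nodes = [nodes[x] for x in keep] + [new_node]
        labels = [labels[x] for x in keep] + [f"@internal{internal_count}"]
        d = d_new

    # three-point resolution around the final internal node
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    if min(la, lb, lc) < 0:
        warnings.warn("neighbor joining produced a negative branch length",
                      RuntimeWarning)
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    return PhyloTree(root=TreeNode(name=None, children=[a, b, c]))


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        body = node.name or ""
    else:
        body = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
    if node.length is not None:
        return f"{body}:{node.length:.6g}"
    return body


def write_newick(tree: PhyloTree) -> str:
    """Serialise a tree to Newick with 6-significant-digit branch lengths."""
    if any(lf.length is not None and lf.length < 0
           for lf in _iter_nodes(tree.root)):
        warnings.warn("writing tree with negative branch length(s)",
                      RuntimeWarning)
    return _newick_node(tree.root) + ";"


def _iter_nodes(node: TreeNode):
    yield node
    for c in node.children:
        yield from _iter_nodes(c)
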