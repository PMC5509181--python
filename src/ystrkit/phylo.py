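"""Neighbor-joining trees and non-metric MDS from genetic distance matrices.

Both consumers require dissimilarities, while AMOVA R_ST matrices routinely
contain small negative entries (sampling noise around zero differentiation),
so matrices are clamped at zero first, with the number of clamped cells
recorded.

Neighbor joining follows Saitou & Nei: repeatedly join the pair minimizing
the Q-criterion, assign branch lengths by the three-point formulas, and
reduce the matrix, leaving a final unrooted trifurcation.  Negative branch
lengths are kept by default (they are what makes NJ exact on additive
matrices); an optional MEGA-style clamp zeroes them and transfers the
length to the adjacent branch.

Non-metric MDS is Kruskal's: start from the classical (Torgerson) scaling
configuration, then alternate monotone (isotonic) regression of the
configuration distances on the input dissimilarity order with line-searched
Guttman updates of the coordinates, minimizing stress-1 =
sqrt(sum (d - dhat)^2 / sum d^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .core import ValidationError


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: Tuple[str, ...]
    d: np.ndarray
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if np.any(np.isnan(self.d)):
            raise ValidationError("distance matrix contains NaN")
        if np.max(np.abs(self.d - self.d.T)) > 1e-9:
            raise ValidationError("distance matrix is asymmetric beyond 1e-9")
        if np.max(np.abs(np.diag(self.d))) > 1e-12:
            raise ValidationError("distance matrix diagonal must be zero")


def clamp_distances(matrix: DistanceMatrix) -> DistanceMatrix:
    """Set negative entries to zero; idempotent; clamp count recorded."""
    d = np.asarray(matrix.d, dtype=float)
    negative = d < 0
    n_clamped = int(negative.sum())
    out = np.where(negative, 0.0, d)
    return DistanceMatrix(labels=matrix.labels, d=out,
                          n_clamped=matrix.n_clamped + n_clamped)


def distance_from_rst(result) -> DistanceMatrix:
    """Clamped distance matrix from an :class:`~ystrkit.amova.RstResult`."""
    return clamp_distances(DistanceMatrix(labels=tuple(result.labels), d=result.rst))


@dataclass
class TreeNode:
    name: Optional[str]
    length: float = 0.0  # branch length to parent; 0 for the root
    children: List["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored as a rooted structure with a trifurcating root."""

    root: TreeNode
    labels: Tuple[str, ...]

    @property
    def sbl(self) -> float:
        return sum_branch_lengths(self)

    def leaves(self) -> List[TreeNode]:
        out: List[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out


def neighbor_joining(matrix: DistanceMatrix, clamp_negative_branches: bool = False) -> Tree:
    """Saitou-Nei neighbor joining.

    Deterministic: Q-criterion ties are broken by the lowest-index pair.
    ``clamp_negative_branches`` applies the MEGA-style convention of zeroing
    negative branch lengths and transferring the deficit to the sibling
    branch (disabled by default so additive matrices are recovered exactly).
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValidationError("neighbor joining needs >= 3 labels")
    if np.any(np.isnan(matrix.d)):
        raise ValidationError("distance matrix contains NaN")
    d = matrix.d.astype(float).copy()
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: argmin of the flattened matrix scans rows first
        flat = np.argmin(q)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if clamp_negative_branches:
            if li < 0:
                lj, li = lj + li, 0.0
            if lj < 0:
                li, lj = li + lj, 0.0
        nodes[i].length = li
        nodes[j].length = lj
        new_node = TreeNode(name=None, children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1))
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = d_next[:-1, -1] = new_d[keep]
        d_next[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new_node]
        d = d_next

    # final trifurcation: three-point formulas
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    nodes[0].length = 0.5 * (d01 + d02 - d12)
    nodes[1].length = 0.5 * (d01 + d12 - d02)
    nodes[2].length = 0.5 * (d02 + d12 - d01)
    if clamp_negative_branches:
        for node in nodes:
            if node.length < 0:
                node.length = 0.0
    root = TreeNode(name=None, children=list(nodes))
    return Tree(root=root, labels=tuple(labels))


def sum_branch_lengths(tree: Tree) -> float:
    """Arithmetic sum of all branch lengths, internal branches included."""
    total = 0.0

    def walk(node: TreeNode) -> None:
        nonlocal total
        for c in node.children:
            total += c.length
            walk(c)

    walk(tree.root)
    return total


def _quote_label(name: str) -> str:
    if any(ch in name for ch in " ()[]':;,"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: Tree) -> str:
    """Newick string with branch lengths at full precision."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{_quote_label(node.name)}:{node.length:.17g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.17g}"

    inner = ",".join(render(c) for c in tree.root.children)
    return f"({inner});"


def patristic_distances(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances along the tree."""
    dists: Dict[str, Dict[str, float]] = {}

    def walk(node: TreeNode) -> Dict[str, float]:
        """Distances from every leaf under `node` up to `node`."""
        if node.is_leaf:
            return {node.name: 0.0}
        below: List[Dict[str, float]] = []
        for c in node.children:
            sub = walk(c)
            below.append({leaf: dist + c.length for leaf, dist in sub.items()})
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for la, da in below[a].items():
                    for lb, db in below[b].items():
                        dists.setdefault(la, {})[lb] = da + db
                        dists.setdefault(lb, {})[la] = da + db
        merged: Dict[str, float] = {}
        for sub in below:
            merged.update(sub)
        return merged

    walk(tree.root)
    labels = tree.labels
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = dists[a][b]
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class MDSResult:
    """2-D (by default) embedding of a dissimilarity matrix."""

    labels: Tuple[str, ...]
    coordinates: np.ndarray
    stress: float
    stress_initial: float
    stress_history: List[float]
    n_iterations: int
    converged: bool
    seed: int


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the double-centered matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def _stress1(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom <= 0.0:
        return 0.0
    return float(np.sqrt(np.sum((dist - disp) ** 2) / denom))


def nmds(
    matrix: DistanceMatrix,
    dims: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MDSResult:
    """Kruskal non-metric MDS with Kruskal stress-1.

    Initializes from classical scaling (with a tiny seeded jitter only if
    that configuration is degenerate), then alternates isotonic regression
    of configuration distances on the dissimilarity order with Guttman
    coordinate updates; a backtracking line search on each update keeps the
    recorded stress history non-increasing.  Iteration stops when the
    improvement falls below ``tol`` or no improving step exists.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValidationError("NMDS needs >= 3 labels")
    if dims >= n:
        raise ValidationError("dims must be smaller than the number of labels")
    delta = squareform(matrix.d, checks=False)  # condensed dissimilarities
    if np.all(delta == 0):
        raise ValidationError("all dissimilarities are zero")
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)

    x = _classical_scaling(matrix.d, dims)
    if np.allclose(pdist(x), 0.0):
        rng = np.random.default_rng(seed)
        x = x + rng.normal(scale=1e-6 * (delta.max() or 1.0), size=x.shape)

    def disparities(dist: np.ndarray) -> np.ndarray:
        dhat = np.empty_like(dist)
        dhat[order] = iso.fit_transform(np.arange(len(order)), dist[order])
        return dhat

    dist = pdist(x)
    dhat = disparities(dist)
    stress = _stress1(dist, dhat)
    stress_initial = stress
    history = [stress]
    converged = False
    n_iter = 0
    eps = 1e-12

    for n_iter in range(1, max_iter + 1):
        # Guttman transform for current disparities
        dist_sq = squareform(dist, checks=False)
        dhat_sq = squareform(dhat, checks=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist_sq > eps, dhat_sq / np.maximum(dist_sq, eps), 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x_guttman = (b @ x) / n

        improved = False
        step = 1.0
        for _ in range(12):
            x_cand = x + step * (x_guttman - x)
            dist_cand = pdist(x_cand)
            dhat_cand = disparities(dist_cand)
            stress_cand = _stress1(dist_cand, dhat_cand)
            if stress_cand < stress:
                x, dist, dhat = x_cand, dist_cand, dhat_cand
                improvement = stress - stress_cand
                stress = stress_cand
                history.append(stress)
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True
            break
        if improvement < tol:
            converged = True
            break

    return MDSResult(
        labels=matrix.labels,
        coordinates=x,
        stress=stress,
        stress_initial=stress_initial,
        stress_history=history,
        n_iterations=n_iter,
        converged=converged,
        seed=seed,
    )
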