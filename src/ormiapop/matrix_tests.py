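"""Matrix-level inference: Mantel tests, partial Mantel tests, and a
neighbor-joining population tree.

Mantel tests correlate the upper-triangle vectors of two labelled distance
matrices (aligned by label) and build the null by simultaneously permuting
the rows and columns of the second matrix.  p-values are one-sided for
positive association with the +1 correction, so the smallest attainable p is
``1/(n_perm + 1)``.

The partial Mantel conditions on a third matrix by correlating the residuals
of simple linear regressions of each matrix's triangle on the third's.  Two
non-equivalent permutation schemes circulate in the literature; the default
here permutes the labels of the response matrix and recomputes the residual
correlation (raw-data permutation), with residual permutation available
behind a flag.

Neighbor joining follows Saitou & Nei's Q-criterion with a deterministic
lowest-label-pair tie-break; negative branch lengths are clamped to zero
with the deficit moved onto the sister branch so path lengths are conserved.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .matrices import DistanceMatrix

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "MantelResult",
    "PopulationTree",
    "TreeNode",
    "mantel",
    "partial_mantel",
    "neighbor_joining",
    "geographic_distances",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    conditioned_on: str | None = None
    permutation_scheme: str = "raw"

    def __repr__(self):
        cond = f" | {self.conditioned_on}" if self.conditioned_on else ""
        return f"MantelResult(r={self.r:.4f}, p={self.p:.4g}{cond})"


def _aligned_triangles(*dms: DistanceMatrix) -> list[np.ndarray]:
    ref = dms[0]
    if ref.n < 4:
        raise ValueError("Mantel tests need >= 4 labels")
    vecs = []
    for dm in dms:
        if set(dm.labels) != set(ref.labels):
            raise ValueError(
                f"label mismatch: {sorted(set(dm.labels) ^ set(ref.labels))}"
            )
        vecs.append(dm.reorder(ref.labels).condensed())
    for v in vecs:
        if np.std(v) == 0:
            raise ValueError("zero-variance distance triangle; Mantel r undefined")
    return vecs


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt((xc @ xc) * (yc @ yc))
    if den == 0.0:
        # a zero-variance residual vector is orthogonal to everything
        return 0.0
    return float(xc @ yc / den)


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test of matrix association, one-sided for positive r.

    ``exhaustive`` enumerates all n! simultaneous row/column permutations of
    dm2 (identity included, so p >= 1/n!) instead of Monte-Carlo sampling;
    only sensible for small n.
    """
    v1, v2 = _aligned_triangles(dm1, dm2)
    m2 = dm2.reorder(dm1.labels).values
    n = dm1.n
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson(v1, v2)
    if exhaustive:
        perms = list(itertools.permutations(range(n)))
        count = 0
        for perm in perms:
            idx = np.asarray(perm)
            r_p = _pearson(v1, m2[np.ix_(idx, idx)][iu])
            if r_p >= r_obs - 1e-12:
                count += 1
        return MantelResult(r_obs, count / len(perms), len(perms), None)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_p = _pearson(v1, m2[np.ix_(idx, idx)][iu])
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, seed)


def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of the simple linear regression of y on x (with intercept)."""
    xc = x - x.mean()
    beta = (xc @ (y - y.mean())) / (xc @ xc)
    return y - (y.mean() + beta * xc)


def partial_mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    dm3: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    permutation_scheme: str = "raw",
) -> MantelResult:
    """Partial Mantel: correlation of dm1 with dm2 conditioned on dm3.

    The statistic is the Pearson correlation of the residuals of vec(dm1) on
    vec(dm3) with the residuals of vec(dm2) on vec(dm3).  Null schemes:
    ``raw`` permutes dm1's labels and recomputes residuals each time;
    ``residual`` permutes the labels of dm1's residual matrix.
    """
    if permutation_scheme not in ("raw", "residual"):
        raise ValueError("permutation_scheme must be 'raw' or 'residual'")
    v1, v2, v3 = _aligned_triangles(dm1, dm2, dm3)
    n = dm1.n
    iu = np.triu_indices(n, k=1)
    r2 = _residuals(v2, v3)
    r1 = _residuals(v1, v3)
    r_obs = _pearson(r1, r2)
    rng = np.random.default_rng(seed)
    m1 = dm1.reorder(dm1.labels).values
    # square form of the dm1 residuals, for the residual-permutation scheme
    res_sq = np.zeros((n, n))
    res_sq[iu] = r1
    res_sq += res_sq.T
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if permutation_scheme == "raw":
            v1p = m1[np.ix_(idx, idx)][iu]
            r1p = _residuals(v1p, v3)
        else:
            r1p = res_sq[np.ix_(idx, idx)][iu]
        r_p = _pearson(r1p, r2)
        if r_p >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(
        r_obs, p, n_perm, seed,
        conditioned_on=dm3.name or "dm3",
        permutation_scheme=permutation_scheme,
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Minimal tree node: leaf name or children with branch lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return self.name
        parts = [
            f"{child._newick_inner()}:{bl:.6g}" for child, bl in self.children
        ]
        return "(" + ",".join(parts) + ")"


@dataclass
class PopulationTree:
    """Unrooted tree over population labels (root is the final NJ
    trifurcation; only the splits are meaningful)."""

    root: TreeNode
    labels: list[str]

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each reported as its smaller/canonical side."""
        all_leaves = frozenset(self.labels)
        splits: set[frozenset[str]] = set()

        def visit(node: TreeNode):
            for child, _bl in node.children:
                side = frozenset(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    other = all_leaves - side
                    splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
                visit(child)

        visit(self.root)
        return splits

    def has_clade(self, labels) -> bool:
        """True when some edge separates exactly this label set."""
        want = frozenset(labels)
        other = frozenset(self.labels) - want
        canon = min(want, other, key=lambda s: (len(s), sorted(s)))
        return canon in self.bipartitions()

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (for additivity round-trips)."""
        dist_to_leaves: dict[int, dict[str, float]] = {}

        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            out = {}
            for child, bl in node.children:
                for leaf, d in collect(child).items():
                    out[leaf] = d + bl
            dist_to_leaves[id(node)] = out
            return out

        collect(self.root)
        n = len(self.labels)
        m = np.zeros((n, n))
        pos = {l: i for i, l in enumerate(self.labels)}

        def pairs(node: TreeNode):
            sub = []
            for child, bl in node.children:
                d = {l: v + bl for l, v in collect(child).items()}
                sub.append(d)
                pairs(child)
            for a, b in itertools.combinations(range(len(sub)), 2):
                for la, da in sub[a].items():
                    for lb, db in sub[b].items():
                        m[pos[la], pos[lb]] = m[pos[lb], pos[la]] = da + db

        pairs(self.root)
        return DistanceMatrix(self.labels, m, name="tree_paths")


def neighbor_joining(dm: DistanceMatrix) -> PopulationTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion resolve to the lexicographically lowest cluster-
    name pair (a cluster is named by its smallest leaf).  Negative branch
    lengths are clamped to 0 and the deficit moved to the sister branch.
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError(
            "infinite distances present; cap or exclude those populations first"
        )
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in dm.labels}
    # cluster key = smallest leaf name in the cluster
    active = {l: nodes[l] for l in dm.labels}
    d = {
        (a, b): dm[a, b]
        for a in dm.labels
        for b in dm.labels
        if a != b
    }

    def dist(a, b):
        return d[(a, b)]

    def clamp(la, lb, dij):
        if la < 0:
            lb, la = lb + la, 0.0
        if lb < 0:
            la, lb = la + lb, 0.0
        return max(la, 0.0), max(lb, 0.0)

    while len(active) > 3:
        keys = sorted(active)
        r = len(keys)
        R = {a: sum(dist(a, b) for b in keys if b != a) for a in keys}
        best = None
        for a, b in itertools.combinations(keys, 2):
            q = (r - 2) * dist(a, b) - R[a] - R[b]
            cand = (q, a, b)
            if best is None or cand < best:
                best = cand
        _q, a, b = best
        dij = dist(a, b)
        la = dij / 2 + (R[a] - R[b]) / (2 * (r - 2))
        lb = dij - la
        la, lb = clamp(la, lb, dij)
        new_key = min(a, b)
        merged = TreeNode(children=[(active[a], la), (active[b], lb)])
        for c in keys:
            if c in (a, b):
                continue
            duc = (dist(a, c) + dist(b, c) - dij) / 2
            d[(new_key, c)] = d[(c, new_key)] = duc
        del active[a], active[b]
        active[new_key] = merged

    (k1, k2, k3) = sorted(active)
    d12, d13, d23 = dist(k1, k2), dist(k1, k3), dist(k2, k3)
    l1 = (d12 + d13 - d23) / 2
    l2 = (d12 + d23 - d13) / 2
    l3 = (d13 + d23 - d12) / 2
    lengths = [max(l, 0.0) for l in (l1, l2, l3)]
    root = TreeNode(
        children=[
            (active[k1], lengths[0]),
            (active[k2], lengths[1]),
            (active[k3], lengths[2]),
        ]
    )
    return PopulationTree(root, list(dm.labels))


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def geographic_distances(coords: Mapping[str, tuple[float, float]]) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from (lat, lon) degrees.

    Intended for synthetic studies and packaged example coordinates; real
    analyses may supply their own matrix (e.g. terrestrial route lengths).
    """
    labels = list(coords)
    lat = np.radians([coords[l][0] for l in labels])
    lon = np.radians([coords[l][1] for l in labels])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    m = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2
    return DistanceMatrix(labels, m, name="geographic_km")
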