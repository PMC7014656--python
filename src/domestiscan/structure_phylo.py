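"""Population structure: allele-sharing distances, neighbor-joining trees
with site-bootstrap support, Newick output, and genotype PCA.

The distance between two samples is the mean over sites non-missing in
both of |dosage_i - dosage_j| / 2 (allele-sharing distance), so identical
samples are at 0 and opposite homozygotes at every site are at 1.  Trees
are built with the Saitou-Nei neighbor-joining algorithm with a
deterministic tie-break, and PCA uses the Patterson normalization
(mean-imputation, centering by 2p, scaling by sqrt(2p(1-p))).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .variant_io import GenotypeMatrix

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")

    def validate(self):
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if (self.d < -1e-12).any():
            raise ValidationError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.d), 0, atol=1e-9):
            raise ValidationError("distance matrix diagonal is not zero")


@dataclass
class TreeNode:
    """Node of an unrooted tree stored with a top-level trifurcation."""

    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, branch_length)
    support: float | None = None  # support of the edge above this node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode  # degree-3 "root" representing the unrooted topology

    def leaves(self):
        return self.root.leaves()

    def bipartitions(self) -> set:
        """Non-trivial leaf bipartitions, one per internal edge.

        Each is normalized as the frozenset of leaves on the side *not*
        containing the lexicographically smallest leaf label, making sets
        comparable across differently-rooted representations.
        """
        all_leaves = frozenset(self.leaves())
        ref = min(all_leaves)
        parts = set()

        def _walk(node):
            for child, _ in node.children:
                if not child.is_leaf:
                    side = frozenset(child.leaves())
                    if ref in side:
                        side = all_leaves - side
                    if 2 <= len(side) <= len(all_leaves) - 2:
                        parts.add(side)
                    _walk(child)

        _walk(self.root)
        return parts

    def internal_nodes(self):
        out = []

        def _walk(node):
            for child, _ in node.children:
                if not child.is_leaf:
                    out.append(child)
                    _walk(child)

        _walk(self.root)
        return out


def pairwise_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance matrix over all sample pairs.

    Missing genotypes are excluded pairwise; a pair sharing no called site
    is an error (its distance would be undefined).
    """
    if gm.n_samples < 2:
        raise ValidationError("need >= 2 samples for a distance matrix")
    d = gm.dosages
    valid = (d >= 0).astype(np.float64)
    shared = valid @ valid.T
    off_diag = ~np.eye(gm.n_samples, dtype=bool)
    if ((shared == 0) & off_diag).any():
        i, j = np.argwhere((shared == 0) & off_diag)[0]
        raise ValidationError(
            f"samples '{gm.samples[i]}' and '{gm.samples[j]}' share no called sites"
        )
    # |a-b| over {0,1,2} decomposes over the two thresholds 0.5 and 1.5:
    # |a-b| = sum_t |1[a>t] - 1[b>t]|, each term a pair of masked matmuls.
    total = np.zeros((gm.n_samples, gm.n_samples))
    for thr in (0.5, 1.5):
        x = ((d > thr) & (d >= 0)).astype(np.float64)
        y = valid - x  # called and <= thr
        total += x @ y.T + y @ x.T
    dist = total / (2.0 * shared)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(list(gm.samples), dist)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing Q = (m-2) d_ij - r_i - r_j,
    with ties broken by the smallest (i, j) pair in current node order so
    the output is deterministic.  Negative branch lengths are clamped to
    zero.  The returned tree keeps the final three lineages as a top-level
    trifurcation (the standard unrooted representation).
    """
    dm.validate()
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    nodes = [TreeNode(name=l) for l in labels]
    D = dm.d.astype(float).copy()
    active = list(range(len(labels)))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) in active order
        flat = np.argmin(q)
        ties = np.argwhere(q == q.flat[flat])
        ai, aj = min((min(i, j), max(i, j)) for i, j in ties)
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        gi, gj = active[ai], active[aj]
        new = TreeNode(children=[(nodes[gi], li), (nodes[gj], lj)])
        nodes.append(new)
        gnew = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for ak in range(m):
            if ak in (ai, aj):
                continue
            gk = active[ak]
            D[gnew, gk] = D[gk, gnew] = 0.5 * (
                sub[ai, ak] + sub[aj, ak] - dij
            )
        active = [g for g in active if g not in (gi, gj)] + [gnew]

    ga, gb, gc = active
    dab, dac, dbc = D[ga, gb], D[ga, gc], D[gb, gc]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    root = TreeNode(children=[(nodes[ga], la), (nodes[gb], lb), (nodes[gc], lc)])
    return Tree(root)


def bootstrap_support(
    gm: GenotypeMatrix, n_replicates: int = 100, seed: int = 0
) -> Tree:
    """Full-data NJ tree with site-bootstrap support on internal edges.

    Sites (columns) are resampled with replacement per replicate; the
    support of an internal edge is the fraction of replicate trees whose
    bipartition set contains that edge's bipartition.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    tree = nj_tree(pairwise_distance(gm))
    counts: dict = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, gm.n_sites, size=gm.n_sites)
        rep = nj_tree(pairwise_distance(gm.take_sites(cols)))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(tree.leaves())
    ref = min(all_leaves)
    for node in tree.internal_nodes():
        side = frozenset(node.leaves())
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.support = counts[side] / n_replicates
    return tree


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _quote(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Newick string with branch lengths and bootstrap supports as
    internal-node labels; labels with metacharacters are quoted."""

    def _fmt(node: TreeNode, length: float | None) -> str:
        if node.is_leaf:
            body = _quote(node.name)
        else:
            inner = ",".join(_fmt(c, l) for c, l in node.children)
            sup = "" if node.support is None else format(node.support, "g")
            body = f"({inner}){sup}"
        if length is None:
            return body
        return f"{body}:{length:.10g}"

    inner = ",".join(_fmt(c, l) for c, l in tree.root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca(gm: GenotypeMatrix, n_components: int = 10):
    """Genotype PCA with Patterson normalization.

    Monomorphic sites are dropped; missing dosages are mean-imputed per
    site; columns are centered by 2p and scaled by sqrt(2p(1-p)).  Returns
    ``(coords, explained)`` where ``coords`` is a DataFrame (samples x
    components, eigenvector * sqrt(eigenvalue) scaling) and ``explained``
    the fraction of total positive variance per component.  The sign of
    each component is fixed so its largest-magnitude coordinate is
    positive.
    """
    snps = gm.snps()
    if snps.n_samples < 2 or snps.n_sites < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 polymorphic sites")
    X = snps.dosages.astype(float)
    X[X < 0] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValidationError("fewer than 2 polymorphic sites after imputation")
    X = X[:, poly]
    p = p[poly]
    X = np.where(np.isnan(X), 2.0 * p, X)
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    cov = Z @ Z.T / Z.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    rank = int(pos.sum())
    k = min(n_components, rank)
    if k < n_components:
        import warnings

        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for j in range(k):
        i_star = np.argmax(np.abs(coords[:, j]))
        if coords[i_star, j] < 0:
            coords[:, j] = -coords[:, j]
    explained = vals[:k] / vals[pos].sum()
    frame = pd.DataFrame(
        coords, index=gm.samples, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return frame, explained
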