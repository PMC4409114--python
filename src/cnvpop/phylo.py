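"""CNV-based genetic distances and distance-based tree building.

Distances come from CNV data in three ways:

* **allele-sharing**: the mean per-locus mismatch fraction (Hamming
  distance / loci) over all cross-population individual pairs of
  carrier-genotype vectors;
* **Nei (1972) standard distance** ``D = -ln(Jxy / sqrt(Jx * Jy))`` on
  per-locus carrier frequencies, each locus treated as biallelic
  (carrier / non-carrier) by default, with a multi-allele CN-state mode;
* **sharing counts**: a pairwise shared-breakpoint count matrix converted
  to distances by ``max - count`` (default) or ``1 - count/max``.

Trees are built by neighbor-joining (Saitou-Nei, exact on additive
matrices) and UPGMA (average linkage, ultrametric output), with strict or
majority-rule consensus. All tie-breaks are deterministic (lexicographic
smallest label pair), so identical inputs give identical Newick output.
"""

from __future__ import annotations

import itertools
import logging

import dendropy
import numpy as np

from .model import DistanceMatrix, FrequencyTable, SharingMatrix, genotype_matrix_distance_ready

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances

def allele_sharing_distance(pop_a: np.ndarray, pop_b: np.ndarray) -> float:
    """Average pairwise genotype difference between two populations.

    ``pop_a`` and ``pop_b`` are individuals x loci genotype matrices
    (carrier 0/1, or CN states). Returns the mean over all cross pairs of
    the fraction of mismatching loci.
    """
    a = genotype_matrix_distance_ready(pop_a)
    b = genotype_matrix_distance_ready(pop_b)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both populations must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"locus-count mismatch: {a.shape[1]} vs {b.shape[1]}")
    if a.shape[1] == 0:
        raise ValueError("need at least one locus")
    mism = (a[:, None, :] != b[None, :, :]).mean(axis=2)
    return float(mism.mean())


def allele_sharing_distance_matrix(genotypes: dict[str, np.ndarray]) -> DistanceMatrix:
    labels = list(genotypes)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = allele_sharing_distance(genotypes[labels[i]], genotypes[labels[j]])
    return DistanceMatrix(labels, d)


def nei_distance(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Nei (1972) standard genetic distance on biallelic carrier frequencies.

    Each locus contributes alleles (f, 1-f). ``Jxy`` is the mean over loci
    of the summed cross-products of allele frequencies, ``Jx``/``Jy`` the
    within-population analogues; ``D = -ln(Jxy / sqrt(Jx*Jy))``. Identical
    profiles give 0. Degenerate input with zero cross-identity (fixed
    opposite alleles at every locus's weight) raises.
    """
    fa = np.asarray(freq_a, dtype=float)
    fb = np.asarray(freq_b, dtype=float)
    if fa.shape != fb.shape or fa.ndim != 1 or fa.size == 0:
        raise ValueError("frequency vectors must be equal-length, 1-D, non-empty")
    for f in (fa, fb):
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
    a = np.stack([fa, 1 - fa], axis=1)
    b = np.stack([fb, 1 - fb], axis=1)
    return _nei_from_allele_freqs(a, b)


def nei_distance_cn(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Nei distance with multi-allele (per-CN-state) frequencies.

    Inputs are loci x states frequency matrices, rows summing to 1.
    """
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("need equal-shape loci x states matrices")
    for f in (a, b):
        if np.any((f < 0) | (f > 1)) or not np.allclose(f.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("rows must be frequency distributions")
    return _nei_from_allele_freqs(a, b)


def _nei_from_allele_freqs(a: np.ndarray, b: np.ndarray) -> float:
    jxy = float((a * b).sum(axis=1).mean())
    jx = float((a * a).sum(axis=1).mean())
    jy = float((b * b).sum(axis=1).mean())
    if jxy <= 0:
        raise ValueError("degenerate input: zero cross-population identity (I <= 0)")
    identity = jxy / np.sqrt(jx * jy)
    return float(max(0.0, -np.log(identity)))


def nei_distance_matrix(freq_table: FrequencyTable) -> DistanceMatrix:
    """Pairwise Nei distances between populations of a frequency table."""
    pops = freq_table.populations
    f = freq_table.freq.to_numpy(dtype=float)
    n = len(pops)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = nei_distance(f[:, i], f[:, j])
    return DistanceMatrix(pops, d)


def sharing_to_distance(m: SharingMatrix, method: str = "max_minus") -> DistanceMatrix:
    """Convert a shared-breakpoint count matrix to distances.

    ``max_minus``: d = (max defined count) - count, preserving count
    differences linearly. ``one_minus_norm``: d = 1 - count/max. NA pairs
    are imputed with the mean of the defined distances in their row and
    column, and logged.
    """
    if method not in ("max_minus", "one_minus_norm"):
        raise ValueError(f"unknown method {method!r}")
    counts = m.counts.copy()
    off = ~np.eye(len(m.populations), dtype=bool)
    defined = off & ~np.isnan(counts)
    if not defined.any():
        raise ValueError("all sharing entries are NA")
    mx = np.nanmax(counts[off])
    if method == "max_minus":
        d = mx - counts
    else:
        d = 1.0 - counts / mx
    np.fill_diagonal(d, 0.0)
    # impute NA pairs from row/column means of defined distances
    nan_pairs = [
        (i, j) for i in range(d.shape[0]) for j in range(i + 1, d.shape[1])
        if np.isnan(d[i, j])
    ]
    for i, j in nan_pairs:
        pool = np.concatenate([d[i, defined[i]], d[j, defined[j]]])
        val = float(pool.mean())
        d[i, j] = d[j, i] = val
        logger.warning(
            "imputed unavailable pair (%s, %s) with row/column mean %.3f",
            m.populations[i], m.populations[j], val,
        )
    return DistanceMatrix(m.populations, d)


# ---------------------------------------------------------------------------
# tree building

def _new_tree(rooted: bool) -> tuple[dendropy.Tree, dendropy.TaxonNamespace]:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = rooted
    return tree, tns


def build_nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining tree (unrooted).

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; branch lengths by the standard
    formulas, negative lengths clamped to 0 with the deficit logged. Ties
    are broken by the lexicographically smallest pair of cluster labels.
    Recovers additive matrices exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    tree, tns = _new_tree(rooted=False)
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=tns.new_taxon(lab))
        nodes.append(nd)
    labels = list(dm.labels)  # representative (lexicographically smallest leaf) label
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, bi in itertools.combinations(active, 2):
            q = (m - 2) * d[ai, bi] - r[ai] - r[bi]
            key = (q,) + tuple(sorted((labels[ai], labels[bi])))
            if best is None or key < best[0]:
                best = (key, ai, bi)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj, labels[i], labels[j])
        parent = dendropy.Node()
        _attach(parent, nodes[i], li)
        _attach(parent, nodes[j], lj)
        # grow matrix by one row/col for the new node
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [new]

    # join the final three on a central node
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = tree.seed_node
    for k, lk in ((a, la), (b, lb), (c, lc)):
        lk_clamped = max(0.0, lk)
        if lk < 0:
            logger.info("clamped negative NJ branch (%s): %.6g", labels[k], lk)
        _attach(center, nodes[k], lk_clamped)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _clamp_pair(li: float, lj: float, lab_i: str, lab_j: str) -> tuple[float, float]:
    if li < 0:
        logger.info("clamped negative NJ branch (%s): %.6g", lab_i, li)
        lj = lj + li  # preserve the pair's total path where possible
        li = 0.0
    if lj < 0:
        logger.info("clamped negative NJ branch (%s): %.6g", lab_j, lj)
        li = li + lj
        lj = 0.0
    return max(0.0, li), max(0.0, lj)


def _attach(parent: dendropy.Node, child: dendropy.Node, edge_length: float) -> None:
    parent.add_child(child)
    child.edge.length = float(edge_length)


def build_upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average linkage) tree; rooted and ultrametric.

    Cluster pair distances are size-weighted averages; the merged node
    sits at height d/2. Ties are broken by the lexicographically smallest
    label pair, so output is deterministic.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    tree, tns = _new_tree(rooted=True)
    nodes = {i: dendropy.Node(taxon=tns.new_taxon(lab)) for i, lab in enumerate(dm.labels)}
    labels = dict(enumerate(dm.labels))
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    d = {frozenset((i, j)): dm.d[i, j] for i, j in itertools.combinations(range(n), 2)}
    nxt = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            key = (d[frozenset((i, j))],) + tuple(sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        h = d[frozenset((i, j))] / 2.0
        parent = dendropy.Node()
        _attach(parent, nodes[i], h - heights[i])
        _attach(parent, nodes[j], h - heights[j])
        for k in active - {i, j}:
            dk = (sizes[i] * d[frozenset((i, k))] + sizes[j] * d[frozenset((j, k))]) / (
                sizes[i] + sizes[j]
            )
            d[frozenset((nxt, k))] = dk
        nodes[nxt] = parent
        labels[nxt] = min(labels[i], labels[j])
        sizes[nxt] = sizes[i] + sizes[j]
        heights[nxt] = h
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    root = nodes[max(nodes)]
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def upgma_merge_order(dm: DistanceMatrix) -> list[tuple[str, str, float]]:
    """Sequence of UPGMA merges as (label_i, label_j, height) triples."""
    n = len(dm.labels)
    labels = dict(enumerate(dm.labels))
    sizes = {i: 1 for i in range(n)}
    d = {frozenset((i, j)): dm.d[i, j] for i, j in itertools.combinations(range(n), 2)}
    active = set(range(n))
    nxt = n
    merges = []
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            key = (d[frozenset((i, j))],) + tuple(sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = d[frozenset((i, j))]
        merges.append((*sorted((labels[i], labels[j])), dij / 2.0))
        for k in active - {i, j}:
            d[frozenset((nxt, k))] = (
                sizes[i] * d[frozenset((i, k))] + sizes[j] * d[frozenset((j, k))]
            ) / (sizes[i] + sizes[j])
        labels[nxt] = min(labels[i], labels[j])
        sizes[nxt] = sizes[i] + sizes[j]
        active -= {i, j}
        active.add(nxt)
        nxt += 1
    return merges


def consensus_tree(trees: list[dendropy.Tree], method: str = "majority") -> dendropy.Tree:
    """Strict or majority-rule consensus of trees on identical leaf sets.

    ``strict`` keeps only bipartitions present in every tree; ``majority``
    those in more than half. Unresolved regions collapse to polytomies and
    branch lengths are omitted.
    """
    if method not in ("strict", "majority"):
        raise ValueError(f"unknown consensus method {method!r}")
    if not trees:
        raise ValueError("need at least one tree")
    leaf_sets = [frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees]
    if len(set(leaf_sets)) != 1:
        raise ValueError("trees have mismatched leaf sets")
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        # compare as unrooted so a rooted and an unrooted tree of the same
        # topology contribute identical bipartitions
        c = dendropy.Tree.get(
            data=t.as_string(schema="newick"), schema="newick", taxon_namespace=tns
        )
        c.is_rooted = False
        c.update_bipartitions()
        tl.append(c)
    min_freq = 1.0 if method == "strict" else 0.5 + 1e-9
    con = tl.consensus(min_freq=min_freq)
    for edge in con.preorder_edge_iter():
        edge.length = None
    return con


# ---------------------------------------------------------------------------
# tree utilities

def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {l.taxon.label for l in tree.leaf_node_iter()}


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


def root_to_leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}
    for leaf in tree.leaf_node_iter():
        depth = 0.0
        nd = leaf
        while nd.parent_node is not None:
            depth += nd.edge.length or 0.0
            nd = nd.parent_node
        depths[leaf.taxon.label] = depth
    return depths


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    depths = list(root_to_leaf_depths(tree).values())
    return (max(depths) - min(depths)) <= tol


def trees_isomorphic(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """Topological identity (zero Robinson-Foulds distance) on shared leaves."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=tns)
    for t in (a, b):
        t.is_rooted = False  # compare unrooted topologies
        t.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b) == 0
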