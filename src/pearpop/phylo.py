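"""Distance-based phylogeny: p-distance, neighbor joining, SNP bootstrap.

Accession relationships are summarized by the p-distance between dosage
vectors (mean per-site allele-content difference over co-called sites),
a neighbor-joining tree on that matrix, and a majority-rule consensus over
trees built from SNP resamples drawn with replacement (200 replicates by
default), with bipartition frequencies as percent support values.

The NJ implementation is the textbook algorithm — Q-criterion pair
selection, standard branch-length formulas, matrix reduction — made fully
deterministic by breaking Q ties toward the lowest index pair; negative
branch lengths are clamped to zero.  NJ is exact on additive matrices,
which the tests exploit as an oracle.  Trees are dendropy objects, so
Newick/Nexus serialization and tree arithmetic come for free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

from .matrix import GenotypeMatrix


def p_distance_matrix(
    matrix: GenotypeMatrix, site_subset: np.ndarray | None = None,
    site_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pairwise p-distance (mean |g_i − g_j|/2 over co-called sites).

    ``site_subset`` restricts to an index array of sites; ``site_weights``
    (e.g. bootstrap multiplicities) weight sites instead of copying them.
    A pair with no co-called site raises an error naming the pair.
    """
    d = matrix.dosages if site_subset is None else matrix.dosages[:, site_subset]
    ids = list(matrix.samples["sample_id"])
    n = len(ids)
    w = np.ones(d.shape[1]) if site_weights is None else np.asarray(site_weights, dtype=np.float64)
    out = np.zeros((n, n))
    called = d >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            denom = float(w[both].sum())
            if denom == 0:
                raise ValueError(f"samples {ids[i]!r} and {ids[j]!r} share no called site")
            diff = np.abs(d[i, both].astype(np.float64) - d[j, both]) / 2.0
            out[i, j] = out[j, i] = float((diff * w[both]).sum()) / denom
    return pd.DataFrame(out, index=ids, columns=ids)


def _nj_topology(dist: np.ndarray, labels: list[str]) -> str:
    """Neighbor joining to a Newick string; deterministic tie-breaking."""
    n = dist.shape[0]
    if n == 2:
        L = max(dist[0, 1], 0.0) / 2.0
        return f"({labels[0]}:{L:.10g},{labels[1]}:{L:.10g});"
    D = dist.astype(np.float64).copy()
    nodes = list(labels)  # newick fragments without trailing edge length
    active = list(range(n))
    while len(active) > 2:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if best is None or Q[a, b] < best[0] - 1e-15:
                    best = (Q[a, b], a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = dij / 2.0 + (R[a] - R[b]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_frag = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        # distances from the new node to the remaining ones
        new_d = np.zeros(D.shape[0] + 1)
        for c in range(r):
            k = active[c]
            if k in (i, j):
                continue
            new_d[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d[:-1]
        D[:-1, -1] = new_d[:-1]
        nodes.append(new_frag)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]
    i, j = active
    L = max(D[i, j], 0.0)
    if i < n and j >= n:
        i, j = j, i  # let the leaf carry the final edge length
    return f"({nodes[i]},{nodes[j]}:{L:.10g});"


def neighbor_joining(
    dm: pd.DataFrame, taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Unrooted NJ tree from a symmetric distance matrix (as a DataFrame)."""
    ids = list(dm.index)
    if list(dm.columns) != ids:
        raise ValueError("distance matrix index and columns differ")
    if len(ids) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    arr = dm.to_numpy(dtype=np.float64)
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    newick = _nj_topology(arr, ids)
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        taxon_namespace=taxon_namespace or dendropy.TaxonNamespace(),
        preserve_underscores=True,
    )
    tree.is_rooted = False
    return tree


def tree_path_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    out = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i < j:
                out[i, j] = out[j, i] = pdm.distance(ti, tj)
    return pd.DataFrame(out, index=ids, columns=ids)


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    node = tree.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    tree.to_outgroup_position(node, update_bipartitions=True)
    return tree


def bootstrap_consensus(
    matrix: GenotypeMatrix,
    n_replicates: int = 200,
    seed: int = 0,
    min_freq: float = 0.5,
) -> dendropy.Tree:
    """Majority-rule consensus of NJ trees over SNP bootstrap replicates.

    Each replicate resamples sites with replacement to the original count
    (implemented as multinomial site weights), rebuilds the p-distance
    matrix and its NJ tree; the consensus keeps bipartitions appearing in
    at least ``min_freq`` of replicates, labels internal nodes with percent
    support, and carries branch lengths over from the full-data NJ tree
    where the bipartition occurs there.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    full_tree = neighbor_joining(p_distance_matrix(matrix), taxon_namespace=tns)
    n_sites = matrix.n_sites
    ids = list(matrix.samples["sample_id"])
    n = len(ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    called = matrix.dosages >= 0
    diff = np.empty((len(pairs), n_sites), dtype=np.float32)
    mask = np.empty((len(pairs), n_sites), dtype=np.float32)
    for k, (i, j) in enumerate(pairs):
        both = called[i] & called[j]
        mask[k] = both
        diff[k] = np.where(
            both, np.abs(matrix.dosages[i].astype(np.int16) - matrix.dosages[j]), 0
        )
    trees = dendropy.TreeList(taxon_namespace=tns)
    for _ in range(n_replicates):
        w = rng.multinomial(n_sites, np.full(n_sites, 1.0 / n_sites)).astype(np.float32)
        numer = diff @ w
        denom = mask @ w
        if np.any(denom == 0):
            raise ValueError("a bootstrap replicate left a sample pair with no co-called site")
        vals = numer / (2.0 * denom)
        dm = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            dm[i, j] = dm[j, i] = vals[k]
        trees.append(neighbor_joining(pd.DataFrame(dm, index=ids, columns=ids),
                                      taxon_namespace=tns))
    consensus = trees.consensus(min_freq=min_freq)
    consensus.encode_bipartitions()
    full_tree.encode_bipartitions()
    full_lengths = {
        edge.bipartition.split_bitmask: edge.length for edge in full_tree.edges()
    }
    for node in consensus:
        support = getattr(node, "support", None)
        if support is not None and not node.is_leaf():
            node.label = f"{100.0 * support:g}"
        edge = node.edge
        if edge is not None and edge.bipartition is not None:
            edge.length = full_lengths.get(edge.bipartition.split_bitmask, edge.length)
    return consensus


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def write_phylip(dm: pd.DataFrame, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"    {len(dm)}\n")
        for sid, row in dm.iterrows():
            vals = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{sid:<12s}{vals}\n")
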