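"""Distance-based tree construction and newick utilities.

UPGMA supplies the rooted ultrametric tree consumed by informativeness
profiling (node height = cluster distance / 2, so cophenetic distances on
ultrametric input are reproduced exactly); neighbor-joining provides
unrooted topology checks.  Both agglomerations break ties by lexicographic
cluster label, making runs bit-reproducible.  Trees are dendropy objects
throughout, so newick I/O and Robinson-Foulds comparisons come for free.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .divergence import DistanceMatrix

log = logging.getLogger(__name__)


def _check_matrix(dm: DistanceMatrix, min_taxa: int) -> None:
    if len(dm.labels) < min_taxa:
        raise ValueError(f"need at least {min_taxa} taxa")
    if dm.has_undefined:
        raise ValueError(
            "distance matrix has undefined (NaN) entries; impute them or "
            "exclude the offending pairs upstream before tree building")


def upgma(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration; rooted, ultrametric output.

    Cluster distances are size-weighted averages of member distances
    (UPGMA proper); merge ties are broken by the lexicographically
    smallest pair of cluster labels.
    """
    _check_matrix(dm, 2)
    labels = list(dm.labels)
    d = {frozenset((a, b)): float(dm.values[i, j])
         for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j}
    # cluster -> (newick string, height, size, sort label)
    active = {lab: (lab, 0.0, 1, lab) for lab in labels}
    while len(active) > 1:
        best = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                key = (d[frozenset((a, b))],
                       min(active[a][3], active[b][3]),
                       max(active[a][3], active[b][3]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dist = d[frozenset((a, b))]
        height = dist / 2
        nwk_a, h_a, size_a, lab_a = active[a]
        nwk_b, h_b, size_b, lab_b = active[b]
        first, second = ((nwk_a, h_a, lab_a), (nwk_b, h_b, lab_b))
        if lab_b < lab_a:
            first, second = second, first
        nwk = (f"({first[0]}:{height - first[1]!r},"
               f"{second[0]}:{height - second[1]!r})")
        new = f"@{min(lab_a, lab_b)}"
        for c in list(active):
            if c in (a, b):
                continue
            dc = (size_a * d[frozenset((a, c))] +
                  size_b * d[frozenset((b, c))]) / (size_a + size_b)
            d[frozenset((new, c))] = dc
        del active[a], active[b]
        active[new] = (nwk, height, size_a + size_b, min(lab_a, lab_b))
    (nwk, _, _, _), = active.values()
    return parse_newick(nwk + ";")


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Negative branch lengths are clamped to zero with a warning; the
    returned tree is unrooted (dendropy stores it with a trifurcating
    seed node).
    """
    _check_matrix(dm, 3)
    labels = list(dm.labels)
    nodes = {lab: (lab, lab) for lab in labels}   # label -> (newick, sort)
    d = {frozenset((a, b)): float(dm.values[i, j])
         for i, a in enumerate(labels) for j, b in enumerate(labels) if i < j}
    active = list(labels)
    clamped = False
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(d[frozenset((a, c))] for c in active if c != a)
                  for a in active}
        best = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                q = (r - 2) * d[frozenset((a, b))] - totals[a] - totals[b]
                key = (q, min(nodes[a][1], nodes[b][1]),
                       max(nodes[a][1], nodes[b][1]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        if la < 0 or lb < 0:
            clamped = True
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = f"@{min(nodes[a][1], nodes[b][1])}"
        nwk = f"({nodes[a][0]}:{la!r},{nodes[b][0]}:{lb!r})"
        nodes[new] = (nwk, min(nodes[a][1], nodes[b][1]))
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((new, c))] = 0.5 * (d[frozenset((a, c))] +
                                            d[frozenset((b, c))] - dab)
        active = [c for c in active if c not in (a, b)] + [new]
    a, b, c = sorted(active, key=lambda x: nodes[x][1])
    dab, dac, dbc = (d[frozenset((a, b))], d[frozenset((a, c))],
                     d[frozenset((b, c))])
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    if min(la, lb, lc) < 0:
        clamped = True
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    if clamped:
        log.warning("negative NJ branch length(s) clamped to 0")
    nwk = (f"({nodes[a][0]}:{la!r},{nodes[b][0]}:{lb!r},"
           f"{nodes[c][0]}:{lc!r});")
    tree = parse_newick(nwk)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# newick utilities

def parse_newick(text: str) -> dendropy.Tree:
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in newick string")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True,
                                 preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in newick string")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def tip_depths(tree: dendropy.Tree) -> dict:
    """Root-to-tip path length per tip label."""
    depths = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        parent_depth = getattr(node.parent_node, "_mc_depth", 0.0) \
            if node.parent_node is not None else 0.0
        node._mc_depth = parent_depth + (edge if node.parent_node else 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = node._mc_depth
    return depths


def root_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(tip_depths(tree).values())


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    """True when all root-to-tip paths agree within tol x depth."""
    depths = list(tip_depths(tree).values())
    depth = max(depths)
    if depth == 0:
        return True
    return (depth - min(depths)) <= tol * depth


def normalize_depth(tree: dendropy.Tree, depth: float = 1.0) -> dendropy.Tree:
    """Rescale all branch lengths so the root-to-tip depth equals ``depth``."""
    current = root_depth(tree)
    if current <= 0:
        raise ValueError("tree has zero depth; cannot normalize")
    factor = depth / current
    clone = tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return clone


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length distances between all tip pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[i],
                                                             taxa[j])
    return DistanceMatrix(gene="cophenetic", labels=labels, values=vals)


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds (symmetric difference) distance."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=write_newick(tree_a), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    tb = dendropy.Tree.get(data=write_newick(tree_b), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
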