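"""Distance-based phylogenetics: p-distances, model correction, neighbor
joining, bootstrap supports, Newick I/O.

Domain trees are built from trimmed alignments in three steps: observed
difference fractions (p-distances) over comparable columns; correction for
multiple hits under the uniform-replacement Poisson model,

    d = -(19/20) * ln(1 - (20/19) * p),

which exactly inverts the simulator's expected difference fraction; and
neighbor joining (Saitou–Nei Q-criterion).  Trees are unrooted — there is no
outgroup for the domain phylogenies — and every downstream "clusters with"
statement is formulated on unrooted splits and patristic distances.

Determinism: ties in the Q-matrix minimization are broken by the
lexicographically smallest pair of cluster representatives (the smallest tip
id each cluster contains), so the same matrix always yields the same tree.
Negative branch-length estimates are clamped to zero.  Pairs at or beyond
the model's saturation point (p >= 19/20) abort with an error naming them
rather than being silently imputed.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter

import dendropy
import numpy as np

from .alignment import Alignment, _identity_array

logger = logging.getLogger(__name__)

#: Saturation point of the uniform-replacement model.
P_MAX = 19.0 / 20.0


class SaturationError(ValueError):
    """A p-distance at or beyond 19/20 cannot be corrected."""


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric distances among tips; NaN marks flagged-missing pairs."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if np.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                fh.write(rid + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i]) + "\n")


def p_distance(alignment: Alignment) -> DistanceMatrix:
    """Observed difference fraction per pair over comparable (both non-gap)
    retained columns; pairs with no comparable column are NaN-flagged."""
    if alignment.n_rows < 2:
        raise ValueError("p_distance needs at least 2 rows")
    ident = _identity_array(alignment.matrix)
    p = 1.0 - ident / 100.0
    np.fill_diagonal(p, 0.0)
    dm = DistanceMatrix(list(alignment.ids), p)
    missing = dm.missing_pairs()
    for a, b in missing:
        logger.warning("no comparable columns between %s and %s", a, b)
    return dm


def correct_distance(p):
    """Poisson correction of an observed difference fraction (scalar or
    array): d = -(19/20) ln(1 - (20/19) p).  Raises :class:`SaturationError`
    at p >= 19/20."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative p-distance")
    if np.any(arr >= P_MAX):
        raise SaturationError(f"p-distance at or beyond saturation ({P_MAX:.4f})")
    d = -P_MAX * np.log1p(-(arr / P_MAX))
    return float(d) if np.isscalar(p) else d


def correct_matrix(
    dm: DistanceMatrix,
    on_saturation: str = "error",
    alignment_length: int | None = None,
) -> DistanceMatrix:
    """Apply :func:`correct_distance` to a whole matrix.

    ``on_saturation`` controls pairs with p >= 19/20:

    * ``"error"`` (default) — raise :class:`SaturationError` naming them;
    * ``"cap"`` — clamp them to the largest p resolvable at the given
      alignment length, ``19/20 - 1/(2 L)`` (or just below 19/20 when the
      length is unknown), with a logged warning.  A finite observed p at or
      beyond 19/20 is a sampling excursion of a deeply diverged pair, not
      evidence of infinite distance; capping keeps the pair's distance large
      but finite instead of aborting the whole tree.
    """
    if on_saturation not in ("error", "cap"):
        raise ValueError(f"unknown saturation policy {on_saturation!r}")
    saturated = []
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if not np.isnan(dm.values[i, j]) and dm.values[i, j] >= P_MAX:
                saturated.append((dm.ids[i], dm.ids[j]))
    values = dm.values
    if saturated:
        if on_saturation == "error":
            raise SaturationError(
                f"saturated pairs (p >= {P_MAX:.4f}): {saturated}; "
                "sequences too diverged for distance correction"
            )
        if alignment_length:
            cap = P_MAX - 1.0 / (2.0 * alignment_length)
        else:
            cap = P_MAX - 1e-3
        logger.warning(
            "capping %d saturated pair(s) at p = %.4f: %s",
            len(saturated), cap, saturated,
        )
        values = np.minimum(values, cap)
    with np.errstate(invalid="ignore"):
        d = -P_MAX * np.log1p(-(values / P_MAX))
    d[np.isnan(dm.values)] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(dm.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(
    dm: DistanceMatrix,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.  Returns an unrooted dendropy tree whose
    seed node is the final trifurcation.  Requires >= 3 tips and a complete
    matrix; negative branch-length estimates are clamped to zero."""
    missing = dm.missing_pairs()
    if missing:
        raise ValueError(f"distance matrix has missing cells: {missing}")
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 tips")
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    nodes: list[dendropy.Node] = []
    reps: list[str] = []  # smallest tip id in each cluster, for tie-breaking
    for tip in dm.ids:
        node = dendropy.Node()
        node.taxon = taxon_namespace.get_taxon(tip)
        if node.taxon is None:
            raise ValueError(f"tip {tip!r} absent from taxon namespace")
        nodes.append(node)
        reps.append(tip)
    D = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        qmin = Q[iu].min()
        candidates = [
            (i, j)
            for i, j in zip(*iu)
            if Q[i, j] == qmin
        ]
        i, j = min(
            candidates,
            key=lambda ij: tuple(sorted((reps[active[ij[0]]], reps[active[ij[1]]]))),
        )
        ai, aj = active[i], active[j]
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        parent = dendropy.Node()
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        nodes[ai].edge.length = max(li, 0.0)
        nodes[aj].edge.length = max(lj, 0.0)
        # distances from the new node to the remaining clusters
        new_row = np.full(D.shape[0] + 1, 0.0)
        for k in active:
            if k in (ai, aj):
                continue
            new_row[k] = 0.5 * (D[ai, k] + D[aj, k] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :] = new_row
        D[:, -1] = new_row
        nodes.append(parent)
        reps.append(min(reps[ai], reps[aj]))
        active = [k for k in active if k not in (ai, aj)] + [D.shape[0] - 1]

    a, b, c = active
    root = tree.seed_node
    for child, other1, other2 in ((a, b, c), (b, a, c), (c, a, b)):
        length = 0.5 * (D[child, other1] + D[child, other2] - D[other1, other2])
        root.add_child(nodes[child])
        nodes[child].edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs path-length (patristic) distances between tips, with ids
    sorted for a deterministic order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (leaf.taxon for leaf in tree.leaf_node_iter()), key=lambda t: t.label
    )
    ids = [t.label for t in taxa]
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids, values)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 100,
    seed: int = 0,
    on_saturation: str = "error",
) -> dendropy.Tree:
    """Neighbor-joining tree with column-resampling bootstrap supports.

    Columns of the trimmed alignment are resampled with replacement
    *n_replicates* times; the support of an internal edge of the base tree
    is the fraction of replicate trees containing its split, stored as the
    edge's head-node label (and ``support`` attribute) in [0, 1].

    A replicate whose resampled columns push a pair past the saturation
    point is handled by capping that replicate's p-distance just below
    19/20; the base tree itself is never capped.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if alignment.n_rows < 4:
        raise ValueError("bootstrap needs >= 4 rows")
    rng = np.random.default_rng(seed)
    base_dm = correct_matrix(
        p_distance(alignment),
        on_saturation=on_saturation,
        alignment_length=int(alignment.mask.sum()),
    )
    namespace = dendropy.TaxonNamespace(base_dm.ids)
    base_tree = neighbor_joining(base_dm, taxon_namespace=namespace)
    base_tree.encode_bipartitions()

    mat = alignment.matrix
    n_cols = mat.shape[1]
    counts: Counter = Counter()
    cap = P_MAX - 1e-9
    for _ in range(n_replicates):
        idx = rng.integers(0, n_cols, size=n_cols)
        p = 1.0 - _identity_array(mat[:, idx]) / 100.0
        np.fill_diagonal(p, 0.0)
        if np.any(np.isnan(p)):
            # all-gap overlap in a resample: treat as maximally distant
            p = np.where(np.isnan(p), cap, p)
        p = np.minimum(p, cap)
        rep_dm = correct_matrix(DistanceMatrix(list(alignment.ids), p))
        rep_tree = neighbor_joining(rep_dm, taxon_namespace=namespace)
        for bipartition in rep_tree.encode_bipartitions():
            counts[bipartition.split_bitmask] += 1

    for node in base_tree.preorder_node_iter():
        if node.is_leaf() or node is base_tree.seed_node:
            continue
        support = counts[node.edge.bipartition.split_bitmask] / n_replicates
        node.support = support
        node.label = f"{support:.3f}"
    return base_tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def read_newick(
    source,
    taxon_namespace: dendropy.TaxonNamespace | None = None,
) -> dendropy.Tree:
    """Parse a Newick string or file path.  Internal node labels (bootstrap
    supports) are preserved as node labels.  Malformed input raises
    :class:`ValueError` with the parser's position information."""
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    try:
        if isinstance(source, str) and "(" in source:
            tree = dendropy.Tree.get(data=source, **kwargs)
        else:
            tree = dendropy.Tree.get(path=source, **kwargs)
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = False
    return tree


def canonicalize(tree: dendropy.Tree) -> dendropy.Tree:
    """Sort children at every node by the smallest descendant tip label, so
    that topologically identical trees serialize to identical bytes."""
    min_label: dict[int, str] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            min_label[id(node)] = node.taxon.label if node.taxon else ""
        else:
            children = sorted(
                node.child_nodes(), key=lambda c: min_label[id(c)]
            )
            node.set_child_nodes(children)
            min_label[id(node)] = min_label[id(children[0])]
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize a tree in canonical child order; returns the Newick string
    and optionally writes it to *path*."""
    canonicalize(tree)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        with open(path, "wt") as fh:
            fh.write(text)
    return text
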