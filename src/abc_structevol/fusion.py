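"""Fusion-mode and HGT inference from annotated domain trees.

This is the inferential core of the pipeline.  Given an unrooted NBD tree
whose tips are domain instances annotated with family, terminal (N/C/half/
single), structure and superkingdom, it answers two questions:

**Which fusion mode produced a family's full (or ABC2) genes?**
Homofusion — fusion shortly after duplication — leaves the N- and C-terminal
domains of full-structure genes clustering with each other before any
half-structure domain.  Heterofusion — fusion of two long-diverged halves —
leaves one terminal clustering with half-structure (or other-family) domains
first.  "Clusters first" is operationalized on the unrooted tree as a
patristic nearest-partition vote: for each full gene, the category of the
nearest candidate tip to its C-terminal instance is found among
{same-gene N-terminal, same-family half, other family}; a homofusion vote
additionally requires the symmetric check from the N-terminal tip to agree.
Terminal tips of *other* same-family full genes are not candidates — their
proximity reflects the post-fusion radiation, not the fusion mode.  Per-gene
votes are aggregated into a family-level call when the winning fraction
reaches a margin threshold (default 0.7); otherwise the call is unresolved.
ABC2 families are classified the same way with single-NBD tips (any family)
playing the role of the half-structure category.

**Which eukaryotic tips are HGT/endosymbiosis candidates?**
A eukaryote tip nested inside a clade of prokaryote tips points to lateral
transfer (or organellar endosymbiosis).  Clades are enumerated root-free as
the sides of the tree's unrooted bipartitions; a eukaryote tip is flagged
when its smallest enclosing split side with at least ``min_clade`` tips is
at least ``min_prok_fraction`` prokaryotic among its other tips.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import dendropy

from .domains import parse_instance_id
from .phylo import patristic_matrix

logger = logging.getLogger(__name__)

DEFAULT_MARGIN = 0.7
DEFAULT_MIN_CLADE = 4
DEFAULT_MIN_PROK_FRACTION = 0.8

PROKARYOTES = frozenset({"bacteria", "archaea"})


@dataclasses.dataclass
class FusionCall:
    """Family-level fusion-mode verdict with vote statistics."""

    family_label: str
    mode: str  # homofusion | heterofusion | unresolved
    votes: dict[str, int]
    margin: float
    n_genes: int


@dataclasses.dataclass
class HgtCandidate:
    instance_id: str
    prokaryote_fraction: float
    clade_size: int


@dataclasses.dataclass
class NearestResult:
    category: str
    tip_id: str
    distance: float
    tie: bool


def annotate_tips(
    tree: dendropy.Tree, tips: Mapping[str, Mapping[str, str]]
) -> dendropy.Tree:
    """Attach tip metadata (family, terminal, structure, superkingdom) to the
    leaves of *tree*.  Every tree tip must appear in *tips*; extra metadata
    rows are ignored with a warning."""
    leaf_ids = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(leaf_ids - set(tips))
    if missing:
        raise ValueError(f"tips without metadata: {missing}")
    extra = sorted(set(tips) - leaf_ids)
    if extra:
        logger.warning("%d metadata rows not in tree (ignored): %s", len(extra), extra[:5])
    for leaf in tree.leaf_node_iter():
        leaf.tip_meta = dict(tips[leaf.taxon.label])
    return tree


def nearest_partition(
    tree: dendropy.Tree,
    tip_id: str,
    categories: Mapping[str, str],
    distances=None,
) -> NearestResult:
    """Category of the patristically nearest candidate tip.

    *categories* maps candidate tip ids to category names; tips absent from
    the mapping (including, by construction, the query itself and any tip
    the caller chose to exclude) are not candidates.  Ties are broken by the
    smallest tip id and flagged.  *distances* may carry a precomputed
    :func:`~abc_structevol.phylo.patristic_matrix` to avoid recomputation.
    """
    dm = distances if distances is not None else patristic_matrix(tree)
    if tip_id not in dm.ids:
        raise ValueError(f"tip {tip_id!r} not in tree")
    qi = dm.ids.index(tip_id)
    candidates = [
        (dm.values[qi, dm.ids.index(t)], t)
        for t in categories
        if t != tip_id and t in dm.ids
    ]
    if not candidates:
        raise ValueError(f"no candidate tips for {tip_id!r}")
    dmin = min(d for d, _ in candidates)
    winners = sorted(t for d, t in candidates if d == dmin)
    return NearestResult(
        category=categories[winners[0]],
        tip_id=winners[0],
        distance=dmin,
        tie=len(winners) > 1,
    )


def _fusion_candidates(
    tips: Mapping[str, Mapping[str, str]],
    family_label: str,
    gene: str,
    partner_tip: str,
    abc2: bool,
) -> dict[str, str]:
    """Candidate categories for one terminal tip of one full/ABC2 gene."""
    categories = {partner_tip: "same_gene"}
    neighbour_cat = "single" if abc2 else "half"
    for iid, meta in tips.items():
        pid, cls, _ = parse_instance_id(iid)
        if cls != "NBD" or pid == gene:
            continue
        if abc2:
            if meta["structure"] == "single":
                categories[iid] = neighbour_cat
            elif meta["family"] != family_label:
                categories[iid] = "other"
        else:
            if meta["family"] == family_label:
                if meta["structure"] == "half":
                    categories[iid] = neighbour_cat
                # other same-family full/ABC2 genes: excluded
            else:
                categories[iid] = "other"
    return categories


def classify_fusion_mode(
    tree: dendropy.Tree,
    tips: Mapping[str, Mapping[str, str]],
    family_label: str,
    margin_threshold: float = DEFAULT_MARGIN,
) -> FusionCall:
    """Family-level homofusion/heterofusion call from per-gene
    nearest-partition votes (see module docstring for the decision rule)."""
    genes: dict[str, dict[str, str]] = {}
    abc2_genes: set[str] = set()
    for iid, meta in tips.items():
        pid, cls, _ = parse_instance_id(iid)
        if cls != "NBD" or meta["family"] != family_label:
            continue
        if meta["structure"] in ("full", "ABC2") and meta["terminal"] in ("N", "C"):
            genes.setdefault(pid, {})[meta["terminal"]] = iid
            if meta["structure"] == "ABC2":
                abc2_genes.add(pid)
    genes = {g: t for g, t in genes.items() if set(t) == {"N", "C"}}
    if not genes:
        present = any(meta["family"] == family_label for meta in tips.values())
        if not present:
            raise ValueError(f"family {family_label!r} absent from tree")
        raise ValueError(
            f"family {family_label!r} has no full/ABC2 gene with both terminals"
        )
    dm = patristic_matrix(tree)
    votes = {"homofusion": 0, "heterofusion": 0, "unresolved": 0}
    for gene in sorted(genes):
        n_tip, c_tip = genes[gene]["N"], genes[gene]["C"]
        abc2 = gene in abc2_genes
        cand_c = _fusion_candidates(tips, family_label, gene, n_tip, abc2)
        x = nearest_partition(tree, c_tip, cand_c, distances=dm)
        if x.category == "same_gene":
            cand_n = _fusion_candidates(tips, family_label, gene, c_tip, abc2)
            y = nearest_partition(tree, n_tip, cand_n, distances=dm)
            votes["homofusion" if y.category == "same_gene" else "unresolved"] += 1
        else:
            votes["heterofusion"] += 1
    n_genes = len(genes)
    winner = max(sorted(votes), key=lambda k: votes[k])
    margin = votes[winner] / n_genes
    mode = winner if margin >= margin_threshold and winner != "unresolved" else "unresolved"
    return FusionCall(
        family_label=family_label,
        mode=mode,
        votes=votes,
        margin=margin,
        n_genes=n_genes,
    )


def detect_hgt_candidates(
    tree: dendropy.Tree,
    tips: Mapping[str, Mapping[str, str]],
    min_clade: int = DEFAULT_MIN_CLADE,
    min_prok_fraction: float = DEFAULT_MIN_PROK_FRACTION,
) -> list[HgtCandidate]:
    """Flag eukaryote tips nested inside prokaryote clades.

    Clades are enumerated root-free as the sides of the tree's unrooted
    bipartitions (consistent with how every other clustering statement in
    this package is formulated).  For each eukaryote tip, its smallest
    enclosing split side with at least *min_clade* tips is found; the tip is
    flagged iff the prokaryote fraction among that side's other tips is at
    least *min_prok_fraction*.  When several minimal sides tie in size, the
    highest prokaryote fraction decides.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < min_clade:
        logger.warning("tree has %d tips < min_clade=%d", len(leaves), min_clade)
        return []
    all_tips = {lf.taxon.label for lf in leaves}
    missing = sorted(all_tips - set(tips))
    if missing:
        raise ValueError(f"tips without metadata: {missing}")
    # both sides of every non-trivial split, plus leaf-edge complements
    sides: list[frozenset] = []
    seen: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_nodes())
        for side in (below, frozenset(all_tips - below)):
            if min_clade <= len(side) < len(all_tips) and side not in seen:
                seen.add(side)
                sides.append(side)
    candidates: list[HgtCandidate] = []
    for tip_id in sorted(all_tips):
        if tips[tip_id]["superkingdom"] != "eukaryote":
            continue
        enclosing = [s for s in sides if tip_id in s]
        if not enclosing:
            continue
        smallest = min(len(s) for s in enclosing)
        best_fraction = 0.0
        for side in enclosing:
            if len(side) != smallest:
                continue
            others = side - {tip_id}
            prok = sum(1 for t in others if tips[t]["superkingdom"] in PROKARYOTES)
            best_fraction = max(best_fraction, prok / len(others))
        if best_fraction >= min_prok_fraction:
            candidates.append(
                HgtCandidate(
                    instance_id=tip_id,
                    prokaryote_fraction=best_fraction,
                    clade_size=smallest,
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_fusion_calls(calls, path) -> None:
    with open(path, "wt") as fh:
        fh.write("family\tmode\tn_genes\tmargin\tvotes_homofusion\t"
                 "votes_heterofusion\tvotes_unresolved\n")
        for c in calls:
            fh.write(
                f"{c.family_label}\t{c.mode}\t{c.n_genes}\t{c.margin:.3f}\t"
                f"{c.votes['homofusion']}\t{c.votes['heterofusion']}\t"
                f"{c.votes['unresolved']}\n"
            )


def write_hgt_candidates(candidates, path) -> None:
    with open(path, "wt") as fh:
        fh.write("instance_id\tprokaryote_fraction\tclade_size\n")
        for c in candidates:
            fh.write(f"{c.instance_id}\t{c.prokaryote_fraction:.3f}\t{c.clade_size}\n")
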