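"""Fusion-mode classification and HGT detection on annotated trees."""

import pytest

from abc_structevol import (
    annotate_tips,
    classify_fusion_mode,
    detect_hgt_candidates,
    nearest_partition,
    read_newick,
)


def _meta(iid, terminal, family="B", structure="full", superkingdom="eukaryote"):
    pid, cls, _ = iid.rsplit("|", 2)
    return {
        "instance_id": iid,
        "protein_id": pid,
        "domain_class": cls,
        "subclass": "NBD",
        "terminal": terminal,
        "family": family,
        "superkingdom": superkingdom,
        "structure": structure,
    }


def _tips(entries):
    return {e["instance_id"]: e for e in entries}


HOMO_NEWICK = "((g1|NBD|1:1,g1|NBD|2:1):2,(h1|NBD|1:1,h2|NBD|1:1):2);"
HETERO_NEWICK = "((g1|NBD|2:1,h1|NBD|1:1):2,(g1|NBD|1:1,h2|NBD|1:1):2);"

MINIMAL_TIPS = _tips(
    [
        _meta("g1|NBD|1", "N"),
        _meta("g1|NBD|2", "C"),
        _meta("h1|NBD|1", "half", structure="half"),
        _meta("h2|NBD|1", "half", structure="half"),
    ]
)


class TestAnnotate:
    def test_full_metadata_annotates_all_tips(self):
        tree = annotate_tips(read_newick(HOMO_NEWICK), MINIMAL_TIPS)
        assert all(hasattr(lf, "tip_meta") for lf in tree.leaf_node_iter())

    def test_missing_tip_named_in_error(self):
        partial = {k: v for k, v in MINIMAL_TIPS.items() if k != "h2|NBD|1"}
        with pytest.raises(ValueError, match="h2"):
            annotate_tips(read_newick(HOMO_NEWICK), partial)

    def test_extra_rows_ignored_with_warning(self, caplog):
        extra = dict(MINIMAL_TIPS)
        extra["ghost|NBD|1"] = _meta("ghost|NBD|1", "half", structure="half")
        tree = annotate_tips(read_newick(HOMO_NEWICK), extra)
        assert len(tree.leaf_nodes()) == 4


class TestNearestPartition:
    def test_same_gene_partner_is_nearest_in_homofusion_tree(self):
        tree = read_newick(HOMO_NEWICK)
        cats = {"g1|NBD|1": "same_gene", "h1|NBD|1": "half", "h2|NBD|1": "half"}
        res = nearest_partition(tree, "g1|NBD|2", cats)
        assert res.category == "same_gene"
        assert res.distance == pytest.approx(2.0)  # vs 6.0 to either half
        assert not res.tie

    def test_half_is_nearest_in_heterofusion_tree(self):
        tree = read_newick(HETERO_NEWICK)
        cats = {"g1|NBD|1": "same_gene", "h1|NBD|1": "half", "h2|NBD|1": "half"}
        res = nearest_partition(tree, "g1|NBD|2", cats)
        assert res.category == "half" and res.tip_id == "h1|NBD|1"
        assert res.distance == pytest.approx(2.0)

    def test_equidistant_candidates_tie_flagged_smallest_id_wins(self):
        tree = read_newick("(q:1,a:1,b:1,z:9);")
        res = nearest_partition(tree, "q", {"a": "ca", "b": "cb"})
        # d(q,a) = 2 = d(q,b) -> alphabetically smallest tip wins, flagged
        assert res.tip_id == "a" and res.category == "ca" and res.tie

    def test_absent_tip_rejected(self):
        with pytest.raises(ValueError, match="not in tree"):
            nearest_partition(read_newick(HOMO_NEWICK), "nope", {"h1|NBD|1": "x"})


class TestClassifyFusionMode:
    def test_minimal_homofusion_margin_one(self):
        call = classify_fusion_mode(read_newick(HOMO_NEWICK), MINIMAL_TIPS, "B")
        assert call.mode == "homofusion"
        assert call.margin == 1.0 and call.n_genes == 1

    def test_minimal_heterofusion_margin_one(self):
        call = classify_fusion_mode(read_newick(HETERO_NEWICK), MINIMAL_TIPS, "B")
        assert call.mode == "heterofusion" and call.margin == 1.0

    def test_split_votes_below_margin_are_unresolved(self):
        newick = (
            "((g1|NBD|1:1,g1|NBD|2:1):2,"
            "((g2|NBD|2:1,h1|NBD|1:1):1,(g2|NBD|1:1,h2|NBD|1:1):1):2);"
        )
        tips = dict(MINIMAL_TIPS)
        tips["g2|NBD|1"] = _meta("g2|NBD|1", "N")
        tips["g2|NBD|2"] = _meta("g2|NBD|2", "C")
        call = classify_fusion_mode(read_newick(newick), tips, "B", margin_threshold=0.7)
        assert call.mode == "unresolved"
        assert call.votes == {"homofusion": 1, "heterofusion": 1, "unresolved": 0}
        assert call.margin == pytest.approx(0.5)

    def test_rotation_invariance(self):
        rotated = "((h2|NBD|1:1,h1|NBD|1:1):2,(g1|NBD|2:1,g1|NBD|1:1):2);"
        call_a = classify_fusion_mode(read_newick(HOMO_NEWICK), MINIMAL_TIPS, "B")
        call_b = classify_fusion_mode(read_newick(rotated), MINIMAL_TIPS, "B")
        assert (call_a.mode, call_a.votes, call_a.margin) == (
            call_b.mode, call_b.votes, call_b.margin
        )

    def test_absent_family_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            classify_fusion_mode(read_newick(HOMO_NEWICK), MINIMAL_TIPS, "G")

    def test_abc2_uses_single_nbd_category(self):
        """An ABC2 gene whose C-terminal NBD clusters with single-structure
        NBDs (any family) is a heterofusion vote; clustering with its own
        N-terminal is homofusion."""
        newick = "((e1|NBD|1:1,e1|NBD|2:1):2,(s1|NBD|1:1,s2|NBD|1:1):2);"
        tips = _tips(
            [
                _meta("e1|NBD|1", "N", family="E", structure="ABC2"),
                _meta("e1|NBD|2", "C", family="E", structure="ABC2"),
                _meta("s1|NBD|1", "single", family="unknown", structure="single",
                      superkingdom="archaea"),
                _meta("s2|NBD|1", "single", family="unknown", structure="single",
                      superkingdom="archaea"),
            ]
        )
        call = classify_fusion_mode(read_newick(newick), tips, "E")
        assert call.mode == "homofusion"


class TestDetectHgt:
    def _prok_meta(self, iid):
        return _meta(iid, "half", family="unknown", structure="half",
                     superkingdom="bacteria")

    def test_grafted_eukaryote_inside_prokaryote_clade_flagged(self):
        newick = (
            "((p1|NBD|1:0.1,p2|NBD|1:0.1,p3|NBD|1:0.1,p4|NBD|1:0.1,x|NBD|1:0.1):1,"
            "(e1|NBD|1:0.1,e2|NBD|1:0.1,e3|NBD|1:0.1,e4|NBD|1:0.1):1);"
        )
        tips = _tips(
            [self._prok_meta(f"p{i}|NBD|1") for i in range(1, 5)]
            + [_meta("x|NBD|1", "half", structure="half")]
            + [_meta(f"e{i}|NBD|1", "half", structure="half") for i in range(1, 5)]
        )
        flagged = detect_hgt_candidates(read_newick(newick), tips)
        assert [c.instance_id for c in flagged] == ["x|NBD|1"]
        assert flagged[0].prokaryote_fraction == 1.0
        # the eukaryote clade members are not flagged
        assert all(not c.instance_id.startswith("e") for c in flagged)

    def test_eukaryote_sister_to_eukaryote_clade_not_flagged(self):
        newick = (
            "((e1|NBD|1:0.1,e2|NBD|1:0.1,e3|NBD|1:0.1,x|NBD|1:0.1):1,"
            "(p1|NBD|1:0.1,p2|NBD|1:0.1,p3|NBD|1:0.1,p4|NBD|1:0.1):1);"
        )
        tips = _tips(
            [self._prok_meta(f"p{i}|NBD|1") for i in range(1, 5)]
            + [_meta("x|NBD|1", "half", structure="half")]
            + [_meta(f"e{i}|NBD|1", "half", structure="half") for i in range(1, 4)]
        )
        assert detect_hgt_candidates(read_newick(newick), tips) == []

    def test_all_eukaryote_tree_yields_empty_list(self):
        newick = "((e1|NBD|1:1,e2|NBD|1:1):1,(e3|NBD|1:1,e4|NBD|1:1):1);"
        tips = _tips(
            [_meta(f"e{i}|NBD|1", "half", structure="half") for i in range(1, 5)]
        )
        assert detect_hgt_candidates(read_newick(newick), tips) == []

    def test_tiny_tree_warns_and_returns_empty(self, caplog):
        newick = "(e1|NBD|1:1,e2|NBD|1:1,p1|NBD|1:1);"
        tips = _tips(
            [
                _meta("e1|NBD|1", "half", structure="half"),
                _meta("e2|NBD|1", "half", structure="half"),
                self._prok_meta("p1|NBD|1"),
            ]
        )
        assert detect_hgt_candidates(read_newick(newick), tips, min_clade=4) == []
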