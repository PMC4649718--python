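"""Substitution model, fusion construction and history simulation."""

import math

import numpy as np
import pytest

from abc_structevol import (
    DomainHit,
    SimConfig,
    build_architecture,
    evolve_sequence,
    expected_difference_fraction,
    make_fusion,
    read_dataset,
    read_newick,
    patristic_matrix,
    resolve_hits,
    simulate_history,
    write_dataset,
)
from abc_structevol.simulate import SimProtein, random_sequence


def _diff_fraction(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestEvolveSequence:
    def test_zero_branch_is_identity(self):
        rng = np.random.default_rng(0)
        seq = random_sequence(500, rng)
        assert evolve_sequence(seq, 0.0, rng) == seq

    @pytest.mark.parametrize("t", [0.1, 0.5, 1.0])
    def test_difference_fraction_matches_closed_form(self, t):
        """Empirical p over 30,000 sites within 3 binomial SE of
        p(t) = (19/20)(1 - exp(-(20/19)t))."""
        n = 30_000
        rng = np.random.default_rng(42)
        seq = random_sequence(n, rng)
        p_exp = expected_difference_fraction(t)
        p_obs = _diff_fraction(seq, evolve_sequence(seq, t, rng))
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(p_obs - p_exp) <= 3 * se

    def test_saturation_limit(self):
        """At huge branch lengths the difference fraction approaches 19/20."""
        rng = np.random.default_rng(7)
        seq = random_sequence(10_000, rng)
        p_obs = _diff_fraction(seq, evolve_sequence(seq, 50.0, rng))
        se = math.sqrt(0.95 * 0.05 / 10_000)
        assert abs(p_obs - 0.95) <= 3 * se

    def test_rejects_negative_branch_and_bad_residues(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            evolve_sequence("ACDE", -0.1, rng)
        with pytest.raises(ValueError, match="non-standard"):
            evolve_sequence("ACDX", 0.1, rng)


class TestMakeFusion:
    def _half(self, pid, rng, tmd=30, linker=5, nbd=20):
        seq = random_sequence(tmd + linker + nbd, rng)
        hits = (
            DomainHit(pid, "ABC_membrane", 1, tmd, 100.0, 1e-30),
            DomainHit(pid, "NBD", tmd + linker + 1, tmd + linker + nbd, 100.0, 1e-30),
        )
        return SimProtein(pid, "t", "eukaryote", "B", seq, hits)

    def test_two_halves_make_full_architecture(self):
        rng = np.random.default_rng(1)
        fused = make_fusion(self._half("a", rng), self._half("b", rng), 0, rng)
        arch = build_architecture(fused.protein_id, resolve_hits(list(fused.hits)))
        assert arch.domain_string == ("TMD", "NBD", "TMD", "NBD")
        assert arch.structure == "full"

    def test_two_singles_make_abc2(self):
        rng = np.random.default_rng(2)
        singles = []
        for pid in ("x", "y"):
            seq = random_sequence(50, rng)
            hits = (DomainHit(pid, "NBD", 1, 50, 100.0, 1e-30),)
            singles.append(SimProtein(pid, "t", "archaea", "E", seq, hits))
        fused = make_fusion(singles[0], singles[1], 5, rng)
        arch = build_architecture(fused.protein_id, resolve_hits(list(fused.hits)))
        assert arch.domain_string == ("NBD", "NBD")
        assert arch.structure == "ABC2"

    def test_second_partner_hits_shift_by_length_plus_linker(self):
        rng = np.random.default_rng(3)
        a, b = self._half("a", rng), self._half("b", rng)
        fused = make_fusion(a, b, 3, rng)
        offset = len(a.sequence) + 3
        assert fused.hits[2].start == b.hits[0].start + offset
        assert len(fused.sequence) == len(a.sequence) + 3 + len(b.sequence)
        # fused subsequences are the partners' sequences verbatim
        assert fused.sequence[: len(a.sequence)] == a.sequence
        assert fused.sequence[offset:] == b.sequence


class TestSimulateHistory:
    def test_homofusion_composition(self, homofusion_dataset):
        ds = homofusion_dataset
        assert ds.truth.fusion_mode == "homofusion"
        fulls = [p for p in ds.proteins if len(p.hits) == 4]
        halves = [p for p in ds.proteins if len(p.hits) == 2]
        assert len(fulls) == 4 and len(halves) == 4

    def test_hgt_mix_has_one_grafted_eukaryote(self):
        ds = simulate_history(
            SimConfig(scenario="hgt_mix", n_taxa=4, n_prokaryote_lineages=3, seed=5)
        )
        graft = ds.truth.graft_tip_protein
        assert graft is not None
        grafted = [p for p in ds.proteins if p.protein_id == graft]
        assert len(grafted) == 1 and grafted[0].superkingdom == "eukaryote"
        # the graft sits inside a prokaryote clade on the truth tree
        tree = read_newick(ds.truth.trees["NBD"])
        leaf = next(
            lf for lf in tree.leaf_node_iter()
            if lf.taxon.label.startswith(graft + "|")
        )
        siblings = {
            lf.taxon.label.split("|")[0]
            for lf in leaf.parent_node.leaf_nodes()
        } - {graft}
        assert siblings and all(s.startswith("prok") for s in siblings)

    def test_determinism_same_seed_same_bytes(self, tmp_path):
        cfg = SimConfig(scenario="heterofusion", n_taxa=3, seed=99)
        for d in ("a", "b"):
            write_dataset(simulate_history(cfg), tmp_path / d)
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            SimConfig(scenario="fission")

    def test_truth_tree_additivity(self, homofusion_dataset):
        """Patristic distances on the truth tree equal the sums of simulated
        branch lengths along the history."""
        cfg = homofusion_dataset.config
        tree = read_newick(homofusion_dataset.truth.trees["NBD"])
        dm = patristic_matrix(tree)
        w = cfg.within_group_divergence
        pre, post = cfg.pre_fusion_divergence, cfg.post_fusion_divergence

        def d(a, b):
            return dm.values[dm.ids.index(a), dm.ids.index(b)]

        # two tips of one clade
        assert d("fullB_t1|NBD|1", "fullB_t2|NBD|1") == pytest.approx(2 * w)
        # N vs C terminal of the same gene: through the duplication node
        assert d("fullB_t1|NBD|1", "fullB_t1|NBD|2") == pytest.approx(
            2 * (w + post + pre)
        )
        # full-gene tip vs half sister lineage: through both sister stems
        assert d("fullB_t1|NBD|1", "halfB_t1|NBD|1") == pytest.approx(
            (w + post + pre) + 2 * post + w
        )

    def test_write_read_round_trip(self, tmp_path, heterofusion_dataset):
        write_dataset(heterofusion_dataset, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        assert back.domain_hits == heterofusion_dataset.domain_hits
        assert [p.sequence for p in back.proteins] == [
            p.sequence for p in heterofusion_dataset.proteins
        ]
        assert back.truth.fusion_mode == "heterofusion"
        assert back.helix_tables == heterofusion_dataset.helix_tables

    def test_empty_dataset_writes_valid_files(self, tmp_path, caplog):
        from abc_structevol.simulate import SimulatedDataset, Truth

        ds = SimulatedDataset(
            SimConfig(scenario="half_only", seed=0),
            [],
            [],
            Truth("half_only", None, [], {}),
        )
        write_dataset(ds, tmp_path / "empty")
        assert (tmp_path / "empty" / "proteins.faa").read_text() == ""
        assert (
            (tmp_path / "empty" / "domain_hits.tsv").read_text().splitlines()[0]
            == "protein_id\tdomain_class\tstart\tend\tscore\tevalue"
        )

    def test_every_simulated_full_classifies_as_full(self, homofusion_dataset):
        for p in homofusion_dataset.proteins:
            arch = build_architecture(p.protein_id, resolve_hits(list(p.hits)))
            expected = "full" if p.protein_id.startswith("full") else "half"
            assert arch.structure == expected
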