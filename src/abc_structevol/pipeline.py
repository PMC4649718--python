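"""End-to-end orchestration: inputs → architectures → domains → alignment →
trees → fusion/HGT calls → helix distributions.

A single JSON config drives the run; unknown keys anywhere in the document
are errors (a silently ignored typo in a threshold would invalidate fusion
calls).  Identical config + seed produces byte-identical result bundles: no
timestamps enter any output file, every random choice is seeded from the
config, and trees are serialized in canonical child order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Any

from . import __version__
from .alignment import Alignment, group_mean_identity, trim_columns
from .architectures import (
    DEFAULT_MAX_EVALUE,
    DEFAULT_MIN_SCORE,
    build_architecture,
    parse_domain_table,
    resolve_hits,
    write_architectures,
)
from .domains import (
    extract_for_architecture,
    write_instance_fasta,
    write_tip_metadata,
)
from .fusion import (
    DEFAULT_MARGIN,
    DEFAULT_MIN_CLADE,
    DEFAULT_MIN_PROK_FRACTION,
    classify_fusion_mode,
    detect_hgt_candidates,
    write_fusion_calls,
    write_hgt_candidates,
)
from .helices import DEFAULT_BOUNDARY, HelixTable, read_helix_tables, spacing_distribution
from .phylo import bootstrap_support, correct_matrix, neighbor_joining, p_distance, write_newick
from .simulate import SimConfig, read_dataset, simulate_history, write_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


def _strict_update(defaults: dict, overrides: dict, context: str) -> dict:
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(overrides)
    return merged


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration; every parameter defaults to the
    module-level default it overrides."""

    mode: str = "simulate"
    out_dir: str = "results"
    simulate: dict = dataclasses.field(default_factory=dict)
    files: dict = dataclasses.field(default_factory=dict)
    architectures: dict = dataclasses.field(default_factory=dict)
    alignment: dict = dataclasses.field(default_factory=dict)
    phylo: dict = dataclasses.field(default_factory=dict)
    fusion: dict = dataclasses.field(default_factory=dict)
    helices: dict = dataclasses.field(default_factory=dict)

    _SIM_DEFAULTS = {
        f.name: (None if f.default is dataclasses.MISSING else f.default)
        for f in dataclasses.fields(SimConfig)
    }
    _FILES_DEFAULTS = {
        "fasta": None,
        "hits": None,
        "hits_dialect": "tsv",
        "metadata": None,
        "alignment_nbd": None,
        "alignment_tmd": None,
        "helices": None,
    }
    _ARCH_DEFAULTS = {"min_score": DEFAULT_MIN_SCORE, "max_evalue": DEFAULT_MAX_EVALUE}
    _ALN_DEFAULTS = {"max_gap_fraction": 0.20}
    _PHYLO_DEFAULTS = {"n_bootstrap": 100, "bootstrap_seed": 0, "on_saturation": "cap"}
    _FUSION_DEFAULTS = {
        "margin_threshold": DEFAULT_MARGIN,
        "min_clade": DEFAULT_MIN_CLADE,
        "min_prok_fraction": DEFAULT_MIN_PROK_FRACTION,
    }
    _HELICES_DEFAULTS = {"boundary": DEFAULT_BOUNDARY}

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and "scenario" not in self.simulate:
            raise ValueError("simulate mode requires simulate.scenario")
        sim_defaults = dict(self._SIM_DEFAULTS)
        sim_defaults["scenario"] = self.simulate.get("scenario")
        self.simulate = _strict_update(sim_defaults, self.simulate, "simulate")
        self.files = _strict_update(self._FILES_DEFAULTS, self.files, "files")
        self.architectures = _strict_update(
            self._ARCH_DEFAULTS, self.architectures, "architectures"
        )
        self.alignment = _strict_update(self._ALN_DEFAULTS, self.alignment, "alignment")
        self.phylo = _strict_update(self._PHYLO_DEFAULTS, self.phylo, "phylo")
        self.fusion = _strict_update(self._FUSION_DEFAULTS, self.fusion, "fusion")
        self.helices = _strict_update(self._HELICES_DEFAULTS, self.helices, "helices")

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, "rt") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    paths: dict[str, str]
    architectures: list
    instances: list
    trees: dict[str, Any]
    identity: Any
    fusion_calls: list
    hgt_candidates: list
    counts: dict[str, Any]


def _require_file(path, what: str):
    if path is None or not os.path.exists(str(path)):
        raise PipelineError(f"stage inputs: missing {what}: {path}")
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages and write the result bundle into ``config.out_dir``."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    paths: dict[str, str] = {}
    counts: dict[str, Any] = {}

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.mode == "simulate":
            sim_cfg = SimConfig(**config.simulate)
            dataset = simulate_history(sim_cfg)
            sim_dir = os.path.join(out, "sim_data")
            write_dataset(dataset, sim_dir)
            paths["sim_data"] = sim_dir
            # round-trip through the on-disk formats so the files mode path
            # is exercised on every simulated run
            dataset = read_dataset(sim_dir)
            proteins = [
                (p.protein_id, p.sequence, p.taxon, p.superkingdom, p.family)
                for p in dataset.proteins
            ]
            hits = dataset.domain_hits
            helix_tables = [HelixTable(iid, spans) for iid, spans in dataset.helix_tables]
        else:
            fasta = _require_file(config.files["fasta"], "FASTA")
            hits_path = _require_file(config.files["hits"], "domain-hit table")
            meta_path = _require_file(config.files["metadata"], "metadata table")
            sequences: dict[str, str] = {}
            order: list[str] = []
            with open(fasta, "rt") as fh:
                pid = None
                for line in fh:
                    line = line.rstrip("\n")
                    if line.startswith(">"):
                        pid = line[1:].split()[0]
                        sequences[pid] = ""
                        order.append(pid)
                    elif pid is not None:
                        sequences[pid] += line
            hits = parse_domain_table(
                hits_path,
                dialect=config.files["hits_dialect"],
                sequence_lengths={k: len(v) for k, v in sequences.items()},
            )
            meta: dict[str, tuple[str, str, str]] = {}
            with open(meta_path, "rt") as fh:
                fh.readline()
                for line in fh:
                    pid, taxon, sk, fam = line.rstrip("\n").split("\t")
                    meta[pid] = (taxon, sk, fam)
            proteins = [
                (pid, sequences[pid], *meta.get(pid, ("unknown", "eukaryote", "unknown")))
                for pid in order
            ]
            helix_tables = (
                read_helix_tables(config.files["helices"])
                if config.files["helices"]
                else []
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage inputs: {exc}") from exc
    counts["n_proteins"] = len(proteins)
    counts["n_domain_hits"] = len(hits)
    logger.info("inputs: %d proteins, %d domain hits", len(proteins), len(hits))

    # ---- stage: architectures ------------------------------------------
    try:
        hits_by_protein: dict[str, list] = {}
        for h in hits:
            hits_by_protein.setdefault(h.protein_id, []).append(h)
        architectures = []
        resolved_by_protein: dict[str, list] = {}
        for pid, seq, taxon, sk, fam in proteins:
            resolved = resolve_hits(
                hits_by_protein.get(pid, []),
                min_score=config.architectures["min_score"],
                max_evalue=config.architectures["max_evalue"],
            )
            resolved_by_protein[pid] = resolved
            architectures.append(build_architecture(pid, resolved, family_label=fam))
        paths["architectures"] = os.path.join(out, "architectures.tsv")
        write_architectures(architectures, paths["architectures"])
    except Exception as exc:
        raise PipelineError(f"stage architectures: {exc}") from exc
    counts["n_suspect"] = sum(a.suspect for a in architectures)

    # ---- stage: domain extraction --------------------------------------
    try:
        instances = []
        for (pid, seq, taxon, sk, fam), arch in zip(proteins, architectures):
            if arch.structure == "other":
                logger.info("protein %s structure 'other': not extracted", pid)
                continue
            instances.extend(
                extract_for_architecture(
                    seq, resolved_by_protein[pid], arch, family=fam, superkingdom=sk
                )
            )
        by_class: dict[str, list] = {"NBD": [], "TMD": []}
        for inst in instances:
            by_class[inst.domain_class].append(inst)
        for cls, members in by_class.items():
            if members:
                paths[f"fasta_{cls}"] = os.path.join(out, f"{cls}.faa")
                write_instance_fasta(members, paths[f"fasta_{cls}"])
        paths["tips"] = os.path.join(out, "tips.tsv")
        write_tip_metadata(instances, paths["tips"])
        tips_meta = {
            inst.instance_id: {
                "instance_id": inst.instance_id,
                "protein_id": inst.protein_id,
                "domain_class": inst.domain_class,
                "subclass": inst.subclass,
                "terminal": inst.terminal,
                "family": inst.family,
                "superkingdom": inst.superkingdom,
                "structure": inst.structure,
            }
            for inst in instances
        }
    except Exception as exc:
        raise PipelineError(f"stage domains: {exc}") from exc
    counts["n_instances"] = {cls: len(m) for cls, m in by_class.items()}

    # ---- stage: alignment ----------------------------------------------
    alignments: dict[str, Alignment] = {}
    try:
        for cls, members in by_class.items():
            if len(members) < 2:
                continue
            external = config.files.get(f"alignment_{cls.lower()}")
            if config.mode == "files" and external:
                aln = Alignment.from_fasta(_require_file(external, f"{cls} alignment"))
            else:
                lengths = {len(m.sequence) for m in members}
                if len(lengths) != 1:
                    raise ValueError(
                        f"{cls} instances have unequal lengths {sorted(lengths)}; "
                        "provide an externally aligned FASTA"
                    )
                aln = Alignment(
                    [m.instance_id for m in members], [m.sequence for m in members]
                )
            alignments[cls] = trim_columns(aln, config.alignment["max_gap_fraction"])
            paths[f"alignment_{cls}"] = os.path.join(out, f"{cls}.trimmed.afa")
            alignments[cls].to_fasta(paths[f"alignment_{cls}"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage alignment: {exc}") from exc
    counts["n_retained_columns"] = {
        cls: int(a.mask.sum()) for cls, a in alignments.items()
    }

    # ---- stage: identity ------------------------------------------------
    identity = None
    try:
        if "NBD" in alignments:
            groups = {
                i: tips_meta[i]["family"] for i in alignments["NBD"].ids
            }
            identity = group_mean_identity(alignments["NBD"], groups)
            paths["identity_NBD"] = os.path.join(out, "identity_NBD.tsv")
            identity.to_tsv(paths["identity_NBD"])
    except Exception as exc:
        raise PipelineError(f"stage identity: {exc}") from exc

    # ---- stage: trees ---------------------------------------------------
    trees: dict[str, Any] = {}
    try:
        for cls, aln in alignments.items():
            if aln.n_rows < 3:
                continue
            n_boot = config.phylo["n_bootstrap"]
            policy = config.phylo["on_saturation"]
            if n_boot > 0 and aln.n_rows >= 4:
                tree = bootstrap_support(
                    aln, n_replicates=n_boot,
                    seed=config.phylo["bootstrap_seed"],
                    on_saturation=policy,
                )
            else:
                dm = correct_matrix(
                    p_distance(aln),
                    on_saturation=policy,
                    alignment_length=int(aln.mask.sum()),
                )
                tree = neighbor_joining(dm)
            trees[cls] = tree
            paths[f"tree_{cls}"] = os.path.join(out, f"tree_{cls}.nwk")
            write_newick(tree, paths[f"tree_{cls}"])
    except Exception as exc:
        raise PipelineError(f"stage trees: {exc}") from exc
    counts["n_tree_tips"] = {
        cls: len(t.leaf_nodes()) for cls, t in trees.items()
    }

    # ---- stage: fusion calls -------------------------------------------
    fusion_calls = []
    try:
        if "NBD" in trees:
            fused_families = sorted(
                {
                    m["family"]
                    for m in tips_meta.values()
                    if m["domain_class"] == "NBD"
                    and m["structure"] in ("full", "ABC2")
                    and m["family"] != "unknown"
                }
            )
            for fam in fused_families:
                fusion_calls.append(
                    classify_fusion_mode(
                        trees["NBD"],
                        tips_meta,
                        fam,
                        margin_threshold=config.fusion["margin_threshold"],
                    )
                )
        paths["fusion_calls"] = os.path.join(out, "fusion_calls.tsv")
        write_fusion_calls(fusion_calls, paths["fusion_calls"])
    except Exception as exc:
        raise PipelineError(f"stage fusion: {exc}") from exc

    # ---- stage: HGT detection ------------------------------------------
    hgt_candidates = []
    try:
        if "NBD" in trees:
            hgt_candidates = detect_hgt_candidates(
                trees["NBD"],
                tips_meta,
                min_clade=config.fusion["min_clade"],
                min_prok_fraction=config.fusion["min_prok_fraction"],
            )
        paths["hgt_candidates"] = os.path.join(out, "hgt_candidates.tsv")
        write_hgt_candidates(hgt_candidates, paths["hgt_candidates"])
    except Exception as exc:
        raise PipelineError(f"stage hgt: {exc}") from exc

    # ---- stage: helix spacing ------------------------------------------
    try:
        if helix_tables:
            fam_map = {
                t.instance_id: tips_meta.get(t.instance_id, {}).get("family", "unknown")
                for t in helix_tables
            }
            for which in ("first_pair", "last_pair"):
                dist = spacing_distribution(
                    helix_tables, fam_map,
                    boundary=config.helices["boundary"], which=which,
                )
                key = f"helix_spacing_{which}"
                paths[key] = os.path.join(out, f"{key}.tsv")
                dist.to_csv(paths[key], sep="\t", float_format="%.3f", na_rep="NA")
    except Exception as exc:
        raise PipelineError(f"stage helices: {exc}") from exc
    counts["n_helix_tables"] = len(helix_tables)
    counts["n_fusion_calls"] = len(fusion_calls)
    counts["n_hgt_candidates"] = len(hgt_candidates)

    # ---- run log --------------------------------------------------------
    log_doc = {
        "package_version": __version__,
        "config": config.to_dict(),
        "counts": counts,
        "fusion_calls": [
            {"family": c.family_label, "mode": c.mode, "margin": c.margin,
             "votes": c.votes, "n_genes": c.n_genes}
            for c in fusion_calls
        ],
        "hgt_candidates": [
            {"instance_id": c.instance_id,
             "prokaryote_fraction": c.prokaryote_fraction,
             "clade_size": c.clade_size}
            for c in hgt_candidates
        ],
    }
    paths["run_log"] = os.path.join(out, "run_log.json")
    with open(paths["run_log"], "wt") as fh:
        json.dump(log_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        config=config,
        paths=paths,
        architectures=architectures,
        instances=instances,
        trees=trees,
        identity=identity,
        fusion_calls=fusion_calls,
        hgt_candidates=hgt_candidates,
        counts=counts,
    )
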