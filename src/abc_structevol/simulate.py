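"""Simulation of ABC transporter duplication–fusion histories.

The structural repertoire of ABC transporters (single, half, ABC2, full) is
thought to have arisen by gene duplication followed by fusion: a TMD and an
NBD fuse into a half transporter; two halves fuse into a full transporter;
two NBDs fuse into the ABC2 structure.  Full/ABC2 genes can arise in two
modes distinguishable from domain phylogenies:

* **homofusion** — fusion shortly after duplication: the N- and C-terminal
  domains of the fused genes cluster with each other before clustering with
  half-structure domains;
* **heterofusion** — fusion of two long-diverged halves: one terminal domain
  clusters with half-structure domains before its own gene's other terminal.

This module generates protein datasets from explicit histories of these two
modes (plus half-only, ABC2 and HGT-mixture scenarios) with full ground
truth: the event log, the true fusion mode, and the true per-domain gene
trees.  Sequences evolve under a uniform-replacement Poisson substitution
model: each site accumulates Poisson(t) substitutions over a branch of
length *t* expected substitutions/site, and each substitution replaces the
residue with one of the other 19 uniformly.  The expected observed
difference fraction is then the closed form

    p(t) = (19/20) * (1 - exp(-(20/19) * t)),

which makes the model analytically invertible (see ``phylo.correct_distance``).
No indels are simulated, so extracted domain instances of one class are
already columnwise homologous ("identity stacking") and the alignment stage
can run without any MSA heuristic.

Determinism: one NumPy generator seeded from the config drives every random
choice, and events are executed in a fixed documented order, so identical
configs produce byte-identical datasets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Sequence

import numpy as np

from .architectures import DomainHit, collapse_class

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARRAY = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

SCENARIOS = ("homofusion", "heterofusion", "half_only", "abc2", "hgt_mix")

#: Synthetic score/E-value attached to simulated domain hits; comfortably
#: inside the default resolution thresholds.
SIM_HIT_SCORE = 100.0
SIM_HIT_EVALUE = 1e-30

#: Transmembrane-helix geometry for simulated helix tables (TMD-local,
#: 1-based).  Family A emulates the long first inter-helix loop.
HELIX_LENGTH = 21
FIRST_LOOP_MEAN = {"A": 130.0}
FIRST_LOOP_MEAN_DEFAULT = 60.0
FIRST_LOOP_SD = 15.0


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated duplication–fusion history.

    Divergences are expected substitutions per site.  ``pre_fusion_divergence``
    is accumulated by *each* duplicate copy between duplication and fusion;
    ``post_fusion_divergence`` is the stem branch of a radiating lineage after
    fusion; ``within_group_divergence`` is the terminal branch of every tip,
    so two tips of one lineage are separated by twice that value.
    """

    scenario: str
    n_taxa: int = 6
    nbd_length: int = 180
    tmd_length: int = 260
    pre_fusion_divergence: float = 0.05
    post_fusion_divergence: float = 0.4
    within_group_divergence: float = 0.1
    linker_length: int = 10
    n_prokaryote_lineages: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.n_taxa < 1 or self.nbd_length < 1 or self.tmd_length < 1:
            raise ValueError("n_taxa and domain lengths must be positive")
        for name in (
            "pre_fusion_divergence",
            "post_fusion_divergence",
            "within_group_divergence",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")
        if self.scenario == "hgt_mix" and self.n_prokaryote_lineages < 1:
            raise ValueError("hgt_mix needs n_prokaryote_lineages >= 1")


@dataclasses.dataclass(frozen=True)
class SimProtein:
    """A simulated protein with its domain hits."""

    protein_id: str
    taxon: str
    superkingdom: str  # eukaryote | bacteria | archaea
    family: str  # A..G | unknown
    sequence: str
    hits: tuple[DomainHit, ...]


@dataclasses.dataclass
class Truth:
    """Ground truth of a simulated dataset."""

    scenario: str
    fusion_mode: str | None  # homofusion | heterofusion | None
    events: list[dict]
    trees: dict[str, str]  # domain class -> Newick with instance-id tips
    graft_tip_protein: str | None = None  # hgt_mix: the grafted eukaryote


@dataclasses.dataclass
class SimulatedDataset:
    config: SimConfig
    proteins: list[SimProtein]
    helix_tables: list[tuple[str, list[tuple[int, int]]]]  # (TMD instance id, spans)
    truth: Truth

    @property
    def domain_hits(self) -> list[DomainHit]:
        return [h for p in self.proteins for h in p.hits]


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def evolve_sequence(seq: str, branch_length: float, rng: np.random.Generator) -> str:
    """Evolve an amino-acid sequence along a branch of the given expected
    number of substitutions per site.

    Each site receives Poisson(branch_length) substitution events; each event
    replaces the current residue with one of the other 19, uniformly.  The
    sequence length never changes (no indels).
    """
    if branch_length < 0:
        raise ValueError(f"negative branch length: {branch_length}")
    if not seq:
        raise ValueError("empty sequence")
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    state = np.searchsorted(_AA_ARRAY, codes)
    if not np.all(_AA_ARRAY[np.clip(state, 0, 19)] == codes):
        bad = sorted(set(seq) - set(AMINO_ACIDS))
        raise ValueError(f"non-standard residues in sequence: {bad}")
    if branch_length == 0:
        return seq
    state = state.copy()
    remaining = rng.poisson(branch_length, size=state.size)
    while True:
        active = np.flatnonzero(remaining > 0)
        if active.size == 0:
            break
        # jump to one of the other 19 residues, uniformly
        state[active] = (state[active] + 1 + rng.integers(0, 19, size=active.size)) % 20
        remaining[active] -= 1
    return _AA_ARRAY[state].tobytes().decode()


def expected_difference_fraction(branch_length: float) -> float:
    """Closed-form expected observed difference fraction of the
    uniform-replacement Poisson model: p(t) = (19/20)(1 - exp(-(20/19) t))."""
    return (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * branch_length))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _AA_ARRAY[rng.integers(0, 20, size=length)].tobytes().decode()


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------


def make_fusion(
    protein_a: SimProtein,
    protein_b: SimProtein,
    linker_length: int,
    rng: np.random.Generator,
    protein_id: str | None = None,
) -> SimProtein:
    """Fuse two proteins head-to-tail with a random linker.

    The fused sequence is ``seq_a + linker + seq_b``; the second protein's
    hits are shifted by ``len(seq_a) + linker_length`` so domain order is
    preserved.  Identity metadata is taken from *protein_a*.
    """
    if not protein_a.hits or not protein_b.hits:
        raise ValueError("both fusion partners must carry domain hits")
    if linker_length < 0:
        raise ValueError("linker_length must be >= 0")
    linker = random_sequence(linker_length, rng) if linker_length else ""
    offset = len(protein_a.sequence) + linker_length
    fused_id = protein_id or f"{protein_a.protein_id}+{protein_b.protein_id}"
    hits = tuple(
        [dataclasses.replace(h, protein_id=fused_id) for h in protein_a.hits]
        + [
            dataclasses.replace(h.shifted(offset), protein_id=fused_id)
            for h in protein_b.hits
        ]
    )
    return SimProtein(
        protein_id=fused_id,
        taxon=protein_a.taxon,
        superkingdom=protein_a.superkingdom,
        family=protein_a.family,
        sequence=protein_a.sequence + linker + protein_b.sequence,
        hits=hits,
    )


# ---------------------------------------------------------------------------
# History simulation
# ---------------------------------------------------------------------------


def _ancestral_half(cfg: SimConfig, rng: np.random.Generator, pid: str) -> SimProtein:
    """Random TMD-NBD half-structure ancestor (TMD-leading)."""
    tmd = random_sequence(cfg.tmd_length, rng)
    linker = random_sequence(cfg.linker_length, rng)
    nbd = random_sequence(cfg.nbd_length, rng)
    nbd_start = cfg.tmd_length + cfg.linker_length + 1
    hits = (
        DomainHit(pid, "ABC_membrane", 1, cfg.tmd_length, SIM_HIT_SCORE, SIM_HIT_EVALUE),
        DomainHit(pid, "NBD", nbd_start, nbd_start + cfg.nbd_length - 1,
                  SIM_HIT_SCORE, SIM_HIT_EVALUE),
    )
    return SimProtein(pid, "ancestor", "eukaryote", "unknown", tmd + linker + nbd, hits)


def _ancestral_single_nbd(cfg: SimConfig, rng: np.random.Generator, pid: str) -> SimProtein:
    nbd = random_sequence(cfg.nbd_length, rng)
    hits = (DomainHit(pid, "NBD", 1, cfg.nbd_length, SIM_HIT_SCORE, SIM_HIT_EVALUE),)
    return SimProtein(pid, "ancestor", "archaea", "unknown", nbd, hits)


def _evolved(p: SimProtein, t: float, rng: np.random.Generator) -> SimProtein:
    return dataclasses.replace(p, sequence=evolve_sequence(p.sequence, t, rng))


def _tip(
    p: SimProtein,
    t: float,
    rng: np.random.Generator,
    pid: str,
    taxon: str,
    superkingdom: str,
    family: str,
) -> SimProtein:
    evolved = evolve_sequence(p.sequence, t, rng)
    hits = tuple(dataclasses.replace(h, protein_id=pid) for h in p.hits)
    return SimProtein(pid, taxon, superkingdom, family, evolved, hits)


def _instance_id(protein_id: str, collapsed: str, ordinal: int) -> str:
    # kept in sync with domains.instance_id; defined here to avoid a cycle
    return f"{protein_id}|{collapsed}|{ordinal}"


def _clade_newick(tip_ids: Sequence[str], tip_len: float, stem: float) -> str:
    inner = ",".join(f"{t}:{tip_len:g}" for t in tip_ids)
    return f"({inner}):{stem:g}"


def _nbd_tips(proteins: Sequence[SimProtein], ordinal: int = 1) -> list[str]:
    return [_instance_id(p.protein_id, "NBD", ordinal) for p in proteins]


def _tmd_tips(proteins: Sequence[SimProtein], ordinal: int = 1) -> list[str]:
    return [_instance_id(p.protein_id, "TMD", ordinal) for p in proteins]


def simulate_history(config: SimConfig) -> SimulatedDataset:
    """Run one duplication–fusion history and return the dataset with truth.

    Scenarios (all radiations are stars; *w* = within_group_divergence,
    *pre* / *post* as in :class:`SimConfig`):

    ``homofusion``
        A half ancestor splits into the fusion lineage and a half sister
        lineage (stem *post* on each side); the fusion lineage duplicates,
        each copy evolves *pre* (short), the copies fuse into a full gene
        which evolves *post* and radiates ``n_taxa`` tips; the sister
        radiates ``n_taxa`` half tips.
    ``heterofusion``
        The ancestor duplicates at the root; each copy evolves *pre* (long);
        one copy then duplicates again at fusion time — one daughter fuses
        (as the C-terminal half) with the other long-diverged copy (the
        N-terminal half), the other daughter remains the extant half lineage.
        Both the full and half lineages then evolve *post* and radiate.
    ``half_only``
        Two half lineages (families A and B) diverge *pre* and radiate.
    ``abc2``
        As ``homofusion`` but fusing two single-NBD genes into an NBD-NBD
        (ABC2) gene, with a single-NBD archaeal sister lineage.
    ``hgt_mix``
        A star of ``n_prokaryote_lineages`` prokaryote half clades plus one
        eukaryote half clade (stem *post* each, tips *w*), with one extra
        eukaryote-labelled tip grafted inside a random prokaryote clade.
    """
    rng = np.random.default_rng(config.seed)
    builder = {
        "homofusion": _simulate_fusion_radiation,
        "heterofusion": _simulate_heterofusion,
        "half_only": _simulate_half_only,
        "abc2": _simulate_fusion_radiation,
        "hgt_mix": _simulate_hgt_mix,
    }[config.scenario]
    dataset = builder(config, rng)
    dataset.helix_tables.extend(_make_helix_tables(dataset.proteins, config, rng))
    return dataset


def _simulate_fusion_radiation(cfg: SimConfig, rng: np.random.Generator) -> SimulatedDataset:
    """Shared homofusion machinery for the ``homofusion`` (half ancestor,
    family B) and ``abc2`` (single-NBD ancestor, family E) scenarios."""
    abc2 = cfg.scenario == "abc2"
    fam = "E" if abc2 else "B"
    pre, post, w = (
        cfg.pre_fusion_divergence,
        cfg.post_fusion_divergence,
        cfg.within_group_divergence,
    )
    stem = post  # sister-lineage split depth on each side of the root
    events: list[dict] = []
    anc = (_ancestral_single_nbd if abc2 else _ancestral_half)(cfg, rng, "anc")
    events.append({"event": "root", "gene": "anc"})
    fusion_side = _evolved(anc, stem, rng)
    sister = _evolved(anc, stem, rng)
    events.append({"event": "divergence", "lineages": ["fusion_side", "sister"],
                   "branch_length": stem})
    alpha = _evolved(fusion_side, pre, rng)
    beta = _evolved(fusion_side, pre, rng)
    events.append({"event": "duplication", "copies": ["alpha", "beta"],
                   "branch_length": pre})
    full_anc = make_fusion(alpha, beta, cfg.linker_length, rng, protein_id="full_anc")
    events.append({"event": "fusion", "mode": "homofusion",
                   "n_terminal": "alpha", "c_terminal": "beta"})
    full_anc = _evolved(full_anc, post, rng)
    prefix = "abc2" if abc2 else "full"
    fused, halves = [], []
    for i in range(1, cfg.n_taxa + 1):
        fused.append(_tip(full_anc, w, rng, f"{prefix}{fam}_t{i}", f"t{i}",
                          "eukaryote", fam))
    sister_kind = "single" if abc2 else "half"
    sister_sk = "archaea" if abc2 else "eukaryote"
    sister_fam = "unknown" if abc2 else fam
    for i in range(1, cfg.n_taxa + 1):
        halves.append(_tip(sister, w, rng, f"{sister_kind}{sister_fam}_t{i}", f"t{i}",
                           sister_sk, sister_fam))
    events.append({"event": "radiation", "n_taxa": cfg.n_taxa, "tip_branch": w})

    trees = {}
    n_clade = _clade_newick([_instance_id(p.protein_id, "NBD", 1) for p in fused],
                            w, pre + post)
    c_clade = _clade_newick([_instance_id(p.protein_id, "NBD", 2) for p in fused],
                            w, pre + post)
    h_clade = _clade_newick(_nbd_tips(halves), w, 2 * stem)
    trees["NBD"] = f"({n_clade},{c_clade},{h_clade});"
    if not abc2:
        n_t = _clade_newick([_instance_id(p.protein_id, "TMD", 1) for p in fused],
                            w, pre + post)
        c_t = _clade_newick([_instance_id(p.protein_id, "TMD", 2) for p in fused],
                            w, pre + post)
        h_t = _clade_newick(_tmd_tips(halves), w, 2 * stem)
        trees["TMD"] = f"({n_t},{c_t},{h_t});"

    truth = Truth(cfg.scenario, "homofusion", events, trees)
    return SimulatedDataset(cfg, fused + halves, [], truth)


def _simulate_heterofusion(cfg: SimConfig, rng: np.random.Generator) -> SimulatedDataset:
    fam = "A"
    pre, post, w = (
        cfg.pre_fusion_divergence,
        cfg.post_fusion_divergence,
        cfg.within_group_divergence,
    )
    events: list[dict] = []
    anc = _ancestral_half(cfg, rng, "anc")
    events.append({"event": "root", "gene": "anc"})
    alpha = _evolved(anc, pre, rng)  # future N-terminal half
    beta = _evolved(anc, pre, rng)  # duplicates again at fusion time
    events.append({"event": "duplication", "copies": ["alpha", "beta"],
                   "branch_length": pre})
    events.append({"event": "duplication", "copies": ["beta_fused", "beta_half"],
                   "branch_length": 0.0})
    full_anc = make_fusion(alpha, beta, cfg.linker_length, rng, protein_id="full_anc")
    events.append({"event": "fusion", "mode": "heterofusion",
                   "n_terminal": "alpha", "c_terminal": "beta_fused"})
    full_anc = _evolved(full_anc, post, rng)
    half_anc = _evolved(beta, post, rng)
    fused, halves = [], []
    for i in range(1, cfg.n_taxa + 1):
        fused.append(_tip(full_anc, w, rng, f"full{fam}_t{i}", f"t{i}", "eukaryote", fam))
    for i in range(1, cfg.n_taxa + 1):
        halves.append(_tip(half_anc, w, rng, f"half{fam}_t{i}", f"t{i}", "eukaryote", fam))
    events.append({"event": "radiation", "n_taxa": cfg.n_taxa, "tip_branch": w})

    trees = {}
    c_clade = _clade_newick([_instance_id(p.protein_id, "NBD", 2) for p in fused], w, post)
    h_clade = _clade_newick(_nbd_tips(halves), w, post)
    n_clade = _clade_newick([_instance_id(p.protein_id, "NBD", 1) for p in fused],
                            w, 2 * pre + post)
    trees["NBD"] = f"({c_clade},{h_clade},{n_clade});"
    c_t = _clade_newick([_instance_id(p.protein_id, "TMD", 2) for p in fused], w, post)
    h_t = _clade_newick(_tmd_tips(halves), w, post)
    n_t = _clade_newick([_instance_id(p.protein_id, "TMD", 1) for p in fused],
                        w, 2 * pre + post)
    trees["TMD"] = f"({c_t},{h_t},{n_t});"

    truth = Truth(cfg.scenario, "heterofusion", events, trees)
    return SimulatedDataset(cfg, fused + halves, [], truth)


def _simulate_half_only(cfg: SimConfig, rng: np.random.Generator) -> SimulatedDataset:
    pre, w = cfg.pre_fusion_divergence, cfg.within_group_divergence
    events: list[dict] = [{"event": "root", "gene": "anc"}]
    anc = _ancestral_half(cfg, rng, "anc")
    lineages = {}
    for fam in ("A", "B"):
        lineages[fam] = _evolved(anc, pre, rng)
    events.append({"event": "divergence", "lineages": ["A", "B"], "branch_length": pre})
    proteins = []
    for fam in ("A", "B"):
        for i in range(1, cfg.n_taxa + 1):
            proteins.append(_tip(lineages[fam], w, rng, f"half{fam}_t{i}", f"t{i}",
                                 "eukaryote", fam))
    events.append({"event": "radiation", "n_taxa": cfg.n_taxa, "tip_branch": w})
    fam_a = [p for p in proteins if p.family == "A"]
    fam_b = [p for p in proteins if p.family == "B"]
    trees = {}
    for cls, tips in (("NBD", _nbd_tips), ("TMD", _tmd_tips)):
        a_clade = _clade_newick(tips(fam_a), w, 2 * pre)
        inner = ",".join(f"{t}:{w:g}" for t in tips(fam_b))
        trees[cls] = f"({inner},{a_clade});"
    truth = Truth(cfg.scenario, None, events, trees)
    return SimulatedDataset(cfg, proteins, [], truth)


def _simulate_hgt_mix(cfg: SimConfig, rng: np.random.Generator) -> SimulatedDataset:
    post, w = cfg.post_fusion_divergence, cfg.within_group_divergence
    n_prok = cfg.n_prokaryote_lineages
    events: list[dict] = [{"event": "root", "gene": "anc"}]
    # the clade receiving the eukaryote graft is chosen before any evolution
    # so that the rng consumption order is fixed
    graft_clade = int(rng.integers(0, n_prok)) + 1
    anc = _ancestral_half(cfg, rng, "anc")
    proteins: list[SimProtein] = []
    clade_tips: dict[str, list[SimProtein]] = {}
    graft_pid = "hgtgraft_t1"
    for j in range(1, n_prok + 1):
        clade_anc = _evolved(anc, post, rng)
        tips = [
            _tip(clade_anc, w, rng, f"prok{j}_t{i}", f"p{j}_{i}", "bacteria", "unknown")
            for i in range(1, cfg.n_taxa + 1)
        ]
        if j == graft_clade:
            tips.append(_tip(clade_anc, w, rng, graft_pid, "euk_hgt", "eukaryote", "B"))
            events.append({"event": "hgt_graft", "clade": j, "tip": graft_pid})
        clade_tips[f"prok{j}"] = tips
        proteins.extend(tips)
    euk_anc = _evolved(anc, post, rng)
    euk = [
        _tip(euk_anc, w, rng, f"euk_t{i}", f"e{i}", "eukaryote", "B")
        for i in range(1, cfg.n_taxa + 1)
    ]
    clade_tips["euk"] = euk
    proteins.extend(euk)
    events.append({"event": "radiation", "n_taxa": cfg.n_taxa, "tip_branch": w})

    trees = {}
    for cls, tips in (("NBD", _nbd_tips), ("TMD", _tmd_tips)):
        clades = [
            _clade_newick(tips(members), w, post) for members in clade_tips.values()
        ]
        trees[cls] = f"({','.join(clades)});"
    truth = Truth(cfg.scenario, None, events, trees, graft_tip_protein=graft_pid)
    return SimulatedDataset(cfg, proteins, [], truth)


def _make_helix_tables(
    proteins: Sequence[SimProtein], cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[str, list[tuple[int, int]]]]:
    """Three-helix span tables for every TMD instance, with the loop between
    the first two helices drawn from a family-conditional distribution
    (family A long, others short), emulating transmembrane-topology output."""
    tables = []
    for p in proteins:
        ordinal = 0
        for h in sorted(p.hits, key=lambda h: h.start):
            if collapse_class(h.domain_class) != "TMD":
                continue
            ordinal += 1
            tmd_len = h.length
            mean = FIRST_LOOP_MEAN.get(p.family, FIRST_LOOP_MEAN_DEFAULT)
            max_loop1 = tmd_len - 3 * HELIX_LENGTH - 45
            loop1 = int(round(np.clip(rng.normal(mean, FIRST_LOOP_SD), 5, max_loop1)))
            loop2 = int(rng.integers(8, 18))
            h1 = (5, 5 + HELIX_LENGTH - 1)
            h2 = (h1[1] + loop1 + 1, h1[1] + loop1 + HELIX_LENGTH)
            h3 = (h2[1] + loop2 + 1, h2[1] + loop2 + HELIX_LENGTH)
            if h3[1] > tmd_len:
                raise AssertionError("helix spans exceed TMD length")
            tables.append((_instance_id(p.protein_id, "TMD", ordinal), [h1, h2, h3]))
    return tables


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

FASTA_NAME = "proteins.faa"
HITS_NAME = "domain_hits.tsv"
METADATA_NAME = "metadata.tsv"
HELICES_NAME = "helices.tsv"
TRUTH_JSON_NAME = "truth.json"


def write_dataset(dataset: SimulatedDataset, directory) -> None:
    """Write a dataset as plain-text files: FASTA, domain-hit TSV, metadata
    TSV, helix TSV, truth trees (Newick) and truth log (JSON).  The files
    round-trip through :func:`read_dataset` and the architectures readers."""
    os.makedirs(directory, exist_ok=True)
    if not dataset.proteins:
        logger.warning("writing empty dataset to %s", directory)
    with open(os.path.join(directory, FASTA_NAME), "wt") as fh:
        for p in dataset.proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    with open(os.path.join(directory, HITS_NAME), "wt") as fh:
        fh.write("protein_id\tdomain_class\tstart\tend\tscore\tevalue\n")
        for h in dataset.domain_hits:
            fh.write(
                f"{h.protein_id}\t{h.domain_class}\t{h.start}\t{h.end}\t"
                f"{h.score:.1f}\t{h.evalue:.3g}\n"
            )
    with open(os.path.join(directory, METADATA_NAME), "wt") as fh:
        fh.write("protein_id\ttaxon\tsuperkingdom\tfamily\n")
        for p in dataset.proteins:
            fh.write(f"{p.protein_id}\t{p.taxon}\t{p.superkingdom}\t{p.family}\n")
    with open(os.path.join(directory, HELICES_NAME), "wt") as fh:
        fh.write("instance_id\thelix_index\tstart\tend\n")
        for instance_id, spans in dataset.helix_tables:
            for k, (s, e) in enumerate(spans, start=1):
                fh.write(f"{instance_id}\t{k}\t{s}\t{e}\n")
    for cls, newick in dataset.truth.trees.items():
        with open(os.path.join(directory, f"truth_{cls}.nwk"), "wt") as fh:
            fh.write(newick + "\n")
    truth_doc = {
        "scenario": dataset.truth.scenario,
        "fusion_mode": dataset.truth.fusion_mode,
        "events": dataset.truth.events,
        "graft_tip_protein": dataset.truth.graft_tip_protein,
        "seed": dataset.config.seed,
        "config": dataclasses.asdict(dataset.config),
    }
    with open(os.path.join(directory, TRUTH_JSON_NAME), "wt") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_dataset(directory) -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    from .architectures import parse_domain_table

    sequences: dict[str, str] = {}
    with open(os.path.join(directory, FASTA_NAME), "rt") as fh:
        pid = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                pid = line[1:].split()[0]
                sequences[pid] = ""
            elif pid is not None:
                sequences[pid] += line
    hits = parse_domain_table(
        os.path.join(directory, HITS_NAME),
        dialect="tsv",
        sequence_lengths={k: len(v) for k, v in sequences.items()},
    )
    hits_by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    meta: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    with open(os.path.join(directory, METADATA_NAME), "rt") as fh:
        fh.readline()
        for line in fh:
            pid, taxon, sk, fam = line.rstrip("\n").split("\t")
            meta[pid] = (taxon, sk, fam)
            order.append(pid)
    proteins = [
        SimProtein(pid, *meta[pid], sequences[pid], tuple(hits_by_protein.get(pid, ())))
        for pid in order
    ]
    helix_tables: list[tuple[str, list[tuple[int, int]]]] = []
    helices_path = os.path.join(directory, HELICES_NAME)
    if os.path.exists(helices_path):
        current: dict[str, list[tuple[int, int]]] = {}
        ids_in_order: list[str] = []
        with open(helices_path, "rt") as fh:
            fh.readline()
            for line in fh:
                iid, _, s, e = line.rstrip("\n").split("\t")
                if iid not in current:
                    current[iid] = []
                    ids_in_order.append(iid)
                current[iid].append((int(s), int(e)))
        helix_tables = [(iid, current[iid]) for iid in ids_in_order]
    with open(os.path.join(directory, TRUTH_JSON_NAME), "rt") as fh:
        doc = json.load(fh)
    trees = {}
    for cls in ("NBD", "TMD"):
        path = os.path.join(directory, f"truth_{cls}.nwk")
        if os.path.exists(path):
            with open(path, "rt") as tfh:
                trees[cls] = tfh.read().strip()
    truth = Truth(
        doc["scenario"], doc["fusion_mode"], doc["events"], trees,
        graft_tip_protein=doc.get("graft_tip_protein"),
    )
    config = SimConfig(**doc["config"])
    return SimulatedDataset(config, proteins, helix_tables, truth)
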