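"""Extraction of NBD/TMD instances from proteins.

Domain instances — the subsequences covered by resolved domain hits — are
the tip units of every downstream phylogeny.  In full and ABC2 proteins the
two instances of a class are distinguished as N-terminal and C-terminal;
those terminal labels carry the fusion-mode signal (a C-terminal NBD that
clusters with half-structure NBDs rather than with its own gene's N-terminal
NBD indicates heterofusion).

Instance ids have the form ``proteinid|CLASS|ordinal`` (ordinal counted
within the collapsed class, 1-based along the protein) so tree tip names are
parseable without a lookup table and safe in Newick.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

from .architectures import Architecture, DomainHit

logger = logging.getLogger(__name__)

TERMINALS = ("N", "C", "half", "single")


def instance_id(protein_id: str, collapsed_class: str, ordinal: int) -> str:
    return f"{protein_id}|{collapsed_class}|{ordinal}"


def parse_instance_id(iid: str) -> tuple[str, str, int]:
    protein_id, cls, ordinal = iid.rsplit("|", 2)
    return protein_id, cls, int(ordinal)


@dataclasses.dataclass
class DomainInstance:
    """An extracted NBD or TMD subsequence with its tree-tip annotations."""

    instance_id: str
    protein_id: str
    domain_class: str  # collapsed: NBD or TMD
    subclass: str  # raw domain class, e.g. ABC_membrane
    terminal: str  # N | C | half | single
    family: str
    superkingdom: str
    structure: str
    sequence: str


def extract_domains(
    sequence: str,
    resolved_hits: Sequence[DomainHit],
    family: str = "unknown",
    superkingdom: str = "eukaryote",
    structure: str = "other",
) -> list[DomainInstance]:
    """Extract one instance per resolved NBD/TMD hit (1-based inclusive
    coordinates).  Hits of collapsed class "other" are skipped — only NBDs
    and TMDs enter the trees.  Terminal labels are left as "single" until
    :func:`label_terminal` assigns them from the structure class."""
    instances: list[DomainInstance] = []
    ordinals: dict[str, int] = {}
    for hit in sorted(resolved_hits, key=lambda h: h.start):
        cls = hit.collapsed_class
        if cls == "other":
            continue
        if hit.end > len(sequence):
            raise ValueError(
                f"hit {hit.start}..{hit.end} beyond sequence length "
                f"{len(sequence)} of {hit.protein_id}"
            )
        ordinals[cls] = ordinals.get(cls, 0) + 1
        instances.append(
            DomainInstance(
                instance_id=instance_id(hit.protein_id, cls, ordinals[cls]),
                protein_id=hit.protein_id,
                domain_class=cls,
                subclass=hit.domain_class,
                terminal="single",
                family=family,
                superkingdom=superkingdom,
                structure=structure,
                sequence=sequence[hit.start - 1 : hit.end],
            )
        )
    return instances


def label_terminal(instances: list[DomainInstance], structure: str) -> list[DomainInstance]:
    """Assign terminal labels in place from the protein's structure class:
    full/ABC2 — the first instance of a duplicated class is N, the second C;
    half — "half"; single — "single".  Counts inconsistent with the structure
    raise :class:`ValueError`."""
    counts: dict[str, int] = {}
    for inst in instances:
        counts[inst.domain_class] = counts.get(inst.domain_class, 0) + 1
    expected = {
        "single": {1},
        "half": {1},
        "ABC2": {2},
        "full": {2},
    }
    if structure not in expected:
        raise ValueError(f"cannot label terminals for structure {structure!r}")
    for cls, n in counts.items():
        if structure == "ABC2" and cls != "NBD":
            raise ValueError("ABC2 protein with non-NBD instances")
        if n not in expected[structure]:
            raise ValueError(
                f"{n} {cls} instances inconsistent with structure {structure}"
            )
    if structure in ("full", "ABC2"):
        seen: dict[str, int] = {}
        for inst in instances:
            seen[inst.domain_class] = seen.get(inst.domain_class, 0) + 1
            inst.terminal = "N" if seen[inst.domain_class] == 1 else "C"
    else:
        label = "half" if structure == "half" else "single"
        for inst in instances:
            inst.terminal = label
    for inst in instances:
        inst.structure = structure
    return instances


def extract_for_architecture(
    sequence: str,
    resolved_hits: Sequence[DomainHit],
    architecture: Architecture,
    family: str = "unknown",
    superkingdom: str = "eukaryote",
) -> list[DomainInstance]:
    """Extract and terminal-label the instances of one classified protein."""
    instances = extract_domains(
        sequence, resolved_hits, family=family, superkingdom=superkingdom,
        structure=architecture.structure,
    )
    return label_terminal(instances, architecture.structure)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

TIP_COLUMNS = [
    "instance_id",
    "protein_id",
    "domain_class",
    "subclass",
    "terminal",
    "family",
    "superkingdom",
    "structure",
]


def write_instance_fasta(instances: Iterable[DomainInstance], path) -> None:
    with open(path, "wt") as fh:
        for inst in instances:
            fh.write(f">{inst.instance_id}\n")
            for i in range(0, len(inst.sequence), 60):
                fh.write(inst.sequence[i : i + 60] + "\n")


def write_tip_metadata(instances: Iterable[DomainInstance], path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(TIP_COLUMNS) + "\n")
        for inst in instances:
            fh.write(
                "\t".join(
                    [
                        inst.instance_id,
                        inst.protein_id,
                        inst.domain_class,
                        inst.subclass,
                        inst.terminal,
                        inst.family,
                        inst.superkingdom,
                        inst.structure,
                    ]
                )
                + "\n"
            )


def read_tip_metadata(path) -> dict[str, dict[str, str]]:
    """Read a tip-metadata TSV into {instance_id: {column: value}}."""
    out: dict[str, dict[str, str]] = {}
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TIP_COLUMNS:
            raise ValueError(f"{path}: unexpected tip-metadata header {header}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row = dict(zip(header, fields))
            out[row["instance_id"]] = row
    return out
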