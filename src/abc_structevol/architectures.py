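"""Domain-architecture classification of ABC transporter proteins.

ABC transporters are built from two domain classes: the nucleotide binding
domain (NBD, the conserved ATPase module) and the transmembrane domain (TMD).
The ordered domain content of a protein determines its *structure class*:

====================  =========================================
domain string         structure (orientation)
====================  =========================================
NBD  or  TMD          single
TMD-NBD               half (TMD-leading)
NBD-TMD               half (NBD-leading)
NBD-NBD               ABC2
TMD-NBD-TMD-NBD       full (TMD-leading)
NBD-TMD-NBD-TMD       full (NBD-leading)
anything else         other
====================  =========================================

This module parses domain-hit tables (a plain TSV dialect or HMMER
``domtblout``), resolves overlapping hits, classifies architectures and flags
family/structure combinations that fall outside the canonical repertoire and
are therefore likely assembly or gene-prediction artifacts.

All residue coordinates are 1-based inclusive (the HMMER/Pfam convention).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence, TextIO

logger = logging.getLogger(__name__)

# The nine Pfam transmembrane-domain classes found in ABC transporters.
TMD_CLASSES = frozenset(
    {
        "ABC_membrane",
        "ABC_membrane_2",
        "ABC_membrane_3",
        "ABC2_membrane",
        "ABC2_membrane_2",
        "ABC2_membrane_3",
        "ABC2_membrane_4",
        "ABC2_membrane_5",
        "ABC2_membrane_6",
    }
)

# Accepted spellings of the nucleotide-binding-domain class.
NBD_CLASSES = frozenset({"NBD", "ABC_tran"})

STRUCTURES = ("single", "half", "ABC2", "full", "other")
ORIENTATIONS = ("TMD_leading", "NBD_leading", "not_applicable")

FAMILIES = ("A", "B", "C", "D", "E", "F", "G", "unknown")

#: Canonical (structure, orientation) repertoire per eukaryotic family.
#: Anything outside this table is flagged as suspect (likely incomplete
#: assembly or gene mis-prediction), except for family "unknown".
CANONICAL_STRUCTURES = {
    "A": {("half", "TMD_leading"), ("full", "TMD_leading")},
    "B": {("half", "TMD_leading"), ("full", "TMD_leading")},
    "C": {("full", "TMD_leading")},
    "D": {("half", "TMD_leading"), ("full", "TMD_leading")},
    "E": {("ABC2", "not_applicable")},
    "F": {("ABC2", "not_applicable")},
    "G": {("half", "NBD_leading"), ("full", "NBD_leading")},
}

DEFAULT_MIN_SCORE = 20.0
DEFAULT_MAX_EVALUE = 1e-3
#: Two hits overlapping by more than this fraction of the shorter hit are
#: considered the same region; only the best-scoring one survives.
OVERLAP_FRACTION = 0.25


@dataclasses.dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein, 1-based inclusive coordinates."""

    protein_id: str
    domain_class: str  # "NBD", one of TMD_CLASSES, or an unknown class
    start: int
    end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid coordinates {self.start}..{self.end} for "
                f"{self.protein_id}/{self.domain_class}"
            )
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.protein_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def collapsed_class(self) -> str:
        return collapse_class(self.domain_class)

    def shifted(self, offset: int) -> "DomainHit":
        return dataclasses.replace(
            self, start=self.start + offset, end=self.end + offset
        )


@dataclasses.dataclass
class Architecture:
    """Classified domain organization of one protein."""

    protein_id: str
    domain_string: tuple[str, ...]  # over {"NBD", "TMD"}, position-sorted
    subclasses: tuple[str, ...]  # raw domain classes, same order
    structure: str
    orientation: str
    suspect: bool = False


def collapse_class(domain_class: str) -> str:
    """Collapse a raw domain class to "NBD", "TMD" or "other".

    The nine Pfam TMD classes are all membrane domains for structure typing;
    the subclass is kept separately as annotation.
    """
    if domain_class in NBD_CLASSES:
        return "NBD"
    if domain_class in TMD_CLASSES:
        return "TMD"
    return "other"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

TSV_COLUMNS = ["protein_id", "domain_class", "start", "end", "score", "evalue"]


def _open_text(source) -> TextIO:
    if hasattr(source, "read"):
        return source
    return open(source, "rt")


def parse_domain_table(
    source,
    dialect: str = "tsv",
    sequence_lengths: dict[str, int] | None = None,
) -> list[DomainHit]:
    """Parse a domain-hit table into :class:`DomainHit` records.

    Parameters
    ----------
    source
        Path or open text stream.
    dialect
        ``"tsv"`` (columns protein_id, domain_class, start, end, score,
        evalue, with header) or ``"domtblout"`` (HMMER per-domain table;
        envelope coordinates, domain i-E-value and domain score are used).
    sequence_lengths
        Optional mapping protein id -> length; when given, hit coordinates
        are validated against it.

    Unknown domain classes are kept (they collapse to "other") with a
    warning.  Malformed rows raise :class:`ValueError` naming the line.
    """
    if dialect not in ("tsv", "domtblout"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    stream = _open_text(source)
    close = not hasattr(source, "read")
    try:
        if dialect == "tsv":
            hits = _parse_tsv(stream)
        else:
            hits = _parse_domtblout(stream)
    finally:
        if close:
            stream.close()
    if sequence_lengths is not None:
        for h in hits:
            if h.protein_id in sequence_lengths and h.end > sequence_lengths[h.protein_id]:
                raise ValueError(
                    f"hit {h.domain_class} {h.start}..{h.end} exceeds length "
                    f"{sequence_lengths[h.protein_id]} of {h.protein_id}"
                )
    for h in hits:
        if h.collapsed_class == "other":
            logger.warning(
                "unknown domain class %r on %s kept as 'other'",
                h.domain_class,
                h.protein_id,
            )
    return hits


def _parse_tsv(stream: TextIO) -> list[DomainHit]:
    hits: list[DomainHit] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header != TSV_COLUMNS:
                raise ValueError(
                    f"line {lineno}: expected header {TSV_COLUMNS}, got {header}"
                )
            continue
        if len(fields) != len(TSV_COLUMNS):
            raise ValueError(
                f"line {lineno}: expected {len(TSV_COLUMNS)} fields, got {len(fields)}"
            )
        try:
            hit = DomainHit(
                protein_id=fields[0],
                domain_class=fields[1],
                start=int(fields[2]),
                end=int(fields[3]),
                score=float(fields[4]),
                evalue=float(fields[5]),
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    if header is None:
        raise ValueError("empty domain table (no header)")
    return hits


def _parse_domtblout(stream: TextIO) -> list[DomainHit]:
    """Parse HMMER3 ``--domtblout`` output (hmmsearch orientation:
    target = protein, query = profile).  Envelope coordinates (columns 20-21),
    per-domain i-E-value (column 13) and per-domain score (column 14)."""
    hits: list[DomainHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split(None, 22)
        if len(fields) < 22:
            raise ValueError(
                f"line {lineno}: domtblout row has {len(fields)} fields, need >= 22"
            )
        try:
            hit = DomainHit(
                protein_id=fields[0],
                domain_class=fields[3],
                start=int(fields[19]),
                end=int(fields[20]),
                score=float(fields[13]),
                evalue=float(fields[12]),
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Hit resolution and classification
# ---------------------------------------------------------------------------


def resolve_hits(
    hits: Sequence[DomainHit],
    min_score: float = DEFAULT_MIN_SCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[DomainHit]:
    """Threshold and de-overlap the hits of one protein.

    Hits with score < *min_score* or E-value > *max_evalue* are dropped.
    Among hits overlapping by more than :data:`OVERLAP_FRACTION` of the
    shorter hit, only the highest-scoring survives (greedy, by descending
    score; ties broken by start coordinate, then end, then class, so the
    result is deterministic).  The survivors are returned sorted by start.

    Idempotent: resolving an already-resolved list returns it unchanged.
    """
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(ids)}")
    kept: list[DomainHit] = []
    candidates = [h for h in hits if h.score >= min_score and h.evalue <= max_evalue]
    for hit in sorted(candidates, key=lambda h: (-h.score, h.start, h.end, h.domain_class)):
        if all(_overlap_fraction(hit, k) <= OVERLAP_FRACTION for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    if overlap <= 0:
        return 0.0
    return overlap / min(a.length, b.length)


def classify_architecture(domain_string: Sequence[str]) -> tuple[str, str]:
    """Map an ordered domain string over {"NBD", "TMD"} to
    (structure, orientation) following the structure table above."""
    ds = tuple(domain_string)
    for d in ds:
        if d not in ("NBD", "TMD"):
            raise ValueError(f"domain string must be over {{NBD, TMD}}, got {d!r}")
    if not ds:
        logger.warning("empty domain string classified as 'other'")
        return ("other", "not_applicable")
    table = {
        ("NBD",): ("single", "not_applicable"),
        ("TMD",): ("single", "not_applicable"),
        ("TMD", "NBD"): ("half", "TMD_leading"),
        ("NBD", "TMD"): ("half", "NBD_leading"),
        ("NBD", "NBD"): ("ABC2", "not_applicable"),
        ("TMD", "NBD", "TMD", "NBD"): ("full", "TMD_leading"),
        ("NBD", "TMD", "NBD", "TMD"): ("full", "NBD_leading"),
    }
    return table.get(ds, ("other", "not_applicable"))


def build_architecture(
    protein_id: str,
    resolved_hits: Sequence[DomainHit],
    family_label: str | None = None,
) -> Architecture:
    """Build the :class:`Architecture` of one protein from resolved hits.

    Hits whose class collapses to "other" are excluded from the domain
    string (they never enter structure typing) but logged.
    """
    ordered = sorted(resolved_hits, key=lambda h: h.start)
    pairs = [
        (h.collapsed_class, h.domain_class)
        for h in ordered
        if h.collapsed_class != "other"
    ]
    domain_string = tuple(p[0] for p in pairs)
    subclasses = tuple(p[1] for p in pairs)
    structure, orientation = classify_architecture(domain_string)
    suspect = False
    if family_label is not None:
        suspect = flag_suspect(structure, orientation, family_label)
    return Architecture(
        protein_id=protein_id,
        domain_string=domain_string,
        subclasses=subclasses,
        structure=structure,
        orientation=orientation,
        suspect=suspect,
    )


def flag_suspect(structure: str, orientation: str, family_label: str) -> bool:
    """True iff (family, structure, orientation) falls outside the canonical
    repertoire — e.g. a single-NBD gene labelled family E, or a half labelled
    family C.  Such sporadic structures are typically incomplete assemblies or
    mis-predicted genes.  Family "unknown" is never flagged."""
    if family_label == "unknown":
        return False
    if family_label not in CANONICAL_STRUCTURES:
        raise ValueError(f"unknown family label {family_label!r}")
    return (structure, orientation) not in CANONICAL_STRUCTURES[family_label]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_architectures(architectures: Iterable[Architecture], path) -> None:
    """Write an architectures table (TSV: protein_id, domain_string,
    subclasses, structure, orientation, suspect)."""
    with open(path, "wt") as fh:
        fh.write("protein_id\tdomain_string\tsubclasses\tstructure\torientation\tsuspect\n")
        for a in architectures:
            fh.write(
                "\t".join(
                    [
                        a.protein_id,
                        "-".join(a.domain_string) or ".",
                        "-".join(a.subclasses) or ".",
                        a.structure,
                        a.orientation,
                        str(a.suspect).lower(),
                    ]
                )
                + "\n"
            )


def read_architectures(path) -> list[Architecture]:
    out: list[Architecture] = []
    with open(path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("protein_id\t"):
            raise ValueError(f"{path}: not an architectures table")
        for line in fh:
            pid, ds, subs, structure, orientation, suspect = line.rstrip("\n").split("\t")
            out.append(
                Architecture(
                    protein_id=pid,
                    domain_string=tuple(ds.split("-")) if ds != "." else (),
                    subclasses=tuple(subs.split("-")) if subs != "." else (),
                    structure=structure,
                    orientation=orientation,
                    suspect=suspect == "true",
                )
            )
    return out
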