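"""Transmembrane-helix spacing analysis within TMDs.

Families differ in the length of the loop between the first two
transmembrane helices of their TMDs — long (typically > 100 residues) in
family A, short elsewhere — while the spacing of the last two helices is
similar across families.  Helix spans are taken as input (from a
transmembrane-topology predictor or the simulator); this module computes
inter-helix distances and per-family binned distributions around a boundary
(default 100 residues).

A distance counts the residues *strictly between* two helices, so adjacent
helices are at distance 0.  Coordinates are TMD-local, 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BOUNDARY = 100


@dataclasses.dataclass
class HelixTable:
    """Sorted, non-overlapping helix spans of one TMD instance."""

    instance_id: str
    spans: list[tuple[int, int]]  # 1-based inclusive, TMD-local

    def __post_init__(self) -> None:
        for k, (s, e) in enumerate(self.spans):
            if s < 1 or e < s:
                raise ValueError(f"{self.instance_id}: invalid span {s}..{e}")
            if k and s <= self.spans[k - 1][1]:
                raise ValueError(f"{self.instance_id}: spans overlap or unsorted")


def helix_spacing(
    spans: Sequence[tuple[int, int]], which: str = "first_pair"
) -> int | None:
    """Residues strictly between the first two ("first_pair") or last two
    ("last_pair") helices; ``None`` when fewer than two helices exist."""
    if which not in ("first_pair", "last_pair"):
        raise ValueError(f"unknown pair selector {which!r}")
    if len(spans) < 2:
        return None
    if which == "first_pair":
        (_, e1), (s2, _) = spans[0], spans[1]
    else:
        (_, e1), (s2, _) = spans[-2], spans[-1]
    return s2 - e1 - 1


def spacing_distribution(
    tables: Iterable[HelixTable],
    families: Mapping[str, str],
    boundary: int = DEFAULT_BOUNDARY,
    which: str = "first_pair",
) -> pd.DataFrame:
    """Per-family counts and fractions of inter-helix distances at or below
    versus above *boundary*.  A distance exactly equal to the boundary falls
    in the <= bin.  Instances with fewer than two helices are excluded (and
    counted in the ``n_missing`` column)."""
    rows: dict[str, dict[str, int]] = {}
    for table in tables:
        fam = families.get(table.instance_id)
        if fam is None:
            raise ValueError(f"instance {table.instance_id!r} has no family label")
        row = rows.setdefault(fam, {"le": 0, "gt": 0, "n_missing": 0})
        d = helix_spacing(table.spans, which=which)
        if d is None:
            row["n_missing"] += 1
        elif d <= boundary:
            row["le"] += 1
        else:
            row["gt"] += 1
    for fam in set(families.values()) - set(rows):
        rows[fam] = {"le": 0, "gt": 0, "n_missing": 0}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "family"
    n = df["le"] + df["gt"]
    with pd.option_context("mode.chained_assignment", None):
        df["fraction_le"] = (df["le"] / n).where(n > 0)
        df["fraction_gt"] = (df["gt"] / n).where(n > 0)
    df = df.rename(columns={"le": f"n_le_{boundary}", "gt": f"n_gt_{boundary}"})
    df = df.rename(
        columns={"fraction_le": f"fraction_le_{boundary}",
                 "fraction_gt": f"fraction_gt_{boundary}"}
    )
    return df


def read_helix_tables(path) -> list[HelixTable]:
    """Read a helix TSV (instance_id, helix_index, start, end)."""
    spans: dict[str, list[tuple[int, int, int]]] = {}
    order: list[str] = []
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["instance_id", "helix_index", "start", "end"]:
            raise ValueError(f"{path}: unexpected helix-table header {header}")
        for line in fh:
            iid, k, s, e = line.rstrip("\n").split("\t")
            if iid not in spans:
                spans[iid] = []
                order.append(iid)
            spans[iid].append((int(k), int(s), int(e)))
    return [
        HelixTable(iid, [(s, e) for _, s, e in sorted(spans[iid])]) for iid in order
    ]


def write_helix_tables(tables: Iterable[HelixTable], path) -> None:
    with open(path, "wt") as fh:
        fh.write("instance_id\thelix_index\tstart\tend\n")
        for t in tables:
            for k, (s, e) in enumerate(t.spans, start=1):
                fh.write(f"{t.instance_id}\t{k}\t{s}\t{e}\n")
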