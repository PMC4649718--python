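"""Alignment handling: gap trimming, percent identity, motif consensus.

Alignments come either from the indel-free simulator (where same-class
domain instances are columnwise homologous by construction) or from an
externally aligned FASTA.  Columns with more than a configurable gap
fraction (default 20%) are removed before identity and tree computations.

Percent identity between two rows is computed over *comparable* columns —
those where both rows are non-gap:

    identity = 100 * identical columns / comparable columns.

This denominator convention determines every identity number downstream
(group-mean identity matrices in particular) and is stated here because
published identity tables rarely spell it out.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GAP = "-"


class Alignment:
    """A fixed set of equal-length aligned rows plus a retained-column mask.

    The mask starts all-true; :func:`trim_columns` returns a copy with the
    mask updated.  ``matrix`` exposes the retained columns as a 2-D array of
    single characters; ``full_matrix`` ignores the mask.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str], mask=None):
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in length")
        if len(rows) == 0:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids")
        self.ids = list(ids)
        self._matrix = np.array([list(r) for r in rows], dtype="U1")
        n_cols = self._matrix.shape[1]
        if mask is None:
            mask = np.ones(n_cols, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n_cols,):
            raise ValueError("mask length must equal alignment length")
        self.mask = mask

    @property
    def n_rows(self) -> int:
        return self._matrix.shape[0]

    @property
    def n_columns(self) -> int:
        """Number of columns in the underlying (untrimmed) alignment."""
        return self._matrix.shape[1]

    @property
    def full_matrix(self) -> np.ndarray:
        return self._matrix

    @property
    def matrix(self) -> np.ndarray:
        """Retained columns only."""
        return self._matrix[:, self.mask]

    def row(self, row_id: str) -> str:
        """The retained-column sequence of one row."""
        return "".join(self.matrix[self.ids.index(row_id)])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        ids, rows = [], []
        with open(path, "rt") as fh:
            current = None
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    ids.append(line[1:].split()[0])
                    rows.append("")
                    current = len(rows) - 1
                elif current is not None:
                    rows[current] += line
        return cls(ids, rows)

    def to_fasta(self, path, trimmed: bool = True) -> None:
        mat = self.matrix if trimmed else self.full_matrix
        with open(path, "wt") as fh:
            for i, rid in enumerate(self.ids):
                fh.write(f">{rid}\n")
                seq = "".join(mat[i])
                for k in range(0, len(seq), 60):
                    fh.write(seq[k : k + 60] + "\n")


def trim_columns(alignment: Alignment, max_gap_fraction: float = 0.20) -> Alignment:
    """Mask out columns whose gap fraction is *strictly greater* than
    *max_gap_fraction* (so a 1-gap column in 5 rows, exactly 20%, is kept at
    the default).  Retained columns keep their original order; the returned
    alignment's mask records the partition."""
    gaps = (alignment.full_matrix == GAP).mean(axis=0)
    mask = gaps <= max_gap_fraction
    removed = int((~mask).sum())
    logger.info(
        "trimmed %d/%d columns at gap fraction > %.2f",
        removed, alignment.n_columns, max_gap_fraction,
    )
    return Alignment(
        alignment.ids,
        ["".join(r) for r in alignment.full_matrix],
        mask=mask & alignment.mask,
    )


def pairwise_identity(row_a: str, row_b: str) -> float | None:
    """Percent identity over comparable (both non-gap) columns; ``None``
    when no column is comparable."""
    if len(row_a) != len(row_b):
        raise ValueError("rows have different lengths")
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    gap = ord(GAP)
    comparable = (a != gap) & (b != gap)
    n = int(comparable.sum())
    if n == 0:
        return None
    ident = int((a[comparable] == b[comparable]).sum())
    return 100.0 * ident / n


@dataclasses.dataclass
class IdentityMatrix:
    """Mean percent identities between (and within) labelled groups.

    ``values`` is symmetric with diagonal cells defined over within-group
    unordered pairs; ``counts`` holds the number of pairs behind each cell.
    Cells with no contributing pair are NaN / 0.
    """

    values: pd.DataFrame
    counts: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.values.round(1).to_csv(path, sep="\t", na_rep="NA")


def _identity_array(matrix: np.ndarray) -> np.ndarray:
    """All-pairs percent identity for the rows of a character matrix
    (NaN where a pair has no comparable column)."""
    m = np.ascontiguousarray(matrix)
    codes = m.view(np.uint32).reshape(m.shape)
    gap = ord(GAP)
    nongap = codes != gap
    n = codes.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        comparable = nongap[i] & nongap
        denom = comparable.sum(axis=1)
        ident = ((codes[i] == codes) & comparable).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(denom > 0, 100.0 * ident / denom, np.nan)
    return out


def group_mean_identity(
    alignment: Alignment, groups: Mapping[str, str]
) -> IdentityMatrix:
    """Mean pairwise identity per ordered group pair, computed on the
    retained columns.  Off-diagonal cells average all cross-group pairs;
    diagonal cells average all within-group unordered pairs (a one-member
    group therefore has an undefined diagonal cell)."""
    missing = [i for i in alignment.ids if i not in groups]
    if missing:
        raise ValueError(f"rows without a group label: {missing}")
    labels = sorted(set(groups[i] for i in alignment.ids))
    ident = _identity_array(alignment.matrix)
    row_groups = np.array([groups[i] for i in alignment.ids])
    values = pd.DataFrame(np.nan, index=labels, columns=labels)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for gi in labels:
        sel_i = row_groups == gi
        for gj in labels:
            sel_j = row_groups == gj
            block = ident[np.ix_(sel_i, sel_j)]
            if gi == gj:
                iu = np.triu_indices(block.shape[0], k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            vals = vals[~np.isnan(vals)]
            if vals.size:
                values.loc[gi, gj] = float(vals.mean())
                counts.loc[gi, gj] = int(vals.size)
    return IdentityMatrix(values=values, counts=counts)


def motif_consensus(
    alignment: Alignment,
    window: tuple[int, int],
    groups: Mapping[str, str],
) -> dict[str, tuple[str, list[int]]]:
    """Per-group majority consensus over a window of retained columns.

    *window* is a half-open (start, stop) pair in 0-based trimmed-column
    coordinates.  Per column the majority non-gap residue wins; ties are
    broken alphabetically and recorded (0-based window offsets) in the
    returned tie list; all-gap columns emit "-".
    """
    start, stop = window
    n = alignment.matrix.shape[1]
    if not (0 <= start < stop <= n):
        raise ValueError(f"window {window} outside trimmed alignment of {n} columns")
    mat = alignment.matrix[:, start:stop]
    row_groups = np.array([groups.get(i) for i in alignment.ids], dtype=object)
    out: dict[str, tuple[str, list[int]]] = {}
    for g in sorted({x for x in row_groups if x is not None}):
        block = mat[row_groups == g]
        consensus = []
        ties: list[int] = []
        for k in range(block.shape[1]):
            col = block[:, k]
            col = col[col != GAP]
            if col.size == 0:
                consensus.append(GAP)
                continue
            residues, freq = np.unique(col, return_counts=True)
            best = freq.max()
            winners = sorted(residues[freq == best])
            consensus.append(winners[0])
            if len(winners) > 1:
                ties.append(k)
        out[g] = ("".join(consensus), ties)
    return out


def write_consensus_report(
    consensus: Mapping[str, tuple[str, list[int]]], path
) -> None:
    with open(path, "wt") as fh:
        fh.write("group\tconsensus\ttie_positions\n")
        for g in sorted(consensus):
            seq, ties = consensus[g]
            fh.write(f"{g}\t{seq}\t{','.join(map(str, ties)) or '.'}\n")
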