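"""Alignment container and per-column classification.

The central object is :class:`Alignment`, a rectangular matrix of aligned
nucleotide sequences over the alphabet ``{A, C, G, T, N, -}``.  ``N`` marks
masked or ambiguous positions (upstream pipelines mask regions of uncertain
homology), ``-`` marks alignment gaps.  Every downstream analysis — window
scanning, barcode statistics, diagnostic-character discovery — is built on
the column classification performed here:

* a column is **variable** (a SNP) if at least two distinct unambiguous
  nucleotides occur in it;
* a column is **parsimony-informative** (PIS) if at least two nucleotides
  each occur in at least two samples.

By default ``N`` and ``-`` are both treated as missing data and ignored in
these definitions; gaps can optionally be counted as a fifth character
state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")
NUCLEOTIDES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


class AlignmentError(ValueError):
    """Raised when input violates the alignment contract (ragged rows,
    duplicate identifiers, empty input, out-of-bounds intervals)."""


@dataclass(frozen=True)
class Alignment:
    """A rectangular multiple sequence alignment.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers, one per row.
    rows
        One upper-case symbol string per sample, all of identical length,
        over ``{A, C, G, T, N, -}``.
    name
        Optional label (e.g. the barcode region the columns came from).
    """

    sample_ids: tuple[str, ...]
    rows: tuple[str, ...]
    name: str = "alignment"

    def __post_init__(self) -> None:
        if len(self.sample_ids) == 0:
            raise AlignmentError("alignment has no sequences")
        if len(self.sample_ids) != len(self.rows):
            raise AlignmentError("sample_ids and rows differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise AlignmentError(f"duplicate sample identifiers: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment has zero columns")
        bad = set("".join(self.rows)) - ALPHABET
        if bad:
            raise AlignmentError(f"symbols outside alphabet ACGTN-: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n_samples, length) byte matrix."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(self.n_samples, self.length)

    def row(self, sample_id: str) -> str:
        try:
            return self.rows[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(sample_id) from None

    def slice_columns(self, start: int, end: int, name: str | None = None) -> "Alignment":
        """Column slice [start, end) preserving sample order."""
        if not (0 <= start < end <= self.length):
            raise AlignmentError(
                f"interval [{start}, {end}) outside alignment of length {self.length}"
            )
        return Alignment(
            sample_ids=self.sample_ids,
            rows=tuple(r[start:end] for r in self.rows),
            name=name if name is not None else f"{self.name}[{start}:{end}]",
        )

    def reverse_complement(self) -> "Alignment":
        """Reverse-complement every row (column order reversed)."""
        return Alignment(
            sample_ids=self.sample_ids,
            rows=tuple(r.translate(_COMPLEMENT)[::-1] for r in self.rows),
            name=f"{self.name}_rc",
        )


@dataclass(frozen=True)
class ColumnSummary:
    """Classification of one alignment column.

    ``counts`` holds occurrences of A, C, G, T among the samples;
    everything else (N, gap by default) is missing.  ``is_variable`` and
    ``is_pis`` follow the SNP / parsimony-informative-site definitions in
    the module docstring.
    """

    column: int
    counts: dict[str, int] = field(compare=False)
    n_missing: int = 0
    is_variable: bool = False
    is_pis: bool = False
    missing_fraction: float = 0.0


def normalize_sequence(seq: str) -> tuple[str, bool]:
    """Upper-case a sequence and demote IUPAC ambiguity codes to N.

    Returns the normalized string and whether any symbol was demoted.
    Upstream consensus callers emit codes like R/Y/W for within-sample
    ambiguity; for barcode design these carry no usable state and are
    treated as masked.
    """
    s = seq.upper()
    if set(s) <= ALPHABET:
        return s, False
    cleaned = "".join(c if c in ALPHABET else "N" for c in s)
    return cleaned, True


def read_alignment(path: str | Path, name: str | None = None) -> Alignment:
    """Read a multi-FASTA alignment, validating shape and alphabet.

    Lowercase letters are upper-cased; IUPAC ambiguity codes other than N
    are converted to N with a warning.  Ragged rows, duplicate identifiers
    and empty files raise :class:`AlignmentError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = []
    rows = []
    demoted = False
    for rec in records:
        ids.append(rec.id)
        row, d = normalize_sequence(str(rec.seq))
        demoted = demoted or d
        rows.append(row)
    if demoted:
        msg = f"{path}: IUPAC ambiguity codes normalized to N"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return Alignment(
        sample_ids=tuple(ids),
        rows=tuple(rows),
        name=name if name is not None else path.stem,
    )


def write_alignment(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write an alignment as wrapped multi-FASTA."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.sample_ids, aln.rows)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def classify_columns(
    aln: Alignment, gaps_as_state: bool = False
) -> list[ColumnSummary]:
    """Classify every column as variable / parsimony-informative.

    Parameters
    ----------
    aln
        The alignment to scan.
    gaps_as_state
        If True, ``-`` is counted as a fifth character state instead of
        missing data.  Default False: masked regions are coded N and gap
        columns mostly reflect indel alignment, which would inflate
        variability counts.

    Returns
    -------
    One :class:`ColumnSummary` per column, in order.
    """
    arr = aln.to_array()
    n = aln.n_samples
    states = NUCLEOTIDES + (("-",) if gaps_as_state else ())
    count_mat = np.stack([np.sum(arr == s.encode(), axis=0) for s in states])
    n_missing = n - count_mat.sum(axis=0)
    n_states_present = np.sum(count_mat >= 1, axis=0)
    n_states_doubled = np.sum(count_mat >= 2, axis=0)
    out: list[ColumnSummary] = []
    for j in range(aln.length):
        out.append(
            ColumnSummary(
                column=j,
                counts={s: int(count_mat[i, j]) for i, s in enumerate(NUCLEOTIDES)},
                n_missing=int(n_missing[j]),
                is_variable=bool(n_states_present[j] >= 2),
                is_pis=bool(n_states_doubled[j] >= 2),
                missing_fraction=float(n_missing[j]) / n,
            )
        )
    return out


def variable_column_mask(aln: Alignment, gaps_as_state: bool = False) -> np.ndarray:
    """Boolean mask over columns: True where the column is variable.

    Vectorized equivalent of ``[c.is_variable for c in classify_columns(aln)]``
    for use in window scans over long alignments.
    """
    arr = aln.to_array()
    states = NUCLEOTIDES + (("-",) if gaps_as_state else ())
    present = np.stack([np.any(arr == s.encode(), axis=0) for s in states])
    return present.sum(axis=0) >= 2


def missing_cell_mask(aln: Alignment, gaps_as_missing: bool = True) -> np.ndarray:
    """Boolean (n_samples, length) mask of missing cells (N, and gaps by default)."""
    arr = aln.to_array()
    mask = arr == b"N"
    if gaps_as_missing:
        mask |= arr == b"-"
    return mask


def percent(count: int, length: int) -> float:
    """Percentage ``100 * count / length`` rounded half-up to 2 decimals.

    Half-up rounding (0.125 -> 0.13) matches the convention of standard
    alignment-statistics reports; Python's built-in ``round`` is
    banker's rounding and differs on exact ties.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if count < 0 or count > length:
        raise ValueError("count must satisfy 0 <= count <= length")
    value = Decimal(100) * Decimal(count) / Decimal(length)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def write_column_summary_tsv(
    summaries: Iterable[ColumnSummary], path: str | Path
) -> None:
    """Export column summaries as TSV (1-based coordinates for humans)."""
    with open(path, "w") as fh:
        fh.write("column_1based\tA\tC\tG\tT\tmissing\tvariable\tpis\n")
        for c in summaries:
            fh.write(
                f"{c.column + 1}\t{c.counts['A']}\t{c.counts['C']}\t"
                f"{c.counts['G']}\t{c.counts['T']}\t{c.n_missing}\t"
                f"{int(c.is_variable)}\t{int(c.is_pis)}\n"
            )
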