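"""Classify query samples against a diagnostic matrix.

A query (e.g. a commercial herbal product sequenced over the barcode
regions) is reduced to its states at the matrix positions and compared to
every OPU profile.  The semantics are pass/fail, as in a pharmacopoeial
test: one conflicting position excludes an OPU (no mismatch budget by
default).  Missing data in the query (N) excludes nothing, and an OPU
whose matrix cell is N or polymorphic carries no exclusionary information
at that position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .diagnostics import FIXED_STATES, DiagnosticMatrix
from .msa import Alignment

CALL_UNIQUE = "unique"
CALL_AMBIGUOUS = "ambiguous"
CALL_NO_MATCH = "no_match"
CALL_UNIDENTIFIABLE = "unidentifiable"


class QueryError(ValueError):
    """Raised when query input cannot be aligned to the matrix positions."""


@dataclass(frozen=True)
class QueryProfile:
    """States of one query at the matrix positions, in matrix order."""

    query_id: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.states) - (set(FIXED_STATES) | {"N"})
        if bad:
            raise QueryError(f"query states must be A/C/G/T/N, got {sorted(bad)}")

    @property
    def all_missing(self) -> bool:
        return all(s == "N" for s in self.states)


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    compatible_opus: frozenset[str]
    call: str
    mismatch_detail: dict[str, list[str]]  # OPU -> conflicting position labels


def profile_from_regions(
    query_id: str,
    region_sequences: Mapping[str, str],
    matrix: DiagnosticMatrix,
) -> QueryProfile:
    """Build a profile from per-region sequences.

    Each sequence must have exactly the region's aligned length (the
    matrix's 1-based positions index into it); a length mismatch means the
    query was not aligned to the reference regions and is rejected with
    instructions rather than silently mis-indexed.  Symbols other than
    A/C/G/T (including gaps and ambiguity codes) become N.
    """
    required: dict[str, int] = {}
    for p in matrix.positions:
        required[p.region] = max(required.get(p.region, 0), p.pos_1based)
    states = []
    for p in matrix.positions:
        if p.region not in region_sequences:
            raise QueryError(
                f"query {query_id!r}: no sequence supplied for region {p.region!r}"
            )
        seq = region_sequences[p.region].upper()
        if len(seq) < required[p.region]:
            raise QueryError(
                f"query {query_id!r}: region {p.region!r} sequence has "
                f"{len(seq)} columns but the matrix indexes position "
                f"{required[p.region]}; align the query to the reference "
                f"region before profiling"
            )
        sym = seq[p.pos_1based - 1]
        states.append(sym if sym in FIXED_STATES else "N")
    return QueryProfile(query_id=query_id, states=tuple(states))


def profile_from_alignment(
    aln: Alignment, matrix: DiagnosticMatrix
) -> list[QueryProfile]:
    """Profiles for every row of an alignment sharing the matrix's
    coordinate system (positions must carry global ``column`` indices)."""
    cols = []
    for p in matrix.positions:
        if p.column is None:
            raise QueryError(
                "matrix positions lack alignment columns; use "
                "profile_from_regions with per-region sequences"
            )
        cols.append(p.column)
    if max(cols) >= aln.length:
        raise QueryError("query alignment shorter than matrix coordinates")
    out = []
    for sid, row in zip(aln.sample_ids, aln.rows):
        states = tuple(
            row[c] if row[c] in FIXED_STATES else "N" for c in cols
        )
        out.append(QueryProfile(query_id=sid, states=states))
    return out


def classify_query(
    profile: QueryProfile,
    matrix: DiagnosticMatrix,
    max_mismatch: int = 0,
) -> ClassificationResult:
    """Compare a query profile to every OPU profile.

    An OPU is compatible when the number of conflicting positions (query
    state and OPU state both unambiguous nucleotides, and different) is at
    most ``max_mismatch``.  The call is ``unique`` for exactly one
    compatible OPU, ``ambiguous`` for several, ``no_match`` for none, and
    ``unidentifiable`` when the query carries no information at all
    (every state N).
    """
    if len(profile.states) != len(matrix.positions):
        raise QueryError(
            f"profile has {len(profile.states)} states for "
            f"{len(matrix.positions)} matrix positions"
        )
    detail: dict[str, list[str]] = {}
    compatible = set()
    for opu, opu_profile in matrix.profiles.items():
        conflicts = [
            matrix.positions[i].label
            for i, (q, s) in enumerate(zip(profile.states, opu_profile))
            if q in FIXED_STATES and s in FIXED_STATES and q != s
        ]
        detail[opu] = conflicts
        if len(conflicts) <= max_mismatch:
            compatible.add(opu)
    if profile.all_missing:
        call = CALL_UNIDENTIFIABLE
    elif not compatible:
        call = CALL_NO_MATCH
    elif len(compatible) == 1:
        call = CALL_UNIQUE
    else:
        call = CALL_AMBIGUOUS
    return ClassificationResult(
        query_id=profile.query_id,
        compatible_opus=frozenset(compatible),
        call=call,
        mismatch_detail=detail,
    )


def read_profile_tsv(path: str | Path) -> list[QueryProfile]:
    """Read query profiles from a TSV: query id, then one state per
    matrix position (header optional, doubled letters accepted)."""
    profiles = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("query", "query_id", "sample"):
                continue
            states = []
            for cell in parts[1:]:
                cell = cell.strip().upper()
                if len(cell) == 2 and cell[0] == cell[1]:
                    cell = cell[0]
                states.append(cell if cell in FIXED_STATES else "N")
            profiles.append(QueryProfile(query_id=parts[0], states=tuple(states)))
    if not profiles:
        raise QueryError(f"{path}: no query profiles found")
    return profiles


def write_classification_tsv(
    results: Iterable[ClassificationResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("query\tcall\tcompatible_opus\tmismatches\n")
        for r in results:
            opus = ";".join(sorted(r.compatible_opus))
            mism = ";".join(
                f"{o}:{','.join(c)}"
                for o, c in sorted(r.mismatch_detail.items())
                if c
            )
            fh.write(f"{r.query_id}\t{r.call}\t{opus}\t{mism}\n")


def write_classification_json(
    results: Iterable[ClassificationResult], path: str | Path
) -> None:
    payload = [
        {
            "query": r.query_id,
            "call": r.call,
            "compatible_opus": sorted(r.compatible_opus),
            "mismatch_detail": {o: c for o, c in r.mismatch_detail.items() if c},
        }
        for r in results
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
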