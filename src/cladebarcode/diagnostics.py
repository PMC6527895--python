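"""Clade-diagnostic nucleotide discovery and minimal barcode construction.

Samples are grouped into Operational Phylogenetic Units (OPUs): clades on a
reference phylogeny used as identification targets when the nominal species
is polyphyletic and cannot carry a species-specific barcode.  For every
variable alignment column each OPU receives a *state*:

* the shared nucleotide, if all non-missing members agree (a *fixed* state),
* ``polymorphic``, if members disagree,
* ``N``, if no member is observed or too many are missing.

A fixed state is **diagnostic** for its OPU when the nucleotide is absent
from every non-missing member of every other OPU — the classic pure
diagnostic character of character-based barcoding.  Columns that are
diagnostic for someone, or that *separate* at least one pair of OPUs
(two fixed, different states), enter the diagnostic matrix.  OPUs whose
state vector (profile) over the matrix is unique are identifiable; OPUs
with identical profiles collide and cannot be told apart by the matrix at
all.  A set-cover search then finds the smallest position subset that
preserves the full matrix's discriminating power.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .msa import Alignment, variable_column_mask
from .windows import BarcodeRegion

POLYMORPHIC = "polymorphic"
FIXED_STATES = frozenset("ACGT")


class OPUError(ValueError):
    """Raised for invalid OPU assignment tables."""


@dataclass(frozen=True)
class OPUAssignment:
    """Mapping of samples to OPU labels."""

    mapping: dict[str, str]
    opu_labels: tuple[str, ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "OPUAssignment":
        labels: list[str] = []
        for opu in mapping.values():
            if opu not in labels:
                labels.append(opu)
        return cls(mapping=dict(mapping), opu_labels=tuple(labels))

    def members(self, opu: str) -> list[str]:
        return [s for s, o in self.mapping.items() if o == opu]

    def restricted_to(self, aln: Alignment) -> tuple["OPUAssignment", list[str]]:
        """Drop samples not present in the alignment; report the dropped.

        Alignment samples absent from the table are returned as the second
        element and simply do not participate in diagnostics.
        """
        present = {s: o for s, o in self.mapping.items() if s in aln.sample_ids}
        unassigned = [s for s in aln.sample_ids if s not in self.mapping]
        return OPUAssignment.from_mapping(present), unassigned


def read_opu_table(path: str | Path) -> OPUAssignment:
    """Read a two-column sample/OPU TSV (header row optional)."""
    mapping: dict[str, str] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                raise OPUError(f"{path}:{lineno}: expected two columns")
            sample, opu = parts[0], parts[1]
            if lineno == 1 and sample.lower() in ("sample", "sample_id", "id"):
                continue
            n_rows += 1
            if sample in mapping and mapping[sample] != opu:
                raise OPUError(
                    f"{path}:{lineno}: sample {sample!r} assigned to both "
                    f"{mapping[sample]!r} and {opu!r}"
                )
            mapping[sample] = opu
    if n_rows == 0:
        raise OPUError(f"{path}: empty OPU table")
    return OPUAssignment.from_mapping(mapping)


def write_opu_table(opus: OPUAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\topu\n")
        for sample, opu in opus.mapping.items():
            fh.write(f"{sample}\t{opu}\n")


@dataclass(frozen=True)
class DiagnosticPosition:
    """One alignment column with its per-OPU states.

    ``column`` is the 0-based column in the source alignment (None for
    positions defined directly from a published matrix); ``region`` and
    ``pos_1based`` give the human-facing coordinate ``region:pos``.
    """

    region: str
    pos_1based: int
    state_by_opu: dict[str, str] = field(compare=False)
    diagnostic_for: frozenset[str] = frozenset()
    column: int | None = None

    @property
    def label(self) -> str:
        return f"{self.region}:{self.pos_1based}"


@dataclass(frozen=True)
class DiagnosticMatrix:
    """OPU x position state table with profile uniqueness analysis."""

    positions: tuple[DiagnosticPosition, ...]
    opu_labels: tuple[str, ...]

    @property
    def profiles(self) -> dict[str, tuple[str, ...]]:
        return {
            opu: tuple(p.state_by_opu[opu] for p in self.positions)
            for opu in self.opu_labels
        }

    @property
    def unique_opus(self) -> set[str]:
        profs = self.profiles
        return {
            o
            for o, v in profs.items()
            if sum(1 for w in profs.values() if w == v) == 1
        }

    @property
    def profile_collisions(self) -> list[frozenset[str]]:
        """Groups of OPUs sharing an identical profile (size >= 2)."""
        by_profile: dict[tuple[str, ...], list[str]] = {}
        for o, v in self.profiles.items():
            by_profile.setdefault(v, []).append(o)
        return [frozenset(g) for g in by_profile.values() if len(g) > 1]

    def restrict(self, indices: Sequence[int]) -> "DiagnosticMatrix":
        return DiagnosticMatrix(
            positions=tuple(self.positions[i] for i in indices),
            opu_labels=self.opu_labels,
        )


def opu_state(
    symbols: Sequence[str], max_missing_in_group: float = 0.5
) -> str:
    """Summarize one OPU's symbols at one column into a state.

    Requires at least one observed (A/C/G/T) member and a missing fraction
    no greater than ``max_missing_in_group``; otherwise the state is N.
    """
    observed = [s for s in symbols if s in FIXED_STATES]
    if not observed:
        return "N"
    if 1 - len(observed) / len(symbols) > max_missing_in_group:
        return "N"
    return observed[0] if len(set(observed)) == 1 else POLYMORPHIC


def find_diagnostic_positions(
    aln: Alignment,
    opus: OPUAssignment,
    max_missing_in_group: float = 0.5,
    regions: Sequence[BarcodeRegion] | None = None,
) -> list[DiagnosticPosition]:
    """Scan variable columns for diagnostic and separating characters.

    A column is reported when some OPU has a diagnostic state there, or
    when at least two OPUs carry fixed but different states (such columns
    carry no single-OPU diagnostic but still separate profiles).

    ``regions`` (optional) translate global columns into region-local
    1-based report coordinates; columns outside every region keep the
    alignment name and a global 1-based position.
    """
    opus, _ = opus.restricted_to(aln)
    if len(opus.opu_labels) < 2:
        raise OPUError("diagnostics need at least two OPUs")
    row_of = {s: aln.rows[i] for i, s in enumerate(aln.sample_ids)}
    member_rows = {o: [row_of[s] for s in opus.members(o)] for o in opus.opu_labels}
    var_mask = variable_column_mask(aln)
    out: list[DiagnosticPosition] = []
    for col in range(aln.length):
        if not var_mask[col]:
            continue
        observed_sets: dict[str, set[str]] = {}
        states: dict[str, str] = {}
        for o in opus.opu_labels:
            symbols = [r[col] for r in member_rows[o]]
            observed_sets[o] = {s for s in symbols if s in FIXED_STATES}
            states[o] = opu_state(symbols, max_missing_in_group)
        diagnostic = frozenset(
            o
            for o, st in states.items()
            if st in FIXED_STATES
            and all(
                st not in observed_sets[other]
                for other in opus.opu_labels
                if other != o
            )
        )
        fixed = {st for st in states.values() if st in FIXED_STATES}
        separates = len(fixed) >= 2
        if diagnostic or separates:
            region, pos = _locate(col, regions, aln.name)
            out.append(
                DiagnosticPosition(
                    region=region,
                    pos_1based=pos,
                    state_by_opu=states,
                    diagnostic_for=diagnostic,
                    column=col,
                )
            )
    return out


def _locate(
    col: int, regions: Sequence[BarcodeRegion] | None, default: str
) -> tuple[str, int]:
    for r in regions or ():
        if r.start <= col < r.end:
            return r.name, col - r.start + 1
    return default, col + 1


def diagnostic_for_from_states(state_by_opu: Mapping[str, str]) -> frozenset[str]:
    """Diagnostic OPUs derivable from a state table alone.

    Without member-level data a fixed state can only be certified absent
    elsewhere when every other OPU is fixed for a different nucleotide;
    polymorphic or N cells might hide the candidate state.
    """
    return frozenset(
        o
        for o, st in state_by_opu.items()
        if st in FIXED_STATES
        and all(
            t in FIXED_STATES and t != st
            for p, t in state_by_opu.items()
            if p != o
        )
    )


def build_matrix(
    positions: Sequence[DiagnosticPosition], opus: OPUAssignment | Sequence[str]
) -> DiagnosticMatrix:
    """Assemble positions into a matrix over the given OPUs."""
    if not positions:
        raise ValueError("cannot build a matrix with no positions")
    labels = tuple(opus.opu_labels if isinstance(opus, OPUAssignment) else opus)
    return DiagnosticMatrix(positions=tuple(positions), opu_labels=labels)


@dataclass(frozen=True)
class MinimalSetResult:
    """Outcome of the minimal diagnostic position search."""

    indices: tuple[int, ...]  # into the candidate matrix's positions
    positions: tuple[DiagnosticPosition, ...]
    achieved_unique: frozenset[str]
    unresolvable: tuple[frozenset[str], ...]  # profile collisions of full matrix
    method: str  # exhaustive | greedy


def _n_unique(matrix: DiagnosticMatrix, indices: Sequence[int]) -> int:
    if not indices:
        return 1 if len(matrix.opu_labels) == 1 else 0
    return len(matrix.restrict(indices).unique_opus)


def minimal_diagnostic_set(
    matrix: DiagnosticMatrix, exhaustive_limit: int = 20
) -> MinimalSetResult:
    """Find a smallest position subset preserving profile uniqueness.

    The target is the number of unique OPUs achieved by the *full* matrix
    (OPUs colliding there are unresolvable by any subset).  With at most
    ``exhaustive_limit`` candidate positions all subsets are enumerated in
    order of cardinality then lexicographic index, so the returned set is
    a true optimum and the lexicographically smallest among optima.
    Larger pools fall back to a greedy forward selection (smallest index
    on ties).
    """
    n = len(matrix.positions)
    full_unique = matrix.unique_opus
    unresolvable = tuple(matrix.profile_collisions)
    target = len(full_unique)
    if target == 0:
        return MinimalSetResult(
            indices=(),
            positions=(),
            achieved_unique=frozenset(),
            unresolvable=unresolvable,
            method="exhaustive",
        )
    if n <= exhaustive_limit:
        for k in range(0, n + 1):
            for combo in combinations(range(n), k):
                if _n_unique(matrix, combo) == target:
                    return MinimalSetResult(
                        indices=combo,
                        positions=tuple(matrix.positions[i] for i in combo),
                        achieved_unique=frozenset(
                            matrix.restrict(combo).unique_opus
                        ),
                        unresolvable=unresolvable,
                        method="exhaustive",
                    )
        raise AssertionError("full matrix must achieve its own uniqueness")
    chosen: list[int] = []
    current = 0
    while current < target:
        best_idx, best_gain = None, 0
        for i in range(n):
            if i in chosen:
                continue
            gain = _n_unique(matrix, sorted(chosen + [i])) - current
            if gain > best_gain:
                best_idx, best_gain = i, gain
        if best_idx is None:
            break  # no single addition helps; greedy plateau
        chosen.append(best_idx)
        chosen.sort()
        current = _n_unique(matrix, chosen)
    return MinimalSetResult(
        indices=tuple(chosen),
        positions=tuple(matrix.positions[i] for i in chosen),
        achieved_unique=frozenset(matrix.restrict(chosen).unique_opus),
        unresolvable=unresolvable,
        method="greedy",
    )


def redundant_diagnostic_set(
    matrix: DiagnosticMatrix,
    redundancy: int = 2,
    exhaustive_limit: int = 20,
) -> tuple[int, ...]:
    """Minimal set augmented with up to ``redundancy`` diagnostic positions
    per OPU.

    A minimal set keeps one diagnostic site per OPU; a single sequencing
    failure at that site then loses the OPU.  Keeping up to ``redundancy``
    diagnostic positions per OPU (lowest indices first) buys robustness at
    the cost of a slightly longer barcode.  Returns sorted position indices.
    """
    base = set(minimal_diagnostic_set(matrix, exhaustive_limit).indices)
    for opu in matrix.opu_labels:
        mine = [
            i
            for i, p in enumerate(matrix.positions)
            if opu in p.diagnostic_for
        ]
        base |= set(mine[:redundancy])
    return tuple(sorted(base))


def write_matrix_tsv(
    matrix: DiagnosticMatrix, path: str | Path, genotype_style: bool = False
) -> None:
    """Matrix TSV: rows = OPUs, columns = region:position, cells = states.

    ``genotype_style`` doubles each haploid letter (A -> AA), the common
    presentation in printed diagnostic tables.
    """

    def render(st: str) -> str:
        if st == POLYMORPHIC:
            return "P"
        return st * 2 if genotype_style else st

    with open(path, "w") as fh:
        fh.write("opu\t" + "\t".join(p.label for p in matrix.positions) + "\n")
        for opu, profile in matrix.profiles.items():
            fh.write(opu + "\t" + "\t".join(render(s) for s in profile) + "\n")


def read_matrix_tsv(path: str | Path) -> DiagnosticMatrix:
    """Read a matrix TSV back into a DiagnosticMatrix.

    Doubled-letter cells (AA) are collapsed to one state; P restores
    ``polymorphic``.  ``diagnostic_for`` is recomputed from the states
    (see :func:`diagnostic_for_from_states`).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        labels = header[1:]
        rows: dict[str, list[str]] = {}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows[parts[0]] = parts[1:]
    if not labels or not rows:
        raise ValueError(f"{path}: empty diagnostic matrix")
    positions = []
    opu_order = list(rows)
    for j, lab in enumerate(labels):
        region, _, pos = lab.rpartition(":")
        states = {}
        for opu in opu_order:
            cell = rows[opu][j].upper()
            if cell == "P" or cell == POLYMORPHIC.upper():
                states[opu] = POLYMORPHIC
            else:
                if len(cell) == 2 and cell[0] == cell[1]:
                    cell = cell[0]
                states[opu] = cell
        positions.append(
            DiagnosticPosition(
                region=region or "matrix",
                pos_1based=int(pos) if pos.isdigit() else j + 1,
                state_by_opu=states,
                diagnostic_for=diagnostic_for_from_states(states),
            )
        )
    return DiagnosticMatrix(positions=tuple(positions), opu_labels=tuple(opu_order))


def write_report_json(
    matrix: DiagnosticMatrix,
    minimal: MinimalSetResult,
    path: str | Path,
    redundant_indices: Sequence[int] | None = None,
) -> None:
    """JSON report: uniqueness, collisions, minimal and redundant sets."""
    report = {
        "n_positions": len(matrix.positions),
        "positions": [p.label for p in matrix.positions],
        "unique_opus": sorted(matrix.unique_opus),
        "profile_collisions": [sorted(c) for c in matrix.profile_collisions],
        "single_site_diagnostic_opus": sorted(
            {o for p in matrix.positions for o in p.diagnostic_for}
        ),
        "minimal_set": {
            "positions": [p.label for p in minimal.positions],
            "size": len(minimal.positions),
            "achieved_unique": sorted(minimal.achieved_unique),
            "method": minimal.method,
        },
    }
    if redundant_indices is not None:
        report["redundant_set"] = {
            "positions": [matrix.positions[i].label for i in redundant_indices],
            "size": len(redundant_indices),
        }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
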