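"""Barcode evaluation: region statistics and haplotype collapsing.

A candidate barcode is judged by its length, number of variable sites
(Var, %Var) and number of parsimony-informative sites (PIS, %PIS), and by
how its sequences partition into haplotypes across samples and taxa.  A
species whose haplotypes are all private to it can be identified by the
region alone; a species sharing every haplotype with congeners cannot,
which is what motivates clade-level (rather than species-level)
identification targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .msa import Alignment, classify_columns, percent
from .windows import BarcodeRegion


@dataclass(frozen=True)
class BarcodeStats:
    """Length / Var / %Var / PIS / %PIS summary for one barcode region."""

    name: str
    length: int
    var_count: int
    pct_var: float
    pis_count: int
    pct_pis: float


@dataclass(frozen=True)
class Haplotype:
    """One distinct sequence over a barcode region and who carries it."""

    label: str  # Roman numeral, in order of first occurrence
    sequence: str
    members: tuple[str, ...]
    group_counts: dict[str, int]  # OPU / species label -> member count

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple[Haplotype, ...]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def haplotype_of(self, sample_id: str) -> Haplotype:
        for h in self.haplotypes:
            if sample_id in h.members:
                return h
        raise KeyError(sample_id)

    def unique_groups(self) -> set[str]:
        """Groups never sharing a haplotype with another group.

        A group (species or OPU label) is haplotype-unique iff no
        haplotype carries it together with a different label.
        """
        shared: set[str] = set()
        seen: set[str] = set()
        for h in self.haplotypes:
            labels = set(h.group_counts)
            seen |= labels
            if len(labels) > 1:
                shared |= labels
        return seen - shared


def extract_region(aln: Alignment, region: BarcodeRegion) -> Alignment:
    """Column slice of the alignment for one region; sample order preserved."""
    return aln.slice_columns(region.start, region.end, name=region.name)


def barcode_stats(sub: Alignment, name: str | None = None) -> BarcodeStats:
    """Compute Var/PIS counts and percentages for a (sub-)alignment."""
    cols = classify_columns(sub)
    var_count = sum(c.is_variable for c in cols)
    pis_count = sum(c.is_pis for c in cols)
    return BarcodeStats(
        name=name if name is not None else sub.name,
        length=sub.length,
        var_count=var_count,
        pct_var=percent(var_count, sub.length),
        pis_count=pis_count,
        pct_pis=percent(pis_count, sub.length),
    )


def to_roman(n: int) -> str:
    """1 -> I, 2 -> II, ... (haplotype labels)."""
    if n < 1:
        raise ValueError("Roman numerals start at 1")
    vals = [
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"),
        (100, "C"), (90, "XC"), (50, "L"), (40, "XL"),
        (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = []
    for v, sym in vals:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)


def collapse_haplotypes(
    sub: Alignment,
    labels: Mapping[str, str] | None = None,
    collapse_missing: bool = False,
) -> HaplotypeTable:
    """Group samples with identical sequences into haplotypes.

    Identity is exact symbol equality; N equals only N, so two sequences
    differing solely by missing data form separate haplotypes (exactness is
    reproducible, unlike ambiguity-aware matching whose result can depend
    on comparison order).  With ``collapse_missing=True`` sequences that
    agree over their mutually non-missing columns are merged greedily, in
    sample order — documented as order-dependent.

    Haplotypes are labelled I, II, III, ... in order of first occurrence.
    Samples absent from ``labels`` are tallied under "unassigned".
    """
    labels = dict(labels or {})
    groups: list[tuple[str, list[str]]] = []  # (representative sequence, members)
    for sid, row in zip(sub.sample_ids, sub.rows):
        placed = False
        for i, (rep, members) in enumerate(groups):
            if row == rep or (collapse_missing and _compatible(row, rep)):
                members.append(sid)
                if collapse_missing:
                    groups[i] = (_merge_states(rep, row), members)
                placed = True
                break
        if not placed:
            groups.append((row, [sid]))
    haplotypes = []
    for i, (rep, members) in enumerate(groups, start=1):
        counts: dict[str, int] = {}
        for sid in members:
            lab = labels.get(sid, "unassigned")
            counts[lab] = counts.get(lab, 0) + 1
        haplotypes.append(
            Haplotype(
                label=to_roman(i),
                sequence=rep,
                members=tuple(members),
                group_counts=counts,
            )
        )
    return HaplotypeTable(haplotypes=tuple(haplotypes))


def _compatible(a: str, b: str) -> bool:
    missing = ("N", "-")
    return all(
        x == y or x in missing or y in missing for x, y in zip(a, b)
    )


def _merge_states(a: str, b: str) -> str:
    missing = ("N", "-")
    return "".join(y if x in missing else x for x, y in zip(a, b))


def hamming_matrix(table: HaplotypeTable, ignore_missing: bool = True) -> np.ndarray:
    """Pairwise Hamming distances between haplotype representatives.

    With ``ignore_missing`` (default) positions where either sequence is N
    or gap do not count as differences, so distances feed a network tool
    without missing-data inflation.
    """
    seqs = [h.sequence for h in table.haplotypes]
    k = len(seqs)
    dist = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x != y:
                    if ignore_missing and (x in "N-" or y in "N-"):
                        continue
                    d += 1
            dist[i, j] = dist[j, i] = d
    return dist


def write_stats_tsv(stats: Iterable[BarcodeStats], path: str | Path) -> None:
    """Barcode statistics table (columns in Length/Var/%Var/PIS/%PIS order)."""
    with open(path, "w") as fh:
        fh.write("barcode\tlength_bp\tvar\tpct_var\tpis\tpct_pis\n")
        for s in stats:
            fh.write(
                f"{s.name}\t{s.length}\t{s.var_count}\t{s.pct_var:.2f}\t"
                f"{s.pis_count}\t{s.pct_pis:.2f}\n"
            )


def write_haplotype_tsv(table: HaplotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("haplotype\tsize\tmembers\tlabels\n")
        for h in table.haplotypes:
            labels = ";".join(f"{k}:{v}" for k, v in sorted(h.group_counts.items()))
            fh.write(f"{h.label}\t{h.size}\t{';'.join(h.members)}\t{labels}\n")


def write_haplotype_fasta(table: HaplotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in table.haplotypes:
            fh.write(f">{h.label} size={h.size}\n{h.sequence}\n")


def write_hamming_tsv(table: HaplotypeTable, path: str | Path) -> None:
    dist = hamming_matrix(table)
    labels = [h.label for h in table.haplotypes]
    with open(path, "w") as fh:
        fh.write("haplotype\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, dist):
            fh.write(lab + "\t" + "\t".join(str(int(d)) for d in row) + "\n")
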