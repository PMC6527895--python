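"""Window scan: SNP density per fixed window and candidate barcode selection.

The alignment is tiled into non-overlapping windows (default 500 bp, the
bin size used for plastome SNP-density plots).  Each window records its SNP
count, variability (SNPs per column) and masked fraction (share of
sample x column cells that are N or gap).  Candidate barcode windows are
those with variability strictly above 5% and masked data strictly below 3%;
runs of adjacent candidates merge into larger regions (two bins -> 1,000 bp,
four bins -> 2,000 bp), which can then be refined at 50 bp resolution by
trimming invariant flanks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .msa import Alignment, missing_cell_mask, variable_column_mask

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500
DEFAULT_MIN_VARIABILITY = 0.05
DEFAULT_MAX_MASKED = 0.03
DEFAULT_SUBWINDOW = 50
DEFAULT_MIN_SUB_VARIABILITY = 0.02


@dataclass(frozen=True)
class WindowDensity:
    """One tile of the alignment with its SNP density.

    ``start``/``end`` are 0-based half-open column coordinates;
    ``variability`` is ``snp_count / (end - start)`` and ``masked_fraction``
    the share of cells (samples x columns) coded N or gap.
    """

    start: int
    end: int
    snp_count: int
    masked_fraction: float

    @property
    def variability(self) -> float:
        return self.snp_count / (self.end - self.start)

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BarcodeRegion:
    """A named half-open column interval marking a (candidate) barcode."""

    name: str
    start: int
    end: int
    source: str = "user-supplied"  # window-merge | refined | user-supplied

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region [{self.start}, {self.end})")

    @property
    def size(self) -> int:
        return self.end - self.start


def scan_windows(
    aln: Alignment,
    window_size: int = DEFAULT_WINDOW,
    gaps_as_state: bool = False,
) -> list[WindowDensity]:
    """Tile the alignment into consecutive windows and count SNPs in each.

    Windows start at column 0; a trailing partial window is emitted with
    its true (shorter) length, which is also the variability denominator.
    If ``window_size`` exceeds the alignment length a single window covers
    all columns.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    var_mask = variable_column_mask(aln, gaps_as_state=gaps_as_state)
    miss = missing_cell_mask(aln)
    out: list[WindowDensity] = []
    for start in range(0, aln.length, window_size):
        end = min(start + window_size, aln.length)
        out.append(
            WindowDensity(
                start=start,
                end=end,
                snp_count=int(var_mask[start:end].sum()),
                masked_fraction=float(miss[:, start:end].mean()),
            )
        )
    return out


def select_candidates(
    windows: Iterable[WindowDensity],
    min_variability: float = DEFAULT_MIN_VARIABILITY,
    max_masked: float = DEFAULT_MAX_MASKED,
) -> list[WindowDensity]:
    """Keep windows with variability > ``min_variability`` and masked
    fraction < ``max_masked``.

    Both inequalities are strict: a 500 bp window needs at least 26 SNPs
    to pass the default 5% threshold.
    """
    if not (0 <= min_variability <= 1 and 0 <= max_masked <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    return [
        w
        for w in windows
        if w.variability > min_variability and w.masked_fraction < max_masked
    ]


def merge_candidates(
    selected: Sequence[WindowDensity], max_gap_windows: int = 0
) -> list[BarcodeRegion]:
    """Merge maximal runs of adjacent selected windows into regions.

    ``max_gap_windows`` adjacent-but-unselected windows may be bridged
    (default 0: only directly abutting windows merge).  Region names are
    generated from 1-based inclusive coordinates.
    """
    if not selected:
        return []
    ordered = sorted(selected, key=lambda w: w.start)
    regions: list[BarcodeRegion] = []
    run_start, run_end = ordered[0].start, ordered[0].end
    for w in ordered[1:]:
        # bridge up to max_gap_windows unselected tiles of this window's width
        gap = w.start - run_end
        if 0 <= gap <= max_gap_windows * w.size:
            run_end = w.end
        else:
            regions.append(_named_region(run_start, run_end))
            run_start, run_end = w.start, w.end
    regions.append(_named_region(run_start, run_end))
    return regions


def _named_region(start: int, end: int) -> BarcodeRegion:
    return BarcodeRegion(
        name=f"bar_{start + 1}_{end}", start=start, end=end, source="window-merge"
    )


def refine_region(
    aln: Alignment,
    region: BarcodeRegion,
    subwindow: int = DEFAULT_SUBWINDOW,
    min_sub_variability: float = DEFAULT_MIN_SUB_VARIABILITY,
    gaps_as_state: bool = False,
) -> BarcodeRegion:
    """Shrink a candidate region to its variable core at sub-window resolution.

    The region is tiled into ``subwindow``-sized tiles (trailing partial
    tile kept); the longest contiguous run of tiles whose variability is
    >= ``min_sub_variability`` becomes the refined region.  This trims
    invariant flanks the 500 bp scan could not see.  If every tile falls
    below the threshold the single most variable tile is returned with a
    warning.  Ties (equal run length, equal best tile) resolve to the
    leftmost, for reproducibility.
    """
    if not (0 <= region.start < region.end <= aln.length):
        raise ValueError(f"region {region.name} outside alignment")
    if subwindow < 1 or subwindow > region.size:
        raise ValueError("subwindow must satisfy 1 <= subwindow <= region size")
    var_mask = variable_column_mask(aln, gaps_as_state=gaps_as_state)
    bounds = list(range(region.start, region.end, subwindow)) + [region.end]
    tiles = list(zip(bounds[:-1], bounds[1:]))
    variabilities = [var_mask[s:e].sum() / (e - s) for s, e in tiles]
    keep = [v >= min_sub_variability for v in variabilities]
    best_run = _longest_true_run(keep)
    if best_run is None:
        best = int(np.argmax(variabilities))
        msg = (
            f"region {region.name}: no {subwindow} bp sub-window reaches "
            f"variability {min_sub_variability}; returning best sub-window"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        s, e = tiles[best]
    else:
        i, j = best_run
        s, e = tiles[i][0], tiles[j - 1][1]
    return BarcodeRegion(
        name=f"{region.name}_refined", start=s, end=e, source="refined"
    )


def _longest_true_run(flags: Sequence[bool]) -> tuple[int, int] | None:
    """Half-open index bounds of the longest run of True, leftmost on ties."""
    best: tuple[int, int] | None = None
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            if best is None or j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def write_density_tsv(windows: Iterable[WindowDensity], path: str | Path) -> None:
    """Density table per window (substitute for a circular density plot)."""
    with open(path, "w") as fh:
        fh.write("start_0based\tend\tsnp_count\tvariability\tmasked_fraction\n")
        for w in windows:
            fh.write(
                f"{w.start}\t{w.end}\t{w.snp_count}\t"
                f"{w.variability:.6g}\t{w.masked_fraction:.6g}\n"
            )


def write_bed(
    regions: Iterable[BarcodeRegion],
    path: str | Path,
    chrom: str = "alignment",
    scores: dict[str, int] | None = None,
) -> None:
    """Write regions as BED (0-based half-open); score column = SNP count."""
    with open(path, "w") as fh:
        for r in regions:
            score = (scores or {}).get(r.name, 0)
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\n")


def read_bed(path: str | Path) -> list[BarcodeRegion]:
    """Read regions from a BED file (chrom ignored; name defaults to coords)."""
    regions: list[BarcodeRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"bar_{start + 1}_{end}"
            regions.append(
                BarcodeRegion(name=name, start=start, end=end, source="user-supplied")
            )
    return regions
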