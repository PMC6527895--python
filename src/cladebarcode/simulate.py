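"""Synthetic alignments with exactly controlled column structure.

The generator emulates a masked, clade-structured plastome alignment while
keeping every column class count *exact by construction*: the background
is constant, and variable columns are planted explicitly as

* **diagnostic** columns — fixed for one state inside a chosen OPU and for
  a different single state everywhere else,
* **extra variable** columns — a singleton substitution (variable but not
  parsimony-informative), or
* **parsimony-informative** columns — a minor allele carried by two
  samples placed in *different* OPUs, so the column is informative but
  neither fixed within nor diagnostic for any group.

Masked blocks overwrite chosen samples with N over an interval; planted
columns are kept outside masked intervals so the recorded truth (variable
and PIS counts, diagnostic columns) holds exactly.  An optional
Jukes-Cantor star-tree mode generates unstructured noise alignments for
stress tests, where counts are random rather than specified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .diagnostics import OPUAssignment
from .msa import Alignment, NUCLEOTIDES, write_alignment
from .diagnostics import write_opu_table


class SimSpecError(ValueError):
    """Raised for infeasible simulation specifications."""


@dataclass(frozen=True)
class SimSpec:
    """Specification of a synthetic alignment.

    ``planted_diagnostics`` maps OPU label -> list of (column, state);
    ``masked_blocks`` is a list of (sample index list, (start, end))
    half-open intervals overwritten with N.
    """

    length: int
    opu_sizes: dict[str, int]
    planted_diagnostics: dict[str, list[tuple[int, str]]] = field(
        default_factory=dict
    )
    n_extra_variable: int = 0
    n_pis: int = 0  # of the extra variable columns, how many are PIS
    masked_blocks: list[tuple[list[int], tuple[int, int]]] = field(
        default_factory=list
    )
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(self.opu_sizes.values())

    def validate(self) -> None:
        if self.length < 1:
            raise SimSpecError("length must be >= 1")
        if not self.opu_sizes or any(v < 1 for v in self.opu_sizes.values()):
            raise SimSpecError("every OPU needs at least one sample")
        if self.n_pis > self.n_extra_variable:
            raise SimSpecError("n_pis cannot exceed n_extra_variable")
        planted = [c for cols in self.planted_diagnostics.values() for c, _ in cols]
        if len(planted) != len(set(planted)):
            raise SimSpecError("planted diagnostic columns overlap")
        if any(c < 0 or c >= self.length for c in planted):
            raise SimSpecError("planted column outside alignment")
        unknown = set(self.planted_diagnostics) - set(self.opu_sizes)
        if unknown:
            raise SimSpecError(f"planted OPUs not in opu_sizes: {sorted(unknown)}")
        masked_cols = self._masked_columns()
        if masked_cols & set(planted):
            raise SimSpecError("planted columns may not fall in masked blocks")
        free = self.length - len(planted) - len(masked_cols)
        if self.n_extra_variable > free:
            raise SimSpecError(
                f"{self.n_extra_variable} extra variable columns do not fit "
                f"in {free} free columns"
            )
        for samples, (s, e) in self.masked_blocks:
            if not (0 <= s < e <= self.length):
                raise SimSpecError(f"masked interval [{s}, {e}) out of bounds")
            if any(i < 0 or i >= self.n_samples for i in samples):
                raise SimSpecError("masked sample index out of range")

    def _masked_columns(self) -> set[int]:
        out: set[int] = set()
        for _, (s, e) in self.masked_blocks:
            out |= set(range(s, e))
        return out


def _pick_other(rng: np.random.Generator, avoid: set[str]) -> str:
    choices = [b for b in NUCLEOTIDES if b not in avoid]
    return choices[rng.integers(len(choices))]


def simulate_alignment(
    spec: SimSpec,
) -> tuple[Alignment, OPUAssignment, dict]:
    """Build the alignment, the OPU assignment, and a truth record.

    The truth record lists planted diagnostic columns per OPU, all
    variable columns, and the exact expected variable/PIS counts, so tests
    and pipelines can verify recovery without re-deriving the ground truth.
    Deterministic: the same spec (including seed) yields identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = []
    opu_of: dict[str, str] = {}
    for opu, size in spec.opu_sizes.items():
        for i in range(size):
            sid = f"{opu}_s{i + 1}"
            sample_ids.append(sid)
            opu_of[sid] = opu
    opu_row_idx: dict[str, list[int]] = {}
    for i, sid in enumerate(sample_ids):
        opu_row_idx.setdefault(opu_of[sid], []).append(i)

    # constant background, one random base per column
    bg = rng.integers(4, size=spec.length)
    arr = np.empty((n, spec.length), dtype="U1")
    for j, b in enumerate(bg):
        arr[:, j] = NUCLEOTIDES[b]

    planted_cols: set[int] = set()
    pis_cols: set[int] = set()
    for opu, plants in spec.planted_diagnostics.items():
        inside = opu_row_idx[opu]
        outside = [i for i in range(n) if i not in inside]
        if not outside:
            raise SimSpecError("a diagnostic column needs samples outside the OPU")
        for col, state in plants:
            out_state = _pick_other(rng, {state})
            arr[:, col] = out_state
            arr[inside, col] = state
            planted_cols.add(col)
            if len(inside) >= 2 and len(outside) >= 2:
                pis_cols.add(col)

    masked_cols = spec._masked_columns()
    free = [
        j
        for j in range(spec.length)
        if j not in planted_cols and j not in masked_cols
    ]
    extra_cols = sorted(
        rng.choice(len(free), size=spec.n_extra_variable, replace=False)
    )
    extra_cols = [free[i] for i in extra_cols]

    # carriers for singleton and PIS substitutions: prefer OPUs with >= 2
    # members so a lone minor allele never becomes fixed in a whole OPU
    multi = [o for o, s in spec.opu_sizes.items() if s >= 2]
    opu_order = list(spec.opu_sizes)
    for k, col in enumerate(extra_cols):
        major = arr[0, col]
        minor = _pick_other(rng, {major})
        if k < spec.n_pis:
            # minor allele in two samples from different OPUs when possible
            if len(opu_order) >= 2:
                o1, o2 = opu_order[k % len(opu_order)], opu_order[
                    (k + 1) % len(opu_order)
                ]
                carriers = [opu_row_idx[o1][0], opu_row_idx[o2][0]]
            else:
                rows = opu_row_idx[opu_order[0]]
                if len(rows) < 2:
                    raise SimSpecError("PIS column needs at least two samples")
                carriers = rows[:2]
            arr[carriers, col] = minor
            pis_cols.add(col)
        else:
            source = multi[k % len(multi)] if multi else opu_order[0]
            arr[opu_row_idx[source][0], col] = minor

    for samples, (s, e) in spec.masked_blocks:
        arr[np.asarray(samples, dtype=int), s:e] = "N"

    aln = Alignment(
        sample_ids=tuple(sample_ids),
        rows=tuple("".join(row) for row in arr),
        name=f"sim_seed{spec.seed}",
    )
    opus = OPUAssignment.from_mapping(opu_of)
    truth = {
        "planted_diagnostics": {
            opu: sorted((c, s) for c, s in plants)
            for opu, plants in spec.planted_diagnostics.items()
        },
        "variable_columns": sorted(planted_cols | set(extra_cols)),
        "n_variable": len(planted_cols) + len(extra_cols),
        "n_pis": len(pis_cols),
        "seed": spec.seed,
    }
    return aln, opus, truth


def exact_count_alignment(
    length: int,
    n_variable: int,
    n_pis: int,
    n_samples: int = 20,
    seed: int = 0,
    name: str = "barcode",
) -> Alignment:
    """Alignment with exact variable / parsimony-informative counts.

    Convenience wrapper emulating a single published barcode row: one OPU,
    ``n_variable`` variable columns of which ``n_pis`` are PIS.
    """
    spec = SimSpec(
        length=length,
        opu_sizes={"all": n_samples},
        n_extra_variable=n_variable,
        n_pis=n_pis,
        seed=seed,
    )
    aln, _, _ = simulate_alignment(spec)
    return Alignment(sample_ids=aln.sample_ids, rows=aln.rows, name=name)


def jukes_cantor_alignment(
    n_samples: int,
    length: int,
    substitution_rate: float = 0.02,
    seed: int = 0,
) -> Alignment:
    """Unstructured noise alignment: i.i.d. substitutions on a star tree.

    Each cell mutates away from a random ancestral base with probability
    ``substitution_rate`` (uniform over the three alternatives).  Column
    class counts are random — use for stress tests, not count targets.
    """
    rng = np.random.default_rng(seed)
    anc = rng.integers(4, size=length)
    arr = np.empty((n_samples, length), dtype="U1")
    for j, b in enumerate(anc):
        arr[:, j] = NUCLEOTIDES[b]
    hits = rng.random((n_samples, length)) < substitution_rate
    for i, j in zip(*np.nonzero(hits)):
        arr[i, j] = _pick_other(rng, {arr[i, j]})
    return Alignment(
        sample_ids=tuple(f"s{i + 1}" for i in range(n_samples)),
        rows=tuple("".join(r) for r in arr),
        name=f"jc_seed{seed}",
    )


def write_simulation(
    spec: SimSpec, outdir: str | Path, prefix: str = "sim"
) -> tuple[Path, Path, Path]:
    """Run a simulation and write FASTA + OPU TSV + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, opus, truth = simulate_alignment(spec)
    fasta = outdir / f"{prefix}.fasta"
    opu_tsv = outdir / f"{prefix}.opus.tsv"
    truth_json = outdir / f"{prefix}.truth.json"
    write_alignment(aln, fasta)
    write_opu_table(opus, opu_tsv)
    with open(truth_json, "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return fasta, opu_tsv, truth_json


def read_simspec(path: str | Path) -> SimSpec:
    """Read a SimSpec from a JSON file (keys as in the dataclass)."""
    with open(path) as fh:
        raw = json.load(fh)
    return SimSpec(
        length=raw["length"],
        opu_sizes=dict(raw["opu_sizes"]),
        planted_diagnostics={
            opu: [(int(c), str(s)) for c, s in cols]
            for opu, cols in raw.get("planted_diagnostics", {}).items()
        },
        n_extra_variable=raw.get("n_extra_variable", 0),
        n_pis=raw.get("n_pis", 0),
        masked_blocks=[
            (list(map(int, samples)), (int(iv[0]), int(iv[1])))
            for samples, iv in raw.get("masked_blocks", [])
        ],
        seed=raw.get("seed", 0),
    )
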