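"""Packaged reference fixtures: the nine-OPU diagnostic matrix.

A published worked example of the method: nine OPUs from a whole-plastome
*Berberis* phylogeny scored at nine diagnostic positions across three
barcode regions (matK, the ndhI-ndhG intergenic spacer, and a non-coding
stretch of the small single-copy region), plus three commercial "market"
test samples.  Two OPUs (clade 3 and the South American clade 8) share an
identical profile and are indistinguishable by this matrix; the market
samples resolve to the Mahonia clade (Market1/2, despite one masked
position) and to the asiatica clade (Market3).
"""

from __future__ import annotations

from .classify import QueryProfile
from .diagnostics import (
    DiagnosticMatrix,
    DiagnosticPosition,
    diagnostic_for_from_states,
)

OPU_LABELS = (
    "clade_1",
    "clade_2",
    "clade_3",
    "aristata_clade_4",
    "asiatica_clade_5",
    "clade_6",
    "clade_7",
    "SA_clade_8",
    "Mahonia_clade_9",
)

# (region, 1-based position within the region's barcode alignment)
POSITIONS = (
    ("matK", 755),
    ("matK", 857),
    ("matK", 976),
    ("matK", 1428),
    ("ndhI-ndhG", 151),
    ("ndhI-ndhG", 182),
    ("ndhI-ndhG", 326),
    ("SSC_noncoding2", 47),
    ("SSC_noncoding2", 700),
)

# one haploid state per cell (published tables double the letters: A -> AA)
PROFILES = {
    "clade_1":          "AGGGCACAG",
    "clade_2":          "AGGACACAA",
    "clade_3":          "AGGGAACAA",
    "aristata_clade_4": "CAGGCACAA",
    "asiatica_clade_5": "AGGGCCCAA",
    "clade_6":          "AGGGCACAA",
    "clade_7":          "AGAGCACAA",
    "SA_clade_8":       "AGGGAACAA",
    "Mahonia_clade_9":  "AGGGAAACA",
}

MARKET_PROFILES = {
    "Market1": "AGGGAANCA",
    "Market2": "AGGGAANCA",
    "Market3": "AGGGCCCAA",
}


def published_matrix_fixture() -> tuple[DiagnosticMatrix, dict[str, QueryProfile]]:
    """The packaged 9 OPU x 9 position matrix and market query profiles."""
    positions = []
    for j, (region, pos) in enumerate(POSITIONS):
        states = {opu: PROFILES[opu][j] for opu in OPU_LABELS}
        positions.append(
            DiagnosticPosition(
                region=region,
                pos_1based=pos,
                state_by_opu=states,
                diagnostic_for=diagnostic_for_from_states(states),
            )
        )
    matrix = DiagnosticMatrix(positions=tuple(positions), opu_labels=OPU_LABELS)
    queries = {
        qid: QueryProfile(query_id=qid, states=tuple(prof))
        for qid, prof in MARKET_PROFILES.items()
    }
    return matrix, queries
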