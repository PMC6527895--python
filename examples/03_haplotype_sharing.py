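"""Haplotype collapsing: who shares a sequence over a barcode region.

Builds a small alignment where one species' haplotype is also carried by a
second species — the situation that makes a species-specific barcode
impossible and motivates clade-level identification units.
"""

from cladebarcode import Alignment, collapse_haplotypes, hamming_matrix

rows = {
    "aristata_1":    "ACGTACGTAC",
    "aristata_2":    "ACGTACGTAC",
    "aristata_3":    "ACGTACGTAC",
    "karnaliensis_1": "ACGTACGTAC",   # shares the aristata haplotype
    "aristata_4":    "ACGAACGTAC",
    "asiatica_1":    "GCGTACTTAC",
    "asiatica_2":    "GCGTACTTAC",
}
species = {sid: sid.rsplit("_", 1)[0] for sid in rows}
aln = Alignment(sample_ids=tuple(rows), rows=tuple(rows.values()))

table = collapse_haplotypes(aln, species)
print("haplotype  size  composition")
for h in table.haplotypes:
    comp = ", ".join(f"{sp} ({n})" for sp, n in sorted(h.group_counts.items()))
    print(f"{h.label:<10} {h.size:>4}  {comp}")

print("\nspecies with only private haplotypes:", sorted(table.unique_groups()))

dist = hamming_matrix(table)
print("\npairwise haplotype distances (substitutions):")
print(dist)

# Haplotype I is shared by aristata and karnaliensis, so no haplotype is
# unique to aristata: identification must target the clade, not the species.
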