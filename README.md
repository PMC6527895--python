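# cladebarcode

Clade-specific DNA barcode design from whole-plastome multiple sequence
alignments.

## The problem

Universal plant barcodes (*matK*, *rbcL*, ITS2, *trnH-psbA*) often cannot
resolve medicinally important species: in evolutionarily complex genera the
pharmacopoeial species may be polyphyletic, so no species-specific marker
can exist. The character-based alternative implemented here targets
**Operational Phylogenetic Units (OPUs)** — clades on a reference
phylogeny — instead of species, and identifies them by **diagnostic
nucleotides**: states fixed within an OPU and absent from every other OPU.
The result is a short published matrix a regulator or quality-control lab
can test a sample against by PCR and Sanger sequencing, pass/fail, like any
other pharmacopoeial standard.

## The method

Given an alignment $A$ of $n$ plastomes over $\{A,C,G,T,N,-\}$ and a
sample-to-OPU assignment:

1. **Window scan.** Tile $A$ into 500 bp windows; a window is a candidate
   when its variability (variable columns per bp) exceeds 5% and its
   masked-cell fraction is below 3%. Adjacent candidates merge (two bins
   → 1,000 bp, four bins → 2,000 bp); merged regions are refined at 50 bp
   resolution by trimming sub-windows below 2% variability.
2. **Barcode evaluation.** For each region: length, variable sites (Var,
   %Var), parsimony-informative sites (PIS, %PIS), and haplotype
   collapsing with per-taxon sharing (a species sharing every haplotype
   cannot be identified by the region alone).
3. **Diagnostics.** For every variable column each OPU gets a state —
   fixed nucleotide, `polymorphic`, or `N` — and a fixed state is
   *diagnostic* when absent from all non-missing members of every other
   OPU. Diagnostic and profile-separating columns form the diagnostic
   matrix; an exhaustive (≤20 candidates) or greedy set-cover search finds
   the smallest position subset preserving the matrix's discriminating
   power, optionally padded to ≥2 diagnostic sites per OPU for redundancy.
4. **Classification.** A query's states at the matrix positions are
   compared to every OPU profile; one observed conflicting nucleotide
   excludes an OPU, missing data excludes nothing. Calls: `unique`,
   `ambiguous`, `no_match`, `unidentifiable`.

A seeded simulator generates alignments with exact variable/PIS counts and
planted diagnostic columns, so every stage is testable without any data
download.

## Worked example

`examples/` contains one narrative script per capability. The packaged
worked example is a nine-OPU, nine-position matrix over three plastid
regions (`examples/04_diagnostic_matrix.py`):

```
unique profiles: 7/9 OPUs
  collision (identical profiles): SA_clade_8 = clade_3

minimal set (exhaustive search): 7 positions
   matK:755, matK:976, matK:1428, ndhI-ndhG:151, ndhI-ndhG:182, ndhI-ndhG:326, SSC_noncoding2:700
redundant set (2 diagnostic sites per OPU): 9 positions
```

Seven OPUs have unique profiles; clades 3 and 8 are identical at every
position and no subset can separate them. Classifying the bundled
commercial test samples (`examples/05_classify_market_samples.py`):

```
query     states      call          compatible OPUs
Market1   AGGGAANCA   unique        Mahonia_clade_9
Market2   AGGGAANCA   unique        Mahonia_clade_9
Market3   AGGGCCCAA   unique        asiatica_clade_5
```

Market1/2 resolve uniquely to the *Mahonia* clade despite a missing
position — evidence of substitution, since the expected pharmacopoeial
clade is different. Market3 matches the *asiatica* clade.

## Command line

The same pipeline as subcommands (`cladebarcode --help`):

```sh
cladebarcode scan aln.fasta --out-density density.tsv --out-bed candidates.bed
cladebarcode stats aln.fasta --regions candidates.bed --out stats.tsv
cladebarcode diagnose aln.fasta opus.tsv --out-matrix matrix.tsv --out-report report.json
cladebarcode classify matrix.tsv queries.tsv --out calls.tsv
cladebarcode simulate spec.json --outdir sim/
```

Logs go to stderr, results to files, so commands compose in pipelines.

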