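"""Find candidate barcode regions by window-scanning an alignment.

Simulates a plastome-like alignment with two planted variability hotspots,
tiles it into 500 bp windows, selects windows with >5% variability and
<3% masked data, merges adjacent windows, and refines the merged region
at 50 bp resolution.
"""

from cladebarcode import (
    SimSpec,
    merge_candidates,
    refine_region,
    scan_windows,
    select_candidates,
    simulate_alignment,
)

# 6 kb alignment; dense variation planted in columns 2100-3400 so that the
# three windows covering them clear the 5% threshold (>25 SNPs / 500 bp)
spec = SimSpec(
    length=6000,
    opu_sizes={"cladeA": 6, "cladeB": 6},
    planted_diagnostics={
        "cladeA": [(c, "T") for c in range(2100, 3400, 15)],
    },
    n_extra_variable=30,
    n_pis=10,
    seed=42,
)
aln, opus, truth = simulate_alignment(spec)

windows = scan_windows(aln, window_size=500)
print("window  SNPs  variability  masked")
for w in windows:
    flag = " <-- candidate" if w.variability > 0.05 and w.masked_fraction < 0.03 else ""
    print(f"{w.start:>5}-{w.end:<5} {w.snp_count:>4}  {w.variability:10.3f}  "
          f"{w.masked_fraction:6.3f}{flag}")

selected = select_candidates(windows)           # strict >5% and <3%
regions = merge_candidates(selected)            # adjacent windows merge
print(f"\n{len(selected)} candidate windows -> {len(regions)} region(s):")
for r in regions:
    refined = refine_region(aln, r)             # trim invariant 50 bp flanks
    print(f"  {r.name}: {r.start}-{r.end} ({r.size} bp) "
          f"-> refined {refined.start}-{refined.end} ({refined.size} bp)")

# The refined interval hugs the planted hotspot: the scan recovers where
# the variation actually lies, at sub-window resolution.
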