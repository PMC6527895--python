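"""Plant diagnostic characters in a simulation and recover them.

The generator fixes chosen columns for one state inside a target OPU and
a different state everywhere else, then adds non-diagnostic variable
columns as noise.  The diagnostic scan must report exactly the planted
columns — 100% precision and recall in this homoplasy-free setting.
"""

from cladebarcode import SimSpec, find_diagnostic_positions, simulate_alignment

spec = SimSpec(
    length=600,
    opu_sizes={"g1": 5, "g2": 4, "g3": 3, "g4": 4},
    planted_diagnostics={
        "g1": [(30, "T"), (90, "C")],
        "g2": [(200, "A")],
        "g3": [(350, "G"), (400, "T")],
    },
    n_extra_variable=25,
    n_pis=10,
    seed=7,
)
aln, opus, truth = simulate_alignment(spec)
print(f"simulated {aln.n_samples} samples x {aln.length} bp, "
      f"{truth['n_variable']} variable columns ({truth['n_pis']} PIS)")

found = {
    p.column: sorted(p.diagnostic_for)
    for p in find_diagnostic_positions(aln, opus)
    if p.diagnostic_for
}
planted = {
    col: [opu]
    for opu, cols in truth["planted_diagnostics"].items()
    for col, _ in cols
}
print("\ncolumn  planted-for  recovered-for")
for col in sorted(planted):
    print(f"{col:>6}  {planted[col][0]:<11}  {found.get(col, ['-'])[0]}")
false_pos = sorted(set(found) - set(planted))
print(f"\nfalse positives: {false_pos or 'none'}  "
      f"missed: {sorted(set(planted) - set(found)) or 'none'}")

# Every planted column is recovered for its OPU and the 25 noise columns
# contribute nothing: the diagnostic definition (fixed inside, absent
# outside) admits no false positives without homoplasy.
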