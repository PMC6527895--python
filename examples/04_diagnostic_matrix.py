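"""The packaged nine-OPU diagnostic matrix and its minimal barcode.

Loads the published worked example — nine clades (OPUs) scored at nine
positions across three barcode regions — and reports which OPUs are
identifiable, which collide, and the smallest position subset that keeps
the full discriminating power.
"""

from cladebarcode import minimal_diagnostic_set, redundant_diagnostic_set, published_matrix_fixture

matrix, _ = published_matrix_fixture()

print("positions:", ", ".join(p.label for p in matrix.positions))
print("\nOPU profiles:")
for opu, profile in matrix.profiles.items():
    diag = [p.label for p in matrix.positions if opu in p.diagnostic_for]
    note = f"   diagnostic sites: {', '.join(diag)}" if diag else ""
    print(f"  {opu:<18} {''.join(profile)}{note}")

print(f"\nunique profiles: {len(matrix.unique_opus)}/{len(matrix.opu_labels)} OPUs")
for coll in matrix.profile_collisions:
    print("  collision (identical profiles):", " = ".join(sorted(coll)))

result = minimal_diagnostic_set(matrix)
print(f"\nminimal set ({result.method} search): {len(result.positions)} positions")
print("  ", ", ".join(p.label for p in result.positions))

redundant = redundant_diagnostic_set(matrix, redundancy=2)
print(f"redundant set (2 diagnostic sites per OPU): {len(redundant)} positions")

# Seven of nine positions already identify the same seven OPUs; the two
# extra published positions are redundancy against failure at single
# sites.  Clades 3 and 8 share a profile and no position subset can
# separate them.
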