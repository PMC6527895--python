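"""Classify commercial test samples against the diagnostic matrix.

The three market samples ship with the packaged matrix; Market1/Market2
carry missing data (N) at one position and still resolve uniquely,
because N excludes nothing — only an observed conflicting nucleotide
excludes an OPU.
"""

from cladebarcode import QueryProfile, classify_query, published_matrix_fixture

matrix, markets = published_matrix_fixture()

print(f"{'query':<10}{'states':<12}{'call':<14}compatible OPUs")
for qid, profile in markets.items():
    result = classify_query(profile, matrix)
    print(f"{qid:<10}{''.join(profile.states):<12}{result.call:<14}"
          f"{', '.join(sorted(result.compatible_opus))}")

# A profile matching the shared clade-3/clade-8 barcode is ambiguous:
shared = QueryProfile(query_id="shared", states=tuple("AGGGAACAA"))
result = classify_query(shared, matrix)
print(f"{'shared':<10}{''.join(shared.states):<12}{result.call:<14}"
      f"{', '.join(sorted(result.compatible_opus))}")

# Market1/2 are Mahonia (a substitution for the pharmacopoeial species!),
# Market3 matches the asiatica clade; the shared profile cannot be
# resolved below the clade-3/clade-8 pair.
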