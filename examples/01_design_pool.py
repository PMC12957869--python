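"""Design an error-correcting barcode pool.

Generates the first 60 barcodes of the default construction (12 nt,
minimum sequence-Levenshtein distance 4, composition filters on), then
keeps the 20 with the greatest mean pairwise distance — the same
generate-then-select recipe used to build a screening library.
"""

from bcscreen import (
    code_guarantees,
    conway_generate,
    mean_pairwise_distance,
    pool_min_distance,
    select_top_k,
)

pool = conway_generate(length=12, d_min=4, stop_after=60)
top = select_top_k(pool, 20)

print(f"generated {len(pool)} barcodes, min pairwise distance "
      f"{pool_min_distance(pool)}")
g = code_guarantees(pool.d_min)
print(f"guarantees: detect <= {g.detectable_errors} edits, "
      f"correct <= {g.correctable_errors} edit(s)")
print(f"selected top {len(top)} by mean pairwise distance "
      f"(mean of means {mean_pairwise_distance(top).mean():.2f})")
print("first five:", ", ".join(top.sequences[:5]))
# Each line of output shows the pool is a valid distance-4 code: every
# pair of barcodes differs by >= 4 edits even when embedded in longer DNA.
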