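"""Characteristic hierarchy scales of a cohort via CSA detection.

Across a cohort, per-level vectors of entropy-derivative values are
correlated; scales at which many proteins branch together produce
blocks of high correlation on the diagonal.  Lowering the display
threshold until the block structure repeats yields the stable
continuous square areas (CSA) — the cohort's characteristic scales.
"""

from anis import (
    build_level_vectors,
    correlation_matrix,
    planted_cohort,
    stability_scan,
)

bands = [(4, 8), (16, 22)]  # planted characteristic scales
curves = planted_cohort(seed=11, n_proteins=200, level_bands=bands, noise=0.1)

vectors = build_level_vectors(curves, min_proteins=10)
matrix = correlation_matrix(vectors, min_pair=10)
print(f"correlation matrix over levels {matrix.levels[0]}..{matrix.levels[-1]}")

result = stability_scan(matrix)
print(f"stable: {result.stable} at threshold {result.threshold:g}")
for block in result.blocks:
    if block.y_end > block.y_start:
        print(f"  CSA block: y = {block.y_start}..{block.y_end}")

# The two wide blocks recover the planted bands; the remaining levels
# appear as singletons (pure noise does not correlate across levels).
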