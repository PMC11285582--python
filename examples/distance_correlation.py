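"""Check that grid proximity reflects curve proximity.

The rank distance d_r = |b_i - b_j| measures separation along the
unfolded curve; the Chebyshev distance d_C measures separation on the
folded 2D grid. Their correlation quantifies how faithfully the folding
preserves the scaffold ordering.
"""

import warnings

from hcase import (
    FixtureSpec,
    build_reference_space,
    distance_correlation,
    embed_library,
    generate_compounds,
    generate_scaffolds,
)

warnings.simplefilter("ignore")

spec = FixtureSpec(n_scaffolds=200, n_compounds=300, seed=11)
scaffolds = generate_scaffolds(spec)
space = build_reference_space(scaffolds, source="example")
embedded = embed_library(generate_compounds(scaffolds, spec), space, z=8)

pearson = distance_correlation(embedded, method="pearson")
kendall = distance_correlation(embedded, method="kendall")
mean, std = distance_correlation(embedded, subset_size=100, n_subsets=3, seed=5)
print(f"all-pairs Pearson correlation (n={len(embedded)}): {pearson:.4f}")
print(f"all-pairs Kendall correlation:                    {kendall:.4f}")
print(f"3 non-overlapping subsets of 100: mean {mean:.4f}, std {std:.4f}")
print(
    "\npositive correlation: compounds close on the curve (similar\n"
    "scaffold rank) also sit close on the 2D map."
)
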