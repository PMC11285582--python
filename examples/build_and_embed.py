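"""Build a reference scaffold space and embed a small library.

The reference space orders Bemis-Murcko scaffolds by their Scaffold-Keys
(size first, then complexity and composition) and assigns each a rank.
Embedding folds the ranks onto a pseudo-Hilbert curve: each compound sits
at the grid cell of its SK-nearest reference scaffold.
"""

import warnings

from hcase import (
    FixtureSpec,
    build_reference_space,
    embed_library,
    generate_compounds,
    generate_scaffolds,
)

warnings.simplefilter("ignore")

spec = FixtureSpec(n_scaffolds=100, n_compounds=20, seed=42)
scaffolds = generate_scaffolds(spec)
space = build_reference_space(scaffolds, source="example")
print(f"reference space: {space.size} scaffolds (checksum {space.checksum()})")
print(f"rank 1 (simplest):  {space.scaffolds[0].scaffold.smiles}")
print(f"rank {space.size} (most complex): {space.scaffolds[-1].scaffold.smiles}")

compounds = generate_compounds(scaffolds, spec)
embedded = embed_library(compounds, space, z=5)
print(f"\nembedded {len(embedded)} compounds on the 32x32 grid (z=5):")
print("compound      nearest_rank  d_SK     bin   (x, y)")
for e in embedded[:6]:
    print(
        f"{e.compound_id}  {e.nearest_rank:12d}  {e.d_sk_nearest:6.3f}  "
        f"{e.b:4d}   ({e.point.x}, {e.point.y})"
    )
print(
    "\nd_SK = 0 means the compound's own scaffold is in the reference set;\n"
    "compounds sharing a scaffold share a grid cell."
)
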