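# Methods

## The embedding model

The method separates the *definition* of a chemical space from the
*embedding* of compounds into it.

**Reference space.** A collection of structures is standardized (largest
fragment by heavy-atom count; ties broken by lexicographically smallest
canonical SMILES), reduced to Bemis–Murcko scaffolds (the toolkit's
standard framework operation, which keeps ring systems, linkers and atoms
double-bonded to them, e.g. exocyclic carbonyls), and described by
Scaffold-Keys. Scaffolds with identical 32-key vectors are collapsed to
one representative (smallest InChI-Key), the survivors are totally ordered
by the key tuple (key 1 most significant; InChI-Key breaks full-vector
ties; a residual tie keeps input order with a warning) and ranked 1…|S|.
Acyclic or unparseable inputs are dropped and counted, never fatal.

**Scaffold-Keys.** Each key is a non-negative integer count computed by a
pure function of the molecular graph; the registry in
`scaffold_keys.KEY_REGISTRY` documents all 32 in order of decreasing
structural significance: overall size (heavy atoms, ring/linker atom and
bond counts), ring architecture (ring count, largest/smallest ring,
aromatic vs aliphatic, fusion/spiro/branching atoms), composition
(heteroatoms overall and per element, in and out of rings), then finer
electronic features (multiple bonds, exocyclic double bonds, branching
degrees, ring systems, charges). The published prose behind this
descriptor family is acknowledged to be ambiguous in places; this registry
is therefore the package's own documented transcription — each key's exact
count is fixed by its function and regression-tested against hand-counted
values on small scaffolds, so vectors are reproducible from the source
alone. Ordering-level properties (size-first progression, determinism,
tie handling) do not depend on the disputed details.

The scaffold distance is d_SK(i,j) = Σ_{n=1..32} √(|SKᵢ(n)−SKⱼ(n)|³)/n: a
unit difference in key *n* contributes exactly 1/n, so disagreement in
significant keys dominates.

**Curve folding.** A pseudo-Hilbert curve of order z ≥ 1 traverses the
2^z × 2^z grid; the index↔coordinate maps are the classic Gray-code
quadrant construction with entry at (0,0) (orientation is a frozen
convention; all tested properties are orientation-independent). Ranks map
to curve bins via l = |S|/(|D|−1) and b = round(r/l) with
round-half-away-from-zero — centralized because a banker's-rounding
implementation would silently shift every .5 tie. Ranks are 1-based so the
top rank lands exactly on the last zero-indexed bin |D|−1. Only the 2D
folding is implemented; the dimension argument exists for interface
symmetry and rejects anything else.

**Embedding.** Per compound: standardize → scaffold → SK → nearest
reference scaffold (argmin of d_SK; ties to the lowest rank, i.e. the
simpler scaffold) → bin → grid cell. The compound's SK is computed from
its scaffold, not the whole molecule. Placement is per-compound, so
subsets embed identically to supersets and input order is irrelevant.
Grids finer than |S|+1 cells are allowed but warned about: beyond that
point extra resolution cannot separate reference scaffolds further (and
the overlap statistic θ becomes exactly z-invariant, since further
refinement only relabels occupied bins bijectively).

## Analysis layer

d_r = |b_i − b_j| is separation along the unfolded curve; d_C =
max(|Δx|,|Δy|) is the perceived distance on the grid. Their correlation
(Pearson or Kendall) is computed over **all unordered pairs** of the
analyzed set — the only pair-enumeration that defines a single number —
optionally over non-overlapping seeded random subsets (mean ± sd
reported). Degenerate sets where either distance is constant are refused
as undefined rather than reported as 0.

θ compares two embeddings of the *same* space and order via their
|D|-length per-bin count vectors; vectors from different spaces (checksum)
or orders are refused, since cross-resolution overlap is not a defined
quantity. θ of two all-zero vectors is an error, not 0. Coverage matrices
index cells as `matrix[y, x]`; the optional image rendering draws row 0 at
the bottom to match coordinate semantics and is outside the tested
contract.

## Synthetic data

The generator emulates what real reference sets and libraries provide:
scaffolds spanning a broad size/complexity/composition gradient, and
compounds that are decorated versions of known scaffolds.

* **Scaffolds** are chains of ring units drawn from a 31-unit grammar
  (aromatic carbo- and N/O/S-heterocycles, saturated 4–7-membered rings,
  carbonyl-bearing rings, 11 fused bicyclics), linked by alkyl linkers of
  length 0–4, with 1–5 rings per scaffold. The breadth is deliberate: a
  narrow unit pool produces many positional isomers that collapse onto the
  same SK vector, capping the achievable SK-distinct space size far below
  the tens-of-thousands regime real reference sets occupy. With this
  grammar, 20,000 draws yield ≈15.6k SK-distinct scaffolds.
* **Compounds** decorate a randomly chosen scaffold with 0–3 acyclic
  substituents from a small pool; the true parent is recorded per
  compound. Because substituents are acyclic, the compound's
  Bemis–Murcko scaffold equals its parent (pinned at ≥80%, measured 100%).
* **Not emulated:** the statistical composition of real drug/screening
  libraries, tautomer/charge diversity, salts beyond the largest-fragment
  step, stereochemical richness, very large macrocycles. Passing tests
  demonstrate the method's structural and algebraic properties, not
  performance claims about any particular real collection.

Seeds are explicit everywhere; no global random state is touched.

## Experiment harnesses and problem sizes

* **Anchor-window ("cherry-picked") set:** nine anchor ranks spread over a
  55,961-scaffold reference space, each with its 50 rank-neighbors per
  side; windows must not overlap, giving 9 × 101 = 909 tracked scaffolds.
  The constructor is rank-level, so it applies to any space size.
* **Convergence:** a 200-scaffold space with a 300-compound library; the
  mean displacement of normalized coordinates (x/N, y/N) between
  consecutive orders z and z+1 is computed for z = 2…8 and decreases
  monotonically (roughly halving per step, the curve's stabilization
  property).
* **Robustness:** the reference set is rebuilt from a random 90% subset
  that retains every tracked scaffold, and tracked scaffolds' normalized
  coordinates are compared at z = 8. Displacement shrinks like |S|^(−1/4)
  (rank-shift standard deviation ~√(0.09·r)/|S| along the curve, Hilbert
  locality √ in the plane), so this is a large-space property; the harness
  uses 20,000 generator draws (≈15.6k-scaffold space) with the nine-anchor
  window design, the largest configuration that keeps the experiment in
  tens of seconds on one CPU. The acceptance threshold (mean displacement
  < 0.05) is an artifact-defined constant for this synthetic regime.
* **Distance correlation sanity:** a 300-compound embedding at z = 8 must
  show all-pairs Pearson(d_r, d_C) > 0.4 — a deliberately loose floor for
  the synthetic regime; real-library values reported for this method are
  ~0.5–0.73.

## Numerical and degenerate-input choices

* Rounding: round-half-away-from-zero, one function, used only by the bin
  mechanism.
* Nearest-reference and KNN ties: deterministic (lowest rank; ascending
  compound id).
* Empty-fingerprint Tanimoto pairs: 0.0 with a warning.
* Embedding batches: skip-and-report per compound, never abort.
* Space files carry a header (format version, source, dedup policy, drop
  count, checksum) so an embedding is reproducible from the file alone;
  embedding files carry (z, N, |D|, l, |S|, space checksum).

## Known limitations

* The SK registry is one documented transcription of a descriptor family
  whose original prose is partly ambiguous; other transcriptions would
  order some scaffold pairs differently (the overall size-first
  progression is stable).
* The Bemis–Murcko variant is the toolkit's standard framework (keeps
  exocyclic double-bonded atoms); no tautomer or charge normalization is
  applied.
* Only 2D folding; no Peano or higher-dimensional curves.
* θ comparisons are restricted to identical space + order by design.
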