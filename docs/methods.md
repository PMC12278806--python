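# Methods

## Model

Activity (pKi, the regression target throughout) is modelled with
epsilon-insensitive support vector regression over similarity kernels on
circular fingerprints. Four kernel variants are implemented:

- **product kernel** (`product`): K = K_T(x⁽¹⁾)·K_T(x⁽²⁾) over the two
  reactant fingerprints — the screening workhorse, because it factorizes
  over components;
- **sum kernel** (`sum`): K_T(x⁽¹⁾) + K_T(x⁽²⁾), deliberately left
  unnormalized (range [0, 2]);
- **concatenated** (`concat`): Tanimoto of the 2·n_bits concatenation,
  component 1 occupying bits [0, n_bits);
- **baseline** (`single_tanimoto`): Tanimoto on the whole-product
  fingerprint.

All four are positive semidefinite (Tanimoto is PSD; products and sums of
PSD kernels are PSD; concatenation is Tanimoto on a wider vector), verified
numerically in the test suite on random 64-point Gram matrices.

Fingerprints are binary ECFP4 (radius 2) folded to 8192 bits. Reactant
fingerprints are computed on site-marked structures: reaction-center atoms
carry isotope 1000 and leaving-group atoms isotope 900, so the hash
invariants separate, say, the reacting NH₂ from a spectator amine. Product
fingerprints (baseline model) are unmarked — products carry no site marks
in this design. The empty-fingerprint convention tanimoto(∅,∅)=1,
tanimoto(∅,x)=0 preserves k(x,x)=1 and avoids 0/0.

## Training

Hyperparameters C and ε are selected by 5-fold cross-validated R² over the
grid C ∈ {0.1, 1, 10, 100, 1000}, ε ∈ {0.01, 0.05, 0.1, 0.5, 1.0} (a
declared default, overridable). The full training Gram matrix is computed
once and sliced per fold; fold assignment is shuffled once from `cv_seed`
and shared by every grid cell, so the search is deterministic. Ties are
broken toward smaller C, then smaller ε (simpler models); improvement must
exceed 1e-12 to displace an earlier cell. The solver is libsvm's
epsilon-SVR on the precomputed kernel; the refit dual solution
(support-vector fingerprints, αᵢ−αᵢ*, intercept) is stored and serialized
to JSON, sufficient for bit-exact reprediction. A degenerate fit with zero
support vectors (constant target inside the tube) predicts the bare
intercept.

## Fast exhaustive screening

With Tanimoto tables T₁ (nSV × n₁) and T₂ (nSV × n₂) precomputed, the
prediction for combination (c₁, c₂) is Σᵢ coefᵢ·T₁[i,c₁]·T₂[i,c₂] + b:
2·nSV multiplications, nSV−1 summation additions, one intercept addition.
An instrumented scalar scorer counts these operations explicitly; the
vectorized path enumerates the grid in column chunks (default 256), keeping
a bounded best-k buffer so memory is O(nSV·chunk + top_k). Exact ties are
ordered by ascending (idx1, idx2), which makes results identical for every
chunk size; this is asserted against a full enumeration-and-sort oracle.

The two-stage focused library ranks all combinations with the product
kernel (default top 10⁶), assembles those products by forward template
application, reranks with the product baseline model (default top 10⁴),
then applies the structural eligibility rules (elements C/N/O/F/P/S/Cl/Br/I,
MW ≤ 800, all SSSR ring sizes ≤ 7) and a template round-trip check:
dissecting the assembled product must regenerate the candidate pair. The
round-trip check is this package's synthesizability verdict; the CLI's
ranked-CSV output carries a `passed_filters` column so an external
retrosynthesis model's verdict can replace it downstream. The
applicability-domain pre-filter (drop candidates whose maximum component
kernel value against the support vectors is below a threshold, e.g. 0.2) is
off by default and flag-enabled.

## Templates and augmentation

Retro templates are reaction SMARTS mapping one product pattern to exactly
two reactant patterns; decompositions into more than two components are
rejected. On dissection, fragment atoms that carry a template atom map
become centers (1000); atoms with no source atom in the product — added by
the retro transform, e.g. the chloride of an alkyl chloride — become
leaving groups (900). Dissection pairs are deduplicated by the ordered
tuple of canonical SMILES including isotopes. Augmentation appends, per
product, every dissection pair not already present, tagged
`provenance=augmented` and sharing the product's measured activity; it
never removes or modifies records.

Candidate pools are filtered to molecules with **exactly one** reaction
center under the component query, counting symmetry-equivalent substructure
matches (same atom set, permuted order) once so a single symmetric site is
not rejected.

## Curation and splitting

Curation order: element whitelist per reactant → MW ≤ 800 per reactant →
SSSR ring sizes ≤ 7 → per-component heavy-atom fence
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] computed on the structural survivors → minimum
dataset size (100; configurable). Site isotopes are ignored when computing
MW (a 1000-label would otherwise dominate the mass). Pairwise dataset
overlap is |shared products| / |smaller dataset|; at ≥ 0.6 the smaller set
is dropped, iterating largest-first until stable.

Product-based splitting assigns unique products 6:4 at a seed, then moves
test records whose product reaches ECFP4 Tanimoto ≥ 0.8 **against any
training product** to `discarded` — the similarity reference is the
training set because the filter exists to enforce train/test separation.
Reactant-based splitting orders the component-1 axis by alternating
most/least frequency and the component-2 axis by descending frequency
(ties lexicographic), then exhaustively searches all cuts (a, b) minimizing
|a·b / (a·b + (n₁−a)(n₂−b)) − 0.6|, i.e. counting all grid cells ("area").
Counting only observed reactions is available via `count_mode="observed"`;
area is the default reading. Cut ties break by smaller |a/n₁ − b/n₂|, then
smaller a. Note that on a fully observed square grid the optimal area cut
is near (0.6·n, n−0.4·n)-style rectangles such as (5, 6) on 10×10 — exact
6:4 — not a near-diagonal corner cut.

## Thompson-sampling comparator

Each reactant of each component holds a Normal belief (running mean,
running sample SD floored at 1e-3 — the update rule is a declared choice).
Warmup scores every reactant against `n_warm` random counterparts (with
replacement if the counterpart pool is smaller) and counts toward the
budget; `n_warm` has no silent default in benchmark runs. Each cycle
samples one value per belief, takes the argmax per component, scores the
pair and updates the two selected beliefs; duplicate proposals are skipped
without consuming budget, with an attempt cap of 50·n_total to guarantee
termination. For head-to-head comparisons with exhaustive screening the
sampler is given the *same* score landscape as the ranking path (the
product-kernel model via precomputed tables), since a dominance gap is only
meaningful on a shared objective; the CLI's `thompson` command instead
scores assembled products with the baseline SVR, the configuration used
when the sampler is a standalone generator.

## Synthetic libraries

The generator emulates a curated single-reaction SAR dataset. Default
reaction: reductive-amination-style coupling, aldehyde (component 1) +
primary amine (component 2) → secondary amine; an acid-chloride amide
coupling variant exists (its products dissect uniquely, so a nonzero
ambiguous fraction there is rejected as infeasible). Building blocks are
head+body SMILES from a deterministic vocabulary (curated aromatic/
aliphatic bodies, then a systematic decorated-chain family); aldehydes and
linear amines draw bodies of opposite parity so two observed cells can
never assemble the same symmetric product. Activity is
y = μ + e₁(r₁) + e₂(r₂) + g(r₁,r₂) + ε with μ = 6.5 (pKi-like scale),
reactant effects e ~ N(0, 0.8), interaction g ~ N(0, 0.1) and noise
ε ~ N(0, 0.3) by default; defaults n₁ = n₂ = 40 at occupancy 0.5 give
≈800 reactions, the size regime of the curated real datasets. Observed
cells are drawn without replacement with Zipf(1.0)-skewed row/column
weights. The ambiguous fraction (default 0.2) is hit exactly by a
subset-sum choice of amine columns; `randomize_observed_dissection`
records a random dissection instead of the generating pair, emulating not
knowing which precursors were actually used. Pools append ~20% decoys
(zero or two reaction centers) that the candidate filter must remove, and
`plant_known_optimum` inserts one dominant building block per component.

What the generator does **not** emulate: realistic SAR landscapes
(activity cliffs, scaffold-dependent effects), ChEMBL-like property and
assay-noise distributions, or pool sizes beyond ~10³ per component.
Passing benchmarks on these libraries therefore demonstrates the
*mechanics* — kernel validity, fast-path exactness, split contracts, the
direction of the augmentation effect, sampling's miss risk — not
real-data accuracy levels.

## Benchmark problem sizes

The packaged benchmarks use 5 seeded libraries of ≈800 reactions for the
accuracy comparisons, a 200×200 candidate grid for fast-path exactness,
and a 300×300 grid (90,000 combinations) with a 10,000-pair budget for the
screening-vs-sampling duel — sizes chosen so the whole suite reruns in a
few minutes on one CPU while keeping every contract non-trivial (top-k
selection crosses many chunks; the sampling budget is ~11% of the grid).

## Numerical choices and edge cases

- Tanimoto matrices: popcounts and intersections via float32 matmul (exact
  for ≤ 8192 bits), division in float64; fast path and dual expansion agree
  to < 1e-9 by test.
- R² is reported NaN (with a warning) when the target is constant; CV folds
  with constant targets are skipped in the grid search.
- Wilcoxon comparisons discard zero differences; all-zero differences give
  p = 1.0; exact null for n ≤ 25, normal approximation above.
- Scaffold networks: Murcko scaffolds, top-20 by occurrence, edges at
  scaffold-ECFP4 Tanimoto strictly > 0.45, simple-graph density
  2E/(V(V−1)) (0 reported for V < 2); acyclic products counted separately
  and excluded from the network. The scaffold-fingerprint choice (rather
  than whole-molecule fingerprints) for edge similarity is a declared
  decision.
- SA score uses the published fragment-contribution scorer on its 1–10
  scale, via the chemistry toolkit's contributed implementation.

## Known limitations

Single-step, two-component reactions only. The reassembly check validates
template consistency, not reaction feasibility (no conditions,
regiochemistry beyond the single-center rule, or protecting groups).
Stereochemistry is retained as given but never enumerated. The screening
fast path is specific to the product kernel; sum/concat models predict
correctly but do not factorize.
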