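# Methods

## Model and procedure

`cladediv` treats a rooted gene tree with branch lengths (expected
substitutions per site) as the observable outcome of evolution after a gene
duplication. The duplication node separates two paralogous clades; within
each clade, every edge records divergence accumulated along one lineage
segment during the speciations that followed. The working hypothesis is
that if one duplicate kept the ancestral function under purifying selection
while the other diverged, the diverging clade's edges are systematically
longer. Taking each clade's multiset of within-clade edge lengths as a
sample (each edge counted once — an outlier lineage inflates one value, not
every pairwise distance it participates in) turns "do the clades diverge
differentially?" into a two-sample location problem.

The full pipeline, in fixed order, when a species pattern is supplied:

1. map each clade's leaves to species ids (first regex match in the label);
2. per clade and species, choose the representative leaf: minimal path
   length to the clade root, ties broken by lexicographically smallest
   label;
3. intersect the species sets; at least two common species are required;
4. prune each clade to the representatives of the common species;
5. collect within-clade branch lengths (stem edge excluded by default);
6. run the three tests (Student, Welch, Mann–Whitney U);
7. summarise the species sets of the *unpruned* clades (Venn counts and the
   superset relation);
8. assemble the report.

Without a pattern, steps 1–4 are skipped and all leaves enter the samples.
Steps 6 and 7 deliberately use different inputs: the test describes the
matched (pruned) comparison, the Venn describes what the clades actually
contain.

## Statistical choices

* **Two-sided alternatives everywhere.** Which copy diverged faster is
  unknown a priori; the null is symmetric. Sign convention is first sample
  minus second, so the less diverged first clade yields negative t.
* **Student's t** uses the pooled variance, df = n₁+n₂−2; **Welch's t**
  uses per-sample variances and Welch–Satterthwaite df; tail probabilities
  come from scipy's t distribution (regularized incomplete beta under the
  hood). Welch reduces exactly to Student when n₁ = n₂ and v₁ = v₂, which
  is asserted in tests.
* **Mann–Whitney U** reports U₁ (the first sample's statistic; under
  argument swap U₁ → n₁n₂ − U₁, p unchanged). For n₁+n₂ ≤ 16 and no ties,
  the two-sided p is exact: the null distribution of U is built with the
  classic count recurrence f(m,n,u) = f(m−1,n,u−n) + f(m,n−1,u), equivalent
  to enumerating all C(n₁+n₂, n₁) group assignments (at most 12,870), and p
  is the null probability of a U at least as far from n₁n₂/2 as observed
  (the null law is symmetric, so this equals the usual doubled tail).
  Tests cross-check this path against literal itertools enumeration. With
  ties or larger samples, midranks with the tie-corrected normal
  approximation and a 0.5 continuity correction are used; this path agrees
  with scipy's asymptotic implementation to machine precision.
* **Degenerate samples** (zero variance) error per test, not per panel: a
  constant-vs-constant comparison still gets a Mann–Whitney answer while
  the t slots carry the error.
* **No multiple-testing correction** across the three tests: they are
  alternative robustness levels of one comparison, reported side by side.
* **Display floor:** p-values below 1e-15 are reported as the raw float
  plus a `p_display` of `"< 1e-15"`, since printed digits at that magnitude
  are not meaningful.

## Tree handling

* Newick parsing/writing is backed by dendropy; underscores in unquoted
  labels are preserved literally, bracket comments are stripped, internal
  labels are names (never interpreted as support values). Duplicate leaf
  labels and missing branch lengths on non-root edges are hard errors — a
  divergence test on a tree without lengths is meaningless, so there is
  deliberately no zero-filling escape hatch. Negative lengths are accepted
  with a logged warning and enter the samples as-is; zero lengths are
  ordinary values. An unrooted (basal trifurcation) Newick is accepted with
  the basal node as root; the rooting must be biologically meaningful,
  which is the user's responsibility.
* **Representative distance is measured to the clade root**, not the tree
  root. Within a fixed clade the two readings order leaves identically
  (all clade leaves share the path above the clade root), and the
  clade-root reading is invariant to where the clade sits in the tree.
* **Pruning** removes unkept leaves, deletes emptied internals, and merges
  each unifurcation's two edges into one of summed length; if the clade
  root retains a single child the result is re-rooted at the kept leaves'
  MRCA. Defining contract (tested against a quadratic path-sum oracle on
  the unpruned tree): patristic distances between kept leaves are preserved
  exactly, no unifurcations remain, and pruning is idempotent.
* **Stem edge:** the edge into the clade root measures divergence of the
  duplicate itself before the speciations under comparison, so it is
  excluded from the samples by default; `include_stem=True` adds it. After
  pruning, the original clade's stem length is the value added — the
  pruning may have consumed stem-ward path segments, but the biological
  stem is unchanged.
* **Superset relation** requires a nonempty intersection: with no shared
  species, "superset" would be vacuous and carries no essentiality signal.

## Synthetic data

`simulate_duplicated_tree` emulates the designed use case: one random
species topology on k species (uniform random joins), instantiated twice
under a root that is the duplication node, every edge length drawn i.i.d.
and scaled by the clade's rate multiplier, leaf labels `gA_sp<i>` /
`gB_sp<i>` matching the default pattern `sp[0-9]+`. Defaults: k = 20
species, exponential base distribution with mean 0.1
substitutions/site — positive and right-skewed like real ML branch
lengths; a `fixed` mode gives deterministic unit-test trees. Optional
species dropout removes clade-B species (modelling loss of a dispensable
duplicate), making clade A a strict superset with known dropped ids.
Identical within-clade topology matches species pairwise across clades.

What the generator does **not** emulate: sequence-level evolution (no
alignments, indels, rate heterogeneity across sites), tree-inference error
(lengths are exact draws, not ML estimates), within-clade duplications or
isoforms, and non-clock rate variation beyond the single per-clade
multiplier. Passing calibration/power checks therefore demonstrates the
statistical machinery behaves correctly on branch-length samples with the
stated effect structure — not that any particular biological dataset will
carry such a clean signal.

`power_sweep` derives per-replicate seeds from the spec seed via
`numpy.random.SeedSequence`, simulates, runs the full species-aware
comparison, and reports per-test rejection fractions at α. With equal
rates this estimates the type-I error (measured ≈ 0.04–0.06 at k = 20,
500 replicates); at a rate ratio of 3 the Mann–Whitney power exceeds 0.95
at 200 replicates and the mean Student t is negative, confirming the sign
convention. Problem sizes in the acceptance script (100 enumeration pairs,
200 random trees up to 64 leaves with 30 spot-checked leaf pairs each,
500/200 simulation replicates) keep the whole recomputation in the
seconds range while leaving Monte-Carlo error well inside the asserted
bands.

## Known limitations

* The user must identify the duplication node; no automated scan over all
  duplication nodes is attempted.
* Branch lengths are taken at face value; uncertainty from tree inference
  (and support values) is ignored.
* Designated clades must be disjoint; non-sister disjoint clades are
  allowed with a warning only.
* The exact Mann–Whitney path is tie-free by construction; tied small
  samples fall back to the normal approximation, which is conservative at
  those sizes.
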