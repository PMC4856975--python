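# Methods

This note documents the models, algorithms and numerical conventions behind
bundlekit, the defaults chosen where the design was genuinely open, and what
the synthetic fixtures do and do not demonstrate.

## Alignment model and alphabets

An MSA is a rectangular matrix of single-character symbols over an explicit
alphabet plus a gap symbol (`-`). Invariants (equal row lengths, unique
labels, alphabet membership) are enforced at construction so downstream code
never revalidates. All public indices are 1-based, matching how sites are
referred to in the sequence-analysis literature ("position 241"); internal
storage is 0-based. Parsing upper-cases symbols and normalizes the Stockholm
gap character `.` to `-`. Ambiguity codes (N, X) are deliberately rejected
rather than silently mapped: a custom `Alphabet` is the escape hatch for
data that genuinely contains them.

The protein alphabet carries three orderings for the bundle y-axis:
alphabetical, Kyte–Doolittle hydropathy (descending; ties at equal hydropathy
broken alphabetically, so D/E/N/Q at −3.5 appear in that order), and a
chemical-class grouping (hydrophobic, aromatic, polar, positive, negative;
histidine is placed with the positives). Orderings are validated
permutations, so a bundle can never drop or duplicate a symbol row.

## Selection queries

The grammar is a minimal realization of "boolean combinations of regular
expressions over labels and sequences": `AND` binds tighter than `OR`, `NOT`
is prefix, parentheses group, and the atoms are `label ~ /re/`,
`seq ~ /re/` and `site(i) = X`. Regexes are unanchored searches (users
anchor with `^…$` themselves) and see the *aligned* row including gaps; a
`degap:` prefix matches against the gap-stripped row instead. The
residue-at-position atom exists because selecting by residue at a site is
the fundamental covariation-exploration gesture. Queries select sequences;
site selection is a separate direct API (`Selection.site_indices`).

## Profile HMM and Fisher scores

With pre-aligned input the HMM state path is known, so only match-state
emissions carry per-sequence information; transition and insert parameters
are constant across sequences and are omitted. Match columns are those with
gap fraction ≤ 0.5 (HMMER-style heuristic; the threshold is a parameter).
Emissions use a symmetric Laplace pseudocount, default α = 1:
`e_k(b) = (n_k(b) + α) / (n_k + α|A|)`.

The embedding is the gradient of the emission log-likelihood
`ℓ(x) = Σ_k log e_k(x_k)` (gap columns contribute nothing) with respect to
the **softmax parameters** of each categorical emission:
`u_{k,b}(x) = 1[x_k = b] − e_k(b)·1[x_k ≠ gap]`. The softmax
parameterization is chosen over the raw-probability gradient because it is
bounded as e → 0 and yields the clean indicator-minus-probability form;
scores at a non-gap column sum to zero over the alphabet, and an all-gap
sequence embeds to the zero vector. The scores are exported unwhitened; an
optional length normalization is available but not default, since no
whitening convention is canonical here. A finite-difference gradient check
(central differences under the same parameterization, tolerance 1e-6) is
part of the test suite.

## Correspondence analysis

CA runs on the 0/1 indicator coding of the MSA — one category per
(column, observed symbol), gap included as a category by default — rather
than on the Fisher scores, which contain negatives and are unsuited to the
chi-square metric; the joint plot's column points are then exactly the
"residue-site" categories a user wants to see. Constant columns carry zero
inertia and break the chi-square scaling, so they are dropped with a log
notice; an entirely constant alignment is an error.

The decomposition is standard: `P = N / n··`, standardized residuals
`S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}`, thin SVD, principal coordinates
`F = D_r^{−1/2}UΣ` and `G = D_c^{−1/2}VΣ`. Numerical conventions: singular
values below 1e-12 are treated as rank deficiency and dropped; each axis is
oriented so its largest-|value| row coordinate is positive (deterministic
sign); requested axes beyond the rank are truncated with a notice. The full
positive spectrum is retained on the result so that
`total_inertia = Σσ² = χ²/n··` holds exactly regardless of truncation.
`nearest_categories` ranks category points by Euclidean distance to the
unweighted centroid of the selected sequence points, ties broken by
(column, symbol); with gap categories included all row masses are equal, so
selecting every sequence puts the centroid at the origin.

## Per-site classification

`detect_sites` trains one linear-kernel SVM (C = 1 default) per column on
one-hot symbol features (alphabet + gap, fixed dimension) over the grouped
sequences only, and scores the column by exact leave-one-out
cross-validation. Because a sequence's features at a column are a function
of its symbol alone, LOOCV folds are equivalent whenever the left-out
sequence shares (symbol, group); folds are computed once per equivalence
class and weighted by its size, which makes the procedure exact and
O(|symbols|·|groups|) fits per column instead of O(n). More than two groups
use one-vs-rest with argmax of decision values, ties resolving to group
declaration order. One-hot features were chosen over Fisher scores for
determinism and because per-site Fisher scores are an affine function of the
same indicators.

The baseline is the LOOCV error of majority-class voting. Note the standard
leave-one-out artifact: with exactly balanced groups the baseline is 1.0
(removing one member always tips the majority the other way). Marker opacity
is the baseline-relative improvement `clamp((base − err)/base, 0, 1)` — 1
for a perfectly explanatory site, 0 for one no better than the baseline; the
mapping is a monotone convention, not a calibrated probability.

## Binomial covariation test

Conditioning on a selection (e.g. carriers of Glu-146), the count of the
target symbol at the target column is compared against its frequency in a
null population — all sequences by default, or the complement of the
selection (both are offered because either null is defensible; all-sequences
is the more conservative default). Tails are exact binomial sums; the
two-sided p-value defaults to the minlike convention (sum of outcome
probabilities ≤ the observed point probability, with the usual 1 + 1e-7
relative tolerance), with a central (doubled smaller tail) alternative. A
degenerate null (frequency 0 or 1 contradicted by the observation) is
flagged but still returns defined p-values.

## Kernel, distances, trees, clustering

The sequence kernel is the mean column-wise substitution score
`s(x,y) = (1/L) Σ_i σ(x_i, y_i)` with σ from BLOSUM62 (any Biopython
substitution matrix by name) for proteins and an identity match/mismatch
matrix for nucleotide alphabets. Gap columns score explicitly —
gap-vs-residue −4, gap-vs-gap 0 by default — because indel structure carries
evolutionary signal and must affect distances rather than be skipped; both
scores are flags. The induced distance is the kernel square-norm form
`d(x,y) = max(0, s(x,x) + s(y,y) − 2s(x,y))`; negative values (possible for
non-PSD score matrices) are clamped to zero and logged, and
triangle-inequality violations are counted, not forbidden.

Neighbour joining is the canonical Saitou–Nei algorithm:
`Q(i,j) = (n−2)d(i,j) − R_i − R_j`, standard limb-length and reduction
formulas, a trifurcating root for n ≥ 3 and a single split edge for n = 2.
Determinism is part of the contract: Q ties (within 1e-12) break by the
lexicographically smallest label pair, an internal node inheriting the
smallest leaf label beneath it; negative limb estimates are clamped to zero
with a log notice. On additive matrices the algorithm provably recovers the
generating topology; the tests verify Robinson–Foulds distance 0 and
path-length agreement to 1e-9 against randomly generated trees.

The Newick parser is a small recursive-descent routine that reports the
failing character position, tolerates unlabeled internal nodes and a
trifurcating root, and round-trips branch lengths through `%.12g`
formatting (identity to 1e-9).

Spectral clustering follows the normalized-cut recipe exactly: Gaussian
affinity `exp(−d²/2σ²)` with zero diagonal, σ defaulting to the median
off-diagonal distance; normalized Laplacian `I − D^{−1/2}AD^{−1/2}`; rows of
the k bottom eigenvectors normalized to unit length; k-means with 10
restarts and a caller-supplied seed. Output groups are named
`cluster1..k` in order of first appearance, so equal seeds give identical
assignments, not merely identical partitions.

Motif-vs-clade status is decided on the **unrooted** tree: carriers of a
motif (sequences matching every (column, symbol) pair) form a synapomorphy
iff they are one side of some edge bipartition; otherwise the motif is a
homoplasy (absent and universal carrier sets are special-cased). Rooted
monophyly would depend on root placement, which is a display choice. The
smallest rooted clade containing all carriers is returned for navigation.

## Bundle rendering

Layout: symbol rows in the chosen ordering top-to-bottom, a gutter, then the
gap row (default on; with it off, gap positions are skipped and the thread
interpolates across the column). Threads sharing a cell are stacked into
lanes — lane = rank among co-occupants by row index, modulo `max_lanes`
(32) — evenly spaced inside a central band of 0.6 × cell height, so
identical sequences remain individually visible and ink density is bounded.
The stacking discipline and the band fraction are this package's own
conventions; only the existence of stacking is inherent to the method.

Each inter-column segment is a cubic Bezier with control points at
horizontal offsets ±c·cell_width from its endpoints; the single curvature
knob c ∈ [0, 0.5] (default 0.35) degenerates to straight polylines at 0.
Default thread opacity auto-scales as `min(1, max(0.02, 8/n_seq))` so large
bundles stay readable. SVG output is deterministic text with a stable float
format; thread paths carry `class="thread"` and a `data-label` attribute,
markers `class="site-marker"` with fill-opacity equal to the per-column
value — these ids are public contract, and byte-identical output for
identical inputs is asserted in tests. PNG output rasterizes the same
geometry with Pillow (Beziers sampled at 24 points per segment, per-thread
alpha compositing) at dpi/96 scaling, so doubling dpi doubles both pixel
dimensions; it is likewise byte-deterministic.

## Synthetic data

`make_fig1a`/`make_fig1b` are the two 1000 × 5 nucleotide alignments (500
copies each of AAAAA/TTTTT and AATTT/TTAAA) whose per-column compositions
are identical while their motifs differ — the defining case for
non-aggregative visualization, and the fixture behind most end-to-end
checks. `make_planted_msa` builds grouped protein-like alignments with
uniform i.i.d. background, planted per-group symbols at chosen columns, and
covariant pairs written jointly into a seeded random half of rows; it
returns the ground truth for recovery tests. A single integer seed drives
everything through `numpy.random.default_rng`; no global state.

These fixtures emulate the *structure* of real subfamily alignments
(discriminative sites, covariation, group-coloured bundles) at desk scale —
tens of sequences for supervised analyses, a thousand for the figure
fixtures — with idealized noise: background columns are i.i.d. uniform and
groups are internally homogeneous at planted sites. Passing tests therefore
demonstrate correctness of the algorithms and determinism of the pipeline,
not robustness to phylogenetic autocorrelation, alignment error, or
compositional bias in real protein families. Real-data effect sizes (which
sites a family's grouping actually hinges on) are outside what synthetic
fixtures can certify.

## Problem sizes and limitations

Test and acceptance runs use desk-scale problems: 50 random alignments for
the gradient check, 100 random 6–10-leaf trees for NJ recovery, 200 random
(tree, motif) cases for clade annotation, 20 planted alignments for site
recovery. Neighbour joining is the O(n³) canonical algorithm and is
comfortable to a few hundred leaves; the per-site LOOCV shortcut keeps
detect_sites linear in alignment length with small constants. Known
limitations: no multiple-testing correction across sites (single-site LOOCV
errors and one binomial p at a time are reported raw); no unaligned-sequence
support or alignment computation; no Dirichlet-mixture priors or transition
scores in the HMM; CA uses plain indicator (MCA) coding without
evolutionary weighting of categories.
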