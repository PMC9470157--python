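# Methods

This note documents the model behind `lcrtools`, the defaults and why they
are what they are, the synthetic data the tests rely on, and the numerical
choices that were genuinely open.

## The dotplot model of low complexity

A protein's self-comparison dotplot `D[i,j] = [s[i] == s[j]]` turns
compositional bias into geometry: a segment that reuses few residues
produces a dense square block on the diagonal, and two compositionally
similar segments in one protein produce a dense off-diagonal block at their
coordinate intersection. Low complexity detection then becomes image
segmentation, and — the distinctive part of this approach — the *type*
structure of a protein's LCRs is read off the off-diagonal blocks for free.

Matching is exact character equality. Non-standard letters (X, U, O, B, Z)
are retained in sequences and match themselves; a trailing `*` is stripped
at parse time. No substitution matrix is used: the signal of interest is
literal reuse of residues, not homology.

### Convolution

`D` is convolved with a uniform k×k kernel (k = 10 by default), so each
pixel's intensity is the integer count of identities in its window,
0..k². The kernel sets the minimum length scale of a callable LCR. For the
even default kernel the window at pixel (i, j) spans offsets −4..+5 on both
axes; this anchor is forced by the boundary correction below — called
regions are widened by exactly −4/+5, which recovers the original sequence
extent only under this anchoring. Outside-matrix cells contribute zero
(zero padding), applied identically to real and null proteomes so the FDR
comparison is fair.

Window sums are computed with an exact integer summed-area table. Proteins
longer than `max_full_matrix` (default 15,000 aa) are processed in row
blocks with a halo, which is algebraically identical to the full-matrix
path (tested), so titin-scale proteins never require two O(N²) integer
matrices at once.

### The null proteome and the FDR threshold

For each proteome a single *null proteome* is simulated: one sequence per
real protein, same length, residues i.i.d. uniform over the 20 standard
amino acids. Uniformity makes the verdict on a given sequence independent
of the host proteome's composition; length matching controls for
species-specific protein-length distributions. Convolved intensities are
pooled over all pixels of all proteins — full matrices, diagonal and both
symmetric halves included (symmetric duplication inflates real and null
counts alike and cancels in the ratio). Intensities are integers, so the
histograms are exact and no binning decisions arise.

The threshold is the smallest intensity t ≥ 1 with

    FDR(t) = null≥t / (real≥t + null≥t) ≤ α,   α = 0.002 by default,

restricted to thresholds that at least one pixel actually passes: a
threshold passed by nothing has FDR 0 only vacuously and segments nothing,
so it is never selected. If no threshold qualifies (e.g. the real proteome
is statistically indistinguishable from the null) the error carries the
full FDR curve for inspection. One null per run is the default; a
`null_replicates` option averages the null histogram over several seeds for
stability studies.

### Calling and typing

Above-threshold pixels are labelled into connected components with
8-connectivity (repeat signatures run diagonally; 4-connectivity would
fracture them; configurable). A component containing at least one diagonal
pixel yields an LCR whose raw extent is the min..max of its *diagonal*
indices — an off-diagonal lobe of the same component never stretches the
call. The extent is widened by −4/+5 (clamped to the protein ends), and
widened intervals that overlap or abut are merged into one call, keeping
per-protein calls non-overlapping.

Two LCRs of a protein are connected iff the off-diagonal rectangle
rows(a)×cols(b) — using the widened, i.e. reported, coordinates — contains
any segmented pixel. Types are the connected components of this graph
(transitively closed), numbered 1..C by their most N-terminal member; the
copy number of every LCR is its component's size. Protein groups follow
from total vs distinct counts: one LCR → `single`; several copies of one
type → `multiple-same`; all types singletons → `multiple-distinct`;
otherwise `multiple-mixed`.

### Entropy validation

Shannon entropy (base 2, configurable; comparisons are base-invariant) of
each called LCR is compared with one random length-matched substring of the
concatenated proteome (concatenation in file order; a draw may span a
protein boundary, exactly as the sampling procedure defines it — a flag
redraws boundary-spanning samples). The two entropy samples are compared
with a one-sided Mann–Whitney U test (LCR entropies lower); the choice of
test is this package's, as only "significantly lower" is specified
upstream. A companion property holds on synthetic data: raising the
segmentation threshold lowers the mean entropy of surviving calls
(Spearman ρ < 0 across thresholds).

## Composition maps

Each LCR is a 20-vector of amino-acid frequencies; non-standard letters are
excluded from the denominator, and an LCR with no standard residues is
dropped with a warning. Clustering is Leiden (leidenalg via scanpy,
`random_state` = 73 by default, resolution = library default 1.0) on the
k-NN graph built in the 20-D composition space; the 2-D UMAP projection is
for display only, so clusters never inherit projection artifacts. Cluster
names are a reproducible proxy for manual annotation: all residues whose
cluster-mean frequency is ≥ 0.5 × the cluster's top mean frequency, joined
by "/" in descending order; the 0.5 fraction is configurable and recorded
in the map parameters.

Residue-enrichment of an annotated LCR set uses, per residue, a Wilcoxon
rank-sum test with tie-corrected normal approximation; the signed
standardized statistic z is reported (positive = enriched in the annotated
set), p-values are two-sided, and Benjamini–Hochberg correction runs across
the 20 residues with α = 0.001. In head-to-head comparisons of two
annotation sets the second set is the reference and rows in both sets are
excluded (the test assumes independent groups). Quartile selections ("top
25 % by E frequency") use the q-quantile with 'higher' interpolation and
≥ selection, so the cutoff is always an observed value and the selected
set is the ceil-sized top fraction, ties included.

### Reproducibility of the embedding

Two non-obvious numerical choices make seeded runs byte-identical across
processes, which the pipeline promises:

- UMAP is initialized with seeded random coordinates rather than the
  spectral default. The spectral initialization solves an ARPACK
  eigenproblem whose internal starting vector varies between processes, so
  two runs of the same program could produce different (equally valid)
  layouts — unacceptable for a pipeline whose outputs must be diffable.
- The stochastic-gradient layout is pinned to one numba thread while it
  runs (restored afterwards); parallel layout interleaves updates
  nondeterministically.

Beyond that, embedding determinism is promised only per library version;
the map parameters record the scanpy version.

## Synthetic data: what it does and does not emulate

`make_planted_proteome` draws background residues i.i.d. from a
configurable distribution (uniform over the 20 standard residues by
default, which makes the simulated null exactly matched — the happy path)
and plants low-entropy blocks of one or two residue letters (entropy ≤ 1
bit) at known coordinates, with ≥ 10 background residues between blocks
and from protein ends. Planting two identical-composition blocks in one
protein creates a ground-truth same-type pair. A biased background option
exists to stress the uniform-null assumption.

Default study conditions used by the deep tests and the acceptance script:
200 proteins of 250–350 aa, homopolymer blocks of 15–30 aa drawn from nine
common LCR-forming residues, every fourth protein carrying an 18+18 same-
type pair; thresholds always derived from the proteome's own simulated
null at FDR 0.002. These sizes keep the full suite under a minute while
giving a few hundred planted blocks per run.

What passing these tests does *not* show about real proteomes: real
backgrounds are compositionally biased and autocorrelated, real LCRs have
soft edges and imperfect repeats, and real proteomes mix length scales
(including 30 k-residue giants) — so recovery rates measured here are an
upper bound on real-data behaviour, and the uniform-null threshold on real
data is calibrated against a deliberately composition-agnostic reference,
not against the host proteome's own biases.

The brute-force oracles (`brute_force_intensities`,
`brute_force_lcr_oracle`) recompute dotplots, window counts, flood-fill
segmentation, diagonal extraction, −4/+5 expansion, merging and
intersection edges with naive loops, sharing no code with the production
path; the test suite asserts exact equality of masks, intervals and edges
on dozens of random proteins per run.

## Degenerate inputs and tie-breaks

- Single-residue protein: a 1×1 dotplot with intensity 1; callable only at
  threshold 1.
- Kernel larger than the matrix: windows clamp; intensities are simply the
  number of dots present.
- Expanded intervals that collide are merged (the −4/+5 widening can make
  adjacent components touch); the merge is associative, so call sets are
  order-independent.
- All-identical composition rows: one Leiden cluster; rank-sum tests on
  fully tied data return z = 0, p = 1 rather than dividing by a zero
  variance.
- Length-matched sampling with L equal to the total proteome length
  returns the whole concatenation (the start-position range is clamped to
  keep at least one valid start).

## Known limitations

- Types are within-protein only; there is no cross-protein LCR typing.
- The null model is uniform-composition only, by design; a
  composition-matched null would change which marginal compositions count
  as "low complexity".
- Disorder/binding predictors are not re-implemented; external per-position
  scores are attached via `mean_score_per_lcr` from a generic TSV.
- Leiden cluster counts on real proteome-scale maps depend on the
  (unspecified upstream) resolution; the library default is used and
  recorded in the output metadata.
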