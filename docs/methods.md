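# Methods

## Network inference

The interactome stage treats a bulk expression profile as a genes ×
populations matrix of FPKM and a ligand-receptor catalogue as a set of
ordered gene-symbol pairs. Inference is deterministic and purely
threshold-based — no statistical null is computed, because the underlying
procedure defines an interaction as co-detection of a catalogued ligand and
receptor, not as a significance call.

Two thresholds govern detection, both in FPKM:

* `min_mean` (default **10**): a gene is analysable when its arithmetic
  mean across all populations is *strictly greater* than this value. The
  strict inequality is deliberate — "greater than 10" — and tested at the
  boundary.
* `per_type_min` (default **10**): a gene is expressed in a population when
  its FPKM there is `≥ per_type_min`. The underlying procedure states only
  the mean filter; reusing its constant for the per-type call is the least
  arbitrary choice, and the value is configurable and echoed into all
  output metadata.

Every ordered (sender, receiver) combination over `T` populations — `T²`
combinations, autocrine included — is evaluated per catalogue pair.
Catalogue genes absent from the profile are skipped silently with a summary
count in the log: a catalogue/assay symbol mismatch is expected, not an
error. Gene matching is case-sensitive by default with an opt-in
case-insensitive mode (mouse vs. human symbol casing differs across
catalogues).

Because the total-interaction accounting of such networks is ambiguous
(distinct gene pairs vs. distinct directed tuples), both numbers are always
emitted: `unique_pair_count` (gene pairs with ≥ 1 edge) and the directed
edge count.

**Edge strength** for ranking is the geometric mean of ligand FPKM in the
sender and receptor FPKM in the receiver: symmetric, zero when either side
is absent, and scale-respecting. `min`, `sum` and `product` are offered as
alternatives since "absolute expression level" of a pair admits any of
them. **Ligand specificity** for the top-N ranking is operationalised as:
the ligand's maximum enrichment across populations is ≥ `specificity_min`
(default 2.0, i.e. twice its cross-population mean) *and* that maximum is
attained in the edge's sender. All orderings break ties totally and
lexicographically on (ligand, receptor, sender, receiver), so outputs are
bit-reproducible.

**Enrichment** of gene `g` in population `t` is `x(g,t)` divided by the
gene's mean across populations. Genes with zero mean are dropped with a
warning (0/0 is undefined, and an undetected gene has no enrichment); for
all retained genes the scores average to exactly 1, which the suite asserts
to 1e-9.

## Gate-purity quantification

Cells are retained when their total transcript count is *strictly* above
`min_transcripts` (default **1,500**) — again a deliberate strict
inequality, boundary-tested. Genes-per-cell statistics (number of genes
with count > 0, with mean ± SEM) are computed after this filter; computing
them before it would only add cells that are by definition poorly sampled.

Clustering is a **contract**, not a fixed algorithm: anything that maps a
filtered matrix to a full cell → cluster assignment works, because purity
is agnostic to the clusterer. The default clusterer depth-normalises each
cell to the median total count, log1p-transforms, restricts to the 500 most
variable genes and runs k-means with a fixed seed (`k="auto"` scans 2–10 by
silhouette). This is intentionally simpler than specialised rare-cell-type
clusterers: the populations being validated are few and well separated,
which is exactly the regime where k-means on normalised log counts is
adequate — and the suite demonstrates adjusted-Rand ≥ 0.95 against planted
identities across seeds under negative-binomial noise.

Cluster identity comes from marker panels, not from gate majority vote:
each cluster is assigned the type whose panel has the highest mean
depth-normalised expression over the cluster's cells, with a lexicographic
tie-break flagged as low confidence. Gate labels enter only afterwards:
`purity(gate)` is the percentage of the gate's retained cells whose cluster
identity equals the type the gate was designed to capture (supplied as a
gate → type map; identity mapping by default). A gate with zero retained
cells is reported as missing, never as 0% or 100%. Per-cluster enriched
genes use the same expression-relative-to-mean score as the bulk stage,
computed over cluster means.

## Synthetic data

The generators define the validation conditions; they are first-class,
tested code.

**Bulk** (`generate_bulk`): four populations by default (neural, mural,
endothelial, microglia). Planted marker genes and ligand/receptor genes are
high (`high_fold` × the 10-FPKM call threshold, default 5× = 50 FPKM) in
their designated population(s) and low (`low_fold` ×, default 0.1× = 1
FPKM) elsewhere; each planted pair draws one sender and one receiver
uniformly, autocrine allowed. Background genes get a single
lognormal(log 20, 1.0) level shared across populations — near-uniform
profiles that exercise the mean filter without generating edges. Noise is
multiplicative lognormal per entry (FPKM are positive and right-skewed;
additive Gaussian would produce negatives), default sd 0.3 on the log
scale. With `noise_sd=0` the expressed/silent pattern is exact and the
default pipeline returns precisely the planted edge set.

**Single cell** (`generate_single_cell`): one gate per population; a cell's
true identity equals its gate with probability `1 − contamination[gate]`,
else a uniformly drawn other type. Counts are negative-binomial
(gamma-Poisson with one common dispersion, default 2.0 — the simplest
overdispersed model the clusterer must tolerate) around type-specific mean
profiles in which a type's own markers carry most of the weight; per-cell
depth is lognormal (default mean 3,000 transcripts, log-sd 0.35) so a
realistic minority of cells falls below the 1,500-transcript filter. Both
generators share one gene-naming scheme so marker panels transfer between
bulk and single-cell data. Defaults for the recovery experiments — 200
cells per gate, 5% contamination, five seeds — are fixed validation
conditions, not tuning knobs.

`thin_profile` emulates shallow single-cell detection on a bulk profile:
each entry survives with probability `x / (x + midpoint)` (saturating
detection; default midpoint 50 FPKM) and is zeroed otherwise. The suite
asserts the qualitative consequence — thinning strictly reduces the edge
count — not any particular fold, which is data-dependent.

What the simulations do **not** emulate: read-level library artefacts, UMI
collisions, doublets, batch effects, ambient contamination, or continuous/
intermediate cell states. Passing recovery tests therefore show the
pipeline's logic is correct under its stated model, not that any particular
real dataset meets that model.

## Recovery-protocol note

The noisy planted-edge recovery experiment (lognormal sd 0.3, 5×
separation) applies the per-type expression call with the cross-type mean
pre-filter disabled (`min_mean=0`). The reason is analytic: a gene high in
one of four populations at 5× the call threshold has a noiseless cross-type
mean of only 13.25 FPKM, so the 10-FPKM mean filter removes ≈16% of planted
genes under sd-0.3 noise regardless of how well detection works. The 5×
separation is defined against the *call* threshold, and that is the
property the experiment measures; the mean filter's strict-boundary
semantics and monotonicity are verified separately. The noiseless recovery
test runs the full default pipeline, both filters on.

## Numerical and degenerate-input choices

* Validation rejects rather than coerces: negative or non-finite FPKM,
  fractional or negative counts, duplicate gene/cell identifiers, and
  unlabelled cells are errors (unlabelled cells may be dropped by explicit
  opt-in). Duplicate gene symbols in expression tables error under the
  default strict policy; the opt-in `collapse` policy averages rows, which
  also serves to average replicate tables.
* All tabular IO is TSV (UTF-8, header row, decimal point); sparse counts
  are MatrixMarket triplets with sidecar name lists; write→read is identity
  on every container, property-tested.
* Filters use strict or non-strict comparison exactly as documented above;
  `per_type_min=0` calls every non-negative entry, zeros included.
* Empty results (all genes filtered, all cells removed, empty subnetwork)
  are warnings with valid empty outputs, except where an empty *input* is
  itself malformed (empty LR catalogue, empty table).
* Problem sizes in the test-suite simulations (≤ 2,000 genes, ≤ 200
  catalogue pairs, ≤ 800 cells, ≤ 10 seeds per experiment) were chosen as
  the smallest sizes at which binomial/sampling error is comfortably inside
  the asserted tolerances.

## Known limitations

* No statistical significance of interactions (no permutation null); the
  method is detection-based by design.
* Purity estimation inherits any clusterer failure: if two true types merge
  into one cluster, the marker-panel assignment flags ambiguity but purity
  for the affected gates is not meaningful.
* The explorer JSON export covers the data contract (nodes, enrichment
  vectors, edges, thresholds) only; no front-end ships with the package.
* Gene-symbol handling is string-exact (optionally case-folded); no
  ortholog or alias mapping.
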