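# Methods

## The inference problem

A fluid compartment shared by several cell types contains proteins secreted
by all of them.  Given (i) the fluid's proteome, (ii) transcriptomes of the
individual cell types, (iii) a genome-wide secretion-confidence catalogue
and (iv) membrane-localisation annotation, the workflow attributes fluid
proteins to their cell of origin and proposes which membrane proteins of
the *other* cell type they may act on.  All reasoning happens in a single
reference-species gene space; the cross-species step is a pure identifier
translation, not a sequence analysis.

## Identifier mapping

The chain protein → species gene → homology group → reference gene is a
composition of three partial many-to-one maps.  Identifiers are opaque,
case-sensitive strings; no syntax validation is applied, so real UniProt /
Entrez dialects and synthetic ids pass through identically.  Where two
homology resources are available the caller supplies one pre-merged
gene→group table; the module does not arbitrate between sources.
Many-to-one collapse is the desired behaviour (redundant accessions and
orthologous entries landing on one gene), and provenance (which source
proteins support each gene) is retained to the network stage.  Inputs that
fail any link are reported, never silently dropped: for every call,
`provenance ∪ unmapped` is a partition of the input.

## Transcriptome selection

**BEC.** The background expression cutoff is the median of *all* matrix
entries (probe sets × samples pooled).  An even count takes the mean of the
two central values — stated because the cutoff feeds a hard threshold.

**Intensity rule.** A probe set must reach `bec_multiplier × BEC`
(default 2×) in at least one target-cell sample.  The single stricter 2×
rule is used rather than a two-pass BEC-then-2×BEC sieve, since the second
pass subsumes the first.

**Effect rule.** Fold change is the linear-scale ratio of group means,
`2^(mean_t − mean_r) ≥ fold_change_min` (default 2, i.e. one log2 unit).

**Significance rule.** A two-group moderated F with empirical-Bayes
variance shrinkage: per probe set the pooled residual variance s² (d
residual df) is shrunk toward a prior s₀² with weight d₀,
s̃² = (d₀s₀² + ds²)/(d₀+d), and F = (m̄_t − m̄_r)²/(s̃²(1/n_t + 1/n_r)) is
referred to F(1, d + d₀).  The hyperparameters (d₀, s₀²) are fitted by
method of moments on log s², whose mean and variance under a scaled-F
model are digamma/trigamma functions of the degrees of freedom; the
trigamma inverse is solved by Newton iteration.  If the spread of log s²
does not exceed chi-square sampling noise, d₀ = ∞ (every probe set tested
against the common variance, F referred to χ²₁).  d₀ = 0 reduces exactly
to the classical pooled-variance two-group test, which the test suite
verifies to 1e−10.  The two germ-cell populations are pooled as one target
group against Sertoli samples (and mirrored), but the API accepts
arbitrary target/reference label sets, so joint or pairwise contrasts are
both expressible.

**FDR.** Benjamini–Hochberg step-up, implemented directly (vectorised
cumulative minimum over the descending sort) and cross-checked in tests
against a quadratic brute force and against statsmodels.

**Gene level.** A gene enters a transcriptome if *any* of its probe sets
passes; genes selected in both cell classes (opposite patterns) are
discarded from both, making the final transcriptomes disjoint by
construction.  Probe sets without a gene link stay in the statistics table
but contribute no genes.

## Annotation

Secretion ranks run 0 (known secreted) to 3 (weak single-predictor call);
the reference secretome keeps ranks ≤ 2.  Genes absent from the rank table
are treated as non-secreted, not as errors, because secretion catalogues
cover only part of the genome.  The membranome is an OR over direct
GO:0005886 / GO:0009986 annotations in a flat gene2go-layout table — no
ontology-graph propagation, and evidence codes / qualifiers are ignored
(logged at debug level).

## Enrichment

The question "is the fluid overlap of this transcriptome enriched for
secreted genes?" is answered with the one-sided upper-tail hypergeometric
probability P(X ≥ k) for k secreted among n fluid-overlap genes drawn from
a transcriptome of N genes with K secreted.  The tail is summed in log
space (`logsumexp` over log-pmf terms) for stability at extreme p.  The
parameterisation is by counts, so the test is reusable for any set pair,
and the population-success count K is always computed from data, never
assumed.  A permutation estimator (n of N labels drawn without replacement
per replicate) provides an independent route that the acceptance suite
requires to agree within three binomial standard errors.  No
multiple-testing correction is applied across enrichment calls — only two
are made per run.

## Crosstalk network

Interaction records are undirected; pairs are normalised lexicographically
and provenance identifiers unioned per pair, so duplicates across source
databases collapse while their evidence accumulates.  An edge enters the
crosstalk network iff its pair is catalogued and one endpoint is in one
cell's secretome while the other is in the *other* cell's membranome; the
semantic direction secreted→membrane is recovered from node classes at
export.  Disjointness of the transcriptomes (enforced upstream) makes
same-cell and self edges impossible.  A gene may serve both as its cell's
secreted factor and as that cell's membrane protein; rather than silently
dropping the second role, such genes become two role-specific nodes
exported with `|sec` / `|mem` suffixes.  Exports: GraphML (node attributes
`gene`, `class`; edge attribute `provenance`), SIF and a TSV edge list;
the GraphML round-trip is lossless and tested.

## PLA statistics

Raw per-field counts (signals per 0.25 mm²) are analysed untransformed;
the assay-vs-control comparison is the classical pooled-variance two-sample
Student's t (two-sided), the textbook default when no variance qualifier is
given.  A zero-pooled-variance tie returns (t = 0, p = 1).

## Synthetic worlds

The generator plants cell-type-specific genes (400 GC, 300 SC and 10
deliberate conflict genes among 2,000 by default), gives them mean log2
intensity 14.6 in their own cell's samples and 14.6 − effect (effect
default +2 log2) elsewhere, against a N(6, 1) background — so planted
genes sit about one effect size above twice the realised BEC (~6.7), which
is what makes the planted truth recoverable by the 2×BEC rule in
principle.  Replicate noise is Gaussian on the log2 scale (sd 0.4 for
active probe sets), three samples per cell population, 1 + Poisson(0.3)
probe sets per gene plus 40 decoy probe sets without gene links.

Fluid detection is Bernoulli with logit −2 + 1.5·z + 2·[secreted], z the
gene's standardised mean expression: the simplest model that couples fluid
content positively to both expression and secretion status (the coupling
is verified as a positive point-biserial correlation, and vanishes when
the bonus is set to 0).  Detected genes are distributed over two species
(ram 0.85, rat 0.45, at least one forced), each gene receiving
1 + Poisson(0.6) protein accessions; protein→gene links break with
probability 0.08 and gene→group / group→reference links with 0.02 / 0.01,
emulating the large accession→gene collapse and mapping losses of real
cross-species lists.  The planted "true" cell secretomes are defined on
genes whose fluid detection survives the mapping chain; biologically
detected but chain-broken genes are recorded separately in the truth
manifest, so recovery metrics measure the pipeline, not the planted
mapping damage.

Interaction catalogues contain 10 planted secreted→membrane cross edges
(alternating directions) among 500 random background pairs, ~10% of pairs
carrying a second provenance record.  PLA counts are Poisson at the two
reported density regimes (312 vs 29 signals/field, 10 fields each; the
field count is a free parameter since no real count is published).  One
integer seed drives a single generator stream; identical configs write
byte-identical files.

What the worlds do *not* emulate: probe-level microarray artefacts and
normalisation, peptide-level mass-spectrometry sampling, real orthology
structure (paralog fan-outs), correlated GO annotation, and interaction
ascertainment bias.  Passing recovery tests therefore demonstrates the
correctness of the set algebra, statistics and plumbing under the stated
generative model — not performance on real data.

## Calibration and problem sizes

The null-calibration study uses 50 worlds of 800 genes per arm (chosen as
a comfortable size for repeated simulation): with effect 0 and secretion
bonus 0, transcriptome selection is expected empty up to the FDR level
(BH at q = 0.01 under a global null bounds the probability of any
selection by ~1%) and the enrichment test degenerates to p = 1; with
expression kept but the bonus removed, enrichment p-values are uniform and
the α = 0.05 rejection rate over seeds is required to stay within binomial
tolerance of 5%.  Recovery acceptance runs on the full default world
(2,000 genes): planted germ-cell secretome precision ≥ 0.9 and recall
≥ 0.8, and network edges exactly equal to a brute-force quadratic scan of
the catalogue against the derived sets.

## Known limitations

- The moderated-test hyperparameter fit assumes a common residual df
  across probe sets (true here, where no values are missing).
- Enrichment is conditional on the realised sets; uncertainty in the
  upstream selection is not propagated.
- The conflict rule discards genes wholesale; a probe-set-level
  reconciliation (e.g. keeping the dominant pattern) is not attempted.
- Identifier mapping is static; versioned identifier history and live
  homology queries are out of scope.
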