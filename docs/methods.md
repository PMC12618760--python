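# Methods

## The model

`stpheno` positions bulk RNA-seq samples on a spatially resolved embryo
reference atlas and quantifies condition-wise divergence per position.
The procedure has three steps.

**Harmonization.** The atlas carries per-position abundances on the
log2(TPM+1) scale. Bulk samples given as raw counts are first
length-normalized to transcripts per million,

    rate_g = count_g / length_g[kb],   TPM_g = rate_g / Σ_g rate_g · 1e6,

then transformed elementwise to log2(TPM+1). Samples already supplied as
TPM skip the length normalization; samples already on log2(TPM+1) pass
through. Effective gene length is the merged union of a gene's exon
intervals (strand-agnostic, GTF coordinates 1-based inclusive). This is the
simplest deterministic length definition; a transcript-averaged or
fragment-length-corrected effective length would shift TPM values slightly,
but not the correlation structure the projection relies on.

**Projection.** For each bulk sample X and each atlas position Y the
Pearson correlation coefficient

    PCC(X, Y) = Cov(X, Y) / (σ_X · σ_Y)

is computed over a restricted gene universe: the intersection of a
spatially informative feature gene set (spatial-domain DEGs) with the genes
present in both the bulk table and the atlas. One common universe is used
for every (sample, position) pair — per-pair complete-case universes would
make PCC values incomparable across positions and corrupt the PDI
subtraction. The position(s) with the highest PCC are a sample's inferred
embryonic location; exact ties are broken lexicographically and all tied
members are reported. A universe smaller than `min_overlap` (default 100)
is an error: correlations over a handful of genes are unstable, and the
floor is configurable where a user knowingly works with short lists.
Zero-variance vectors make the PCC undefined; such cells are surfaced as
NaN plus an explicit mask and a logged warning, never coerced to a number.

**Phenotypic difference index.** For a case condition (e.g. a knockout)
and a control condition measured at the same timepoint,

    PDI(position) = PCC_case(position) − PCC_control(position),

which lies in [−2, 2]. Zero means no change in association strength with
that position; positive values an enhanced, negative values an attenuated
transcriptional concordance of the case. Classification uses the boundary
at 0 (configurable dead band ε). The defining equation is written for a
single sample per side; with replicates the default aggregation takes the
mean of per-replicate PCCs per group (`mean_pcc`). An alternative
`pooled_profile` mode averages the groups' log2(TPM+1) profiles first and
correlates each pooled profile once — the two agree exactly when replicates
are identical and differ slightly otherwise; both are exposed rather than
hiding the choice. Comparisons are always matched within timepoint labels;
a timepoint present on only one side is skipped with a warning.

## Single-cell reference comparison

When the reference is an annotated single-cell dataset rather than a
spatial atlas, member cells of each cell type are summed into one
pseudo-bulk column, scaled to counts per million and log2(CPM+1)
transformed. CPM (no gene length) is the appropriate normalization for
summed UMI-style counts, and the output scale is tagged `logCPM1` so it is
never silently mixed with length-normalized data. The feature set is the
union of each type's top-ranked markers (top 50 by default; shorter lists
contribute everything they have, with a warning), and bulk-vs-pseudo-bulk
similarity uses Spearman's rank correlation with average ranks for ties —
rank correlation is robust to the residual scale differences between a
length-normalized bulk profile and a CPM pseudo-bulk profile.

## Synthetic data generator

`simulate_atlas` builds a staged corn-plot reference: a shared baseline
expression per gene (|N(4, baseline_sd²)| on the log2(TPM+1) scale) with a
disjoint block of marker genes per position elevated by a fixed effect
size. `simulate_bulk` draws replicates as the origin position's signature
plus Gaussian noise on the log scale, clipped at 0; a knockout-style fate
shift is a convex mixture `(1−w)·signature(origin) + w·signature(target)`.
Defaults: 10 positions, 2000 genes, 50 markers per position, effect size
2 log2-units, baseline SD 1, noise SD 0.5, 3 replicates, mixing weight
w = 0.5 — marker effects of ~2 log2-units over a noisy baseline are typical
of strong spatial-domain DEGs, and triplicate bulk RNA-seq is the common
design. All randomness flows through one `numpy` Generator seed recorded in
the returned ground truth.

What the generator does **not** emulate: count-level sampling noise
(negative-binomial depth effects), correlated gene modules, partial marker
overlap between adjacent positions, batch effects, or the real anatomy of
a gastrula corn plot beyond a labeled grid. Passing recovery tests
therefore demonstrates that the projection and PDI machinery is correct
and well-conditioned under its own assumptions — not that any particular
biological mapping is accurate.

`recovery_report` scores a run against the ground truth: origin recovery is
the fraction of samples whose top-1 position equals their true origin,
computed over unperturbed samples (w = 0) by default — a half-mixed sample
is equidistant from origin and target by construction, so its top-1 label
carries no information (an `include_perturbed` flag gives the unrestricted
rate). PDI sign agreement is the fraction of perturbed case/control
comparisons whose PDI at the perturbation target is positive. Under the
default scenario both rates are ≥ 0.95/0.9 across seeds; origin recovery
degrades monotonically as noise grows (checked at noise SD 0, 0.5, 2, 8).

## Numerical choices

- Correlations are computed by centered dot products; results are clipped
  to [−1, 1] to absorb last-ulp excursions. Undefined (zero-variance)
  correlations raise (scalar path) or mask (matrix path).
- TPM columns must sum to 1e6 within relative 1e-6; this invariant is
  enforced at construction, not only at creation time.
- Gene identifiers are matched purely by canonicalized string (Ensembl
  version suffix stripped); no symbol↔accession translation is attempted,
  because a silent cross-namespace join corrupts correlations invisibly.
- Duplicate gene rows collapse by summation only for count data; on any
  normalized scale duplicates are an error, since summing normalized values
  is meaningless.
- Missing cells are errors, not imputations: the correlation assumes
  complete vectors.
- All TSV output uses fixed `%.10g` float formatting and sorted/stable
  orderings, and SVG output pins the hash salt and omits timestamps, so a
  rerun with the same inputs is byte-identical.
- Corn-plot panels draw higher section indices lower (distal at the bottom,
  matching proximal→distal embryo depictions); `flip` inverts this.
  PDI panels use a diverging palette symmetric about 0 (±max|PDI|), PCC
  panels a sequential palette on [min, max]; undefined cells are hatched.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the default scenario size (10 positions × 2000 genes, 500 feature genes,
60 bulk samples) or smaller; a full pipeline run at this size takes well
under a second, and the whole suite a few seconds.

## Known limitations

- The atlas is consumed as given: no averaging of replicate positions into
  domain profiles is performed; if a published atlas provides several
  samples per anatomical domain, the user decides whether to average them
  during atlas preparation.
- No significance testing accompanies the PDI; it is a descriptive index.
- The GTF reader targets the GENCODE dialect; exotic attribute layouts may
  need a pre-pass.
- No cross-species or symbol↔accession gene id mapping.
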