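# Methods

This note documents the models, parameters and numerical choices behind
`phosphonorm`, and what its synthetic-data tests do and do not establish
about real data.

## Proteome normalization of phosphosite regulation

**Model.** The measured log2 fold change of a phosphosite between two
conditions decomposes as stoichiometry change plus parent-protein
abundance change. The corrected fold change is

    log2FC_corrected = log2FC_phospho − log2FC_protein

joined through the leading accession of the protein group on both sides.
Significance is then made conservative by dampening the phosphosite's raw
p-value `p_ptm` as

    p_dampened = 10^(log10(p_ptm) · r_FC),
    r_FC = clamp(log2FC_corrected / log2FC_phospho, 0, 1).

`r_FC = 1` (protein flat) passes the p-value through unchanged; `r_FC = 0`
(protein explains the full change, or more) forces `p_dampened = 1`.
Because the transform scales the *logged* p-value, `p_ptm = 10^-k` maps to
`10^(−k·r)`: each 0.1 drop in `r_FC` costs k/10 orders of magnitude.

**Numerical choices.**

* The ratio is clamped to [0, 1]. Unclamped, a corrected FC larger than
  the original (`r > 1`) would *gain* significance, and opposite signs
  (`r < 0`) would invert the transform; the clamp keeps the procedure
  strictly conservative (`p_dampened ≥ p_ptm` always). The policy is
  recorded in the output table's metadata.
* A site with original FC exactly 0 has nothing to dampen: `r_FC = 1`,
  avoiding a 0/0.
* `p_ptm = 0` is floored at 1e-300 before the log, with a warning.
* At `r_FC = 1` the p-value is passed through verbatim rather than via
  `10^log10(p)`, so unmatched sites round-trip bit-identically.
* Benjamini–Hochberg is re-applied across the dampened p-values of all
  tested sites, so downstream significance calls reflect the corrected
  evidence. Unmatched sites are flagged, never dropped.

**Behavior under estimation noise.** For a truly protein-driven site the
*estimated* corrected FC is noise centered at 0, so the sign of
`r_FC` before clamping is a coin flip: roughly half of such sites clamp
to `r = 0` (`p_dampened` exactly 1) and the rest land just below 1. The
end-to-end tests therefore check a point mass at 1 plus an order-one
median, not "all equal 1".

## Differential expression engine

Per feature with ≥ 2 valid values per group (configurable): log2 fold
change = mean(B) − mean(A) of log2 intensities; p-value from Welch's
unequal-variance t-test; BH adjustment across the tested features of the
contrast. The fold-change correction and dampening above are agnostic to
the DE engine — any method producing a per-feature (log2FC, p) pair can
feed them; Welch's t-test was chosen as a transparent, dependency-free
engine whose contract is easy to verify. Peptide-pair empirical-error
models used in some published pipelines would slot in behind the same
interface. Degenerate equality (zero statistic) is reported as p = 1;
zero within-group variance with a nonzero difference is off the t scale
and reported at the 1e-300 floor with a warning. At triplicate scale the
Welch–Satterthwaite df approximation is slightly conservative; the null
p-value uniformity test runs at n = 10 per group, where the approximation
is accurate. Volcano classification uses adj. p < 0.05 and |log2FC| > 1.

## Phosphosite collapse

A precursor contributes to a site (protein group, 1-based position,
residue) iff that site's localization probability is ≥ the class-I cutoff
(default 0.75). The cutoff applies per site: a doubly-phosphorylated
precursor can support one confident site and fail the other. Site
intensity is the **sum** of contributing precursor intensities — linear
aggregation preserves total intensity mass, which gives a testable
conservation invariant (alternatives like max or median do not). A site
cell is missing only if every contributing precursor is missing in that
sample. Multiplicity is carried as annotation but does not split site
identities. Shared peptides contribute only to their reported protein
group; no FASTA re-mapping or sequence-window extraction is performed.

## Imputation, z-scoring, correlation analytics

* **Left-shifted Gaussian imputation**: missing values of each feature
  are drawn from N(x̄ − downshift·s, (width·s)²) with defaults
  downshift = 3, width = 0.3, using that feature's own observed mean x̄
  and sample sd s (ddof = 1). This presumes left-censored (MNAR)
  missingness: values are missing because they are low. Only missing
  cells are altered; observed values are bit-identical after imputation.
  Features with < 2 observed values are dropped with a warning.
* **z-scoring** divides by the population sd (ddof = 0) so a transformed
  row has sd exactly 1; constant rows are an error, named.
* **Cross-omics replicate correlations** pair every proteomics replicate
  with every transcriptomics replicate within a condition (3×3 = 9
  pairings per group) and compute Pearson r and a least-squares line over
  matched features, on *complete pairs only* — imputation is reserved for
  the heatmap workflow, which applies impute → z-score → correlate in
  exactly that order. Condition comparisons of r values use two-sided
  independent Student's t-tests (pooled variance).
* **CVs** are computed per feature across replicates on the linear scale
  (sd/mean; CV is not meaningful on log values); replicate
  reproducibility (r²) on the log2 scale.
* **Sample ordering** for correlation heatmaps comes from single-linkage
  agglomeration on Euclidean distances between sample profiles
  (scipy `linkage` defaults for those settings).
* Gene↔protein mapping is applied as given; many-to-many pairs are
  excluded, not guessed, and unmapped features are dropped from
  integration only.

## Cell-type profiling

One-way ANOVA runs across all (cell type × treatment) groups — six in
the default design — per feature on complete observations; features
where any group has < 2 observed values are excluded and counted. For a
two-group design this reduces to the pooled-variance t-test (F = t²),
which is checked numerically. K-means (k = 6 by default, 25 restarts,
fixed seed, best inertia kept) clusters significant features by their
per-group mean z-profiles, matching a heatmap layout of group columns.
Pairwise enrichment runs the DE engine over all cell-type pairs within
each treatment and treated-vs-control within each cell type, then
summarizes treatment responses as shared (regulated in all cell types)
vs cell-type-specific (exactly one).

## Synthetic-data generator

The generator emulates the study design — 3 cell types × 2 treatments ×
3 replicates — at desk scale (defaults 2000 proteins, 500 phosphosites):

* **Baselines** are log-normal: protein log2 abundance ~ N(18, 2.8),
  spanning ~5 orders of magnitude as in deep DIA proteomes; mRNA
  baselines share a latent component mixed to hit a target mRNA–protein
  Pearson correlation (default 0.6 on log abundances; bulk matched
  datasets typically report 0.4–0.6).
* **Replicate noise** is Gaussian on the log2 scale with
  σ = sqrt(ln(1 + CV²))/ln 2, inflated by the c4 constant
  (E[s] = c4(n)·σ) so the *observed* mean sample CV at the design's
  replicate count matches the targets — 9.3% for proteomics, 21.8% for
  transcriptomics, the reproducibility regime of sorted-cell DIA
  proteomes vs bulk RNA-seq. Without the c4 correction the realized CV
  at n = 3 would sit ~11% below target purely from sd-estimator bias.
* **Effects**: a fraction of features are cell-type markers (enriched
  +2 log2 units in one cell type) and a fraction respond to treatment
  (+2 log2 units), either in all cell types or in one — together seven
  archetypes (3 marker, 3 cell-specific response, 1 shared response)
  recorded in the ground truth.
* **Phosphosites** come in three classes: stoichiometry-change (site FC
  with flat parent protein), protein-driven (site FC identical to the
  parent protein's; true corrected FC 0), and null. Each site is
  reported by 1–4 precursors whose intensities equal the site profile
  times a fixed log-normal ionization-efficiency offset, so
  collapse-by-sum recovers the site profile exactly. Each site keeps at
  least one class-I precursor; additional precursors fall below the 0.75
  cutoff with probability 0.1 to exercise the filter.
* **Missingness** is left-censored MNAR: cell-level missingness
  probability ∝ exp(−steepness · z) of the standardized log2 intensity,
  with the constant solved by bisection so the expected missing fraction
  equals the requested rate. MNAR is assumed because the downshifted
  Gaussian imputation downstream presumes it.
* **Determinism**: all randomness flows from one seed through
  `numpy.random.SeedSequence` with fixed per-stage sub-streams;
  identical configs give byte-identical serialized outputs.

**What passing tests show — and don't.** Recovery of injected effects,
FDR control on nulls, and separation of stoichiometry from
protein-driven sites (AUC ≥ 0.9 at |log2FC| = 2, n = 3) demonstrate the
pipeline's correctness under the generator's assumptions: Gaussian log
noise, effects constant within groups, precursors perfectly consistent
with their site, MNAR missingness of known form. Real data add
peptide-level interference, batch structure, non-Gaussian tails and
mixed missingness mechanisms that the generator deliberately omits
(no spectrum-level, retention-time or ion-mobility modeling, no FASTA
digestion), so passing here validates the statistics, not instrument
behavior.

## Problem sizes and defaults

End-to-end tests run at 2000 proteins / 500 phosphosites / 18 samples,
which keeps the full suite in a few seconds while leaving ~150 sites per
phospho class; Monte-Carlo calibration checks use 10⁵ draws (imputation)
and 10⁴ features (null uniformity). Key defaults: localization cutoff
0.75; min valid values per group 2; volcano thresholds adj. p < 0.05,
|log2FC| > 1; imputation downshift 3, width 0.3; k-means k = 6 with 25
restarts.

## Known limitations

* The dampening heuristic treats the protein fold-change estimate as
  exact; its own uncertainty is not propagated into `r_FC`.
* Site-to-protein matching by leading accession can mismatch when
  isoform-level protein groups share leading accessions.
* No moderated-variance (empirical-Bayes) shrinkage and no paired
  designs in the DE engine.
* ANOVA is one-way across the six groups; no interaction decomposition.
* The generator's treatment effects are all positive log2 shifts; sign
  symmetry of the pipeline is covered by the DE antisymmetry property
  rather than by the generator.
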