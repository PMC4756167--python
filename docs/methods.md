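# Methods

## Study design and statistical model

The pipeline targets a replicated two-tissue ethylene time course: leaf
abscission zone (LAZ) vs adjacent petiole (NAZ), times {0, 12, 24, 48, 72} h,
three biological replicates, ~4×10⁶ reads per sample. All inference operates
on RPKM, computed with the per-sample denominator equal to the reads mapped
to the genes in the matrix (upstream read trimming, alignment and rRNA
removal are out of scope; the count matrix is the interface).

Two conventions matter downstream and are applied exactly once each:

* the **0.1 floor** is applied to condition (replicate-mean) RPKM values and
  only where ratios are formed, so a ratio never has a zero numerator or
  denominator. Replicate-level testing instead uses `log2(x + 0.1)`, which
  stabilizes the log transform near zero without collapsing replicate
  variance the way flooring individual replicates would. Whether the floor
  is applied per replicate or to the mean is genuinely underdetermined; the
  choice here is exposed through `ConditionSummary(floor=…)`.
* the **expression call** is per gene, not per condition: a gene is analyzed
  if any tissue/timepoint has replicate-mean RPKM ≥ 1.0.

## Differential selection

Specificity `S_t = log2(LAZ/NAZ)` and temporal `T_t = log2(LAZ_t/LAZ_0)`
ratios use floored means. Significance is a two-sided t-test on log2
replicate values. The test family is a deliberate choice: only a p-value
threshold (0.015) is inherited from the protocol, not a named test; Welch's
unequal-variance t is the default because n = 3 per group gives no power to
verify variance homogeneity, and a Student's-t variant is exposed
(`equal_var=True`). Each group's variance is floored at 10⁻⁸ so identical
groups yield t = 0, p = 1 rather than 0/0. All fold thresholds are strict
inequalities ("more than eight-fold": |log2| > 3; window rule: |log2| > 2).
No multiple-testing correction is applied at selection — the raw-p cut-off
is part of the protocol being reimplemented — and FDR control appears only
in enrichment.

TF calling is annotation-driven: a gene is a TF when its ontology-propagated
term set hits a configurable include list (default: the transcription
regulator activity branch), and excluded when it hits the exclusion list
(DNA methylation/demethylation, DNA-directed RNA polymerase), mirroring the
upstream protocol's removal of transcription-adjacent enzymatic classes.

## Window clustering and dendrogram support

The window rule requires the four-fold specificity condition (with its
p-value) at **both** timepoints of a consecutive pair. This is the strictest
of the defensible readings (fold-change and significance at both points);
requiring significance at both points is configurable in principle but kept
fixed here because it makes the planted-truth contract unambiguous. Genes
passing at ≥3 consecutive timepoints qualify in several windows; the primary
label is the earliest window and `run_length`/`multi_window` record the
ambiguity instead of resolving it silently.

Dendrograms use 1 − Pearson distance across the 10 condition means with
average linkage (the cited clustering tool's defaults), leaf order fixed by
lexicographic gene id. Support values follow the multiscale-bootstrap
recipe: condition columns are resampled with replacement at scales
r ∈ {0.5, 0.6, …, 1.4} (⌈r·m⌉ of m columns), the tree is rebuilt, and the
per-edge bootstrap probability curve BP(r) is fitted by weighted least
squares as Φ⁻¹(1 − BP(r)) = d·√r + c/√r with binomial weights
`nboot·φ(z)²/(BP(1−BP))`; AU = 1 − Φ(d − c), BP_fitted = 1 − Φ(d + c). BP
values are clipped to [1/(nboot+1), nboot/(nboot+1)] before probit
transformation; curves saturated at one extreme are reported as AU ∈ {0, 1}
with a `degenerate` flag rather than fitted. Default nboot is 1000 (the
tool-default); the acceptance script uses 1000, the unit tests 20–100.

## GO enrichment

Over-representation only (upper-tail hypergeometric), after closing
annotations under is_a/part_of ancestors. The universe is the set of
**expressed** genes carrying ≥1 propagated annotation — not the whole
genome — because the selection that produces every test set is itself
conditioned on expression; the universe is a parameter of `enrich` for
users who prefer a genomic background. Only terms with k ≥ 1 in the test set
enter the BH adjustment, mirroring the behaviour of standard enrichment
tools; q < 0.05 flags significance.

## Network projection

Soy TFs map through a best-match ortholog table (ties resolved by highest
similarity score, then lexicographically smallest Arabidopsis id; the map is
an *input* — no similarity search is performed here). Matched ids are
intersected with the signed edge table's vocabulary and the induced subgraph
extracted. The **bridge rule** (default on) additionally admits regulome
genes with no soybean member that are adjacent, in either direction, to at
least two matched nodes: published projections of this kind include such
connector TFs, and the ≥2 threshold keeps single-edge halos out. Node
direction classes (`up` = LAZ-high, `down` = NAZ-high, `mixed`, `none`) are
derived from the members' significant S_t excursions past ±3. Exports (SIF,
GraphML, node/edge TSVs) are lexicographically ordered and byte-stable.

## Synthetic data generator

The generator emulates the study's design and statistical structure with a
recoverable truth, not its biology:

* **Counts** are negative binomial with variance μ + φμ² (gamma–Poisson),
  φ = 0.05 by default; `dispersion=0` is implemented as the deterministic
  noise-free limit (counts = rounded expectations), which provides exactly
  reproducible fixtures. Per-sample depth is lognormal around 4×10⁶ reads
  with CV 0.1. The master seed spawns independent substreams per component
  (lengths, baselines, TF labels, class assignment, annotations, orthologs,
  regulome, depth, counts), so regenerating one layer never perturbs another.
* **Planted classes**: eight window archetypes (up/down × W1..W4, 50 genes
  each) put the full ±4 log2 effect on the LAZ at exactly the two timepoints
  of their window, NAZ flat — so planted genes are both tissue-specific
  (|S| = 4) and, for windows away from 0 h, temporal (|T| = 4), reproducing
  the specific-and-temporal overlap structure of the real study.
  `temporal_only` genes decline 16-fold in both tissues after 0 h (like
  auxin-responsive transcripts after leaf-blade removal): they must pass the
  temporal filter and, in expectation, never the specificity filter.
  `constitutive` genes are flat housekeeping-like controls; `null` genes are
  flat with genome-like baselines.
* **Baselines** are lognormal with a heavy tail (σ = 2.3) and rescaled once
  so the all-baseline condition carries 10⁶ RPKM·kb — this pins expected
  column sums to the nominal depth and makes both the 0.1 floor and the
  RPKM ≥ 1 call operative on a realistic minority of genes. Planted and
  control classes draw from a tighter, well-expressed distribution
  (median ≈ 20 pre-scale RPKM) so the planted truth is recoverable at the
  study's depth. Active LAZ windows shift realized column totals by a few
  tens of percent — the compositional artifact real RPKM data also carries.
  Gene lengths are lognormal (median ≈ 1.5 kb, bounded [200, 20000] bp).
* **TF fraction** defaults to 0.10 (the genome-wide TF fraction in the
  source system is ≈ 9.6%); each planted class is stratified to contain
  round(0.10 × 50) = 5 TF genes so both TF and non-TF pools are always
  represented. A 5% subfraction of TFs carries an exclusion-class
  annotation.
* **Ontology/annotations**: a small rooted DAG (≥3 levels, is_a and part_of)
  with a TF-activity branch, two exclusion branches, a planted term
  annotated to 90% of `up_W1` genes and 2% of others, and filler terms.
* **Regulome**: 80% of the planted specific-TF orthologs enter a sparse
  signed edge table, plus one bridge gene adjacent to two matched nodes,
  disconnected decoys, and a degree-1 dangler (which must *not* be bridged
  in). The ground-truth projected network is recorded directly from the
  construction, independently of the projection code it validates.

What the generator does **not** emulate: read-level noise and mapping
artifacts, splice variants, gene–gene correlation beyond the planted
classes, GC/length biases, and library-composition effects beyond the
planted mass shifts. Passing tests therefore demonstrate that the pipeline
recovers a known truth under the study's design and a standard count-noise
model — not performance on real libraries.

## Numerical choices and degenerate inputs

* Zero-variance expression profiles have undefined Pearson correlation;
  they are assigned distance 1 with a warning rather than an error.
* Hypergeometric tails come from the survival function of the exact
  distribution (log-space internally); tests verify agreement with brute
  force enumeration to 10⁻¹² for all N ≤ 12.
* Welch degrees of freedom use the Welch–Satterthwaite approximation on
  floored variances.
* Problem sizes: the default synthetic study is 2,000 genes × 30 samples,
  which exercises every selection boundary while keeping a full pipeline
  run in seconds; bootstrap-support checks use 12-gene profile sets at
  nboot = 1000.

## Known limitations

* The published headline counts of the original experiment (e.g., 188
  abscission-specific TFs) derive from the deposited sequencing data and are
  not reproducible from synthetic inputs; this package reproduces the
  *procedure* and validates it on planted truth plus the published ortholog
  worked example (58 soybean TFs → 40 distinct Arabidopsis TFs).
* The ortholog map is consumed, never computed: the original best-match
  method (similarity search protocol, thresholds) is unspecified.
* The rule by which published network figures admitted non-matched
  connector genes is undocumented; the ≥2-neighbour bridge rule is an
  explicit, configurable stand-in.
* p-values at n = 3 replicates are fragile by construction; the pipeline
  reports them faithfully but they should be read as the protocol's filter,
  not as calibrated error rates.
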