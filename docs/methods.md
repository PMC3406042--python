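# Methods

This note records the models behind `ppicontext`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic corpora do and
do not demonstrate.

## Orthology

Orthologs are operational: reciprocal best hits (RBH) between the query
genome and each reference genome, ranked by bit score, filtered at e-value
≤ 1e-4 (inclusive). Choices where the standard recipe is underspecified:

* **Ranking field.** "Best" means maximal bit score; the e-value serves only
  as the filter. Bit scores are length-normalized and comparable across
  database sizes, which makes them the safer ranking key.
* **Ties** between equal-bit-score subjects break to the lexicographically
  smallest subject id — ties are rare and determinism matters for testing.
* **Multi-HSP input** keeps only the first line per query–subject pair
  (tabular output lists the best HSP first).

## Phylogenetic profiles

`BPPM` correlates binary presence/absence vectors; `SPPM` correlates
normalized bit-score vectors. The normalization is two-stage and sequential:

1. each row is divided by its maximum bit score, removing per-protein
   divergence scale (the best-conserved ortholog becomes 1);
2. each nonzero cell is divided by the minimum *nonzero* value of its
   column, computed on the stage-1 values, removing per-genome species
   divergence.

Zeros encode absence and stay exactly zero through both stages; including
them in the column minimum would make the divisor zero, so the minimum is
taken over nonzero cells only. Pearson correlations are computed over the
full genome vector, zeros included — absence is signal in profiling.
A protein whose row is entirely zero is excluded and reported.

The column normalization absorbs a uniform rescaling of one genome's bit
scores exactly as long as the rescaling does not relocate any row's maximum;
if the scaled column holds some rows' maxima and not others, the two stages
mix scales and invariance is only approximate. The property test exercises
the exact regime.

Constant profiles (e.g. all-ones rows when the reference set is a tight
clade) have undefined correlation; they receive the no-score sentinel
(`None`) and rank strictly last in evaluation, i.e. they predict "no
interaction".

## Gene context

A *gene cluster* is a maximal run of consecutive co-directional genes with
intergenic gaps ≤ `idc` nucleotides (default 100; the sweep values
100–500 are supported). Gaps are `start(downstream) − end(upstream) − 1`;
overlapping genes clamp to gap 0. On circular chromosomes the last→first
adjacency is tested and wrap-around runs merge.

`GCM` is the plain fraction (Σᵢ XYᵢ)/n over the full reference-set size n —
no background correction. `MDM` measures the distance d between translation
start sites (start on `+`, end on `−`) in both directions around the circle,
keeps the minimum, converts it to the exact uniform-pair probability
min(1, 2d/N), and takes the minimum over reference genomes. Genomes holding
only one ortholog contribute to neither score; a pair with no co-occurring
genome gets the no-score sentinel. MDM is oriented "smaller is stronger";
the evaluator takes a per-method orientation flag rather than negating
stored scores.

## Mirrortree family

Distance matrices come from aligned families via the p-distance (fraction of
mismatched columns among pairwise-ungapped columns) or Kimura's correction
−ln(1 − p − p²/5), capped at 10 where it diverges. A pair of sequences with
no ungapped overlap is an error. Correlations are Pearson over the strict
upper triangle (the always-zero diagonal would inflate them), require at
least 15 shared genomes by default, and return the sentinel when a triangle
is constant.

Both corrections use a *scaling factor*: the maximum correlation between the
reference matrix (16S rRNA distances for Tol, genome distances for GD) and
any protein family. Correction divides **both** the protein matrix and the
reference matrix by that factor and subtracts:
`corrected = (D_X − D_ref) / factor`. A separate factor is computed per
reference kind. Genome distances are one minus the Tanimoto similarity of
the genomes' shared ortholog complements, so GD ∈ [0, 1].

## Reference sets

Genome similarity is the Tanimoto coefficient of query-ortholog sets; pairs
at ≥ 0.9 are linked and the graph is clustered by MCL (inflation 2.0 — the
algorithm's conventional default, exposed as a parameter; self-loops of
weight 1 added before expansion, iteration to a 1e-6 fixpoint). The cluster
representative is the genome with the most query orthologs, ties
lexicographic. Curated set definitions are user-supplied genome lists, not
re-derived taxonomy.

## Benchmark harness

High-quality positives require physical evidence (interaction database or
co-complex) AND functional evidence (pathway co-membership or curated
functional pairs) AND both proteins' orthologs in at least a configurable
fraction of the reference set (default 200/565 ≈ 0.354, the published
threshold expressed as a fraction so synthetic sets of any size scale).
Low-quality positives are the de-duplicated union of sources, with pathway
pairs restricted to those sharing exactly one pathway. Negatives are sampled
uniformly (seeded, without replacement) from pairs with *different*
localization AND *different* functional category — the conjunction of the
two published pool definitions, the stricter reading — excluding proteins
with ambiguous localization or multiple categories, at a 1:5
positive:negative ratio.

ROC/PR sweeps group tied scores at a single threshold, so the trapezoidal
AUC equals the Mann–Whitney probability with half credit for ties. No-score
pairs form a strictly-worst final group. The sweep is implemented in the
package because the sentinel ranking, orientation flags and tie policy are
part of the contract; scikit-learn's ROC serves as an independent
cross-check in the test suite.

## Synthetic corpora

The generator emulates exactly the structure the methods assume, from one
seed (identical configuration ⇒ byte-identical corpora):

* **Genome tree** — random joins with exponential branch lengths (default
  scale 0.12, giving root-to-leaf divergences around 0.3–1.2 substitutions
  per site); an optional clade attaches a subtree whose internal branches
  are shrunk (default ×0.05) to emulate over-sampled near-identical genera.
* **Presence/absence** — per-branch loss (default 0.06), so a typical family
  survives in roughly half to three-quarters of 60 leaves. A planted pair's
  second partner copies each branch outcome with probability ρ (default
  0.9).
* **Bit scores** — base 400 · exp(−1.5 · λₚ · depth · exp(0.6·z)) with a
  lognormal per-protein rate λₚ and per-(protein, genome) noise z that
  partners share with probability ρ, floored at 25. This is the minimal
  model in which bit-score profiles carry divergence information beyond
  presence/absence.
* **Genomes** — 1 Mb circular chromosomes; ancestral operons (default 15
  operons of 2 genes, gaps ≤ 80 nt) break per branch at rate 0.05; broken
  operons and free genes relocate uniformly, so gene order outside conserved
  operons is randomized per genome.
* **Alignments** — i.i.d. uniform-exchange substitution over 20 residues
  (Jukes–Cantor-like; sufficient for distance-matrix structure without an
  external evolution simulator), with per-branch, per-family lognormal rate
  distortion (σ = 0.8). A planted pair copies the partner's root and whole
  per-branch substitution events with probability equal to the coupling
  (default 0.9), so full coupling reproduces the partner's sequences
  exactly. A 16S-like reference alignment evolves on the undistorted tree
  at half rate.
* **Gold annotations** — operon members share a pathway and category;
  localizations cycle through cytosolic/secretory/membrane; two proteins
  are tagged ambiguous to exercise the exclusion path. Negatives for a
  corpus's own gold standard are drawn among the proteins constituting the
  positives, so positives and negatives share the same phyletic-spread
  distribution and only genomic signal separates them.

The matched null corpus (`zero_coupling()`) sets the co-loss, operon and
coevolution couplings to zero while keeping everything else fixed; every
method then calibrates to AUC ≈ 0.5.

**What passing tests do not show.** The corpora contain no horizontal gene
transfer, duplication/paralogy, indels, composition bias or alignment error;
bit scores come from a clean decay model, not an actual aligner; operon
evolution has no transcriptional constraint. Near-perfect AUCs on planted
corpora demonstrate correctness of the computational chain, not expected
accuracy on real genomes.

## Problem sizes

The shipped evaluations use a 60-genome, 60-protein corpus with 15 planted
pairs (gold standard of 90 pairs) for signal recovery; eight matched null
replicates for calibration; twenty 40-genome replicates with a 12-genome
clade for the SPPM/BPPM contrast; and twenty 30-genome, 16-family replicates
for the speciation-background contrast. These sizes give stable means (the
AUC standard error of a single 90-pair gold standard is ≈ 0.09 under the
null, hence the replicate averaging) while keeping the whole suite fast on a
single CPU.

## Known limitations

* MCL cluster extraction uses connected components of the converged matrix's
  support; for graphs with long weakly-linked chains the partition can
  depend on the inflation parameter, as with any MCL implementation.
* The Kimura cap (distance 10) is arbitrary but only reachable for p ≳ 0.85,
  far beyond the divergence where mirrortree correlations are meaningful.
* The scaling-factor correction assumes the reference and protein matrices
  are on commensurate scales after division by one correlation coefficient;
  this mirrors the published recipe rather than a principled normalization.
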