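# Methods

This note records the models implemented in `mutacc`, the conventions and
parameter choices behind them, what the synthetic-data generators do and
do not emulate, and known limitations.

## Spectra and classification

Substitutions are classified into the 96 channels `X[R>A]Y` (R ∈ {C,T})
with pyrimidine-strand collapse: a record whose reference base is a purine
is reverse-complemented — ref, alt and both flanks complemented, flanks
swapped — before channel assignment. Channel order is substitution-type
major (C>A block first), 5′ flank before 3′ flank, each in A,C,G,T order;
catalogs read from disk are reordered to this canonical order regardless
of their row order.

Records at a contig edge, or whose trinucleotide window contains an N, are
excluded from both numerator and denominator with a logged count rather
than raising: real MA data near telomeres or assembly gaps would
otherwise abort a run. A mismatch between a record's `ref` field and the
genome is always an error, never a silent strand flip — the
generation-0 differencing step depends on trustworthy ref fields.

Cohort spectra average per-sample *proportion* vectors with equal sample
weights (the "average percentage across samples" convention); pooling raw
counts is available separately (`pool_counts`) because the two differ
whenever sample sizes differ. Reported percentages are rounded to one
decimal for display only; all comparisons happen pre-rounding.

The POLE-EDM discriminator applies its three thresholds inclusively, as
printed: C>A ≥ 20 %, T>G ≥ 4 %, C>G ≤ 0.6 %.

## Region annotation

GFF3 feature types map to region classes through a configurable
`class_map` (default: CDS; five/three-prime UTR → UTR; intron;
nc/r/t/sn/sno-RNA → ncRNA). Overlaps resolve by a declared priority,
default CDS > UTR > intron > ncRNA; uncovered positions are `intergenic`.
The expected distribution is simply each class's fraction of genome
length × 100. Both the class map and the priority are open choices — no
single convention exists — so they are parameters, not constants.

## Humanization

Composition correction multiplies each channel by
f_target(t)/f_source(t), where t is the channel's pyrimidine-collapsed
flanking trinucleotide and the f's are 32-trinucleotide frequency tables
(both strands collapsed, N-containing windows excluded from denominators).
Renormalization happens once, at the end; doing it after each of the two
conceptual steps (divide by source, multiply by target) is mathematically
identical for the final pattern. Zero channels stay zero; a *nonzero*
channel whose context has zero frequency in either table is an error
(undefined correction). The transform is exactly invertible by swapping
the tables, which the tests exercise as a round-trip identity.

The bundled `data/human_exome_trinuc_synthetic.tsv` is a **synthetic**
stand-in: trinucleotide frequencies of a 400-kb i.i.d. GC ≈ 0.52 sequence
with CpG dinucleotides thinned to ~25 % of their i.i.d. rate. It has the
qualitative features that matter for exercising the correction (GC-richer
than an AT-rich yeast genome, CpG-depleted) but is not derived from a real
exome; the table is an input, and a real one is a drop-in replacement.

## Signature comparison and refitting

Cosine similarity is dot(a,b)/(‖a‖‖b‖) on non-negative vectors, so it is
scale-invariant and lives in [0,1]. 0.80 is used as the "high similarity"
flag. Display order comes from average-linkage hierarchical clustering on
1 − cosine distances, using plain dendrogram leaf order (no optimal-leaf
reordering). Best-hit ties resolve to the first catalog column and are
flagged in the output.

Decomposition against a *fixed, known* catalog is solved by non-negative
least squares (min ‖v − S·w‖₂, w ≥ 0) rather than iterative NMF: with the
basis fixed, NMF reduces to exactly this one-sided problem, and NNLS is
deterministic, so tests can assert exact recovery (noiseless mixtures of
linearly independent columns recover weights to 1e−6). De-novo signature
extraction is out of scope. Weights are normalized to fractions; an
optional `min_weight` zeroes trace exposures and renormalizes. Small
weights are where NNLS and a particular NMF implementation can differ,
which is why only the dominant exposures should be interpreted.

## Flank profiles and AT runs

Flank profiles align 103-bp windows (halfwidth 51) on the mutated
position, on the reference strand as given — no pyrimidine collapse,
since the object of interest is the genomic neighbourhood itself.
Window positions truncated by a contig end, or covering an N, contribute
nothing to that position's denominator, so every populated column still
sums to 1. The random control samples n centers uniformly among positions
with a complete N-free window, seeded; if n exceeds the number of valid
centers it samples with replacement and warns.

The A/T asymmetry score averages A- and T-frequencies over offsets
+1..+12 and −12..−1 (the 10–12 bp scale on which the hypermutator's flank
bias appears) and reports (A−T)_right − (A−T)_left; any left/right
symmetric profile scores exactly 0.

"AT-rich region" is operationalized as a **maximal run of consecutive A/T
bases on the reference strand** — the central interpretive decision in
this module, since windows above an AT-content threshold or annotated
elements would be defensible alternatives. The definition is
strand-symmetric by construction. A mutation is assigned to the run
containing its position using the PRE-mutation reference base (a mutated
A or T still counts as inside its run). Runs are binned 9–20, 21–50 and
>50 bp; the expected fraction per bin is the fraction of genome positions
inside runs of that class, which is independent of the mutation list. The
chi-squared goodness-of-fit includes the implicit "outside" class so
expected proportions sum to 1; no continuity correction.

A note on interpretation: mutations drawn from a *context-specific*
signature are not uniform over the genome — e.g. a T[C>A]T-dominated
process centers mutations on cytosines, which cannot lie inside pure A/T
runs — so even synthetic data can show mild, real depletion or enrichment
relative to the genome-uniform expectation. The analysis driver
demonstrates exactly this.

## Mutation-accumulation filters

Differencing keeps generation-200 records whose full (contig, pos, ref,
alt) key is absent from generation 0; the same position with a different
alt in the founder does not mask a new change. The cross-replicate
consensus uses union semantics with a conflict veto: positions seen in
only some variant files are kept, but any disagreement between files that
do report a position drops every record there (logged). The source rule
("retained SNPs from different genome positions and, for the same
position, only when the same change occurs in all variant files") is
ambiguous about partially-observed positions; union-with-veto is our
reading, and `strict_intersection=True` provides the intersection
alternative. Consensus output is sorted, making it invariant to replicate
order.

Lineage summaries report per-strain arithmetic means and (min, max)
ranges — matching how MA experiments with 2–3 lineages per strain are
usually presented — and a per-bp per-generation substitution rate using
the N-excluded genome length and 200 generations by default (the ~200
generations / 11 passages design). `strain_summary_from_counts` accepts
printed per-lineage totals directly, for re-deriving summary statistics
from published tables.

## Fluctuation analysis

The Ma–Sandri–Sarkar recursion gives the Luria–Delbrück pmf exactly;
because the tail falls like m/k², the mass captured up to kmax is short
of 1 by ≈ m/kmax (e.g. ~5e−4 at m = 5, kmax = 10⁴). This is a property of
the distribution, not a numerical defect, and the tests assert the
deficit's m/kmax scaling rather than an arbitrary small epsilon.

The MLE maximizes Σ log p_{k_i}(m) by bounded scalar search on log m over
[1e−10, 1e6]. The pmf is evaluated up to the largest observed count,
capped at `kmax_cap` (default 10⁴; the heavy analyses use 5000); counts
beyond the cap contribute the lumped tail mass log(1 − Σp). All-zero
counts give m̂ = 0 with a one-sided upper bound (the likelihood e^(−nm)
is monotone). Confidence intervals invert the likelihood ratio at
χ²₁(0.95)/2; bracketing failures return NaN bounds with a warning.
A fine-grid brute-force maximizer is provided as an independent oracle
and agrees with the bounded search to 1e−4.

Plating a fraction ε of each culture is corrected by
m = m_obs·(ε−1)/(ε ln ε) (≈ 1.305 at the protocol's ε = 0.6), applied
before rate conversion and toggleable. Empirically this classic
first-order correction is accurate at small m (within ~1 % at m = 0.5)
but systematically low at large m (≈ −8 % at m = 7, −11 % at m = 35,
measured against the simulator), because binomial thinning changes the
shape of the count distribution, not just its scale. The rate-contrast
analyses therefore run at ε = 1, where the estimator is unbiased at all
m tested; the correction is validated in its own small-m test. Rates are
reported as m/N_t per cell per culture growth (the estimator's common
convention), with m/(N_t ln 2) per division available as an option.

Rate ratios combine the two profile CIs on the log scale
(delta-method-style); a zero denominator rate raises with a pointer to
the p₀-based bound instead.

## Synthetic-data generators

All generators take a seed, are bit-reproducible under it, and report
realized parameters where the construction is stochastic.

* `simulate_genome`: i.i.d. uniform bases, or — given a target 32-trinuc
  table — a second-order Markov chain whose conditionals p(z|xy) come
  from the 64-mer expansion of the collapsed target (each collapsed
  frequency split evenly between a trinucleotide and its reverse
  complement). Second order is the minimal memory that can match 3-mer
  targets; realized frequencies are recovered with
  `trinucleotide_frequencies`.
* `simulate_mutations`: draws channels i.i.d. from a signature, then a
  uniform site among positions whose collapsed context matches, emitting
  the change on the reference strand. Sites may repeat across draws
  (logged); deduplication is an upstream concern in real MA data.
* `simulate_fluctuation`: the classic discrete-growth construction — the
  number of mutations per culture is Poisson(m), m = μ(N_t − N0); each
  mutation arises at a uniformly random division, so a mutation occurring
  at population size N founds a clone of final size ⌊N_t/N⌋; plating
  thins mutant cells binomially by ε. Clone sizes are capped at N_t/N0 by
  construction, a truncation of the ideal distribution's infinite tail
  that is negligible for N_t/N0 ≥ 10³ at the m values used. A
  continuous-time filtered-Poisson model would be the main alternative;
  the discrete construction is adequate for testing the MSS estimator it
  feeds.
* `embed_at_asymmetry`: plants C>A records at cytosines whose chosen-side
  flank (A−T) score is steered onto background + excess. Because
  per-site scores are quantized in units of 1/12, sites are selected
  greedily from below and above the target so the *mean* lands on it;
  the realized excess is reported and an unreachable request errors.
* `pole_like_signature`: six-type mass 33/0/25/5/22/15 % (C>A, C>G, C>T,
  T>A, T>C, T>G) with C>A concentrated in NCT (strongest TCT) and T>G in
  NTT (strongest TTT) contexts — the hypermutator's printed six-type
  profile with the reported context preferences. The exact within-type
  flank weights (4:2:0.3) are a modeling choice.
* Study-condition defaults: 200-kb genomes at 64 % A+T (fission-yeast
  composition); 1073 hypermutator / 746 wild-type SNVs (the study's
  consensus list sizes); fluctuation cultures with N0 = 2500,
  N_t = 2.5×10⁷ (a 0.25 ml culture from 10⁴ cells/ml grown to ~10⁸
  cells/ml), m_wt = 0.5, and rate folds 14× (exonuclease-null) and 70×
  (P287R-like), giving the 70× and 5× contrasts.

What the generators do **not** emulate: sequencing error and coverage,
real chromosomal composition heterogeneity (isochores, centromeres,
telomeres), selection during MA passaging, phenotypic lag or fitness
costs in fluctuation assays, and methylation-dependent processes. Passing
tests therefore demonstrate correctness of the *computations* under the
stated statistical assumptions, not robustness to every artifact of real
sequencing data.

## Problem sizes

Sampling-based checks use sizes at which their tolerances are
comfortable: 100–200 kb genomes, 50 000 signature draws for channel-wise
recovery (cosine > 0.999), 960 cultures per strain for rate contrasts,
10⁴ cultures for MSS parameter recovery, 200 replicate experiments for CI
coverage. Simultaneous sampling bounds over many cells (96 channels,
4×103 profile cells) use 4σ rather than per-cell 3σ.

## Known limitations

* The plating correction's large-m bias (above) — use ε = 1 designs or a
  full thinned-likelihood treatment when m·ε is large.
* NNLS exposures can differ from specific NMF implementations in trace
  weights; interpret dominant exposures only.
* The AT-run definition is one of several defensible operationalizations
  of "AT-rich region"; results for borderline run lengths depend on it.
* Humanization assumes context frequencies are the only compositional
  difference that matters; regional opportunity corrections (e.g.
  replication timing) are out of scope.
* The consensus rule's union semantics keep singleton-file positions;
  use `strict_intersection` when replicate files are expected to be
  complete.
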