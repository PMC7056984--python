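# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic-data generator does and
does not emulate, and the design decisions that were genuinely open.

## Codon substitution simulation

Ortholog pairs are simulated under an MG94×HKY codon model: the
instantaneous rate from codon *i* to *j* is nonzero only for single
nucleotide changes and equals the target nucleotide's stationary
frequency, multiplied by κ for transitions and by ω for nonsynonymous
changes; changes to stop codons are disallowed. The matrix is rescaled so
the stationary mean rate is one substitution per codon per unit time, and
`branch_length` is therefore the expected number of substitutions per
codon on each of the two branches from the sampled ancestor (total
divergence = 2 × branch_length). Evolution is simulated as a Markov jump
process per codon (exponential waiting times, categorical jumps), which
is exact for the model; codons are independent. The ancestor is drawn
from the stationary codon distribution (uniform over the 61 sense codons
by default). This parameterisation matches the estimand of the
divergence stage directly: ω and κ are generative inputs, so estimator
recovery is a well-posed test.

Defaults (300 codons, κ = 2, base ω = 0.2 with lognormal gene-to-gene
jitter of σ = 0.5 in log space, branch length 0.15 per branch) give
pairwise dS around 0.3 and dN/dS around 0.1–0.2 — the regime of closely
related congeners where counting estimators are reliable and retention
filters (dN, dS < 1.5) almost never trigger.

## dN/dS estimators

**NG86.** Synonymous site fractions per codon are the fraction of the
nine single-nucleotide changes that are synonymous (changes to stops
count as nonsynonymous opportunities), averaged over the two sequences;
S + N = 3 × (codons) exactly. Differences are partitioned by averaging
over all minimal mutational pathways with equal weights, excluding
pathways through stop codons (if all orderings cross a stop, the
differences count as nonsynonymous). Jukes–Cantor corrects pS and pN;
pS ≥ 3/4 marks the estimate unconverged. dS = 0 leaves ω undefined
(`None`), never a sentinel value.

**YN00-style.** Codon usage is estimated from the data as F3×4. κ is
estimated from positions that are fourfold-degenerate (or
nondegenerate) in both codons of a column, via K80 on each class and a
site-count-weighted average, falling back to 1 when fewer than 10 usable
sites or saturated. Site counts weight each possible change by
κ (transitions) × the F3×4 frequency of the target codon; difference
counts weight each minimal pathway by the product over its steps of
(κ for transitions) × (ω for nonsynonymous steps) × target-codon
frequency. Synonymous and nonsynonymous differences, split into
transitions and transversions, get separate K80-type distance
corrections. Because pathway weights depend on ω, the procedure iterates
from ω = 1 to convergence (tolerance 10⁻⁶ on dN and dS, cap 100
iterations; non-convergence is reported, not raised). Against the
generative model the estimator's mean ω̂ is within a few percent of
truth across ω ∈ {0.1, 0.5, 1.0} (see `analysis/02_estimator_recovery.py`),
and it agrees with NG86 to ≈1% when κ = 1 and codon usage is uniform —
the limit in which the two schemes coincide.

## Alignment and filtering

The paper-scale workflow aligns orthologs with an external multiple
aligner and trims with a conserved-block tool; for pairwise data this
package uses a deterministic global protein alignment (Needleman–Wunsch,
BLOSUM62, gap open −10, extend −0.5, via Biopython's PairwiseAligner)
back-translated to codons, so gaps are whole codons and results are
fully reproducible. Gap stripping removes every column with a gap in
either sequence. The divergent-segment filter is a two-sequence analogue
of conserved-block trimming, where conservation degenerates to identity:
a codon column is dropped when the amino-acid identity of its 12-column
window falls below 0.5 or when it lies in a run of more than 8
consecutive mismatched columns, and surviving blocks shorter than 10
columns are dropped too. All three parameters are configurable and the
filter can be disabled; the ≥33-codon length filter is applied *after*
filtering (the stricter reading).

## Expression and sex-bias classification

FPKM = counts × 10⁹ / (library size × CDS length), with library size the
per-sample column sum over the CDS set (reads are assumed mapped to CDS,
not the genome) and no pseudocounts. Replicate concordance is Spearman's
ρ with a QC warning below 0.91. Tissue values are arithmetic means of
replicate FPKM.

The differential-expression test is a negative-binomial Wald test:
median-of-ratios size factors; gene-wise method-of-moments dispersions
from within-group variance; a robust a₀ + a₁/μ mean–dispersion trend;
and shrinkage of gene-wise values toward the trend with a prior weight
of 10 pseudo-degrees-of-freedom (with 2 + 2 replicates the gene-wise
estimate has ~2 df, so the trend dominates, as it must). The Wald
statistic is the log ratio of normalised group means (stabilised with
+0.5) over its delta-method standard error. On null simulations the
p < 0.05 rate is ≈0.05; planted 8-fold changes at moderate depth are
detected essentially always. This approximates, and does not reproduce
bit-for-bit, the shrinkage DE packages used on the real data.

A gene is sex-biased for a contrast iff fold ≥ 2 (computed on tissue
*averages*, ≥ is inclusive, zero denominators count as infinite fold),
p < 0.05 (unadjusted, matching the original analysis; BH correction is
available behind a flag), and the larger tissue average is ≥ 1 FPKM.
Everything else is unbiased; classes are exhaustive and exclusive per
contrast, and a gene may be biased in both contrasts at once.

## Chromosome-level statistics

Strata are X vs pooled autosomes (LG2–LG10), with unmapped genes pooled
into the autosome side by default (configurable), crossed with the seven
sex-bias classes plus "all genes". Genes with undefined ω (dS = 0) are
excluded from ω summaries and counted. Medians carry percentile-bootstrap
95% CIs with 1,000 replicates; the RNG protocol is part of the contract:
`numpy.random.Generator` (PCG64) seeded per stratum, one
`integers(0, n, size=n)` index draw per replicate, in order. Mann–Whitney
U is exact by full enumeration when min(n) ≤ 8 and the pooled sample has
no ties, otherwise the tie-corrected normal approximation with
continuity correction. The 2×2 composition test is χ² with Yates'
continuity correction; direction tests are exact two-sided binomial sign
tests. All ratios are computed from unrounded statistics.

Dosage ratios use, for the autosomal side, the median of the nine
per-autosome medians by default ("median_of_medians", with pooled genes
as an alternative); MWU p-values always compare pooled gene-level
distributions, and unmapped genes are excluded from dosage analyses.
Note that within-tissue ratios (X_Ts/A_Ts) cancel library size exactly,
whereas between-tissue ratios (X_Ts/X_Ov) inherit library-composition
effects of FPKM normalisation — recovery tests therefore rely on the
within-tissue ratios. Expression breadth counts tissues with average
FPKM strictly greater than 1.

## The expression generator, and what recovery tests can show

`simulate_expression` plants, per gene: a chromosome (X with probability
0.056, matching the small X of the motivating genome; otherwise uniform
over LG2–LG10); a gonad class (ovary-biased with probability 0.54 on X
vs 0.16 on autosomes — the observed enrichment regime — testis-biased
0.12); a GT-soma class (5% each direction); a lognormal baseline mean
(µ = 5, σ = 1.5 in log space); and negative-binomial counts with
dispersion 0.05 for 2 replicates × 4 tissues. Bias is planted as a
symmetric geometric split (favoured tissue × √fold, disfavoured ÷ √fold,
default fold 8 — strong, unambiguous bias), so a biased gene's overall
level stays at baseline. The male-X dosage factor multiplies X-linked
means in male tissues (TS, GTM). The truth table records the planted
labels *and* the true post-dosage means.

Two interactions matter when interpreting recovery tests. First, with
more than half of X-linked genes ovary-biased, the X chromosome's
tissue medians necessarily carry a composition effect — the all-genes
X_Ts/A_Ts under a 0.4 dosage factor lands well below 0.4, just as the
real data's testis ratio conflates composition and dosage. The dosage
factor itself is recovered on the planted-unbiased subset, where it is
the only male/female asymmetry. Second, a dosage factor below 0.5 *is*
a ≥2-fold ovary-ward shift for X-linked genes whose label was planted
"unbiased": by the classifier's own definition such genes are truly
ovary-biased, so classifier recovery is judged against the class implied
by the true means, not the planted label. Both effects are features of
the biology being emulated, not artifacts.

What the generator does not emulate: mapping ambiguity, GC or length
biases, isoform mixtures, correlated genes, batch effects, or library
composition beyond what planted fold changes induce. Passing recovery
tests therefore validates the pipeline's arithmetic and statistical
calibration under its stated model — not robustness to the full
messiness of real RNA-seq.

## Fixture bundle and similarity scores

`emit_fixture_bundle` writes species-A/B CDS FASTA (framed with ATG and
a terminal stop), the gene map, counts, truth, and forward/reverse
12-column tabular hit files. Similarity e-values and bit scores are
deterministic surrogates, monotone in alignment identity and length —
no search engine is run (running one is explicitly out of scope).
Decoy hits are shuffled-codon derivatives whose scores are strictly
weaker than the true pair's, or, optionally, share the true hit's
e-value with a lower bit score to exercise the bit-score tie-break.
Identical seeds give byte-identical bundles.

## Problem sizes

Validation runs use 200 replicate pairs per ω condition (300 codons),
100 pairs for the κ = 1 agreement check, 5,000 genes for calibration,
1,000 datasets × 1,000 resamples for bootstrap coverage, and a pooled
20-seed × 500-gene slow-X study; these sizes make each headline quantity's
Monte-Carlo error small relative to the effects being recovered while
keeping a full rerun around a minute on one CPU.

## Known limitations

- The YN00-style estimator simplifies the original's HKY-based distance
  correction to K80 per difference class; residual bias is ≲5% over the
  tested regime but grows with extreme codon-usage skew.
- The NB Wald test with two replicates leans heavily on the dispersion
  trend; genes with genuinely outlying dispersion are anticonservative.
- The pairwise block filter is an identity heuristic; it does not
  reproduce any specific external trimming tool's output.
- dS = 0 pairs are excluded from ω summaries (configurable); with very
  short alignments this can bias stratum medians downward.
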