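# fasterx

Chromosome-level molecular evolution and expression analysis for a pair of
congeneric species with an X/Y (or X/0) sex-determination system. The
package asks the classic *faster-X* question — do X-linked protein-coding
genes evolve faster than autosomal ones? — and connects the answer to
sex-biased gene expression and X-chromosome dosage compensation, the two
forces expected to modulate selection on the hemizygous X.

It was built for transcriptome-scale beetle data (gonads plus
gonadectomised male and female soma, two replicates each, with orthologs
called between two sister species), but every stage is generic: any two
CDS sets, any 12-column tabular similarity search output, and any
per-gene read-count matrix with the four-tissue replicated design will
do. A synthetic-data generator produces all of these inputs with known
ground truth, so the entire pipeline is testable without downloading
anything.

## What it computes

1. **Orthologs** — CDS validity filtering (ATG start, no ambiguous
   bases, no internal stops, ≥33 aa, longest CDS per gene) and
   reciprocal-best-hit pairing from forward/reverse similarity searches
   (e-value < 10⁻⁶, ties broken by bit score).
2. **Pairwise dN/dS** — protein-guided codon alignment, gap stripping
   and divergent-segment masking, then either Nei–Gojobori (1986)
   counting or a Yang–Nielsen (2000)-style estimator
   (F3×4 codon frequencies, κ from fourfold-degenerate and
   nondegenerate sites, κ/frequency/ω-weighted pathway counting,
   K80-type corrections, iterated to convergence). Pairs are retained
   when dN < 1.5, dS < 1.5 and the filtered alignment is ≥33 codons.
3. **Sex-biased expression** — FPKM from counts (library = column sum
   over the CDS set), replicate QC (Spearman ρ), tissue averaging, an
   in-package negative-binomial Wald test, and the three-way
   classification: biased iff fold ≥ 2, p < 0.05 and max tissue average
   ≥ 1 FPKM, separately for the gonad (TS vs OV) and GT-soma
   (GTM vs GTF) contrasts.
4. **X vs autosomes** — per-stratum median dN/dS with 1,000-replicate
   percentile-bootstrap CIs, X/A ratios of medians, Mann–Whitney U
   tests (exact when min(n) ≤ 8 without ties), Yates-corrected χ² for
   class-composition tables, exact sign tests, per-chromosome median
   FPKM, the eight dosage ratios (X_Ts/A_Ts, X_Ov/A_Ov, …), and
   expression breadth (tissues with >1 FPKM).

## Worked example

Simulate a "slow-X" species pair — X-linked ω multiplied by 0.7, male-X
dosage factor 0.4, ovary-bias enrichment on the X — and run everything:

```
$ fasterx run-all --out-dir results/demo --seed 11 --n-genes 500 \
      --x-omega-multiplier 0.7 --male-x-dosage-factor 0.4
manifest: results/demo/manifest.json
X/A_dN/dS(all genes)    0.7295
X/A_dN/dS(ovary-biased) 0.8054
X_Ts/A_Ts               0.1474
X_Ov/A_Ov               1.137
...
```

The first two numbers are ratios of median dN/dS between X-linked and
pooled-autosomal genes: values below 1 mean the X evolves *slower* —
the planted 0.7 multiplier is recovered, i.e. no faster-X effect. The
dosage ratios compare median expression: testis expression of X-linked
genes is far below autosomal levels (no dosage compensation in the male
germ line, amplified here by the planted ovary-bias concentration on
the X), while ovary expression is mildly elevated. Per-stage tables
(`orthologs.tsv`, `dnds.tsv`, `calls_gonad.tsv`, `xa_summaries.tsv`,
`dosage_ratios.tsv`, …) land next to the manifest.

The numbered scripts under `analysis/` run the same machinery as a
narrative study: `01_simulate_fixtures.py` (inputs), 
`02_estimator_recovery.py` (estimator validation),
`03_slowx_pipeline.py` (multi-seed pooled slow-X study) and
`04_null_calibration.py` (test calibration), each writing its table
under `results/`.

## Real-data mode

Point the stages at your own files instead of simulating: `fasterx
orthologs --fwd fwd.tsv --rev rev.tsv`, `fasterx align-dnds --cds-a
A.fa --cds-b B.fa --pairs pairs.tsv --method yn00`, `fasterx fpkm`,
`fasterx classify`, or a single `fasterx run-all --config run.yaml
--no-simulate` with paths in the config. Input formats are plain FASTA,
TSV and 12-column tabular search output; see `docs/methods.md` for
conventions, parameter defaults and caveats.
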