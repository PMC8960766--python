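# Methods

## Coordinate substrate

All computation runs on one transcript per gene — the one with the
longest genomic span, ties broken by lexicographically smallest
transcript id. Internally coordinates are 0-based half-open; GTF I/O
(1-based inclusive) converts exactly at the boundary. Introns are the
gaps between consecutive exons, indexed 5′→3′ in transcription
direction; each carries its distance from its 3′ end to the transcript's
polyA site (on the minus strand, from the intron's genomic start to the
transcript's genomic start). Genes with no intron are excluded from all
splicing indices: the GSI is undefined when the exon set equals the
transcript span.

## Counting

Reads come from a strand-specific library; the default orientation is
`reverse` (dUTP-style: read strand opposite the transcript, mates of a
pair flipped). Junction classification per intron:

- **EE** — a splice gap (CIGAR `N`) matching the intron exactly.
  Deletions (`D`) are treated as contiguous coverage so short deletions
  cannot masquerade as junctions. Gaps matching no annotated intron are
  logged as novel junctions and not counted.
- **EI / IE** — one aligned block crossing the donor / acceptor boundary
  with at least `min_overhang` bases (default 6 bp) on each side. A read
  may hit several introns but contributes at most one category per
  intron; the rare block spanning a whole intron counts once, as EI.

Coverage counting runs three independent passes (exons, introns,
pre-mRNA span): a read counts toward every feature its aligned blocks
overlap on the correct strand, so boundary-straddling reads count in
both the exon and the intron pass, matching the behaviour of standard
overlap counters run once per feature type. RPKM uses the number of
mapped reads in the stream as the per-million denominator unless a
library size is supplied. Multi-mapped reads are assumed removed
upstream; paired mates count as independent reads unless callers
pre-filter.

## Indices

Formulas as in the README. Undefined values propagate as NaN, never 0
(0 is the meaningful "fully unspliced" value). `ISI_c` is not clipped at
0 — intron-denser-than-exon cases are real and clipping would bias the
variance analyses. Deciles (polyA distance, GSI, length, expression) are
rank-based with stable tie-breaking, so any monotone transform of the
variable gives the same assignment and decile sizes differ by at most
one. The polyA profile orders decile 1 nearest the polyA site and
records that convention in its output; per-decile p-values are Welch
t-tests against decile 1.

### Within-gene variance test

Genes with ≥2 defined ISI values contribute one observed variance each.
The reference distribution permutes the pooled ISI values across introns
while preserving every gene's intron count (sampling without
replacement), 199 permutations by default, seed recorded. Two p-values
are reported. The descriptive `p_value` is the conventional unpaired
t-test between observed and permuted variance distributions; because
both are built from the same value pool they are positively dependent
and this test is conservative under the null (its measured null
rejection rate is ~0). The decision-grade `p_perm` is the rank of the
observed mean within-gene variance in the permutation distribution of
that mean — exactly calibrated by construction (verified at 5.4%
rejection over 1000 null datasets at α = 0.05) and one-sided in the
scientifically relevant direction (coordination = smaller within-gene
variance).

## Splice-site strength

Site strength is the log2 odds of a window under a maximum-entropy
sequence model against background composition. The model constrains the
distribution to the training set's adjacent-pair (and hence
single-position) marginals; the maxent distribution under these
constraints is exactly the first-order Markov chain implied by the pair
tables, which keeps the 23-nt acceptor window as cheap as the 9-nt
donor. Pair tables are made chain-consistent at fit time so the closed
form is a proper distribution; the test suite confirms the closed form
against an independent iterative-proportional-fitting fit over the full
9-mer space to 10⁻¹⁴. Windows: donor = last 3 exonic + first 6 intronic
bases, acceptor = last 20 intronic + 3 exonic bases, on the transcribed
strand; windows containing N are skipped, not imputed; non-GT/AG introns
are flagged but still scored. First and last introns are excluded from
per-gene means (their splicing is dominated by coupling to capping and
cleavage/polyadenylation). Model files are plain-text YAML with a
checksum; the bundled default models are *synthetic* — fit from
consensus-derived training pools matching the synthetic genome
generator — and are labelled as such in their provenance string.

The GC covariate is the GC fraction of the concatenated exons divided by
that of the concatenated introns (strand-symmetric, so genomic-strand
slices suffice).

## L×E matrix, gradient, regression

The L×E matrix bins genes by length decile × pre-mRNA-level decile and
stores cell means of a chosen statistic plus counts. The gradient field
uses central differences with unit decile spacing on interior cells
(2–9 on each axis), falling back to a flagged one-sided difference at
missing neighbours.

The structural regression is OLS of GSI on log2 gene length, log2
pre-mRNA RPKM, intron number, mean donor/acceptor strength and GC ratio
(length and expression are log2-transformed — they span orders of
magnitude; the transform choice is recorded in the prepared table's
column names). Complete-case analysis with dropped-row counts. Relative
importance is the LMG decomposition — each predictor's R² increment
averaged over all predictor orderings — computed exactly by enumerating
all 2^p subsets (p ≤ 10 enforced); importances sum to total R² by
construction. A forward sweep reproduces the increasing-subset model
series, and length-stratified fits use deciles 1–2 (short) and 9–10
(long).

## Differential analysis

TMM normalization follows the standard procedure exactly: reference
column by 75th count-fraction percentile closest to the mean, 30% trim
on M, 5% on A, inverse-asymptotic-variance weighting, factors rescaled
to geometric mean 1; it agrees with the Bioconductor reference
implementation to 10⁻¹⁰ on constructed matrices.

The moderated two-group model fits per-gene means and pooled residual
variance s² (d residual df), then shrinks variances toward a prior
s₀² with d₀ df estimated by method of moments on log s² (scaled-F
model, trigamma inversion by Newton); the moderated t has d + d₀ df.
The implementation reproduces the reference empirical-Bayes pipeline
(lmFit + eBayes) to 10⁻¹⁴ on a frozen fixture. Deliberate
simplifications: no mean–variance precision weights (with two replicates
per condition the trend is not estimable in a meaningful way) and no
multiple-testing correction in the classification rule — ΔGSI calls use
raw p < 0.05 with |ΔGSI| ≥ 0.5, with a BH-FDR column emitted for
information only. Expression log2FC uses TMM-scaled effective library
sizes and a 0.5 pseudocount, then the same moderated machinery.

## Synthetic data

The generator emulates the statistical structure of a nascent RNA-seq
study of an epithelial line under growth-factor treatment at desk scale:

- gene spans log-normal (default median ~8 kb, clipped to 2–200 kb),
  intron number Poisson-coupled to length (0.6/kb, ≥1), exons 100–250 bp,
  introns ≥150 bp;
- expression λ_g log-normal (σ = 1), optional silent fraction;
- per-gene efficiency θ_g uniform on (0.1, 0.95) with small per-intron
  dispersion (σ_θ = 0.02) and an exponential reduction near the polyA
  site (`polya_decay`, e-folding 20 kb) — less transcription time, less
  splicing;
- depths: coverage 1000 reads/kb at λ = 1 (~50× at 50-bp reads),
  junction depth 50 per intron (about the boundary-crossing depth
  implied by that coverage), Poisson counts throughout;
- mature mRNA ∝ λ_g·θ_g — export proportional to spliced output, the
  simplest link producing the observed positive mature/pre-mRNA vs
  efficiency relation;
- two conditions × two replicates, a configurable gene subset shifted in
  GSI (implemented as a per-intron θ change solved from the density
  model) and/or expression fold change, log-normal replicate noise on λ.

Junction rates are EE ~ Poisson(j·λ·θ) and EI, IE ~ Poisson(j·λ·(1−θ))
each, so the expected junction index equals θ. Junction-spanning reads
belong to the same library as body coverage: each occupies one coverage
slot in each of the two features it overlaps, a feature's coverage
count is max(density draw, junction demand), body reads realise the
remainder, and the pre-mRNA count counts every read once. This makes
the count tables and the SAM emitted by `simulate_reads` exactly
interconvertible — running the junction classifier and feature counter
on the reads reproduces the generating tables identically (the closure
property the test suite asserts) — while coverage stays
density-faithful, so ISI_c recovers θ without boundary-inflation bias
(the demand clipping binds for well under 1% of exons at default
depths). The per-gene expected GSI exported with the ground truth
includes the small pre-mRNA deficit this bookkeeping implies.

What the generator does **not** model: sequencing errors and base
qualities, fragment-size distributions, multi-mapping, overdispersion
beyond Poisson (a negative-binomial stress switch is out of scope),
overlapping genes, alternative isoforms, and positional coverage biases.
Passing tests therefore demonstrate correctness of the statistics under
an idealised read model, not robustness to alignment artefacts in real
libraries.

## Problem sizes

The test suite uses 15–40-gene studies for read-level closure and
end-to-end CLI runs, 300 genes for parameter-recovery and polyA-profile
checks, 200 replicate datasets of 100 genes × 5 introns for variance-
test calibration, and 2000 genes × 4 samples for the differential
benchmark; the full suite runs in well under a minute and
`scripts/acceptance.py` in a few seconds.

## Known limitations

- One transcript per gene: isoform-level splicing and overlapping genes
  are out of scope; reads are assigned per gene without cross-gene
  exclusion.
- The expression filter threshold (default 1 RPKM pre-mRNA) is a
  convention, not derived from data.
- The bundled splice-site models are synthetic; for real genomes, fit
  `fit_maxent_model` on annotated sites or load externally trained
  tables.
- With two replicates per condition the moderated test leans heavily on
  the variance prior; strong per-gene variance heterogeneity would
  weaken its calibration.
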