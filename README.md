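# ctsplice

Quantification of **co-transcriptional splicing (CTS) efficiency** from
nascent RNA-seq.

Chromatin-associated RNA-seq (ChrRNA-seq) captures transcripts still
attached to elongating RNA polymerase II, so the fraction of reads left
in introns measures how much splicing has already happened while the
gene was being transcribed. `ctsplice` is for computational biologists
who have such data (or want to simulate it) and need per-intron and
per-gene splicing-efficiency statistics, the structural models that
explain them, and differential calls between conditions.

## The statistics

Per intron *i* of a gene's longest transcript:

- **Junction-based index**
  `ISI_j = 1 − 0.5(EI+IE) / (0.5(EI+IE) + EE)`
  where `EI`/`IE` count reads crossing the exon–intron / intron–exon
  boundary contiguously (intron retained) and `EE` counts spliced reads
  whose alignment gap matches the intron exactly. 1 = fully spliced.
- **Coverage-based index**
  `ISI_c = 1 − I_i / (0.5 (E_i + E_{i+1}))`
  on RPKM values of the intron and its flanking exons.

Per gene:

- **Gene Splicing Index**
  `GSI = log2[ (Σ reads_exon / Σ len_exon) / (reads_pre-mRNA / len_pre-mRNA) ]`,
  the log-ratio of exonic to whole-pre-mRNA read density; high GSI =
  efficient CTS. Differential GSI between two replicated conditions is
  tested with an empirical-Bayes moderated t and classified
  *increased*/*decreased* when `|ΔGSI| ≥ 0.5` and `p < 0.05`.

Around these sit: a polyA-distance decile profile (introns close to the
polyA site have had less transcription time and splice less), a
within-gene variance test (introns of one gene splice more alike than
random intron sets — a permutation-calibrated comparison), a
maximum-entropy splice-site strength model (9-nt donor and 23-nt
acceptor windows), the exon/intron GC-content ratio, a 10×10 gene-length
× expression (L×E) decile matrix with a finite-difference gradient
field, and an OLS regression of GSI on structural features with an
exact LMG decomposition of R² into per-predictor importances.

A first-class synthetic-data generator (`ctsplice.synthetic_data`)
produces toy genomes, GTF/FASTA/SAM files and count tables with known
per-gene efficiency θ, expression λ, polyA-distance decay and
two-condition effects, so every stage is testable against ground truth.

## Worked example

```python
from ctsplice import synthetic_data as sd, indices

scenario = sd.SyntheticScenario(n_genes=300, seed=42, polya_decay=0.35)
ann = sd.simulate_annotation(scenario)            # toy genome + annotation
counts = sd.simulate_counts(scenario, ann)        # one ChrRNA-seq sample
isi = indices.isi_table(counts.junctions, counts.coverage, ann.transcripts)
gsi = indices.gsi_table(counts.coverage, ann.transcripts)

merged = isi.merge(ann.intron_truth, on=["gene_id", "intron_index"])
print("median |ISI_c - theta|:",
      round((merged.isi_c - merged.theta).abs().median(), 3))
print("mean GSI:", round(gsi.gsi.mean(), 3))
```

prints

```
median |ISI_c - theta|: 0.026
mean GSI: 0.714
```

meaning the coverage index recovers each intron's true splicing
probability to about three percentage points at ~50× exon coverage, and
the average gene converts a log2 density ratio of ~0.7 (genes here are
about 60% spliced co-transcriptionally on average).

The same stages are available from the shell:

```bash
ctsplice simulate --outdir run --seed 17 --n-genes 200 --reads
ctsplice count    --gtf run/annotation.gtf --alignments run/reads.sam --outdir run
ctsplice isi      --gtf run/annotation.gtf --outdir run
ctsplice gsi      --gtf run/annotation.gtf --outdir run
ctsplice features --gtf run/annotation.gtf --fasta run/genome.fa --outdir run
ctsplice regress  --outdir run
```

Every stage appends to `run/manifest.json` (parameters, seeds, input
checksums) so a run can be reproduced bit-exactly.

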