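"""Synthetic nascent RNA-seq data with known ground truth.

Generates toy genomes, annotations, count tables and aligned reads whose
statistical structure mirrors a chromatin-associated RNA-seq study of an
epithelial cell line under a growth-factor treatment: per-gene
transcription levels (log-normal), per-gene mean splicing efficiency
theta with small within-gene dispersion, a decay of splicing probability
for introns close to the polyA site (less transcription time), and a
two-condition x two-replicate design in which a subset of genes shifts
in splicing efficiency and/or expression.

Generative count model, per gene g and intron i (all Poisson):

* exon coverage          ~ Poisson(c * lambda_g * exon_len / 1e3)
* intron coverage        ~ Poisson(c * lambda_g * (1 - theta_gi) * intron_len / 1e3)
* spliced junction EE    ~ Poisson(j * lambda_g * theta_gi)
* retention EI, IE       ~ Poisson(j * lambda_g * (1 - theta_gi)) each
* mature mRNA reads      ~ Poisson(m * lambda_g * f(theta_g) * exon_len / 1e3)

with theta_gi = theta_g reduced by the polyA-distance decay, c the body
coverage rate (reads per kb at lambda=1), j the junction depth and
f(theta) = theta (nuclear export proportional to spliced output, the
simplest link consistent with the observed mature/pre-mRNA behaviour).
Under these rates the expected junction index 1 - (EI+IE)*0.5 /
((EI+IE)*0.5 + EE) and the expected coverage index both equal theta_gi.

Junction-spanning reads are part of the same library as body coverage:
each junction read occupies one coverage slot in each of the two
features it overlaps (an EI read covers exon i and intron i, an EE read
both flanking exons), so a feature's coverage count is
max(density draw, junction demand) and body reads realise the
remainder.  ``simulate_reads`` emits literal SAM records with exactly
this geometry, so the read-level pipeline (classify + count) reproduces
the generating tables identically — the closure property the
test-suite leans on.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import TranscriptModel, build_transcript_model

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")

# splice-site consensus (transcribed strand): donor window = 3 exonic +
# 6 intronic bases, acceptor window = 20 intronic + 3 exonic bases
DONOR_CONSENSUS = "CAGGTAAGT"
ACCEPTOR_CONSENSUS = "TTTTTTTTTTTTTTTTTCAGGTC"


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study; the seed fully determines output."""

    n_genes: int = 300
    seed: int = 0
    # gene structure
    gene_length_log2_mean: float = 13.0   # ~8 kb median span
    gene_length_log2_sd: float = 1.2
    min_gene_length: int = 2_000
    max_gene_length: int = 200_000
    introns_per_kb: float = 0.6
    max_introns: int = 40
    min_intron_length: int = 150
    exon_length_range: tuple[int, int] = (100, 250)
    # sequence composition
    exon_gc: float = 0.52
    intron_gc: float = 0.42
    gc_jitter: float = 0.04
    donor_match_prob: float = 0.9         # per-position consensus match rate
    acceptor_match_prob: float = 0.9
    # expression and splicing efficiency
    expression_log_sd: float = 1.0        # lambda_g ~ LogNormal(0, sd)
    fraction_silent: float = 0.0
    theta_range: tuple[float, float] = (0.1, 0.95)
    sigma_theta: float = 0.02             # within-gene dispersion of theta_gi
    polya_decay: float = 0.0              # delta: max fractional loss near polyA
    polya_decay_scale: float = 20_000.0   # bp e-folding of the decay
    # sequencing depth
    coverage_reads_per_kb: float = 1_000.0  # ~50x at 50 bp reads, lambda=1
    junction_depth: float = 50.0          # ~boundary-crossing depth at 50x
    mature_reads_per_kb: float = 1_000.0
    read_length: int = 50
    # two-condition design
    n_replicates: int = 2
    effect_fraction: float = 0.1
    gsi_shift: float = -0.8               # additive shift on log2 GSI scale
    expression_log2fc: float = 0.0
    replicate_lambda_sd: float = 0.05     # log-scale replicate noise on lambda
    replicate_theta_sd: float = 0.0       # replicate noise on theta (logit-free, clipped)
    # layout
    chrom_capacity: int = 8_000_000
    intergenic_gap: int = 2_000

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("exon_length_range", "theta_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)


@dataclass
class SyntheticAnnotation:
    """Toy genome + annotation + per-gene generative truth."""

    transcripts: dict[str, TranscriptModel]
    chromosomes: dict[str, str]
    truth: pd.DataFrame                   # per-gene theta, lambda, silent, ...
    intron_truth: pd.DataFrame            # per-intron theta_gi, expected ISI

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        from .annotation import write_gtf

        write_gtf(self.transcripts.values(), path)


def _sample_consensus(rng: np.random.Generator, consensus: str,
                      match_prob: float) -> str:
    out = []
    for base in consensus:
        if rng.random() < match_prob:
            out.append(base)
        else:
            out.append(str(rng.choice(_BASES)))
    return "".join(out)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _intron_theta(theta_g: float, dist_polya: float,
                  scenario: SyntheticScenario,
                  rng: np.random.Generator | None = None) -> float:
    """Per-intron efficiency: gene mean, polyA-proximity decay, dispersion."""
    decay = scenario.polya_decay * math.exp(-dist_polya / scenario.polya_decay_scale)
    theta = theta_g * (1.0 - decay)
    if rng is not None and scenario.sigma_theta > 0:
        theta += rng.normal(0.0, scenario.sigma_theta)
    return float(np.clip(theta, 1e-3, 1.0))


def simulate_annotation(
    scenario: SyntheticScenario, seed: int | None = None
) -> SyntheticAnnotation:
    """Build a toy genome and annotation realising the scenario.

    Genes are placed left to right on synthetic chromosomes with fixed
    intergenic gaps (never overlapping), alternate strands, and carry
    splice-site windows drawn from the donor/acceptor consensus pools at
    the scenario's match probability.  Exon and intron GC contents are
    controlled per gene.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    transcripts: dict[str, TranscriptModel] = {}
    chrom_parts: dict[str, list[str]] = {}
    chrom_pos: dict[str, int] = {}
    chrom_idx = 1

    n = scenario.n_genes
    lengths = np.clip(
        2.0 ** rng.normal(scenario.gene_length_log2_mean,
                          scenario.gene_length_log2_sd, n),
        scenario.min_gene_length, scenario.max_gene_length,
    )
    lambdas = np.exp(rng.normal(0.0, scenario.expression_log_sd, n))
    silent = rng.random(n) < scenario.fraction_silent
    lambdas = np.where(silent, 0.0, lambdas)
    lo, hi = scenario.theta_range
    thetas = rng.uniform(lo, hi, n)

    truth_rows, intron_rows = [], []
    for g in range(n):
        gene_id = f"gene{g + 1:04d}"
        target_len = float(lengths[g])
        if scenario.introns_per_kb <= 0:
            n_introns = 0
        else:
            mu = max(scenario.introns_per_kb * target_len / 1e3, 1.0)
            n_introns = int(
                np.clip(rng.poisson(mu), 1, scenario.max_introns)
            )
        elo, ehi = scenario.exon_length_range
        exon_lens = rng.integers(elo, ehi + 1, n_introns + 1)
        budget = target_len - exon_lens.sum()
        min_intron = scenario.min_intron_length
        extra = max(budget - min_intron * n_introns, 0.0)
        weights = rng.dirichlet(np.ones(n_introns))
        intron_lens = (min_intron + np.floor(weights * extra)).astype(int)
        strand = "+" if g % 2 == 0 else "-"

        # sequence in transcription orientation
        exon_gc = float(np.clip(
            scenario.exon_gc + rng.normal(0.0, scenario.gc_jitter), 0.2, 0.8))
        intron_gc = float(np.clip(
            scenario.intron_gc + rng.normal(0.0, scenario.gc_jitter), 0.2, 0.8))
        segments = []
        for i in range(n_introns + 1):
            segments.append(_random_seq(rng, int(exon_lens[i]), exon_gc))
            if i < n_introns:
                segments.append(_random_seq(rng, int(intron_lens[i]), intron_gc))
        # overwrite splice-site windows with consensus-pool draws
        for i in range(n_introns):
            donor = _sample_consensus(rng, DONOR_CONSENSUS,
                                      scenario.donor_match_prob)
            acceptor = _sample_consensus(rng, ACCEPTOR_CONSENSUS,
                                         scenario.acceptor_match_prob)
            ex_up, intr, ex_dn = segments[2 * i], segments[2 * i + 1], segments[2 * i + 2]
            segments[2 * i] = ex_up[:-3] + donor[:3]
            intr = donor[3:9] + intr[6:]
            segments[2 * i + 1] = intr[:-20] + acceptor[:20]
            segments[2 * i + 2] = acceptor[20:] + ex_dn[3:]
        gene_seq_tx = "".join(segments)
        gene_len = len(gene_seq_tx)

        # place on chromosome
        chrom = f"chrS{chrom_idx}"
        if chrom_pos.get(chrom, 0) + gene_len + scenario.intergenic_gap \
                > scenario.chrom_capacity:
            chrom_idx += 1
            chrom = f"chrS{chrom_idx}"
        parts = chrom_parts.setdefault(chrom, [])
        pos = chrom_pos.get(chrom, 0)
        parts.append(_random_seq(rng, scenario.intergenic_gap, 0.4))
        start = pos + scenario.intergenic_gap
        genomic_seq = gene_seq_tx if strand == "+" else _revcomp(gene_seq_tx)
        parts.append(genomic_seq)
        chrom_pos[chrom] = start + gene_len

        # exon coordinates: walk transcription order, map to genomic
        exon_coords_tx = []
        off = 0
        for i in range(n_introns + 1):
            exon_coords_tx.append((off, off + int(exon_lens[i])))
            off += int(exon_lens[i])
            if i < n_introns:
                off += int(intron_lens[i])
        if strand == "+":
            exon_coords = [(start + s, start + e) for s, e in exon_coords_tx]
        else:
            exon_coords = [
                (start + gene_len - e, start + gene_len - s)
                for s, e in exon_coords_tx
            ]
        tx = build_transcript_model(
            gene_id, f"{gene_id}.t1", chrom, strand, exon_coords
        )
        transcripts[gene_id] = tx

        theta_g = float(thetas[g])
        for intron in tx.introns:
            theta_gi = _intron_theta(theta_g, intron.dist_polya, scenario, rng)
            intron_rows.append(
                {
                    "gene_id": gene_id,
                    "intron_index": intron.index,
                    "theta": theta_gi,
                    "dist_polya": intron.dist_polya,
                    "expected_isi": theta_gi,
                }
            )
        exon_total = int(exon_lens.sum())
        intron_thetas = (
            [r["theta"] for r in intron_rows[-n_introns:]] if n_introns else []
        )
        unspliced_len = exon_total + sum(
            (1.0 - t) * le for t, le in zip(intron_thetas, intron_lens)
        )
        # junction reads occupy coverage slots in two features but count once
        # in premRNA; the expected pipeline GSI reflects that small deficit
        junc_adjust = (
            1e3 * scenario.junction_depth / scenario.coverage_reads_per_kb
            * sum(2.0 - t for t in intron_thetas)
        )
        expected_gsi = math.log2(
            gene_len / max(unspliced_len - junc_adjust, 1.0)
        )
        truth_rows.append(
            {
                "gene_id": gene_id,
                "theta": theta_g,
                "lambda": float(lambdas[g]),
                "silent": bool(silent[g]),
                "gene_length": gene_len,
                "exon_length_total": exon_total,
                "n_introns": n_introns,
                "strand": strand,
                "exon_gc": exon_gc,
                "intron_gc": intron_gc,
                "expected_gsi": expected_gsi,
            }
        )

    chromosomes = {c: "".join(p) for c, p in chrom_parts.items()}
    return SyntheticAnnotation(
        transcripts=transcripts,
        chromosomes=chromosomes,
        truth=pd.DataFrame(truth_rows),
        intron_truth=pd.DataFrame(intron_rows),
    )


# ---------------------------------------------------------------------------
# Count-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCounts:
    """One sample's count tables plus the drawn per-intron body counts."""

    junctions: pd.DataFrame     # gene_id, intron_index, EI, IE, EE
    coverage: pd.DataFrame      # gene_id, feature, raw_count, length_bp, rpkm
    mature: pd.DataFrame        # gene_id, mature_count, mature_rpkm
    library_size: int
    body_counts: dict = field(repr=False, default_factory=dict)


def simulate_counts(
    scenario: SyntheticScenario,
    ann: SyntheticAnnotation,
    seed: int | None = None,
    lambda_scale: pd.Series | None = None,
    theta_override: pd.DataFrame | None = None,
) -> SyntheticCounts:
    """Draw junction + coverage + mature count tables for one sample.

    ``lambda_scale`` (indexed by gene_id) multiplies each gene's
    expression — used for replicate noise and condition fold changes.
    ``theta_override`` (gene_id, intron_index, theta) replaces per-intron
    efficiencies — used for condition effects on splicing.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    lam = ann.truth.set_index("gene_id")["lambda"].copy()
    if lambda_scale is not None:
        lam = lam * lambda_scale.reindex(lam.index).fillna(1.0)
    thetas = ann.intron_truth.set_index(["gene_id", "intron_index"])["theta"]
    if theta_override is not None:
        ov = theta_override.set_index(["gene_id", "intron_index"])["theta"]
        thetas = ov.combine_first(thetas)

    jrows = []
    body: dict[tuple[str, str], int] = {}
    cov_rows = []
    mature_rows = []
    mature_total = 0
    total_reads = 0
    gene_truth = ann.truth.set_index("gene_id")
    for gene_id, tx in ann.transcripts.items():
        lg = float(lam[gene_id])
        n_int = tx.n_introns
        cov_exon, cov_intron = {}, {}
        for exon in tx.exons:
            mu = scenario.coverage_reads_per_kb * lg * exon.length / 1e3
            cov_exon[exon.rank] = int(rng.poisson(mu))
        ee_d, ei_d, ie_d = {}, {}, {}
        for intron in tx.introns:
            th = float(thetas[(gene_id, intron.index)])
            mu = (scenario.coverage_reads_per_kb * lg * (1.0 - th)
                  * intron.length / 1e3)
            cov_intron[intron.index] = int(rng.poisson(mu))
            ee_d[intron.index] = int(
                rng.poisson(scenario.junction_depth * lg * th))
            ei_d[intron.index] = int(
                rng.poisson(scenario.junction_depth * lg * (1.0 - th)))
            ie_d[intron.index] = int(
                rng.poisson(scenario.junction_depth * lg * (1.0 - th)))
            jrows.append(
                {"gene_id": gene_id, "intron_index": intron.index,
                 "EI": ei_d[intron.index], "IE": ie_d[intron.index],
                 "EE": ee_d[intron.index]}
            )
        # junction reads occupy coverage slots of the features they overlap;
        # a feature's coverage cannot be below its junction demand
        gene_reads = 0
        for exon in tx.exons:
            r = exon.rank
            demand = (ei_d.get(r, 0) + ee_d.get(r, 0)
                      + ie_d.get(r - 1, 0) + ee_d.get(r - 1, 0))
            cov = max(cov_exon[r], demand)
            body[(gene_id, f"exon_{r}")] = cov - demand
            cov_rows.append((gene_id, f"exon_{r}", cov, exon.length))
            gene_reads += cov - demand
        for intron in tx.introns:
            i = intron.index
            demand = ei_d[i] + ie_d[i]
            cov = max(cov_intron[i], demand)
            body[(gene_id, f"intron_{i}")] = cov - demand
            cov_rows.append((gene_id, f"intron_{i}", cov, intron.length))
            gene_reads += cov - demand
        n_junc = sum(ee_d.values()) + sum(ei_d.values()) + sum(ie_d.values())
        gene_reads += n_junc
        cov_rows.append((gene_id, "premRNA", gene_reads, tx.gene_length))
        total_reads += gene_reads

        theta_g = float(gene_truth.loc[gene_id, "theta"])
        exon_len = sum(e.length for e in tx.exons)
        mu_m = scenario.mature_reads_per_kb * lg * theta_g * exon_len / 1e3
        cnt = int(rng.poisson(mu_m))
        mature_rows.append(
            {"gene_id": gene_id, "mature_count": cnt, "exon_length": exon_len}
        )
        mature_total += cnt

    junctions = pd.DataFrame(
        jrows, columns=["gene_id", "intron_index", "EI", "IE", "EE"]
    )
    from .counting import rpkm as _rpkm

    lib = max(total_reads, 1)
    coverage = pd.DataFrame(
        cov_rows, columns=["gene_id", "feature", "raw_count", "length_bp"]
    )
    coverage["rpkm"] = [
        _rpkm(c, le, lib)
        for c, le in zip(coverage["raw_count"], coverage["length_bp"])
    ]
    coverage["library_size"] = lib
    mature = pd.DataFrame(mature_rows)
    mlib = max(mature_total, 1)
    mature["mature_rpkm"] = [
        _rpkm(c, le, mlib)
        for c, le in zip(mature["mature_count"], mature["exon_length"])
    ]
    return SyntheticCounts(
        junctions=junctions, coverage=coverage, mature=mature,
        library_size=lib, body_counts=body,
    )


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    scenario: SyntheticScenario,
    ann: SyntheticAnnotation,
    counts: SyntheticCounts,
    sam_path: str | Path,
    seed: int | None = None,
    min_overhang: int = 6,
) -> None:
    """Write SAM records realising ``counts`` exactly.

    * EE reads: two anchor blocks confined to the flanking exons with an
      N gap spanning the intron precisely.
    * EI / IE reads: one contiguous block crossing the donor / acceptor
      boundary with >= ``min_overhang`` bases on each side, confined to
      the adjacent exon and intron.
    * body reads: contiguous, fully inside their feature.

    The library is reverse-stranded: read strand opposite the transcript.
    Running the junction classifier and feature counter on the output
    reproduces the generating tables.
    """
    import pysam

    rng = np.random.default_rng(scenario.seed + 2 if seed is None else seed)
    rl = scenario.read_length
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)}
            for name, seq in ann.chromosomes.items()
        ],
    }
    jc = counts.junctions.set_index(["gene_id", "intron_index"])
    n_read = 0
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        ref_ids = {name: i for i, name in enumerate(ann.chromosomes)}

        def emit(chrom: str, strand: str, start: int, cigar, name: str):
            nonlocal n_read
            a = pysam.AlignedSegment()
            a.query_name = f"{name}_{n_read}"
            n_read += 1
            length = sum(ln for op, ln in cigar if op in (0, 1, 4))
            a.query_sequence = "A" * length
            a.reference_id = ref_ids[chrom]
            a.reference_start = start
            a.cigartuples = cigar
            a.mapping_quality = 60
            a.flag = 16 if strand == "+" else 0  # reverse-stranded library
            out.write(a)

        for gene_id, tx in ann.transcripts.items():
            for exon in tx.exons:
                cnt = counts.body_counts.get((gene_id, f"exon_{exon.rank}"), 0)
                ln = min(rl, exon.length)
                for _ in range(cnt):
                    s = int(rng.integers(exon.start, exon.end - ln + 1))
                    emit(tx.chrom, tx.strand, s, [(0, ln)], f"{gene_id}_body")
            for intron in tx.introns:
                cnt = counts.body_counts.get(
                    (gene_id, f"intron_{intron.index}"), 0)
                ln = min(rl, intron.length)
                for _ in range(cnt):
                    s = int(rng.integers(intron.start, intron.end - ln + 1))
                    emit(tx.chrom, tx.strand, s, [(0, ln)], f"{gene_id}_body")

                row = jc.loc[(gene_id, intron.index)]
                up = tx.exons[intron.index - 1]     # exon i (transcription order)
                dn = tx.exons[intron.index]         # exon i+1
                half = max(min_overhang, rl // 2)
                a_up = min(half, up.length)
                a_dn = min(half, dn.length)
                o_in = min(half, intron.length - 1)
                if tx.strand == "+":
                    donor, acceptor = intron.start, intron.end
                    for _ in range(int(row["EE"])):
                        emit(tx.chrom, "+", donor - a_up,
                             [(0, a_up), (3, intron.length), (0, a_dn)],
                             f"{gene_id}_EE")
                    for _ in range(int(row["EI"])):
                        emit(tx.chrom, "+", donor - a_up,
                             [(0, a_up + o_in)], f"{gene_id}_EI")
                    for _ in range(int(row["IE"])):
                        emit(tx.chrom, "+", acceptor - o_in,
                             [(0, o_in + a_dn)], f"{gene_id}_IE")
                else:
                    donor, acceptor = intron.end, intron.start
                    for _ in range(int(row["EE"])):
                        emit(tx.chrom, "-", acceptor - a_dn,
                             [(0, a_dn), (3, intron.length), (0, a_up)],
                             f"{gene_id}_EE")
                    for _ in range(int(row["EI"])):
                        emit(tx.chrom, "-", donor - o_in,
                             [(0, o_in + a_up)], f"{gene_id}_EI")
                    for _ in range(int(row["IE"])):
                        emit(tx.chrom, "-", acceptor - a_dn,
                             [(0, a_dn + o_in)], f"{gene_id}_IE")


# ---------------------------------------------------------------------------
# Two-condition design
# ---------------------------------------------------------------------------

def _delta_theta_for_gsi_shift(
    ann: SyntheticAnnotation, gene_id: str, shift: float
) -> float:
    """Uniform per-intron efficiency change moving expected GSI by ``shift``.

    Expected GSI under the density model is log2(L / U) with unspliced
    length U = Lex + sum_i (1 - theta_i) * L_i; shifting every intron's
    theta by d changes U to U - d * Lint, so d = U * (1 - 2^-shift) / Lint.
    """
    tx = ann.transcripts[gene_id]
    L = tx.gene_length
    Lex = sum(e.length for e in tx.exons)
    Lint = L - Lex
    thetas = ann.intron_truth.loc[
        ann.intron_truth["gene_id"] == gene_id
    ].set_index("intron_index")["theta"]
    U = Lex + sum(
        (1.0 - thetas[i.index]) * i.length for i in tx.introns
    )
    return float(U * (1.0 - 2.0 ** (-shift)) / Lint)


@dataclass
class TwoConditionDataset:
    """Counts for every (condition, replicate) sample plus ground truth."""

    samples: dict[tuple[str, int], SyntheticCounts]
    design: pd.DataFrame                  # sample, condition, replicate
    truth: pd.DataFrame                   # per-gene effect flags & true shift


def simulate_two_condition(
    scenario: SyntheticScenario,
    ann: SyntheticAnnotation,
    seed: int | None = None,
    conditions: tuple[str, str] = ("vehicle", "treatment"),
) -> TwoConditionDataset:
    """Simulate a replicated two-condition contrast.

    A random ``effect_fraction`` of genes receives the scenario's GSI
    shift (implemented as a change of splicing efficiency theta) and/or
    expression fold change in the treatment condition.  Replicate noise
    multiplies lambda by independent log-normal factors per sample.
    """
    if scenario.n_replicates < 2:
        raise ValueError("need >=2 replicates per condition")
    if not 0 <= scenario.effect_fraction <= 1:
        raise ValueError("effect_fraction must be in [0, 1]")
    base_seed = scenario.seed + 10 if seed is None else seed
    rng = np.random.default_rng(base_seed)
    gene_ids = list(ann.transcripts)
    n_effect = int(round(scenario.effect_fraction * len(gene_ids)))
    effect_genes = set(
        rng.choice(gene_ids, size=n_effect, replace=False).tolist()
    )

    theta_override_rows = []
    intron_theta = ann.intron_truth.set_index(["gene_id", "intron_index"])["theta"]
    for g in sorted(effect_genes):
        if scenario.gsi_shift != 0.0:
            d_theta = _delta_theta_for_gsi_shift(ann, g, scenario.gsi_shift)
            for intron in ann.transcripts[g].introns:
                old = intron_theta.loc[(g, intron.index)]
                theta_override_rows.append(
                    {"gene_id": g, "intron_index": intron.index,
                     "theta": float(np.clip(old + d_theta, 1e-3, 1.0))}
                )
    theta_override = (
        pd.DataFrame(theta_override_rows) if theta_override_rows else None
    )

    samples: dict[tuple[str, int], SyntheticCounts] = {}
    design_rows = []
    for ci, cond in enumerate(conditions):
        for rep in range(1, scenario.n_replicates + 1):
            noise = pd.Series(
                np.exp(rng.normal(0.0, scenario.replicate_lambda_sd,
                                  len(gene_ids))),
                index=gene_ids,
            )
            if ci == 1:
                fc = pd.Series(1.0, index=gene_ids)
                if scenario.expression_log2fc != 0.0:
                    fc[fc.index.isin(effect_genes)] = \
                        2.0 ** scenario.expression_log2fc
                noise = noise * fc
                override = theta_override
            else:
                override = None
            sample_seed = int(rng.integers(0, 2**31 - 1))
            samples[(cond, rep)] = simulate_counts(
                scenario, ann, seed=sample_seed,
                lambda_scale=noise, theta_override=override,
            )
            design_rows.append(
                {"sample": f"{cond}_rep{rep}", "condition": cond,
                 "replicate": rep}
            )

    truth = ann.truth[["gene_id", "theta", "lambda", "silent",
                       "expected_gsi"]].copy()
    truth["is_effect"] = truth["gene_id"].isin(effect_genes)
    truth["true_gsi_shift"] = np.where(
        truth["is_effect"], scenario.gsi_shift, 0.0)
    truth["true_expression_log2fc"] = np.where(
        truth["is_effect"], scenario.expression_log2fc, 0.0)
    return TwoConditionDataset(
        samples=samples, design=pd.DataFrame(design_rows), truth=truth
    )


def simulate_gsi_matrix(
    n_genes: int = 2000,
    n_replicates: int = 2,
    effect_fraction: float = 0.1,
    gsi_shift: float = -0.8,
    noise_sd: float = 0.1,
    baseline_mean: float = 1.5,
    baseline_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Direct GSI-level two-condition benchmark (no count simulation).

    Each gene has a baseline GSI; effect genes shift by ``gsi_shift`` in
    the treatment; independent Gaussian replicate noise of ``noise_sd``
    is added per sample.  Returns (gsi_matrix, design, truth) where the
    matrix columns are samples on the log2 GSI scale.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    n_effect = int(round(effect_fraction * n_genes))
    effect = np.zeros(n_genes, dtype=bool)
    effect[rng.choice(n_genes, size=n_effect, replace=False)] = True
    cols = {}
    design_rows = []
    for cond in ("vehicle", "treatment"):
        for rep in range(1, n_replicates + 1):
            mean = baseline + (gsi_shift * effect if cond == "treatment" else 0.0)
            cols[f"{cond}_rep{rep}"] = mean + rng.normal(0.0, noise_sd, n_genes)
            design_rows.append(
                {"sample": f"{cond}_rep{rep}", "condition": cond,
                 "replicate": rep}
            )
    matrix = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "baseline_gsi": baseline, "is_effect": effect,
         "true_gsi_shift": np.where(effect, gsi_shift, 0.0)}
    )
    return matrix, pd.DataFrame(design_rows), truth


def simulate_isi_table(
    n_genes: int = 100,
    introns_per_gene: int = 5,
    gene_effect: bool = True,
    theta_range: tuple[float, float] = (0.2, 0.9),
    sigma_within: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Lightweight per-intron ISI table for variance-test calibration.

    With ``gene_effect`` the per-gene mean efficiency varies across genes
    and introns scatter tightly around it; without it every intron's ISI
    is an independent draw from the pooled distribution (the iid null).
    """
    rng = np.random.default_rng(seed)
    lo, hi = theta_range
    rows = []
    if gene_effect:
        means = rng.uniform(lo, hi, n_genes)
        for g in range(n_genes):
            vals = np.clip(
                rng.normal(means[g], sigma_within, introns_per_gene), 0.0, 1.0)
            for i, v in enumerate(vals, start=1):
                rows.append({"gene_id": f"g{g + 1:04d}", "intron_index": i,
                             "isi_c": float(v)})
    else:
        total = n_genes * introns_per_gene
        pool = rng.uniform(lo, hi, total)
        k = 0
        for g in range(n_genes):
            for i in range(1, introns_per_gene + 1):
                rows.append({"gene_id": f"g{g + 1:04d}", "intron_index": i,
                             "isi_c": float(pool[k])})
                k += 1
    return pd.DataFrame(rows)
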