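"""Read counting: junction classification and per-feature coverage.

Turns strand-specific alignments (SAM/BAM) into the two count substrates
of the splicing indices:

* per-intron junction counts — ``EE`` spliced reads whose gap matches the
  intron exactly, and ``EI`` / ``IE`` reads crossing the donor / acceptor
  exon boundary contiguously (evidence of intron retention);
* per-feature coverage counts — reads overlapping each exon, intron, and
  the whole pre-mRNA span, counted in three independent passes, with
  RPKM normalisation.

Nascent RNA-seq libraries are typically reverse-stranded; the default
``strand_mode='reverse'`` expects the read strand opposite to the
transcript strand (mates of a pair flip).
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import TranscriptModel

STRAND_MODES = ("forward", "reverse", "unstranded")

# CIGAR operation codes consuming the reference contiguously
_REF_CONSUME_CONTIG = {0, 2, 7, 8}  # M, D, =, X
_REF_SKIP = 3  # N


class CountingError(ValueError):
    pass


def rpkm(raw_count: float, length_bp: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_bp <= 0:
        raise CountingError(f"length_bp must be > 0, got {length_bp}")
    if library_size <= 0:
        raise CountingError(f"library_size must be > 0, got {library_size}")
    return raw_count / (length_bp / 1e3) / (library_size / 1e6)


def _aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Contiguous reference blocks of a read, split only at N (splice) gaps.

    Deletions (D) are treated as contiguous coverage so that a short
    deletion does not masquerade as a junction.
    """
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start
    block_start = pos
    open_block = False
    for op, length in read.cigartuples or []:
        if op in _REF_CONSUME_CONTIG:
            if not open_block:
                block_start = pos
                open_block = True
            pos += length
        elif op == _REF_SKIP:
            if open_block:
                blocks.append((block_start, pos))
                open_block = False
            pos += length
        # insertions / clips consume no reference
    if open_block:
        blocks.append((block_start, pos))
    return blocks


def _read_strand(read: pysam.AlignedSegment) -> str:
    s = "-" if read.is_reverse else "+"
    if read.is_paired and read.is_read2:
        s = "-" if s == "+" else "+"
    return s


def _strand_ok(read_strand: str, feature_strand: str, strand_mode: str) -> bool:
    if strand_mode == "unstranded":
        return True
    if strand_mode == "forward":
        return read_strand == feature_strand
    if strand_mode == "reverse":
        return read_strand != feature_strand
    raise CountingError(f"strand_mode must be one of {STRAND_MODES}")


def _iter_alignments(alignments) -> Iterable[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            for read in fh:
                yield read
    else:
        yield from alignments


def _transcript_tree(
    transcripts: Mapping[str, TranscriptModel],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for tx in transcripts.values():
        trees[tx.chrom].addi(tx.span_start, tx.span_end, tx)
    return dict(trees)


def classify_junction_reads(
    alignments,
    transcripts: Mapping[str, TranscriptModel],
    *,
    strand_mode: str = "reverse",
    min_overhang: int = 6,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify reads into EE / EI / IE junction counts per intron.

    A read is ``EE`` for intron i when one of its splice gaps matches the
    intron's coordinates exactly; ``EI`` (``IE``) when one aligned block
    crosses the donor (acceptor) boundary with at least ``min_overhang``
    aligned bases on each side.  A read may hit several introns but is
    counted in at most one category per intron (a rare block spanning both
    boundaries of one intron counts as EI only).

    Parameters
    ----------
    alignments : path to SAM/BAM, or iterable of pysam.AlignedSegment
    transcripts : gene_id -> TranscriptModel (one transcript per gene)
    strand_mode : library orientation, 'reverse' for typical dUTP kits
    min_overhang : minimum aligned bases on each side of a boundary

    Returns
    -------
    (counts, log)
        counts: DataFrame with columns gene_id, intron_index, EI, IE, EE
        (every annotated intron appears, zero-filled); log: numbers of
        wrong-strand reads discarded and unannotated (novel) junctions.
    """
    if strand_mode not in STRAND_MODES:
        raise CountingError(f"strand_mode must be one of {STRAND_MODES}")
    trees = _transcript_tree(transcripts)
    counts: dict[tuple[str, int], list[int]] = {
        (tx.gene_id, intron.index): [0, 0, 0]  # EI, IE, EE
        for tx in transcripts.values()
        for intron in tx.introns
    }
    log = {"wrong_strand": 0, "novel_junction": 0, "unmapped": 0}

    for read in _iter_alignments(alignments):
        if read.is_unmapped:
            log["unmapped"] += 1
            continue
        chrom = read.reference_name
        tree = trees.get(chrom)
        if tree is None:
            continue
        blocks = _aligned_blocks(read)
        if not blocks:
            continue
        gaps = [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(blocks, blocks[1:])
        ]
        rstrand = _read_strand(read)
        span = (blocks[0][0], blocks[-1][1])
        hits = tree.overlap(span[0], span[1])
        matched_any_strand = False
        gap_annotated = {g: False for g in gaps}
        for hit in hits:
            tx: TranscriptModel = hit.data
            if not _strand_ok(rstrand, tx.strand, strand_mode):
                continue
            matched_any_strand = True
            for intron in tx.introns:
                key = (tx.gene_id, intron.index)
                if (intron.start, intron.end) in gaps:
                    counts[key][2] += 1
                    gap_annotated[(intron.start, intron.end)] = True
                    continue
                # donor = 5' end of intron, acceptor = 3' end, strand-aware
                if tx.strand == "+":
                    donor, acceptor = intron.start, intron.end
                else:
                    donor, acceptor = intron.end, intron.start
                crosses_donor = any(
                    bs <= donor - min_overhang and be >= donor + min_overhang
                    for bs, be in blocks
                )
                crosses_acceptor = any(
                    bs <= acceptor - min_overhang and be >= acceptor + min_overhang
                    for bs, be in blocks
                )
                if crosses_donor:
                    counts[key][0] += 1
                elif crosses_acceptor:
                    counts[key][1] += 1
        if hits and not matched_any_strand and strand_mode != "unstranded":
            log["wrong_strand"] += 1
        log["novel_junction"] += sum(
            1 for g, annotated in gap_annotated.items() if not annotated
        )

    rows = [
        {"gene_id": g, "intron_index": i, "EI": v[0], "IE": v[1], "EE": v[2]}
        for (g, i), v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "intron_index", "EI", "IE", "EE"]), log


def _feature_intervals(
    transcripts: Mapping[str, TranscriptModel],
) -> list[tuple[str, str, str, int, int, str]]:
    """(gene_id, feature, chrom, start, end, strand) for exons, introns, premRNA."""
    feats = []
    for tx in transcripts.values():
        for exon in tx.exons:
            feats.append(
                (tx.gene_id, f"exon_{exon.rank}", tx.chrom, exon.start, exon.end,
                 tx.strand)
            )
        for intron in tx.introns:
            feats.append(
                (tx.gene_id, f"intron_{intron.index}", tx.chrom, intron.start,
                 intron.end, tx.strand)
            )
        feats.append(
            (tx.gene_id, "premRNA", tx.chrom, tx.span_start, tx.span_end, tx.strand)
        )
    return feats


def count_reads_in_features(
    alignments,
    transcripts: Mapping[str, TranscriptModel],
    *,
    strand_mode: str = "reverse",
    library_size: int | None = None,
) -> pd.DataFrame:
    """Count reads overlapping each exon, intron, and pre-mRNA span.

    The three feature classes are counted independently: a read straddling
    an exon–intron boundary counts for both the exon and the intron, and
    every read inside the gene span counts for premRNA.  A read counts
    toward a feature when its aligned span overlaps it on the correct
    strand for ``strand_mode``.

    ``library_size`` defaults to the number of mapped reads in the stream;
    RPKM uses it as the per-million denominator.

    Returns a DataFrame with columns gene_id, feature, raw_count,
    length_bp, rpkm, library_size.
    """
    if strand_mode not in STRAND_MODES:
        raise CountingError(f"strand_mode must be one of {STRAND_MODES}")
    feats = _feature_intervals(transcripts)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, (_g, _f, chrom, start, end, _s) in enumerate(feats):
        trees[chrom].addi(start, end, idx)
    raw = [0] * len(feats)

    n_mapped = 0
    for read in _iter_alignments(alignments):
        if read.is_unmapped:
            continue
        n_mapped += 1
        tree = trees.get(read.reference_name)
        if tree is None:
            continue
        blocks = _aligned_blocks(read)
        if not blocks:
            continue
        rstrand = _read_strand(read)
        hit_idx: set[int] = set()
        for bs, be in blocks:
            for hit in tree.overlap(bs, be):
                hit_idx.add(hit.data)
        for idx in hit_idx:
            if _strand_ok(rstrand, feats[idx][5], strand_mode):
                raw[idx] += 1

    if n_mapped == 0:
        import warnings

        warnings.warn("empty alignment stream: all counts are zero")
    lib = library_size if library_size is not None else max(n_mapped, 1)
    rows = [
        {
            "gene_id": g,
            "feature": f,
            "raw_count": raw[idx],
            "length_bp": end - start,
            "rpkm": rpkm(raw[idx], end - start, lib),
            "library_size": lib,
        }
        for idx, (g, f, _c, start, end, _s) in enumerate(feats)
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "feature", "raw_count", "length_bp", "rpkm",
                 "library_size"],
    )
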