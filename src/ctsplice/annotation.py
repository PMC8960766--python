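"""Gene annotation handling: transcript models, introns, polyA distances.

Parses GTF exon records (1-based, inclusive coordinates), selects one
transcript per gene (the longest genomic span, as is conventional for
splicing-index work), derives introns as the gaps between consecutive
exons, and computes the positional quantities the splicing indices need
— most importantly each intron's distance to the polyA site, the proxy
for how much transcription time remains when the intron is synthesised.

Internally all coordinates are 0-based half-open; conversion from and to
the 1-based inclusive GTF convention happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class AnnotationError(ValueError):
    """Raised for malformed GTF input or inconsistent transcript models."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon, 0-based half-open, with 1-based rank in transcription order."""

    chrom: str
    start: int
    end: int
    strand: str
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"exon start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IntronInterval:
    """One intron, 0-based half-open, 1-based index i in transcription order.

    ``dist_polya`` is the genomic distance (bp) from the intron's 3' end to
    the transcript's 3' terminus (cleavage/polyadenylation site).
    """

    chrom: str
    start: int
    end: int
    strand: str
    index: int
    dist_polya: int
    is_first: bool
    is_last: bool

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"intron start must be < end, got [{self.start}, {self.end})"
            )
        if self.dist_polya < 0:
            raise AnnotationError("dist_polya must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One gene's chosen transcript: ordered exons plus derived introns.

    Exons and introns are ordered 5'->3' in transcription direction; for
    minus-strand transcripts that is decreasing genomic coordinate.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[ExonInterval]
    introns: list[IntronInterval] = field(default_factory=list)

    @property
    def span_start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def span_end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def gene_length(self) -> int:
        return self.span_end - self.span_start

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def validate(self) -> None:
        """Check structural invariants; raise AnnotationError on violation."""
        ranks = [e.rank for e in self.exons]
        if ranks != list(range(1, len(self.exons) + 1)):
            raise AnnotationError(
                f"{self.transcript_id}: exon ranks not consecutive from 1: {ranks}"
            )
        by_coord = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_coord, by_coord[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        total = sum(e.length for e in self.exons) + sum(i.length for i in self.introns)
        if total != self.gene_length:
            raise AnnotationError(
                f"{self.transcript_id}: exon+intron lengths ({total}) do not "
                f"reconstruct span length ({self.gene_length})"
            )


def _derive_introns(exons: list[ExonInterval], chrom: str, strand: str,
                    span_start: int, span_end: int) -> list[IntronInterval]:
    """Introns between consecutive exons, in transcription order."""
    by_coord = sorted(exons, key=lambda e: e.start)
    gaps = [
        (a.end, b.start) for a, b in zip(by_coord, by_coord[1:]) if b.start > a.end
    ]
    if strand == "-":
        gaps = gaps[::-1]
    n = len(gaps)
    introns = []
    for i, (start, end) in enumerate(gaps, start=1):
        if strand == "+":
            dist = span_end - end
        else:
            dist = start - span_start
        introns.append(
            IntronInterval(
                chrom=chrom, start=start, end=end, strand=strand, index=i,
                dist_polya=dist, is_first=(i == 1), is_last=(i == n),
            )
        )
    return introns


def build_transcript_model(
    gene_id: str,
    transcript_id: str,
    chrom: str,
    strand: str,
    exon_coords: Iterable[tuple[int, int]],
) -> TranscriptModel:
    """Assemble a TranscriptModel from 0-based half-open exon coordinates.

    Exons may be given in any order; ranks are assigned in transcription
    direction (rank 1 = 5'-most exon).
    """
    coords = sorted(exon_coords)
    if not coords:
        raise AnnotationError(f"{transcript_id}: no exons")
    if strand == "-":
        ordered = coords[::-1]
    else:
        ordered = coords
    exons = [
        ExonInterval(chrom=chrom, start=s, end=e, strand=strand, rank=r)
        for r, (s, e) in enumerate(ordered, start=1)
    ]
    span_start = coords[0][0]
    span_end = coords[-1][1]
    tx = TranscriptModel(
        gene_id=gene_id,
        transcript_id=transcript_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        introns=_derive_introns(exons, chrom, strand, span_start, span_end),
    )
    tx.validate()
    return tx


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise AnnotationError(
                f"GTF line {lineno}: cannot parse attribute chunk {chunk!r}"
            )
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def load_annotation(gtf_path: str | Path) -> dict[str, list[TranscriptModel]]:
    """Parse a GTF file into TranscriptModels grouped by gene.

    Only ``exon`` features are used; each must carry ``gene_id`` and
    ``transcript_id`` attributes.  GTF coordinates (1-based inclusive) are
    converted exactly to the internal 0-based half-open convention.
    Single-exon transcripts yield zero introns.

    Raises
    ------
    AnnotationError
        On a malformed line (with its line number) or a transcript whose
        exons overlap.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"GTF line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _frame, attr = fields
            if ftype != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"GTF line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise AnnotationError(
                    f"GTF line {lineno}: invalid coordinate range {start1}-{end1}"
                )
            if strand not in ("+", "-"):
                raise AnnotationError(
                    f"GTF line {lineno}: invalid strand {strand!r}"
                )
            attrs = _parse_attributes(attr, lineno)
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise AnnotationError(f"GTF line {lineno}: missing {key}")
            tid = attrs["transcript_id"]
            rec = per_tx.setdefault(
                tid,
                {"gene_id": attrs["gene_id"], "chrom": chrom, "strand": strand,
                 "exons": []},
            )
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise AnnotationError(
                    f"GTF line {lineno}: transcript {tid} spans multiple "
                    "chromosomes or strands"
                )
            if tid not in order:
                order.append(tid)
            # 1-based inclusive -> 0-based half-open
            rec["exons"].append((start1 - 1, end1))

    genes: dict[str, list[TranscriptModel]] = {}
    for tid in order:
        rec = per_tx[tid]
        tx = build_transcript_model(
            rec["gene_id"], tid, rec["chrom"], rec["strand"], rec["exons"]
        )
        genes.setdefault(rec["gene_id"], []).append(tx)
    return genes


def write_gtf(models: Iterable[TranscriptModel], path: str | Path,
              source: str = "ctsplice") -> None:
    """Write transcript models back to GTF (exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in models:
            for exon in sorted(tx.exons, key=lambda e: e.start):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [tx.chrom, source, "exon", str(exon.start + 1),
                         str(exon.end), ".", tx.strand, ".", attrs]
                    ) + "\n"
                )


def introns_to_bed6(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write all introns as BED6 (0-based half-open) for inspection."""
    with open(path, "w") as fh:
        for tx in models:
            for intron in tx.introns:
                name = f"{tx.gene_id}:intron{intron.index}"
                fh.write(
                    "\t".join(
                        [intron.chrom, str(intron.start), str(intron.end),
                         name, "0", intron.strand]
                    ) + "\n"
                )


def transcript_table(models: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Summary table: one row per transcript model."""
    rows = [
        {
            "gene_id": tx.gene_id,
            "transcript_id": tx.transcript_id,
            "chrom": tx.chrom,
            "strand": tx.strand,
            "span_start": tx.span_start,
            "span_end": tx.span_end,
            "gene_length": tx.gene_length,
            "n_exons": len(tx.exons),
            "n_introns": tx.n_introns,
        }
        for tx in models
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_longest_transcript(
    transcripts: Iterable[TranscriptModel],
) -> TranscriptModel:
    """The transcript with the largest genomic span.

    Ties are broken deterministically by lexicographically smallest
    transcript_id.
    """
    txs = list(transcripts)
    if not txs:
        raise AnnotationError("no transcripts to select from")
    return min(txs, key=lambda t: (-t.gene_length, t.transcript_id))


def longest_transcript_per_gene(
    genes: Mapping[str, list[TranscriptModel]],
) -> dict[str, TranscriptModel]:
    """Map gene_id -> its longest transcript (the substrate for all indices)."""
    return {g: select_longest_transcript(txs) for g, txs in genes.items()}


def intron_polya_distance(intron: IntronInterval, tx: TranscriptModel) -> int:
    """Genomic distance (bp) from an intron's 3' end to the polyA site.

    Strand-aware: on ``+`` the 3' end of the intron is its half-open end
    and the polyA site is ``span_end``; on ``-`` they are the intron start
    and ``span_start``.  The last intron's distance equals the length of
    the last exon.
    """
    if intron not in tx.introns:
        raise AnnotationError(
            f"intron [{intron.start},{intron.end}) does not belong to "
            f"{tx.transcript_id}"
        )
    if tx.strand == "+":
        return tx.span_end - intron.end
    return intron.start - tx.span_start


def filter_expressed(
    gene_table: pd.DataFrame,
    min_level: float = 1.0,
    level_column: str = "premrna_rpkm",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep genes whose pre-mRNA expression is at or above ``min_level`` RPKM.

    Returns the filtered table and a ``{"kept": .., "dropped": ..}`` report.
    The threshold default of 1 RPKM is a configurable convention; only
    genes passing it should enter splicing-index statistics.
    """
    keep = gene_table[level_column] >= min_level
    report = {"kept": int(keep.sum()), "dropped": int((~keep).sum())}
    return gene_table.loc[keep].copy(), report
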