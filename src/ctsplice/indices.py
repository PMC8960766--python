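"""Splicing indices: per-intron ISI, per-gene GSI, and analyses built on them.

Three statistics quantify co-transcriptional splicing efficiency:

* ``isi_junction`` — junction-based intron splicing index,
  ``1 - 0.5*(EI+IE) / (0.5*(EI+IE) + EE)``: the complement of the
  proportion of intron-inclusion junction reads.  1 = fully spliced.
* ``isi_coverage`` — coverage-based intron splicing index,
  ``1 - I / (0.5*(E_left + E_right))`` on RPKM values: intron read
  density relative to the mean of its flanking exons.  May be negative
  when the intron is denser than its exons; negative values are kept
  (clipping would bias downstream variance statistics).
* ``gsi`` — Gene Splicing Index, the log2 ratio of exonic read density
  to whole pre-mRNA read density over the gene's longest transcript.
  High GSI = efficient co-transcriptional splicing.

Undefined indices propagate as NaN, never as 0 (0 means "fully
unspliced", a real value).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


class IndexError_(ValueError):
    """Invalid input to an index computation."""


def isi_junction(EI: float, IE: float, EE: float) -> float:
    """Junction-based intron splicing index from EI/IE/EE junction counts.

    Returns NaN when no junction reads were observed (EI+IE+EE == 0).
    """
    if EI < 0 or IE < 0 or EE < 0:
        raise IndexError_(f"negative junction count: EI={EI}, IE={IE}, EE={EE}")
    inclusion = (EI + IE) * 0.5
    denom = inclusion + EE
    if denom == 0:
        return math.nan
    return 1.0 - inclusion / denom


def isi_coverage(I_rpkm: float, E_left_rpkm: float, E_right_rpkm: float) -> float:
    """Coverage-based intron splicing index from intron/flanking-exon RPKM.

    Returns NaN when both flanking exons have zero RPKM.  Values below 0
    (intron denser than flanking exons) are passed through unclipped.
    """
    if I_rpkm < 0 or E_left_rpkm < 0 or E_right_rpkm < 0:
        raise IndexError_("negative RPKM input")
    exon_mean = 0.5 * (E_left_rpkm + E_right_rpkm)
    if exon_mean == 0:
        return math.nan
    return 1.0 - I_rpkm / exon_mean


def gsi(
    exon_reads_total: float,
    exon_length_total: float,
    premrna_reads: float,
    premrna_length: float,
) -> float:
    """Gene Splicing Index: log2(exonic read density / pre-mRNA read density).

    ``exon_reads_total`` and ``exon_length_total`` sum over all exons of
    the gene's transcript; the pre-mRNA terms use the whole transcript
    span.  Undefined (NaN) when any input is non-positive — a gene with
    no reads has no measurable splicing efficiency.  Invariant under
    uniform scaling of both read counts (library depth cancels).
    """
    if min(exon_reads_total, exon_length_total, premrna_reads, premrna_length) <= 0:
        return math.nan
    exon_density = exon_reads_total / exon_length_total
    pre_density = premrna_reads / premrna_length
    return math.log2(exon_density / pre_density)


def mature_pre_ratio(mature_rpkm: float, premrna_rpkm: float) -> float:
    """log2 ratio of mature mRNA level to pre-mRNA level.

    Indexes the post-transcriptional yield of a gene; NaN when either
    level is non-positive.
    """
    if mature_rpkm <= 0 or premrna_rpkm <= 0:
        return math.nan
    return math.log2(mature_rpkm / premrna_rpkm)


# ---------------------------------------------------------------------------
# Table-level computation from counting outputs
# ---------------------------------------------------------------------------

def isi_table(
    junction_counts: pd.DataFrame,
    coverage_counts: pd.DataFrame,
    transcripts,
) -> pd.DataFrame:
    """Per-intron table of both splicing indices plus polyA distance.

    Parameters
    ----------
    junction_counts : columns gene_id, intron_index, EI, IE, EE
    coverage_counts : columns gene_id, feature, rpkm (exon_i / intron_i rows)
    transcripts : gene_id -> TranscriptModel

    Returns
    -------
    DataFrame with gene_id, intron_index, isi_j, isi_c, dist_polya.
    """
    cov = coverage_counts.set_index(["gene_id", "feature"])["rpkm"]
    jc = junction_counts.set_index(["gene_id", "intron_index"])
    rows = []
    for gene_id, tx in transcripts.items():
        for intron in tx.introns:
            i = intron.index
            if (gene_id, i) in jc.index:
                rec = jc.loc[(gene_id, i)]
                ij = isi_junction(rec["EI"], rec["IE"], rec["EE"])
            else:
                ij = math.nan
            try:
                intron_rpkm = cov.loc[(gene_id, f"intron_{i}")]
                e_left = cov.loc[(gene_id, f"exon_{i}")]
                e_right = cov.loc[(gene_id, f"exon_{i + 1}")]
                ic = isi_coverage(intron_rpkm, e_left, e_right)
            except KeyError:
                ic = math.nan
            rows.append(
                {"gene_id": gene_id, "intron_index": i, "isi_j": ij,
                 "isi_c": ic, "dist_polya": intron.dist_polya}
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "intron_index", "isi_j", "isi_c", "dist_polya"]
    )


def gsi_table(coverage_counts: pd.DataFrame, transcripts) -> pd.DataFrame:
    """Per-gene GSI with its components, from coverage counts.

    Sums exon reads/lengths per gene, takes the pre-mRNA span counts, and
    applies the GSI formula.  Genes with zero exonic or pre-mRNA reads or
    no introns get NaN GSI with a reason code.
    """
    cov = coverage_counts.set_index(["gene_id", "feature"])
    rows = []
    for gene_id, tx in transcripts.items():
        exon_feats = [f"exon_{e.rank}" for e in tx.exons]
        exon_reads = float(
            sum(cov.loc[(gene_id, f), "raw_count"] for f in exon_feats)
        )
        exon_len = int(sum(e.length for e in tx.exons))
        pre_reads = float(cov.loc[(gene_id, "premRNA"), "raw_count"])
        pre_len = tx.gene_length
        pre_rpkm = float(cov.loc[(gene_id, "premRNA"), "rpkm"])
        if tx.n_introns == 0:
            value, reason = math.nan, "no_introns"
        elif pre_reads <= 0 or exon_reads <= 0:
            value, reason = math.nan, "zero_reads"
        else:
            value, reason = gsi(exon_reads, exon_len, pre_reads, pre_len), ""
        rows.append(
            {
                "gene_id": gene_id,
                "gsi": value,
                "exon_reads_total": exon_reads,
                "exon_length_total": exon_len,
                "premrna_reads": pre_reads,
                "premrna_length": pre_len,
                "premrna_rpkm": pre_rpkm,
                "n_introns": tx.n_introns,
                "gene_length": tx.gene_length,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Descriptive analyses
# ---------------------------------------------------------------------------

def polya_decile_profile(
    isis: pd.DataFrame,
    value_column: str = "isi_c",
    ascending: bool = True,
) -> pd.DataFrame:
    """Summarise ISI by decile of distance to the polyA site.

    Introns are rank-split into ten near-equal deciles of ``dist_polya``
    (decile 1 = closest to the polyA site when ``ascending``; the
    direction is recorded in the output).  Each decile row reports n,
    mean, quartiles, and the two-tailed unpaired t-test p-value of that
    decile's ISI values against decile 1.

    Splicing is co-transcriptional, so introns far from the polyA site
    have had more transcription time and are expected to show higher ISI.
    """
    data = isis.dropna(subset=[value_column, "dist_polya"])
    if len(data) < 10:
        raise IndexError_(
            f"need >=10 defined {value_column} values, got {len(data)}"
        )
    order = data["dist_polya"].rank(method="first", ascending=ascending)
    decile = np.ceil(order * 10 / len(data)).astype(int).clip(1, 10)
    ref = data.loc[decile == 1, value_column].to_numpy()
    rows = []
    for d in range(1, 11):
        vals = data.loc[decile == d, value_column].to_numpy()
        if d == 1 or len(vals) < 2 or len(ref) < 2:
            p = math.nan if d != 1 else 1.0
        elif vals.var() == 0 and ref.var() == 0:
            p = 1.0 if np.isclose(vals.mean(), ref.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(vals, ref, equal_var=False).pvalue)
        rows.append(
            {
                "decile": d,
                "direction": "1=nearest_polyA" if ascending else "1=farthest_polyA",
                "n": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else math.nan,
                "q25": float(np.percentile(vals, 25)) if len(vals) else math.nan,
                "median": float(np.median(vals)) if len(vals) else math.nan,
                "q75": float(np.percentile(vals, 75)) if len(vals) else math.nan,
                "p_vs_decile1": p,
            }
        )
    return pd.DataFrame(rows)


def _group_variances(pool: np.ndarray, sizes: np.ndarray,
                     starts: np.ndarray) -> np.ndarray:
    """Per-group sample variances of a flat pool partitioned by sizes."""
    sums = np.add.reduceat(pool, starts)
    sq = np.add.reduceat(pool * pool, starts)
    return (sq - sums * sums / sizes) / (sizes - 1)


def within_gene_variance_test(
    isis: pd.DataFrame,
    value_column: str = "isi_c",
    n_randomizations: int = 199,
    seed: int = 0,
) -> dict:
    """Test whether introns of the same gene splice more alike than chance.

    For every gene with >=2 defined ISI values the observed per-gene
    variance is computed.  The null reference permutes the pooled ISI
    values across introns while keeping each gene's intron count
    (sampling without replacement — a permutation of the observed pool),
    and recomputes per-pseudo-gene variances.

    Two p-values are returned.  ``p_value`` is the unpaired two-tailed
    t-test between the observed and randomized variance distributions,
    the conventional descriptive comparison; because the randomized
    variances are built from the same value pool it is conservative
    under the null.  ``p_perm`` is an exactly calibrated one-sided
    permutation p-value: the rank of the observed mean within-gene
    variance in the permutation distribution of that mean (small when
    introns of a gene are more alike than random sets of introns).
    """
    data = isis.dropna(subset=[value_column])
    groups = [
        g[value_column].to_numpy()
        for _, g in data.groupby("gene_id", sort=True)
        if len(g) >= 2
    ]
    if not groups:
        raise IndexError_("no gene with >=2 defined ISI values")
    sizes = np.array([len(v) for v in groups])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    pool = np.concatenate(groups)
    observed = _group_variances(pool, sizes, starts)
    rng = np.random.default_rng(seed)
    randomized = np.empty((n_randomizations, len(groups)))
    for b in range(n_randomizations):
        randomized[b] = _group_variances(rng.permutation(pool), sizes, starts)
    t, p = stats.ttest_ind(observed, randomized.ravel(), equal_var=False)
    obs_mean = float(observed.mean())
    perm_means = randomized.mean(axis=1)
    p_perm = float(
        (1 + np.sum(perm_means <= obs_mean)) / (n_randomizations + 1)
    )
    return {
        "observed_variances": observed,
        "randomized_variances": randomized.ravel(),
        "observed_mean": obs_mean,
        "randomized_mean": float(perm_means.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
        "p_perm": p_perm,
        "n_genes": len(groups),
        "n_randomizations": n_randomizations,
        "seed": seed,
    }


def gene_mean_isi(isis: pd.DataFrame) -> pd.DataFrame:
    """Per-gene means of both ISI variants over defined introns."""
    return (
        isis.groupby("gene_id")[["isi_j", "isi_c"]]
        .mean()
        .reset_index()
        .rename(columns={"isi_j": "mean_isi_j", "isi_c": "mean_isi_c"})
    )


def mature_pre_ratio_table(
    gsi_records: pd.DataFrame, mature_rpkm: pd.Series
) -> pd.DataFrame:
    """Attach log2(mature/pre-mRNA) ratios to a GSI table.

    ``mature_rpkm`` is indexed by gene_id (from total RNA-seq).
    """
    out = gsi_records.copy()
    out["mature_rpkm"] = out["gene_id"].map(mature_rpkm)
    out["mature_pre_ratio"] = [
        mature_pre_ratio(m, p) if (pd.notna(m) and pd.notna(p)) else math.nan
        for m, p in zip(out["mature_rpkm"], out["premrna_rpkm"])
    ]
    return out
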