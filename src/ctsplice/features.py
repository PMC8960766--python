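"""Sequence-derived gene covariates: splice-site strength and GC ratio.

Splice-site strength is scored with a maximum-entropy sequence model.
The model approximates the joint distribution of bases in a splice-site
window by the maximum-entropy distribution consistent with the observed
single-position and adjacent-pair marginals of a training set of real
sites; that distribution has a closed form — a first-order Markov chain
over the window — which makes 9-mer donor and 23-mer acceptor windows
equally tractable.  The score of a window is the log2 odds of the site
model against a background composition:

    score(x) = log2( P_me(x) / P_bg(x) ),
    P_me(x)  = p_1(x_1) * prod_i P(x_{i+1} | x_i)

Windows follow the standard convention: the donor window is 9 nt (last
3 exonic + first 6 intronic bases) and the acceptor window is 23 nt
(last 20 intronic + first 3 exonic bases), both read on the transcribed
strand.  First and last introns of each transcript are excluded from
per-gene averages (their splicing is dominated by capping and
cleavage/polyadenylation coupling rather than site strength).

The second covariate is the exon/intron GC ratio,
%GC_exons / %GC_introns over the concatenated exonic and intronic
sequence of the gene's transcript.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

DONOR_LENGTH = 9        # 3 exonic + 6 intronic
ACCEPTOR_LENGTH = 23    # 20 intronic + 3 exonic
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTN", "TGCAN")


class FeatureError(ValueError):
    pass


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SpliceSiteWindow:
    """A donor (9 nt) or acceptor (23 nt) window on the transcribed strand."""

    gene_id: str
    intron_index: int
    site_type: str                 # 'donor' | 'acceptor'
    sequence: str

    def __post_init__(self) -> None:
        expected = DONOR_LENGTH if self.site_type == "donor" else ACCEPTOR_LENGTH
        if self.site_type not in ("donor", "acceptor"):
            raise FeatureError(f"unknown site type {self.site_type!r}")
        if len(self.sequence) != expected:
            raise FeatureError(
                f"{self.site_type} window must be {expected} nt, "
                f"got {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGTN"):
            raise FeatureError(f"invalid characters in {self.sequence!r}")

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence

    @property
    def is_canonical(self) -> bool:
        """GT..AG rule: donor windows start the intron with GT, acceptor ends AG."""
        if self.site_type == "donor":
            return self.sequence[3:5] == "GT"
        return self.sequence[18:20] == "AG"


@dataclass
class MaxEntModel:
    """Maximum-entropy splice-site model (adjacent-pair constraints).

    ``marginals``: (L, 4) per-position base probabilities;
    ``pairs``: (L-1, 4, 4) adjacent-position joint probabilities;
    ``background``: (4,) background composition.  The maxent distribution
    under these constraints is the Markov chain implied by the tables.
    """

    site_type: str
    length: int
    marginals: np.ndarray
    pairs: np.ndarray
    background: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.marginals = np.asarray(self.marginals, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.marginals.shape != (self.length, 4):
            raise FeatureError("marginal table shape mismatch")
        if self.pairs.shape != (self.length - 1, 4, 4):
            raise FeatureError("pair table shape mismatch")
        if np.any(self.marginals <= 0) or np.any(self.pairs <= 0) \
                or np.any(self.background <= 0):
            raise FeatureError("model probabilities must be in (0, 1]")

    # -- persistence --------------------------------------------------------
    def checksum(self) -> str:
        h = hashlib.sha256()
        for arr in (self.marginals, self.pairs, self.background):
            h.update(np.round(arr, 12).tobytes())
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        payload = {
            "site_type": self.site_type,
            "length": self.length,
            "provenance": self.provenance,
            "checksum": self.checksum(),
            "background": self.background.tolist(),
            "marginals": self.marginals.tolist(),
            "pairs": self.pairs.tolist(),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "MaxEntModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        model = cls(
            site_type=payload["site_type"],
            length=payload["length"],
            marginals=np.array(payload["marginals"]),
            pairs=np.array(payload["pairs"]),
            background=np.array(payload["background"]),
            provenance=payload.get("provenance", ""),
        )
        stored = payload.get("checksum")
        if stored and stored != model.checksum():
            raise FeatureError(f"checksum mismatch loading {path}")
        return model

    # -- scoring ------------------------------------------------------------
    def log_prob(self, sequence: str) -> float:
        """log2 probability of a window under the maxent (Markov) model."""
        idx = [_BASE_INDEX[b] for b in sequence]
        lp = math.log2(self.marginals[0, idx[0]])
        for i in range(self.length - 1):
            joint = self.pairs[i, idx[i], idx[i + 1]]
            lp += math.log2(joint / self.marginals[i, idx[i]])
        return lp

    def score(self, sequence: str) -> float:
        """log2-odds score vs background; NaN if the window contains N."""
        if len(sequence) != self.length:
            raise FeatureError(
                f"window length {len(sequence)} != model length {self.length}"
            )
        if "N" in sequence:
            return math.nan
        bg = sum(math.log2(self.background[_BASE_INDEX[b]]) for b in sequence)
        return self.log_prob(sequence) - bg


def fit_maxent_model(
    training_sequences: Iterable[str],
    site_type: str,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
    provenance: str = "",
) -> MaxEntModel:
    """Fit the maxent splice-site model from aligned training windows.

    Estimates per-position and adjacent-pair marginals with a symmetric
    pseudocount; the maxent distribution under those constraints is
    returned in its closed Markov form.
    """
    seqs = [s.upper() for s in training_sequences]
    if not seqs:
        raise FeatureError("no training sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise FeatureError("training sequences have unequal lengths")
    pair_counts = np.full((length - 1, 4, 4), pseudocount)
    for s in seqs:
        idx = [_BASE_INDEX.get(b, -1) for b in s]
        if -1 in idx:
            continue
        for i in range(length - 1):
            pair_counts[i, idx[i], idx[i + 1]] += 1
    pairs_raw = pair_counts / pair_counts.sum(axis=(1, 2), keepdims=True)
    # chain-consistent pair tables: position i's marginal agrees between
    # pairs[i-1] (column sums) and pairs[i] (row sums), so the Markov
    # factorisation is exactly the maxent distribution for these constraints
    pairs = np.empty_like(pairs_raw)
    marginals = np.empty((length, 4))
    marginals[0] = pairs_raw[0].sum(axis=1)
    for i in range(length - 1):
        rows = pairs_raw[i].sum(axis=1)
        pairs[i] = pairs_raw[i] / rows[:, None] * marginals[i][:, None]
        marginals[i + 1] = pairs[i].sum(axis=0)
    if background is None:
        background = np.full(4, 0.25)
    return MaxEntModel(
        site_type=site_type, length=length, marginals=marginals, pairs=pairs,
        background=np.asarray(background, float), provenance=provenance,
    )


def build_synthetic_models(
    n_training: int = 2000,
    match_prob: float = 0.9,
    seed: int = 2024,
) -> dict[str, MaxEntModel]:
    """Synthetic donor/acceptor maxent models fit from consensus-pool draws.

    These stand in for models trained on annotated splice sites: training
    windows are drawn around the canonical donor/acceptor consensus at
    the given per-position match probability, exactly the pool the
    synthetic genome generator uses.  Deterministic under the seed.
    """
    from .synthetic_data import ACCEPTOR_CONSENSUS, DONOR_CONSENSUS

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def draws(consensus: str) -> list[str]:
        out = []
        for _ in range(n_training):
            chars = [
                c if rng.random() < match_prob else str(rng.choice(bases))
                for c in consensus
            ]
            out.append("".join(chars))
        return out

    tag = f"synthetic consensus pool (n={n_training}, match={match_prob}, seed={seed})"
    return {
        "donor": fit_maxent_model(draws(DONOR_CONSENSUS), "donor",
                                  provenance=tag),
        "acceptor": fit_maxent_model(draws(ACCEPTOR_CONSENSUS), "acceptor",
                                     provenance=tag),
    }


# ---------------------------------------------------------------------------
# Window extraction and per-gene features
# ---------------------------------------------------------------------------

def _fetch(genome, chrom: str, start: int, end: int) -> str | None:
    """Sequence slice (0-based half-open); None if out of bounds."""
    if start < 0:
        return None
    if isinstance(genome, Mapping):
        seq = genome[chrom]
        if end > len(seq):
            return None
        return str(seq[start:end]).upper()
    # pyfaidx.Fasta or similar
    record = genome[chrom]
    if end > len(record):
        return None
    return str(record[start:end]).upper()


def extract_ss_windows(tx, genome) -> tuple[list[SpliceSiteWindow], list[str]]:
    """Donor/acceptor windows for the internal introns of one transcript.

    First and last introns are excluded; a transcript with fewer than
    three introns yields no windows.  Windows running off a chromosome
    end are skipped and reported in the returned log.
    """
    windows: list[SpliceSiteWindow] = []
    log: list[str] = []
    n = tx.n_introns
    for intron in tx.introns:
        if intron.is_first or intron.is_last or n < 3:
            continue
        if tx.strand == "+":
            donor_seq = _fetch(genome, tx.chrom, intron.start - 3, intron.start + 6)
            acceptor_seq = _fetch(genome, tx.chrom, intron.end - 20, intron.end + 3)
        else:
            donor_raw = _fetch(genome, tx.chrom, intron.end - 6, intron.end + 3)
            acceptor_raw = _fetch(genome, tx.chrom, intron.start - 3,
                                  intron.start + 20)
            donor_seq = _revcomp(donor_raw) if donor_raw is not None else None
            acceptor_seq = (
                _revcomp(acceptor_raw) if acceptor_raw is not None else None
            )
        for site_type, seq in (("donor", donor_seq), ("acceptor", acceptor_seq)):
            if seq is None:
                log.append(
                    f"{tx.gene_id} intron {intron.index}: {site_type} window "
                    "out of chromosome bounds, skipped"
                )
                continue
            windows.append(
                SpliceSiteWindow(
                    gene_id=tx.gene_id, intron_index=intron.index,
                    site_type=site_type, sequence=seq,
                )
            )
    return windows, log


def maxent_score(window: SpliceSiteWindow, model: MaxEntModel) -> float:
    """Score one window; NaN for windows containing N."""
    if window.site_type != model.site_type:
        raise FeatureError(
            f"window is {window.site_type}, model is {model.site_type}"
        )
    return model.score(window.sequence)


def gene_ss_strength(
    tx, genome, models: Mapping[str, MaxEntModel]
) -> tuple[float, float]:
    """Mean donor and acceptor scores over scorable internal introns."""
    windows, _ = extract_ss_windows(tx, genome)
    scores = {"donor": [], "acceptor": []}
    for w in windows:
        s = maxent_score(w, models[w.site_type])
        if not math.isnan(s):
            scores[w.site_type].append(s)
    mean5 = float(np.mean(scores["donor"])) if scores["donor"] else math.nan
    mean3 = float(np.mean(scores["acceptor"])) if scores["acceptor"] else math.nan
    return mean5, mean3


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / acgt


def exon_intron_gc_ratio(tx, genome) -> float:
    """%GC over concatenated exons divided by %GC over concatenated introns.

    GC content is strand-symmetric, so genomic-strand slices suffice.
    NaN when the transcript has no introns or intronic GC is zero.
    """
    if tx.n_introns == 0:
        return math.nan
    exon_seq = "".join(
        _fetch(genome, tx.chrom, e.start, e.end) or "" for e in tx.exons
    )
    intron_seq = "".join(
        _fetch(genome, tx.chrom, i.start, i.end) or "" for i in tx.introns
    )
    gc_i = gc_fraction(intron_seq)
    gc_e = gc_fraction(exon_seq)
    if not gc_i or math.isnan(gc_i) or math.isnan(gc_e):
        return math.nan
    return gc_e / gc_i


def features_table(
    transcripts: Mapping[str, object],
    genome,
    models: Mapping[str, MaxEntModel] | None = None,
) -> pd.DataFrame:
    """Per-gene feature table: mean_5ss, mean_3ss, gc_ratio, intron counts.

    Also flags introns whose donor/acceptor dinucleotides are
    non-canonical (not GT..AG); those windows are still scored.
    """
    if models is None:
        models = build_synthetic_models()
    rows = []
    for gene_id, tx in transcripts.items():
        windows, _ = extract_ss_windows(tx, genome)
        mean5, mean3 = gene_ss_strength(tx, genome, models)
        n_internal = sum(1 for w in windows if w.site_type == "donor")
        n_noncanon = sum(1 for w in windows if not w.is_canonical)
        rows.append(
            {
                "gene_id": gene_id,
                "mean_5ss": mean5,
                "mean_3ss": mean3,
                "gc_ratio": exon_intron_gc_ratio(tx, genome),
                "n_internal_introns": n_internal,
                "n_noncanonical_windows": n_noncanon,
            }
        )
    return pd.DataFrame(rows)
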