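"""Sequence-class scoring of haplotypes and the haplotype function score.

A sequence scorer maps a 4096-bp DNA string to 39 sequence-class scores
(promoter, enhancer subtypes, transcription, polycomb, heterochromatin,
transcription-factor classes ...). An external deep-learning scorer can
be plugged in through :class:`SequenceScorer`; the packaged
:class:`SurrogateScorer` is a fast deterministic motif-count scorer with
the same contract, used for simulation and testing.

The haplotype function score (HFS) of an individual at a locus is the
mean of its two haplotypes' scores in the locus's reference sequence
class, centered on the reference haplotype's score and rounded to two
decimals so that a homozygous-reference individual scores exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEQUENCE_CLASSES",
    "SequenceScorer",
    "SurrogateScorer",
    "ScoreMatrix",
    "score_sequences",
    "reference_class",
    "round_half_away",
    "compute_hfs",
    "adjacent_ld",
]

# 39 sequence classes; the 40th (heterochromatin 6, centromeric) is
# dropped at the scorer-adapter boundary and never appears here.
SEQUENCE_CLASSES: tuple[str, ...] = (
    "P promoter",
    *(f"E{i} enhancer" for i in range(1, 13)),
    *(f"TN{i} transcription" for i in range(1, 5)),
    *(f"L{i} low signal" for i in range(1, 9)),
    *(f"HET{i} heterochromatin" for i in range(1, 6)),
    *(f"PC{i} polycomb" for i in range(1, 5)),
    *(f"TF{i} tf binding" for i in range(1, 5)),
    "CTCF",
)
assert len(SEQUENCE_CLASSES) == 39

N_CLASSES = len(SEQUENCE_CLASSES)
_ALPHABET = frozenset("ACGTN")
MOTIF_K = 6
_MANIFEST_SEED = 271828  # fixes the surrogate motif manifest across releases
_MANIFEST_VERSION = 1


class SequenceScorer(Protocol):
    """Contract: deterministically map a 4096-bp sequence to 39 scores."""

    class_names: Sequence[str]

    def score(self, sequence: str) -> np.ndarray: ...


def _validate(sequence: str, seq_len: int = 4096) -> str:
    if len(sequence) != seq_len:
        raise ValueError(f"sequence length {len(sequence)} != {seq_len}")
    seq = sequence.upper()
    if not _ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"sequence contains invalid characters: {bad}")
    return seq


@dataclass
class SurrogateScorer:
    """Deterministic motif-count stand-in for a deep sequence model.

    Each sequence class owns a fixed set of 6-mer motifs with fixed
    positive weights (generated once from a versioned seed, so the
    manifest is stable across runs and releases). The class score is

        score_c = logistic( sum_k w_ck * count(motif_ck) )

    where counts include overlapping occurrences. A poly-N sequence has
    all counts 0 and scores 0.5 in every class, and a substitution can
    only change the scores of classes whose motifs overlap the edited
    base (locality).
    """

    motifs_per_class: int = 3
    seq_len: int = 4096
    class_names: Sequence[str] = SEQUENCE_CLASSES
    manifest_version: int = _MANIFEST_VERSION
    manifest: dict[str, list[tuple[str, float]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(_MANIFEST_SEED + self.manifest_version)
        bases = np.array(list("ACGT"))
        self.manifest = {}
        seen: set[str] = set()
        for name in self.class_names:
            entries = []
            while len(entries) < self.motifs_per_class:
                motif = "".join(rng.choice(bases, size=MOTIF_K))
                if motif in seen:
                    continue
                seen.add(motif)
                entries.append((motif, float(rng.uniform(0.15, 0.5))))
            self.manifest[name] = entries
        # inverted index: motif -> [(class index, weight)]
        self._index: dict[str, list[tuple[int, float]]] = {}
        for c, name in enumerate(self.class_names):
            for motif, w in self.manifest[name]:
                self._index.setdefault(motif, []).append((c, w))

    def motif_counts(self, sequence: str) -> np.ndarray:
        """Overlapping motif-hit weighted sums per class (pre-logistic)."""
        seq = _validate(sequence, self.seq_len)
        acc = np.zeros(len(self.class_names))
        for i in range(len(seq) - MOTIF_K + 1):
            hits = self._index.get(seq[i : i + MOTIF_K])
            if hits:
                for c, w in hits:
                    acc[c] += w
        return acc

    def score(self, sequence: str) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.motif_counts(sequence)))


@dataclass
class ScoreMatrix:
    """Haplotypes x 39 sequence-class scores for one locus; row 0 is the
    reference haplotype."""

    locus_id: str
    scores: np.ndarray
    class_names: Sequence[str] = SEQUENCE_CLASSES
    reference_row: int = 0

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[1] != len(self.class_names):
            raise ValueError(
                f"expected {len(self.class_names)} score columns, got {self.scores.shape[1]}"
            )
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")


def score_sequences(
    scorer: SequenceScorer, sequences: Sequence[str], locus_id: str = ""
) -> ScoreMatrix:
    """Score each haplotype sequence; identical sequences are scored once."""
    cache: dict[str, np.ndarray] = {}
    rows = []
    for seq in sequences:
        key = seq.upper()
        if key not in cache:
            cache[key] = np.asarray(scorer.score(seq), dtype=float)
        rows.append(cache[key])
    return ScoreMatrix(locus_id, np.vstack(rows), class_names=scorer.class_names)


def reference_class(reference_scores: np.ndarray) -> int:
    """Sequence class of a locus: argmax of the reference haplotype's
    scores, ties broken toward the lowest index."""
    v = np.asarray(reference_scores, dtype=float)
    if np.isnan(v).all():
        raise ValueError("all-NaN score vector")
    return int(np.nanargmax(v))


def round_half_away(x: np.ndarray | float, decimals: int = 2):
    """Round half away from zero (numpy rounds half to even)."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.shape else float(out)


def compute_hfs(
    score_matrix: ScoreMatrix,
    individual_map: np.ndarray,
    class_index: int | None = None,
) -> np.ndarray:
    """Per-individual HFS at one locus.

    HFS_i = mean(score[hap1, c], score[hap2, c]) - score[reference, c],
    rounded to two decimals (half away from zero), where c is the
    locus's reference sequence class. Individuals with a -1 haplotype
    index (dropped at QC) get NaN.
    """
    imap = np.asarray(individual_map)
    if class_index is None:
        class_index = reference_class(score_matrix.scores[score_matrix.reference_row])
    col = score_matrix.scores[:, class_index]
    valid = (imap >= 0).all(axis=1)
    if imap[valid].size and imap[valid].max() >= len(col):
        raise ValueError("haplotype index outside the score matrix")
    ref = col[score_matrix.reference_row]
    out = np.full(len(imap), np.nan)
    out[valid] = (col[imap[valid, 0]] + col[imap[valid, 1]]) / 2.0 - ref
    out[valid] = round_half_away(out[valid], 2)
    return out


def adjacent_ld(
    hfs: pd.DataFrame | np.ndarray,
    chroms: Sequence[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Squared Pearson correlation between consecutive loci's HFS columns.

    Columns must be in genomic order. Pairs spanning a chromosome
    boundary (per ``chroms``) are excluded; pairs where either column is
    constant yield NaN and are excluded from the median.

    Returns ``(per-pair R^2 array, median over defined pairs)``.
    """
    X = np.asarray(hfs, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two loci")
    if X.shape[0] < 3:
        raise ValueError("need at least three individuals")
    m = X.shape[1]
    r2 = np.full(m - 1, np.nan)
    sd = X.std(axis=0)
    for j in range(m - 1):
        if chroms is not None and chroms[j] != chroms[j + 1]:
            continue
        if sd[j] == 0 or sd[j + 1] == 0:
            continue
        r = np.corrcoef(X[:, j], X[:, j + 1])[0, 1]
        r2[j] = r * r
    defined = r2[np.isfinite(r2)]
    if defined.size == 0:
        raise ValueError("no usable adjacent pairs")
    return r2, float(np.median(defined))
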