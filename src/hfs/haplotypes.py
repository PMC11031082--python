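"""Per-locus variant QC, haplotype enumeration and sequence construction.

Starting from phased genotypes, each locus yields a table of distinct
haplotypes (defined by their allele vector over retained variants) and,
for each haplotype, a fixed-length DNA sequence built by editing the
reference sequence. Sequences are forced to exactly 4096 bp: insertions
push bases off the 3' end, deletions are padded with N at the 3' end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .segmentation import Locus

__all__ = [
    "VariantRecord",
    "HaplotypeTable",
    "hwe_exact_test",
    "qc_filter",
    "enumerate_haplotypes",
    "build_sequence",
    "read_locus_variants",
    "locus_haplotypes",
]

log = logging.getLogger(__name__)

SEQ_LEN = 4096


@dataclass
class VariantRecord:
    """One biallelic variant with phased genotypes.

    ``pos`` is 1-based (VCF convention). ``genotypes`` is an (n, 2)
    int8 array of allele indices with -1 for missing; ``phased`` is an
    (n,) boolean array.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    phased: np.ndarray | None = None
    info_score: float | None = None
    vid: str | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != 2:
            raise ValueError("genotypes must be (n, 2)")
        if self.phased is None:
            self.phased = np.ones(len(self.genotypes), dtype=bool)
        else:
            self.phased = np.asarray(self.phased, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def missing_mask(self) -> np.ndarray:
        return (self.genotypes < 0).any(axis=1)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class HaplotypeTable:
    """Distinct haplotypes at one locus.

    ``alleles`` is (H, m): allele vector of each haplotype over the m
    retained variants; row 0 is always the all-reference haplotype, even
    when absent from the sample. ``individual_map`` is (n, 2) with the
    haplotype index of each individual's two phased haplotypes;
    dropped individuals carry -1. ``sequences``, when built, holds one
    4096-bp string per haplotype.
    """

    locus_id: str
    alleles: np.ndarray
    individual_map: np.ndarray
    hap_counts: np.ndarray
    variants: list[VariantRecord] = field(default_factory=list)
    dropped_individuals: list[int] = field(default_factory=list)
    sequences: list[str] | None = None

    @property
    def n_haplotypes(self) -> int:
        return len(self.alleles)


def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts no more likely than the observed one (the
    standard exact test; no mid-p correction).
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # probabilities over all het counts with the same parity as n_rare
    het_min = n_rare % 2
    hets = np.arange(het_min, n_rare + 1, 2)
    # log P(het) up to a constant, via the standard recurrence made explicit
    from scipy.special import gammaln

    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * math.log(2)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het]
    if len(obs) == 0:  # parity mismatch: impossible configuration
        return 1.0
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


def qc_filter(
    variants: Sequence[VariantRecord],
    n_individuals: int,
    info_threshold: float = 0.8,
    hwe_threshold: float = 1e-6,
    mac_threshold: int = 10,
    missing_threshold: float = 0.10,
    individual_missing_threshold: float = 0.10,
) -> tuple[list[VariantRecord], list[int]]:
    """Variant and individual QC within one locus.

    A variant is retained iff its imputation INFO score is >= 0.8 (or
    absent), the exact HWE p-value is >= 1e-6, the minor allele count is
    >= 10 and the genotype missing rate is <= 10%. Individuals missing
    more than 10% of the retained variants are then reported as dropped.

    Returns ``(retained_variants, dropped_individual_indices)``.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    retained: list[VariantRecord] = []
    for v in variants:
        if v.info_score is not None and v.info_score < info_threshold:
            continue
        miss = v.missing_mask
        if miss.mean() > missing_threshold:
            continue
        complete = v.genotypes[~miss]
        alt_per_ind = (complete > 0).sum(axis=1)
        n_het = int((alt_per_ind == 1).sum())
        n_hom_alt = int((alt_per_ind == 2).sum())
        n_hom_ref = int((alt_per_ind == 0).sum())
        if hwe_exact_test(n_het, n_hom_ref, n_hom_alt) < hwe_threshold:
            continue
        ac = n_het + 2 * n_hom_alt
        mac = min(ac, 2 * len(complete) - ac)
        if mac < mac_threshold:
            continue
        retained.append(v)

    dropped: list[int] = []
    if retained:
        miss_counts = np.zeros(n_individuals)
        for v in retained:
            miss_counts += v.missing_mask
        dropped = list(np.nonzero(miss_counts / len(retained) > individual_missing_threshold)[0])
    return retained, dropped


class UnphasedGenotypeError(ValueError):
    pass


def enumerate_haplotypes(
    variants: Sequence[VariantRecord],
    locus_id: str,
    dropped_individuals: Sequence[int] = (),
) -> HaplotypeTable:
    """Enumerate distinct haplotypes from phased genotypes.

    Haplotypes are identified by their allele vector over the retained
    variants. The all-reference haplotype occupies index 0 whether or
    not it occurs in the sample. Missing alleles surviving QC are filled
    with the reference allele (logged). Heterozygous unphased genotypes
    raise :class:`UnphasedGenotypeError`.
    """
    if variants:
        n = variants[0].n_individuals
    else:
        n = 0
    dropped = set(int(i) for i in dropped_individuals)
    m = len(variants)

    hap_alleles = np.zeros((n, 2, m), dtype=np.int8)
    n_filled = 0
    for j, v in enumerate(variants):
        g = v.genotypes
        het = (g[:, 0] != g[:, 1]) & (g >= 0).all(axis=1)
        bad = np.nonzero(het & ~v.phased)[0]
        bad = [i for i in bad if i not in dropped]
        if bad:
            raise UnphasedGenotypeError(
                f"{locus_id}: unphased heterozygous genotype for individual {bad[0]}"
            )
        filled = np.where(g < 0, 0, g)
        n_filled += int((g < 0).sum())
        hap_alleles[:, :, j] = filled
    if n_filled:
        log.info("%s: %d missing alleles reference-filled", locus_id, n_filled)

    ref_key = bytes(m)
    index: dict[bytes, int] = {ref_key: 0}
    alleles_list: list[np.ndarray] = [np.zeros(m, dtype=np.int8)]
    counts: dict[int, int] = {0: 0}
    individual_map = np.full((n, 2), -1, dtype=np.int64)
    for i in range(n):
        if i in dropped:
            continue
        for c in (0, 1):
            key = hap_alleles[i, c].tobytes()
            h = index.get(key)
            if h is None:
                h = len(alleles_list)
                index[key] = h
                alleles_list.append(hap_alleles[i, c].copy())
                counts[h] = 0
            counts[h] += 1
            individual_map[i, c] = h

    H = len(alleles_list)
    hap_counts = np.array([counts.get(h, 0) for h in range(H)], dtype=np.int64)
    return HaplotypeTable(
        locus_id=locus_id,
        alleles=np.vstack(alleles_list) if H else np.zeros((1, m), dtype=np.int8),
        individual_map=individual_map,
        hap_counts=hap_counts,
        variants=list(variants),
        dropped_individuals=sorted(dropped),
    )


def build_sequence(
    reference_seq: str,
    allele_vector: Sequence[int],
    variants: Sequence[VariantRecord],
    locus_start: int,
    seq_len: int = SEQ_LEN,
) -> str:
    """Build one haplotype's DNA sequence from the locus reference.

    The sequence start is anchored to the reference start. Alternate
    alleles are spliced in at their (locus-relative) offsets; the result
    is then forced back to ``seq_len``: extra 3' bases from net insertion
    are discarded, net deletion is padded with N at the 3' end.

    ``locus_start`` is the 0-based genomic start of the reference
    sequence; variant positions are 1-based genomic coordinates.
    """
    if len(reference_seq) != seq_len:
        raise ValueError(f"reference sequence must be {seq_len} bp")
    applied = [
        (v, int(a))
        for v, a in zip(variants, allele_vector)
        if a > 0
    ]
    applied.sort(key=lambda t: t[0].pos)
    pieces: list[str] = []
    cursor = 0
    prev_end = -1
    ref_upper = reference_seq.upper()
    for v, _ in applied:
        offset = v.pos - 1 - locus_start
        if offset < 0 or offset >= seq_len:
            raise ValueError(f"variant {v.chrom}:{v.pos} outside locus")
        if offset < prev_end:
            raise ValueError(f"overlapping variants at {v.chrom}:{v.pos}")
        ref_allele = v.ref.upper()
        alt_allele = v.alt.upper()
        if offset + len(ref_allele) > seq_len:
            # REF span crosses the locus boundary: truncate to the locus
            keep = seq_len - offset
            ref_allele = ref_allele[:keep]
            alt_allele = alt_allele[: max(keep, 1)]
        if ref_upper[offset : offset + len(ref_allele)] != ref_allele:
            raise ValueError(
                f"REF mismatch at {v.chrom}:{v.pos}: expected {ref_allele}, "
                f"found {ref_upper[offset:offset + len(ref_allele)]}"
            )
        pieces.append(reference_seq[cursor:offset])
        pieces.append(alt_allele)
        cursor = offset + len(ref_allele)
        prev_end = cursor
    pieces.append(reference_seq[cursor:])
    seq = "".join(pieces)
    if len(seq) > seq_len:
        seq = seq[:seq_len]
    elif len(seq) < seq_len:
        seq = seq + "N" * (seq_len - len(seq))
    return seq


def _split_multiallelic(chrom, pos, ref, alts, gt, phased, info, vid):
    """Split a multi-allelic record into biallelic VariantRecords."""
    out = []
    for k, alt in enumerate(alts, start=1):
        g = np.where(gt < 0, -1, (gt == k).astype(np.int8))
        out.append(
            VariantRecord(chrom, pos, ref, alt, g, phased=phased, info_score=info, vid=vid)
        )
    return out


def read_locus_variants(
    vcf_path: str | Path,
    locus: Locus,
    info_field: str = "INFO_SCORE",
) -> tuple[list[VariantRecord], list[str]]:
    """Read biallelic variant records overlapping a locus from a VCF.

    Multi-allelic records are split into biallelic ones. Returns the
    variant list and the VCF sample names.
    """
    import os

    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    indexed = os.path.exists(f"{vcf_path}.tbi") or os.path.exists(f"{vcf_path}.csi")
    if indexed:
        records = vcf(f"{locus.chrom}:{locus.start + 1}-{locus.end}")
    else:  # plain-text VCF: full scan with position filtering
        records = (
            rec
            for rec in vcf
            if rec.CHROM == locus.chrom and locus.start < rec.POS <= locus.end
        )
    out: list[VariantRecord] = []
    for rec in records:
        gt = np.asarray(rec.genotype.array())
        phased = gt[:, 2].astype(bool) if gt.shape[1] > 2 else np.ones(len(gt), bool)
        alleles = gt[:, :2].astype(np.int16)
        info = rec.INFO.get(info_field)
        info = float(info) if info is not None else None
        out.extend(
            _split_multiallelic(
                rec.CHROM, rec.POS, rec.REF, rec.ALT, alleles, phased, info, rec.ID
            )
        )
    return out, samples


def locus_haplotypes(
    vcf_path: str | Path,
    fasta,
    locus: Locus,
    info_field: str = "INFO_SCORE",
    build_sequences: bool = True,
) -> HaplotypeTable:
    """Full per-locus pipeline: read, QC, enumerate, build sequences.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> sliceable
    sequence). Terminal loci shorter than 4096 bp are N-padded at the 3'
    end before variant splicing.
    """
    variants, samples = read_locus_variants(vcf_path, locus, info_field)
    n = len(samples)
    retained, dropped = qc_filter(variants, n_individuals=n)
    table = enumerate_haplotypes(retained, locus.locus_id, dropped)
    if table.individual_map.shape[0] == 0:
        # no retained variants: every individual is homozygous reference
        table.individual_map = np.zeros((n, 2), dtype=np.int64)
        table.hap_counts = np.array([2 * n], dtype=np.int64)
    if build_sequences:
        ref = str(fasta[locus.chrom][locus.start : locus.end])
        if len(ref) < SEQ_LEN:
            ref = ref + "N" * (SEQ_LEN - len(ref))
        table.sequences = [
            build_sequence(ref, row, table.variants, locus.start)
            for row in table.alleles
        ]
    return table
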