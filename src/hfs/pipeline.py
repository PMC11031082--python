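"""End-to-end glue: cohort files -> HFS matrix -> association -> PIPs.

Thin orchestration over the per-stage modules, shared by the command
line interface and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association, finemap, haplotypes, scoring, segmentation

__all__ = ["CohortHFS", "hfs_from_cohort", "associate_all", "finemap_blocks"]

DEFAULT_ACTIVE_STATES = {"TSS", "TX", "Enh", "Prom"}


@dataclass
class CohortHFS:
    """Per-cohort HFS matrix with per-locus metadata."""

    matrix: pd.DataFrame  # individuals x loci
    meta: pd.DataFrame  # per locus: reference_class, reference_score, n_haplotypes
    score_matrices: dict[str, scoring.ScoreMatrix]
    loci: list[segmentation.Locus]


def hfs_from_cohort(
    vcf_path: str | Path,
    fasta_path: str | Path,
    loci: Sequence[segmentation.Locus],
    scorer: scoring.SequenceScorer | None = None,
    info_field: str = "INFO_SCORE",
) -> CohortHFS:
    """Build the individuals x loci HFS matrix for a cohort.

    Per locus: read and QC variants, enumerate haplotypes, build their
    sequences against the reference genome, score them, and reduce to
    the reference-class HFS.
    """
    from pyfaidx import Fasta

    scorer = scorer or scoring.SurrogateScorer()
    fasta = Fasta(str(fasta_path))
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    score_mats: dict[str, scoring.ScoreMatrix] = {}
    index = None
    for locus in loci:
        table = haplotypes.locus_haplotypes(vcf_path, fasta, locus, info_field=info_field)
        sm = scoring.score_sequences(scorer, table.sequences, locus_id=locus.locus_id)
        c = scoring.reference_class(sm.scores[sm.reference_row])
        columns[locus.locus_id] = scoring.compute_hfs(sm, table.individual_map, c)
        score_mats[locus.locus_id] = sm
        meta_rows.append(
            {
                "locus_id": locus.locus_id,
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "reference_class": c,
                "reference_class_name": sm.class_names[c],
                "reference_score": float(sm.scores[sm.reference_row, c]),
                "n_haplotypes": table.n_haplotypes,
            }
        )
    from cyvcf2 import VCF

    samples = list(VCF(str(vcf_path)).samples)
    matrix = pd.DataFrame(columns, index=samples)
    meta = pd.DataFrame(meta_rows).set_index("locus_id")
    return CohortHFS(matrix=matrix, meta=meta, score_matrices=score_mats, loci=list(loci))


def associate_all(
    cohort: CohortHFS, trait: association.PreparedTrait
) -> list[association.AssocResult]:
    """Per-locus simple regression of the prepared trait on HFS."""
    results = []
    for locus in cohort.loci:
        results.append(
            association.associate(
                cohort.matrix[locus.locus_id].to_numpy(),
                trait,
                locus_id=locus.locus_id,
                chrom=locus.chrom,
                start=locus.start,
                end=locus.end,
            )
        )
    return results


def finemap_blocks(
    hfs: pd.DataFrame,
    loci: Sequence[segmentation.Locus],
    trait: association.PreparedTrait | np.ndarray,
    blocks: Sequence[finemap.Block] | None = None,
    L: int = 10,
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Fit SuSiE per independent block; concatenate per-locus results.

    With ``blocks`` omitted, each chromosome is one block. Returns a
    table indexed by locus id with PIP, posterior effect and credible
    set membership (-1 = none).
    """
    y = trait.values if isinstance(trait, association.PreparedTrait) else np.asarray(trait)
    if blocks is None:
        chroms = sorted({l.chrom for l in loci})
        blocks = [
            finemap.Block(c, c, 0, max(l.end for l in loci if l.chrom == c) + 1)
            for c in chroms
        ]
    block_of = finemap.assign_blocks(loci, blocks)
    rows = []
    for blk_id in sorted({b for b in block_of.values()}):
        members = [l for l in loci if block_of[l.locus_id] == blk_id]
        ids = [l.locus_id for l in members]
        X = hfs[ids].to_numpy(dtype=float)
        keep_rows = np.isfinite(X).all(axis=1) & np.isfinite(y)
        Xb, yb = X[keep_rows], y[keep_rows]
        if not (Xb.std(axis=0) > 0).any():
            for lid in ids:
                rows.append({"locus_id": lid, "block": blk_id, "pip": 0.0,
                             "posterior_effect": 0.0, "credible_set": -1})
            continue
        fit = finemap.susie_fit(Xb, yb, L=min(L, Xb.shape[1]), coverage=coverage)
        cs_of = {}
        for k, cs in enumerate(fit.credible_sets):
            for j in cs.members:
                cs_of[j] = k
        for j, lid in enumerate(ids):
            rows.append(
                {
                    "locus_id": lid,
                    "block": blk_id,
                    "pip": float(fit.pip[j]),
                    "posterior_effect": float(fit.posterior_effect[j]),
                    "credible_set": cs_of.get(j, -1),
                }
            )
    return pd.DataFrame(rows).set_index("locus_id")
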