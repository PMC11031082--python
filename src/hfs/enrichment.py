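"""Annotation construction and PIP-enrichment regression.

Fine-mapping PIPs are regressed on a panel of per-locus baseline
annotations (haplotype diversity, reference sequence-class scores,
conservation/selection statistics, genic-region flags) plus one
functional annotation at a time — a pathway (linked through SNP-to-gene
scores), a tissue chromatin-activity track, or a cell-type open-chromatin
track. An annotation is enriched when its coefficient is positive and
its Bonferroni-adjusted p-value is below 0.05; terms significant in more
than half of the traits are treated as confounder artifacts and removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "annotate_overlap",
    "prune_pathways",
    "link_pathway",
    "pip_regression",
    "bonferroni_significant",
    "filter_recurrent",
    "baseline_table",
    "aggregate_position_stats",
    "read_gmt",
]


def annotate_overlap(
    loci: Sequence, features: Sequence[tuple[str, int, int]], min_fraction: float = 0.1
) -> np.ndarray:
    """Binary overlap annotation per locus.

    A locus is flagged 1 when its total base overlap with the (merged)
    feature intervals is at least ``ceil(min_fraction * locus_length)``
    — the semantics of ``bedtools intersect -f``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, *_ in features:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        acc: list[list[int]] = []
        for s, e in ivs:
            if acc and s <= acc[-1][1]:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = [(s, e) for s, e in acc]

    out = np.zeros(len(loci), dtype=np.int8)
    for i, loc in enumerate(loci):
        need = math.ceil(min_fraction * loc.length)
        total = 0
        for s, e in merged.get(loc.chrom, ()):
            total += max(0, min(e, loc.end) - max(s, loc.start))
        out[i] = 1 if total >= need else 0
    return out


def _overlap_fraction(a: frozenset, b: frozenset) -> float:
    return len(a & b) / min(len(a), len(b))


def prune_pathways(
    gene_sets: Mapping[str, set],
    min_genes: int = 5,
    max_genes: int = 500,
    overlap_threshold: float = 0.3,
) -> dict[str, set]:
    """Size-filter and de-redundify gene sets.

    Sets with more than ``min_genes`` and fewer than ``max_genes``
    members (both strict) are kept; the rest are dropped. Survivors are
    ordered by average-linkage hierarchical clustering on Jaccard
    distance so similar sets sit next to each other, then adjacent pairs
    overlapping by more than ``overlap_threshold`` of the smaller set
    lose the smaller member (on a size tie, the later one). The scan is
    repeated to a fixed point, so pruning is idempotent.
    """
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    kept = {
        name: frozenset(genes)
        for name, genes in gene_sets.items()
        if min_genes < len(genes) < max_genes
    }
    while len(kept) > 1:
        names = list(kept)
        universe = sorted(set().union(*kept.values()))
        gene_idx = {g: i for i, g in enumerate(universe)}
        M = np.zeros((len(names), len(universe)), dtype=bool)
        for i, name in enumerate(names):
            M[i, [gene_idx[g] for g in kept[name]]] = True
        order = (
            hierarchy.leaves_list(hierarchy.linkage(pdist(M, metric="jaccard"), "average"))
            if len(names) > 2
            else range(len(names))
        )
        ordered = [names[i] for i in order]
        removed: set[str] = set()
        survivor = ordered[0]
        for nxt in ordered[1:]:
            if _overlap_fraction(kept[survivor], kept[nxt]) > overlap_threshold:
                if len(kept[nxt]) <= len(kept[survivor]):
                    removed.add(nxt)
                    continue  # survivor stays, compare it to the next set
                removed.add(survivor)
            survivor = nxt
        if not removed:
            break
        kept = {n: s for n, s in kept.items() if n not in removed}
    return {n: set(s) for n, s in kept.items()}


def link_pathway(
    loci: Sequence,
    link_table: pd.DataFrame,
    gene_set: set,
    score_threshold: float = 0.5,
) -> np.ndarray:
    """SNP-to-gene pathway annotation of loci.

    A locus is annotated 1 for a pathway when it contains a SNP linked
    to a pathway gene with a link (cS2G-style) score strictly greater
    than ``score_threshold``. ``link_table`` needs columns
    ``chrom, pos, gene, score`` (pos 1-based).
    """
    hits = link_table[
        (link_table["score"] > score_threshold) & link_table["gene"].isin(gene_set)
    ]
    out = np.zeros(len(loci), dtype=np.int8)
    if hits.empty:
        return out
    for i, loc in enumerate(loci):
        sub = hits[
            (hits["chrom"] == loc.chrom)
            & (hits["pos"] > loc.start)
            & (hits["pos"] <= loc.end)
        ]
        if len(sub):
            out[i] = 1
    return out


@dataclass
class EnrichmentResult:
    annotation: str
    coef: float
    t: float
    p: float
    skipped: bool = False
    reason: str | None = None


def pip_regression(
    pip: np.ndarray,
    baseline: np.ndarray | pd.DataFrame,
    annotation: np.ndarray,
    name: str = "",
) -> EnrichmentResult:
    """OLS of PIP on the baseline panel plus one functional annotation.

    PIP is modeled directly on its [0, 1] scale. Returns the
    annotation coefficient, its t statistic and two-sided p-value; an
    annotation collinear with the baseline is skipped with a reason
    code rather than tested.
    """
    import statsmodels.api as sm

    pip = np.asarray(pip, dtype=float)
    B = np.asarray(baseline, dtype=float)
    a = np.asarray(annotation, dtype=float)
    if pip.ndim != 1 or len(pip) != len(a) or len(pip) != B.shape[0]:
        raise ValueError("inconsistent input lengths")
    design_base = np.column_stack([np.ones(len(pip)), B])
    if len(pip) <= design_base.shape[1] + 2:
        raise ValueError("too few loci for the baseline panel")
    # collinearity check: does the annotation add rank?
    coef, *_ = np.linalg.lstsq(design_base, a, rcond=None)
    resid = a - design_base @ coef
    if np.var(a) == 0 or float(resid @ resid) < 1e-10 * max(float(a @ a), 1e-300):
        return EnrichmentResult(name, np.nan, np.nan, np.nan, skipped=True,
                                reason="collinear_with_baseline")
    design = np.column_stack([design_base, a])
    fit = sm.OLS(pip, design).fit()
    return EnrichmentResult(
        name, float(fit.params[-1]), float(fit.tvalues[-1]), float(fit.pvalues[-1])
    )


def bonferroni_significant(
    results: Sequence[EnrichmentResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the positive-coefficient + Bonferroni rule over one family.

    The family is every annotation actually tested (not skipped) for one
    trait. Returns a table with adjusted p-values and significance calls.
    """
    tested = [r for r in results if not r.skipped]
    n_tests = len(tested)
    rows = []
    for r in results:
        p_adj = min(r.p * n_tests, 1.0) if not r.skipped else np.nan
        rows.append(
            {
                "annotation": r.annotation,
                "coef": r.coef,
                "t": r.t,
                "p": r.p,
                "p_adj": p_adj,
                "significant": bool(
                    not r.skipped and r.coef > 0 and p_adj < alpha
                ),
                "skipped": r.skipped,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def filter_recurrent(
    significant_by_trait: Mapping[str, set], n_traits: int | None = None
) -> tuple[dict[str, set], set]:
    """Drop terms significant in more than half of the traits.

    Such recurrent terms likely reflect unrecognized confounders rather
    than trait biology. Returns the filtered per-trait sets and the set
    of removed terms.
    """
    if n_traits is None:
        n_traits = len(significant_by_trait)
    counts: dict[str, int] = {}
    for terms in significant_by_trait.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    recurrent = {t for t, c in counts.items() if c > n_traits / 2}
    return (
        {trait: terms - recurrent for trait, terms in significant_by_trait.items()},
        recurrent,
    )


def aggregate_position_stats(
    loci: Sequence, table: pd.DataFrame, value: str, how: str
) -> np.ndarray:
    """Per-locus aggregate (max/min/mean) of a per-position statistic.

    ``table`` needs columns ``chrom, pos`` (1-based) and ``value``.
    Loci with no overlapping positions get NaN.
    """
    fn = {"max": np.max, "min": np.min, "mean": np.mean}[how]
    out = np.full(len(loci), np.nan)
    for i, loc in enumerate(loci):
        sub = table[
            (table["chrom"] == loc.chrom)
            & (table["pos"] > loc.start)
            & (table["pos"] <= loc.end)
        ]
        if len(sub):
            out[i] = fn(sub[value].to_numpy(dtype=float))
    return out


def baseline_table(
    loci: Sequence,
    n_haplotypes: np.ndarray,
    score_matrices: Sequence,
    region_flags: Mapping[str, np.ndarray] | None = None,
    position_stats: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the per-locus baseline annotation panel.

    Columns: number of haplotypes; HFS range across haplotypes scaled by
    the absolute reference score (NaN-guarded when the reference score
    is ~0, flagged in ``hfs_range_undefined``); the 39 reference
    sequence-class scores; then any supplied binary genomic-region flags
    and per-locus selection/age statistics.
    """
    from .scoring import reference_class

    rows = {}
    rows["n_haplotypes"] = np.asarray(n_haplotypes, dtype=float)
    hfs_range = np.full(len(loci), np.nan)
    undefined = np.zeros(len(loci))
    ref_scores = np.zeros((len(loci), score_matrices[0].scores.shape[1]))
    for i, sm_ in enumerate(score_matrices):
        c = reference_class(sm_.scores[sm_.reference_row])
        col = sm_.scores[:, c]
        ref = col[sm_.reference_row]
        if abs(ref) < 1e-12:
            undefined[i] = 1
        else:
            hfs_range[i] = (col.max() - col.min()) / abs(ref)
        ref_scores[i] = sm_.scores[sm_.reference_row]
    rows["hfs_range"] = hfs_range
    rows["hfs_range_undefined"] = undefined
    df = pd.DataFrame(rows)
    for j, name in enumerate(score_matrices[0].class_names):
        df[f"ref_score:{name}"] = ref_scores[:, j]
    for name, flags in (region_flags or {}).items():
        df[name] = np.asarray(flags, dtype=float)
    for name, vals in (position_stats or {}).items():
        df[name] = np.asarray(vals, dtype=float)
    return df


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name, description, genes...."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            out[fields[0]] = set(g for g in fields[2:] if g)
    return out
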