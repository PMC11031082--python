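"""Synthetic data generation and the fine-mapping evaluation study.

Two generators are provided. :func:`generate_synthetic_hfs` emulates a
cohort's HFS matrix directly: each locus carries a pool of haplotype
scores with a rare-skewed frequency spectrum, individuals draw two
haplotypes, and a weak latent correlation along each block reproduces
the near-independence of adjacent loci seen in real data (median
adjacent R^2 about 0.013). :func:`generate_fixture_cohort` writes a
full toy cohort on disk (genome FASTA, phased VCF, chromatin-state and
gap BEDs, phenotype table, truth manifest) for end-to-end pipeline
tests.

The evaluation study follows the standard recipe: select 1% of loci as
causal with standard-normal effect sizes, simulate a trait at
h^2 = 0.1, fine-map every block, and summarize discrimination (AUC of
the PIP for causal vs non-causal loci) and calibration (FDR among loci
called at PIP > 0.95) across replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .scoring import round_half_away

__all__ = [
    "SimTruth",
    "EvalSummary",
    "SyntheticHFS",
    "generate_synthetic_hfs",
    "simulate_trait",
    "evaluate_finemap",
    "run_simulation_study",
    "FixtureParams",
    "generate_fixture_cohort",
]

# study conditions of the reference evaluation, scaled to preserve the
# per-causal-locus non-centrality n * h^2 / m_causal = 10
DESK_N = 5_000
DESK_M = 5_000
DESK_BLOCKS = 50
DESK_PROP_CAUSAL = 0.01
DESK_H2 = 0.1
DEFAULT_ADJACENT_R2 = 0.013


@dataclass
class SimTruth:
    causal: np.ndarray  # locus column indices
    effects: np.ndarray  # standard-normal effect sizes, one per causal locus
    h2: float
    seed: int
    replicate: int = 0


@dataclass
class EvalSummary:
    replicates: pd.DataFrame
    median_auc: float
    median_fdr: float

    def to_json(self) -> dict:
        return {
            "median_auc": self.median_auc,
            "median_fdr": self.median_fdr,
            "replicates": self.replicates.to_dict(orient="records"),
        }


@dataclass
class SyntheticHFS:
    """An individuals x loci HFS matrix with its generating metadata."""

    values: np.ndarray
    block_of: np.ndarray  # block index per locus
    pools: list  # per locus: (sorted score offsets, haplotype frequencies)
    rho: float
    seed: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def block_slices(self) -> list[slice]:
        out = []
        start = 0
        for b in range(self.block_of.max() + 1):
            size = int((self.block_of == b).sum())
            out.append(slice(start, start + size))
            start += size
        return out


FUNCTIONAL_LOCUS_FRACTION = 0.4
FUNCTIONAL_OFFSET_SD = 0.25
NOISE_OFFSET_SD = 0.003  # below the 0.01 rounding quantum


def _locus_pools(
    rng: np.random.Generator,
    m: int,
    rare_fraction: float | None,
    functional_fraction: float = FUNCTIONAL_LOCUS_FRACTION,
):
    """Per-locus haplotype score pools.

    Haplotype frequencies follow a renormalized Beta(0.2, 2) spectrum,
    which guarantees a tail of rare haplotypes; the reference haplotype
    (score offset 0) receives the largest frequency. Only a
    ``functional_fraction`` of loci carry haplotypes whose score offsets
    are on a functional scale (sd 0.25); at the rest, offsets are
    scorer-level noise (sd 0.003) that the two-decimal rounding sets to
    exactly zero — emulating that most genomic windows harbor no common
    haplotype that moves their class score. ``rare_fraction`` optionally
    forces that fraction of loci to carry only rare alternative
    haplotypes (combined frequency capped at 5%), for studies of
    rare-haplotype signal specifically. Pools are returned ordered by
    score offset so a shared latent uniform induces positive
    cross-locus score correlation.
    """
    pools = []
    rare = rng.random(m) < (rare_fraction or 0.0)
    functional = rng.random(m) < functional_fraction
    for j in range(m):
        K = int(rng.integers(3, 11))
        freqs = rng.beta(0.2, 2.0, size=K)
        freqs = freqs / freqs.sum()
        freqs = np.sort(freqs)[::-1]
        scale = FUNCTIONAL_OFFSET_SD if functional[j] else NOISE_OFFSET_SD
        offsets = np.concatenate([[0.0], rng.normal(0.0, scale, size=K - 1)])
        if rare[j]:
            alt = freqs[1:].sum()
            if alt > 0.05:
                freqs = np.concatenate([[0.0], freqs[1:] * (0.05 / alt)])
                freqs[0] = 1.0 - freqs[1:].sum()
        order = np.argsort(offsets, kind="stable")
        pools.append((offsets[order], freqs[order]))
    return pools


def _draw_matrix(
    rng: np.random.Generator,
    pools: list,
    n: int,
    block_sizes: Sequence[int],
    rho: float,
) -> np.ndarray:
    """Draw the HFS matrix given pools and the latent AR(1) strength."""
    m = len(pools)
    values = np.empty((n, m))
    j0 = 0
    for bs in block_sizes:
        z = rng.standard_normal((n, 2))
        for j in range(j0, j0 + bs):
            if j > j0 and rho > 0:
                z = rho * z + np.sqrt(1.0 - rho * rho) * rng.standard_normal((n, 2))
            elif j > j0:
                z = rng.standard_normal((n, 2))
            u = ndtr(z)
            offsets, freqs = pools[j]
            h = np.searchsorted(np.cumsum(freqs), u, side="right")
            h = np.clip(h, 0, len(offsets) - 1)
            s = offsets[h]
            values[:, j] = (s[:, 0] + s[:, 1]) / 2.0
        j0 += bs
    return round_half_away(values, 2)


def _median_adjacent_r2(values: np.ndarray, block_of: np.ndarray) -> float:
    sd = values.std(axis=0)
    r2 = []
    for j in range(values.shape[1] - 1):
        if block_of[j] != block_of[j + 1] or sd[j] == 0 or sd[j + 1] == 0:
            continue
        r = np.corrcoef(values[:, j], values[:, j + 1])[0, 1]
        r2.append(r * r)
    return float(np.median(r2)) if r2 else np.nan


def generate_synthetic_hfs(
    n: int,
    m: int,
    n_blocks: int = 1,
    target_adjacent_r2: float = DEFAULT_ADJACENT_R2,
    rare_fraction: float | None = None,
    functional_fraction: float = FUNCTIONAL_LOCUS_FRACTION,
    seed: int = 0,
) -> SyntheticHFS:
    """Generate an individuals x loci HFS matrix.

    Values are reference-centered (a homozygous-reference draw scores
    exactly 0) and rounded to two decimals. The latent AR(1)
    correlation along each block is calibrated on a pilot draw so the
    realized median adjacent-locus R^2 lands near
    ``target_adjacent_r2``; ``target_adjacent_r2 = 0`` gives fully
    independent loci. Fully reproducible from ``seed``.
    """
    if n < 2 or m < 2:
        raise ValueError("need n, m >= 2")
    if not (0 <= target_adjacent_r2 < 1):
        raise ValueError("target adjacent R^2 must be in [0, 1)")
    ss = np.random.SeedSequence(seed)
    rng_pool, rng_pilot, rng_final = (np.random.default_rng(s) for s in ss.spawn(3))

    base = m // n_blocks
    block_sizes = [base + (1 if b < m % n_blocks else 0) for b in range(n_blocks)]
    block_of = np.repeat(np.arange(n_blocks), block_sizes)
    pools = _locus_pools(rng_pool, m, rare_fraction, functional_fraction)

    rho = 0.0
    if target_adjacent_r2 > 0:
        # one-step pilot calibration of the latent correlation
        rho0 = 0.25
        n_pilot = min(n, 2000)
        pilot = _draw_matrix(rng_pilot, pools, n_pilot, block_sizes, rho0)
        a0 = _median_adjacent_r2(pilot, block_of)
        if not np.isfinite(a0) or a0 <= 0:
            raise ValueError("infeasible correlation target: pilot carries no signal")
        rho = float(np.clip(rho0 * np.sqrt(target_adjacent_r2 / a0), 0.0, 0.99))

    values = _draw_matrix(rng_final, pools, n, block_sizes, rho)
    return SyntheticHFS(values=values, block_of=block_of, pools=pools, rho=rho, seed=seed)


def simulate_trait(
    hfs: np.ndarray | SyntheticHFS,
    prop_causal: float = DESK_PROP_CAUSAL,
    h2: float = DESK_H2,
    seed: int = 0,
    replicate: int = 0,
    standardize: bool = True,
) -> tuple[np.ndarray, SimTruth]:
    """Simulate a quantitative trait from an HFS matrix.

    ``round(prop_causal * m)`` loci are drawn as causal (uniformly among
    polymorphic loci) with Normal(0, 1) effect sizes; the genetic
    liability g is their weighted column sum, and noise orthogonal to g
    is added so that var(g) / var(trait) equals ``h2`` exactly
    in-sample.

    With ``standardize`` (the default, and the field's standard
    liability construction) each causal column is scaled to unit
    variance before weighting, so every causal locus contributes
    beta_j^2 of the genetic variance regardless of its allele-frequency
    profile; ``standardize=False`` weights the raw HFS values instead.
    """
    X = hfs.values if isinstance(hfs, SyntheticHFS) else np.asarray(hfs, float)
    n, m = X.shape
    n_causal = int(round(prop_causal * m))
    if n_causal < 1:
        raise ValueError("prop_causal * m must be at least 1")
    if not (0 < h2 <= 1):
        raise ValueError("h2 must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))
    sd = X.std(axis=0)
    eligible = np.nonzero(sd > 0)[0] if standardize else np.arange(m)
    if len(eligible) < n_causal:
        raise ValueError("not enough polymorphic loci for the causal set")
    for attempt in range(2):
        causal = np.sort(rng.choice(eligible, size=n_causal, replace=False))
        effects = rng.standard_normal(n_causal)
        Xc = X[:, causal]
        if standardize:
            Xc = (Xc - Xc.mean(axis=0)) / sd[causal]
        g = Xc @ effects
        if g.var() > 0:
            break
    else:
        raise ValueError("all causal columns constant; cannot simulate a trait")
    if h2 >= 1.0:
        return g.copy(), SimTruth(causal, effects, h2, seed, replicate)
    e = rng.standard_normal(n)
    gc = g - g.mean()
    e = e - e.mean() - (e @ gc) / (gc @ gc) * gc  # orthogonal to g
    e *= np.sqrt(g.var() * (1.0 - h2) / h2 / e.var())
    return g + e, SimTruth(causal, effects, h2, seed, replicate)


def evaluate_finemap(
    pips: np.ndarray, truth: SimTruth, pip_threshold: float = 0.95
) -> dict:
    """Discrimination and calibration of one replicate's PIPs.

    AUC is the rank-based probability that a causal locus outranks a
    non-causal one (ties mid-ranked); FDR is false calls over all calls
    at PIP > threshold, 0 by convention when nothing is called
    (``n_calls`` reports the case).
    """
    from sklearn.metrics import roc_auc_score

    pips = np.asarray(pips, dtype=float)
    labels = np.zeros(len(pips), dtype=int)
    if len(truth.causal) == 0:
        raise ValueError("truth contains no causal loci")
    labels[truth.causal] = 1
    auc = float(roc_auc_score(labels, pips))
    called = pips > pip_threshold
    n_calls = int(called.sum())
    tp = int((called & (labels == 1)).sum())
    fp = n_calls - tp
    fdr = fp / n_calls if n_calls else 0.0
    return {
        "auc": auc,
        "fdr": float(fdr),
        "n_calls": n_calls,
        "tp": tp,
        "fp": fp,
        "n_causal": int(len(truth.causal)),
    }


def run_simulation_study(
    n: int = DESK_N,
    m: int = DESK_M,
    n_blocks: int = DESK_BLOCKS,
    prop_causal: float = DESK_PROP_CAUSAL,
    h2: float = DESK_H2,
    reps: int = 5,
    seed: int = 0,
    L: int = 10,
    coverage: float = 0.95,
    pip_threshold: float = 0.95,
    target_adjacent_r2: float = DEFAULT_ADJACENT_R2,
) -> EvalSummary:
    """The scaled fine-mapping evaluation study.

    Per replicate: generate a fresh synthetic HFS matrix, simulate a
    trait, standardize it, fit SuSiE independently in every block, and
    score the concatenated PIPs against the planted causal set. Medians
    across replicates summarize discrimination (AUC) and calibration
    (FDR at PIP > 0.95).
    """
    from .finemap import susie_fit

    rows = []
    for r in range(reps):
        rep_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(1000 + r,)).generate_state(1)[0] % (2**31))
        synth = generate_synthetic_hfs(
            n, m, n_blocks=n_blocks, target_adjacent_r2=target_adjacent_r2, seed=rep_seed
        )
        y, truth = simulate_trait(synth, prop_causal=prop_causal, h2=h2,
                                  seed=rep_seed, replicate=r)
        y = (y - y.mean()) / y.std()
        pips = np.zeros(m)
        for sl in synth.block_slices():
            Xb = synth.values[:, sl]
            if (Xb.std(axis=0) > 0).any():
                fit = susie_fit(Xb, y, L=L, coverage=coverage)
                pips[sl] = fit.pip
        row = evaluate_finemap(pips, truth, pip_threshold=pip_threshold)
        row["replicate"] = r
        row["seed"] = rep_seed
        rows.append(row)
    df = pd.DataFrame(rows)
    return EvalSummary(
        replicates=df,
        median_auc=float(df["auc"].median()),
        median_fdr=float(df["fdr"].median()),
    )


# ---------------------------------------------------------------------------
# on-disk toy cohort


@dataclass
class FixtureParams:
    """Study conditions of the end-to-end toy cohort."""

    n_individuals: int = 150
    n_loci: int = 48  # genome length = n_loci * 4096
    n_active_regions: int = 6
    n_causal: int = 3
    h2: float = 0.6
    snp_rate: float = 0.8  # fraction of loci carrying polymorphism
    max_haplotypes: int = 4
    effect_motif_repeats: int = 8


def _write_fasta(path: Path, chrom: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _vcf_header(chrom: str, length: int, samples: list[str]) -> str:
    cols = "\t".join(samples)
    return (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={chrom},length={length}>\n"
        '##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="Imputation quality">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n"
    )


def generate_fixture_cohort(
    out_dir: str | Path, seed: int = 0, params: FixtureParams | None = None
) -> dict:
    """Write a self-consistent toy cohort and return its truth manifest.

    Files: ``genome.fa``, ``cohort.vcf`` (phased GT + INFO_SCORE),
    ``states/<tissue>_<sample>.bed`` chromatin-state BEDs, ``gaps.bed``,
    ``chrom.sizes``, ``phenotype.tsv`` and ``manifest.json``.

    Causal loci carry an alternative haplotype in which a stretch of
    sequence is replaced by repeats of a motif of the locus's reference
    sequence class, so the surrogate scorer sees a real functional
    shift; the trait is built from the causal-haplotype dosages at the
    planted heritability.
    """
    from .scoring import SurrogateScorer, reference_class
    from .segmentation import LOCUS_SIZE

    params = params or FixtureParams()
    out = Path(out_dir)
    (out / "states").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(77,)))
    chrom = "chrS"
    glen = params.n_loci * LOCUS_SIZE
    genome = "".join(rng.choice(list("ACGT"), size=glen))
    _write_fasta(out / "genome.fa", chrom, genome)
    with open(out / "chrom.sizes", "w") as fh:
        fh.write(f"{chrom}\t{glen}\n")

    # assembly gap in the last locus-sized window
    gap = (glen - LOCUS_SIZE, glen - LOCUS_SIZE // 2)
    with open(out / "gaps.bed", "w") as fh:
        fh.write(f"{chrom}\t{gap[0]}\t{gap[1]}\n")

    # chromatin states: active regions centered on their locus window so
    # segmentation reproduces the aligned windows; quiescent elsewhere
    region_windows = np.sort(
        rng.choice(np.arange(2, params.n_loci - 2), params.n_active_regions, replace=False)
    )
    active_regions = []
    for j in region_windows:
        half = int(rng.integers(400, 1500))
        center = j * LOCUS_SIZE + LOCUS_SIZE // 2
        active_regions.append((center - half, center + half))
    states = ("TSS", "TX", "Enh", "Prom")
    for tissue in ("tissueA", "tissueB"):
        regions = active_regions if tissue == "tissueA" else active_regions[::2]
        for sample in ("s1", "s2"):
            with open(out / "states" / f"{tissue}_{sample}.bed", "w") as fh:
                cursor = 0
                for k, (s, e) in enumerate(regions):
                    if s > cursor:
                        fh.write(f"{chrom}\t{cursor}\t{s}\tQuies\n")
                    fh.write(f"{chrom}\t{s}\t{e}\t{states[k % len(states)]}\n")
                    cursor = e
                fh.write(f"{chrom}\t{cursor}\t{glen}\tQuies\n")

    # per-locus haplotype structure over simple windows
    n = params.n_individuals
    samples = [f"ind{i:03d}" for i in range(n)]
    scorer = SurrogateScorer()
    windows = [(j * LOCUS_SIZE, (j + 1) * LOCUS_SIZE) for j in range(params.n_loci)]
    poly = [
        j
        for j in range(params.n_loci)
        if rng.random() < params.snp_rate and windows[j][1] <= gap[0]
    ]
    causal = sorted(rng.choice(poly, size=params.n_causal, replace=False).tolist())

    vcf_rows: list[tuple[int, str]] = []
    manifest_loci = {}
    dosages = np.zeros((n, len(causal)))
    for j in poly:
        w0, w1 = windows[j]
        is_causal = j in causal
        mnp_pos = w0 + LOCUS_SIZE // 2  # reserved for the causal edit
        mnp_span = 6 * params.effect_motif_repeats
        n_snps = int(rng.integers(1, 4))
        candidates = np.concatenate(
            [np.arange(w0 + 100, mnp_pos - 10), np.arange(mnp_pos + mnp_span + 10, w1 - 100)]
        )
        positions = np.sort(rng.choice(candidates, n_snps, replace=False))
        # distinct nonzero patterns over n_snps SNPs bound the pool size
        n_hap = int(min(rng.integers(2, params.max_haplotypes + 1), 2**n_snps))
        # haplotype allele patterns; row 0 = reference
        patterns = np.zeros((n_hap, n_snps), dtype=int)
        for h in range(1, n_hap):
            while True:
                patterns[h] = rng.integers(0, 2, n_snps)
                if patterns[h].any() and not (patterns[:h] == patterns[h]).all(axis=1).any():
                    break
        # haplotype counts: every planted haplotype occurs often enough
        # that each variant deterministically clears the allele-count QC
        raw = np.sort(rng.dirichlet(np.ones(n_hap) * 0.8))[::-1]
        counts = np.maximum(np.round(raw * 2 * n).astype(int), 14)
        counts[0] = 2 * n - counts[1:].sum()
        hap_list = np.repeat(np.arange(n_hap), counts)
        rng.shuffle(hap_list)
        hap_idx = hap_list.reshape(n, 2)

        variant_list = []
        for k, pos0 in enumerate(positions):  # pos0 is 0-based
            ref = genome[pos0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            carried = patterns[:, k]
            gts = carried[hap_idx]  # (n, 2)
            variant_list.append((int(pos0), ref, alt, gts))

        if is_causal:
            # replace a stretch with repeats of a reference-class motif
            ref_seq = genome[w0:w1]
            c = reference_class(scorer.score(ref_seq))
            motif = scorer.manifest[scorer.class_names[c]][0][0]
            ref_allele = genome[mnp_pos : mnp_pos + mnp_span]
            alt_allele = motif * params.effect_motif_repeats
            # carried by every non-reference haplotype
            carried = (np.arange(n_hap) > 0).astype(int)
            gts = carried[hap_idx]
            variant_list.append((mnp_pos, ref_allele, alt_allele, gts))
            dosages[:, causal.index(j)] = gts.sum(axis=1)

        variant_list.sort(key=lambda t: t[0])
        for pos0, ref, alt, gts in variant_list:
            info = float(np.round(rng.uniform(0.9, 1.0), 3))
            gt_strs = [f"{a}|{b}" for a, b in gts]
            vcf_rows.append(
                (
                    pos0,
                    f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t"
                    f"INFO_SCORE={info}\tGT\t" + "\t".join(gt_strs),
                )
            )
        manifest_loci[f"{chrom}:{w0}-{w1}"] = {
            "window": [w0, w1],
            "n_variants": len(variant_list),
            "expected_haplotypes": n_hap,
            "causal": is_causal,
            "variant_positions": [int(p) + 1 for p, *_ in variant_list],
        }

    vcf_rows.sort(key=lambda t: t[0])
    with open(out / "cohort.vcf", "w") as fh:
        fh.write(_vcf_header(chrom, glen, samples))
        for _, row in vcf_rows:
            fh.write(row + "\n")

    # trait from causal-haplotype dosages at the planted heritability
    effects = rng.normal(1.0, 0.25, size=len(causal)) * rng.choice([-1, 1], len(causal))
    g = dosages @ effects
    e = rng.standard_normal(n)
    gc = g - g.mean()
    e = e - e.mean() - (e @ gc) / (gc @ gc) * gc
    e *= np.sqrt(g.var() * (1 - params.h2) / params.h2 / max(e.var(), 1e-12))
    trait = g + e
    age = rng.integers(40, 70, n)
    sex = rng.integers(0, 2, n)
    pd.DataFrame(
        {"id": samples, "trait": trait, "age": age, "sex": sex}
    ).to_csv(out / "phenotype.tsv", sep="\t", index=False)

    manifest = {
        "seed": seed,
        "chrom": chrom,
        "genome_length": glen,
        "n_individuals": n,
        "gap": list(gap),
        "active_regions": [[int(r[0]), int(r[1])] for r in active_regions],
        "causal_windows": [f"{chrom}:{windows[j][0]}-{windows[j][1]}" for j in causal],
        "effects": effects.tolist(),
        "h2": params.h2,
        "loci": manifest_loci,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
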