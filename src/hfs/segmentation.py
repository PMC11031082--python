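"""Genome segmentation into fixed-size loci.

The unit of analysis is a 4096-bp locus. Loci are derived from
chromatin-state annotations: per tissue, bases called in an active state
(TSS, transcribed, enhancer, promoter) by at least half of the samples
form active regions; the cross-tissue union of active regions seeds the
loci. Short regions get a single locus centered on them, long regions are
tiled outward from their midpoint, and the rest of the genome is covered
by non-overlapping gap-fill blocks.

All coordinates are BED-style: 0-based, half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ActiveRegion",
    "Locus",
    "read_bed",
    "read_chrom_sizes",
    "derive_active_regions",
    "tile_genome",
    "sliding_shift",
    "write_loci_bed",
    "read_loci_bed",
]

LOCUS_SIZE = 4096


@dataclass(frozen=True)
class ActiveRegion:
    """A merged genomic interval active in enough samples."""

    chrom: str
    start: int
    end: int
    n_supporting: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Locus:
    """A fixed-size analysis window.

    ``origin`` records provenance: ``centered`` (around a short active
    region), ``midpoint_tile`` (tiled from a long region's midpoint) or
    ``gap_fill`` (covering the remaining genome). ``flagged`` marks loci
    that were clipped, shifted into chromosome bounds, or are terminal
    remainders shorter than the nominal size.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    origin: str
    flagged: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class BedFormatError(ValueError):
    """A BED line that cannot be parsed, reported with its line number."""


def read_bed(path: str | Path, min_fields: int = 3) -> list[tuple]:
    """Parse a BED file into ``(chrom, start, end, *rest)`` tuples.

    Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedFormatError(f"{path}:{lineno}: expected >= {min_fields} fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise BedFormatError(f"{path}:{lineno}: end < start")
            out.append((fields[0], start, end, *fields[3:]))
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def _merge(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping or abutting intervals, per chromosome."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def _threshold_coverage(
    per_sample: Sequence[list[tuple[str, int, int]]], min_count: int
) -> list[tuple[str, int, int, int]]:
    """Sweep-line per-base coverage counting.

    Returns maximal intervals where the number of samples covering every
    base is >= ``min_count``, with the peak support count attached.
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for sample_iv in per_sample:
        # each sample contributes at most +1 per base
        for chrom, start, end in _merge(sample_iv):
            events.setdefault(chrom, []).append((start, +1))
            events[chrom].append((end, -1))
    out: list[tuple[str, int, int, int]] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        open_start = None
        peak = 0
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth >= min_count and open_start is None:
                open_start, peak = pos, depth
            elif open_start is not None:
                peak = max(peak, depth)
                if depth < min_count:
                    out.append((chrom, open_start, pos, peak))
                    open_start = None
    return out


def derive_active_regions(
    state_beds: Mapping[str, Sequence[str | Path]] | Sequence[str | Path],
    active_states: set[str],
    min_fraction: float = 0.5,
    gaps: Sequence[tuple[str, int, int]] | None = None,
) -> list[ActiveRegion]:
    """Call active regions from per-sample chromatin-state BEDs.

    Parameters
    ----------
    state_beds
        Either a mapping ``tissue -> [sample BED paths]`` or a flat list
        of sample BED paths (treated as a single tissue). Each BED must
        carry the state name in column 4.
    active_states
        State names counted as active (e.g. ``{"TSS", "TX", "Enh", "Prom"}``).
    min_fraction
        Within each tissue, a base is active when at least
        ``ceil(min_fraction * n_samples)`` samples assign it an active
        state. Counting is per base, not per interval.
    gaps
        Assembly gap intervals; any thresholded region overlapping a gap
        is removed.

    Returns
    -------
    list of :class:`ActiveRegion`, the cross-tissue union, merged, sorted.
    """
    if not isinstance(state_beds, Mapping):
        state_beds = {"_all": list(state_beds)}
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    per_tissue: list[tuple[str, int, int, int]] = []
    for tissue, paths in state_beds.items():
        paths = list(paths)
        if not paths:
            raise ValueError(f"tissue {tissue!r} has no sample BEDs")
        sample_ivs = []
        for p in paths:
            rows = read_bed(p, min_fields=4)
            sample_ivs.append(
                [(c, s, e) for c, s, e, *rest in rows if rest[0] in active_states]
            )
        min_count = math.ceil(min_fraction * len(paths))
        per_tissue.extend(_threshold_coverage(sample_ivs, min_count))

    support = {}
    for chrom, start, end, peak in per_tissue:
        support[(chrom, start, end)] = max(support.get((chrom, start, end), 0), peak)
    union = _merge((c, s, e) for c, s, e, _ in per_tissue)

    if gaps:
        gap_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e, *_ in gaps:
            gap_by_chrom.setdefault(c, []).append((s, e))
        union = [
            (c, s, e)
            for c, s, e in union
            if not any(s < ge and gs < e for gs, ge in gap_by_chrom.get(c, ()))
        ]

    out = []
    for chrom, start, end in union:
        peak = max(
            (p for (c, s, e, p) in per_tissue if c == chrom and s < end and start < e),
            default=0,
        )
        out.append(ActiveRegion(chrom, start, end, n_supporting=peak))
    return out


def _candidates_for_region(
    region: ActiveRegion, locus_size: int
) -> list[tuple[int, int, str]]:
    """Candidate loci for one active region, unclipped.

    Regions not longer than the locus size get a single locus centered on
    the region midpoint. Longer regions are tiled with the midpoint as a
    tile boundary, alternately rightward then leftward; only tiles that
    overlap the region are kept.
    """
    half = locus_size // 2
    if region.length <= locus_size:
        center = (region.start + region.end) // 2
        return [(center - half, center + half, "centered")]
    mid = (region.start + region.end) // 2
    tiles: list[tuple[int, int, str]] = []
    k = 0
    while True:
        right = (mid + k * locus_size, mid + (k + 1) * locus_size)
        left = (mid - (k + 1) * locus_size, mid - k * locus_size)
        r_ok = right[0] < region.end
        l_ok = left[1] > region.start
        if r_ok:
            tiles.append((right[0], right[1], "midpoint_tile"))
        if l_ok:
            tiles.append((left[0], left[1], "midpoint_tile"))
        if not (r_ok or l_ok):
            break
        k += 1
    return sorted(tiles)


def tile_genome(
    regions: Sequence[ActiveRegion],
    chrom_sizes: Mapping[str, int],
    gaps: Sequence[tuple[str, int, int]] | None = None,
    locus_size: int = LOCUS_SIZE,
) -> list[Locus]:
    """Emit the genome-wide locus set.

    Active regions are converted to centered / midpoint-tiled loci; the
    remaining genome (minus gaps) is covered with gap-fill blocks of the
    same size. Terminal remainders shorter than ``locus_size`` are
    emitted with their true length and flagged. The output is
    non-overlapping and sorted by (chrom, start).
    """
    if locus_size <= 0 or locus_size % 2:
        raise ValueError("locus_size must be a positive even integer")
    for r in regions:
        if r.chrom not in chrom_sizes:
            raise ValueError(f"chromosome {r.chrom} not in chrom_sizes")
        if r.end > chrom_sizes[r.chrom]:
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} beyond chromosome end")

    by_chrom: dict[str, list[ActiveRegion]] = {}
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        by_chrom.setdefault(r.chrom, []).append(r)

    gap_by_chrom: dict[str, list[tuple[int, int]]] = {}
    if gaps:
        for c, s, e, *_ in gaps:
            gap_by_chrom.setdefault(c, []).append((s, e))

    loci: list[Locus] = []
    for chrom in sorted(set(by_chrom) | set(chrom_sizes)):
        size = chrom_sizes[chrom]
        cands: list[tuple[int, int, str, bool]] = []
        for region in by_chrom.get(chrom, ()):
            for s, e, origin in _candidates_for_region(region, locus_size):
                flagged = False
                if s < 0:  # shift into bounds, length preserved
                    s, e, flagged = 0, locus_size, True
                if e > size:
                    s, e, flagged = max(0, size - locus_size), size, True
                cands.append((s, e, origin, flagged))
        cands.sort()
        active: list[tuple[int, int, str, bool]] = []
        for idx, (s, e, origin, flagged) in enumerate(cands):
            if active and s < active[-1][1]:
                # shift right to abut the previously emitted locus
                shift = active[-1][1] - s
                s, e, flagged = s + shift, e + shift, True
                nxt = cands[idx + 1] if idx + 1 < len(cands) else None
                if e > size or (nxt is not None and e > nxt[0]):
                    continue  # no room: drop
            active.append((s, e, origin, flagged))

        # gap-fill: complement of active loci and assembly gaps
        blocked = _merge(
            [(chrom, s, e) for s, e, *_ in active]
            + [(chrom, s, e) for s, e in gap_by_chrom.get(chrom, ())]
        )
        fill: list[tuple[int, int, str, bool]] = []
        cursor = 0
        for _, bs, be in blocked + [(chrom, size, size)]:
            pos = cursor
            while pos + locus_size <= bs:
                fill.append((pos, pos + locus_size, "gap_fill", False))
                pos += locus_size
            if pos < bs:  # short remainder before the next blocked interval
                fill.append((pos, bs, "gap_fill", True))
            cursor = max(cursor, be)

        for s, e, origin, flagged in sorted(active + fill):
            loci.append(Locus(f"{chrom}:{s}-{e}", chrom, s, e, origin, flagged))

    loci.sort(key=lambda l: (l.chrom, l.start))
    for a, b in zip(loci, loci[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise AssertionError(f"overlapping loci {a.locus_id} / {b.locus_id}")
    return loci


def sliding_shift(loci: Sequence[Locus], shift: int = LOCUS_SIZE // 2) -> list[Locus]:
    """Shift every locus ``shift`` bp toward the 5' end (lower coordinates).

    Starts that would become negative are clipped to 0 with the locus
    length preserved; such loci are flagged. Output size equals input size.
    """
    if shift >= LOCUS_SIZE:
        raise ValueError("shift must be smaller than the locus size")
    out = []
    for loc in loci:
        start = loc.start - shift
        flagged = loc.flagged
        if start < 0:
            start, flagged = 0, True
        end = start + loc.length
        out.append(Locus(f"{loc.chrom}:{start}-{end}", loc.chrom, start, end, loc.origin, flagged))
    return out


def write_loci_bed(loci: Sequence[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.locus_id}\t"
                f"{loc.origin}\t{int(loc.flagged)}\n"
            )


def read_loci_bed(path: str | Path) -> list[Locus]:
    out = []
    for row in read_bed(path, min_fields=4):
        chrom, start, end, locus_id, *rest = row
        origin = rest[0] if rest else "gap_fill"
        flagged = bool(int(rest[1])) if len(rest) > 1 else False
        out.append(Locus(locus_id, chrom, start, end, origin, flagged))
    return out
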