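"""Coverage-track set algebra for lineage-specific and unmapped sequence.

"Mapped" means read depth >= min_depth (default 1); zero-depth runs of a
track are "unmapped" sequence, which — when consistent across a panel —
marks sequence absent from those lines' genomes.  Three set operations
cover the pipeline's uses:

* regions unmapped in one line (large deletions / absent segments),
* regions unmapped in *every* line of a panel (lineage-specific sequence
  of the reference's own lineage),
* regions mapped by every line of panel A but unmapped in line B
  (common sequence of A absent from B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import InvariantError
from .formats import CoverageTrack, Region

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# interval primitives (sorted, disjoint, half-open)
# ---------------------------------------------------------------------------

def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _intersect_all(sets: Sequence[Sequence[Interval]],
                   length: int) -> list[Interval]:
    cur: list[Interval] = [(0, length)]
    for s in sets:
        cur = _intersect(cur, s)
        if not cur:
            break
    return cur


def _to_regions(chrom: str, intervals: Sequence[Interval], min_len: int,
                label: str = "") -> list[Region]:
    return [Region(chrom, s, e, label)
            for s, e in intervals if e - s >= min_len]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def zero_coverage_regions(track: CoverageTrack, min_len: int = 100,
                          label: str = "unmapped") -> list[Region]:
    """Maximal zero-depth runs of length >= min_len, sorted and disjoint."""
    if min_len < 1:
        raise InvariantError("min_len must be >= 1")
    return _to_regions(track.chrom, track.zero_intervals(), min_len, label)


def uncovered_by_all(tracks: Sequence[CoverageTrack], min_len: int = 100,
                     label: str = "specific") -> list[Region]:
    """Regions with zero depth in *every* track (one chromosome).

    Equivalent to the zero-coverage set of the per-base maximum-depth
    track.  With the reference from lineage X and tracks from lineage Y
    reads, these are candidate X-specific sequences.
    """
    if not tracks:
        raise InvariantError("uncovered_by_all needs at least one track")
    chroms = {t.chrom for t in tracks}
    lengths = {t.length for t in tracks}
    if len(chroms) > 1 or len(lengths) > 1:
        raise InvariantError("tracks must share one reference chromosome")
    inter = _intersect_all([t.zero_intervals() for t in tracks],
                           tracks[0].length)
    return _to_regions(tracks[0].chrom, inter, min_len, label)


def covered_by_all_uncovered_by(tracks_a: Sequence[CoverageTrack],
                                track_b: CoverageTrack,
                                min_len: int = 100,
                                min_depth: int = 1,
                                label: str = "common") -> list[Region]:
    """Regions mapped (depth >= min_depth) in every track of panel A and
    unmapped in track B: common sequence of A's lineage absent from B."""
    if not tracks_a:
        raise InvariantError("panel A must be non-empty")
    for t in list(tracks_a) + [track_b]:
        if t.chrom != track_b.chrom or t.length != track_b.length:
            raise InvariantError("tracks must share one reference chromosome")
    sets = [t.covered_intervals(min_depth) for t in tracks_a]
    sets.append(track_b.zero_intervals())
    inter = _intersect_all(sets, track_b.length)
    return _to_regions(track_b.chrom, inter, min_len, label)


@dataclass(frozen=True)
class UnmappedSummary:
    """Counts and cumulative span of large zero-coverage regions."""

    count: int
    cumulative_bp: int
    count_over_10kb: int
    largest_bp: int
    regions: tuple[Region, ...]


def large_unmapped_summary(track: CoverageTrack,
                           min_len: int = 1000,
                           sub_threshold: int = 10_000,
                           ) -> UnmappedSummary:
    """Summary of zero-coverage runs strictly longer than ``min_len``
    (the ">1 kb" convention), with a sub-count of runs > ``sub_threshold``."""
    regs = [Region(track.chrom, s, e, "unmapped")
            for s, e in track.zero_intervals() if e - s > min_len]
    cum = sum(r.length for r in regs)
    over = sum(1 for r in regs if r.length > sub_threshold)
    largest = max((r.length for r in regs), default=0)
    return UnmappedSummary(len(regs), cum, over, largest, tuple(regs))


def summarize_trackset(tracks: Mapping[str, CoverageTrack],
                       min_len: int = 1000) -> UnmappedSummary:
    """Genome-wide :func:`large_unmapped_summary` over per-chromosome
    tracks of one accession."""
    parts = [large_unmapped_summary(t, min_len) for t in tracks.values()]
    regions = tuple(r for p in parts for r in p.regions)
    return UnmappedSummary(
        sum(p.count for p in parts),
        sum(p.cumulative_bp for p in parts),
        sum(p.count_over_10kb for p in parts),
        max((p.largest_bp for p in parts), default=0),
        regions,
    )
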