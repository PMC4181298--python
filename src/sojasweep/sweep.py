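"""Pooled-heterozygosity selective-sweep scan.

Per-line allele read counts are depth-normalised (binomial thinning toward
a target depth), summed into population pools, and screened in sliding
windows.  For a window, with SnMAJ and SnMIN the summed major/minor allele
read counts over all SNP positions in it,

    Hp = 2 * SnMAJ * SnMIN / (SnMAJ + SnMIN)^2

is the pooled heterozygosity (0 <= Hp <= 0.5; 0.5 iff the pooled counts are
balanced).  Genome-wide Z-standardisation of Hp turns the scan into an
outlier test: windows in the extreme negative tail (here Z < -4) mark
allele fixation, the footprint of a selective sweep.  Monomorphic sites
within the panel-wide SNP union are *retained* in the pools — depressed
minor-allele mass is exactly the signal being measured — while sites
polymorphic in no pool never enter the union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvariantError
from .formats import (AccessionCallSet, GeneModel, GenomeIndex, Genotype,
                      Region)

WINDOW = 100_000
STEP = 50_000
MIN_SITES = 10
POOL_MIN_DEPTH = 10
POOL_MAX_DEPTH = 500
Z_CUT = -4.0
EXCLUSION_Z = -2.0


@dataclass
class LineCounts:
    """Per-site ref/alt read counts of one line at the union SNP sites.

    Positions are 0-based; arrays are parallel and sorted by
    (chromosome order, position).
    """

    accession: str
    chrom: np.ndarray          # object/str array
    pos: np.ndarray            # int, 0-based
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self):
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref_count)
                == len(self.alt_count) == n):
            raise InvariantError("LineCounts arrays must be parallel")
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise InvariantError("negative read counts")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.pos) else 0.0


def union_snp_sites(callsets: Sequence[AccessionCallSet],
                    genome: GenomeIndex,
                    ) -> list[tuple[str, int, str, str]]:
    """Sites (chrom, 0-based pos, ref, alt) carrying the variant allele in
    at least one line of the panel, sorted by genome order."""
    sites = set()
    for cs in callsets:
        for rec in cs.snps():
            if rec.genotype is not Genotype.HOM_REF:
                sites.add((rec.chrom, rec.pos - 1, rec.ref_allele,
                           rec.alt_allele))
    return sorted(sites, key=lambda s: (genome.order(s[0]), s[1]))


def line_counts_from_callset(callset: AccessionCallSet,
                             sites: Sequence[tuple[str, int, str, str]],
                             ) -> LineCounts:
    """Project one accession's calls onto the union site list.

    Sites without a record for the line contribute zero reads (the line's
    pool contribution there is simply absent).
    """
    by_pos = {(r.chrom, r.pos - 1): r for r in callset.snps()}
    n = len(sites)
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    refc = np.zeros(n, dtype=np.int64)
    altc = np.zeros(n, dtype=np.int64)
    for i, (c, p, ref, alt) in enumerate(sites):
        chrom[i], pos[i] = c, p
        rec = by_pos.get((c, p))
        if rec is not None and rec.ref_allele == ref and rec.alt_allele == alt:
            refc[i] = rec.depth - rec.alt_support
            altc[i] = rec.alt_support
    return LineCounts(callset.accession, chrom, pos, refc, altc)


def downsample_depth(counts: LineCounts, target_depth: float,
                     seed: int | np.random.Generator,
                     ) -> LineCounts:
    """Thin a line's allele counts toward a target mean depth.

    Lines already at or below the target are returned unchanged; otherwise
    each site's major and minor counts are independently binomially thinned
    with retention probability target/mean, the count-level equivalent of
    randomly subsampling the line's reads.
    """
    if target_depth <= 0:
        raise InvariantError("target_depth must be positive")
    mean = counts.mean_depth
    if mean <= target_depth:
        return counts
    p = target_depth / mean
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return LineCounts(
        counts.accession, counts.chrom, counts.pos,
        rng.binomial(counts.ref_count, p),
        rng.binomial(counts.alt_count, p),
    )


def pool_counts(lines: Sequence[LineCounts],
                pool: str = "",
                min_depth: int = POOL_MIN_DEPTH,
                max_depth: int = POOL_MAX_DEPTH,
                ) -> pd.DataFrame:
    """Sum per-line counts into pooled nMAJ/nMIN per site.

    The major allele is whichever of ref/alt has the larger pooled count
    (ties resolved to ref).  Sites with pooled depth outside the inclusive
    [min_depth, max_depth] coverage gate are dropped: depauperate sites are
    noise and extreme-depth sites are collapsed repeats.  Monomorphic
    sites inside the gate are retained.
    """
    if not lines:
        raise InvariantError("pool_counts needs at least one line")
    first = lines[0]
    for lc in lines[1:]:
        if (len(lc.pos) != len(first.pos)
                or np.any(lc.pos != first.pos)):
            raise InvariantError("lines must share one union site list")
    ref_sum = np.sum([lc.ref_count for lc in lines], axis=0)
    alt_sum = np.sum([lc.alt_count for lc in lines], axis=0)
    total = ref_sum + alt_sum
    keep = (total >= min_depth) & (total <= max_depth)
    n_major = np.maximum(ref_sum, alt_sum)[keep]
    n_minor = np.minimum(ref_sum, alt_sum)[keep]
    df = pd.DataFrame({
        "chrom": first.chrom[keep],
        "pos": first.pos[keep],
        "n_major": n_major.astype(np.int64),
        "n_minor": n_minor.astype(np.int64),
    })
    df.attrs["pool"] = pool
    return df


def hp_windows(pooled: pd.DataFrame,
               genome: GenomeIndex,
               window: int = WINDOW,
               step: int = STEP,
               min_sites: int = MIN_SITES,
               ) -> pd.DataFrame:
    """Windowed pooled heterozygosity over the step grid of each chromosome.

    Windows are tiled at every ``step`` from 0; the last window of a
    chromosome may be truncated.  Windows with fewer than ``min_sites``
    SNPs get Hp = NaN and are excluded from the Z distribution: near-empty
    windows produce spurious Hp extremes.
    """
    if step > window:
        raise InvariantError("step must not exceed window size")
    if step <= 0:
        raise InvariantError("step must be positive")
    out: list[pd.DataFrame] = []
    for chrom in genome.names:
        length = genome.length(chrom)
        sub = pooled[pooled["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        maj = sub["n_major"].to_numpy()[order]
        mino = sub["n_minor"].to_numpy()[order]
        cmaj = np.concatenate([[0], np.cumsum(maj)])
        cmin = np.concatenate([[0], np.cumsum(mino)])
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n_sites = hi - lo
        sum_major = cmaj[hi] - cmaj[lo]
        sum_minor = cmin[hi] - cmin[lo]
        out.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_sites": n_sites,
            "sum_major": sum_major, "sum_minor": sum_minor,
        }))
    df = pd.concat(out, ignore_index=True)
    tot = df["sum_major"] + df["sum_minor"]
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = 2.0 * df["sum_major"] * df["sum_minor"] / (tot * tot)
    hp[df["n_sites"] < min_sites] = np.nan
    df["hp"] = hp
    df["z"] = np.nan
    df.attrs["pool"] = pooled.attrs.get("pool", "")
    df.attrs["step"] = step
    df.attrs["window"] = window
    return df


def hp_brute_force(pooled: pd.DataFrame, chrom: str,
                   start: int, end: int) -> tuple[int, int, int, float]:
    """Independent per-window recomputation by an explicit site loop;
    oracle for :func:`hp_windows`."""
    sm = sn = k = 0
    for c, p, nm, nn in zip(pooled["chrom"], pooled["pos"],
                            pooled["n_major"], pooled["n_minor"]):
        if c == chrom and start <= p < end:
            sm += int(nm)
            sn += int(nn)
            k += 1
    hp = 2.0 * sm * sn / (sm + sn) ** 2 if sm + sn > 0 else float("nan")
    return k, sm, sn, hp


def z_transform(windows: pd.DataFrame) -> pd.DataFrame:
    """Standardise Hp genome-wide: z = (Hp - mean) / sd with the population
    (divisor-N) standard deviation, over windows with defined Hp."""
    hp = windows["hp"].to_numpy()
    mask = ~np.isnan(hp)
    if mask.sum() < 2:
        raise InvariantError("z_transform needs at least 2 windows with Hp")
    mu = hp[mask].mean()
    sd = hp[mask].std(ddof=0)
    if sd == 0:
        raise InvariantError("degenerate Hp distribution (sd = 0)")
    out = windows.copy()
    z = np.full_like(hp, np.nan)
    z[mask] = (hp[mask] - mu) / sd
    out["z"] = z
    out.attrs.update(windows.attrs)
    return out


@dataclass(frozen=True)
class SweepRegion:
    """Merged run of significant windows; ``z`` is the most extreme
    (minimum) window Z inside the region."""

    region: Region
    z: float
    pool: str = ""
    n_windows: int = 1

    @property
    def chrom(self) -> str:
        return self.region.chrom

    @property
    def start(self) -> int:
        return self.region.start

    @property
    def end(self) -> int:
        return self.region.end


def call_sweeps(windows: pd.DataFrame,
                z_cut: float = Z_CUT,
                ) -> list[SweepRegion]:
    """Windows with Z strictly below ``z_cut``, merged when overlapping or
    adjacent on the step grid, become candidate selected regions."""
    pool = windows.attrs.get("pool", "")
    sig = windows[windows["z"] < z_cut]
    regions: list[SweepRegion] = []
    cur = None  # [chrom, start, end, min_z, n]
    for _, row in sig.sort_values(["chrom", "start"]).iterrows():
        c, s, e, z = row["chrom"], int(row["start"]), int(row["end"]), row["z"]
        if cur is not None and cur[0] == c and s <= cur[2]:
            cur[2] = max(cur[2], e)
            cur[3] = min(cur[3], z)
            cur[4] += 1
        else:
            if cur is not None:
                regions.append(SweepRegion(
                    Region(cur[0], cur[1], cur[2], "sweep"),
                    cur[3], pool, cur[4]))
            cur = [c, s, e, z, 1]
    if cur is not None:
        regions.append(SweepRegion(
            Region(cur[0], cur[1], cur[2], "sweep"), cur[3], pool, cur[4]))
    return regions


def _grid_step(windows: pd.DataFrame) -> int | None:
    step = windows.attrs.get("step")
    if step is not None:
        return int(step)
    starts = windows.sort_values(["chrom", "start"])["start"].to_numpy()
    diffs = np.diff(starts)
    diffs = diffs[diffs > 0]
    return int(diffs.min()) if diffs.size else None


def differential_loci(cultivated_sweeps: Sequence[SweepRegion],
                      wild_windows: pd.DataFrame,
                      semiwild_windows: pd.DataFrame,
                      exclusion_z: float = EXCLUSION_Z,
                      ) -> list[SweepRegion]:
    """Cultivated-only selected loci.

    A cultivated sweep region is retained iff no overlapping window of the
    wild or semi-wild pool shows even a relaxed sweep signal
    (Z < ``exclusion_z``); such loci are candidate targets of improvement
    selection absent from both wild-derived pools.
    """
    steps = {_grid_step(wild_windows), _grid_step(semiwild_windows)}
    steps.discard(None)
    if len(steps) > 1:
        raise InvariantError(
            f"window grids have different steps: {sorted(steps)}")

    def excluded_by(windows: pd.DataFrame, sweep: SweepRegion) -> bool:
        sub = windows[(windows["chrom"] == sweep.chrom)
                      & (windows["start"] < sweep.end)
                      & (windows["end"] > sweep.start)]
        z = sub["z"].to_numpy()
        return bool(np.any(z[~np.isnan(z)] < exclusion_z))

    return [s for s in cultivated_sweeps
            if not excluded_by(wild_windows, s)
            and not excluded_by(semiwild_windows, s)]


def genes_in_regions(regions: Sequence[SweepRegion | Region],
                     genes: Sequence[GeneModel],
                     ) -> list[tuple[Region, list[str]]]:
    """Genes overlapping each region by at least 1 bp (strand-agnostic).

    A gene can appear in several regions' lists but is counted once in
    :func:`union_gene_count`.
    """
    out: list[tuple[Region, list[str]]] = []
    for reg in regions:
        r = reg.region if isinstance(reg, SweepRegion) else reg
        hits = [g.gene_id for g in genes
                if g.chrom == r.chrom and g.start < r.end and r.start < g.end]
        out.append((r, hits))
    return out


def union_gene_count(assignment: Sequence[tuple[Region, list[str]]]) -> int:
    return len({g for _, hits in assignment for g in hits})


def plot_zhp(windows: pd.DataFrame, path, z_cut: float = Z_CUT,
             genome: GenomeIndex | None = None) -> None:
    """Z(Hp) along concatenated chromosomes with the outlier cut-off line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    chroms = (genome.names if genome is not None
              else list(dict.fromkeys(windows["chrom"])))
    for i, chrom in enumerate(chroms):
        sub = windows[windows["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2 + offset
        ax.scatter(mid, sub["z"], s=2,
                   color="tab:blue" if i % 2 == 0 else "tab:orange")
        offset += (genome.length(chrom) if genome is not None
                   else int(sub["end"].max() or 0))
    ax.axhline(z_cut, linestyle="--", color="red", linewidth=1)
    ax.set_xlabel("genome position")
    ax.set_ylabel("Z(Hp)")
    pool = windows.attrs.get("pool", "")
    if pool:
        ax.set_title(f"{pool} pool")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
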