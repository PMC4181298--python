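"""Domain types and readers/writers for every external format the pipeline touches.

All other modules consume the types defined here.  Internal coordinates are
0-based half-open everywhere; the 1-based conventions of VCF and GFF3 are
converted at the format boundary and nowhere else.  The one deliberate
exception is :class:`VariantRecord`, whose ``pos`` field keeps the VCF
1-based position because variant records are keyed and reported in VCF
coordinates throughout.

Parsing of standard formats is delegated to established libraries (cyvcf2
for VCF, gffutils for GFF3, pyfaidx for FASTA, pandas for tabular files);
this module only maps their objects onto the package's domain types.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvariantError

POPULATIONS = ("wild", "semiwild", "cultivated")

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_sites", "sum_major", "sum_minor", "hp", "z"
]


class Genotype(enum.Enum):
    """Diploid genotype call at a biallelic site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"

    @property
    def dosage(self) -> int:
        """Number of variant alleles carried (0, 1 or 2)."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2}[self.value]


# ---------------------------------------------------------------------------
# coordinate conversion helpers (the only place the two conventions meet)
# ---------------------------------------------------------------------------

def one_based_to_interval(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive span (VCF/GFF3 style) to 0-based half-open."""
    return start1 - 1, end1


def interval_to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to a 1-based inclusive span."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths of one reference genome.

    The stored order is stable and used for sorting every output the
    pipeline writes.
    """

    names: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise InvariantError("duplicate chromosome names in GenomeIndex")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise InvariantError(f"non-positive length for {name}")
        object.__setattr__(self, "lengths", dict(self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise FormatError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def order(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise FormatError(f"unknown chromosome {chrom!r}") from None

    def sort_key(self, chrom: str, pos: int) -> tuple[int, int]:
        return self.order(chrom), pos

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        names = tuple(fa.keys())
        return cls(names, {n: len(fa[n]) for n in names})

    @classmethod
    def from_fai(cls, path: str | Path) -> "GenomeIndex":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["name", "length"], dtype={"name": str})
        return cls(tuple(df["name"]), dict(zip(df["name"], df["length"])))


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One biallelic variant call of one accession (VCF 1-based position).

    Indels are carried with ``is_snp=False`` so they can be counted, but
    every downstream statistic (pi, Hp, tree, haplotype sharing) uses SNPs
    only.
    """

    chrom: str
    pos: int                 # 1-based, as in the source VCF
    ref_allele: str
    alt_allele: str
    genotype: Genotype
    depth: int
    alt_support: int
    is_snp: bool = True

    def validate(self, genome: GenomeIndex | None = None) -> None:
        if self.pos < 1:
            raise InvariantError(f"position {self.pos} < 1")
        if genome is not None and self.pos > genome.length(self.chrom):
            raise InvariantError(
                f"{self.chrom}:{self.pos} beyond chromosome end")
        if self.alt_support > self.depth:
            raise InvariantError(
                f"{self.chrom}:{self.pos} alt_support {self.alt_support} "
                f"> depth {self.depth}")
        if self.ref_allele == self.alt_allele:
            raise InvariantError(f"{self.chrom}:{self.pos} ref == alt")


@dataclass
class AccessionCallSet:
    """All variant calls of one accession, sorted by genome position."""

    accession: str
    population: str
    records: list[VariantRecord]
    genome: GenomeIndex | None = None

    def __post_init__(self):
        if self.population not in POPULATIONS:
            raise InvariantError(
                f"population {self.population!r} not one of {POPULATIONS}")
        if self.genome is not None:
            key = lambda r: (self.genome.order(r.chrom), r.pos)
        else:
            key = lambda r: (r.chrom, r.pos)
        self.records = sorted(self.records, key=key)
        seen = set()
        for r in self.records:
            if (r.chrom, r.pos) in seen:
                raise InvariantError(
                    f"{self.accession}: duplicate record at {r.chrom}:{r.pos}")
            seen.add((r.chrom, r.pos))

    def __len__(self) -> int:
        return len(self.records)

    def snps(self) -> list[VariantRecord]:
        return [r for r in self.records if r.is_snp]

    def variant_sites(self, snps_only: bool = True) -> list[VariantRecord]:
        """Records where the accession actually carries the variant allele."""
        return [r for r in self.records
                if r.genotype is not Genotype.HOM_REF
                and (r.is_snp or not snps_only)]


@dataclass
class CoverageTrack:
    """Run-length encoded per-base read depth over one chromosome.

    Only non-zero runs are stored; positions absent from ``runs`` have
    depth 0.  Runs are sorted, non-overlapping, within bounds, and adjacent
    runs of equal depth are merged on construction.
    """

    chrom: str
    length: int
    runs: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        runs = sorted((s, e, d) for s, e, d in self.runs if d != 0)
        merged: list[tuple[int, int, int]] = []
        prev_end = 0
        for s, e, d in runs:
            if s >= e:
                raise InvariantError(f"{self.chrom}: empty run ({s},{e})")
            if d < 0:
                raise InvariantError(f"{self.chrom}: negative depth {d}")
            if s < prev_end:
                raise InvariantError(f"{self.chrom}: overlapping runs at {s}")
            if e > self.length:
                raise InvariantError(
                    f"{self.chrom}: run end {e} beyond length {self.length}")
            if merged and merged[-1][1] == s and merged[-1][2] == d:
                merged[-1] = (merged[-1][0], e, d)
            else:
                merged.append((s, e, d))
            prev_end = e
        self.runs = merged

    # -- interval views ----------------------------------------------------
    def covered_intervals(self, min_depth: int = 1) -> list[tuple[int, int]]:
        """Maximal intervals with depth >= min_depth ("mapped" sequence)."""
        out: list[tuple[int, int]] = []
        for s, e, d in self.runs:
            if d >= min_depth:
                if out and out[-1][1] == s:
                    out[-1] = (out[-1][0], e)
                else:
                    out.append((s, e))
        return out

    def zero_intervals(self) -> list[tuple[int, int]]:
        """Maximal intervals with depth 0 (the complement of all runs)."""
        out: list[tuple[int, int]] = []
        prev = 0
        for s, e, _ in self.runs:
            if s > prev:
                out.append((prev, s))
            prev = e
        if prev < self.length:
            out.append((prev, self.length))
        return out

    def to_array(self) -> np.ndarray:
        """Dense per-base depth; only for small chromosomes/tests."""
        arr = np.zeros(self.length, dtype=np.int64)
        for s, e, d in self.runs:
            arr[s:e] = d
        return arr

    @classmethod
    def from_array(cls, chrom: str, depths: np.ndarray) -> "CoverageTrack":
        depths = np.asarray(depths)
        if depths.size == 0:
            return cls(chrom, 0, [])
        breaks = np.flatnonzero(np.diff(depths)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [depths.size]])
        runs = [(int(s), int(e), int(depths[s]))
                for s, e in zip(starts, ends) if depths[s] != 0]
        return cls(chrom, int(depths.size), runs)


@dataclass(frozen=True, slots=True)
class Region:
    """0-based half-open genomic interval with a free-text label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InvariantError(
                f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True, slots=True)
class GeneModel:
    """Gene span in 0-based half-open coordinates; strand is carried but
    ignored by overlap queries (selected loci are strand-agnostic)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise InvariantError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise InvariantError(f"gene {self.gene_id}: bad strand")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, panel: Mapping[str, str],
             genome: GenomeIndex | None = None,
             ) -> dict[str, AccessionCallSet]:
    """Read a (possibly multi-sample) VCF into one call set per sample.

    Multi-allelic records are split into one biallelic record per ALT
    allele; a sample carrying a *different* ALT at a split record is
    treated as missing for that record.  Non-SNP alleles are flagged
    ``is_snp=False`` and excluded from all downstream statistics.

    Requires GT and AD (allele depth) FORMAT fields; DP is used for total
    depth when present, otherwise the AD sum.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in panel:
            raise FormatError(f"sample {s!r} missing from population panel")
    records: dict[str, list[VariantRecord]] = {s: [] for s in samples}

    for line_no, var in enumerate(vcf, start=1):
        if genome is not None and var.CHROM not in genome:
            raise FormatError(
                f"VCF record {var.CHROM}:{var.POS}: chromosome not in genome index")
        gts = var.genotypes
        if gts is None or len(gts) != len(samples):
            raise FormatError(
                f"missing GT field at record {line_no} ({var.CHROM}:{var.POS})")
        ad = var.format("AD")
        dp = var.format("DP")
        if ad is None:
            raise FormatError(
                f"missing AD field at record {line_no} ({var.CHROM}:{var.POS})")
        for alt_idx, alt in enumerate(var.ALT):
            is_snp = len(var.REF) == 1 and len(alt) == 1 and alt != "*"
            alt_code = alt_idx + 1
            for si, sample in enumerate(samples):
                alleles = [a for a in gts[si][:2] if a != -1]
                if len(alleles) < 2:
                    continue  # missing call for this sample
                if any(a not in (0, alt_code) for a in alleles):
                    continue  # carries a different ALT: missing for this split
                n_alt = sum(a == alt_code for a in alleles)
                if n_alt == 0 and alt_idx > 0:
                    continue  # hom_ref belongs to the first split only
                genotype = (Genotype.HOM_REF, Genotype.HET,
                            Genotype.HOM_ALT)[n_alt]
                row = np.atleast_1d(ad[si])
                alt_support = int(row[alt_code]) if row.size > alt_code else 0
                if dp is not None:
                    depth = int(np.atleast_1d(dp[si])[0])
                else:
                    depth = int(row[row >= 0].sum())
                if depth < alt_support:
                    depth = alt_support
                rec = VariantRecord(var.CHROM, var.POS, var.REF, alt,
                                    genotype, depth, alt_support, is_snp)
                rec.validate(genome)
                records[sample].append(rec)

    return {
        s: AccessionCallSet(s, panel[s], records[s], genome) for s in samples
    }


# ---------------------------------------------------------------------------
# depth TSV (samtools-depth style: chrom, 1-based pos, depth)
# ---------------------------------------------------------------------------

def read_depth_tsv(path: str | Path, genome: GenomeIndex,
                   ) -> dict[str, CoverageTrack]:
    """Read a 3-column depth TSV into run-length tracks (one per chromosome).

    Positions may be sparse; unlisted positions have depth 0.  Every
    chromosome of the genome index gets a track, even if it has no rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "pos", "depth"],
                         dtype={"chrom": str, "pos": np.int64,
                                "depth": np.int64})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"malformed depth TSV {path}: {exc}") from exc

    tracks: dict[str, CoverageTrack] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise FormatError(f"depth TSV chromosome {chrom!r} not in genome")
        length = genome.length(chrom)
        pos = grp["pos"].to_numpy()
        dep = grp["depth"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos, dep = pos[order], dep[order]
        if pos.size and (pos[0] < 1 or pos[-1] > length):
            bad = pos[0] if pos[0] < 1 else pos[-1]
            raise FormatError(f"{chrom}: position {bad} outside [1,{length}]")
        if np.any(np.diff(pos) == 0):
            dup = int(pos[np.flatnonzero(np.diff(pos) == 0)[0]])
            raise FormatError(f"{chrom}: duplicated position {dup}")
        start0 = pos - 1  # to 0-based
        keep = dep != 0
        start0, dep2 = start0[keep], dep[keep]
        # run-length encode: break where positions jump or depth changes
        if start0.size:
            brk = np.flatnonzero((np.diff(start0) != 1)
                                 | (np.diff(dep2) != 0)) + 1
            run_starts = np.concatenate([[0], brk])
            run_ends = np.concatenate([brk, [start0.size]])
            runs = [(int(start0[a]), int(start0[b - 1]) + 1, int(dep2[a]))
                    for a, b in zip(run_starts, run_ends)]
        else:
            runs = []
        tracks[chrom] = CoverageTrack(chrom, length, runs)

    for chrom in genome.names:
        tracks.setdefault(chrom, CoverageTrack(chrom, genome.length(chrom)))
    return tracks


def write_depth_tsv(tracks: Iterable[CoverageTrack], path: str | Path,
                    include_zero: bool = False) -> None:
    """Write tracks back to samtools-depth layout (1-based positions)."""
    with open(path, "w") as fh:
        for track in tracks:
            if include_zero:
                arr = track.to_array()
                for i, d in enumerate(arr):
                    fh.write(f"{track.chrom}\t{i + 1}\t{int(d)}\n")
            else:
                for s, e, d in track.runs:
                    for p in range(s, e):
                        fh.write(f"{track.chrom}\t{p + 1}\t{d}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(regions: Sequence[Region], path: str | Path,
              genome: GenomeIndex | None = None,
              merge: bool = False) -> None:
    """Write BED3/BED4 (0-based half-open), sorted; optionally merge
    overlapping regions that share a label."""
    if genome is not None:
        key = lambda r: (genome.order(r.chrom), r.start, r.end)
    else:
        key = lambda r: (r.chrom, r.start, r.end)
    regs = sorted(regions, key=key)
    if merge:
        merged: list[Region] = []
        for r in regs:
            if (merged and merged[-1].chrom == r.chrom
                    and merged[-1].label == r.label
                    and r.start <= merged[-1].end):
                last = merged.pop()
                merged.append(replace(last, end=max(last.end, r.end)))
            else:
                merged.append(r)
        regs = merged
    with open(path, "w") as fh:
        for r in regs:
            if r.label:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bed(path: str | Path) -> list[Region]:
    regions: list[Region] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            label = parts[3] if len(parts) > 3 else ""
            try:
                regions.append(
                    Region(parts[0], int(parts[1]), int(parts[2]), label))
            except (ValueError, InvariantError) as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return regions


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Extract ``gene`` features from a GFF3 file (1-based inclusive ->
    0-based half-open)."""
    import gffutils

    try:
        db = gffutils.create_db(str(path), ":memory:",
                                merge_strategy="error", keep_order=True)
    except ValueError as exc:
        raise FormatError(f"GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [None])[0] or feat.id
        if gene_id is None or gene_id.startswith("gene_"):  # gffutils autokey
            if "ID" not in feat.attributes:
                raise FormatError(
                    f"GFF3 {path}: gene at {feat.seqid}:{feat.start} lacks ID")
        if gene_id in seen:
            raise FormatError(f"GFF3 {path}: duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        start0, end0 = one_based_to_interval(feat.start, feat.end)
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(GeneModel(gene_id, feat.seqid, start0, end0, strand))
    if not genes:
        warnings.warn(f"GFF3 {path}: no gene features found")
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# panel TSV
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> dict[str, str]:
    """Read the accession -> population panel (TSV, optional header)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["accession", "population"], dtype=str,
                     comment="#")
    if df.iloc[0].tolist() == ["accession", "population"]:
        df = df.iloc[1:]
    panel: dict[str, str] = {}
    for _, row in df.iterrows():
        acc, pop = row["accession"], row["population"]
        if pop not in POPULATIONS:
            raise FormatError(
                f"panel: {acc}: population {pop!r} not one of {POPULATIONS}")
        if acc in panel:
            raise FormatError(f"panel: duplicate accession {acc!r}")
        panel[acc] = pop
    return panel


def write_panel(panel: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc, pop in panel.items():
            fh.write(f"{acc}\t{pop}\n")


# ---------------------------------------------------------------------------
# window-statistic TSV (internal tabular format, round-trip safe)
# ---------------------------------------------------------------------------

def write_windows_tsv(windows: pd.DataFrame, path: str | Path) -> None:
    windows.to_csv(path, sep="\t", index=False, columns=[
        c for c in WINDOW_COLUMNS if c in windows.columns])


def read_windows_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in WINDOW_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise FormatError(f"windows TSV {path}: missing columns {missing}")
    return df
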