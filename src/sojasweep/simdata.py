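"""Synthetic *Soja*-like panel generator with truth labels.

Emulates the three-population study design the pipeline targets:

* **wild** lines drawing genotypes from an ancestral, U-shaped allele
  frequency spectrum (Beta(0.2, 0.2) alternate-allele frequencies);
* **cultivated** lines drawn from a bottlenecked frequency set — each
  ancestral polymorphism survives the bottleneck with a retention
  probability, surviving frequencies are drift-perturbed, lost ones are
  fixed — with configurable sweep segments forced monomorphic for the
  major allele;
* **semi-wild** lines built as recent F1 (one wild gamete + one cultivated
  gamete) or F2 (one selfing meiosis with a single crossover per
  chromosome) hybrids, which is what gives them their elevated
  heterozygosity.

Per-site read support is Poisson depth with binomial allele sampling at a
symmetric base-call error rate; per-base coverage tracks are piecewise
constant over small tiles, with lineage-specific genome segments present
in carrier lines and zero-depth in all others.  Everything is reproducible
from a single seed, and every emitted file parses back through the
``formats`` module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvariantError
from .formats import (AccessionCallSet, CoverageTrack, GenomeIndex, Genotype,
                      Region, VariantRecord, write_bed, write_fasta,
                      write_panel)
from .sweep import LineCounts

_BASES = np.array(list("ACGT"))
_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclass(frozen=True)
class SweepSpec:
    """One injected sweep segment.  ``pools`` lists the populations forced
    monomorphic inside it ("cultivated", optionally also "wild")."""

    chrom: str
    start: int
    length: int
    pools: tuple[str, ...] = ("cultivated",)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic panel.

    Defaults mirror the real panel's composition (19 wild, 10 semi-wild
    and 14 cultivated lines; ~3-4x depth after normalisation) on a
    desk-scale 20 x 1 Mb genome, with an ancestral SNP density chosen so
    the wild pool's nucleotide diversity lands near 2e-3 substitutions
    per site and a bottleneck retention that depresses cultivated
    diversity to roughly 0.6 of the wild value.
    """

    n_chromosomes: int = 20
    chromosome_length: int = 1_000_000
    n_wild: int = 19
    n_semiwild: int = 10
    n_cultivated: int = 14
    snp_density: float = 0.015          # ancestral SNPs per bp
    bottleneck_retention: float = 0.6   # P(polymorphism survives bottleneck)
    drift_concentration: float = 4.0    # Beta concentration of surviving freqs
    inbreeding_wild: float = 0.95       # selfing species: mostly homozygous
    inbreeding_cultivated: float = 0.99
    n_sweeps: int = 5
    sweep_length: int = 300_000
    n_shared_sweeps: int = 0            # fixed in wild AND cultivated
    sweep_placement: str = "spaced"     # "spaced" | "random"
    sweeps: list[SweepSpec] | None = None   # explicit specs override above
    hybrid_pedigree: str = "F1"         # "F1" | "F2"
    n_specific_segments: int = 2        # per carrier population
    specific_segment_length: int = 50_000
    semiwild_carries_specific: bool = True
    mean_depth: float = 4.0
    coverage_tile: int = 1000           # bp of constant coverage per tile
    error_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chromosomes", "chromosome_length", "n_wild",
                     "n_semiwild", "n_cultivated", "coverage_tile"):
            if getattr(self, name) <= 0:
                raise InvariantError(f"{name} must be positive")
        if not 0 < self.snp_density < 1:
            raise InvariantError("snp_density must be in (0,1)")
        if not 0 <= self.bottleneck_retention <= 1:
            raise InvariantError("bottleneck_retention must be in [0,1]")
        if self.hybrid_pedigree not in ("F1", "F2"):
            raise InvariantError("hybrid_pedigree must be 'F1' or 'F2'")
        if self.sweep_placement not in ("spaced", "random"):
            raise InvariantError("sweep_placement must be spaced|random")
        for name in ("inbreeding_wild", "inbreeding_cultivated"):
            if not 0 <= getattr(self, name) <= 1:
                raise InvariantError(f"{name} must be in [0,1]")
        if self.sweeps is None and self.n_sweeps + self.n_shared_sweeps > 0:
            if self.sweep_length > self.chromosome_length:
                raise InvariantError("sweep longer than chromosome")


@dataclass
class TruthSet:
    """Ground truth of one simulated panel."""

    sweeps: list[SweepSpec]
    specific_segments: dict[str, list[Region]]
    p_diff: dict[str, float]            # expected het fraction per hybrid
    genotypes: dict[str, np.ndarray]    # accession -> dosage vector

    @property
    def cultivated_only_sweeps(self) -> list[SweepSpec]:
        return [s for s in self.sweeps if s.pools == ("cultivated",)]

    @property
    def shared_sweeps(self) -> list[SweepSpec]:
        return [s for s in self.sweeps if "wild" in s.pools]


class SimulatedPanel:
    """In-memory result of :func:`simulate_panel`.

    Holds the genome index, site table, per-line genotypes and read
    counts, coverage tracks and the truth set; ``write`` emits the full
    file bundle (FASTA, per-accession VCFs, depth TSVs, panel TSV, truth
    BED/JSON).
    """

    def __init__(self, config: SimulationConfig, genome: GenomeIndex,
                 site_chrom: np.ndarray, site_pos: np.ndarray,
                 ref: np.ndarray, alt: np.ndarray,
                 accessions: list[str], panel: dict[str, str],
                 genotypes: np.ndarray, depth: np.ndarray,
                 alt_reads: np.ndarray,
                 coverage: dict[str, dict[str, CoverageTrack]],
                 truth: TruthSet, sequences: dict[str, np.ndarray]):
        self.config = config
        self.genome = genome
        self.site_chrom = site_chrom      # str array per site
        self.site_pos = site_pos          # 0-based
        self.ref = ref
        self.alt = alt
        self.accessions = accessions
        self.panel = panel                # accession -> population
        self.genotypes = genotypes        # (n_acc, n_sites) dosage 0/1/2
        self.depth = depth                # (n_acc, n_sites)
        self.alt_reads = alt_reads        # (n_acc, n_sites)
        self.coverage = coverage
        self.truth = truth
        self._sequences = sequences       # chrom -> base array

    # -- views -------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_pos)

    def lines_of(self, population: str) -> list[str]:
        return [a for a in self.accessions if self.panel[a] == population]

    def union_sites(self) -> list[tuple[str, int, str, str]]:
        """Panel-wide variant union (sites carried by at least one line)."""
        mask = (self.genotypes > 0).any(axis=0)
        return [(self.site_chrom[i], int(self.site_pos[i]),
                 str(self.ref[i]), str(self.alt[i]))
                for i in np.flatnonzero(mask)]

    def line_counts(self, population: str) -> list[LineCounts]:
        """Per-line allele read counts at the panel-wide union sites,
        ready for the sweep pipeline (no call-set materialisation)."""
        mask = (self.genotypes > 0).any(axis=0)
        idx = np.flatnonzero(mask)
        chrom = self.site_chrom[idx]
        pos = self.site_pos[idx]
        out = []
        for acc in self.lines_of(population):
            i = self.accessions.index(acc)
            altc = self.alt_reads[i, idx].astype(np.int64)
            refc = (self.depth[i, idx] - self.alt_reads[i, idx]).astype(
                np.int64)
            out.append(LineCounts(acc, chrom, pos, refc, altc))
        return out

    def callset(self, accession: str) -> AccessionCallSet:
        """Materialise one accession's call set (sites with reads only)."""
        i = self.accessions.index(accession)
        records = []
        for j in range(self.n_sites):
            d = int(self.depth[i, j])
            if d == 0:
                continue
            g = (Genotype.HOM_REF, Genotype.HET,
                 Genotype.HOM_ALT)[int(self.genotypes[i, j])]
            records.append(VariantRecord(
                self.site_chrom[j], int(self.site_pos[j]) + 1,
                str(self.ref[j]), str(self.alt[j]), g, d,
                int(self.alt_reads[i, j])))
        return AccessionCallSet(accession, self.panel[accession], records,
                                self.genome)

    def callsets(self, population: str | None = None,
                 ) -> list[AccessionCallSet]:
        accs = (self.accessions if population is None
                else self.lines_of(population))
        return [self.callset(a) for a in accs]

    # -- emission ----------------------------------------------------------
    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        fasta = out / "reference.fa"
        write_fasta({c: "".join(self._sequences[c])
                     for c in self.genome.names}, fasta)
        paths["reference"] = fasta

        panel_path = out / "panel.tsv"
        write_panel(self.panel, panel_path)
        paths["panel"] = panel_path

        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for acc in self.accessions:
            p = vcf_dir / f"{acc}.vcf"
            self._write_vcf(acc, p)
            paths[f"vcf:{acc}"] = p

        depth_dir = out / "depth"
        depth_dir.mkdir(exist_ok=True)
        for acc in self.accessions:
            p = depth_dir / f"{acc}.depth.tsv"
            with open(p, "w") as fh:
                for chrom in self.genome.names:
                    for s, e, d in self.coverage[acc][chrom].runs:
                        for pos in range(s, e):
                            fh.write(f"{chrom}\t{pos + 1}\t{d}\n")
            paths[f"depth:{acc}"] = p

        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        sweep_bed = truth_dir / "sweeps.bed"
        write_bed([Region(s.chrom, s.start, s.end, "+".join(s.pools))
                   for s in self.truth.sweeps], sweep_bed, self.genome)
        paths["truth:sweeps"] = sweep_bed
        for pop, regs in self.truth.specific_segments.items():
            p = truth_dir / f"specific_{pop}.bed"
            write_bed(regs, p, self.genome)
            paths[f"truth:specific:{pop}"] = p
        truth_json = truth_dir / "truth.json"
        with open(truth_json, "w") as fh:
            json.dump({
                "p_diff": self.truth.p_diff,
                "sweeps": [asdict(s) for s in self.truth.sweeps],
                "seed": self.config.seed,
            }, fh, indent=1)
        paths["truth:json"] = truth_json
        return paths

    def _write_vcf(self, accession: str, path: Path) -> None:
        i = self.accessions.index(accession)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                     'Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                     'Description="Read depth">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allele depths">\n')
            for c in self.genome.names:
                fh.write(f"##contig=<ID={c},length={self.genome.length(c)}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     f"{accession}\n")
            for j in range(self.n_sites):
                d = int(self.depth[i, j])
                if d == 0:
                    continue
                ar = int(self.alt_reads[i, j])
                gt = _GT_STR[int(self.genotypes[i, j])]
                fh.write(f"{self.site_chrom[j]}\t{int(self.site_pos[j]) + 1}"
                         f"\t.\t{self.ref[j]}\t{self.alt[j]}\t.\t.\t.\t"
                         f"GT:DP:AD\t{gt}:{d}:{d - ar},{ar}\n")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_sweeps(config: SimulationConfig,
                  genome: GenomeIndex,
                  rng: np.random.Generator) -> list[SweepSpec]:
    if config.sweeps is not None:
        for s in config.sweeps:
            if s.end > genome.length(s.chrom):
                raise InvariantError(f"sweep beyond chromosome end: {s}")
        return list(config.sweeps)
    specs: list[SweepSpec] = []
    kinds = ([("cultivated",)] * config.n_sweeps
             + [("cultivated", "wild")] * config.n_shared_sweeps)
    if not kinds:
        return specs
    if config.sweep_placement == "spaced":
        # one sweep per chromosome, cycling, centred and grid-aligned
        for k, pools in enumerate(kinds):
            chrom = genome.names[k % len(genome.names)]
            mid = genome.length(chrom) // 2
            start = max(0, mid - config.sweep_length // 2)
            start = (start // 50_000) * 50_000
            specs.append(SweepSpec(chrom, start, config.sweep_length, pools))
    else:
        for pools in kinds:
            for _ in range(1000):
                chrom = genome.names[rng.integers(len(genome.names))]
                start = int(rng.integers(
                    0, genome.length(chrom) - config.sweep_length + 1))
                cand = SweepSpec(chrom, start, config.sweep_length, pools)
                if all(c.chrom != cand.chrom or c.end <= cand.start
                       or cand.end <= c.start for c in specs):
                    specs.append(cand)
                    break
            else:
                raise InvariantError("could not place non-overlapping sweeps")
    return specs


def _place_segments(config: SimulationConfig, genome: GenomeIndex,
                    sweeps: Sequence[SweepSpec],
                    rng: np.random.Generator) -> dict[str, list[Region]]:
    """Lineage-specific presence/absence segments, clear of sweeps."""
    out: dict[str, list[Region]] = {"cultivated": [], "wild": []}
    taken = [(s.chrom, s.start, s.end) for s in sweeps]
    for pop in out:
        for k in range(config.n_specific_segments):
            for _ in range(1000):
                chrom = genome.names[rng.integers(len(genome.names))]
                L = genome.length(chrom)
                if config.specific_segment_length >= L:
                    continue
                start = int(rng.integers(
                    0, L - config.specific_segment_length + 1))
                end = start + config.specific_segment_length
                if all(c != chrom or e0 <= start or end <= s0
                       for c, s0, e0 in taken):
                    out[pop].append(
                        Region(chrom, start, end, f"{pop}_specific"))
                    taken.append((chrom, start, end))
                    break
            else:
                raise InvariantError("could not place specific segments")
    return out


def _site_mask(site_chrom: np.ndarray, site_pos: np.ndarray,
               regions: Sequence) -> np.ndarray:
    mask = np.zeros(len(site_pos), dtype=bool)
    for r in regions:
        mask |= ((site_chrom == r.chrom) & (site_pos >= r.start)
                 & (site_pos < r.end))
    return mask


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate a full synthetic panel with truth labels (seeded)."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (seq_ss, site_ss, geno_ss, hybrid_ss, reads_ss,
     cov_ss, place_ss) = root.spawn(7)
    rng_site = np.random.default_rng(site_ss)
    rng_geno = np.random.default_rng(geno_ss)
    rng_hyb = np.random.default_rng(hybrid_ss)
    rng_reads = np.random.default_rng(reads_ss)
    rng_cov = np.random.default_rng(cov_ss)
    rng_place = np.random.default_rng(place_ss)

    names = tuple(f"chr{i + 1:02d}" for i in range(config.n_chromosomes))
    genome = GenomeIndex(names, {n: config.chromosome_length for n in names})

    # reference sequence (deterministic per chromosome)
    rng_seq = np.random.default_rng(seq_ss)
    sequences = {c: _BASES[rng_seq.integers(0, 4, genome.length(c))]
                 for c in names}

    # ancestral SNP sites
    chrom_list, pos_list = [], []
    for c in names:
        L = genome.length(c)
        n = rng_site.binomial(L, config.snp_density)
        pos = np.sort(rng_site.choice(L, size=n, replace=False))
        pos_list.append(pos)
        chrom_list.append(np.full(n, c, dtype=object))
    site_chrom = np.concatenate(chrom_list)
    site_pos = np.concatenate(pos_list).astype(np.int64)
    n_sites = len(site_pos)

    ref = np.concatenate([sequences[c][p] for c, p in
                          zip(names, pos_list)]) if n_sites else np.array([])
    # alt differs from ref: shift by 1..3 in base order
    shift = rng_site.integers(1, 4, n_sites)
    base_idx = np.searchsorted(_BASES, ref)
    alt = _BASES[(base_idx + shift) % 4]

    p_anc = rng_site.beta(0.2, 0.2, n_sites)

    sweeps = _place_sweeps(config, genome, rng_place)
    segments = _place_segments(config, genome, sweeps, rng_place)

    # population allele frequencies
    retained = rng_geno.random(n_sites) < config.bottleneck_retention
    c = config.drift_concentration
    p_cult = np.where(
        retained,
        rng_geno.beta(np.maximum(c * p_anc, 1e-3),
                      np.maximum(c * (1 - p_anc), 1e-3)),
        (rng_geno.random(n_sites) < p_anc).astype(float),
    )

    wild_names = [f"W{i + 1:02d}" for i in range(config.n_wild)]
    cult_names = [f"C{i + 1:02d}" for i in range(config.n_cultivated)]
    semi_names = [f"Z{i + 1:02d}" for i in range(config.n_semiwild)]
    accessions = wild_names + semi_names + cult_names
    panel = {**{a: "wild" for a in wild_names},
             **{a: "semiwild" for a in semi_names},
             **{a: "cultivated" for a in cult_names}}

    def draw_genotypes(p: np.ndarray, n_lines: int,
                       inbreeding: float) -> np.ndarray:
        """Genotypes with excess homozygosity from partial selfing:
        with probability F a line is autozygous at the site (one allele
        drawn and doubled), otherwise a Hardy-Weinberg draw."""
        hw = rng_geno.binomial(2, p, (n_lines, n_sites))
        auto = 2 * rng_geno.binomial(1, p, (n_lines, n_sites))
        selfed = rng_geno.random((n_lines, n_sites)) < inbreeding
        return np.where(selfed, auto, hw).astype(np.int8)

    g_wild = draw_genotypes(p_anc, config.n_wild, config.inbreeding_wild)
    g_cult = draw_genotypes(p_cult, config.n_cultivated,
                            config.inbreeding_cultivated)

    # force sweeps monomorphic for the major allele
    for spec in sweeps:
        m = _site_mask(site_chrom, site_pos, [spec])
        if "cultivated" in spec.pools:
            g_cult[:, m] = (2 * (p_cult[m] > 0.5)).astype(np.int8)
        if "wild" in spec.pools:
            fix = (2 * (p_anc[m] > 0.5)).astype(np.int8)
            g_wild[:, m] = fix
            g_cult[:, m] = fix  # shared sweep: same allele in both pools

    # hybrids
    g_semi = np.zeros((config.n_semiwild, n_sites), dtype=np.int8)
    p_diff: dict[str, float] = {}
    chrom_codes = np.searchsorted(np.array(names, dtype=object), site_chrom)
    for h, name in enumerate(semi_names):
        wp = g_wild[rng_hyb.integers(config.n_wild)]
        cp = g_cult[rng_hyb.integers(config.n_cultivated)]
        gam_w = (rng_hyb.random(n_sites) < wp / 2.0).astype(np.int8)
        gam_c = (rng_hyb.random(n_sites) < cp / 2.0).astype(np.int8)
        if config.hybrid_pedigree == "F1":
            g = gam_w + gam_c
        else:  # F2: self the F1 with one crossover per chromosome per gamete
            g = np.zeros(n_sites, dtype=np.int8)
            for _ in range(2):
                pick = np.zeros(n_sites, dtype=bool)  # False=w, True=c
                for ci, chrom in enumerate(names):
                    m = chrom_codes == ci
                    xo = rng_hyb.integers(genome.length(chrom))
                    left = site_pos[m] < xo
                    first = bool(rng_hyb.integers(2))
                    pick[m] = np.where(left, first, not first)
                g += np.where(pick, gam_c, gam_w).astype(np.int8)
        g_semi[h] = g
        variant = g > 0
        n_var = int(variant.sum())
        p_diff[name] = (float((g == 1).sum()) / n_var if n_var else 0.0)

    genotypes = np.vstack([g_wild, g_semi, g_cult])

    # read support
    depth = rng_reads.poisson(config.mean_depth,
                              genotypes.shape).astype(np.int32)
    e = config.error_rate
    f_alt = genotypes / 2.0 * (1 - e) + (1 - genotypes / 2.0) * e
    alt_reads = rng_reads.binomial(depth, f_alt).astype(np.int32)

    # absence of non-carried segments: no reads there
    seg_masks = {pop: _site_mask(site_chrom, site_pos, regs)
                 for pop, regs in segments.items()}
    for i, acc in enumerate(accessions):
        pop = panel[acc]
        for seg_pop, m in seg_masks.items():
            carrier = (pop == seg_pop
                       or (pop == "semiwild"
                           and config.semiwild_carries_specific))
            if not carrier:
                depth[i, m] = 0
                alt_reads[i, m] = 0

    # coverage tracks (piecewise constant over tiles)
    coverage: dict[str, dict[str, CoverageTrack]] = {}
    tile = config.coverage_tile
    for i, acc in enumerate(accessions):
        pop = panel[acc]
        coverage[acc] = {}
        for chrom in names:
            L = genome.length(chrom)
            n_tiles = (L + tile - 1) // tile
            depths = rng_cov.poisson(config.mean_depth, n_tiles)
            arr = np.repeat(depths, tile)[:L]
            for seg_pop, regs in segments.items():
                carrier = (pop == seg_pop
                           or (pop == "semiwild"
                               and config.semiwild_carries_specific))
                if carrier:
                    continue
                for r in regs:
                    if r.chrom == chrom:
                        arr[r.start:r.end] = 0
            coverage[acc][chrom] = CoverageTrack.from_array(chrom, arr)

    truth = TruthSet(sweeps, segments, p_diff,
                     {acc: genotypes[i] for i, acc in enumerate(accessions)})
    return SimulatedPanel(config, genome, site_chrom, site_pos, ref, alt,
                          accessions, panel, genotypes, depth, alt_reads,
                          coverage, truth, sequences)


# ---------------------------------------------------------------------------
# clustering log-probability table
# ---------------------------------------------------------------------------

def simulate_lnp_table(true_k: int, k_range: Sequence[int] = range(2, 10),
                       replicates: int = 8, noise_sd: float = 0.5,
                       seed: int = 0,
                       base: float = -12_000.0,
                       rise: float = 300.0, plateau: float = 10.0,
                       ) -> pd.DataFrame:
    """Piecewise-linear lnP(K) curves with a slope break at ``true_k``.

    The mean curve rises steeply (``rise`` per K) up to ``true_k`` and
    then flattens (``plateau`` per K); replicate noise is Gaussian.
    ``true_k`` must be interior to the K range (delta-K is undefined at
    the boundaries) and ``noise_sd`` must be positive (a zero replicate
    sd leaves delta-K undefined).
    """
    ks = sorted(k_range)
    if true_k <= ks[0] or true_k >= ks[-1]:
        raise InvariantError("true_k must be interior to k_range")
    if noise_sd <= 0:
        raise InvariantError("noise_sd must be positive")
    if replicates < 2:
        raise InvariantError("need at least 2 replicates per K")
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        mean = (base + rise * (min(k, true_k) - ks[0])
                + plateau * max(0, k - true_k))
        for r in range(replicates):
            rows.append({"K": k, "replicate": r,
                         "lnP": mean + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows)
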