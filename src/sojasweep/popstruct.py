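"""Population-structure summaries from a merged SNP table.

Covers the tree-SNP selection filter (coverage, heterozygosity and
physical-spacing rules), p-distance + neighbor-joining tree with optional
locus-resampling bootstrap, the Evanno delta-K post-processing of a
clustering log-probability table, and a haplotype-sharing check used for
organellar SNP sets.

Tree construction itself is the classic Saitou-Nei neighbor joining and is
delegated to scikit-bio; the filters, distances, bootstrap and delta-K
logic live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvariantError
from .formats import GenomeIndex, Genotype
from .variants import MergedVariantTable, SiteKey

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Accessions x loci genotype codes (0 ref, 1 alt, -1 missing)."""

    accessions: list[str]
    loci: list[SiteKey]
    codes: np.ndarray                      # int8, shape (n_acc, n_loci)
    attrition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.accessions), len(self.loci)):
            raise InvariantError("codes shape does not match labels")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def restrict(self, chrom: str) -> "GenotypeMatrix":
        """Loci of one molecule only (e.g. a chloroplast SNP set)."""
        idx = [i for i, k in enumerate(self.loci) if k[0] == chrom]
        return GenotypeMatrix(self.accessions,
                              [self.loci[i] for i in idx],
                              self.codes[:, idx])


def select_tree_snps(table: MergedVariantTable,
                     min_cov: int = 3,
                     excl_dist: int = 50,
                     genome: GenomeIndex | None = None,
                     het_policy: str = "drop_locus",
                     ) -> GenotypeMatrix:
    """Three-stage locus selection for phylogeny/structure input.

    1. keep biallelic SNP loci with read depth >= ``min_cov`` in *every*
       accession (a call must exist in every line);
    2. drop any locus heterozygous in any accession
       (``het_policy='drop_locus'``, default — NJ needs a complete,
       haplotype-like matrix; ``'drop_genotype'`` instead blanks only the
       heterozygous genotypes to missing);
    3. drop *both* members of any pair of surviving loci within
       ``excl_dist`` bp on the same chromosome (tightly linked pairs are
       likely alignment artefacts).

    Raises with stage-wise attrition counts if nothing survives.
    """
    if het_policy not in ("drop_locus", "drop_genotype"):
        raise ValueError("het_policy must be 'drop_locus' or 'drop_genotype'")
    accs = table.accessions
    candidates = [k for k in table.calls
                  if table.is_snp[k] and k not in table.multiallelic]
    attrition = {"candidates": len(candidates)}

    # stage 1: coverage in every line
    stage1 = []
    for key in candidates:
        site = table.calls[key]
        if all(acc in site and site[acc].depth >= min_cov for acc in accs):
            stage1.append(key)
    attrition["min_coverage"] = len(stage1)

    # stage 2: heterozygosity
    blanked: dict[SiteKey, set[str]] = {}
    if het_policy == "drop_locus":
        stage2 = [k for k in stage1
                  if all(table.calls[k][a].genotype is not Genotype.HET
                         for a in accs)]
    else:
        stage2 = stage1
        for k in stage1:
            hets = {a for a in accs
                    if table.calls[k][a].genotype is Genotype.HET}
            if hets:
                blanked[k] = hets
    attrition["het_filter"] = len(stage2)

    # stage 3: physical spacing
    if genome is not None:
        stage2 = sorted(stage2, key=lambda k: (genome.order(k[0]), k[1]))
    else:
        stage2 = sorted(stage2, key=lambda k: (k[0], k[1]))
    drop: set[SiteKey] = set()
    for prev, cur in zip(stage2, stage2[1:]):
        if prev[0] == cur[0] and cur[1] - prev[1] <= excl_dist:
            drop.add(prev)
            drop.add(cur)
    stage3 = [k for k in stage2 if k not in drop]
    attrition["spacing_filter"] = len(stage3)

    if not stage3:
        raise InvariantError(
            f"no loci survive tree-SNP selection; attrition: {attrition}")

    codes = np.zeros((len(accs), len(stage3)), dtype=np.int8)
    for j, key in enumerate(stage3):
        site = table.calls[key]
        for i, acc in enumerate(accs):
            g = site[acc].genotype
            if g is Genotype.HET or acc in blanked.get(key, ()):
                codes[i, j] = MISSING
            else:
                codes[i, j] = 0 if g is Genotype.HOM_REF else 1
    return GenotypeMatrix(list(accs), stage3, codes, attrition)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise InvariantError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise InvariantError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise InvariantError("distance matrix diagonal not zero")


def p_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Proportion of differing loci per accession pair (pairwise-complete
    over non-missing loci)."""
    if matrix.n_loci == 0:
        raise InvariantError("p_distance needs at least one locus")
    codes = matrix.codes
    n = codes.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] != MISSING) & (codes[j] != MISSING)
            if not ok.any():
                raise InvariantError(
                    f"no comparable loci between {matrix.accessions[i]} "
                    f"and {matrix.accessions[j]}")
            d[i, j] = d[j, i] = np.mean(codes[i][ok] != codes[j][ok])
    return DistanceMatrix(list(matrix.accessions), d)


def nj_tree(distances: DistanceMatrix):
    """Saitou-Nei neighbor joining (via scikit-bio); returns an unrooted
    ``skbio.TreeNode``.  Negative branch lengths are clamped to zero."""
    import skbio
    from skbio.tree import nj

    if len(distances.ids) < 3:
        raise InvariantError("neighbor joining needs at least 3 taxa")
    dm = skbio.DistanceMatrix(distances.values, ids=distances.ids)
    return nj(dm, neg_as_zero=True)


def tree_to_newick(tree) -> str:
    return str(tree).strip()


def _bipartitions(tree, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical tip-name subsets."""
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            out.add(min(side, other, key=lambda s: sorted(s)))
    return out


def bootstrap_tree(matrix: GenotypeMatrix, n_replicates: int = 1000,
                   seed: int | np.random.Generator = 0):
    """NJ tree with bipartition support from locus resampling.

    Loci are resampled with replacement ``n_replicates`` times; each
    internal branch of the full-data tree is annotated (node name) with
    the fraction of replicate trees containing its bipartition.
    Returns ``(tree, support)`` where ``support`` maps bipartition ->
    fraction.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    main = nj_tree(p_distance(matrix))
    taxa = frozenset(matrix.accessions)
    target = _bipartitions(main, taxa)
    counts = {bp: 0 for bp in target}
    for _ in range(n_replicates):
        idx = rng.integers(0, matrix.n_loci, size=matrix.n_loci)
        rep = GenotypeMatrix(matrix.accessions,
                             [matrix.loci[i] for i in idx],
                             matrix.codes[:, idx])
        try:
            rep_bps = _bipartitions(nj_tree(p_distance(rep)), taxa)
        except InvariantError:
            continue
        for bp in target & rep_bps:
            counts[bp] += 1
    support = {bp: c / n_replicates for bp, c in counts.items()}
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            bp = min(side, taxa - side, key=lambda s: sorted(s))
            node.name = f"{support[bp]:.2f}"
    return main, support


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(lnp_table: pd.DataFrame) -> pd.DataFrame:
    """Second-order rate of change of the clustering log probability.

    Input columns: ``K``, ``replicate``, ``lnP``.  With L_r(K) the
    replicate curves, for each interior K:

        |L''_r(K)| = |L_r(K+1) - 2 L_r(K) + L_r(K-1)|
        deltaK(K)  = mean_r |L''_r(K)| / sd_r(L_r(K))

    Replicates are paired by their rank within each K (replicate ids need
    not match across K, but counts must).  Output has one row per K with
    ``mean_lnp``, ``sd_lnp``, ``delta_k`` (NaN at boundary K and where
    sd = 0, which is flagged with a warning).
    """
    df = lnp_table[["K", "replicate", "lnP"]].copy()
    ks = np.sort(df["K"].unique())
    if len(ks) < 3:
        raise InvariantError("delta-K needs at least 3 distinct K values")
    if np.any(np.diff(ks) != 1):
        raise InvariantError("K values must be consecutive integers")
    counts = df.groupby("K").size()
    if counts.min() < 2:
        raise InvariantError("delta-K needs >= 2 replicates per K")
    if counts.nunique() != 1:
        raise InvariantError("unequal replicate counts across K")
    n_rep = int(counts.iloc[0])
    # rank-pair replicates: matrix L[k_index, rep]
    L = np.empty((len(ks), n_rep))
    for i, k in enumerate(ks):
        L[i] = np.sort(df.loc[df["K"] == k, "lnP"].to_numpy())
    mean_lnp = L.mean(axis=1)
    sd_lnp = L.std(axis=1, ddof=1)
    second = np.abs(L[2:] - 2 * L[1:-1] + L[:-2])       # per replicate
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd_lnp[i] == 0:
            warnings.warn(f"delta-K undefined at K={ks[i]} (sd = 0)")
            continue
        delta[i] = second[i - 1].mean() / sd_lnp[i]
    return pd.DataFrame({"K": ks, "mean_lnp": mean_lnp,
                         "sd_lnp": sd_lnp, "delta_k": delta})


def best_k(delta_table: pd.DataFrame) -> int:
    """K at the delta-K peak (interior K only)."""
    d = delta_table["delta_k"]
    if d.isna().all():
        raise InvariantError("delta-K undefined at every interior K")
    return int(delta_table.loc[d.idxmax(), "K"])


# ---------------------------------------------------------------------------
# haplotype sharing
# ---------------------------------------------------------------------------

def shared_haplotype(matrix: GenotypeMatrix,
                     group: Sequence[str],
                     ) -> tuple[bool, list[str]]:
    """Do all accessions of ``group`` carry one identical haplotype?

    Missing genotypes are treated as mismatches.  Returns the verdict and
    the distinct haplotype strings observed in the group ('?' = missing).
    """
    if not group:
        raise InvariantError("empty group")
    idx = []
    for acc in group:
        try:
            idx.append(matrix.accessions.index(acc))
        except ValueError:
            raise InvariantError(f"accession {acc!r} not in matrix") from None
    haplos = []
    for i in idx:
        haplos.append("".join("?" if c == MISSING else str(int(c))
                              for c in matrix.codes[i]))
    distinct = sorted(set(haplos))
    if len(idx) == 1:
        return True, distinct
    shared = len(distinct) == 1 and "?" not in distinct[0]
    return shared, distinct
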