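"""Cross-accession SNP retention filter and per-accession heterozygosity.

A variant called in a single low-coverage line is likely a mapping or
sequencing artefact, so the panel-wide retention rule keeps a site only if
the variant allele is seen in at least two accessions, or in exactly one
accession backed by more than ``min_reads`` variant-supporting reads.
"Present in an accession" means the accession carries the variant allele
(genotype het or hom_alt); hom_ref and missing calls do not count as
presence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InvariantError
from .formats import AccessionCallSet, Genotype, VariantRecord

SiteKey = tuple[str, int, str, str]  # chrom, 1-based pos, ref, alt


@dataclass(frozen=True, slots=True)
class SiteCall:
    """One accession's call at one merged site."""

    genotype: Genotype
    depth: int
    alt_support: int


@dataclass
class MergedVariantTable:
    """Union of per-accession call sets keyed by (chrom, pos, ref, alt).

    ``calls[key]`` maps accession id -> :class:`SiteCall`; accessions absent
    from the inner mapping are missing at the site.  Sites where more than
    one ALT allele segregates across accessions appear under one key per
    ALT, each flagged multi-allelic and excluded downstream.
    """

    accessions: list[str]
    calls: dict[SiteKey, dict[str, SiteCall]]
    is_snp: dict[SiteKey, bool]
    multiallelic: set[SiteKey]

    def accession_count(self, key: SiteKey) -> int:
        """Accessions with a non-missing call at the site."""
        return len(self.calls[key])

    def presence_count(self, key: SiteKey) -> int:
        """Accessions actually carrying the variant allele at the site."""
        return sum(1 for c in self.calls[key].values()
                   if c.genotype is not Genotype.HOM_REF)

    def __len__(self) -> int:
        return len(self.calls)


def merge_callsets(callsets: Sequence[AccessionCallSet]) -> MergedVariantTable:
    """Combine per-accession calls into one site-keyed table.

    Two accessions reporting different REF bases at the same position is a
    reference inconsistency and raises; different ALT bases are legal and
    produce two keys, both flagged multi-allelic.
    """
    accessions = [cs.accession for cs in callsets]
    if len(set(accessions)) != len(accessions):
        raise InvariantError("duplicate accession ids in merge")
    calls: dict[SiteKey, dict[str, SiteCall]] = {}
    is_snp: dict[SiteKey, bool] = {}
    ref_at: dict[tuple[str, int], str] = {}
    alts_at: dict[tuple[str, int], set[str]] = {}

    for cs in callsets:
        for rec in cs.records:
            posk = (rec.chrom, rec.pos)
            prev_ref = ref_at.get(posk)
            if prev_ref is None:
                ref_at[posk] = rec.ref_allele
            elif prev_ref != rec.ref_allele:
                raise InvariantError(
                    f"conflicting reference allele at {rec.chrom}:{rec.pos} "
                    f"({prev_ref!r} vs {rec.ref_allele!r})")
            key = (rec.chrom, rec.pos, rec.ref_allele, rec.alt_allele)
            calls.setdefault(key, {})[cs.accession] = SiteCall(
                rec.genotype, rec.depth, rec.alt_support)
            is_snp[key] = rec.is_snp
            alts_at.setdefault(posk, set()).add(rec.alt_allele)

    multi = {key for key in calls
             if len(alts_at[(key[0], key[1])]) > 1}
    return MergedVariantTable(accessions, calls, is_snp, multi)


def cross_accession_filter(table: MergedVariantTable,
                           min_accessions: int = 2,
                           min_reads: int = 10,
                           support: str = "alt",
                           ) -> set[SiteKey]:
    """Panel-wide SNP retention rule.

    A site is retained iff the variant allele is present in at least
    ``min_accessions`` accessions, OR it is present in exactly one accession
    whose supporting reads are strictly greater than ``min_reads``.
    ``support`` selects whether the single-carrier threshold applies to
    variant-supporting reads (``"alt"``, default) or total site depth
    (``"depth"``); published pipelines are often ambiguous on this point.
    """
    if support not in ("alt", "depth"):
        raise ValueError("support must be 'alt' or 'depth'")
    retained: set[SiteKey] = set()
    for key, site in table.calls.items():
        carriers = [c for c in site.values()
                    if c.genotype is not Genotype.HOM_REF]
        if len(carriers) >= min_accessions:
            retained.add(key)
        elif len(carriers) == 1:
            reads = (carriers[0].alt_support if support == "alt"
                     else carriers[0].depth)
            if reads > min_reads:
                retained.add(key)
    return retained


@dataclass(frozen=True, slots=True)
class HetReport:
    """Per-accession heterozygosity among its own variant sites."""

    accession: str
    n_snps: int
    n_het: int

    @property
    def het_rate(self) -> float:
        """n_het / n_snps; NaN when the accession has no variant sites."""
        if self.n_snps == 0:
            return math.nan
        return self.n_het / self.n_snps


def het_rate(callset: AccessionCallSet,
             variant_class: str = "snp",
             retained: Iterable[SiteKey] | None = None,
             ) -> HetReport:
    """Heterozygosity rate over the accession's variant sites.

    The denominator is the accession's own variant-site count (sites where
    it carries the variant allele), optionally restricted to a retained
    site-key set from :func:`cross_accession_filter`.  ``variant_class``
    selects SNPs (default) or indels; indel genotyping conventions differ
    between callers, so indel rates are convention-dependent.
    """
    if variant_class not in ("snp", "indel"):
        raise ValueError("variant_class must be 'snp' or 'indel'")
    want_snp = variant_class == "snp"
    keys = set(retained) if retained is not None else None
    n_var = n_het = 0
    for rec in callset.records:
        if rec.is_snp != want_snp:
            continue
        if rec.genotype is Genotype.HOM_REF:
            continue
        if keys is not None and (rec.chrom, rec.pos, rec.ref_allele,
                                 rec.alt_allele) not in keys:
            continue
        n_var += 1
        if rec.genotype is Genotype.HET:
            n_het += 1
    return HetReport(callset.accession, n_var, n_het)


def het_report_table(callsets: Sequence[AccessionCallSet],
                     variant_class: str = "snp",
                     retained: Iterable[SiteKey] | None = None):
    """Convenience: het reports for a panel as a pandas DataFrame."""
    import pandas as pd

    rows = []
    ret = set(retained) if retained is not None else None
    for cs in callsets:
        rep = het_rate(cs, variant_class, ret)
        rows.append({"accession": rep.accession,
                     "population": cs.population,
                     "n_snps": rep.n_snps, "n_het": rep.n_het,
                     "het_rate": rep.het_rate})
    return pd.DataFrame(rows)
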