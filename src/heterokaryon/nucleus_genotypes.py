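"""Per-nucleus genotype calling, discordance and recombination-block detection.

Single-nucleus sequencing of a dikaryon should show every nucleus carrying
exactly one allele per site, with allele identity locked to the nucleus's
MAT locus.  Departures are informative: a site where both alleles occur
*within* one MAT group (a discordant SNP) is a candidate signal of
inter-nucleus recombination, and a run of at least ``min_run`` consecutive
discordant SNPs on one contig is called a recombination block.

Calls are filtered the way the source data demand for amplified single
nuclei: heterozygous-looking sites (both alleles above a read-fraction
threshold in any nucleus, an amplification/contamination artefact in haploid
nuclei) are removed together with their +/- ``proximity_bp`` neighborhoods,
and low-coverage observations are treated as missing.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .vcf_io import GenomicIntervals, VariantTable, intersect_tables
from .site_filters import PoolFilterParams, filter_pool_snps

REF, ALT, MISSING = 0, 1, -1


@dataclasses.dataclass(frozen=True)
class HetFilterParams:
    """Heterozygosity, proximity and depth thresholds for nucleus calls."""

    het_fraction: float = 0.1
    proximity_bp: int = 500
    min_depth: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.het_fraction < 0.5:
            raise ValueError("het_fraction must lie in (0, 0.5)")
        if self.proximity_bp < 0 or self.min_depth < 0:
            raise ValueError("proximity_bp and min_depth must be >= 0")


@dataclasses.dataclass
class NucleusCallSet:
    """One nucleus's calls (0 ref / 1 alt / -1 missing) over a shared site list."""

    nucleus_id: str
    mat: str | None
    calls: np.ndarray
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites),):
            raise ValueError("calls must align 1:1 with the site list")

    def subset(self, mask: np.ndarray, sites: pd.DataFrame) -> "NucleusCallSet":
        return NucleusCallSet(self.nucleus_id, self.mat, self.calls[mask], sites)


@dataclasses.dataclass(frozen=True)
class RecombinationBlock:
    """A maximal run of consecutive MAT-discordant SNPs on one contig.

    ``first_site_index``/``last_site_index`` are 0-based inclusive positions
    in the contig's ordered (post-filter) SNP list.
    """

    contig: str
    first_site_index: int
    last_site_index: int
    n_snps: int
    nuclei: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_snps != self.last_site_index - self.first_site_index + 1:
            raise ValueError("n_snps inconsistent with index range")


def call_nucleus(
    table: VariantTable,
    nucleus: str,
    params: HetFilterParams = HetFilterParams(),
    mat: str | None = None,
) -> tuple[NucleusCallSet, list[tuple[str, int]]]:
    """Call one nucleus's per-site alleles and flag heterozygous-looking sites.

    Per site: depth below ``min_depth`` (or missing data) gives a missing
    call; both allele fractions strictly above ``het_fraction`` flags the
    site heterozygous (call missing); otherwise the majority allele is
    called.  Returns the call set and the (contig, pos) keys of the
    heterozygous sites.
    """
    c = table.sample_counts(nucleus)
    calls = np.full(table.n_sites, MISSING, dtype=np.int8)
    usable = ~c.missing & (c.dp >= params.min_depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = np.where(usable, c.ro / np.maximum(c.dp, 1), 0.0)
        fa = np.where(usable, c.ao / np.maximum(c.dp, 1), 0.0)
    het = usable & (fr > params.het_fraction) & (fa > params.het_fraction)
    callable_ = usable & ~het
    # RO == AO without tripping the het rule means >=80% of reads supported
    # neither allele; no defensible majority call exists, so leave missing
    decidable = callable_ & (c.ro != c.ao)
    calls[decidable & (c.ao > c.ro)] = ALT
    calls[decidable & (c.ro > c.ao)] = REF
    het_keys = [
        (table.sites.at[i, "contig"], int(table.sites.at[i, "pos"]))
        for i in np.flatnonzero(het)
    ]
    callset = NucleusCallSet(nucleus_id=nucleus, mat=mat, calls=calls, sites=table.sites)
    return callset, het_keys


def call_all_nuclei(
    table: VariantTable,
    mat_labels: Mapping[str, str],
    params: HetFilterParams = HetFilterParams(),
) -> tuple[list[NucleusCallSet], list[tuple[str, int]]]:
    """Call every sample in the table; het sites are pooled across nuclei."""
    callsets: list[NucleusCallSet] = []
    het: set[tuple[str, int]] = set()
    for nucleus in table.samples:
        cs, keys = call_nucleus(table, nucleus, params, mat=mat_labels.get(nucleus))
        callsets.append(cs)
        het.update(keys)
    return callsets, sorted(het)


def exclude_heterozygous_neighborhoods(
    sites: pd.DataFrame,
    het_sites: Sequence[tuple[str, int]],
    proximity_bp: int = 500,
) -> np.ndarray:
    """Mask of sites retained after removing het sites and their neighborhoods.

    A site is dropped iff it is itself heterozygous (in any nucleus) or lies
    within ``proximity_bp`` (inclusive) of a heterozygous site on the same
    contig.
    """
    keep = np.ones(len(sites), dtype=bool)
    if not het_sites:
        return keep
    by_contig: dict[str, list[int]] = {}
    for contig, pos in het_sites:
        by_contig.setdefault(contig, []).append(pos)
    pos_all = sites["pos"].to_numpy()
    contig_all = sites["contig"].to_numpy()
    for contig, het_pos in by_contig.items():
        het_arr = np.sort(np.asarray(het_pos))
        rows = np.flatnonzero(contig_all == contig)
        if rows.size == 0:
            continue
        p = pos_all[rows]
        idx = np.searchsorted(het_arr, p)
        dist_right = np.where(idx < het_arr.size, het_arr[np.clip(idx, 0, het_arr.size - 1)] - p, np.inf)
        dist_left = np.where(idx > 0, p - het_arr[np.clip(idx - 1, 0, None)], np.inf)
        near = np.minimum(dist_left, dist_right) <= proximity_bp
        keep[rows[near]] = False
    return keep


@dataclasses.dataclass
class DiscordanceResult:
    flags: np.ndarray  # bool per site: discordant within some MAT group
    n_total: int
    n_discordant: int
    sites: pd.DataFrame


def find_discordant_snps(callsets: Sequence[NucleusCallSet]) -> DiscordanceResult:
    """Flag sites where both alleles occur among nuclei sharing a MAT identity.

    Missing calls are excluded from the group test.  Requires at least two
    nuclei sharing some MAT identity.
    """
    if len(callsets) < 2:
        raise ValueError("need at least 2 nuclei")
    mats = [cs.mat for cs in callsets]
    if any(m is None for m in mats):
        raise ValueError("every nucleus needs a MAT identity")
    if max(mats.count(m) for m in set(mats)) < 2:
        raise ValueError("no MAT identity is shared by two or more nuclei")
    sites = callsets[0].sites
    calls = np.vstack([cs.calls for cs in callsets])  # nuclei x sites
    flags = np.zeros(calls.shape[1], dtype=bool)
    for mat in sorted(set(mats)):
        group = calls[np.array([m == mat for m in mats])]
        has_ref = (group == REF).any(axis=0)
        has_alt = (group == ALT).any(axis=0)
        flags |= has_ref & has_alt
    return DiscordanceResult(
        flags=flags, n_total=int(flags.size), n_discordant=int(flags.sum()), sites=sites
    )


def discordance_percentage(n_discordant: int, n_total: int) -> float:
    """Percentage of SNPs not matching their MAT identity."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_discordant / n_total


def find_recombination_blocks(
    sites: pd.DataFrame,
    flags: np.ndarray,
    callsets: Sequence[NucleusCallSet] | None = None,
    min_run: int = 5,
    min_snps_per_contig: int = 2,
) -> list[RecombinationBlock]:
    """Maximal runs of >= ``min_run`` consecutive discordant SNPs per contig.

    Contigs carrying fewer than ``min_snps_per_contig`` SNPs in total are
    skipped; blocks never span contigs.  When call sets are supplied, each
    block records the union of nuclei carrying the minority allele within
    their MAT group across the block's sites.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (len(sites),):
        raise ValueError("flags must align with sites")
    blocks: list[RecombinationBlock] = []
    calls = np.vstack([cs.calls for cs in callsets]) if callsets else None
    for contig, group in sites.groupby("contig", sort=False):
        rows = group.index.to_numpy()
        if rows.size < min_snps_per_contig:
            continue
        f = flags[rows]
        i = 0
        while i < f.size:
            if not f[i]:
                i += 1
                continue
            j = i
            while j + 1 < f.size and f[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                nuclei: set[str] = set()
                if calls is not None and callsets is not None:
                    for local in range(i, j + 1):
                        nuclei |= _minority_nuclei(callsets, calls, rows[local])
                blocks.append(
                    RecombinationBlock(
                        contig=contig,
                        first_site_index=i,
                        last_site_index=j,
                        n_snps=j - i + 1,
                        nuclei=frozenset(nuclei),
                    )
                )
            i = j + 1
    return blocks


def _minority_nuclei(
    callsets: Sequence[NucleusCallSet], calls: np.ndarray, site: int
) -> set[str]:
    """Nuclei carrying the within-group minority allele at one site."""
    out: set[str] = set()
    mats = [cs.mat for cs in callsets]
    col = calls[:, site]
    for mat in set(mats):
        rows = np.array([m == mat for m in mats])
        sub = col[rows]
        n_ref = int((sub == REF).sum())
        n_alt = int((sub == ALT).sum())
        if n_ref == 0 or n_alt == 0:
            continue
        if n_alt < n_ref:
            minority = {ALT}
        elif n_ref < n_alt:
            minority = {REF}
        else:  # tie: implicate carriers of both alleles
            minority = {REF, ALT}
        for k in np.flatnonzero(rows):
            if calls[k, site] in minority:
                out.add(callsets[k].nucleus_id)
    return out


def similarity_matrix(callsets: Sequence[NucleusCallSet]) -> pd.DataFrame:
    """Pairwise fraction of co-called sites with identical calls (NaN if none)."""
    if len(callsets) < 2:
        raise ValueError("need at least 2 nuclei")
    ids = [cs.nucleus_id for cs in callsets]
    calls = np.vstack([cs.calls for cs in callsets])
    k = len(ids)
    out = np.full((k, k), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            both = (calls[i] != MISSING) & (calls[j] != MISSING)
            n = int(both.sum())
            if n > 0:
                out[i, j] = out[j, i] = float((calls[i, both] == calls[j, both]).mean())
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclasses.dataclass
class NucleusAnalysis:
    """End-to-end result of the single-nucleus concordance pipeline."""

    callsets: list[NucleusCallSet]
    sites: pd.DataFrame
    discordance: DiscordanceResult
    blocks: list[RecombinationBlock]
    similarity: pd.DataFrame
    n_het_excluded_sites: int


def analyze_nuclei(
    pool_table: VariantTable,
    nuclei_table: VariantTable,
    mat_labels: Mapping[str, str],
    het_params: HetFilterParams = HetFilterParams(),
    pool_params: PoolFilterParams | None = None,
    pool_sample: str | None = None,
    repeats: GenomicIntervals | None = None,
    min_run: int = 5,
    min_snps_per_contig: int = 2,
    unpaired_only_mask: np.ndarray | None = None,
) -> NucleusAnalysis:
    """Run the full pipeline: intersect with the pooled SNP set, apply the
    heterozygosity/proximity/depth filters, then call discordant SNPs, blocks
    and inter-nucleus similarity.

    ``unpaired_only_mask`` optionally marks sites (aligned with the pooled
    table) supported by non-paired reads only; such read-pairing information
    is not derivable from count data, so the default is a no-op.
    """
    if pool_params is not None:
        if pool_sample is None:
            pool_sample = pool_table.samples[0]
        pool_table = filter_pool_snps(pool_table, pool_sample, pool_params, repeats)
    elif repeats is not None and not repeats.is_empty():
        pool_table = pool_table.subset_sites(~repeats.mask_sites(pool_table.sites))
    if unpaired_only_mask is not None:
        pool_table = pool_table.subset_sites(~np.asarray(unpaired_only_mask, bool))
    pool_keys = pool_table.site_index()
    shared = nuclei_table.subset_sites(nuclei_table.site_index().isin(pool_keys))

    callsets, het_keys = call_all_nuclei(shared, mat_labels, het_params)
    keep = exclude_heterozygous_neighborhoods(shared.sites, het_keys, het_params.proximity_bp)
    sites = shared.sites.loc[keep].reset_index(drop=True)
    callsets = [cs.subset(keep, sites) for cs in callsets]

    discordance = find_discordant_snps(callsets)
    blocks = find_recombination_blocks(
        sites, discordance.flags, callsets, min_run=min_run,
        min_snps_per_contig=min_snps_per_contig,
    )
    sim = similarity_matrix(callsets)
    return NucleusAnalysis(
        callsets=callsets,
        sites=sites,
        discordance=discordance,
        blocks=blocks,
        similarity=sim,
        n_het_excluded_sites=int((~keep).sum()),
    )
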