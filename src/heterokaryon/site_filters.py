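"""Pooled-DNA and RNA SNP filters, density statistics and rDNA heterogeneity.

The pooled filter keeps biallelic SNPs whose depth falls inside an explicit
coverage window (default 85-135x, i.e. mean 110 +/- 25) and which show at
least ``min_allele_obs`` reads of *both* alleles; SNPs inside annotated
repeats are optionally excluded.  The RNA filter requires a minimum
replicate-summed depth and both-allele support within every host.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .vcf_io import GenomicIntervals, VariantTable

RDNA_ALPHABET = set("ACGT-N")


@dataclasses.dataclass(frozen=True)
class PoolFilterParams:
    """Thresholds for the pooled-DNA SNP filter (depth bounds inclusive)."""

    cov_lo: int = 85
    cov_hi: int = 135
    min_allele_obs: int = 10
    exclude_repeats: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.cov_lo <= self.cov_hi:
            raise ValueError("require 0 < cov_lo <= cov_hi")
        if self.min_allele_obs < 0:
            raise ValueError("min_allele_obs must be >= 0")


@dataclasses.dataclass(frozen=True)
class RnaFilterParams:
    """Thresholds for the expressed-SNP filter.

    With ``pool_replicates`` (the default) counts are summed across a host's
    replicates before thresholding; otherwise every replicate must pass
    individually.
    """

    min_depth: int = 20
    min_allele_obs: int = 10
    require_all_hosts: bool = True
    pool_replicates: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < self.min_allele_obs:
            raise ValueError("min_depth must be >= min_allele_obs")


def coverage_window(mean_depth: float, half_width: float) -> tuple[float, float]:
    """Symmetric depth window around the mean mapping depth."""
    if not 0 < half_width < mean_depth:
        raise ValueError("require 0 < half_width < mean_depth")
    return (mean_depth - half_width, mean_depth + half_width)


def filter_pool_snps(
    table: VariantTable,
    sample: str,
    params: PoolFilterParams = PoolFilterParams(),
    repeats: GenomicIntervals | None = None,
) -> VariantTable:
    """Apply the pooled-sample SNP filter to one sample's counts.

    A site survives iff ``cov_lo <= DP <= cov_hi``, both ``RO`` and ``AO``
    are at least ``min_allele_obs``, and (when repeat exclusion is on) the
    site lies outside the repeat annotation.  Site order is preserved; all
    sample columns are retained.
    """
    c = table.sample_counts(sample)
    keep = (
        ~c.missing
        & (c.dp >= params.cov_lo)
        & (c.dp <= params.cov_hi)
        & (c.ro >= params.min_allele_obs)
        & (c.ao >= params.min_allele_obs)
    )
    if params.exclude_repeats and repeats is not None and not repeats.is_empty():
        keep &= ~repeats.mask_sites(table.sites)
    return table.subset_sites(keep)


def filter_rna_snps(
    tables: Mapping[str, Sequence[VariantTable]],
    params: RnaFilterParams = RnaFilterParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter expressed SNPs across hosts and compute per-host alt frequencies.

    Parameters
    ----------
    tables
        Mapping host name -> replicate tables (one sample per table).
    params
        Thresholds; with ``require_all_hosts`` a site must pass in every host.

    Returns
    -------
    sites, frequencies
        Surviving site frame (contig, pos, ref, alt) and a DataFrame of
        per-host alt frequencies ``AO / (RO + AO)`` from replicate-summed
        counts, aligned with ``sites``.
    """
    if not tables:
        raise ValueError("at least one host required")
    for host, reps in tables.items():
        if len(reps) == 0:
            raise ValueError(f"host {host!r} has zero replicates")

    # union of site keys observed in any host (sites a host never expressed
    # are treated as failing that host's depth threshold)
    all_keys: pd.MultiIndex | None = None
    for reps in tables.values():
        for t in reps:
            idx = t.site_index()
            all_keys = idx if all_keys is None else all_keys.union(idx, sort=False)
    assert all_keys is not None
    key_frame = all_keys.to_frame(index=False)
    key_frame = key_frame.sort_values(["contig", "pos"]).reset_index(drop=True)
    all_keys = pd.MultiIndex.from_frame(key_frame)
    n = len(all_keys)

    pass_host = {}
    freq_host = {}
    for host, reps in tables.items():
        dp_sum = np.zeros(n)
        ro_sum = np.zeros(n)
        ao_sum = np.zeros(n)
        rep_pass = np.ones(n, dtype=bool)
        for t in reps:
            sample = t.samples[0]
            c = t.sample_counts(sample)
            pos = all_keys.get_indexer(t.site_index())
            present = pos >= 0
            rows = pos[present]
            covered = ~c.missing[present]
            dp_r = np.zeros(n)
            ro_r = np.zeros(n)
            ao_r = np.zeros(n)
            dp_r[rows[covered]] = c.dp[present][covered]
            ro_r[rows[covered]] = c.ro[present][covered]
            ao_r[rows[covered]] = c.ao[present][covered]
            dp_sum += dp_r
            ro_sum += ro_r
            ao_sum += ao_r
            rep_pass &= (
                (dp_r >= params.min_depth)
                & (ro_r >= params.min_allele_obs)
                & (ao_r >= params.min_allele_obs)
            )
        pooled_pass = (
            (dp_sum >= params.min_depth)
            & (ro_sum >= params.min_allele_obs)
            & (ao_sum >= params.min_allele_obs)
        )
        pass_host[host] = pooled_pass if params.pool_replicates else rep_pass
        with np.errstate(invalid="ignore", divide="ignore"):
            tot = ro_sum + ao_sum
            freq_host[host] = np.where(tot > 0, ao_sum / np.where(tot > 0, tot, 1), np.nan)

    stacked = np.vstack(list(pass_host.values()))
    keep = stacked.all(axis=0) if params.require_all_hosts else stacked.any(axis=0)
    sites = key_frame.loc[keep].reset_index(drop=True)
    freqs = pd.DataFrame(
        {host: f[keep] for host, f in freq_host.items()}, index=sites.index
    )
    if not params.require_all_hosts:
        # report frequencies only for hosts where the site actually passed
        for host in tables:
            freqs.loc[~pass_host[host][keep], host] = np.nan
    return sites, freqs


def snp_density(n_snps: int, genome_length: int) -> float:
    """SNPs per kilobase: ``1000 * n_snps / genome_length``."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return 1000.0 * n_snps / genome_length


def repeat_fraction(total_repeat_length: int, genome_length: int) -> float:
    """Percentage of the genome annotated as repetitive."""
    if not 0 <= total_repeat_length <= genome_length:
        raise ValueError("require 0 <= total_repeat_length <= genome_length")
    return 100.0 * total_repeat_length / genome_length


def mean_contig_length(genome_length: int, n_contigs: int) -> float:
    """Average contig length of an assembly, in bp."""
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    return genome_length / n_contigs


def rdna_pairwise_differences(
    copies: Sequence[str] | Sequence[tuple[str, str]],
) -> tuple[np.ndarray, int, bool]:
    """Pairwise differences among aligned rDNA copies.

    Positions where either sequence carries a gap or ``N`` are skipped; a
    position is polymorphic when at least two distinct A/C/G/T residues occur
    across copies.  Alignment itself is out of scope: sequences must already
    be of equal length.

    Returns
    -------
    matrix, n_polymorphic, all_distinct
        Symmetric difference-count matrix, the number of polymorphic
        positions, and whether every pair of copies differs somewhere.
    """
    seqs = [c[1] if isinstance(c, tuple) else c for c in copies]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length (pre-aligned input required)")
    arr = np.array([list(s.upper()) for s in seqs])
    bad = set("".join(seqs).upper()) - RDNA_ALPHABET
    if bad:
        raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")
    valid = np.isin(arr, list("ACGT"))
    k = len(seqs)
    matrix = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            d = int(np.sum(arr[i, both] != arr[j, both]))
            matrix[i, j] = matrix[j, i] = d
    n_poly = 0
    for col in range(length):
        residues = {arr[i, col] for i in range(k) if valid[i, col]}
        if len(residues) >= 2:
            n_poly += 1
    off_diag = matrix[~np.eye(k, dtype=bool)]
    return matrix, n_poly, bool((off_diag > 0).all())
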