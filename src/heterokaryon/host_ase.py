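"""Host-dependent allele-specific expression comparison.

RNA-seq allele counts from the same fungal inoculum colonizing different
host plants can show different allele-frequency spectra — e.g. a clear 50%
peak on one host versus twin ~33/67% peaks on another — indicating that the
two nucleotypes contribute unequally to the mRNA pool in a host-dependent
way.  Two summary statistics make the visual contrast testable:

* ``central_mass`` — the fraction of expressed SNPs with allele frequency
  within a window of 0.5 (high when expression of the two nucleotypes is
  balanced);
* pairwise two-sample Kolmogorov-Smirnov distances between host frequency
  vectors, with replicate consistency as the natural null scale.

The statistics quantify expression-level shifts only; without matched DNA
from the same material they cannot distinguish differential nucleotype
expression from a change in the underlying nucleotype ratio.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .nucleotype_inference import AfSpectrum
from .site_filters import RnaFilterParams, filter_rna_snps
from .vcf_io import VariantTable

import pandas as pd


@dataclasses.dataclass
class HostSpectra:
    """Per-host allele-frequency spectra over a shared expressed-SNP set."""

    hosts: list[str]
    spectra: dict[str, AfSpectrum]
    sites: pd.DataFrame
    replicate_spectra: dict[str, list[AfSpectrum]] | None = None

    @property
    def n_shared_sites(self) -> int:
        return len(self.sites)


@dataclasses.dataclass
class AseShiftStat:
    """Central-mass and pairwise-distance summary of host spectra."""

    central_mass: dict[str, float]
    pairwise_distance: dict[tuple[str, str], float]
    window_w: float


def host_spectra(
    tables: Mapping[str, Sequence[VariantTable]],
    params: RnaFilterParams = RnaFilterParams(),
    keep_replicates: bool = True,
) -> HostSpectra:
    """Filter expressed SNPs across hosts and build per-host spectra.

    Applies :func:`filter_rna_snps` with ``require_all_hosts`` semantics, so
    every host's spectrum covers the identical site set.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 hosts")
    sites, freqs = filter_rna_snps(tables, params)
    if len(sites) == 0:
        diag = {
            host: int(sum(t.n_sites for t in reps)) for host, reps in tables.items()
        }
        raise ValueError(
            "no SNP passed the expressed-in-all-hosts filter "
            f"(per-host input site counts: {diag}; thresholds: depth >= "
            f"{params.min_depth}, both alleles >= {params.min_allele_obs})"
        )
    spectra = {
        host: AfSpectrum(freqs[host].to_numpy()) for host in tables
    }
    rep_spectra: dict[str, list[AfSpectrum]] | None = None
    if keep_replicates:
        keys = pd.MultiIndex.from_frame(sites)
        rep_spectra = {}
        for host, reps in tables.items():
            lst = []
            for t in reps:
                order = t.site_index().get_indexer(keys)
                present = order >= 0
                f = t.alt_frequencies(t.samples[0])[order[present]]
                lst.append(AfSpectrum(f[~np.isnan(f)]))
            rep_spectra[host] = lst
    return HostSpectra(
        hosts=list(tables), spectra=spectra, sites=sites, replicate_spectra=rep_spectra
    )


def ase_shift(
    spectra: HostSpectra,
    window_w: float = 0.07,
    min_sites: int = 100,
) -> AseShiftStat:
    """Quantify between-host shifts in the expressed allele-frequency spectrum."""
    if len(spectra.hosts) < 2:
        raise ValueError("need at least 2 hosts")
    if spectra.n_shared_sites < min_sites:
        raise ValueError(
            f"need at least {min_sites} shared sites, got {spectra.n_shared_sites}"
        )
    central = {
        host: float(
            np.mean(np.abs(sp.frequencies - 0.5) <= window_w)
        )
        for host, sp in spectra.spectra.items()
    }
    dist: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(spectra.hosts, 2):
        fa, fb = spectra.spectra[a].frequencies, spectra.spectra[b].frequencies
        if np.array_equal(fa, fb):
            d = 0.0  # ks_2samp is undefined-ish on identical degenerate vectors
        else:
            d = float(stats.ks_2samp(fa, fb).statistic)
        dist[(a, b)] = d
    return AseShiftStat(central_mass=central, pairwise_distance=dist, window_w=window_w)


def replicate_consistency(
    replicate_spectra: Mapping[str, Sequence[AfSpectrum]],
    max_distance: float = 0.1,
) -> pd.DataFrame:
    """Mean pairwise KS distance among each host's replicate spectra.

    Returns a frame with the per-host mean within-host distance and a flag
    for hosts whose replicates disagree more than ``max_distance``.
    """
    rows = []
    for host, reps in replicate_spectra.items():
        if len(reps) < 2:
            raise ValueError(f"host {host!r} needs at least 2 replicates")
        dists = []
        for a, b in itertools.combinations(reps, 2):
            if np.array_equal(a.frequencies, b.frequencies):
                dists.append(0.0)
            else:
                dists.append(float(stats.ks_2samp(a.frequencies, b.frequencies).statistic))
        mean_d = float(np.mean(dists))
        rows.append((host, mean_d, mean_d > max_distance))
    return pd.DataFrame(rows, columns=["host", "mean_ks_distance", "inconsistent"]).set_index(
        "host"
    )
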