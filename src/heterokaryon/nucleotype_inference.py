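"""Karyotype and nucleotype-ratio inference from pooled allele-frequency spectra.

A monokaryotic isolate shows residual variants only, a balanced dikaryon a
single allele-frequency peak at 50%, and an unbalanced dikaryon (nuclear
ratio r) twin peaks at ``100*(1-r)`` and ``100*r`` percent — e.g. 33/67% at
a 2:1 nucleotype ratio.  Two complementary estimators are provided:

* :func:`detect_modes` — kernel-smoothed spectrum peaks, the direct
  quantitative analogue of reading histogram peaks by eye;
* :func:`estimate_ratio_mle` — a two-component binomial mixture maximum-
  likelihood estimate.  Each site's alternate allele is carried by the major
  or the minor nucleotype with equal prior probability, so site counts
  ``AO ~ Binom(RO+AO, r)`` or ``Binom(RO+AO, 1-r)`` and the per-site
  likelihood is the equal-weight mixture of the two.

MAT-locus coverage provides an independent, SNP-free ratio estimate, and a
PCA over shared-SNP allele frequencies compares samples.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats
from sklearn.decomposition import PCA

from .vcf_io import VariantTable

MONOKARYON_THRESHOLD = 0.95


@dataclasses.dataclass
class AfSpectrum:
    """Alt-allele frequencies of one sample, with a histogram bin width."""

    frequencies: np.ndarray
    bin_width: float = 0.01

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.size and (np.nanmin(f) < 0 or np.nanmax(f) > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        self.frequencies = f

    @property
    def n_sites(self) -> int:
        return self.frequencies.size

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        edges = np.arange(0.0, 1.0 + self.bin_width, self.bin_width)
        counts, edges = np.histogram(self.frequencies, bins=edges)
        return counts, edges


@dataclasses.dataclass
class RatioEstimate:
    """Mixture-MLE result: major-nucleotype share, karyotype call and modes."""

    ratio_r: float
    log_likelihood: float
    karyotype: str  # "monokaryon" | "dikaryon"
    modes: list[float]

    @property
    def minor_share(self) -> float:
        return 1.0 - self.ratio_r


def af_spectrum(table: VariantTable, sample: str, bin_width: float = 0.01) -> AfSpectrum:
    """Per-site alt frequencies ``AO/(RO+AO)``; sites without allele reads are skipped."""
    f = table.alt_frequencies(sample)
    return AfSpectrum(frequencies=f[~np.isnan(f)], bin_width=bin_width)


def detect_modes(
    spectrum: AfSpectrum,
    smoothing_bandwidth: float = 0.02,
    min_prominence: float = 0.10,
) -> list[float]:
    """Modes of the Gaussian-kernel-smoothed spectrum, in percent, ascending.

    The spectrum is smoothed with a fixed-bandwidth Gaussian kernel on a
    0.1%-resolution grid; local maxima whose prominence exceeds
    ``min_prominence`` times the peak density are reported.
    """
    f = spectrum.frequencies
    if f.size < 2:
        raise ValueError("need at least 2 frequencies to detect modes")
    grid = np.arange(0.0, 1.0 + 1e-9, 0.001)
    h = smoothing_bandwidth
    density = np.exp(-0.5 * ((grid[:, None] - f[None, :]) / h) ** 2).sum(axis=1)
    peaks, _ = signal.find_peaks(density, prominence=min_prominence * density.max())
    return sorted(float(100.0 * grid[p]) for p in peaks)


def _mixture_loglik(r: np.ndarray, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Sum over sites of log[ 0.5*Binom(k; n, r) + 0.5*Binom(k; n, 1-r) ]."""
    r = np.atleast_1d(np.clip(r, 1e-9, 1 - 1e-9))
    la = stats.binom.logpmf(k[:, None], n[:, None], r[None, :])
    lb = stats.binom.logpmf(k[:, None], n[:, None], 1.0 - r[None, :])
    return (np.logaddexp(la, lb) + np.log(0.5)).sum(axis=0)


def estimate_ratio_mle(
    table: VariantTable,
    sample: str,
    min_sites: int = 50,
    monokaryon_threshold: float = MONOKARYON_THRESHOLD,
) -> RatioEstimate:
    """Maximum-likelihood nucleotype ratio from one sample's allele counts.

    The major-nucleotype share r is maximized over [0.5, 1] on a 0.001 grid
    followed by local refinement.  A maximizing r at or above
    ``monokaryon_threshold`` is called a monokaryon (residual low-frequency
    variants keep real monokaryons just short of r = 1).
    """
    c = table.sample_counts(sample)
    use = ~c.missing & ((c.ro + c.ao) > 0)
    n = (c.ro + c.ao)[use].astype(np.int64)
    k = c.ao[use].astype(np.int64)
    if n.size < min_sites:
        raise ValueError(f"need at least {min_sites} sites with allele reads, got {n.size}")
    if np.all((k == 0) | (k == n)):
        ll = float(_mixture_loglik(np.array([1.0]), k, n)[0])
        return RatioEstimate(ratio_r=1.0, log_likelihood=ll, karyotype="monokaryon", modes=[])
    grid = np.arange(0.5, 1.0 + 1e-12, 0.001)
    ll_grid = _mixture_loglik(grid, k, n)
    best = grid[int(np.argmax(ll_grid))]
    lo, hi = max(0.5, best - 0.002), min(1.0, best + 0.002)
    res = optimize.minimize_scalar(
        lambda r: -float(_mixture_loglik(np.array([r]), k, n)[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    r_hat = float(res.x)
    ll = -float(res.fun)
    karyotype = "monokaryon" if r_hat >= monokaryon_threshold else "dikaryon"
    freqs = k / n
    modes = (
        detect_modes(AfSpectrum(freqs)) if freqs.size >= 100 else []
    )
    return RatioEstimate(ratio_r=r_hat, log_likelihood=ll, karyotype=karyotype, modes=modes)


def mat_coverage_ratio(depth_mat1: float, depth_mat2: float) -> tuple[float, float]:
    """Nucleotype proportions from mean per-base depth over the two MAT loci."""
    if depth_mat1 < 0 or depth_mat2 < 0:
        raise ValueError("depths must be non-negative")
    total = depth_mat1 + depth_mat2
    if total == 0:
        raise ValueError("both MAT locus depths are zero")
    return (depth_mat1 / total, depth_mat2 / total)


@dataclasses.dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance: np.ndarray
    n_shared_sites: int


def pca_shared_snps(
    tables: Mapping[str, VariantTable],
    n_components: int = 2,
) -> PcaResult:
    """PCA of samples on alt-allele frequencies at sites covered in all samples.

    Columns (sites) are centered and scaled to unit variance; zero-variance
    columns are dropped beforehand.
    """
    if len(tables) < 3:
        raise ValueError("need at least 3 samples for PCA")
    names = list(tables)
    shared: pd.MultiIndex | None = None
    for t in tables.values():
        idx = t.site_index()
        shared = idx if shared is None else shared.intersection(idx, sort=False)
    assert shared is not None
    rows = []
    covered_all: np.ndarray | None = None
    for name in names:
        t = tables[name]
        order = t.site_index().get_indexer(shared)
        f = t.alt_frequencies(t.samples[0])[order]
        rows.append(f)
        cov = ~np.isnan(f)
        covered_all = cov if covered_all is None else (covered_all & cov)
    if shared.size == 0 or covered_all is None or not covered_all.any():
        raise ValueError("no sites shared and covered across all samples")
    X = np.vstack(rows)[:, covered_all]
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if X.shape[1] == 0:
        raise ValueError("all shared sites have zero variance across samples")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    n_comp = min(n_components, len(names), X.shape[1])
    pca = PCA(n_components=n_comp)
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords, index=names, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    return PcaResult(
        coordinates=frame,
        explained_variance=pca.explained_variance_ratio_,
        n_shared_sites=int(covered_all.sum()),
    )
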