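"""Synthetic dikaryon genomes, nuclear populations and read-count data.

The generator emulates the statistical structure the downstream analysis
assumes for a dikaryote-like AM fungus:

* two nucleotypes (haploid nuclear genotypes) distinguished by their MAT
  locus, mixed at ratio ``r`` in a common cytoplasm;
* biallelic SNPs each carried by exactly one nucleotype, plus a minority of
  low-frequency variants carried by a sub-fraction of one nucleotype's
  nuclei;
* recombination tracts implanted in individual nuclei, swapping a run of
  consecutive SNPs to the opposite nucleotype's consensus — the ground truth
  the block caller must recover;
* read counts sampled binomially at configurable depth for a pooled DNA
  sample, single amplified nuclei (with dropout and cross-nucleus
  contamination) and per-host RNA (with nucleotype-specific expression
  weights);
* repeat-masked regions and a small set of mutually distinct 45S rDNA
  copies.

Counts are generated directly; no read-level FASTQ simulation, mapping or
assembly is modelled.  All generators are deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .vcf_io import GenomicIntervals, VariantTable, SITE_COLUMNS

MAT1 = "MAT-1"
MAT2 = "MAT-2"
LOW_FREQUENCY = "low_frequency"

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass(frozen=True)
class SnpSite:
    """One biallelic locus and, for synthetic data, its true carrier."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    in_repeat: bool = False
    alt_carrier: str = MAT2
    low_freq_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if (self.low_freq_fraction > 0) != (self.alt_carrier == LOW_FREQUENCY):
            raise ValueError("low_freq_fraction > 0 iff alt_carrier is low_frequency")


@dataclasses.dataclass(frozen=True)
class NucleotypeModel:
    """Two-nucleotype mixture: nuclear ratio, sequencing error and depth law.

    ``ratio_r`` is the proportion of MAT-1 nuclei.  Depth is drawn from a
    negative binomial with mean ``mean_depth`` and variance
    ``mean_depth + depth_dispersion * mean_depth**2`` (pure Poisson at
    dispersion 0).
    """

    ratio_r: float
    error_rate: float = 0.0
    mean_depth: float = 110.0
    depth_dispersion: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_r <= 1.0:
            raise ValueError("ratio_r must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.mean_depth <= 0 or self.depth_dispersion < 0:
            raise ValueError("mean_depth > 0 and depth_dispersion >= 0 required")

    def draw_depths(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.depth_dispersion == 0:
            return rng.poisson(self.mean_depth, size=n)
        shape = 1.0 / self.depth_dispersion
        lam = rng.gamma(shape, self.mean_depth / shape, size=n)
        return rng.poisson(lam)


@dataclasses.dataclass
class GenomeModel:
    """A simulated assembly: contigs, repeat annotation, SNP sites, rDNA copies."""

    contigs: list[tuple[str, int]]
    repeat_intervals: GenomicIntervals
    sites: list[SnpSite]
    rdna_copies: list[tuple[str, str]]

    def __post_init__(self) -> None:
        lengths = dict(self.contigs)
        last: dict[str, int] = {}
        for s in self.sites:
            if not 1 <= s.pos <= lengths[s.contig]:
                raise ValueError(f"site {s.contig}:{s.pos} outside contig")
            if s.pos <= last.get(s.contig, 0):
                raise ValueError(f"sites on {s.contig} not strictly increasing")
            last[s.contig] = s.pos
        if self.rdna_copies:
            n = len(self.rdna_copies[0][1])
            if any(len(seq) != n for _, seq in self.rdna_copies):
                raise ValueError("rDNA copies must have equal length")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.contigs)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.contig, s.pos, s.ref, s.alt, s.in_repeat, s.alt_carrier, s.low_freq_fraction)
                for s in self.sites
            ],
            columns=SITE_COLUMNS + ["in_repeat", "alt_carrier", "low_freq_fraction"],
        )

    def contig_lengths(self) -> dict[str, int]:
        return dict(self.contigs)


@dataclasses.dataclass(frozen=True)
class RecombinedTract:
    """Ground truth for one implanted recombination tract.

    Site indices are 0-based positions in the contig's ordered SNP list,
    inclusive at both ends.
    """

    nucleus_id: str
    contig: str
    first_site_index: int
    last_site_index: int


@dataclasses.dataclass
class NucleusPopulation:
    """Haploid nuclei with per-site allele vectors over a genome's SNP list."""

    genome: GenomeModel
    nucleus_ids: list[str]
    mats: list[str]
    alleles: np.ndarray  # (n_nuclei, n_sites) of {0: ref, 1: alt}
    recombined_tracts: list[RecombinedTract]

    def __post_init__(self) -> None:
        n, m = len(self.nucleus_ids), self.genome.n_sites
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (n, m):
            raise ValueError("allele matrix shape mismatch")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("allele vectors must be 0 (ref) or 1 (alt)")

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_ids)

    def mat_labels(self) -> dict[str, str]:
        return dict(zip(self.nucleus_ids, self.mats))

    def mat_mask(self, mat: str) -> np.ndarray:
        return np.array([m == mat for m in self.mats])

    def alt_nucleus_counts(self) -> np.ndarray:
        """Number of nuclei carrying the alternate allele, per site."""
        return self.alleles.sum(axis=0)


# ----------------------------------------------------------------------
# genome
# ----------------------------------------------------------------------


def make_genome(
    n_contigs: int,
    contig_length: int,
    snp_per_kb: float,
    repeat_fraction: float = 0.0,
    low_freq_site_fraction: float = 0.0,
    seed: int = 0,
    *,
    alt_mat1_prob: float = 0.5,
    low_freq_range: tuple[float, float] = (0.10, 0.25),
    repeat_window: int = 2000,
    n_rdna_copies: int = 8,
    rdna_length: int = 600,
) -> GenomeModel:
    """Generate a synthetic assembly with SNPs, repeats and rDNA copies.

    Per-contig SNP counts are Poisson with mean
    ``contig_length * snp_per_kb / 1000``; repeat annotation is built by
    marking fixed windows as repetitive with probability ``repeat_fraction``
    (so the expected masked fraction equals ``repeat_fraction``).  Non-low-
    frequency sites assign their alternate allele to MAT-1 with probability
    ``alt_mat1_prob`` and to MAT-2 otherwise; low-frequency sites draw their
    carrier sub-fraction uniformly from ``low_freq_range``.
    """
    if n_contigs <= 0 or contig_length <= 0:
        raise ValueError("n_contigs and contig_length must be positive")
    if snp_per_kb <= 0:
        raise ValueError("snp_per_kb must be positive")
    for name, val in [
        ("repeat_fraction", repeat_fraction),
        ("low_freq_site_fraction", low_freq_site_fraction),
    ]:
        if not 0.0 <= val < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    width = len(str(n_contigs))
    contigs = [(f"contig_{i + 1:0{width}d}", contig_length) for i in range(n_contigs)]

    repeats: dict[str, list[tuple[int, int]]] = {}
    if repeat_fraction > 0:
        for cname, clen in contigs:
            starts = np.arange(0, clen, repeat_window)
            marked = rng.random(len(starts)) < repeat_fraction
            repeats[cname] = [
                (int(s), int(min(s + repeat_window, clen))) for s in starts[marked]
            ]
    intervals = GenomicIntervals(repeats)

    sites: list[SnpSite] = []
    mean_snps = contig_length * snp_per_kb / 1000.0
    for cname, clen in contigs:
        n_snps = min(int(rng.poisson(mean_snps)), clen)
        positions = np.sort(rng.choice(clen, size=n_snps, replace=False)) + 1
        in_rep = intervals.contains(cname, positions) if n_snps else np.array([], bool)
        ref_idx = rng.integers(0, 4, size=n_snps)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
        is_lf = rng.random(n_snps) < low_freq_site_fraction
        on_mat1 = rng.random(n_snps) < alt_mat1_prob
        lf_frac = rng.uniform(*low_freq_range, size=n_snps)
        for k in range(n_snps):
            if is_lf[k]:
                carrier, frac = LOW_FREQUENCY, float(lf_frac[k])
            else:
                carrier, frac = (MAT1 if on_mat1[k] else MAT2), 0.0
            sites.append(
                SnpSite(
                    contig=cname,
                    pos=int(positions[k]),
                    ref=str(_BASES[ref_idx[k]]),
                    alt=str(_BASES[alt_idx[k]]),
                    in_repeat=bool(in_rep[k]),
                    alt_carrier=carrier,
                    low_freq_fraction=frac,
                )
            )

    base = rng.choice(_BASES, size=rdna_length)
    rdna: list[tuple[str, str]] = []
    for i in range(n_rdna_copies):
        copy = base.copy()
        # copy i differs from the base at exactly i positions, so no two
        # copies are identical (distinct mutation-set sizes)
        if i > 0:
            mut_pos = rng.choice(rdna_length, size=i, replace=False)
            shift = rng.integers(1, 4, size=i)
            idx = np.searchsorted(_BASES, copy[mut_pos])
            copy[mut_pos] = _BASES[(idx + shift) % 4]
        rdna.append((f"rdna_copy_{i + 1}", "".join(copy)))

    return GenomeModel(contigs=contigs, repeat_intervals=intervals, sites=sites, rdna_copies=rdna)


# ----------------------------------------------------------------------
# nuclear population
# ----------------------------------------------------------------------


def mat_consensus(genome: GenomeModel, mat: str) -> np.ndarray:
    """The consensus allele vector (0 ref / 1 alt) of one nucleotype."""
    return np.array(
        [1 if s.alt_carrier == mat else 0 for s in genome.sites], dtype=np.int8
    )


def make_nucleus_population(
    genome: GenomeModel,
    model: NucleotypeModel,
    n_nuclei: int,
    n_recomb_tracts: int = 0,
    tract_len_snps: int = 5,
    seed: int = 0,
) -> NucleusPopulation:
    """Assemble a nuclear population with optional implanted recombination tracts.

    ``floor(ratio_r * n_nuclei)`` nuclei are MAT-1, the remainder MAT-2; each
    nucleus carries its nucleotype's consensus allele at every site, except
    that low-frequency sites assign their alternate allele to a random
    sub-fraction of one nucleotype's nuclei, and each recombination tract
    swaps ``tract_len_snps`` consecutive sites in one randomly chosen nucleus
    to the opposite consensus.  Tracts on the same contig are kept separated
    by at least one unswapped site so ground-truth boundaries stay distinct.
    """
    if n_nuclei < 2:
        raise ValueError("n_nuclei must be >= 2")
    if tract_len_snps < 1:
        raise ValueError("tract_len_snps must be >= 1")
    rng = np.random.default_rng(seed)
    n_mat1 = math.floor(model.ratio_r * n_nuclei)
    mats = [MAT1] * n_mat1 + [MAT2] * (n_nuclei - n_mat1)
    width = max(2, len(str(n_nuclei)))
    ids = [f"Nuc{i + 1:0{width}d}" for i in range(n_nuclei)]

    cons = {MAT1: mat_consensus(genome, MAT1), MAT2: mat_consensus(genome, MAT2)}
    alleles = np.vstack([cons[m] for m in mats]) if n_nuclei else np.empty((0, 0), np.int8)

    site_frame = genome.site_frame()
    for gidx, s in enumerate(genome.sites):
        if s.alt_carrier != LOW_FREQUENCY:
            continue
        mat = MAT1 if rng.random() < 0.5 else MAT2
        members = np.flatnonzero([m == mat for m in mats])
        if len(members) == 0:
            members = np.arange(n_nuclei)
        k = int(round(s.low_freq_fraction * len(members)))
        if k > 0:
            chosen = rng.choice(members, size=k, replace=False)
            alleles[chosen, gidx] = 1

    # contig -> global indices of its sites, in order
    contig_sites = {
        c: grp.index.to_numpy() for c, grp in site_frame.groupby("contig", sort=False)
    }
    eligible = [c for c, idx in contig_sites.items() if len(idx) >= tract_len_snps]
    if n_recomb_tracts > 0 and not eligible:
        raise ValueError("tract_len_snps exceeds every contig's SNP count")

    tracts: list[RecombinedTract] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for _ in range(n_recomb_tracts):
        for _attempt in range(1000):
            contig = eligible[rng.integers(len(eligible))]
            n_c = len(contig_sites[contig])
            start = int(rng.integers(0, n_c - tract_len_snps + 1))
            end = start + tract_len_snps - 1
            if all(
                end < s0 - 1 or start > e0 + 1 for s0, e0 in occupied.get(contig, [])
            ):
                break
        else:
            raise ValueError("could not place non-overlapping recombination tracts")
        occupied.setdefault(contig, []).append((start, end))
        nuc = int(rng.integers(n_nuclei))
        other = MAT2 if mats[nuc] == MAT1 else MAT1
        gsel = contig_sites[contig][start : end + 1]
        alleles[nuc, gsel] = cons[other][gsel]
        tracts.append(RecombinedTract(ids[nuc], contig, start, end))

    return NucleusPopulation(
        genome=genome, nucleus_ids=ids, mats=mats, alleles=alleles, recombined_tracts=tracts
    )


# ----------------------------------------------------------------------
# read-count simulation
# ----------------------------------------------------------------------


def _draw_counts(
    p_alt_true: np.ndarray,
    depths: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(RO, AO) per site given the true alt read probability and depths.

    A read reports its source allele unless it errors (probability
    ``error_rate``), in which case it reports one of the three other bases
    uniformly; errors landing on neither allele leave RO + AO < DP.
    """
    e = error_rate
    p_alt = p_alt_true * (1 - e) + (1 - p_alt_true) * (e / 3)
    p_ref = (1 - p_alt_true) * (1 - e) + p_alt_true * (e / 3)
    ao = rng.binomial(depths, p_alt)
    rest = depths - ao
    with np.errstate(invalid="ignore", divide="ignore"):
        p_ref_given_rest = np.where(p_alt < 1, p_ref / (1 - p_alt), 0.0)
    ro = rng.binomial(rest, np.clip(p_ref_given_rest, 0.0, 1.0))
    return ro, ao


def simulate_pool_counts(
    population: NucleusPopulation,
    model: NucleotypeModel,
    seed: int = 0,
    sample_name: str = "pool",
) -> VariantTable:
    """Pooled ("meta-genome") DNA read counts over all sites.

    Each read draws its source nucleus uniformly at random, so the true
    alt-read probability at a site is the fraction of nuclei carrying the
    alternate allele.
    """
    if population.n_nuclei == 0:
        raise ValueError("population is empty")
    rng = np.random.default_rng(seed)
    n_sites = population.genome.n_sites
    p_alt = population.alt_nucleus_counts() / population.n_nuclei
    depths = model.draw_depths(n_sites, rng)
    ro, ao = _draw_counts(p_alt, depths, model.error_rate, rng)
    sites = population.genome.site_frame()[SITE_COLUMNS]
    return VariantTable.from_counts(sites, {sample_name: (depths, ro, ao)})


def simulate_nucleus_counts(
    population: NucleusPopulation,
    model: NucleotypeModel,
    contamination_rate: float = 0.0,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> VariantTable:
    """Single-nucleus (WGA-style) read counts, one sample column per nucleus.

    Amplification artefacts are modelled as (a) per-nucleus dropout: a
    ``dropout_rate`` fraction of sites gets depth 0 and is recorded missing,
    and (b) contamination: a read reports a uniformly chosen *other* nucleus's
    allele with probability ``contamination_rate``.
    """
    for name, val in [("contamination_rate", contamination_rate), ("dropout_rate", dropout_rate)]:
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genome = population.genome
    n_sites, n_nuclei = genome.n_sites, population.n_nuclei
    alt_counts = population.alt_nucleus_counts()
    counts: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    missing: dict[str, np.ndarray] = {}
    for i, nucleus in enumerate(population.nucleus_ids):
        focal = population.alleles[i].astype(float)
        if n_nuclei > 1:
            other_mean = (alt_counts - population.alleles[i]) / (n_nuclei - 1)
        else:
            other_mean = focal
        p_alt = (1 - contamination_rate) * focal + contamination_rate * other_mean
        depths = model.draw_depths(n_sites, rng)
        n_drop = int(round(dropout_rate * n_sites))
        if n_drop > 0:
            dropped = rng.choice(n_sites, size=n_drop, replace=False)
            depths[dropped] = 0
        ro, ao = _draw_counts(p_alt, depths, model.error_rate, rng)
        counts[nucleus] = (depths, ro, ao)
        missing[nucleus] = depths == 0
    sites = genome.site_frame()[SITE_COLUMNS]
    return VariantTable.from_counts(sites, counts, missing=missing)


def simulate_rna_counts(
    population: NucleusPopulation,
    model: NucleotypeModel,
    host_weights: Mapping[str, tuple[float, float]],
    expressed_fraction: float = 0.8,
    n_replicates: int = 3,
    seed: int = 0,
) -> dict[str, list[VariantTable]]:
    """Per-host RNA read counts with nucleotype-specific expression weights.

    For host ``h`` with weights ``(w1, w2)``, a read's source nucleotype is
    MAT-1 with probability ``n1*w1 / (n1*w1 + n2*w2)`` where ``n1, n2`` count
    the nuclei of each type.  Each host expresses a random
    ``expressed_fraction`` subset of non-repeat sites, reused across its
    replicates.
    """
    if not 0.0 < expressed_fraction <= 1.0:
        raise ValueError("expressed_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    genome = population.genome
    site_frame = genome.site_frame()
    non_repeat = np.flatnonzero(~site_frame["in_repeat"].to_numpy())
    n1 = int(population.mat_mask(MAT1).sum())
    n2 = population.n_nuclei - n1
    m1 = population.mat_mask(MAT1)
    alt_share = {
        MAT1: population.alleles[m1].mean(axis=0) if n1 else np.zeros(genome.n_sites),
        MAT2: population.alleles[~m1].mean(axis=0) if n2 else np.zeros(genome.n_sites),
    }
    out: dict[str, list[VariantTable]] = {}
    for host, (w1, w2) in host_weights.items():
        if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
            raise ValueError(f"host {host!r}: weights must be non-negative, not both zero")
        total = n1 * w1 + n2 * w2
        if total == 0:
            raise ValueError(f"host {host!r}: no expressing nucleotype")
        p_mat1 = n1 * w1 / total
        n_expr = int(round(expressed_fraction * len(non_repeat)))
        expressed = np.sort(rng.choice(non_repeat, size=n_expr, replace=False))
        p_alt = p_mat1 * alt_share[MAT1][expressed] + (1 - p_mat1) * alt_share[MAT2][expressed]
        sites = site_frame.loc[expressed, SITE_COLUMNS].reset_index(drop=True)
        reps: list[VariantTable] = []
        for j in range(n_replicates):
            depths = model.draw_depths(len(expressed), rng)
            ro, ao = _draw_counts(p_alt, depths, model.error_rate, rng)
            reps.append(
                VariantTable.from_counts(sites, {f"{host}_rep{j + 1}": (depths, ro, ao)})
            )
        out[host] = reps
    return out


# ----------------------------------------------------------------------
# spore bottleneck drift
# ----------------------------------------------------------------------


def spore_bottleneck(
    ratio_r: float,
    n_nuclei_per_spore: int,
    n_generations: int,
    n_lineages: int,
    mixing_rate: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Nucleotype-ratio drift across spore generations.

    Each generation every lineage samples ``n_nuclei_per_spore`` nuclei
    binomially at its current ratio (the spore bottleneck); with mixing rate
    ``m`` the post-sampling ratio is pulled toward the across-lineage mean
    ratio, emulating nuclear exchange through hyphal fusion:
    ``r' = (1 - m) * sampled + m * mean(sampled)``.

    Returns an array of shape ``(n_lineages, n_generations + 1)`` whose first
    column is the founding ratio.
    """
    if not 0.0 <= ratio_r <= 1.0:
        raise ValueError("ratio_r must lie in [0, 1]")
    if n_nuclei_per_spore < 1:
        raise ValueError("n_nuclei_per_spore must be >= 1")
    if not 0.0 <= mixing_rate <= 1.0:
        raise ValueError("mixing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    traj = np.empty((n_lineages, n_generations + 1))
    current = np.full(n_lineages, float(ratio_r))
    traj[:, 0] = current
    for g in range(1, n_generations + 1):
        sampled = rng.binomial(n_nuclei_per_spore, current) / n_nuclei_per_spore
        if mixing_rate > 0:
            sampled = (1 - mixing_rate) * sampled + mixing_rate * sampled.mean()
        current = sampled
        traj[:, g] = current
    return traj


# ----------------------------------------------------------------------
# on-disk dataset
# ----------------------------------------------------------------------


def write_rdna_fasta(genome: GenomeModel, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.rdna_copies
    ]
    SeqIO.write(records, path, "fasta")


def read_rdna_fasta(path: str) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def _tract_pos(genome: GenomeModel, tract: RecombinedTract, local_index: int) -> int:
    contig_positions = [s.pos for s in genome.sites if s.contig == tract.contig]
    return contig_positions[local_index]


def write_ground_truth(
    path: str,
    population: NucleusPopulation,
    model: NucleotypeModel,
    host_weights: Mapping[str, tuple[float, float]] | None = None,
) -> None:
    """JSON sidecar recording everything a test harness needs to score against."""
    truth = {
        "ratio_r": model.ratio_r,
        "error_rate": model.error_rate,
        "mean_depth": model.mean_depth,
        "depth_dispersion": model.depth_dispersion,
        "n_nuclei": population.n_nuclei,
        "mat_labels": population.mat_labels(),
        "recombined_tracts": [
            {
                **dataclasses.asdict(t),
                "first_pos": int(_tract_pos(population.genome, t, t.first_site_index)),
                "last_pos": int(_tract_pos(population.genome, t, t.last_site_index)),
            }
            for t in population.recombined_tracts
        ],
        "host_weights": {h: list(w) for h, w in (host_weights or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
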