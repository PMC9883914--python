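"""Read and write the VCF/BED/TSV dialects the pipeline touches.

All variant data moves through :class:`VariantTable`, an in-memory table of
biallelic SNP sites with per-sample read-count triples in the freebayes
FORMAT dialect:

* ``DP`` — total read depth at the site,
* ``RO`` — reads supporting the reference allele,
* ``AO`` — reads supporting the alternate allele.

Missing sample data (uncovered sites, dropped-out nuclei) is represented
explicitly and excluded from denominators downstream — it is never imputed
as zero.  Coordinates follow the usual conventions: VCF positions are
1-based, BED intervals half-open 0-based.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

SITE_COLUMNS = ["contig", "pos", "ref", "alt"]

REQUIRED_FORMAT_FIELDS = ("DP", "RO", "AO")


class VcfFormatError(ValueError):
    """Raised when an input VCF/BED file violates the expected dialect."""


@dataclasses.dataclass
class SampleCounts:
    """Count vectors for one sample, aligned with a site list."""

    dp: np.ndarray
    ro: np.ndarray
    ao: np.ndarray
    missing: np.ndarray  # bool; True where the sample has no data at the site

    @property
    def covered(self) -> np.ndarray:
        return ~self.missing


@dataclasses.dataclass
class VariantTable:
    """Biallelic SNP sites with per-(site, sample) allele counts.

    Parameters
    ----------
    sites
        DataFrame with columns ``contig, pos, ref, alt``; unique keys,
        sorted by (contig, pos).
    samples
        Ordered sample names.
    dp, ro, ao
        Integer arrays of shape ``(n_sites, n_samples)``.
    missing
        Boolean array marking absent sample data; counts there are ignored.
    """

    sites: pd.DataFrame
    samples: list[str]
    dp: np.ndarray
    ro: np.ndarray
    ao: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        n, m = len(self.sites), len(self.samples)
        for name in ("dp", "ro", "ao", "missing"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n, m):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n, m)}"
                )
            setattr(self, name, arr)
        if len(set(self.samples)) != m:
            raise ValueError("duplicate sample names")
        valid = ~self.missing
        if np.any((self.ro[valid] + self.ao[valid]) > self.dp[valid]):
            raise ValueError("RO + AO exceeds DP")

    # -- basic views --------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.sites[SITE_COLUMNS])

    def sample_counts(self, sample: str) -> SampleCounts:
        j = self._sample_pos(sample)
        return SampleCounts(
            dp=self.dp[:, j],
            ro=self.ro[:, j],
            ao=self.ao[:, j],
            missing=self.missing[:, j],
        )

    def _sample_pos(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in table") from None

    def subset_sites(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            dp=self.dp[mask],
            ro=self.ro[mask],
            ao=self.ao[mask],
            missing=self.missing[mask],
        )

    def alt_frequencies(self, sample: str) -> np.ndarray:
        """AO/(RO+AO) for covered sites with at least one allele read (NaN elsewhere)."""
        c = self.sample_counts(sample)
        tot = (c.ro + c.ao).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(c.missing | (tot == 0), np.nan, c.ao / np.where(tot == 0, 1, tot))
        return f

    @staticmethod
    def from_counts(
        sites: pd.DataFrame,
        counts: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        missing: Mapping[str, np.ndarray] | None = None,
    ) -> "VariantTable":
        """Assemble a table from per-sample ``(dp, ro, ao)`` triples."""
        samples = list(counts)
        n = len(sites)
        dp = np.zeros((n, len(samples)), dtype=np.int64)
        ro = np.zeros_like(dp)
        ao = np.zeros_like(dp)
        miss = np.zeros((n, len(samples)), dtype=bool)
        for j, s in enumerate(samples):
            dp[:, j], ro[:, j], ao[:, j] = (np.asarray(a) for a in counts[s])
            if missing is not None and s in missing:
                miss[:, j] = np.asarray(missing[s], dtype=bool)
        return VariantTable(sites=sites.copy(), samples=samples, dp=dp, ro=ro, ao=ao, missing=miss)


# ----------------------------------------------------------------------
# interval sets (BED)
# ----------------------------------------------------------------------


class GenomicIntervals:
    """Merged half-open 0-based intervals keyed by contig."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if intervals:
            for contig, ivs in intervals.items():
                self._data[contig] = _merge(ivs)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._data)

    def intervals(self, contig: str) -> np.ndarray:
        return self._data.get(contig, np.empty((0, 2), dtype=np.int64))

    def total_length(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self._data.values()))

    def is_empty(self) -> bool:
        return self.total_length() == 0

    def contains(self, contig: str, pos: int | np.ndarray) -> np.ndarray | bool:
        """Membership of 1-based position(s): pos p is inside [s, e) iff s <= p-1 < e."""
        iv = self.intervals(contig)
        p0 = np.asarray(pos) - 1
        if iv.shape[0] == 0:
            out = np.zeros(p0.shape, dtype=bool)
            return bool(out) if out.shape == () else out
        idx = np.searchsorted(iv[:, 0], p0, side="right") - 1
        inside = (idx >= 0) & (p0 < iv[np.clip(idx, 0, None), 1])
        return bool(inside) if inside.shape == () else inside

    def mask_sites(self, sites: pd.DataFrame) -> np.ndarray:
        """Boolean mask over a site frame: True where the site falls in an interval."""
        out = np.zeros(len(sites), dtype=bool)
        for contig, group in sites.groupby("contig", sort=False):
            out[group.index.to_numpy()] = self.contains(contig, group["pos"].to_numpy())
        return out


def _merge(ivs: Iterable[tuple[int, int]]) -> np.ndarray:
    arr = sorted((int(s), int(e)) for s, e in ivs)
    merged: list[list[int]] = []
    for s, e in arr:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged or np.empty((0, 2)), dtype=np.int64).reshape(-1, 2)


def read_repeat_bed(path: str) -> GenomicIntervals:
    """Read a 3+-column BED file of repeat intervals; overlaps are merged."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise VcfFormatError(f"{path}:{lineno}: BED line has <3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise VcfFormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            raw.setdefault(contig, []).append((start, end))
    return GenomicIntervals(raw)


def write_repeat_bed(intervals: GenomicIntervals, path: str) -> None:
    with open(path, "w") as fh:
        for contig in intervals.contigs:
            for s, e in intervals.intervals(contig):
                fh.write(f"{contig}\t{s}\t{e}\n")


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------


def read_vcf(path: str, required_fields: Sequence[str] = REQUIRED_FORMAT_FIELDS) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Multiallelic records and non-SNP variants are excluded (the pipeline only
    ever considers biallelic SNPs).  Samples with missing FORMAT values at a
    site are recorded as missing, not zero.

    Raises
    ------
    VcfFormatError
        If a required FORMAT field is absent from the header, or the file is
        not coordinate-sorted.
    """
    vf = pysam.VariantFile(path)
    for field in required_fields:
        if field not in vf.header.formats:
            raise VcfFormatError(f"required FORMAT field {field!r} missing from {path}")
    samples = list(vf.header.samples)
    recs: list[tuple[str, int, str, str]] = []
    cols: list[list[tuple[int, int, int, bool]]] = []
    seen_contigs: list[str] = []
    last_pos = -1
    for rec in vf:
        if not seen_contigs or rec.contig != seen_contigs[-1]:
            if rec.contig in seen_contigs:
                raise VcfFormatError(f"{path}: unsorted input (contig {rec.contig} revisited)")
            seen_contigs.append(rec.contig)
            last_pos = -1
        if rec.pos <= last_pos:
            raise VcfFormatError(
                f"{path}: unsorted input at {rec.contig}:{rec.pos}"
            )
        last_pos = rec.pos
        if rec.alts is None or len(rec.alts) != 1:
            continue  # multiallelic or ALT-less records are excluded
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            continue  # indels / symbolic alleles
        recs.append((rec.contig, rec.pos, ref, alt))
        row = []
        for s in samples:
            sd = rec.samples[s]
            dp = sd.get("DP")
            ro = sd.get("RO")
            ao = sd.get("AO")
            if isinstance(ao, tuple):
                ao = ao[0]
            if dp is None or ro is None or ao is None:
                row.append((0, 0, 0, True))
            else:
                row.append((int(dp), int(ro), int(ao), False))
        cols.append(row)
    vf.close()
    sites = pd.DataFrame(recs, columns=SITE_COLUMNS)
    n, m = len(sites), len(samples)
    dp = np.zeros((n, m), dtype=np.int64)
    ro = np.zeros_like(dp)
    ao = np.zeros_like(dp)
    missing = np.zeros((n, m), dtype=bool)
    for i, row in enumerate(cols):
        for j, (d, r, a, mi) in enumerate(row):
            dp[i, j], ro[i, j], ao[i, j], missing[i, j] = d, r, a, mi
    return VariantTable(sites=sites, samples=samples, dp=dp, ro=ro, ao=ao, missing=missing)


def write_vcf(
    table: VariantTable,
    path: str,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a VariantTable as VCF v4.2 with per-sample DP:RO:AO."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=heterokaryon",
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">',
        '##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">',
    ]
    contigs = list(dict.fromkeys(table.sites["contig"]))
    for c in contigs:
        if contig_lengths and c in contig_lengths:
            lines.append(f"##contig=<ID={c},length={contig_lengths[c]}>")
        else:
            lines.append(f"##contig=<ID={c}>")
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    if table.samples:
        header += "\t" + "\t".join(table.samples)
    lines.append(header)
    sites = table.sites
    for i in range(table.n_sites):
        fields = [
            str(sites.at[i, "contig"]),
            str(int(sites.at[i, "pos"])),
            ".",
            str(sites.at[i, "ref"]),
            str(sites.at[i, "alt"]),
            ".",
            ".",
            ".",
            "DP:RO:AO",
        ]
        for j in range(table.n_samples):
            if table.missing[i, j]:
                fields.append(".:.:.")
            else:
                fields.append(f"{table.dp[i, j]}:{table.ro[i, j]}:{table.ao[i, j]}")
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def intersect_tables(a: VariantTable, b: VariantTable) -> VariantTable:
    """Restrict two tables to their shared (contig, pos, ref, alt) keys.

    The result carries the sample columns of both inputs, in order.
    """
    dup = set(a.samples) & set(b.samples)
    if dup:
        raise ValueError(f"duplicate sample names across inputs: {sorted(dup)}")
    ia = a.site_index()
    ib = b.site_index()
    shared = ia.intersection(ib, sort=False)
    ma = ia.isin(shared)
    mb = ib.isin(shared)
    sa = a.subset_sites(ma)
    sb = b.subset_sites(mb)
    # align b's rows to a's (sorted) site order
    order = sb.site_index().get_indexer(sa.site_index())
    return VariantTable(
        sites=sa.sites,
        samples=sa.samples + sb.samples,
        dp=np.hstack([sa.dp, sb.dp[order]]),
        ro=np.hstack([sa.ro, sb.ro[order]]),
        ao=np.hstack([sa.ao, sb.ao[order]]),
        missing=np.hstack([sa.missing, sb.missing[order]]),
    )


# ----------------------------------------------------------------------
# sidecar tables
# ----------------------------------------------------------------------


def read_mat_labels(path: str) -> dict[str, str]:
    """Two-column TSV (nucleus_id, MAT identity) -> mapping."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise VcfFormatError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_mat_labels(labels: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for nucleus, mat in labels.items():
            fh.write(f"{nucleus}\t{mat}\n")
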