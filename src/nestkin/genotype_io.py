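"""Readers, writers and the shared data model for clutch genotype data.

The pipeline works on biallelic SNP genotypes coded as alternate-allele
counts {0, 1, 2} with per-genotype read depths, plus three small metadata
tables: sample -> nest, per-nest records (dates, mtDNA haplotype, clutch
metrics) and a haplotype -> origin lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype in :attr:`GenotypeMatrix.genotypes`
MISSING = -1


class VcfFormatError(ValueError):
    """Raised when an input VCF lacks a required field or has no usable records."""


class MetadataError(ValueError):
    """Raised when the metadata tables fail cross-reference validation."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci with allele-count genotypes and read depths.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers (rows).
    locus_ids
        Ordered locus identifiers, ``"chrom:pos"`` with 1-based positions
        (columns).
    genotypes
        ``(n_samples, n_loci)`` int8 array of alternate-allele counts in
        {0, 1, 2}, with :data:`MISSING` (-1) for uncalled genotypes.
    depths
        ``(n_samples, n_loci)`` non-negative int array of read depths.  A
        missing genotype may still carry a depth.
    info
        Free-form provenance notes (e.g. dropped-record counts); not part
        of equality.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    genotypes: np.ndarray
    depths: np.ndarray
    info: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        shape = (len(self.sample_ids), len(self.locus_ids))
        if self.genotypes.shape != shape or self.depths.shape != shape:
            raise ValueError(
                f"genotypes/depths shape mismatch: expected {shape}, got "
                f"{self.genotypes.shape} and {self.depths.shape}"
            )
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotypes must be in {0,1,2} or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            list(sample_ids), list(self.locus_ids),
            self.genotypes[idx], self.depths[idx],
        )

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset columns by boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            list(self.sample_ids), [self.locus_ids[i] for i in keep],
            self.genotypes[:, keep], self.depths[:, keep],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), list(self.locus_ids),
            self.genotypes.copy(), self.depths.copy(), dict(self.info),
        )


@dataclass(frozen=True)
class SampleMetadata:
    """One genotyped hatchling: which nest it came from and its tissue source."""

    sample_id: str
    nest_id: str
    source: str = ""


@dataclass
class NestRecord:
    """Per-nest field record: dates, mtDNA haplotype and clutch metrics."""

    nest_id: str
    year: int
    laying_date: date | None = None
    emergence_date: date | None = None
    haplotype: str | None = None
    clutch_size: int | None = None
    hatching_success: float | None = None
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if (
            self.laying_date is not None
            and self.emergence_date is not None
            and not self.emergence_date > self.laying_date
        ):
            raise MetadataError(
                f"nest {self.nest_id}: emergence date {self.emergence_date} "
                f"not after laying date {self.laying_date}"
            )
        if self.hatching_success is not None and not 0.0 <= self.hatching_success <= 1.0:
            raise MetadataError(
                f"nest {self.nest_id}: hatching_success must be in [0,1]"
            )

    @property
    def incubation_days(self) -> int | None:
        if self.laying_date is None or self.emergence_date is None:
            return None
        return (self.emergence_date - self.laying_date).days


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF with per-genotype GT and DP into a :class:`GenotypeMatrix`.

    Only biallelic records are kept; multi-allelic records are dropped and
    counted in ``matrix.info["n_multiallelic_dropped"]``.  ``./.`` genotypes
    map to :data:`MISSING`; phased and unphased separators are equivalent.

    Raises
    ------
    VcfFormatError
        If the per-sample DP field is absent or no usable record remains.
    """
    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    genotypes: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        try:
            dp = variant.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            raise VcfFormatError(
                f"{path}: per-sample FORMAT field 'DP' is required but absent "
                f"at {variant.CHROM}:{variant.POS}"
            )
        gt = np.asarray(variant.gt_types, dtype=np.int8)  # 0/1/2, 3=missing
        gt[gt == 3] = MISSING
        dp = np.asarray(dp, dtype=np.int64).reshape(-1)
        dp[dp < 0] = 0  # missing DP recorded as zero depth
        genotypes.append(gt)
        depths.append(dp.astype(np.int32))
        locus_ids.append(f"{variant.CHROM}:{variant.POS}")
    if n_multi:
        logger.info("read_vcf: dropped %d multi-allelic records", n_multi)
    if not locus_ids:
        raise VcfFormatError(f"{path}: no biallelic records found")
    matrix = GenotypeMatrix(
        sample_ids,
        locus_ids,
        np.column_stack(genotypes),
        np.column_stack(depths),
    )
    matrix.info["n_multiallelic_dropped"] = n_multi
    return matrix


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=nestkin
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a minimal VCF v4.2 with GT:DP per genotype.

    Output is byte-deterministic (no timestamps), so identical matrices
    produce identical files.  REF/ALT are emitted as placeholder A/C: the
    pipeline's statistics depend only on allele counts, not on the bases.
    """
    contigs = {lid.rsplit(":", 1)[0] for lid in matrix.locus_ids}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in sorted(contigs):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, lid in enumerate(matrix.locus_ids):
            chrom, pos = lid.rsplit(":", 1)
            calls = "\t".join(
                f"{_GT_STR[int(g)]}:{int(d)}"
                for g, d in zip(matrix.genotypes[:, j], matrix.depths[:, j])
            )
            fh.write(f"{chrom}\t{pos}\t.\tA\tC\t.\tPASS\t.\tGT:DP\t{calls}\n")


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.upper() in ("NA", "N/A", "NONE"):
        return None
    return date.fromisoformat(text)


def _parse_optional(value, cast):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.upper() in ("NA", "N/A", "NONE"):
        return None
    return cast(value)


def read_metadata(
    samples_path: str | Path,
    nests_path: str | Path,
    haplotypes_path: str | Path | None = None,
) -> tuple[list[SampleMetadata], dict[str, NestRecord], dict[str, str]]:
    """Read the three tab-separated metadata tables and cross-validate them.

    ``samples_path``: columns ``sample_id  nest_id`` (optional ``source``).
    ``nests_path``: ``nest_id  year  laying_date  emergence_date  haplotype
    clutch_size  hatching_success  lat  lon`` with ISO-8601 dates.
    ``haplotypes_path``: ``haplotype  origin`` with origin in
    {Atlantic, Mediterranean, Shared}.

    Raises :class:`MetadataError` for orphan samples (nest not declared);
    warns and leaves the origin absent for haplotypes missing from the
    lookup table.
    """
    samples_df = pd.read_csv(samples_path, sep="\t", dtype=str)
    nests_df = pd.read_csv(nests_path, sep="\t", dtype=str)

    nests: dict[str, NestRecord] = {}
    for row in nests_df.itertuples(index=False):
        rec = NestRecord(
            nest_id=row.nest_id,
            year=int(row.year),
            laying_date=_parse_date(getattr(row, "laying_date", None)),
            emergence_date=_parse_date(getattr(row, "emergence_date", None)),
            haplotype=_parse_optional(getattr(row, "haplotype", None), str),
            clutch_size=_parse_optional(getattr(row, "clutch_size", None), lambda v: int(float(v))),
            hatching_success=_parse_optional(getattr(row, "hatching_success", None), float),
            lat=_parse_optional(getattr(row, "lat", None), float),
            lon=_parse_optional(getattr(row, "lon", None), float),
        )
        nests[rec.nest_id] = rec

    samples = [
        SampleMetadata(
            sample_id=row.sample_id,
            nest_id=row.nest_id,
            source=str(getattr(row, "source", "") or ""),
        )
        for row in samples_df.itertuples(index=False)
    ]
    orphans = sorted({s.sample_id for s in samples if s.nest_id not in nests})
    if orphans:
        raise MetadataError(
            f"samples reference undeclared nests: {', '.join(orphans)}"
        )

    origins: dict[str, str] = {}
    if haplotypes_path is not None:
        hap_df = pd.read_csv(haplotypes_path, sep="\t", dtype=str)
        origins = dict(zip(hap_df["haplotype"], hap_df["origin"]))
    unknown = sorted(
        {r.haplotype for r in nests.values() if r.haplotype is not None}
        - set(origins)
    )
    if unknown and haplotypes_path is not None:
        logger.warning(
            "haplotypes without an origin entry (origin left absent): %s",
            ", ".join(unknown),
        )
    return samples, nests, origins


def write_metadata(
    samples: list[SampleMetadata],
    nests: dict[str, NestRecord],
    origins: dict[str, str],
    samples_path: str | Path,
    nests_path: str | Path,
    haplotypes_path: str | Path,
) -> None:
    """Write metadata tables in the layout :func:`read_metadata` accepts."""
    pd.DataFrame(
        [(s.sample_id, s.nest_id, s.source) for s in samples],
        columns=["sample_id", "nest_id", "source"],
    ).to_csv(samples_path, sep="\t", index=False)
    rows = []
    for rec in nests.values():
        rows.append(
            (
                rec.nest_id, rec.year,
                rec.laying_date.isoformat() if rec.laying_date else "NA",
                rec.emergence_date.isoformat() if rec.emergence_date else "NA",
                rec.haplotype or "NA",
                rec.clutch_size if rec.clutch_size is not None else "NA",
                rec.hatching_success if rec.hatching_success is not None else "NA",
                rec.lat if rec.lat is not None else "NA",
                rec.lon if rec.lon is not None else "NA",
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "nest_id", "year", "laying_date", "emergence_date", "haplotype",
            "clutch_size", "hatching_success", "lat", "lon",
        ],
    ).to_csv(nests_path, sep="\t", index=False)
    pd.DataFrame(
        sorted(origins.items()), columns=["haplotype", "origin"]
    ).to_csv(haplotypes_path, sep="\t", index=False)


def samples_by_nest(samples: list[SampleMetadata]) -> dict[str, list[str]]:
    """Group sample ids by nest, preserving input order."""
    grouped: dict[str, list[str]] = {}
    for s in samples:
        grouped.setdefault(s.nest_id, []).append(s.sample_id)
    return grouped
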