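"""Genotype- and locus-level SNP filters.

The filtering order is fixed: individual genotypes supported by fewer than
``min_genotype_depth`` reads are first set missing; loci whose mean depth is
strictly above the depth cutoff (a fixed value, or the Tukey upper whisker
Q3 + 1.5*IQR of per-locus mean depths) are then dropped; finally loci called
in less than ``completeness`` of the samples (after the depth masking) are
dropped.  Boundary semantics are strict: depth 5 survives a "less than 5"
cutoff, mean depth 50.1 fails an "above 50" cutoff, and 19/20 = 0.95 called
satisfies a 95% completeness requirement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_genotype_depth: int = 5
    #: numeric cutoff, or the string "whisker" for Q3 + 1.5*IQR of
    #: per-locus mean depths
    max_locus_mean_depth: float | str = 50.0
    completeness: float = 0.95

    def __post_init__(self) -> None:
        if self.min_genotype_depth < 0:
            raise ValueError("min_genotype_depth must be >= 0")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must be in (0, 1]")
        if isinstance(self.max_locus_mean_depth, str):
            if self.max_locus_mean_depth != "whisker":
                raise ValueError(
                    "max_locus_mean_depth must be a number or 'whisker'"
                )


@dataclass
class FilterReport:
    n_loci_input: int
    n_genotypes_masked: int
    n_loci_removed_depth: int
    n_loci_removed_completeness: int
    n_loci_retained: int
    depth_threshold_used: float
    #: per-locus mean depth is taken over all samples with a recorded depth
    mean_depth_convention: str = "all samples with recorded depth"
    quartile_convention: str = "linear interpolation (type 7)"

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


class EmptyFilterResult(ValueError):
    """All loci were removed; the offending report is attached."""

    def __init__(self, report: FilterReport):
        super().__init__("no loci retained after filtering")
        self.report = report


def filter_genotypes_by_depth(
    matrix: GenotypeMatrix, config: FilterConfig
) -> GenotypeMatrix:
    """Set genotypes with depth < ``min_genotype_depth`` to missing."""
    out = matrix.copy()
    if config.min_genotype_depth > 0:
        low = out.depths < config.min_genotype_depth
        out.genotypes[low] = MISSING
    return out


def locus_mean_depth_whisker(matrix: GenotypeMatrix) -> float:
    """Tukey upper whisker Q3 + 1.5*(Q3 - Q1) of the per-locus mean depths.

    Quartiles use linear interpolation between order statistics (the
    ubiquitous "type 7" convention).  Requires at least 4 loci.
    """
    if matrix.n_loci < 4:
        raise ValueError("whisker threshold needs at least 4 loci")
    means = matrix.depths.mean(axis=0)
    q1, q3 = np.percentile(means, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


def filter_loci(
    matrix: GenotypeMatrix, config: FilterConfig, n_genotypes_masked: int = 0
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop high-mean-depth loci, then incomplete loci; report what happened.

    Assumes :func:`filter_genotypes_by_depth` has already been applied so
    that completeness reflects post-masking missingness.
    """
    if isinstance(config.max_locus_mean_depth, str):
        threshold = locus_mean_depth_whisker(matrix)
    else:
        threshold = float(config.max_locus_mean_depth)

    mean_depth = matrix.depths.mean(axis=0)
    keep_depth = mean_depth <= threshold
    n_removed_depth = int((~keep_depth).sum())
    after_depth = matrix.subset_loci(keep_depth)

    called_frac = (after_depth.genotypes != MISSING).mean(axis=0)
    keep_complete = called_frac >= config.completeness
    n_removed_complete = int((~keep_complete).sum())
    out = after_depth.subset_loci(keep_complete)

    report = FilterReport(
        n_loci_input=matrix.n_loci,
        n_genotypes_masked=n_genotypes_masked,
        n_loci_removed_depth=n_removed_depth,
        n_loci_removed_completeness=n_removed_complete,
        n_loci_retained=out.n_loci,
        depth_threshold_used=threshold,
    )
    if out.n_loci == 0:
        raise EmptyFilterResult(report)
    logger.info(
        "filter_loci: %d -> %d loci (depth cutoff %.2f removed %d, "
        "completeness %.2f removed %d)",
        matrix.n_loci, out.n_loci, threshold, n_removed_depth,
        config.completeness, n_removed_complete,
    )
    return out, report


def apply_filters(
    matrix: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Full filter cascade: depth masking, then the two locus filters."""
    config = config or FilterConfig()
    masked = filter_genotypes_by_depth(matrix, config)
    n_masked = int(
        ((masked.genotypes == MISSING) & (matrix.genotypes != MISSING)).sum()
    )
    return filter_loci(masked, config, n_genotypes_masked=n_masked)
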