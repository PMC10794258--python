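"""Per-nest genetic-diversity summaries.

Two relative-diversity measures per nest: the percentage of retained loci
that are polymorphic among the nest's hatchlings (a locus counts as
polymorphic when at least two distinct alleles are observed in the nest's
non-missing genotypes, so a single heterozygote suffices) and the observed
heterozygosity Ho of each hatchling (heterozygous calls / non-missing
calls), averaged per nest.  Aggregate means use the sample SD (n-1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleMetadata, samples_by_nest

logger = logging.getLogger(__name__)


def percent_polymorphic(
    matrix: GenotypeMatrix,
    samples: list[SampleMetadata],
    nest_id: str,
    include_all_missing_loci: bool = True,
) -> float:
    """Percent of loci with >= 2 distinct observed alleles within a nest.

    ``include_all_missing_loci`` keeps loci with no call in the nest in the
    denominator (the default); set False to restrict the denominator to loci
    observed at least once in the nest.
    """
    grouped = samples_by_nest(samples)
    if nest_id not in grouped:
        raise KeyError(f"unknown nest {nest_id!r}")
    idx = [matrix.sample_index(s) for s in grouped[nest_id]]
    g = matrix.genotypes[idx]
    observed = g != MISSING
    has_het = ((g == 1) & observed).any(axis=0)
    has_ref = ((g == 0) & observed).any(axis=0)
    has_alt = ((g == 2) & observed).any(axis=0)
    poly = has_het | (has_ref & has_alt)
    denom = matrix.n_loci if include_all_missing_loci else int(observed.any(axis=0).sum())
    if denom == 0:
        raise ValueError(f"nest {nest_id}: no loci in denominator")
    return 100.0 * float(poly.sum()) / denom


def observed_heterozygosity(matrix: GenotypeMatrix) -> pd.Series:
    """Ho per sample: heterozygous genotypes / non-missing genotypes.

    Samples with zero non-missing genotypes get NaN (and a warning); they
    are excluded from any mean taken downstream.
    """
    called = (matrix.genotypes != MISSING).sum(axis=1)
    het = (matrix.genotypes == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    empty = [s for s, c in zip(matrix.sample_ids, called) if c == 0]
    if empty:
        logger.warning("samples with no called genotypes (Ho absent): %s", empty)
    return pd.Series(ho, index=matrix.sample_ids, name="ho")


def diversity_report(
    matrix: GenotypeMatrix,
    samples: list[SampleMetadata],
    include_all_missing_loci: bool = True,
) -> pd.DataFrame:
    """One row per nest: n samples, percent polymorphic, mean Ho +/- SD."""
    ho = observed_heterozygosity(matrix)
    grouped = samples_by_nest(samples)
    rows = []
    for nest_id, ids in grouped.items():
        nest_ho = ho.loc[ids].dropna()
        rows.append(
            {
                "nest_id": nest_id,
                "n_samples": len(ids),
                "pct_polymorphic": percent_polymorphic(
                    matrix, samples, nest_id, include_all_missing_loci
                ),
                "mean_ho": nest_ho.mean() if len(nest_ho) else np.nan,
                "sd_ho": nest_ho.std(ddof=1) if len(nest_ho) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def aggregate_nest_summaries(table: pd.DataFrame) -> dict[str, float]:
    """Across-nest aggregates of a per-nest summary table.

    Expects columns ``pct_polymorphic``, ``mean_ho``, ``mean_relatedness``
    (optional), ``n_samples`` and ``haplotype``; nests with NA genomic
    values are ignored.  SDs are sample SDs (ddof=1).
    """
    gen = table.dropna(subset=["pct_polymorphic"])
    out = {
        "mean_pct_polymorphic": float(gen["pct_polymorphic"].mean()),
        "sd_pct_polymorphic": float(gen["pct_polymorphic"].std(ddof=1)),
        "mean_ho": float(gen["mean_ho"].mean()),
        "n_samples": int(gen["n_samples"].sum()),
        "n_nests": int(len(gen)),
        "n_haplotypes": int(gen["haplotype"].nunique()),
    }
    if "mean_relatedness" in gen:
        out["mean_relatedness"] = float(gen["mean_relatedness"].mean())
        out["sd_relatedness"] = float(gen["mean_relatedness"].std(ddof=1))
    return out
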