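"""Incubation-duration sex-ratio curves and SST-nesting correlations.

Sea-turtle sex is temperature-dependent: warm (short) incubations produce
females, cool (long) ones males.  With nest temperature unrecorded, the
incubation duration (laying to first emergence, in days) is the standard
proxy, mapped to an expected female fraction through a decreasing logistic

    f(d) = 1 / (1 + exp(s * (d - p)))

with pivotal duration ``p`` (f = 0.5) and steepness ``s`` per published
model.  Because different studies fit different curves, the module takes a
*set* of models and reports the min/max envelope per nest.

The module also supports the phenology-side checks of colonisation studies:
a tie-aware Spearman rank correlation (permutation p-value) between annual
nesting-event counts and mean June-July SST of a foraging area, and a flag
for the ~21 degC SST threshold below which nesting is not expected to start
in the Western Mediterranean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .genotype_io import NestRecord

NESTING_SST_THRESHOLD_C = 21.0


@dataclass(frozen=True)
class SexRatioModel:
    """Logistic duration-to-female-fraction curve."""

    name: str
    pivot_days: float  # duration giving a 0.5 female fraction
    steepness: float  # per-day slope parameter, > 0

    def __post_init__(self) -> None:
        if self.pivot_days <= 0 or self.steepness <= 0:
            raise ValueError("pivot_days and steepness must be positive")


def example_sex_ratio_models() -> list[SexRatioModel]:
    """Four synthetic logistic curves for tests and demonstrations.

    Pivots span the 58-62 day range in which loggerhead clutches shift from
    female- to male-biased; the parameters are illustrative placeholders,
    not fits of any published model — supply your own curves for real data.
    """
    return [
        SexRatioModel("synthetic_a", pivot_days=58.5, steepness=0.60),
        SexRatioModel("synthetic_b", pivot_days=59.5, steepness=0.45),
        SexRatioModel("synthetic_c", pivot_days=60.5, steepness=0.35),
        SexRatioModel("synthetic_d", pivot_days=61.5, steepness=0.50),
    ]


def female_fraction(duration_days: float, model: SexRatioModel) -> float:
    """Expected fraction of female hatchlings at a given incubation duration."""
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    return float(
        1.0 / (1.0 + np.exp(model.steepness * (duration_days - model.pivot_days)))
    )


def nest_sex_ratio_range(
    nest: NestRecord, models: list[SexRatioModel]
) -> tuple[float, float] | None:
    """Min/max female fraction over the configured models, or None without dates."""
    if not models:
        raise ValueError("at least one sex-ratio model is required")
    duration = nest.incubation_days
    if duration is None:
        return None
    values = [female_fraction(duration, m) for m in models]
    return (min(values), max(values))


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected (average-rank) Spearman rho: Pearson r of the ranks."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return float((rx * ry).sum() / denom)


def spearman_events_vs_sst(
    events: pd.DataFrame,
    sst: pd.DataFrame,
    area: str,
    n_permutations: int = 100_000,
    method: str = "permutation",
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation of annual event counts against an area's SST.

    ``events`` has columns ``year, n_events``; ``sst`` has
    ``year, area, mean_sst_c``.  Years present in both tables are paired.
    The two-sided p-value is computed by seeded permutation of one ranked
    vector (default), or by the large-sample t approximation
    (``method="t"``).
    """
    sub = sst[sst["area"] == area]
    merged = events.merge(sub, on="year", how="inner")
    if len(merged) < 5:
        raise ValueError(
            f"need >= 5 paired years for area {area!r}, got {len(merged)}"
        )
    x = merged["n_events"].to_numpy(dtype=float)
    y = merged["mean_sst_c"].to_numpy(dtype=float)
    rho = _spearman_rho(x, y)
    n = len(merged)

    if method == "t":
        stat = rho * np.sqrt((n - 2) / max(1.0 - rho ** 2, 1e-300))
        p = 2.0 * float(t_dist.sf(abs(stat), df=n - 2))
        return CorrelationResult(rho, min(p, 1.0), n, "t approximation")

    rng = np.random.default_rng(seed)
    rx = rankdata(x) - (n + 1) / 2.0
    ry = rankdata(y) - (n + 1) / 2.0
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    # permute one vector; correlations for all permutations at once
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    stats = (ry[perms] * rx).sum(axis=1) / denom
    count = int((np.abs(stats) >= abs(rho) - 1e-12).sum())
    p = (1 + count) / (n_permutations + 1)
    return CorrelationResult(
        rho, p, n, f"permutation ({n_permutations} draws, tie-aware average ranks)"
    )


def nesting_threshold_flag(
    events: pd.DataFrame,
    sst: pd.DataFrame,
    area: str,
    threshold_c: float = NESTING_SST_THRESHOLD_C,
) -> pd.DataFrame:
    """Per event year: was the area's mean June-July SST above the threshold?

    Years absent from the SST series get a null flag.
    """
    sub = sst[sst["area"] == area][["year", "mean_sst_c"]]
    merged = events.merge(sub, on="year", how="left")
    merged["above_threshold"] = merged["mean_sst_c"].apply(
        lambda v: None if pd.isna(v) else bool(v > threshold_c)
    )
    merged["area"] = area
    return merged
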