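"""Classify nest pairs as laid by the same female or by different females.

The decision combines three independent lines of evidence, mirroring how
same-female nests are recognised in sporadic sea-turtle nesting studies:

1. mtDNA haplotype concordance is an absolute exclusion — hatchlings inherit
   the mother's haplotype, so nests with different haplotypes cannot share a
   mother, whatever the nuclear kinship says.
2. Cross-nest nuclear kinship: a same-mother nest pair contains cross-nest
   siblings, so the median cross-nest Manichaikul phi should sit at
   sibling grade.  The default threshold ``tau_sib`` = 0.1875 is the
   midpoint of the half-sib (0.125) and full-sib (0.25) kinship
   expectations.  An optional permutation rank test asks in addition
   whether cross-nest kinship is separable from pooled within-nest kinship.
3. Dates: a same-mother pair in one season is a re-nester (typical
   loggerhead internesting interval 12-16 days, possibly several cycles);
   across seasons it is a remigrant — the signature of philopatric return.

Multiple paternity within a nest is flagged when the mean within-nest phi
falls below ``tau_mp``: a two-sire clutch is a mixture of full and half
sibs, depressing the mean below the full-sib expectation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from math import ceil

import numpy as np
import pandas as pd

from .genotype_io import NestRecord, SampleMetadata
from .kinship_mds import KinshipMatrix
from .genotype_io import samples_by_nest

logger = logging.getLogger(__name__)

VERDICTS = (
    "same_female_renester",
    "same_female_remigrant",
    "different_females",
    "inconclusive",
)


@dataclass
class AssignmentConfig:
    #: kinship treated as sibling grade (midpoint of half-sib and full-sib)
    tau_sib: float = 0.1875
    #: within-nest mean phi below which multiple paternity is flagged
    tau_mp: float = 0.1875
    internesting_min_days: int = 12
    internesting_max_days: int = 16
    cross_nest_test: str = "threshold"  # or "rank_test"
    alpha: float = 0.05
    n_permutations: int = 10_000
    seed: int = 0
    #: cross-nest median phi in [halfsib_floor, tau_sib) earns a
    #: possible_same_mother_halfsib note
    halfsib_floor: float = 0.0625

    def __post_init__(self) -> None:
        for tau in (self.tau_sib, self.tau_mp):
            if not 0.0 < tau < 0.5:
                raise ValueError("tau thresholds must be in (0, 0.5)")
        if self.internesting_min_days > self.internesting_max_days:
            raise ValueError("internesting_min_days must be <= max")
        if self.cross_nest_test not in ("threshold", "rank_test"):
            raise ValueError("cross_nest_test must be 'threshold' or 'rank_test'")


@dataclass
class PairEvidence:
    nest_a: str
    nest_b: str
    haplotype_match: str  # yes / no / unknown
    cross_phi_median: float | None
    cross_phi_min: float | None
    cross_phi_max: float | None
    within_phi_mean_a: float | None
    within_phi_mean_b: float | None
    temporal_relation: str  # same_season / different_season
    internesting_window_days: tuple[float, float] | None
    window_consistent: bool | None
    verdict: str
    reasons: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class AssignmentReport:
    pairs: list[PairEvidence]
    multiple_paternity: dict[str, bool | None]
    n_distinct_females: int
    warnings: list[str] = field(default_factory=list)

    def same_female_pairs(self) -> list[tuple[str, str, str]]:
        return [
            (p.nest_a, p.nest_b, p.verdict)
            for p in self.pairs
            if p.verdict.startswith("same_female")
        ]

    def to_json(self, path=None) -> str:
        payload = {
            "pairs": [asdict(p) for p in self.pairs],
            "multiple_paternity": self.multiple_paternity,
            "n_distinct_females": self.n_distinct_females,
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.pairs])


# ---------------------------------------------------------------------------
# Multiple paternity
# ---------------------------------------------------------------------------

def flag_multiple_paternity(
    nest_means: pd.Series,
    nest_sizes: dict[str, int],
    config: AssignmentConfig | None = None,
) -> dict[str, bool | None]:
    """Flag nests whose mean within-nest kinship falls below ``tau_mp``.

    Nests with fewer than two genotyped hatchlings cannot be assessed and
    get ``None``.
    """
    config = config or AssignmentConfig()
    flags: dict[str, bool | None] = {}
    for nest_id, mean_phi in nest_means.items():
        if nest_sizes.get(nest_id, 0) < 2 or np.isnan(mean_phi):
            flags[nest_id] = None
        else:
            flags[nest_id] = bool(mean_phi < config.tau_mp)
    return flags


# ---------------------------------------------------------------------------
# Internesting window
# ---------------------------------------------------------------------------

def incubation_range_from_records(
    nests: dict[str, NestRecord]
) -> tuple[int, int] | None:
    """Min/max incubation duration over nests with both dates recorded."""
    durations = [
        r.incubation_days for r in nests.values() if r.incubation_days is not None
    ]
    if not durations:
        return None
    return min(durations), max(durations)


def internesting_window(
    nest_a: NestRecord,
    nest_b: NestRecord,
    incubation_range_days: tuple[int, int] | None,
) -> tuple[float, float] | None:
    """Feasible laying-to-laying interval between two nests, in days.

    With both laying dates known the window is the exact difference.  When
    one nest only has an emergence date, its laying date is back-computed
    from the supplied incubation range, giving an interval
    ``[emergence - max_inc - laying, emergence - min_inc - laying]``.
    Returns None when no usable dates exist.
    """
    a, b = nest_a, nest_b
    if a.laying_date is None and b.laying_date is not None:
        a, b = b, a
    if a.laying_date is None:
        return None
    if b.laying_date is not None:
        days = abs((b.laying_date - a.laying_date).days)
        return (float(days), float(days))
    if b.emergence_date is None or incubation_range_days is None:
        return None
    lo_inc, hi_inc = incubation_range_days
    span = (b.emergence_date - a.laying_date).days
    return (float(span - hi_inc), float(span - lo_inc))


def window_consistent_with_cycles(
    window: tuple[float, float],
    config: AssignmentConfig,
) -> bool:
    """Whether the window can be spanned by >= 1 internesting cycles.

    Checks intersection with ``[k*min_days, k*max_days]`` for each cycle
    count k >= 1.
    """
    lo, hi = window
    if hi < config.internesting_min_days:
        return False
    k_max = ceil(hi / config.internesting_min_days)
    for k in range(1, k_max + 1):
        if k * config.internesting_min_days <= hi and k * config.internesting_max_days >= lo:
            return True
    return False


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

def _rank_test_pvalue(
    cross: np.ndarray, within: np.ndarray, config: AssignmentConfig
) -> float:
    """Permutation p-value of a two-sample rank-sum comparison.

    The statistic is the rank sum of the cross-nest phi values within the
    pooled sample; small samples (a handful of pairs per nest) rule out the
    normal approximation, so the null is built by permutation.
    """
    from scipy.stats import rankdata

    rng = np.random.default_rng(config.seed)
    pooled = np.concatenate([cross, within])
    n_cross = len(cross)
    ranks = rankdata(pooled)
    observed = ranks[:n_cross].sum()
    expected = n_cross * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - expected)
    count = 0
    for _ in range(config.n_permutations):
        perm = rng.permutation(len(pooled))
        stat = ranks[perm[:n_cross]].sum()
        if abs(stat - expected) >= obs_dev - 1e-12:
            count += 1
    return (1 + count) / (config.n_permutations + 1)


def classify_nest_pair(
    nest_a: str,
    nest_b: str,
    kinship: KinshipMatrix,
    samples: list[SampleMetadata],
    nests: dict[str, NestRecord],
    config: AssignmentConfig | None = None,
    incubation_range_days: tuple[int, int] | None = None,
) -> PairEvidence:
    """Apply the rule cascade to one nest pair.

    (1) differing haplotypes exclude shared maternity outright;
    (2) matching (or unknown, with a warning) haplotypes make the pair a
    same-mother candidate when cross-nest kinship reaches sibling grade;
    (3) candidates in the same calendar year are re-nesters (with an
    internesting-window consistency note); (4) in different years,
    remigrants; (5) anything else is different females.
    """
    config = config or AssignmentConfig()
    grouped = samples_by_nest(samples)
    for nid in (nest_a, nest_b):
        if nid not in grouped:
            raise KeyError(f"nest {nid!r} has no samples in the kinship matrix")
        missing = set(grouped[nid]) - set(kinship.sample_ids)
        if missing:
            raise KeyError(f"nest {nid!r}: samples absent from kinship: {missing}")

    idx = {s: i for i, s in enumerate(kinship.sample_ids)}
    ia = [idx[s] for s in grouped[nest_a]]
    ib = [idx[s] for s in grouped[nest_b]]
    cross = np.array([kinship.phi[i, j] for i in ia for j in ib])
    cross = cross[~np.isnan(cross)]

    def within_vals(members):
        vals = [
            kinship.phi[idx[x], idx[y]]
            for k, x in enumerate(members)
            for y in members[k + 1:]
        ]
        return np.array([v for v in vals if not np.isnan(v)])

    within_a, within_b = within_vals(grouped[nest_a]), within_vals(grouped[nest_b])
    rec_a, rec_b = nests[nest_a], nests[nest_b]
    same_year = rec_a.year == rec_b.year

    hap_a, hap_b = rec_a.haplotype, rec_b.haplotype
    if hap_a is None or hap_b is None:
        hap_match = "unknown"
    else:
        hap_match = "yes" if hap_a == hap_b else "no"

    evidence = PairEvidence(
        nest_a=nest_a,
        nest_b=nest_b,
        haplotype_match=hap_match,
        cross_phi_median=float(np.median(cross)) if cross.size else None,
        cross_phi_min=float(cross.min()) if cross.size else None,
        cross_phi_max=float(cross.max()) if cross.size else None,
        within_phi_mean_a=float(within_a.mean()) if within_a.size else None,
        within_phi_mean_b=float(within_b.mean()) if within_b.size else None,
        temporal_relation="same_season" if same_year else "different_season",
        internesting_window_days=None,
        window_consistent=None,
        verdict="inconclusive",
        reasons=[],
    )

    # rule 1: mtDNA exclusion
    if hap_match == "no":
        evidence.reasons.append(
            f"rule1: haplotypes differ ({hap_a} vs {hap_b}) -> different females"
        )
        evidence.verdict = "different_females"
        return evidence
    if hap_match == "unknown":
        evidence.reasons.append(
            "rule2: haplotype unknown for at least one nest; "
            "proceeding on nuclear kinship alone"
        )
        logger.warning(
            "pair (%s, %s): haplotype unknown, maternity not excludable by mtDNA",
            nest_a, nest_b,
        )
    else:
        evidence.reasons.append(f"rule2: haplotypes match ({hap_a})")

    if cross.size == 0:
        evidence.reasons.append("no defined cross-nest kinship values -> inconclusive")
        evidence.verdict = "inconclusive"
        return evidence

    median_cross = float(np.median(cross))
    candidate = median_cross >= config.tau_sib
    evidence.reasons.append(
        f"rule2: median cross-nest phi {median_cross:.4f} "
        f"{'>=' if candidate else '<'} tau_sib {config.tau_sib}"
    )
    if candidate and config.cross_nest_test == "rank_test":
        within_pooled = np.concatenate([within_a, within_b])
        if within_pooled.size:
            p = _rank_test_pvalue(cross, within_pooled, config)
            separable = p < config.alpha
            evidence.reasons.append(
                f"rank_test: cross vs within rank-sum permutation p={p:.4f} "
                f"({'separable' if separable else 'not separable'} at "
                f"alpha={config.alpha})"
            )
            candidate = candidate and not separable

    if config.halfsib_floor <= median_cross < config.tau_sib:
        evidence.notes.append("possible_same_mother_halfsib")

    if not candidate:
        evidence.verdict = "different_females"
        evidence.reasons.append("rule5: not a same-mother candidate -> different females")
        return evidence

    if same_year:
        evidence.verdict = "same_female_renester"
        evidence.reasons.append("rule3: same calendar year -> re-nester")
        window = internesting_window(rec_a, rec_b, incubation_range_days)
        evidence.internesting_window_days = window
        if window is not None:
            consistent = window_consistent_with_cycles(window, config)
            evidence.window_consistent = consistent
            evidence.reasons.append(
                f"rule3: feasible internesting window {window[0]:.0f}-"
                f"{window[1]:.0f} d is {'consistent' if consistent else 'NOT consistent'} "
                f"with {config.internesting_min_days}-{config.internesting_max_days} d cycles"
            )
        else:
            evidence.reasons.append("rule3: internesting window not computable from dates")
    else:
        evidence.verdict = "same_female_remigrant"
        evidence.reasons.append("rule4: different years -> remigrant")
    return evidence


def classify_all(
    kinship: KinshipMatrix,
    samples: list[SampleMetadata],
    nests: dict[str, NestRecord],
    config: AssignmentConfig | None = None,
    incubation_range_days: tuple[int, int] | None = None,
) -> list[PairEvidence]:
    """Classify every unordered pair of nests that has genotyped samples.

    When ``incubation_range_days`` is not supplied it is derived from the
    dataset's nests that have both laying and emergence dates.
    """
    config = config or AssignmentConfig()
    if incubation_range_days is None:
        incubation_range_days = incubation_range_from_records(nests)
    nest_ids = sorted(samples_by_nest(samples))
    return [
        classify_nest_pair(
            a, b, kinship, samples, nests, config, incubation_range_days
        )
        for i, a in enumerate(nest_ids)
        for b in nest_ids[i + 1:]
    ]


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def summarize_assignment(
    evidence: list[PairEvidence],
    multiple_paternity: dict[str, bool | None],
) -> AssignmentReport:
    """Merge same-female verdicts into distinct inferred females.

    Transitive inconsistencies (A=B and B=C but A!=C) are merged anyway,
    with a loud warning recorded in the report.
    """
    nest_ids = sorted({p.nest_a for p in evidence} | {p.nest_b for p in evidence})
    uf = _UnionFind(nest_ids)
    for p in evidence:
        if p.verdict.startswith("same_female"):
            uf.union(p.nest_a, p.nest_b)
    warnings_list = []
    for p in evidence:
        if p.verdict == "different_females" and uf.find(p.nest_a) == uf.find(p.nest_b):
            msg = (
                f"inconsistent triangle: {p.nest_a} and {p.nest_b} judged "
                "different females but merged through a third nest"
            )
            warnings_list.append(msg)
            logger.warning(msg)
    n_females = len({uf.find(n) for n in nest_ids})
    return AssignmentReport(
        pairs=evidence,
        multiple_paternity=multiple_paternity,
        n_distinct_females=n_females,
        warnings=warnings_list,
    )
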