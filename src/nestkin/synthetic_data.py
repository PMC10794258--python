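"""Synthetic clutch-genotype generator with known pedigree ground truth.

Emulates a post-genotyping biallelic SNP matrix for hatchlings sampled from
sea-turtle nests: two differentiated source populations (Atlantic and
Mediterranean) under a Balding-Nichols divergence model, Hardy-Weinberg
parents, Mendelian clutches with optional multiple paternity, maternally
inherited mtDNA haplotype labels, negative-binomial read depths, and simple
missingness/genotyping-error noise.  Every random choice is recorded in a
:class:`PedigreeTruth` so that downstream inference can be scored against
the truth.

The default scenario (:func:`baseline_scenario`) mirrors the sampling design
of the 2016-2019 sporadic nesting events on the Spanish coast: eight
genotyped nests of 2-8 hatchlings each (45 samples), ~2,300 loci at mean
depth ~25, one pair of same-season nests laid by the same female and one
small nest with two sires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import yaml

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    NestRecord,
    SampleMetadata,
)

ATLANTIC = "Atlantic"
MEDITERRANEAN = "Mediterranean"


@dataclass
class NestSpec:
    """Declaration of one simulated nest.

    Nests sharing a ``mother_id`` are laid by the same female (and therefore
    share her mtDNA haplotype); nests sharing a ``father_group`` draw sires
    from the same father pool, so a planted same-mother pair with a common
    father group contains cross-nest full siblings.  ``father_group``
    defaults to the nest id (private sires).
    """

    nest_id: str
    mother_id: str
    mother_population: str
    n_hatchlings: int
    year: int
    n_fathers: int = 1
    laying_date: date | None = None
    emergence_date: date | None = None
    haplotype: str | None = None  # fixed label; drawn from pop freqs if None
    father_group: str | None = None

    def __post_init__(self) -> None:
        if self.n_hatchlings < 1:
            raise ValueError(f"nest {self.nest_id}: n_hatchlings must be >= 1")
        if self.n_fathers < 1:
            raise ValueError(f"nest {self.nest_id}: n_fathers must be >= 1")
        if self.mother_population not in (ATLANTIC, MEDITERRANEAN):
            raise ValueError(
                f"nest {self.nest_id}: unknown population "
                f"{self.mother_population!r}"
            )
        if self.father_group is None:
            self.father_group = self.nest_id


@dataclass
class SimulationConfig:
    """Scenario parameters for :func:`simulate_clutches`.

    ``fst`` is the Balding-Nichols divergence F between the two source
    populations; ``depth_dispersion`` is the negative-binomial size
    parameter (None means Poisson depths); ``error_rate`` is the
    probability that an emitted genotype is perturbed one step
    (0<->1<->2).
    """

    nests: list[NestSpec]
    n_loci: int = 2300
    fst: float = 0.10
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    planted_same_mother_pairs: list[tuple[str, str]] = field(default_factory=list)
    mean_depth: float = 25.0
    depth_dispersion: float | None = 5.0
    missing_rate: float = 0.02
    error_rate: float = 0.005
    haplotype_freqs: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        for p in (self.missing_rate, self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missing_rate and error_rate must be in [0,1]")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        nest_ids = [n.nest_id for n in self.nests]
        if len(set(nest_ids)) != len(nest_ids):
            raise ValueError("duplicate nest ids")
        for a, b in self.planted_same_mother_pairs:
            if a not in nest_ids or b not in nest_ids:
                raise ValueError(f"planted pair ({a},{b}) references unknown nest")
            specs = {n.nest_id: n for n in self.nests}
            if specs[a].mother_id != specs[b].mother_id:
                raise ValueError(
                    f"planted pair ({a},{b}) declared but mother ids differ"
                )

    # --- scenario file round-trip -------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        def _nest(n: NestSpec) -> dict:
            return {
                "nest_id": n.nest_id,
                "mother_id": n.mother_id,
                "mother_population": n.mother_population,
                "n_hatchlings": n.n_hatchlings,
                "year": n.year,
                "n_fathers": n.n_fathers,
                "laying_date": n.laying_date.isoformat() if n.laying_date else None,
                "emergence_date": (
                    n.emergence_date.isoformat() if n.emergence_date else None
                ),
                "haplotype": n.haplotype,
                "father_group": n.father_group,
            }

        payload = {
            "n_loci": self.n_loci,
            "fst": self.fst,
            "ancestral_freq_range": list(self.ancestral_freq_range),
            "mean_depth": self.mean_depth,
            "depth_dispersion": self.depth_dispersion,
            "missing_rate": self.missing_rate,
            "error_rate": self.error_rate,
            "seed": self.seed,
            "haplotype_freqs": self.haplotype_freqs,
            "planted_same_mother_pairs": [list(p) for p in self.planted_same_mother_pairs],
            "nests": [_nest(n) for n in self.nests],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        payload = yaml.safe_load(Path(path).read_text())
        nests = [
            NestSpec(
                nest_id=n["nest_id"],
                mother_id=n["mother_id"],
                mother_population=n["mother_population"],
                n_hatchlings=n["n_hatchlings"],
                year=n["year"],
                n_fathers=n.get("n_fathers", 1),
                laying_date=(
                    date.fromisoformat(n["laying_date"]) if n.get("laying_date") else None
                ),
                emergence_date=(
                    date.fromisoformat(n["emergence_date"])
                    if n.get("emergence_date")
                    else None
                ),
                haplotype=n.get("haplotype"),
                father_group=n.get("father_group"),
            )
            for n in payload["nests"]
        ]
        return cls(
            nests=nests,
            n_loci=payload.get("n_loci", 2300),
            fst=payload.get("fst", 0.10),
            ancestral_freq_range=tuple(payload.get("ancestral_freq_range", (0.05, 0.95))),
            planted_same_mother_pairs=[
                tuple(p) for p in payload.get("planted_same_mother_pairs", [])
            ],
            mean_depth=payload.get("mean_depth", 25.0),
            depth_dispersion=payload.get("depth_dispersion", 5.0),
            missing_rate=payload.get("missing_rate", 0.02),
            error_rate=payload.get("error_rate", 0.005),
            haplotype_freqs=payload.get("haplotype_freqs", {}),
            seed=payload.get("seed", 0),
        )


@dataclass
class PedigreeTruth:
    """Ground-truth parentage of a simulated dataset."""

    mother_of_nest: dict[str, str]
    father_of_sample: dict[str, str]
    mother_of_sample: dict[str, str]
    haplotype_of_mother: dict[str, str]
    population_of_mother: dict[str, str]

    def pair_relationship(self, nest_a: str, nest_b: str) -> str:
        """``same_mother`` or ``different_mothers`` for a nest pair."""
        if self.mother_of_nest[nest_a] == self.mother_of_nest[nest_b]:
            return "same_mother"
        return "different_mothers"

    def n_true_mothers(self) -> int:
        return len(set(self.mother_of_nest.values()))

    def nests_with_multiple_fathers(self) -> set[str]:
        fathers_by_nest: dict[str, set[str]] = {}
        for sample, father in self.father_of_sample.items():
            nest = sample.rsplit("_h", 1)[0]
            fathers_by_nest.setdefault(nest, set()).add(father)
        return {n for n, f in fathers_by_nest.items() if len(f) > 1}


# ---------------------------------------------------------------------------
# Population model
# ---------------------------------------------------------------------------

def draw_population_freqs(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw per-population alternate-allele frequencies per locus.

    The ancestral frequency ``p`` is uniform on ``ancestral_freq_range``;
    each population's frequency follows the Balding-Nichols distribution
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
    ``F p (1-p)``.  With F = 0 both populations equal the ancestral
    frequency.
    """
    lo, hi = config.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=config.n_loci)
    freqs: dict[str, np.ndarray] = {"ancestral": ancestral}
    for pop in (ATLANTIC, MEDITERRANEAN):
        if config.fst == 0.0:
            freqs[pop] = ancestral.copy()
        else:
            scale = (1.0 - config.fst) / config.fst
            freqs[pop] = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
    return freqs


def _hw_genotype(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Hardy-Weinberg individual: Binomial(2, p) per locus."""
    return rng.binomial(2, freqs).astype(np.int8)


def _mendelian_offspring(
    mother: np.ndarray, father: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One transmitted allele per parent per locus."""
    a = rng.binomial(1, mother / 2.0)
    b = rng.binomial(1, father / 2.0)
    return (a + b).astype(np.int8)


def _assign_fathers(
    n_hatchlings: int, father_ids: list[str], rng: np.random.Generator
) -> list[str]:
    """Assign sires to hatchlings.

    Each declared father sires at least one sampled hatchling (a declared
    two-father nest genuinely has two sires among the sampled offspring);
    the remainder are assigned uniformly at random.
    """
    if len(father_ids) == 1:
        return [father_ids[0]] * n_hatchlings
    if n_hatchlings < len(father_ids):
        raise ValueError("more declared fathers than sampled hatchlings")
    assignment = list(father_ids) + list(
        rng.choice(father_ids, size=n_hatchlings - len(father_ids))
    )
    perm = rng.permutation(n_hatchlings)
    return [assignment[i] for i in perm]


# ---------------------------------------------------------------------------
# Main simulator
# ---------------------------------------------------------------------------

def simulate_clutches(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[SampleMetadata], dict[str, NestRecord], PedigreeTruth]:
    """Simulate hatchling genotypes for the configured nests.

    Parents are Hardy-Weinberg draws from their population's Balding-Nichols
    frequencies; each hatchling receives one allele per parent per locus;
    depth is negative-binomial with the configured mean and dispersion;
    genotypes are independently set missing with ``missing_rate`` and
    perturbed one step (0<->1<->2) with ``error_rate``.  Identical seeds and
    configs give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    freqs = draw_population_freqs(config, rng)

    # mothers (one draw per distinct female, shared across her nests)
    mothers: dict[str, np.ndarray] = {}
    hap_of_mother: dict[str, str] = {}
    pop_of_mother: dict[str, str] = {}
    for spec in config.nests:
        if spec.mother_id in mothers:
            if pop_of_mother[spec.mother_id] != spec.mother_population:
                raise ValueError(
                    f"mother {spec.mother_id} declared in two populations"
                )
            continue
        pop_of_mother[spec.mother_id] = spec.mother_population
        mothers[spec.mother_id] = _hw_genotype(freqs[spec.mother_population], rng)
        if spec.haplotype is not None:
            hap_of_mother[spec.mother_id] = spec.haplotype
        else:
            pool = config.haplotype_freqs.get(spec.mother_population)
            if not pool:
                raise ValueError(
                    f"no haplotype for mother {spec.mother_id}: set "
                    "NestSpec.haplotype or haplotype_freqs"
                )
            labels = sorted(pool)
            probs = np.array([pool[h] for h in labels], dtype=float)
            hap_of_mother[spec.mother_id] = labels[
                rng.choice(len(labels), p=probs / probs.sum())
            ]

    # father pools (shared across nests with the same father_group)
    father_pools: dict[str, dict[str, np.ndarray]] = {}
    for spec in config.nests:
        pool = father_pools.setdefault(spec.father_group, {})
        while len(pool) < spec.n_fathers:
            fid = f"{spec.father_group}_F{len(pool) + 1}"
            pool[fid] = _hw_genotype(freqs[spec.mother_population], rng)

    sample_ids: list[str] = []
    genotype_rows: list[np.ndarray] = []
    samples: list[SampleMetadata] = []
    nests: dict[str, NestRecord] = {}
    father_of_sample: dict[str, str] = {}
    mother_of_sample: dict[str, str] = {}
    mother_of_nest: dict[str, str] = {}

    for spec in config.nests:
        mother_of_nest[spec.nest_id] = spec.mother_id
        father_ids = sorted(father_pools[spec.father_group])[: spec.n_fathers]
        sires = _assign_fathers(spec.n_hatchlings, father_ids, rng)
        for k in range(spec.n_hatchlings):
            sid = f"{spec.nest_id}_h{k + 1:02d}"
            g = _mendelian_offspring(
                mothers[spec.mother_id], father_pools[spec.father_group][sires[k]], rng
            )
            sample_ids.append(sid)
            genotype_rows.append(g)
            samples.append(SampleMetadata(sid, spec.nest_id, source="simulated"))
            father_of_sample[sid] = sires[k]
            mother_of_sample[sid] = spec.mother_id
        nests[spec.nest_id] = NestRecord(
            nest_id=spec.nest_id,
            year=spec.year,
            laying_date=spec.laying_date,
            emergence_date=spec.emergence_date,
            haplotype=hap_of_mother[spec.mother_id],
        )

    genotypes = np.vstack(genotype_rows)
    n, L = genotypes.shape

    # genotyping error: move one step with prob error_rate
    if config.error_rate > 0:
        err = rng.random((n, L)) < config.error_rate
        direction = rng.integers(0, 2, size=(n, L))  # het -> hom-ref or hom-alt
        perturbed = genotypes.copy()
        perturbed[err & (genotypes == 0)] = 1
        perturbed[err & (genotypes == 2)] = 1
        het_err = err & (genotypes == 1)
        perturbed[het_err] = (2 * direction[het_err]).astype(np.int8)
        genotypes = perturbed

    # read depths
    if config.depth_dispersion is None or np.isinf(config.depth_dispersion):
        depths = rng.poisson(config.mean_depth, size=(n, L))
    else:
        k = config.depth_dispersion
        p = k / (k + config.mean_depth)
        depths = rng.negative_binomial(k, p, size=(n, L))

    # missingness
    if config.missing_rate > 0:
        miss = rng.random((n, L)) < config.missing_rate
        genotypes[miss] = MISSING

    matrix = GenotypeMatrix(
        sample_ids,
        [f"tag{j + 1:05d}:17" for j in range(L)],
        genotypes,
        depths.astype(np.int32),
    )
    truth = PedigreeTruth(
        mother_of_nest=mother_of_nest,
        father_of_sample=father_of_sample,
        mother_of_sample=mother_of_sample,
        haplotype_of_mother=hap_of_mother,
        population_of_mother=pop_of_mother,
    )
    return matrix, samples, nests, truth


def write_truth(truth: PedigreeTruth, path: str | Path) -> None:
    """Dump the per-sample parentage truth as a TSV."""
    with open(path, "w") as fh:
        fh.write("sample_id\tmother_id\tfather_id\thaplotype\tpopulation\n")
        for sid in truth.father_of_sample:
            mid = truth.mother_of_sample[sid]
            fh.write(
                f"{sid}\t{mid}\t{truth.father_of_sample[sid]}\t"
                f"{truth.haplotype_of_mother[mid]}\t"
                f"{truth.population_of_mother[mid]}\n"
            )


# ---------------------------------------------------------------------------
# Relationship pairs for estimator calibration
# ---------------------------------------------------------------------------

RELATIONSHIPS = ("full_sib", "half_sib", "parent_offspring", "unrelated")

#: pedigree kinship coefficient per supported relationship
EXPECTED_KINSHIP = {
    "full_sib": 0.25,
    "half_sib": 0.125,
    "parent_offspring": 0.25,
    "unrelated": 0.0,
    "self": 0.5,
}


def simulate_relationship_pair(
    relationship: str,
    n_loci: int,
    rng: np.random.Generator,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[np.ndarray, np.ndarray]:
    """Error-free genotype vectors for a pair with a known pedigree relation.

    Both individuals come from one Hardy-Weinberg population with allele
    frequencies uniform on ``freq_range``.
    """
    p = rng.uniform(*freq_range, size=n_loci)
    if relationship == "unrelated":
        return _hw_genotype(p, rng), _hw_genotype(p, rng)
    if relationship == "parent_offspring":
        parent = _hw_genotype(p, rng)
        mate = _hw_genotype(p, rng)
        child = _mendelian_offspring(parent, mate, rng)
        return parent, child
    if relationship == "full_sib":
        mother, father = _hw_genotype(p, rng), _hw_genotype(p, rng)
        return (
            _mendelian_offspring(mother, father, rng),
            _mendelian_offspring(mother, father, rng),
        )
    if relationship == "half_sib":
        shared = _hw_genotype(p, rng)
        mate_a, mate_b = _hw_genotype(p, rng), _hw_genotype(p, rng)
        return (
            _mendelian_offspring(shared, mate_a, rng),
            _mendelian_offspring(shared, mate_b, rng),
        )
    raise ValueError(f"unknown relationship {relationship!r}")


# ---------------------------------------------------------------------------
# Baseline scenario
# ---------------------------------------------------------------------------

def baseline_scenario(seed: int = 0) -> SimulationConfig:
    """The default study-design scenario.

    Eight genotyped nests with 2,2,8,4,7,7,7,8 sampled hatchlings (45
    samples) across 2016-2019, ~2,300 loci at mean depth 25; nests SN05 and
    SN08 are a planted same-female pair laid in the same season (same sire,
    shared rare Mediterranean haplotype); nest SN01 has two sires (multiple
    paternity).  Haplotype labels and dates follow the published nest table.
    """
    nests = [
        NestSpec("SN01", "M01", ATLANTIC, 2, 2016, n_fathers=2,
                 laying_date=date(2016, 7, 3), emergence_date=date(2016, 9, 5),
                 haplotype="CC-A2.1"),
        NestSpec("SN02", "M02", ATLANTIC, 2, 2017,
                 emergence_date=date(2017, 10, 11), haplotype="CC-A1.1"),
        NestSpec("SN03", "M03", ATLANTIC, 8, 2018,
                 laying_date=date(2018, 8, 1), emergence_date=date(2018, 9, 28),
                 haplotype="CC-A3.1"),
        NestSpec("SN04", "M04", MEDITERRANEAN, 4, 2018,
                 emergence_date=date(2018, 9, 16), haplotype="CC-A2.1"),
        NestSpec("SN05", "M05", MEDITERRANEAN, 7, 2019,
                 laying_date=date(2019, 7, 13), emergence_date=date(2019, 9, 14),
                 haplotype="CC-A31.1", father_group="FG_renester"),
        NestSpec("SN06", "M06", ATLANTIC, 7, 2019,
                 laying_date=date(2019, 7, 25), emergence_date=date(2019, 9, 10),
                 haplotype="CC-A2.1"),
        NestSpec("SN07", "M07", MEDITERRANEAN, 7, 2019,
                 laying_date=date(2019, 7, 28), emergence_date=date(2019, 9, 18),
                 haplotype="CC-A2.1"),
        NestSpec("SN08", "M05", MEDITERRANEAN, 8, 2019,
                 emergence_date=date(2019, 10, 6),
                 haplotype="CC-A31.1", father_group="FG_renester"),
    ]
    return SimulationConfig(
        nests=nests,
        n_loci=2300,
        fst=0.10,
        planted_same_mother_pairs=[("SN05", "SN08")],
        mean_depth=25.0,
        depth_dispersion=5.0,
        missing_rate=0.02,
        error_rate=0.005,
        seed=seed,
    )


def remigrant_scenario(seed: int = 0) -> SimulationConfig:
    """Baseline variant: the planted same-mother pair is laid in different
    years (a remigrant female) instead of the same season."""
    config = baseline_scenario(seed)
    for spec in config.nests:
        if spec.nest_id == "SN08":
            spec.year = 2021
            spec.emergence_date = date(2021, 10, 6)
    return config


# ---------------------------------------------------------------------------
# Phenology fixtures
# ---------------------------------------------------------------------------

def simulate_sst_and_events(
    seed: int = 0,
    years: tuple[int, int] = (1990, 2019),
    area: str = "Catalano-Balearic",
):
    """Plausible per-year June-July SST and nesting-event counts.

    SST warms slowly over the period around a ~22 degC June-July mean;
    annual event counts increase with SST (zero expected events below the
    21 degC nesting-onset threshold), so the two series are positively
    rank-correlated and events only fall in above-threshold years,
    mimicking the qualitative pattern of Western Mediterranean records.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    yrs = np.arange(years[0], years[1] + 1)
    trend = 21.6 + 0.02 * (yrs - yrs[0])
    sst = trend + rng.normal(0.0, 0.25, size=yrs.size)
    rate = np.where(sst > 21.0, np.exp(-40.0 + 1.85 * sst), 0.0)
    events = rng.poisson(rate)
    sst_df = pd.DataFrame({"year": yrs, "area": area, "mean_sst_c": np.round(sst, 3)})
    events_df = pd.DataFrame({"year": yrs, "n_events": events})
    return events_df, sst_df
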