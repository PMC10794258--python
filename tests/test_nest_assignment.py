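from datetime import date

import numpy as np
import pandas as pd
import pytest

from nestkin.datasets import load_spanish_nest_table
from nestkin.genotype_io import NestRecord, SampleMetadata
from nestkin.kinship_mds import manichaikul_kinship, nest_relatedness_summary
from nestkin.nest_assignment import (
    AssignmentConfig,
    PairEvidence,
    classify_all,
    classify_nest_pair,
    flag_multiple_paternity,
    incubation_range_from_records,
    internesting_window,
    summarize_assignment,
    window_consistent_with_cycles,
)
from nestkin.synthetic_data import (
    ATLANTIC,
    NestSpec,
    SimulationConfig,
    simulate_clutches,
)

from conftest import make_matrix


class TestMultiplePaternityFlag:
    def test_published_nest_means_flag_only_the_low_nest(self):
        """Within-nest mean 0.082 is below sibling grade; 0.235 is not."""
        table = load_spanish_nest_table().dropna(subset=["mean_relatedness"])
        means = pd.Series(
            table["mean_relatedness"].to_numpy(), index=table["nest_id"]
        )
        sizes = dict(zip(table["nest_id"], table["n_samples"].astype(int)))
        flags = flag_multiple_paternity(means, sizes)
        assert flags["SP01"] is True
        assert flags["SP04"] is False
        # SP01 (0.082) is far below sibling grade; all nests at or above
        # half-sib/full-sib midpoint stay unflagged.  SP02's published
        # 0.180 is marginally below the 0.1875 midpoint and is also
        # flagged by the threshold rule.
        assert {n for n, v in flags.items() if v} == {"SP01", "SP02"}

    def test_single_sample_nest_unknown(self):
        flags = flag_multiple_paternity(pd.Series({"N1": np.nan}), {"N1": 1})
        assert flags["N1"] is None

    def test_two_sire_small_nest_flagged_in_most_replicates(self):
        """A two-hatchling nest with two sires holds half sibs: the mean
        within-nest kinship (~0.125) sits well below tau_mp."""
        flagged = 0
        for seed in range(30):
            config = SimulationConfig(
                nests=[NestSpec("N1", "M1", ATLANTIC, 2, 2019, n_fathers=2,
                                haplotype="CC-A2.1")],
                n_loci=2300, error_rate=0.0, missing_rate=0.0, seed=seed,
            )
            matrix, samples, _, _ = simulate_clutches(config)
            means, _ = nest_relatedness_summary(manichaikul_kinship(matrix), samples)
            flagged += flag_multiple_paternity(means, {"N1": 2})["N1"]
        assert flagged >= 27  # >= 90%

    def test_single_sire_clutch_rarely_flagged(self):
        flagged = 0
        for seed in range(30):
            config = SimulationConfig(
                nests=[NestSpec("N1", "M1", ATLANTIC, 7, 2019,
                                haplotype="CC-A2.1")],
                n_loci=2300, error_rate=0.0, missing_rate=0.0, seed=seed,
            )
            matrix, samples, _, _ = simulate_clutches(config)
            means, _ = nest_relatedness_summary(manichaikul_kinship(matrix), samples)
            flagged += flag_multiple_paternity(means, {"N1": 7})["N1"]
        assert flagged <= 3  # not flagged in >= 90%

    def test_two_sire_clutch_mean_depressed_below_single_sire(self):
        """Multiple paternity mixes half sibs into the clutch, lowering the
        mean within-nest kinship below the full-sib expectation."""
        def mean_phi(n_fathers, seed):
            config = SimulationConfig(
                nests=[NestSpec("N1", "M1", ATLANTIC, 8, 2019,
                                n_fathers=n_fathers, haplotype="CC-A2.1")],
                n_loci=2300, error_rate=0.0, missing_rate=0.0, seed=seed,
            )
            matrix, samples, _, _ = simulate_clutches(config)
            means, _ = nest_relatedness_summary(manichaikul_kinship(matrix), samples)
            return means["N1"]

        two = np.mean([mean_phi(2, s) for s in range(10)])
        one = np.mean([mean_phi(1, s) for s in range(10)])
        assert two < one - 0.04
        assert one == pytest.approx(0.25, abs=0.02)


class TestInternestingWindow:
    def test_exact_interval_from_two_laying_dates(self):
        a = NestRecord("A", 2019, laying_date=date(2019, 7, 1))
        b = NestRecord("B", 2019, laying_date=date(2019, 7, 15))
        assert internesting_window(a, b, None) == (14.0, 14.0)
        assert window_consistent_with_cycles((14.0, 14.0), AssignmentConfig())

    def test_window_from_emergence_and_incubation_range(self):
        """Laying day 0, emergence day 85, incubation 47-64 d -> 21-38 d."""
        a = NestRecord("A", 2019, laying_date=date(2019, 7, 13))
        b = NestRecord("B", 2019, emergence_date=date(2019, 10, 6))
        assert internesting_window(a, b, (47, 64)) == (21.0, 38.0)

    def test_degenerate_incubation_range_collapses(self):
        a = NestRecord("A", 2019, laying_date=date(2019, 7, 1))
        b = NestRecord("B", 2019, emergence_date=date(2019, 9, 9))  # day 70
        assert internesting_window(a, b, (55, 55)) == (15.0, 15.0)

    def test_no_usable_dates(self):
        a = NestRecord("A", 2019)
        b = NestRecord("B", 2019, emergence_date=date(2019, 10, 6))
        assert internesting_window(a, b, (47, 64)) is None

    @pytest.mark.parametrize(
        "window,expected",
        [((14, 14), True), ((21, 38), True), ((17, 19), False),
         ((11, 11), False), ((24, 32), True)],
    )
    def test_cycle_consistency(self, window, expected):
        assert window_consistent_with_cycles(window, AssignmentConfig()) is expected

    def test_incubation_range_derived_from_records(self, baseline_run):
        assert incubation_range_from_records(baseline_run["nests"]) == (47, 64)


def _pair_fixture(phi_cross, hap_a="CC-A2.1", hap_b="CC-A2.1",
                  year_a=2019, year_b=2019):
    """Two 2-sample nests with a constant planted cross-nest phi by
    construction of identical/disjoint genotype blocks."""
    # sample pairs engineered so kinship is high within and controllable across
    if phi_cross == "high":
        rows = [[1, 1, 0, 2, 1, 0]] * 4  # identical samples -> phi 0.5 all pairs
    else:
        rows = [
            [1, 1, 0, 2, 1, 0], [1, 1, 0, 2, 1, 0],
            [0, 0, 1, 1, 2, 2], [0, 0, 1, 1, 2, 2],
        ]
    m = make_matrix(rows, sample_ids=["a1", "a2", "b1", "b2"])
    samples = [
        SampleMetadata("a1", "A"), SampleMetadata("a2", "A"),
        SampleMetadata("b1", "B"), SampleMetadata("b2", "B"),
    ]
    nests = {
        "A": NestRecord("A", year_a, haplotype=hap_a,
                        laying_date=date(year_a, 7, 1)),
        "B": NestRecord("B", year_b, haplotype=hap_b,
                        laying_date=date(year_b, 7, 15)),
    }
    return manichaikul_kinship(m), samples, nests


class TestClassifyPair:
    def test_haplotype_mismatch_is_absolute(self):
        """High kinship cannot override an mtDNA exclusion."""
        kin, samples, nests = _pair_fixture("high", hap_a="CC-A1.1",
                                            hap_b="CC-A2.1")
        for config in (
            AssignmentConfig(),
            AssignmentConfig(tau_sib=0.01, tau_mp=0.01),
            AssignmentConfig(cross_nest_test="rank_test"),
        ):
            ev = classify_nest_pair("A", "B", kin, samples, nests, config)
            assert ev.verdict == "different_females"
            assert ev.haplotype_match == "no"
            assert "rule1" in ev.reasons[0]

    def test_matched_haplotype_high_kinship_same_year_renester(self):
        kin, samples, nests = _pair_fixture("high")
        ev = classify_nest_pair("A", "B", kin, samples, nests,
                                AssignmentConfig())
        assert ev.verdict == "same_female_renester"
        assert ev.internesting_window_days == (14.0, 14.0)
        assert ev.window_consistent is True

    def test_matched_haplotype_high_kinship_different_year_remigrant(self):
        kin, samples, nests = _pair_fixture("high", year_b=2021)
        ev = classify_nest_pair("A", "B", kin, samples, nests,
                                AssignmentConfig())
        assert ev.verdict == "same_female_remigrant"

    def test_shared_haplotype_unrelated_different_females(self):
        kin, samples, nests = _pair_fixture("low")
        ev = classify_nest_pair("A", "B", kin, samples, nests,
                                AssignmentConfig())
        assert ev.verdict == "different_females"
        assert any("rule5" in r for r in ev.reasons)

    def test_unknown_haplotype_proceeds_with_warning(self, caplog):
        kin, samples, nests = _pair_fixture("high", hap_a=None)
        nests["A"].haplotype = None
        with caplog.at_level("WARNING"):
            ev = classify_nest_pair("A", "B", kin, samples, nests,
                                    AssignmentConfig())
        assert ev.haplotype_match == "unknown"
        assert ev.verdict == "same_female_renester"

    def test_halfsib_grade_noted(self):
        kin, samples, nests = _pair_fixture("high")
        kin.phi[np.ix_([0, 1], [2, 3])] = 0.1
        kin.phi[np.ix_([2, 3], [0, 1])] = 0.1
        ev = classify_nest_pair("A", "B", kin, samples, nests,
                                AssignmentConfig())
        assert ev.verdict == "different_females"
        assert "possible_same_mother_halfsib" in ev.notes

    def test_unknown_nest_rejected(self):
        kin, samples, nests = _pair_fixture("high")
        with pytest.raises(KeyError):
            classify_nest_pair("A", "NOPE", kin, samples, nests)


class TestEndToEnd:
    def test_planted_renester_recovered(self, baseline_run):
        evidence = classify_all(
            baseline_run["kinship"], baseline_run["samples"], baseline_run["nests"]
        )
        same = [(p.nest_a, p.nest_b, p.verdict) for p in evidence
                if p.verdict.startswith("same_female")]
        assert same == [("SN05", "SN08", "same_female_renester")]
        ev = next(p for p in evidence if (p.nest_a, p.nest_b) == ("SN05", "SN08"))
        assert ev.internesting_window_days == (21.0, 38.0)
        assert ev.window_consistent is True

    def test_rank_test_mode_keeps_planted_pair(self, baseline_run):
        config = AssignmentConfig(cross_nest_test="rank_test",
                                  n_permutations=2000, seed=5)
        evidence = classify_all(
            baseline_run["kinship"], baseline_run["samples"],
            baseline_run["nests"], config,
        )
        same = [(p.nest_a, p.nest_b) for p in evidence
                if p.verdict.startswith("same_female")]
        assert ("SN05", "SN08") in same

    def test_verdicts_invariant_to_sample_order(self, baseline_run):
        m = baseline_run["matrix"]
        shuffled = list(m.sample_ids)
        np.random.default_rng(1).shuffle(shuffled)
        kin2 = manichaikul_kinship(m.subset_samples(shuffled))
        ev1 = classify_all(baseline_run["kinship"], baseline_run["samples"],
                           baseline_run["nests"])
        ev2 = classify_all(kin2, baseline_run["samples"], baseline_run["nests"])
        v1 = {(p.nest_a, p.nest_b): p.verdict for p in ev1}
        v2 = {(p.nest_a, p.nest_b): p.verdict for p in ev2}
        assert v1 == v2


def _evidence(a, b, verdict):
    return PairEvidence(
        nest_a=a, nest_b=b, haplotype_match="yes", cross_phi_median=None,
        cross_phi_min=None, cross_phi_max=None, within_phi_mean_a=None,
        within_phi_mean_b=None, temporal_relation="same_season",
        internesting_window_days=None, window_consistent=None, verdict=verdict,
    )


class TestSummary:
    def test_one_same_female_pair_gives_n_minus_one(self):
        ev = [_evidence("A", "B", "same_female_renester"),
              _evidence("A", "C", "different_females"),
              _evidence("B", "C", "different_females")]
        report = summarize_assignment(ev, {})
        assert report.n_distinct_females == 2

    def test_no_merges_gives_n(self):
        ev = [_evidence("A", "B", "different_females"),
              _evidence("A", "C", "different_females"),
              _evidence("B", "C", "different_females")]
        assert summarize_assignment(ev, {}).n_distinct_females == 3

    def test_inconsistent_triangle_merged_with_warning(self):
        ev = [_evidence("A", "B", "same_female_renester"),
              _evidence("B", "C", "same_female_renester"),
              _evidence("A", "C", "different_females")]
        report = summarize_assignment(ev, {})
        assert report.n_distinct_females == 1
        assert report.warnings

    def test_report_serialization(self, tmp_path, baseline_run):
        evidence = classify_all(
            baseline_run["kinship"], baseline_run["samples"], baseline_run["nests"]
        )
        report = summarize_assignment(evidence, {"SN01": True})
        text = report.to_json(tmp_path / "r.json")
        assert "same_female_renester" in text
        df = report.to_dataframe()
        assert len(df) == 28  # C(8,2) nest pairs
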