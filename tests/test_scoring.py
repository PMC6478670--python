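"""Individual scoring: profile totals, missing-data policies, RR conversion."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import polyrisk as pr


def _profile_at(score_table, pick):
    """Build a profile choosing each factor's level by ``pick(levels)``."""
    return pr.IndividualProfile(
        "p", {f.name: pick(f.levels).label for f in score_table}
    )


class TestScoreIndividual:
    def test_maximum_risk_profile_totals_32(self, scoring_table):
        profile = _profile_at(
            scoring_table, lambda lvs: max(lvs, key=lambda lv: lv.final_score)
        )
        result = pr.score_individual(scoring_table, profile)
        assert result.total_pps == 32.0
        assert result.n_missing == 0

    def test_baseline_profile_totals_minus_9_5(self, scoring_table):
        """Sum of the configured per-factor baseline scores.

        This is the sum of the published baseline rows; it equals the
        configured minimum (-9.5) rather than the separately printed -7.5,
        a discrepancy the package documents rather than resolves.
        """
        profile = pr.IndividualProfile(
            "base",
            {
                "Childhood trauma": "No",
                "Ethnicity": "White",
                "Immigration": "Not immigrant",
                "Premorbid IQ": ">93.6",
                "Non-right handedness": "No",
                "Olfactory identification impairment": "No",
                "Clinical high risk state for psychosis": "<9",
                "Urbanicity": "No",
            },
        )
        result = pr.score_individual(scoring_table, profile)
        assert result.total_pps == -9.5
        assert result.total_pps == scoring_table.min_total

    def test_total_is_sum_of_contributions(self, scoring_table):
        profile = _profile_at(scoring_table, lambda lvs: lvs[0])
        result = pr.score_individual(scoring_table, profile)
        assert result.total_pps == pytest.approx(
            sum(result.per_factor.values()), abs=1e-9
        )
        assert result.equivalent_rr == pytest.approx(
            10 ** (result.total_pps / 10), rel=1e-9
        )

    def test_empty_profile_omit_policy(self, scoring_table):
        result = pr.score_individual(
            scoring_table, pr.IndividualProfile("e"), missing_policy="omit"
        )
        assert result.total_pps == 0.0
        assert result.n_missing == len(scoring_table)

    def test_empty_profile_population_average_policy(self, scoring_table):
        result = pr.score_individual(
            scoring_table, pr.IndividualProfile("e"),
            missing_policy="population_average",
        )
        expected = sum(f.population_mean_final for f in scoring_table)
        assert result.total_pps == pytest.approx(expected, abs=1e-9)
        # population-average imputation stays within rounding of zero
        assert abs(result.total_pps) <= 0.25 * len(scoring_table)

    def test_missing_factor_under_error_policy(self, scoring_table):
        with pytest.raises(pr.ValidationError, match="missing"):
            pr.score_individual(
                scoring_table,
                pr.IndividualProfile("e", {"Urbanicity": "Yes"}),
                missing_policy="error",
            )

    def test_unknown_level_rejected(self, scoring_table):
        with pytest.raises(pr.ValidationError, match="unknown level"):
            pr.score_individual(
                scoring_table, pr.IndividualProfile("e", {"Urbanicity": "Maybe"})
            )

    def test_unknown_factor_rejected(self, scoring_table):
        with pytest.raises(pr.ValidationError, match="unknown factor"):
            pr.score_individual(
                scoring_table, pr.IndividualProfile("e", {"Diet": "Yes"})
            )

    def test_permutation_invariance(self, scoring_table):
        profile = _profile_at(scoring_table, lambda lvs: lvs[-1])
        items = list(profile.assignments.items())
        rng = random.Random(0)
        for _ in range(5):
            rng.shuffle(items)
            shuffled = pr.IndividualProfile("p", dict(items))
            assert (
                pr.score_individual(scoring_table, shuffled).total_pps
                == pr.score_individual(scoring_table, profile).total_pps
            )

    def test_adding_an_exposure_never_lowers_the_total(self, scoring_table):
        """Moving any one factor from baseline to its top level raises S."""
        base = _profile_at(
            scoring_table, lambda lvs: min(lvs, key=lambda lv: lv.final_score)
        )
        base_total = pr.score_individual(scoring_table, base).total_pps
        for f in scoring_table:
            bumped = dict(base.assignments)
            bumped[f.name] = max(f.levels, key=lambda lv: lv.final_score).label
            total = pr.score_individual(
                scoring_table, pr.IndividualProfile("b", bumped)
            ).total_pps
            assert total >= base_total

    def test_plain_mapping_accepted(self, scoring_table):
        result = pr.score_individual(
            scoring_table, {"Urbanicity": "Yes"}, missing_policy="omit"
        )
        assert result.total_pps == 1.0


class TestRRConversion:
    @pytest.mark.parametrize(
        "pps, rr",
        [(0.0, 1.0), (5.0, 3.1623), (10.0, 10.0), (-7.5, 0.17783), (32.0, 1584.89)],
    )
    def test_pps_to_rr_known_values(self, pps, rr):
        assert pr.pps_to_rr(pps) == pytest.approx(rr, rel=1e-4)

    @pytest.mark.parametrize(
        "rr, pps", [(3.0, 4.7712), (30.0, 14.7712), (1.0, 0.0)]
    )
    def test_rr_to_pps_known_values(self, rr, pps):
        assert pr.rr_to_pps(rr) == pytest.approx(pps, abs=1e-4)

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(pr.DomainError):
            pr.rr_to_pps(0.0)

    @given(st.floats(-20, 35))
    def test_exact_inverse_pair(self, pps):
        assert pr.rr_to_pps(pr.pps_to_rr(pps)) == pytest.approx(pps, abs=1e-9)

    @given(st.floats(-20, 34), st.floats(0.01, 5))
    def test_pps_to_rr_strictly_increasing(self, pps, step):
        assert pr.pps_to_rr(pps + step) > pr.pps_to_rr(pps)


class TestProfileIO:
    def test_csv_round_trip(self, scoring_table, tmp_path):
        profiles = [
            pr.IndividualProfile("a", {"Urbanicity": "Yes", "Childhood trauma": "No"}),
            pr.IndividualProfile("b", {"Urbanicity": "No"}),
        ]
        path = tmp_path / "profiles.csv"
        pr.write_profiles(profiles, path, factor_order=scoring_table.names)
        back = pr.read_profiles(path)
        assert [p.id for p in back] == ["a", "b"]
        assert back[0].assignments == profiles[0].assignments
        assert back[1].assignments == profiles[1].assignments

    def test_json_records(self, tmp_path):
        path = tmp_path / "profiles.json"
        path.write_text('[{"id": "x", "Urbanicity": "Yes"}]')
        back = pr.read_profiles(path)
        assert back[0].id == "x"
        assert back[0].assignments == {"Urbanicity": "Yes"}

    def test_empty_profile_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,Urbanicity\n")
        with pytest.raises(pr.ValidationError, match="no individuals"):
            pr.read_profiles(path)

    def test_results_frame_columns(self, scoring_table):
        results = pr.score_cohort(
            scoring_table,
            [pr.IndividualProfile("a", {"Urbanicity": "Yes"})],
            missing_policy="omit",
        )
        frame = pr.results_to_frame(results, per_factor=True)
        assert list(frame.columns[:4]) == ["id", "total_pps", "equivalent_rr", "n_missing"]
        assert frame.loc[0, "score[Urbanicity]"] == 1.0
        assert frame.loc[0, "n_missing"] == len(scoring_table) - 1
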