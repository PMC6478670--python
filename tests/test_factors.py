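"""Factor configuration: validation, serialization, composites, diagnostics."""

import math

import pytest

import polyrisk as pr
from polyrisk.factors import table_to_frame


class TestValidation:
    def test_nonpositive_rr_rejected(self):
        with pytest.raises(pr.ValidationError, match="relative_risk"):
            pr.FactorLevel("x", -1.0, 0.5)

    def test_prevalence_outside_unit_interval_rejected(self):
        with pytest.raises(pr.ValidationError, match="prevalence"):
            pr.FactorLevel("x", 2.0, 1.2)

    def test_component_product_must_match_rr(self):
        with pytest.raises(pr.ValidationError, match="product"):
            pr.FactorLevel("x", 3.0, 0.5, components=(("a", 2.0), ("b", 2.0)))
        # exact product accepted
        pr.FactorLevel("x", 4.0, 0.5, components=(("a", 2.0), ("b", 2.0)))

    def test_prevalences_must_sum_to_one(self):
        with pytest.raises(pr.ValidationError, match="sum"):
            pr.RiskFactor(
                "f",
                (pr.FactorLevel("a", 2.0, 0.5), pr.FactorLevel("b", 1.0, 0.4)),
                baseline_label="b",
            )

    def test_duplicate_level_labels_rejected(self):
        with pytest.raises(pr.ValidationError, match="duplicate"):
            pr.RiskFactor(
                "f",
                (pr.FactorLevel("a", 2.0, 0.5), pr.FactorLevel("a", 1.0, 0.5)),
                baseline_label="a",
            )

    def test_baseline_must_exist(self):
        with pytest.raises(pr.ValidationError, match="baseline"):
            pr.RiskFactor(
                "f",
                (pr.FactorLevel("a", 2.0, 0.5), pr.FactorLevel("b", 1.0, 0.5)),
                baseline_label="zzz",
            )

    def test_factor_names_unique(self, urbanicity):
        with pytest.raises(pr.ValidationError, match="unique"):
            pr.FactorTable(factors=(urbanicity, urbanicity))


class TestSerialization:
    def test_shipped_default_has_eight_factor_groups(self):
        table = pr.load_factor_table(pr.default_config_path())
        assert len(table) == 8
        assert table.names == pr.default_factor_table().names

    def test_shipped_file_matches_programmatic_table(self, default_table):
        loaded = pr.load_factor_table(pr.default_config_path())
        for f0, f1 in zip(default_table, loaded):
            assert f0.baseline_label == f1.baseline_label
            for l0, l1 in zip(f0.levels, f1.levels):
                assert l0 == l1

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_round_trip_lossless(self, default_table, tmp_path, fmt):
        path = tmp_path / f"table.{fmt}"
        pr.save_factor_table(default_table, path)
        back = pr.load_factor_table(path)
        for f0, f1 in zip(default_table, back):
            assert f0.levels == f1.levels
            assert f0.baseline_label == f1.baseline_label
            assert f0.evidence_class == f1.evidence_class

    def test_single_factor_csv(self, tmp_path):
        path = tmp_path / "urb.csv"
        path.write_text(
            "factor,level,relative_risk,prevalence,baseline\n"
            "Urbanicity,Yes,2.2,0.736,False\n"
            "Urbanicity,No,1.0,0.264,True\n"
        )
        table = pr.load_factor_table(path)
        assert len(table) == 1
        assert table.factor("Urbanicity").labels == ("Yes", "No")
        assert table.factor("Urbanicity").level("Yes").relative_risk == 2.2

    def test_bad_prevalence_sum_raises_validation_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "factor,level,relative_risk,prevalence,baseline\n"
            "f,a,2.0,0.5,False\nf,b,1.0,0.4,True\n"
        )
        with pytest.raises(pr.ValidationError, match="sum"):
            pr.load_factor_table(path)

    def test_missing_column_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("factor,level\nf,a\n")
        with pytest.raises(pr.ConfigParseError, match="missing required columns"):
            pr.load_factor_table(path)

    def test_malformed_json_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(pr.ConfigParseError, match="invalid JSON"):
            pr.load_factor_table(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(pr.ConfigParseError, match="not found"):
            pr.load_factor_table(tmp_path / "nope.json")

    def test_frame_has_one_row_per_level(self, default_table):
        frame = table_to_frame(default_table)
        assert len(frame) == sum(len(f.levels) for f in default_table)


class TestCompositeFactors:
    def test_immigration_block_has_five_levels(self, default_table):
        imm = default_table.factor("Immigration")
        assert len(imm.levels) == 5
        assert imm.baseline_label == "Not immigrant"
        assert imm.labels == (
            "Not immigrant",
            "1st generation, from North Africa",
            "1st generation, from other regions",
            "2nd generation, from North Africa",
            "2nd generation, from other regions",
        )

    def test_ethnicity_block_has_seven_levels(self, default_table):
        eth = default_table.factor("Ethnicity")
        assert len(eth.levels) == 7
        assert eth.baseline_label == "White"

    def test_composite_prevalences_sum_to_one(self, default_table):
        for name in ("Immigration", "Ethnicity"):
            total = sum(lv.prevalence for lv in default_table.factor(name).levels)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_log_additivity_of_shipped_composites(self, default_table):
        """Composite log-RR equals the sum of component log-RRs."""
        for name in ("Immigration", "Ethnicity"):
            for lv in default_table.factor(name).levels:
                assert lv.components is not None
                assert math.log10(lv.relative_risk) == pytest.approx(
                    sum(math.log10(r) for _, r in lv.components), abs=1e-9
                )

    def test_extra_risk_equal_across_generations(self, default_table):
        """North-Africa origin multiplies both generations' RR equally."""
        imm = default_table.factor("Immigration")
        rr = {lv.label: lv.relative_risk for lv in imm.levels}
        first = rr["1st generation, from North Africa"] / rr["1st generation, from other regions"]
        second = rr["2nd generation, from North Africa"] / rr["2nd generation, from other regions"]
        assert first == pytest.approx(second, rel=1e-12)

    def test_single_component_passes_through(self, urbanicity):
        out = pr.build_composite_factor(
            "Urbanicity", [urbanicity], {"Yes": 0.736, "No": 0.264}
        )
        assert out.labels == urbanicity.labels
        assert out.baseline_label == urbanicity.baseline_label
        for a, b in zip(out.levels, urbanicity.levels):
            assert a.relative_risk == b.relative_risk
            assert a.prevalence == b.prevalence
            assert a.components is None

    def _components(self):
        gen = pr.RiskFactor(
            "generation",
            (
                pr.FactorLevel("none", 1.0, 0.8),
                pr.FactorLevel("1st", 2.0, 0.1),
                pr.FactorLevel("2nd", 1.5, 0.1),
            ),
            baseline_label="none",
        )
        origin = pr.RiskFactor(
            "origin",
            (pr.FactorLevel("NA", 1.3, 0.1), pr.FactorLevel("other", 1.0, 0.9)),
            baseline_label="other",
        )
        return gen, origin

    def test_missing_joint_prevalence_is_an_error(self):
        gen, origin = self._components()
        with pytest.raises(pr.ValidationError, match="missing"):
            pr.build_composite_factor(
                "imm", [gen, origin],
                {("none",): 0.8, ("1st", "NA"): 0.1, ("1st", "other"): 0.1},
                collapse={"none"},
            )

    def test_prevalence_for_excluded_combination_is_an_error(self):
        gen, origin = self._components()
        joint = {
            ("none",): 0.7,
            ("none", "NA"): 0.1,  # excluded: collapsed level crossed anyway
            ("1st", "NA"): 0.02, ("1st", "other"): 0.08,
            ("2nd", "NA"): 0.02, ("2nd", "other"): 0.08,
        }
        with pytest.raises(pr.ValidationError, match="excluded"):
            pr.build_composite_factor("imm", [gen, origin], joint, collapse={"none"})

    def test_composite_rr_is_product(self):
        gen, origin = self._components()
        out = pr.build_composite_factor(
            "imm", [gen, origin],
            {
                ("none",): 0.8,
                ("1st", "NA"): 0.01, ("1st", "other"): 0.09,
                ("2nd", "NA"): 0.01, ("2nd", "other"): 0.09,
            },
            collapse={"none"},
        )
        assert out.level("1st, NA").relative_risk == pytest.approx(2.6)
        assert out.level("2nd, other").relative_risk == pytest.approx(1.5)

    def test_overlapping_component_labels_rejected(self, urbanicity):
        with pytest.raises(pr.ValidationError, match="overlapping"):
            pr.build_composite_factor(
                "x", [urbanicity, urbanicity], {}, collapse={"No"}
            )


class TestProfileSupport:
    def test_valid_profile_has_no_problems(self, default_table):
        profile = pr.IndividualProfile(
            "p1", {"Childhood trauma": "Yes", "Urbanicity": "No"}
        )
        assert pr.validate_profile_support(default_table, profile) == []

    def test_unknown_factor_reported(self, default_table):
        problems = pr.validate_profile_support(default_table, {"Diet": "Yes"})
        assert problems == ["unknown factor: Diet"]

    def test_unknown_level_reported(self, default_table):
        problems = pr.validate_profile_support(
            default_table, {"Urbanicity": "Maybe"}
        )
        assert len(problems) == 1
        assert problems[0].startswith("unknown level 'Maybe'")
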