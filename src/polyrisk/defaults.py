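"""Shipped default factor configuration for the psychosis polyrisk score.

Eight factor groups, all umbrella-review class I–III and pragmatically
measurable: childhood trauma, ethnicity × ethnic density, immigration
(generation × region of origin), premorbid IQ, non-right-handedness,
olfactory identification impairment, clinical-high-risk screening status,
and urbanicity.  Odds ratios from the umbrella-review evidence base are
used in the relative-risk role throughout, and protective factors
(olfactory identification OR 0.19, premorbid IQ OR 0.47) are re-oriented so
the scored level is the risk-increasing direction (RR 1/0.19 and 1/0.47).

Prevalence provenance: only the urbanicity prevalence (73.6% urban) is a
published value.  The remaining prevalences are reconstructed by inverting
the published final scores — for each factor the baseline score pins the
prevalence-weighted mean raw score to an interval of width ±0.25/10 on the
log10 scale, and a realistic value is chosen inside that interval (see
docs/methods.md for each choice).  They are therefore approximate, flagged
as such in the table's provenance, and swappable: scoring individuals does
not depend on them, only centering, the population distribution and the
missing-data imputation do.

Composite relative risks are pinned by the published score differences to
exact powers of ten (e.g. black Caribbean in a low ethnic-density area:
10^0.8 ≈ 6.31); component RRs keep the published marginal effect where one
exists (black Caribbean OR 4.87) and carry the residual as the partner
component's multiplier.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .factors import FactorLevel, FactorTable, RiskFactor, build_composite_factor

__all__ = [
    "default_factor_table",
    "default_config_path",
    "TABLE2_FINAL_SCORES",
]

PROVENANCE = (
    "polyrisk default configuration v1; umbrella-review odds ratios used as "
    "relative risks; prevalences approximate (reconstructed from the "
    "published scoring table, urbanicity prevalence printed)"
)

#: the published final scores the default configuration reproduces,
#: factor -> level -> score
TABLE2_FINAL_SCORES: dict[str, dict[str, float]] = {
    "Childhood trauma": {"Yes": 4.0, "No": -0.5},
    "Ethnicity": {
        "White": -2.0,
        "Black Caribbean, low ethnic density": 6.0,
        "Black Caribbean, medium ethnic density": 5.5,
        "Black Caribbean, high ethnic density": 3.5,
        "Other non-white, low ethnic density": 3.5,
        "Other non-white, medium ethnic density": 3.0,
        "Other non-white, high ethnic density": 1.0,
    },
    "Immigration": {
        "Not immigrant": -0.5,
        "1st generation, from North Africa": 3.0,
        "1st generation, from other regions": 2.0,
        "2nd generation, from North Africa": 2.5,
        "2nd generation, from other regions": 1.5,
    },
    "Premorbid IQ": {"<93.6": 2.0, ">93.6": -1.0},
    "Non-right handedness": {"Yes": 2.0, "No": 0.0},
    "Olfactory identification impairment": {"Yes": 5.5, "No": -1.5},
    "Clinical high risk state for psychosis": {">9": 8.5, "<9": -1.5},
    "Urbanicity": {"Yes": 1.0, "No": -2.5},
}


def _two_level(
    name: str,
    exposed_label: str,
    baseline_label: str,
    rr: float,
    prevalence: float,
    **meta: str,
) -> RiskFactor:
    return RiskFactor(
        name=name,
        levels=(
            FactorLevel(exposed_label, rr, prevalence),
            FactorLevel(baseline_label, 1.0, 1.0 - prevalence),
        ),
        baseline_label=baseline_label,
        **meta,
    )


def _ethnicity_factor() -> RiskFactor:
    # Component RRs: black Caribbean keeps its published OR 4.87; "other
    # non-white" is the residual 4.87/10^0.25 ≈ 2.74 implied by the constant
    # 2.5-point gap between the two blocks; ethnic-density multipliers carry
    # the rest so each composite RR is the exact power of ten the published
    # scores pin down.  The black Caribbean share of the non-white population
    # is assumed equal across density strata (0.2), with the non-white
    # population split 0.2/0.3/0.5 over low/medium/high density areas.
    bc = 4.87
    ethnicity = RiskFactor(
        name="ethnic group",
        levels=(
            FactorLevel("White", 1.0, 0.60),
            FactorLevel("Black Caribbean", bc, 0.08),
            FactorLevel("Other non-white", bc / 10**0.25, 0.32),
        ),
        baseline_label="White",
    )
    density = RiskFactor(
        name="ethnic density",
        levels=(
            FactorLevel("low ethnic density", 10**0.80 / bc, 0.20),
            FactorLevel("medium ethnic density", 10**0.75 / bc, 0.30),
            FactorLevel("high ethnic density", 10**0.55 / bc, 0.50),
        ),
        baseline_label="high ethnic density",
    )
    joint = {
        ("White",): 0.60,
        ("Black Caribbean", "low ethnic density"): 0.016,
        ("Black Caribbean", "medium ethnic density"): 0.024,
        ("Black Caribbean", "high ethnic density"): 0.040,
        ("Other non-white", "low ethnic density"): 0.064,
        ("Other non-white", "medium ethnic density"): 0.096,
        ("Other non-white", "high ethnic density"): 0.160,
    }
    return build_composite_factor(
        "Ethnicity",
        [ethnicity, density],
        joint,
        collapse={"White"},
        evidence_class="I",
        instrument="Self-defined",
        cutoff="Non-white ethnicity",
    )


def _immigration_factor() -> RiskFactor:
    # Generation RRs 10^0.25 (1st) and 10^0.2 (2nd); the North-Africa origin
    # multiplier 10^0.1 is assumed equal across generations (the 1st-gen
    # North African product 10^0.35 ≈ 2.24 matches the published North
    # African OR 2.22).  20% immigrants, split evenly between generations,
    # with a 10% North African share in each.
    generation = RiskFactor(
        name="immigrant generation",
        levels=(
            FactorLevel("Not immigrant", 1.0, 0.80),
            FactorLevel("1st generation", 10**0.25, 0.10),
            FactorLevel("2nd generation", 10**0.20, 0.10),
        ),
        baseline_label="Not immigrant",
    )
    origin = RiskFactor(
        name="region of origin",
        levels=(
            FactorLevel("from North Africa", 10**0.10, 0.10),
            FactorLevel("from other regions", 1.0, 0.90),
        ),
        baseline_label="from other regions",
    )
    joint = {
        ("Not immigrant",): 0.80,
        ("1st generation", "from North Africa"): 0.01,
        ("1st generation", "from other regions"): 0.09,
        ("2nd generation", "from North Africa"): 0.01,
        ("2nd generation", "from other regions"): 0.09,
    }
    return build_composite_factor(
        "Immigration",
        [generation, origin],
        joint,
        collapse={"Not immigrant"},
        evidence_class="II",
        instrument="Self-defined",
        cutoff="First- or second-generation",
    )


def default_factor_table() -> FactorTable:
    """Build the shipped 8-factor-group default configuration."""
    factors = (
        _two_level(
            "Childhood trauma",
            "Yes",
            "No",
            2.87,
            0.109,
            evidence_class="III",
            instrument="Childhood trauma questionnaire",
            cutoff="Moderate to severe",
        ),
        _ethnicity_factor(),
        _immigration_factor(),
        _two_level(
            "Premorbid IQ",
            "<93.6",
            ">93.6",
            1.0 / 0.47,
            0.335,
            evidence_class="II",
            instrument="National adult reading test",
            cutoff="<93.6",
        ),
        _two_level(
            "Non-right handedness",
            "Yes",
            "No",
            1.58,
            0.10,
            evidence_class="II",
            instrument="Self-defined",
            cutoff="Non-right handedness",
        ),
        _two_level(
            "Olfactory identification impairment",
            "Yes",
            "No",
            1.0 / 0.19,
            0.22,
            evidence_class="II",
            instrument="University of Pennsylvania smell identification test",
            cutoff="Mild microsmia",
        ),
        _two_level(
            "Clinical high risk state for psychosis",
            ">9",
            "<9",
            9.32,
            0.14,
            evidence_class="I",
            instrument="Prodromal questionnaire (16-item version)",
            cutoff=">9",
        ),
        _two_level(
            "Urbanicity",
            "Yes",
            "No",
            2.2,
            0.736,
            evidence_class="I",
            instrument="Population density of local authority",
            cutoff="Majority of population in an urban center of >=50,000",
        ),
    )
    return FactorTable(factors=factors, provenance=PROVENANCE)


def default_config_path() -> Path:
    """Path of the packaged default configuration JSON file."""
    return Path(resources.files("polyrisk").joinpath("data/pps_default.json"))
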