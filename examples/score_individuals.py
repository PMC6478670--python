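"""Score individual factor profiles, including partial ones.

A profile maps factor names to level labels; unassessed factors can be
imputed at the population average (the zero-information value under the
centering construction), omitted, or treated as an error.
"""

import polyrisk as pr

table = pr.build_scoring_table(pr.default_factor_table())

people = [
    pr.IndividualProfile(
        "urban-trauma",
        {
            "Childhood trauma": "Yes",
            "Ethnicity": "White",
            "Immigration": "Not immigrant",
            "Premorbid IQ": ">93.6",
            "Non-right handedness": "No",
            "Olfactory identification impairment": "No",
            "Clinical high risk state for psychosis": "<9",
            "Urbanicity": "Yes",
        },
    ),
    # a screening-stage profile: only the self-reported factors are known
    pr.IndividualProfile(
        "screen-only",
        {"Childhood trauma": "Yes", "Urbanicity": "Yes", "Immigration": "1st generation, from other regions"},
    ),
]

for person in people:
    result = pr.score_individual(table, person, missing_policy="population_average")
    print(f"{person.id}: total score {result.total_pps:+.2f} "
          f"(equivalent RR {result.equivalent_rr:.2f}, "
          f"{result.n_missing} factor(s) imputed)")

print("\nAn equivalent RR above 1 means more risk than the population average;")
print(f"a total of +5 equals RR {pr.pps_to_rr(5):.2f}, +10 equals RR {pr.pps_to_rr(10):.0f}.")
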