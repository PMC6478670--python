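{
  "provenance": "polyrisk default configuration v1; umbrella-review odds ratios used as relative risks; prevalences approximate (reconstructed from the published scoring table, urbanicity prevalence printed)",
  "factors": [
    {
      "name": "Childhood trauma",
      "baseline": "No",
      "evidence_class": "III",
      "instrument": "Childhood trauma questionnaire",
      "cutoff": "Moderate to severe",
      "levels": [
        {
          "label": "Yes",
          "relative_risk": 2.87,
          "prevalence": 0.109
        },
        {
          "label": "No",
          "relative_risk": 1.0,
          "prevalence": 0.891
        }
      ]
    },
    {
      "name": "Ethnicity",
      "baseline": "White",
      "evidence_class": "I",
      "instrument": "Self-defined",
      "cutoff": "Non-white ethnicity",
      "levels": [
        {
          "label": "White",
          "relative_risk": 1.0,
          "prevalence": 0.6,
          "components": [
            [
              "ethnic group:White",
              1.0
            ]
          ]
        },
        {
          "label": "Black Caribbean, low ethnic density",
          "relative_risk": 6.309573444801933,
          "prevalence": 0.016,
          "components": [
            [
              "ethnic group:Black Caribbean",
              4.87
            ],
            [
              "ethnic density:low ethnic density",
              1.2956002966739082
            ]
          ]
        },
        {
          "label": "Black Caribbean, medium ethnic density",
          "relative_risk": 5.623413251903491,
          "prevalence": 0.024,
          "components": [
            [
              "ethnic group:Black Caribbean",
              4.87
            ],
            [
              "ethnic density:medium ethnic density",
              1.1547049798569797
            ]
          ]
        },
        {
          "label": "Black Caribbean, high ethnic density",
          "relative_risk": 3.548133892335755,
          "prevalence": 0.04,
          "components": [
            [
              "ethnic group:Black Caribbean",
              4.87
            ],
            [
              "ethnic density:high ethnic density",
              0.728569587748615
            ]
          ]
        },
        {
          "label": "Other non-white, low ethnic density",
          "relative_risk": 3.548133892335755,
          "prevalence": 0.064,
          "components": [
            [
              "ethnic group:Other non-white",
              2.738602253677
            ],
            [
              "ethnic density:low ethnic density",
              1.2956002966739082
            ]
          ]
        },
        {
          "label": "Other non-white, medium ethnic density",
          "relative_risk": 3.1622776601683795,
          "prevalence": 0.096,
          "components": [
            [
              "ethnic group:Other non-white",
              2.738602253677
            ],
            [
              "ethnic density:medium ethnic density",
              1.1547049798569797
            ]
          ]
        },
        {
          "label": "Other non-white, high ethnic density",
          "relative_risk": 1.99526231496888,
          "prevalence": 0.16,
          "components": [
            [
              "ethnic group:Other non-white",
              2.738602253677
            ],
            [
              "ethnic density:high ethnic density",
              0.728569587748615
            ]
          ]
        }
      ]
    },
    {
      "name": "Immigration",
      "baseline": "Not immigrant",
      "evidence_class": "II",
      "instrument": "Self-defined",
      "cutoff": "First- or second-generation",
      "levels": [
        {
          "label": "Not immigrant",
          "relative_risk": 1.0,
          "prevalence": 0.8,
          "components": [
            [
              "immigrant generation:Not immigrant",
              1.0
            ]
          ]
        },
        {
          "label": "1st generation, from North Africa",
          "relative_risk": 2.23872113856834,
          "prevalence": 0.01,
          "components": [
            [
              "immigrant generation:1st generation",
              1.7782794100389228
            ],
            [
              "region of origin:from North Africa",
              1.2589254117941673
            ]
          ]
        },
        {
          "label": "1st generation, from other regions",
          "relative_risk": 1.7782794100389228,
          "prevalence": 0.09,
          "components": [
            [
              "immigrant generation:1st generation",
              1.7782794100389228
            ],
            [
              "region of origin:from other regions",
              1.0
            ]
          ]
        },
        {
          "label": "2nd generation, from North Africa",
          "relative_risk": 1.99526231496888,
          "prevalence": 0.01,
          "components": [
            [
              "immigrant generation:2nd generation",
              1.5848931924611136
            ],
            [
              "region of origin:from North Africa",
              1.2589254117941673
            ]
          ]
        },
        {
          "label": "2nd generation, from other regions",
          "relative_risk": 1.5848931924611136,
          "prevalence": 0.09,
          "components": [
            [
              "immigrant generation:2nd generation",
              1.5848931924611136
            ],
            [
              "region of origin:from other regions",
              1.0
            ]
          ]
        }
      ]
    },
    {
      "name": "Premorbid IQ",
      "baseline": ">93.6",
      "evidence_class": "II",
      "instrument": "National adult reading test",
      "cutoff": "<93.6",
      "levels": [
        {
          "label": "<93.6",
          "relative_risk": 2.127659574468085,
          "prevalence": 0.335
        },
        {
          "label": ">93.6",
          "relative_risk": 1.0,
          "prevalence": 0.665
        }
      ]
    },
    {
      "name": "Non-right handedness",
      "baseline": "No",
      "evidence_class": "II",
      "instrument": "Self-defined",
      "cutoff": "Non-right handedness",
      "levels": [
        {
          "label": "Yes",
          "relative_risk": 1.58,
          "prevalence": 0.1
        },
        {
          "label": "No",
          "relative_risk": 1.0,
          "prevalence": 0.9
        }
      ]
    },
    {
      "name": "Olfactory identification impairment",
      "baseline": "No",
      "evidence_class": "II",
      "instrument": "University of Pennsylvania smell identification test",
      "cutoff": "Mild microsmia",
      "levels": [
        {
          "label": "Yes",
          "relative_risk": 5.2631578947368425,
          "prevalence": 0.22
        },
        {
          "label": "No",
          "relative_risk": 1.0,
          "prevalence": 0.78
        }
      ]
    },
    {
      "name": "Clinical high risk state for psychosis",
      "baseline": "<9",
      "evidence_class": "I",
      "instrument": "Prodromal questionnaire (16-item version)",
      "cutoff": ">9",
      "levels": [
        {
          "label": ">9",
          "relative_risk": 9.32,
          "prevalence": 0.14
        },
        {
          "label": "<9",
          "relative_risk": 1.0,
          "prevalence": 0.86
        }
      ]
    },
    {
      "name": "Urbanicity",
      "baseline": "No",
      "evidence_class": "I",
      "instrument": "Population density of local authority",
      "cutoff": "Majority of population in an urban center of >=50,000",
      "levels": [
        {
          "label": "Yes",
          "relative_risk": 2.2,
          "prevalence": 0.736
        },
        {
          "label": "No",
          "relative_risk": 1.0,
          "prevalence": 0.264
        }
      ]
    }
  ]
}
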