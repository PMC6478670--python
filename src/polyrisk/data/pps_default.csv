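factor,level,relative_risk,prevalence,baseline,evidence_class,instrument,cutoff,components
Childhood trauma,Yes,2.87,0.109,False,III,Childhood trauma questionnaire,Moderate to severe,
Childhood trauma,No,1.0,0.891,True,III,Childhood trauma questionnaire,Moderate to severe,
Ethnicity,White,1.0,0.6,True,I,Self-defined,Non-white ethnicity,ethnic group:White=1.0
Ethnicity,"Black Caribbean, low ethnic density",6.309573444801933,0.016,False,I,Self-defined,Non-white ethnicity,ethnic group:Black Caribbean=4.87|ethnic density:low ethnic density=1.2956002966739082
Ethnicity,"Black Caribbean, medium ethnic density",5.623413251903491,0.024,False,I,Self-defined,Non-white ethnicity,ethnic group:Black Caribbean=4.87|ethnic density:medium ethnic density=1.1547049798569797
Ethnicity,"Black Caribbean, high ethnic density",3.548133892335755,0.04,False,I,Self-defined,Non-white ethnicity,ethnic group:Black Caribbean=4.87|ethnic density:high ethnic density=0.728569587748615
Ethnicity,"Other non-white, low ethnic density",3.548133892335755,0.064,False,I,Self-defined,Non-white ethnicity,ethnic group:Other non-white=2.738602253677|ethnic density:low ethnic density=1.2956002966739082
Ethnicity,"Other non-white, medium ethnic density",3.1622776601683795,0.096,False,I,Self-defined,Non-white ethnicity,ethnic group:Other non-white=2.738602253677|ethnic density:medium ethnic density=1.1547049798569797
Ethnicity,"Other non-white, high ethnic density",1.99526231496888,0.16,False,I,Self-defined,Non-white ethnicity,ethnic group:Other non-white=2.738602253677|ethnic density:high ethnic density=0.728569587748615
Immigration,Not immigrant,1.0,0.8,True,II,Self-defined,First- or second-generation,immigrant generation:Not immigrant=1.0
Immigration,"1st generation, from North Africa",2.23872113856834,0.01,False,II,Self-defined,First- or second-generation,immigrant generation:1st generation=1.7782794100389228|region of origin:from North Africa=1.2589254117941673
Immigration,"1st generation, from other regions",1.7782794100389228,0.09,False,II,Self-defined,First- or second-generation,immigrant generation:1st generation=1.7782794100389228|region of origin:from other regions=1.0
Immigration,"2nd generation, from North Africa",1.99526231496888,0.01,False,II,Self-defined,First- or second-generation,immigrant generation:2nd generation=1.5848931924611136|region of origin:from North Africa=1.2589254117941673
Immigration,"2nd generation, from other regions",1.5848931924611136,0.09,False,II,Self-defined,First- or second-generation,immigrant generation:2nd generation=1.5848931924611136|region of origin:from other regions=1.0
Premorbid IQ,<93.6,2.127659574468085,0.335,False,II,National adult reading test,<93.6,
Premorbid IQ,>93.6,1.0,0.665,True,II,National adult reading test,<93.6,
Non-right handedness,Yes,1.58,0.1,False,II,Self-defined,Non-right handedness,
Non-right handedness,No,1.0,0.9,True,II,Self-defined,Non-right handedness,
Olfactory identification impairment,Yes,5.2631578947368425,0.22,False,II,University of Pennsylvania smell identification test,Mild microsmia,
Olfactory identification impairment,No,1.0,0.78,True,II,University of Pennsylvania smell identification test,Mild microsmia,
Clinical high risk state for psychosis,>9,9.32,0.14,False,I,Prodromal questionnaire (16-item version),>9,
Clinical high risk state for psychosis,<9,1.0,0.86,True,I,Prodromal questionnaire (16-item version),>9,
Urbanicity,Yes,2.2,0.736,False,I,Population density of local authority,"Majority of population in an urban center of >=50,000",
Urbanicity,No,1.0,0.264,True,I,Population density of local authority,"Majority of population in an urban center of >=50,000",
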