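# SYNTHETIC per-category rubric annotations. The published keyword tables
# print only total I-scale scores; these category breakdowns are
# reconstructions consistent with the rubric's point-assignment rules
# (e.g. "COVID" generic=1, "coronavirus bill gates" misinformative=1,
# "coronavirus laboratory" misinformative=2, country names discriminatory=1).
# Row totals match the published scores exactly.
moniker,generic,misinformative,discriminatory,deviant,other
coronavirus,2,1,0,1,0
corona,2,2,2,2,0
COVID,1,0,0,0,0
virus,2,2,0,2,0
corona virus,2,2,0,2,1
coronavirus Italy,1,1,1,1,0
COVID-19,0,0,0,0,0
coronavirus USA,1,1,1,1,0
coronavirus China,1,2,1,2,0
coronavirus Germany,1,1,1,1,0
corona Italy,2,2,1,2,0
corona Deutschland,2,2,1,2,0
SARS,2,1,0,2,0
corona China,2,2,1,2,2
corona Wuhan,2,2,1,2,2
SARS-CoV-2,0,0,0,0,0
coronavirus ozone,0,2,0,1,2
coronavirus laboratory,1,2,2,2,2
coronavirus 5G,2,2,0,2,2
coronavirus conspiracy,1,2,2,2,2
coronavirus bill gates,1,1,0,2,2
coronavirus milk,2,2,0,2,2
coronavirus military,0,2,2,2,2
coronavirus uv,0,2,0,2,1
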