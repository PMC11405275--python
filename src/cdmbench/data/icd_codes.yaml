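# ICD-9 / ICD-10 diagnosis code prefixes per target pathology, used to
# filter candidate admissions.  Matching strips dots and compares by
# prefix.  Seeded from the standard code families (K35/540 appendicitis,
# K81/575 cholecystitis, K57/562 diverticular disease, K85/577.0
# pancreatitis); replaceable configuration.
appendicitis:
  icd9: ["540", "541", "542"]
  icd10: ["K35", "K36", "K37"]
cholecystitis:
  icd9: ["5750", "5751"]
  icd10: ["K81"]
diverticulitis:
  icd9: ["562"]
  icd10: ["K57"]
pancreatitis:
  icd9: ["5770"]
  icd10: ["K85"]
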