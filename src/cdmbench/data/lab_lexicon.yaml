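# Laboratory test synonym dictionary and panel definitions.
# Canonical test name -> list of accepted synonyms/abbreviations.
# This is a reconstruction seeded with standard clinical vocabulary and is
# meant to be edited/replaced; matching is case- and punctuation-insensitive.
tests:
  white blood cell count: [wbc, white blood cells, leukocytes, leukocyte count, white count]
  c-reactive protein: [crp]
  hemoglobin: [hgb, hb]
  hematocrit: [hct]
  platelet count: [platelets, plt]
  sodium: [na, serum sodium]
  potassium: [k, serum potassium]
  chloride: [cl]
  bicarbonate: [hco3, co2, carbon dioxide]
  blood urea nitrogen: [bun, urea nitrogen]
  creatinine: [creat, serum creatinine]
  glucose: [blood sugar, blood glucose]
  calcium: [ca, serum calcium]
  total bilirubin: [bilirubin, tbili, bilirubin total]
  alkaline phosphatase: [alp, alk phos]
  aspartate aminotransferase: [ast, sgot]
  alanine aminotransferase: [alt, sgpt]
  gamma-glutamyl transferase: [ggt, gamma gt]
  albumin: []
  lipase: []
  amylase: []
  lactate: [lactic acid]
  urine ph: []
  urine white blood cells: [urine wbc, urine leukocytes]
  blood culture: [blood cultures]

panels:
  complete blood count: [white blood cell count, hemoglobin, hematocrit, platelet count]
  cbc: [white blood cell count, hemoglobin, hematocrit, platelet count]
  basic metabolic panel: [sodium, potassium, chloride, bicarbonate, blood urea nitrogen, creatinine, glucose, calcium]
  bmp: [sodium, potassium, chloride, bicarbonate, blood urea nitrogen, creatinine, glucose, calcium]
  liver function panel: [total bilirubin, alkaline phosphatase, aspartate aminotransferase, alanine aminotransferase, gamma-glutamyl transferase, albumin]
  liver function tests: [total bilirubin, alkaline phosphatase, aspartate aminotransferase, alanine aminotransferase, gamma-glutamyl transferase, albumin]
  lfts: [total bilirubin, alkaline phosphatase, aspartate aminotransferase, alanine aminotransferase, gamma-glutamyl transferase, albumin]
  renal function panel: [blood urea nitrogen, creatinine]
  urinalysis: [urine ph, urine white blood cells]
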