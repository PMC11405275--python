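# Standard adult reference ranges for the shipped test vocabulary,
# used by the synthetic-case generator and the interpretation task.
# test -> [low, high, unit]
white blood cell count: [4.0, 11.0, "K/uL"]
c-reactive protein: [0.0, 5.0, "mg/L"]
hemoglobin: [12.0, 17.0, "g/dL"]
hematocrit: [36.0, 50.0, "%"]
platelet count: [150.0, 400.0, "K/uL"]
sodium: [135.0, 145.0, "mEq/L"]
potassium: [3.5, 5.0, "mEq/L"]
chloride: [98.0, 107.0, "mEq/L"]
bicarbonate: [22.0, 29.0, "mEq/L"]
blood urea nitrogen: [7.0, 20.0, "mg/dL"]
creatinine: [0.5, 1.2, "mg/dL"]
glucose: [70.0, 100.0, "mg/dL"]
calcium: [8.5, 10.5, "mg/dL"]
total bilirubin: [0.2, 1.2, "mg/dL"]
alkaline phosphatase: [40.0, 130.0, "U/L"]
aspartate aminotransferase: [10.0, 40.0, "U/L"]
alanine aminotransferase: [7.0, 56.0, "U/L"]
gamma-glutamyl transferase: [8.0, 61.0, "U/L"]
albumin: [3.5, 5.0, "g/dL"]
lipase: [13.0, 60.0, "U/L"]
amylase: [30.0, 110.0, "U/L"]
lactate: [0.5, 2.0, "mmol/L"]
urine ph: [5.0, 8.0, ""]
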