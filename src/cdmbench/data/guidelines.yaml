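# Diagnostic and treatment guideline rules per pathology.
#
# lab_categories: required diagnostic-test categories; a category is met
#   when at least one member test was requested.  Category membership is
#   a reconstruction seeded from the standard guideline tests (signs of
#   inflammation; liver/gallbladder function; pancreas enzymes;
#   pancreatitis severity) and is meant to be replaceable.
# essential_treatments: expected for every correctly diagnosed patient.
# case_specific_treatments: expected only when the patient actually
#   received the matching procedure (keyword/code predicates below).
# support_mode: "any" = mention of fluids OR pain management OR
#   monitoring suffices; "all" = all three are required.
pathologies:
  appendicitis:
    lab_categories:
      inflammation: [white blood cell count, c-reactive protein]
    essential_treatments: [antibiotics, support]
    case_specific_treatments:
      appendectomy:
        procedure_keywords: [appendectomy, appendicectomy]
        procedure_codes: ["470", "471", "0DTJ", "0DBJ"]
      drainage:
        procedure_keywords: [drain, drainage]
        procedure_codes: ["5491", "0D9"]
    support_mode: any
  cholecystitis:
    lab_categories:
      inflammation: [white blood cell count, c-reactive protein]
      liver_gallbladder: [total bilirubin, alkaline phosphatase,
                          aspartate aminotransferase, alanine aminotransferase,
                          gamma-glutamyl transferase]
    essential_treatments: [antibiotics, support]
    case_specific_treatments:
      cholecystectomy:
        procedure_keywords: [cholecystectomy]
        procedure_codes: ["5122", "5123", "0FT4", "0FB4"]
      ercp:
        procedure_keywords: [ercp, endoscopic retrograde cholangiopancreatography]
        procedure_codes: ["5110", "BF10", "BF11"]
      drainage:
        procedure_keywords: [drain, drainage, cholecystostomy]
        procedure_codes: ["5101", "0F9"]
    support_mode: any
  diverticulitis:
    lab_categories:
      inflammation: [white blood cell count, c-reactive protein]
    essential_treatments: [antibiotics, support, colonoscopy]
    case_specific_treatments:
      colectomy:
        procedure_keywords: [colectomy, sigmoidectomy, colon resection, hartmann]
        procedure_codes: ["457", "0DTN", "0DBN", "0DTM"]
      drainage:
        procedure_keywords: [drain, drainage]
        procedure_codes: ["5491", "0W9G"]
    support_mode: any
  pancreatitis:
    lab_categories:
      inflammation: [white blood cell count, c-reactive protein]
      pancreas_enzymes: [lipase, amylase]
      severity: [hematocrit, blood urea nitrogen, creatinine, calcium, lactate]
    essential_treatments: [support]
    case_specific_treatments:
      ercp:
        procedure_keywords: [ercp, endoscopic retrograde cholangiopancreatography]
        procedure_codes: ["5110", "BF10", "BF11"]
      cholecystectomy:
        procedure_keywords: [cholecystectomy]
        procedure_codes: ["5122", "5123", "0FT4"]
      drainage:
        procedure_keywords: [drain, drainage, necrosectomy]
        procedure_codes: ["529", "0F9G"]
    support_mode: all

# Surface keywords for recognizing treatment mentions in an agent's
# free-text treatment plan.  A small negation guard upstream prevents
# "no surgery"-style phrases from counting as recommendations.
treatment_keywords:
  antibiotics: [antibiotic, antibiotics, ceftriaxone, metronidazole, piperacillin,
                tazobactam, ciprofloxacin, cefoxitin, cephalosporin]
  appendectomy: [appendectomy, appendicectomy, removal of the appendix, remove the appendix]
  cholecystectomy: [cholecystectomy, gallbladder removal, removal of the gallbladder,
                    remove the gallbladder]
  colectomy: [colectomy, sigmoidectomy, colon resection, bowel resection, hartmann]
  drainage: [drainage, drain placement, percutaneous drain, drained, necrosectomy]
  colonoscopy: [colonoscopy]
  ercp: [ercp, endoscopic retrograde cholangiopancreatography]

support_keywords:
  fluids: [fluid, fluids, hydration, crystalloid, lactated ringer, normal saline]
  pain_management: [pain, analgesia, analgesic, morphine, acetaminophen, opioid, nsaid]
  monitoring: [monitor, monitoring, observation, serial exams, vital signs]
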