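# Accepted alternative phrasings per target pathology.  A diagnosis is
# correct only if its *first* mentioned diagnosis contains the pathology
# name or one of these medically equivalent phrasings; descriptive
# findings without the inflammatory condition (e.g. plain "gallstones")
# do not count.  Lists must stay disjoint across pathologies.
pathologies:
  appendicitis:
    - acute appendicitis
    - appendiceal inflammation
    - inflamed appendix
    - inflammation of the appendix
    - ruptured appendix
    - perforated appendix
  cholecystitis:
    - acute cholecystitis
    - gallbladder inflammation
    - inflammation of the gallbladder
    - inflamed gallbladder
    - acute calculous cholecystitis
    - gallbladder empyema
  diverticulitis:
    - acute diverticulitis
    - sigmoid diverticulitis
    - inflamed diverticula
    - inflammation of colonic diverticula
  pancreatitis:
    - acute pancreatitis
    - pancreatic inflammation
    - inflammation of the pancreas
    - inflamed pancreas
    - necrotizing pancreatitis
    - gallstone pancreatitis
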