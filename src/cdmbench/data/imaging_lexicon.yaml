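# Uniquely identifying keywords for imaging modalities and anatomical
# regions, plus special-exam mappings applied before the keyword scan.
# No keyword may appear under two modalities or two regions.
modalities:
  CT: [ct, cat scan, computed tomography]
  Ultrasound: [ultrasound, us, sonogram, sonography, duplex]
  MRI: [mri, mr, magnetic resonance]
  Radiograph: [x ray, xray, radiograph, plain film]

regions:
  abdomen: [abdomen, abdominal, abd, pelvis, right lower quadrant, right upper quadrant,
            left lower quadrant, rlq, ruq, llq, gallbladder, appendix, pancreas, liver]
  chest: [chest, thorax, thoracic, lung]
  head: [head, brain, cranial]
  spine: [spine, spinal, lumbar]

special_exams:
  mrcp: {modality: MRI, region: abdomen}
  magnetic resonance cholangiopancreatography: {modality: MRI, region: abdomen}
  ct urography: {modality: CT, region: abdomen}
  kub: {modality: Radiograph, region: abdomen}
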