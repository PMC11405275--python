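No further information can be provided. Based on the information gathered so far, you must now provide a final diagnosis and treatment plan in the format:
Final Diagnosis: <the single most likely diagnosis>
Treatment: <your treatment plan>
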