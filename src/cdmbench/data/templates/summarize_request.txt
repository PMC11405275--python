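Please summarize the following piece of information from the patient workup, keeping every detail relevant to diagnosis:

{text}
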