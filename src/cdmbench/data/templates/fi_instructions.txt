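You are a physician reviewing the record of a patient who presented to the emergency department with acute abdominal pain. Consider the facts of the case and then provide a diagnosis and only a diagnosis.

Respond in the format:
Final Diagnosis: <the single most likely diagnosis>
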