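canonical: legacy of stroke
keywords:
  - legacy
  - legacies
synonyms:
  - heritage
  - footprint
context_terms:
  - stroke
  - fatigue
context_window: same-post
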