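# Forward-only negation triggers (NegEx style). A concept mention is
# negated when a trigger ends within scope_window word tokens before the
# mention start in the same sentence, unless the trigger occurrence is
# part of a pseudo-trigger phrase.
pre_triggers:
  - "no"
  - "not"
  - "denies"
  - "denied"
  - "without"
  - "negative"
  - "negative for"
  - "no evidence of"
  - "absence of"
  - "free of"
  - "rule out"
pseudo_triggers:
  - "no increase"
  - "no change"
  - "not ruled out"
  - "no further"
scope_window: 6
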