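# Default structured-data rule configuration.
# The diagnosis-code sets are RECONSTRUCTED defaults (the source code sets
# are site-specific and not distributed); edit freely — the rule logic only
# tests set membership.
ln_icd9_codes: ["583.81", "710.0"]
ln_icd10_codes: ["M32.14", "M32.15"]
proteinuria_threshold: 0.5
proteinuria_scale: ratio   # ratio | grams_per_24h (0.5 ratio ~ 500 mg/24 h)
use_rbc_casts: false
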