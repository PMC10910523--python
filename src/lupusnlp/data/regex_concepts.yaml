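# Regular-expression patterns for the five nephritis text concepts.
# Patterns are compiled case-insensitively. They cover canonical phrasings
# (nephritis class IV / class IV lupus nephritis), roman and arabic
# numerals, the LN abbreviation ("LN class 4", "class 2 LN") and the
# "stage 2 LN" paraphrase, plus quantified proteinuria expressions
# ("proteinuria > 0.5", "urine protein/creatinine ratio of 0.8").
nephritis_class_II:
  - '(?:lupus\s+)?nephritis,?\s+class\s+(?:ii|2)\b'
  - '\bclass\s+(?:ii|2)\s+(?:lupus\s+)?nephritis\b'
  - '\bln\s+class\s+(?:ii|2)\b'
  - '\bclass\s+(?:ii|2)\s+ln\b'
  - '\bstage\s+(?:ii|2)\s+ln\b'
nephritis_class_III:
  - '(?:lupus\s+)?nephritis,?\s+class\s+(?:iii|3)\b'
  - '\bclass\s+(?:iii|3)\s+(?:lupus\s+)?nephritis\b'
  - '\bln\s+class\s+(?:iii|3)\b'
  - '\bclass\s+(?:iii|3)\s+ln\b'
  - '\bstage\s+(?:iii|3)\s+ln\b'
nephritis_class_IV:
  - '(?:lupus\s+)?nephritis,?\s+class\s+(?:iv|4)\b'
  - '\bclass\s+(?:iv|4)\s+(?:lupus\s+)?nephritis\b'
  - '\bln\s+class\s+(?:iv|4)\b'
  - '\bclass\s+(?:iv|4)\s+ln\b'
  - '\bstage\s+(?:iv|4)\s+ln\b'
nephritis_class_V:
  - '(?:lupus\s+)?nephritis,?\s+class\s+(?:v|5)\b'
  - '\bclass\s+(?:v|5)\s+(?:lupus\s+)?nephritis\b'
  - '\bln\s+class\s+(?:v|5)\b'
  - '\bclass\s+(?:v|5)\s+ln\b'
  - '\bstage\s+(?:v|5)\s+ln\b'
proteinuria:
  - 'proteinuria\s*\(?\s*(?:>|≥|greater\s+than)\s*\d+(?:\.\d+)?'
  - 'proteinuria\s+of\s+\d+(?:\.\d+)?'
  - 'urine\s+protein\s*/\s*creatinine\s+ratio\s+(?:of\s+)?\d+(?:\.\d+)?'
  - '24[\s-]?h(?:our)?\s+urine\s+protein\s+(?:of\s+)?\d+(?:\.\d+)?'
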