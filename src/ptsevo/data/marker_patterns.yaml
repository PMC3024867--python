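# Product-text fallback patterns for synteny markers (case-insensitive regex).
# Domain-label evidence (signature_vocab.tsv) outranks these.
sigma54: "rpoN|sigma[ -]?54"
sis: "sugar isomerase|\\bSIS\\b"
is_element: "transposase|insertion sequence|\\bIS[A-Z]?\\d"
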