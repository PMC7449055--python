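# Fixture ESE hexamer panel: a small, synthetic stand-in subset of
# purine-rich (GAR-type) exonic splice enhancer hexamers of the kind found
# in published human ESE panels.  Ships for tests and worked examples; for
# real analyses supply the full published panel file instead.
AAGAAG
AGAAGG
GAAGAA
AGAAGA
TGAAGA
CAGAAG
AAGGAA
GAAGGA
GGAAGA
TGGAAG
ATGAAG
CTGAAG
GATGAA
GAAGAT
AAGAAA
GAAGGT
TTCAAG
ACGAAG
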