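# Mouse core and linker histone gene symbols (proteomic-ruler anchors).
# One symbol per line; lines starting with '#' are ignored.
# Override with your own file via the histone_genes option.
H1f0
Hist1h1a
Hist1h1b
Hist1h1c
Hist1h1d
Hist1h1e
Hist1h1t
Hist1h2aa
Hist1h2ab
Hist1h2ac
Hist1h2ad
Hist1h2ae
Hist1h2ba
Hist1h2bb
Hist1h2bc
Hist1h2be
Hist1h2bf
Hist1h2bg
Hist1h2bh
Hist1h2bj
Hist1h2bk
Hist1h3a
Hist1h3b
Hist1h3c
Hist1h3d
Hist1h3e
Hist1h3f
Hist1h4a
Hist1h4b
Hist1h4c
Hist1h4d
Hist1h4f
Hist1h4h
Hist1h4i
Hist1h4j
Hist1h4k
Hist2h2aa1
Hist2h2ab
Hist2h2be
Hist2h3b
Hist3h2a
Hist3h2ba
H2afz
H2afx
H2afy
H3f3a
H3f3b
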