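granzymes	cytotoxic granule serine proteases	Gzma	Gzmb	Gzmc	Gzmd	Gzme	Gzmf	Gzmg	Gzmk	Gzmm	Gzmn	Prf1
glycolysis	core glycolytic enzymes	Hk1	Hk2	Hk3	Gpi1	Pfkl	Pfkm	Pfkp	Aldoa	Aldob	Aldoc	Tpi1	Gapdh	Pgk1	Pgam1	Eno1	Eno2	Eno3	Pkm	Ldha	Ldhb
chaperones	major cytosolic chaperones	Hspa1a	Hspa1b	Hspa5	Hspa8	Hspa9	Hsp90aa1	Hsp90ab1	Hsp90b1	Hspd1	Hspe1	Cct2	Cct3	Cct4	Cct5	Cct6a	Cct7	Cct8	Tcp1
cytoskeleton	abundant cytoskeletal proteins	Actb	Actg1	Tuba1a	Tuba1b	Tuba4a	Tubb4b	Tubb5	Vim	Tln1	Vcl	Myh9	Actn1	Actn4	Cfl1	Pfn1	Tmsb4x	Cotl1	Lcp1
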