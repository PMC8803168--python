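# Synthetic stand-in for the published stringent 54-hexamer exonic-
# splicing-enhancer set: the first 54 motifs of the synthetic 238 set,
# mimicking the real nesting of the stringent set. Not the published
# sequences.
TGATAG
AAATGC
AGGCGA
GTGGCT
TACGAG
ATAAGA
CCGTAA
GAAAGG
AAGGGG
AGGAAG
GGAAGA
TGGGGC
GGGGCG
GGTGGT
TCAGGG
CCTAAG
GAAGTG
GAGAAG
GCACGG
GGAGGT
AGATGA
TACATG
GATCCA
GGATAA
AAAGCG
CGTAAT
CTTAGA
CGGGGA
GTGAAA
ACCTAT
AAAGGA
CATGAG
TGGATG
AAGAAG
GAGGCA
GACAGT
GCCCAC
GAGGGG
AGACTC
GAAAAG
GAAGAC
GAGGTA
GGGGAG
TGTAAA
AGGAGA
GATGGG
AAGAGT
GTTAGT
TGACCG
TGTATC
ATGAGG
TGGAAA
GTAGCA
CAATGG
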