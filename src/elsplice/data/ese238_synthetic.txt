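# Synthetic stand-in for the published 238-hexamer exonic-splicing-
# enhancer set (deterministically generated, purine-rich); not the
# published sequences.
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
ATCGTA
AGAAGG
GGTTAG
TTAAGA
AAATAT
GATGCG
TAAAAA
AGGGGA
GTCAGG
GTGTAG
GAGGAG
GGAAAA
AACTTG
GAGAAA
TCGGAG
CAAACA
GGAGAA
GCAAAG
GGGGGT
AGAAAG
AGACAT
GGGTAC
AAACCA
GGCGAG
GAGAGC
GAAAGT
AGCCAG
GAAGAT
AAGTGG
GAACAG
CAGGCA
AAAAGG
GCAAAA
ATGAAG
CAGTCG
GATCTA
GAGGGA
AGAAGA
ATGTGA
GACGGT
TCACAC
AAGGGT
TAAGAT
GAGCCG
AGGGGG
ACGAAA
TAGAAA
GACAAA
GGGCAA
GTGCGA
GCGGAA
ACATGA
ATCCTC
CAACGA
AAGTAG
GGAATA
AAAAAA
TAGGAA
GAGTAG
TTAGAG
GGAAAC
AAAGAG
AACTAA
CGTAGG
GGTAAG
AACAGA
GCCCAG
TAAACC
GGTAGA
ATAATG
ACGGTG
ATGGGG
ATGTTG
GGGGAC
GGAACA
GGGAAG
GACGAC
CAGGGG
GACAAC
GAAATA
GAACGC
TGCAAT
CGTAAG
TGCCTG
ACGGGG
TGTTAG
CAGCAG
TCGCGG
GGGTGA
GATAAA
AAGCAG
AGAAAC
GGCCGA
CGGGAT
AGGTAG
GACAGC
AAACGC
CGGGGG
GGAGAG
GGGGAA
GGCCAG
ATAGAC
CGTAAC
GGATGA
GGGAAA
ACAGTG
GGACAA
GAAGTA
GATAGA
GAAACG
AAAAAG
AGGGAG
AAAACT
GGGAGA
AGGAGC
GTGAAC
GATCAC
AGAGGG
AGCTAG
GAAGAG
TGAGAG
TCAGAA
ACGGAG
CACGAA
GACAGA
TGACGA
GTAGGG
GAAAAA
AGAAGC
GGCAGG
ACAGCA
AACGAG
AAGGTG
AGGCAT
GGAGGG
CGATGC
GTCGCA
GGACGC
CAAGAA
GTATTA
TAGTAG
TAAGCT
GTATGA
AGGCGG
GCGGTC
CAAAAC
GAAGAA
TCCCGC
CGTTCA
AAGATG
AGACTA
TAGATA
ATAGAA
GCCAGG
GAATAG
AGGATG
ATAGGG
AACACA
GATTCA
CTAAAG
AATAGG
TATGGA
GGGATA
AGTGGA
AGGAGG
AACGAA
GGCTCA
AGGGTG
ACACAA
TGGTAA
GTACAG
AACAGC
CCGAGT
AGAGCA
GATGCT
TAGAAG
GAGGAA
CTGGAT
CCCACC
GGGAAC
TTATGC
CCTGTG
AAAGAA
AAGACT
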