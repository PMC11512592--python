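>mini_mtDNA synthetic 2000-bp circular test genome
GATATCTCATTTCGCACTGCTCCATCACTGCTAATTGGATGAATTACCAATTAATACCAACACACATCCA
GTTCGTCCTCGGATGTATTTAGGTTATGGGCAATCACCCACTCACCAGACGTTACTTTCTCCATCCAAAG
GGGAAACGCTAATTAAACCCCTAGATCAGCGAATCTGCATGTTGTGAGGCTTGCAAAGTTCACGCCCACA
GCTCAGCCACAAACGATGTCTGATAGGGTCAATCATAGAAACATTACTCTCAAAACCAAGCCGGTAATGC
CGTCGGACCTAAGCGTCTGAAGAAACGTGCCCGACAGCCTAAATTTTTCTATACAAGGCACTATTTCAAG
TAGACGCAAAGCCCTGCCCGGGACGACTCGAGGGTTCGCGGCGACTTATAATTATCTCCAATATTATCAT
GGTTTGAATAGCTCAGACTCGCACGGGCATGTCTAGCTGGTCCCACCCGGTTCGAGTACTAGATCGCGCT
CTAGCATGGAGTAGGCGCGGAACTCACGCGCGTGGGTACGGCGTTTAATGGATTGCCTAATACGACCGGT
GATTCCAGCTTGTTTTCGGGGCTTTATCGGCGCGGTCCGCGGGTAGTAAGTCACAACTTGCTCATGCATT
CATTGGGGGTGAGTCGTCCCGCTGCGATCTCGAGAGATTTGCGGGAGAGTGCGATTTTCTCCGAGCCACT
GATATAAGGTAACTCGAGGGAATACACTACTTAAAGCACCTGAGGTTCTAATTCCTCTTCCGGGCTGAAA
GTAGAACGCAGTATTACCCAGTTTCAAATAACTGCAAGATACGTGTATTCTGAAGTCGGTAAGCCACTGA
TAGCTTTTACGCGGTTTGTCCTTAGATATCCGCCATGGCACTGGACCTATTTGCTGTTTCCCTAATGGTT
TGAGTTTGATTTACTTAGAATGCTCCGTATATAGCGCGTACTTGTCAGTTACAATTGATGCCGGCGGCTC
TATGTCCACCCTCTGGTAGGACGTTCCCTGTATCGTATACAACGCTCGACATCCCTTCAGGTGCGGAACC
TTTGCCTTGTAATTGCGCTATATTTTAATGGGACTACTTTGGCATCCCAGGATATAACGGCCTATAGGAG
TTTCGACTATAGTCCGAAAGGTGCGACCGCTCGGGCCAGGGGGACGCAACGATGATTCGGGCTGAGCCAC
TCTGCCGGGTGTCCTATTCGCGGTTATTGCAATTGTTCGTATCTAAAGGCAGGACTCGAGCTGAGCTCGA
GATTTTCACTTTCATAAACAATTAGGTATCGCTCTGCCCCACTAGAGAGATGTTTTGCGTGACGTACGTC
ACAGATGGGACTTGGATAGCATCTTAAATCGCGCAGCGCTTCATTGCTGAGATACGCGACTCCATCTATA
TAAATCATGACTCCTCTCTGAGCTGATTGATACTCCATAGCAATGCCGGTCACAAGGCCGCCGGCATACA
GTTAGAGGGTGCCCTATCAAATGGGAGCGGCCGGGAGCTGTCACCGTCCCTGGTCCTGTACTGGGGAATC
GCTAGTACAGTTATTCTGGTTACGCGAAGTTTCGGCCATTTCTTATTGTATATCCTTTCCAACTCTGCGT
GCAGACATGTTACAGACTTCACTCCTTCCGGTTACCCGCTTCTCGTTGGTATATGTTTCGGCTACAGCCT
TGCTCAGGTTTCATGTACCCGAGAATTATAGGCTTAGTTGATGTTAGTTAGTACATGTATTGTGAGAGTG
AGAAGACTTCCCCGTGTAAAAGGAAGGCCATACACTTGTTAAACTGTCGCTTAGTGTATGATGTTTCTGG
GCCGAAAGTCGATACGACCCTTTATAGCGGGGCTTATTAAATCTCCATCGGCTAGGCGAAATATTTGGGC
TACCACGAATAGCATTCACTTTGAAACTACCTCCGCAACACCGAATCAGCCGGCGAGAGCCCTTGAGGCA
TATTTATTGTATCGAATTGAGGTCTTGACCACGAGAGACT
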