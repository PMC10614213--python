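>demo_plasmid synthetic 7 kb circular test plasmid
TCCCGAGAAGTAAAGCGGCCCCAATCTTGACTGGTCGTGATTATGCTATGAGCCACTTACAAGAGCTTCG
TAGAGTTTGACCTTTTTACGATTCGGTTGTCTGAGCCTTTCCTGAATCGCTCTCGTCCTCTTACAGGCCC
ATAGTACCCACTCTTCCCTCCCATCGCGGCGCAGGCTAACTGATTCTAGCGAACAGGGGCAATCCTCTAG
TGGAGCTCTTACATGAGAGGGATCCGAGTGTGCTGTGACAATGGATCGCTCACCACGTGCAGCCTTACCA
CCTAGGCGGTAAACAATACAGGGTTCTCTAGTAACTGCGACACATCAGTTTGTGTGAACGGCCGTTTACG
CAGCCTTGTTTCTTGGTCCCTCTTTCTGGAGAAGGCGCTAAGCCGATTATGTACGAACAGTACTGATGGA
CGGGACAATCTCTCTGATTATCATCGACGCCTTCCCAATCTGACTAAAAAGTGGCACACTTGCCGGTAAG
AACTGTAATACCCCAACTCCCCGTGCATCTACCAGTGCTTGCCCGTAGGCCCCTCTGATTACGTCTAGGG
ACAGAGCGACCACCCGCATCCGGAACCTTGCGACCCGGGTACTACCCTCAGGTAATCCCCCCACAGTAGG
GGGATAGGTGATCTAGTCGGATTCCAGCTGATGTTAAAAATCTAAGACGAGTTCATGCACTTCTAACTCT
GTGCCCCCTCGTGCGTTACCTCGTACACTACGGCCAAGGTTCCTACCGCCATACGCGGTCCAGGTTAGGC
CAAAGATTAGCACACTTCCCCTACCTGCTCGTCTAAGTGTTCCTATTGTGCGCTTAACAGATTAGTCGCC
GAAGAAAGAAAGCTAACTGCGGAGCCGACACGCAGAGGTTAGTAGACGCATATGGTACACCTTGCCGCAA
GTGTAGCGGAAAGAAGGTCGGGTACAAAAATGGAATTTGTGTGGCGTCTAACACACCAATATCCTGTGAA
TGAGCGTTGTTGGACGTGTGGCCCAGACGCGATACCCATTTGTATTGTGTCAGAATCCTGACAAGAGTAT
CTACTCTGAGTTTCCTTCCGTCCACCGTACGTGATGCACGAGCATTATGCTCTGTTGGACCCAGCTCCTT
CACGAGGAGACCCGCGCTACCGCCGTTACTTGTGAAATACGGAGGGTGAAGTAATTCACGTTGCATCATA
AATAGACTGAGTCCTTTGTGGCACTATATATTAGAGCCTTAGTCTCTATACGTCGAAAGGCACCACTGCA
TACAGCTTTGGCCCACAAGGACACCTGTGAACGGTTTACATCGCAGCCATACGGACCTAACGGTACACCG
GGGCGGTAACCCTGCCGAGCACCAAGGTCGTTAAAATGCGAAGACAAAAGTCACCACTTTCGGCGGGGAT
AGGGCAAGTTGCATTCCACTTTTAGGTGTACTGGCATCCCTAAAGTTTGTGTGATAAGCCTAGACCATAC
ACTGGCCCTTCGTTTCTCCGCTGTGCTGGTGAAAAAGGCAAAGCATTAAACAGGGCTAAACCAGCAATAC
AGGCTTGACCGATTGCTAACTCGACTGCAGTTAAACTCCTATTGCTGGCGGATTTTGGTCTGCCAACCCA
AAGTCTTAGCAAAACAAATTTTAGAGGAGGCGTGTCCGTTGATGCGCGTTACGCCCCCCGTCATAATGAA
TCTATGCTAGCTAGTCACCAACAAGCTGTTAACCGGTATCAGACCGACAATGCACTGGCGATGGCGGGCT
GTCTCTGTATACCTGACGAGATCCGATCCGACATGTTGTGCGCAACGTAAATACTTGGGATTCGAACATT
GAATTAACGTCGCTTAAGATTGGCACTACTGAACGCTAATATGGAGAGATACCACTTGGATTGTTAGATC
AACCAGTACTTTGAGATGTTCCCGTCCTGTGTGCCTTTGATCCTGGTTGAGTGACCCTTCTGGCCACAAT
TCTAGTTGAGCATGCGCTGATTTTAAGTTAGCATCAAGCAAAACGCTAACTCACTCGCGCGTCCGAGGCG
GTTTCACATCGATGGCAAAGTGCAAAATCCCGTATGCTATGTGTTATCCCTATAACTATCCTCTCGTACC
TCTGCCCAGTTTCAGACACCCCAAACCGAGCGTCCTCTCCAGTTGCTCCACCCGCTTGTTTCCTTGTCAT
CCGCTTTGGATTGACCGGCGCGATTAAGAGAGCAACAGAGGGAACACCTTCTTATCTCCCCGAGGAAATC
TCAGTAGACTTGAAACTCAGGGCTAATCTACAGACTGGTTGTTGGCACCACCTTTCATAATATGTCGGCT
TTACGAGTTATGGCAGGGTGAAATCACGACAAGGGTTCCGTACCTCCTGGTTAAGCGACTAGCTAGACAT
CCATGACCACCATACAGAGAATGTACGTGCTAGCACATAGATGCACACACTATCCTTCCCGTTCATATAC
GCCAAACGAACCCCGTACTGGCAACAGACCGGACCTATTTGCTCAACAGCGTTTAGACCGTACATTGCGG
CAAGTAGACTCGCCGAGAGTGAAAATAAAACCTTTATTAGGTTTCAGCTAGCGTGGCTCGGTTTGTACCG
GCTTGAGTGTGTCACAATGGGTCGACGTAACGTTTGACGCATAGTCTGCACTGGCTTGGTTTGTTAAGAA
TAGCGCTGTGCTACGTTCCGACACACTGTGTGTTTATAGATGGTGTCCCAATCCCTGGAGCTCAGGATAA
TCAGGATCGATATCTTTCGTTGCCATCGTTGACGGAGAGTCCGACTGGCATGCCAAATAATCCCCCTGAA
GGTGTTTTCGGACCTTCCGCGGTGATGACATCAGGACGGGGCGGGGTCACGCTTGGAAGCGTCTCCCTCT
CGCCGTCACGTAGACCGTGAGAGCGCACACGTGCTCTCAAAACTGGTGTTTCTAGAGAGCGGTCTCGAAA
TGTCGTTATTTCAACGATATAGAACGTAGGTCGGCAATCGGGCGAATATTAGCGCTCTGGCGAGAATCAA
TCCCACTTAATATGAACGATGGACCGCTACCCCGGGCCAATCACTCATTATACGAACGGAGGTTCTTCGT
CCGGCTAAGCGCTTCGGAGCACGTATATGAGCACCAGCGAGGTGTGCAAGACGACTTATAATAGCTATTG
GGCACGTTACCTTACCACATCAGGATAAGAGGCTCGTGGCGCGTTCGAGATTCGTTGTAACTTGCGGTCT
AAATGCCATAAATTCGGAACACCGTATGTAGAGTACTTGCCCACAATTCAACATCGTGTCAAAGACGGGT
TGTTGGACTAGGAGGGCTGTAAGGCTCGCCAGGGGCTAAGGCGAGAACGGGTTAGTGGTGCACCCGCGCA
GACTCTGTTCGCTGAGATACGCCGATTACCCGAGAGGTCGGCTAATCCACCTCCGACTATTGTGGCCGGT
GACTGGAGGGTGCCACCTTATTAGATTGACCCTATTTCATACCACACACGGATCAACGACGTGCCGTCCG
CAGCTGAGGGACGACTTGGTCAAGCCTGCCGTATAATGTTCCTGGCTAATCACTGGAGAGGATCTCAATG
GCTACGATGGAGTACTCGACTCGCGACAGGTGGCATCCCTCCTGAAGGATTGGTAAAGGCATTCTGAAGA
GGTTAACATAAGCTATCACGACAGACTATCGAATCGGTCGAACTATGTAGGTGCAAACTTTAGACGAGAC
CCGAAGCGAAGGAGACGTTCATAACTCATGGCGCGTGCGATTGACAATGTTCCAAGGATGTGAGGGCCGT
CCGAAGCACTAGCGCCAGGTATACCGAAGTGGACCGGCAGAGTACGGTACGCACTGGATCTTTCTATCGC
TATATCCTTCCCCCCGAAAGGTAAGGTGAACACGTGGATACTAGGGACTGAGAGATTTACACGGCGGATA
ACTGATAGCCGAGTTGTCTATGTCTTGTGTAGGGTCCCGGTGTATTCTGACTTATGTCGACCAGAAGTGC
TATAGGGGAGCGAAACGATACATCCGAGCACTGTAATAAAGGAAGCGTGTAGCAAACCGTGATGTTAGTC
AGATACAGTACGAATCGCGCACCCAGAAGGAGAGCGAAACGTCGTAACAAGGAGGCACAACCAGAGGGTG
TGGAGACCTTCAGTGGATGTTGCGGTGCGGTTCCGAGCACGGGAGTGTTAGCGAAGAAGTGATTGCACAA
CGGTGCAGCACCAGATGGGAACGGTTCTCGGAGCCGCTAACAGCGCTTCTAGTGCAATTCTCTTGCAGCG
AAGTCTGCCTTAGTAAGGACCGGTTAATGTTCGAAGGAGTAGAACTTTCGCTGCGCTCAGCTGATTCTGC
GTCATAGTGTGGTGATGGTAGTAATGCATGGAGCACGACAGTCAGCATTTTCGTCGGTCGGAACGGTGCC
TGAGGTGGCACGAATACTAGCGGATATGATTCATTTCGGGGTAATAGGTCTGTTAGGTGGCAAGCTTTGG
CCCGCAAGTTTAGGAGACTCAGACGCTTGCCCGTCCGATTTCAGTATCTGATCCGTATACAACTCACTTA
AAGTATAGGGCAGATCAAGTCATTTCTATCAGGTGCGTCGAGAAAATGACACCTGTCGGAGTTGTATGTG
CCTCACTCTCTCGACGAGAGTGATGCTGCCCTGGGTTTCAGACAATCGATCGGCCGTTCGGTTCCATCAG
GTTTTCCTTCTAAGGATGCTGTGACCTTCGATTATACCGCTTCGTGGTCGCAAATGGGCAGCTATCACAT
ACGAGCATTACACTGCCAGAATCATTTATCTGGACAATAAGCGGGGAGCCTGCTAAAGTTCATTAGGGTA
TGCGGACGACAGGCGTCCGCCCTAGTACTTGTCAATTGGCCCATCAGTAGTCATAAGTACTGTTGTAGGC
GTGCTGTATCTGCCCCTTGTTCGGCGTAAAGTAACTTAGTTATTGTCCTCAGCTAACTCAGCGAACCGAA
CTTCGTGGGTGGCACGCTTTGTTTTTGGTGTCCTGACCCCCATGTTATACTATAGCCGGATAGGGGAGCG
TTTCATCTTACAGCCTCGCCACCACTCGTACTAGGAATAATTTCATGCGCCGCTACTTTATCTAGAAGAG
GGACTGCCTGCGTGTCGTCATGGACATTGGACCGATGCGCTTAGTACAAGATTATGTTCCGCAGGCCATC
CAGGGTGTAAACTTAACTTGAACTATCCTCCTTTCGAGGATCATAGTCAGTACGCGGATAGGGGATACTT
TTGCGGAACGTGCTCAGTCATTTTTTAGGAGCTGGTGACGCTGCTGTCACCCAGAGTAAGGAAGGGACCG
TTGGAGCATAAAGCTAGTAACCAGATACCGCAGGAGAATCTCACGTCGGTCATTGTATAGCCCGGTGTTC
ATAACCTATTGAAAGGATTAGATACGACGGTCTCTTATTAGTCTAGTATTTCGGTCAATTCACACTCCCC
ACTTATGTCTTAAACCGCTATGACTTGCTTTCCGGACCCACGTCGTAGCGAGTCATAAGGCCAGGGCAGC
GCCAAGGAGCTCCTCCGGGTAATTTGAAAACGAGGGCAAACCATCTTTTTCACGAATACAATGCTCACAG
CGATCTGCACGGCGGCGTACCGAATTCCCTAGAAGTTAAGCCAGAGCAAAAGCACGGGTACATCGGATCT
TTTTCACTGCTCTCGCCGGACAATCCCCTGGATAGTACAACTTCTAAAGTTGTGCAGCGAGTCAGGCGAG
GGGCAGCCCTTATTACCTGCACCGCGATGGGATGAGAACGACCCAGGAGGAGGCCAATACTTACACCGGC
CCGGCATCATATACTAGGGGCGTACGATTTGCGAGACGATACATCCGATTGCAGCCACGCCTAACAGTGT
TACCGAATGTCTCGGTTACCCTATCTTTGGTCGCCTTGCAATGCTCGCAGAGAAATGGGGTATAGGCGTA
CAGCTCCCGATCTATCCAGTAAGACGATTTTATATCACTTTGCTTGTCATCCTAAGAGGTATATATTGGG
CGCCTTGGGACCGGGATCGGTTCGCATTACCATCCGTTCACTCCAATATCTTCTTAAGGTTTTCCTCATA
CTGTAAGAGGGTACGATTCATGCGAAAAATCTAGGCATCTGGCGACTTGAACGCCCACTCTCTTGCCCGC
TTTGATCGTCTCACATCGAGGCAGTTATGTTTCATGCTCAATTGAGAACAGTCGCACTCCTGATGTCGGA
ATCTCAGTCCTCACGAATCCGCAATCCTCGCCGCTACCATGGATCACGGGCTACTTTCGGAACGGTAACA
CAGATAACCGTGACTTATGGTTGCGCAATACGGCTGGCTAGGTTAAACTTTTCTCGCCCATGTTCAAATA
GGTATTACAGCTCCATCTGAGCAGGGTGACGACTACGCACTTTTGACGTCAGACAAAATCTGGCGCAGTT
TCAGGGTGAATGCATATTCGCACTAGCAGCGTTAAGAACACAGAACATGATAACGTGCTGTCGACGGTTT
GCCCGTTAGCATGGGTACCGCCGCGTGATGGCACCAGCAGTCAGGCAGGCTTGCTGAGTTACTCCCAGTT
GACAAATGGGACTTGGCTTTACCCATCCCTCTGAGTCCATACATCGCGTGGTCTTTTGGCCATGCTGTAC
CACTAGGATTGTGACACCATGTGCAAGAGGACGCCAAGTCCTTATTGCAAGATTAATCGGATAACTTACG
GCCGGTGAGGACTTAGGATAGGGGAGAATACCCCCTCCAAGTCAAGCGGTCATGTCTGCATTGACGATTC
ACGGAAAGTGTGGCCCCGCAGACTCAGAAGCCAGCGGTACGCGCAGGCCGGTAGCTAGTAAGACTTAACA
CTTCCTGCGCTTGTCATTACGGGTCACCAAGGCGGACACTGTCCGACAAAGCGACCTGACTAAGGCCCAC
AAAACGGCAGTTCAGCAGAATCTAAGGAAACACAAAACATACTGTGAGAGTCACGGTGCTAAAAGGCGGG
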