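>synthetic_phix_like synthetic stand-in for a PhiX-style sequencing control
CCCCTCCACGGGACAAAGCATCTATGCGGACGTCTAGGACGCGTAACTTTTGCCCGCAGGATGCAGTGCG
CCGTTGAGCACCGCGTTGGCCAGACCAGTATCTCAGGGAACAGTTATGCCCCCTATGAAATGAAACCTTA
GCAGAGGTGTAACGACAGCTTTGAGCGGAGTCTGTCACGGTCGAGTTCCGCGGGGGCCAACCTTATCGCA
ATACGTTCAAATGATAAGCGCGCATTGATAATAGCAGGTGCTTATCTGTCTGCGGCCTCGCCTTCTATGG
CCACGCCGTAAATTCCCAGTTCATTGGATCACGAATTGTAGGTAAATGTGTCGACCGCTTTTGAAGATTC
CGTTGCAAAACAATCGTTTAACAGGGCGCGGCACGATGGGTCCCACTAGCGTTACTCCGCGAATTATGGC
CGCTGGATCGGAGTCCTAGGCTATCCAATGAAACGCACATACACTAGTACACCTCACTGACCTCTATATA
TGCCTGCAGTAGACACGCTGCCATGAGTGCACGGTATCAGATGTGCAATGGCTAGCAACAAGACCGTGAT
TGCGCGCAACTACTGCTACGCTTCTAAGGATGCAAAGGGCAGTTACAGTCCTAGTCGGAGCCACAATCTG
CCACCGTTCCCAAAAATAACGGTGGGGGTATCTCTTCAATCACATTCGATCAAGCTATGTATCAAAGGGG
AAGATCCTCCTTAATGACCCTGACCTGAACGCTGATTGTCCGCAACCCGAATCAGTATGACATGCTACCC
TGTGGTGATGGGAAGAAATACGCCATGATCTGCCAGACGGGTCTGCTGATTCTTATTTTATAGCCCTAGT
CCTAGTTCCTATCAGATGTGGCTGGGTGTAATACTTCTCTTAGGCAGTGAAGAATGGTACCCCTCAGGCG
ATTAAGAGACCCACGGGATCTTACGCGGCATAAGCGACATTGCGCCCACCCATTGTGTGATCGACCGACG
ATAGTCACAGGTCATCAATCTGCGCGGTAGAGCATTTCATAATATTTGACTAAGTTAATGCGCTCATAAC
GCGCCCCCCTATCGACGCGAGACATCTGGTCCTAGCATCCGGCATTTATTTGGAATATAAGGTGCTAGTG
AGCGTATTTTGATACAGCCTCCGATTAGCGTTTACCGCTGGATCCCGCATGGCACACCACGCTTGCTCCC
ATGCCCACTA
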