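primer,chromosome,annealing_c,forward,reverse,tnb,npb,ppb,pic
RM583,1,55,agatccatccctgtggagag,gcgaactcgcgttgtaatc,10,10,100.0,0.86
RM71,2,55,ctagaggcgaaaacgagatg,gggtgggcgaggtaataatg,8,8,100.0,0.84
RM85,3,55,ccaaagatgaaacctggattg,gcacaaggtgagcagtcc,9,9,100.0,0.85
RM471,4,55,acgcacaagcagatgatgag,gggagaagacgaatgtttgc,8,6,75.0,0.86
RM274,5,55,cctcgcttatgagagcttcg,cttctccatcactcccatgg,12,12,100.0,0.84
RM190,6,55,ctttgtctatctcaagacac,ttgcagatgttcttcctgatg,5,5,100.0,0.74
RM336,7,55,cttacagagaaacggcatcg,gctggtttgtttcaggttcg,7,7,100.0,0.79
RM72,8,55,ccggcgataaaacaatgag,gcatcggtcctaactaaggg,12,9,75.0,0.86
RM219,9,55,cgtcggatgatgtaaagcct,catatcggcattcgcctg,2,2,100.0,0.36
RM311,10,55,tggtagtataggtactaaacat,tcctatacacatacaaacatac,2,1,50.0,0.37
RM209,11,55,atatgagttgctgtcgtgcg,caacttgcatcctcccctcc,4,3,75.0,0.67
RM19,12,55,caaaaacagagcagatgac,ctcaagatggacgccaaga,12,9,75.0,0.86
RM1195,1,55,atggaccacaaacgaccttc,cgactcccttgttcttctgg,8,8,100.0,0.84
RM208,2,55,tctgcaagccttgtctgatg,taagtcgatcattgtgtggacc,5,4,80.0,0.75
RM232,3,55,ccggtatccttcgatattgc,ccgacttttcctcctgacg,10,10,100.0,0.87
RM119,4,67,catccccctgctgctgctgctg,cgccggatgtgtgggactagcg,7,4,57.14,0.79
RM267,5,55,tgcagacatagagaaggaagtg,agcaacagcacaacttgatg,9,5,56.56,0.85
RM253,6,55,tccttcaagagtgcaaaacc,gcattgtcatgtcgaagcc,6,6,100.0,0.75
RM481,7,55,tagctagccgattgaatggc,ctccacctcctatgttgttg,7,7,100.0,0.8
RM339,8,55,gtaatcgatgctgtgggaag,gagtcatgtgatagccgatatg,8,8,100.0,0.79
RM278,9,55,gtagtgagcctaacaataatc,tcaactcagcatctctgtcc,14,14,100.0,0.85
RM258,10,55,tgctgtatgtagctcgcacc,tggcctttaaagctgtcgc,7,6,85.71,0.8
RM224,11,55,atcgatcgatcttcacgagg,tgctataaaaggcattcggg,8,8,100.0,0.84
RM17,12,55,tgccctgttattttcttctctc,ggtgatcctttcccatttca,9,9,100.0,0.78
RM493,1,55,tagctccaacaggatcgacc,gtacgtaaacgcggaaggtg,7,7,100.0,0.83
RM561,2,55,gagctgttttggactacggc,gagtagctttctcccacccc,8,5,62.5,0.85
RM8277,3,55,agcacaagtaggtgcatttc,atttgcctgtgatgtaatagc,7,7,100.0,0.75
RM551,4,55,agcccagactagcatgattg,gaaggcgagaaggatcacag,6,6,100.0,0.68
RM598,5,55,gaatcgcacacgtgatgaac,atgcgactgatcggtactcc,9,5,55.56,0.75
RM176,6,67,cggctcccgctacgacgtctcc,agcgatgcgctggaagaggtgc,10,7,70.0,0.88
RM432,7,55,ttctgtctcacgctggattg,agctgcgtacgtgatgaatg,5,5,100.0,0.71
RM331,8,55,gaaccagaggacaaaaatgc,catcatacatttgcagccag,8,7,87.5,0.82
OSR28,9,55,agcagctatagcttagctgg,actgcacatgagcagagaca,10,9,90.0,0.8
RM590,10,55,catctccgctctccatgc,ggagttggggtcttgttcg,9,6,66.67,0.87
RM21,11,55,acagtattccgtaggcacgg,gctccatgagggtggtagag,11,11,100.0,0.87
RM3331,12,50,cctcctccatgagctaatgc,aggaggagcggatttctctc,6,4,66.67,0.8
RM443,1,55,gatggttttcatcggctacg,agtcccagaatgtcgtttcg,10,7,70.0,0.75
RM490,1,55,atctgcacactgcaaacacc,agcaagcagtgctttcagag,9,9,100.0,0.82
RM424,2,55,tttgtggctcaccagttgag,tggcgcattcatgtcatc,5,5,100.0,0.72
RM423,2,55,agcacccatgccttatgttg,cctttttcagtagccctccc,7,7,100.0,0.82
RM571,3,55,ggaggtgaaagcgaatcatg,cctgctgctctttcatcagc,7,7,100.0,0.67
RM231,3,55,ccagattatttcctgaggtc,cacttgcatagttctgcattg,12,12,100.0,0.84
RM567,4,55,atcagggaaatcctgaaggg,ggaaggagcaatcaccactg,10,10,100.0,0.78
RM289,5,55,ttccatggcacacaagcc,ctgtgcacgaacttccaaag,10,10,100.0,0.88
RM542,7,55,tgaatcaagcccctcactac,ctgcaacgagtaaggcagag,8,7,87.5,0.84
RM316,9,55,ctagttgggcatacgatggc,acgcttatatgttacgtcaac,2,2,100.0,0.19
RM332,11,55,gcgaaggcgaaggtgaag,catgagtgatctcactcaccc,10,8,80.0,0.88
RM7102,12,55,taggagtgtttagagtgcca,tcggtttgcttatacatcag,3,3,100.0,0.43
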