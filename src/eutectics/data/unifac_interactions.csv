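# UNIFAC (original, VLE) main-group interaction parameters a_mn in Kelvin,
# psi_mn = exp(-a_mn / T).  Asymmetric: a_mn != a_nm; a_mm = 0 implied.
# Subset of Hansen et al., Ind. Eng. Chem. Res. 30 (1991) 2352 for main
# groups 1 (CH2), 3 (ACH), 4 (ACCH2), 5 (OH), 8 (ACOH), 9 (CH2CO).
main_i,main_j,a_ij
1,3,61.13
3,1,-11.12
1,4,76.50
4,1,-69.70
1,5,986.5
5,1,156.4
1,8,1333.0
8,1,275.8
1,9,476.4
9,1,26.76
3,4,167.0
4,3,-146.8
3,5,636.1
5,3,89.60
3,8,1329.0
8,3,25.34
3,9,25.77
9,3,140.1
4,5,803.2
5,4,25.82
4,8,884.9
8,4,244.2
4,9,-52.10
9,4,365.8
5,8,-259.7
8,5,-451.6
5,9,84.00
9,5,164.5
8,9,-356.1
9,8,-133.1
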