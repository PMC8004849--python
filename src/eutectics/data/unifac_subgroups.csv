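# UNIFAC (original, VLE) subgroup volume and surface parameters.
# Subset of the published table of Hansen et al., Ind. Eng. Chem. Res. 30
# (1991) 2352 (revisions: Gmehling et al. 1993; Oracz et al. 1996),
# covering the alkane, aromatic, alcohol, phenol and ketone chemistries.
# R: van der Waals volume, Q: surface area (Bondi-normalised).
subgroup,subgroup_id,main_id,main_name,R,Q
CH3,1,1,CH2,0.9011,0.848
CH2,2,1,CH2,0.6744,0.540
CH,3,1,CH2,0.4469,0.228
C,4,1,CH2,0.2195,0.000
ACH,9,3,ACH,0.5313,0.400
ACCH3,11,4,ACCH2,1.2663,0.968
ACCH2,12,4,ACCH2,1.0396,0.660
ACCH,13,4,ACCH2,0.8121,0.348
OH,14,5,OH,1.0000,1.200
ACOH,17,8,ACOH,0.8952,0.680
CH3CO,18,9,CH2CO,1.6724,1.488
CH2CO,19,9,CH2CO,1.4457,1.180
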