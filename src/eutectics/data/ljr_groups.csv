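# Modified Lydersen-Joback-Reid group contributions.
# dTbM: Joback-Reid normal-boiling-point contribution, K (Tb = 198.2 + sum).
# dTM, dPM, dVM: modified-Lydersen contributions entering
#   Tc = Tb / (0.5703 + 1.0121*S_T - S_T^2)      [K]
#   Pc = M / (0.2573 + S_P)^2                    [bar], M in g/mol
#   Vc = 6.75 + S_V                              [cm3/mol]
# Sources: Joback & Reid, Chem. Eng. Commun. 57 (1987) 233;
# Alvarez & Valderrama, J. Chil. Chem. Soc. 49 (2004);
# Valderrama & Robles, Ind. Eng. Chem. Res. 46 (2007) 1338.
# Suffix "(ring)" marks cyclic-environment groups; "(phenol)" the aromatic OH.
group,dTbM,dTM,dPM,dVM
CH3,23.58,0.0275,0.3031,66.81
CH2,22.88,0.0159,0.2165,57.11
CH,21.74,0.0002,0.1140,45.70
C,18.25,-0.0206,0.0539,21.78
=CH2,18.18,0.0170,0.2493,60.37
=CH,24.96,0.0182,0.1866,49.92
=C,24.14,-0.0003,0.0832,34.90
OH,92.88,0.0742,0.1330,30.40
O,22.42,0.0051,0.1300,15.61
C=O,76.75,0.0380,0.2341,69.76
CHO,72.24,0.0400,0.3128,77.46
COOH,169.06,0.0654,0.4537,88.60
CH2(ring),27.15,0.0116,0.1982,51.64
CH(ring),21.78,0.0081,0.1773,30.56
C(ring),21.32,-0.0180,0.0139,17.62
=CH(ring),26.73,0.0114,0.1693,42.55
=C(ring),31.01,0.0051,0.0955,31.28
OH(phenol),76.34,0.0240,0.0354,-17.44
C=O(ring),94.97,0.0284,0.2556,45.88
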