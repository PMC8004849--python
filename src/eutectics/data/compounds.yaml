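# Built-in compound registry: the four monoterpenes used to prepare the
# binary eutectic solvent systems Men:Bor, Men:Cam, Thy:Bor and Thy:Cam.
# Melting data from DSC (second reheating cycle); dh_fus stored in kJ/mol.
# Group decompositions are declared, atom-balanced data (they are not
# perceived from structures): unifac_groups use the original-UNIFAC VLE
# subgroup names, ljr_groups the modified Lydersen-Joback-Reid table.
compounds:
  - name: menthol
    formula: C10H20O
    t_fus_K: 309.72
    dh_fus_kJ_per_mol: 13.62
    unifac_groups: {CH3: 3, CH2: 3, CH: 4, OH: 1}
    ljr_groups: {CH3: 3, CH: 1, "CH2(ring)": 3, "CH(ring)": 3, OH: 1}
  - name: thymol
    formula: C10H14O
    t_fus_K: 324.31
    dh_fus_kJ_per_mol: 18.54
    unifac_groups: {ACH: 3, ACCH3: 1, ACCH: 1, CH3: 2, ACOH: 1}
    ljr_groups: {CH3: 3, CH: 1, "=CH(ring)": 3, "=C(ring)": 3, "OH(phenol)": 1}
  - name: borneol
    formula: C10H18O
    t_fus_K: 481.33
    dh_fus_kJ_per_mol: 7.23
    unifac_groups: {CH3: 3, CH2: 3, CH: 2, C: 2, OH: 1}
    ljr_groups: {CH3: 3, "CH2(ring)": 3, "CH(ring)": 2, "C(ring)": 2, OH: 1}
  - name: camphor
    formula: C10H16O
    t_fus_K: 452.41
    dh_fus_kJ_per_mol: 6.32
    unifac_groups: {CH3: 3, CH2: 2, CH: 1, C: 2, CH2CO: 1}
    ljr_groups: {CH3: 3, "CH2(ring)": 3, "CH(ring)": 1, "C(ring)": 2, "C=O(ring)": 1}

# Binary systems at the compositions at which the solvents were prepared
# (mole ratio of the first-listed component; x_i refers to that component).
systems:
  - label: "Men:Bor"
    comp_i: menthol
    comp_j: borneol
    x_i: 0.7
  - label: "Men:Cam"
    comp_i: menthol
    comp_j: camphor
    x_i: 0.6
  - label: "Thy:Bor"
    comp_i: thymol
    comp_j: borneol
    x_i: 0.7
  - label: "Thy:Cam"
    comp_i: thymol
    comp_j: camphor
    x_i: 0.5

# TGA/DSC thermal records of the prepared mixtures (stored observations;
# not consumed by any computation).  Units: K except dh_cr_J_per_g.
thermal_records:
  - label: "Men:Bor"
    t_d_K: 366.02
    t_cr_K: 254.08
    dh_cr_J_per_g: 21.17
    t_g_K: 223.03
  - label: "Men:Cam"
    t_d_K: 358.29
    t_cr_K: 239.92
    dh_cr_J_per_g: 28.60
    t_g_K: 196.98
  - label: "Thy:Bor"
    t_d_K: 355.04
    t_cr_K: 284.64
    dh_cr_J_per_g: 0.098
    t_g_K: 215.17
  - label: "Thy:Cam"
    t_d_K: 370.74
    t_cr_K: 260.69
    dh_cr_J_per_g: 0.077
    t_g_K: 194.23
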