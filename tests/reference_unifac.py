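"""Independent scalar-loop UNIFAC transcription used as a test oracle.

Written directly from the canonical published equations (Fredenslund,
Jones & Prausnitz 1975; Hansen et al. 1991) with plain dictionaries and
explicit loops, deliberately sharing no code or data files with
``eutectics.activity``: parameter values are restated here as literals so
that the two routes agree only if both transcriptions are faithful.
"""

import math

# subgroup -> (main group, R, Q)
SUBGROUPS = {
    "CH3": (1, 0.9011, 0.848),
    "CH2": (1, 0.6744, 0.540),
    "CH": (1, 0.4469, 0.228),
    "C": (1, 0.2195, 0.000),
    "ACH": (3, 0.5313, 0.400),
    "ACCH3": (4, 1.2663, 0.968),
    "ACCH": (4, 0.8121, 0.348),
    "OH": (5, 1.0000, 1.200),
    "ACOH": (8, 0.8952, 0.680),
    "CH3CO": (9, 1.6724, 1.488),
    "CH2CO": (9, 1.4457, 1.180),
}

# (main m, main n) -> a_mn in K; a_mm = 0
A = {
    (1, 3): 61.13, (3, 1): -11.12,
    (1, 4): 76.50, (4, 1): -69.70,
    (1, 5): 986.5, (5, 1): 156.4,
    (1, 8): 1333.0, (8, 1): 275.8,
    (1, 9): 476.4, (9, 1): 26.76,
    (3, 4): 167.0, (4, 3): -146.8,
    (3, 5): 636.1, (5, 3): 89.60,
    (3, 8): 1329.0, (8, 3): 25.34,
    (3, 9): 25.77, (9, 3): 140.1,
    (4, 5): 803.2, (5, 4): 25.82,
    (4, 8): 884.9, (8, 4): 244.2,
    (4, 9): -52.10, (9, 4): 365.8,
    (5, 8): -259.7, (8, 5): -451.6,
    (5, 9): 84.00, (9, 5): 164.5,
    (8, 9): -356.1, (9, 8): -133.1,
}


def _psi(m, n, t):
    if m == n:
        return 1.0
    return math.exp(-A[(m, n)] / t)


def _group_gammas(group_counts, t):
    """ln(Gamma_k) for every subgroup present in ``group_counts``."""
    names = sorted(group_counts)
    total = sum(group_counts.values())
    X = {k: group_counts[k] / total for k in names}
    qx = {k: SUBGROUPS[k][2] * X[k] for k in names}
    s = sum(qx.values())
    theta = {k: qx[k] / s for k in names}
    out = {}
    for k in names:
        mk = SUBGROUPS[k][0]
        log_term = math.log(
            sum(theta[m] * _psi(SUBGROUPS[m][0], mk, t) for m in names))
        frac_term = 0.0
        for m in names:
            mm = SUBGROUPS[m][0]
            denom = sum(theta[n] * _psi(SUBGROUPS[n][0], mm, t)
                        for n in names)
            frac_term += theta[m] * _psi(mk, mm, t) / denom
        out[k] = SUBGROUPS[k][2] * (1.0 - log_term - frac_term)
    return out


def ln_gamma(molecules, x, t, z=10.0):
    """ln(gamma) for each molecule; molecules are subgroup-count dicts."""
    n = len(molecules)
    r = [sum(cnt * SUBGROUPS[g][1] for g, cnt in mol.items())
         for mol in molecules]
    q = [sum(cnt * SUBGROUPS[g][2] for g, cnt in mol.items())
         for mol in molecules]
    sum_xr = sum(x[i] * r[i] for i in range(n))
    sum_xq = sum(x[i] * q[i] for i in range(n))
    l = [z / 2.0 * (r[i] - q[i]) - (r[i] - 1.0) for i in range(n)]
    sum_xl = sum(x[i] * l[i] for i in range(n))
    ln_c = []
    for i in range(n):
        phi_x = r[i] / sum_xr
        theta_x = q[i] / sum_xq
        ln_c.append(math.log(phi_x) + z / 2.0 * q[i]
                    * math.log(theta_x / phi_x) + l[i] - phi_x * sum_xl)
    mixture_counts = {}
    for i, mol in enumerate(molecules):
        for g, cnt in mol.items():
            mixture_counts[g] = mixture_counts.get(g, 0.0) + x[i] * cnt
    ln_G_mix = _group_gammas(mixture_counts, t)
    ln_r = []
    for i, mol in enumerate(molecules):
        ln_G_pure = _group_gammas(mol, t)
        ln_r.append(sum(cnt * (ln_G_mix[g] - ln_G_pure[g])
                        for g, cnt in mol.items()))
    return [c + rr for c, rr in zip(ln_c, ln_r)]
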