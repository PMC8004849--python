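# Methods

This package models binary terpene eutectic solvent systems — menthol,
thymol, borneol and camphor combined pairwise as Men:Bor (7:3), Men:Cam
(3:2), Thy:Bor (7:3) and Thy:Cam (1:1) — and asks the question that defines
a deep eutectic solvent (DES): does the real eutectic temperature fall
significantly below the ideal-solution prediction?

## Solid–liquid equilibrium

Each liquidus branch follows the simplified melting-equilibrium relation
(Schröder–van Laar form, heat-capacity change on fusion neglected):

    ln(x_i γ_i) = (ΔH_fus,i / R) (1/T_fus,i − 1/T)

with R = 8.314 J/(mol K).  The eutectic (x_E, T_E) is the temperature at
which the two branch mole fractions sum to one.  Melting data are the DSC
values shipped with the package (menthol 309.72 K / 13.62 kJ/mol, thymol
324.31 K / 18.54 kJ/mol, borneol 481.33 K / 7.23 kJ/mol, camphor 452.41 K /
6.32 kJ/mol).

**Units.** The source table labels ΔH_fus "J/mol", but the magnitudes are
only consistent with kJ/mol: in J/mol the melting-point depressions would be
thousands of kelvin.  The package therefore stores ΔH_fus in kJ/mol and
converts to J/mol at the point of use; the ideal eutectics this yields
(289.9 K for Men:Bor, 284.7 K for Men:Cam, 300.1 K for Thy:Cam) match the
published summary, which confirms the reading.

**Numerics.** The outer solve brackets T on [t_floor, min T_fus) and uses
Brent iteration (tolerance 1e-8 K); the default floor of 150 K sits well
below any plausible terpene eutectic while still catching strongly
non-ideal systems.  The inner composition solve uses the ideal closed form
as a starting point, damped successive substitution (damping 0.5, ≤200
iterations, residual < 1e-10), and falls back to a bracketed Brent solve
on ln(xγ) − RHS scanning from x = 1 downward, which also handles strongly
non-ideal models where fixed-point iteration leaves (0, 1].  Every
reported eutectic carries both branch residuals and a convergence flag.

**Known inconsistencies in the published summary.** Two printed ideal
values are not self-consistent with the printed melting data: the Thy:Bor
ideal point (309.6 K, 0.722) lies on the thymol branch alone — the
simultaneous solution is ≈305.1 K at x ≈ 0.648 — and the Thy:Cam ideal
composition (0.457) disagrees with the self-consistent 0.574 even though
its temperature (300.1 K) reproduces; a digit transposition is plausible.
The solver reports the self-consistent values and the tests document the
discrepancy rather than forcing agreement.  Men:Bor is a milder case: the
printed (289.8 K, 0.696) pair sums its branch fractions to 0.998, and the
exact solution is 289.9 K / 0.697 — agreement is asserted at ±0.2 K.

## Activity models

`ideal` returns γ = 1.  `unifac` is an original-UNIFAC implementation
(Flory–Huggins combinatorial with Staverman–Guggenheim correction, z = 10;
solution-of-groups residual with ψ_mn = exp(−a_mn/T)) against the
published VLE parameter table (Hansen et al. 1991 lineage), shipped as CSV
data files with provenance headers and a version tag recorded in every
result.  Correctness is anchored two ways: a scalar-loop reference
transcription written independently of the vectorized implementation
(agreement to 1e-6 in ln γ), and the published worked example of dilute
acetone in n-pentane at 307 K (γ ≈ 4.99 / 1.005).

Group assignments are declared data, atom-balanced against each compound's
formula: menthol 3×CH3 + 3×CH2 + 4×CH + OH; borneol 3×CH3 + 3×CH2 + 2×CH +
2×C + OH; camphor 3×CH3 + 2×CH2 + CH + 2×C + CH2CO; thymol 3×ACH + ACCH3 +
ACCH + 2×CH3 + ACOH.  For the two terpene-alcohol pairs this predicts
near-ideality (γ ≤ 1.01 along the Men:Bor liquidus) and a Men:Bor eutectic
of 290.0 K, both matching the published analysis.  For the thymol systems
the phenol-type ACOH fragmentation predicts a much stronger negative
deviation (eutectics at 269.1 and 274.7 K) than the published UNIFAC
values (300.8 and 281.7 K).  The original fragmentation and the exact
parameter revision used there are not recoverable from the publication;
the alternative fragmentation (bare aromatic carbon + alkanol OH) flips
the deviation positive and is qualitatively wrong, so the ACOH assignment
is retained and the quantitative gap is documented (one acceptance test
records it as an expected failure of reproduction, not of the solver).
The deep-eutectic classification itself — T_E,real < T_E,ideal − 0.5 K —
is reproduced for both thymol systems under either reading.

## Critical properties and property correlations

The empirical density, surface-tension and refractive-index correlations
consume mixture pseudocritical properties.  These are estimated by the
modified Lydersen–Joback–Reid group-contribution chain:

* Tb = 198.2 + Σ n_k ΔTbM_k (Joback–Reid),
* Tc = Tb / (0.5703 + 1.0121 S_T − S_T²), Pc = M/(0.2573 + S_P)² bar,
  Vc = 6.75 + S_V cm³/mol (modified Lydersen),
* acentric factor from (Tb, Tc, Pc) — Rudkin's equation by default, as
  customarily paired with this chain in the DES property-correlation
  literature; Edmister and Lee–Kesler are available as strategies,
* Lee–Kesler combining rules for the mixture (mole-fraction-linear
  averaging as the alternative strategy).

The publication's own appendix of numeric critical properties is not
reprinted in the text available to us, so the chain is validated end to
end instead: it reproduces the published theoretical densities of all four
systems to 0.2–1% and the refractive indices to 0.1–0.3%, which would not
happen if the group table, the ω correlation or the mixing rule deviated
materially from the original chain.

**Refractive-index term grouping.**  The published correlation is typeset
flattened; the a6 term is read as a6 ω²/M_w — the only reading producing
physical values (the printed "mol/g" unit for a6 is then a g/mol
transposition).

**Surface-tension term grouping — unresolved.**  The flattened typesetting
of the surface-tension correlation admits many readings.  The unique
dimensionally consistent grouping (σ5 a3 M_w √T/P_c · ln(V_c ρ a4/√T))
produces ~370 mN/m — unphysical — and a systematic scan of ~900 candidate
groupings (exponent and placement variants over T, P_c, M_w, ω, with
theoretical or measured density) found none that reproduces the published
values (best RMSE ≈ 5.7 mN/m, with the wrong ordering across systems).
The package therefore ships both the dimensional reading and the
best-matching "empirical" reading (default; it at least yields physical
magnitudes in the 20–35 mN/m range), exposes the choice as a parameter,
and pins both by regression tests.  The published *error* table is
unaffected: it follows from the published property values themselves,
which the package reproduces cell by cell.

Molar masses derive from the conventional IUPAC atomic weights
(C 12.0107, H 1.00794, O 15.9994); these reproduce the published mixture
molecular weights to 2 d.p., which newer CIAAW roundings do not.

## NMR temperature coefficients

The temperature coefficient of an O–H proton is the OLS slope of chemical
shift vs temperature (ppm/K), fit by `scipy.stats.linregress` over at
least three strictly increasing temperatures.  Classification follows the
standard nonpolar-solvent thresholds: slope < −0.005 ppm/K →
intermolecular hydrogen bonding, slope > −0.003 ppm/K → intramolecular;
the closed band [−0.005, −0.003] is reported as indeterminate because the
published thresholds are strict inequalities and leave it unassigned.  The
per-system shift series behind the original figures are not printed
numerically anywhere, so all series used in tests are synthetic
reconstructions (linear with Gaussian noise, slopes inside the reported
−0.0212…−0.012 ppm/K window) and are labelled as such.

## Synthetic data and oracles

The generators are pure functions of (spec, seed).  Synthetic binary
systems draw melting points from 300–490 K and fusion enthalpies from
5–20 kJ/mol — the neighbourhood spanned by the four terpenes — with
fabricated molar masses in 120–200 g/mol.  The two-parameter Margules
model serves as the analytic non-ideal oracle (closed-form γ, tunable
deviation sign); it is a test instrument, not a claim about the chemistry.
The brute-force eutectic locator scans (x, T) for the point minimizing the
joint liquidus residuals; the scan is pyramidal (coarse full-range pass,
then full-resolution refinement around the coarse optimum, final accuracy
bounded by the requested 1e-4 / 0.01 K steps), which is valid because the
joint-residual surface of a simple-eutectic system is unimodal.  Solver
and oracle agree within grid resolution on the fixture systems and on 20
seeded synthetic systems under both ideal and Margules models.

What the synthetic data do not emulate: DSC thermograms, solid solutions
or co-crystals, ternary systems, and spectral peak shapes.  Passing the
synthetic suites therefore demonstrates solver correctness under the
stated thermodynamic model, not the model's adequacy for any particular
real mixture.

## Problem sizes

Default test and acceptance workloads are small by construction: liquidus
grids of ~100 points, 20-seed oracle batteries, 200-seed NMR Monte Carlo,
brute-force refinement windows of a few hundred thousand grid points.  The
full pipeline over all four systems and both activity models completes in
seconds.
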