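# eutectics

Thermodynamic characterization of binary terpene eutectic solvent systems:
solid–liquid equilibrium (SLE) phase diagrams, eutectic-point location,
deep-eutectic classification, group-contribution critical properties,
empirical physical-property correlations, and ¹H-NMR temperature-coefficient
hydrogen-bond analysis.

Monoterpene pairs such as menthol:borneol or thymol:camphor form
low-melting liquids that are candidate deep eutectic solvents (DES) — green
media for pharmaceutical and extraction applications.  Whether a pair truly
qualifies as "deep" is a thermodynamic question: its measured eutectic
temperature must fall significantly below the ideal-solution prediction,
i.e. T_E,real < T_E,ideal.  This package answers that question
computationally for any binary pair with known melting properties, and for
the four built-in terpene systems in particular.

## The model

For each component *i* in equilibrium with its pure solid, the liquidus
obeys (ΔC_p neglected)

    ln(x_i γ_i) = (ΔH_fus,i / R) · (1/T_fus,i − 1/T)

The eutectic is the intersection of the two branches, solved by bracketed
Brent iteration on T with inner composition solves.  Activity coefficients
γ come from a pluggable model: the ideal solution (γ = 1) or a from-scratch
original UNIFAC (Flory–Huggins + Staverman–Guggenheim combinatorial,
solution-of-groups residual, published VLE parameter table shipped as CSV).
Physical properties (density, surface tension, refractive index) follow
empirical DES correlations driven by mixture pseudocritical properties from
the modified Lydersen–Joback–Reid group-contribution method with Lee–Kesler
mixing rules.  NMR shift-vs-temperature series are fit by OLS and
classified by the standard −0.005 / −0.003 ppm/K thresholds.  See
`docs/methods.md` for assumptions, parameter provenance and limitations.

## Worked example

```python
from eutectics import builtin_fixtures, find_eutectic, UNIFAC, classify_deep

reg = builtin_fixtures()           # the four terpenes, four systems
system = reg["Men:Bor"]            # menthol:borneol (7:3)

ideal = find_eutectic(system)
real = find_eutectic(system, UNIFAC.default())
print(f"ideal  : T_E = {ideal.t_e:.1f} K, x_E = {ideal.x_e:.3f}")
print(f"UNIFAC : T_E = {real.t_e:.1f} K, x_E = {real.x_e:.3f}")
print(classify_deep(real.t_e, ideal.t_e))
```

prints

```
ideal  : T_E = 289.9 K, x_E = 0.697
UNIFAC : T_E = 290.0 K, x_E = 0.697
~ideal
```

i.e. the menthol:borneol eutectic melts near 290 K at about 70 mol%
menthol, and UNIFAC — both components being terpene alcohols with the same
functional groups — predicts nearly ideal mixing (γ ≤ 1.01), so any deep
eutectic behaviour for this pair must come from interactions the
group-contribution model does not capture.  The thymol systems, by
contrast, show a clear negative deviation (`classify_deep` reports a DES
candidate).

The same pipeline is scriptable from the shell:

```sh
eutectics eutectic "Thy:Cam" -a ideal -a unifac   # JSON eutectic summary
eutectics props "Men:Bor" -t 298                  # property report (CSV)
eutectics diagram "Men:Cam" --plot mencam.png     # liquidus curves
eutectics tcoeff shifts.csv                       # NMR T-coefficients
eutectics report --outdir results                 # everything, with provenance
```

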