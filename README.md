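# synergize

Boltzmann-energy analysis of two-colour fluorescence images of immune
synapses: does protein segregation at the contact follow from
extracellular-domain **size** alone?

At T- and NK-cell synapses, short receptor–ligand pairs (CD2–CD58,
KIR–HLA-Cw6; bond length `z_C ≈ 13 nm`) segregate from the long unbound
ligand ICAM1 (`z_I = 18 nm`). If both species pay a quadratic elastic
price for a mismatched inter-membrane separation `z`,

```
E_C(z) = λ_C (z − z_C)²,   E_I(z) = λ_I (z − z_I)²      [kT]
```

then local Boltzmann equilibrium (`c = c_ref e⁻ᴱ`) predicts a *linear*
relation between the square-root exclusion energies (SQRE) of the two
fluorophores at every pixel:

```
e_I = α − β e_C,    β = √(λ_I/λ_C),    α = √λ_I (z_I − z_C)
```

and the reaction–diffusion model built on the same springs predicts
spontaneous patterning exactly when the uniform state crosses the
stability curve `e_I(2e_C² − 1) + β e_C(2e_I² − 1) = 0` — a curve set by
the same β the image regression measures. The package implements the
whole chain:

- `energy_model` — springs, Boltzmann energy/concentration maps, the
  SQRE line, membrane-sheet effective spring constant;
- `pattern_dynamics` — the 5-field reaction–diffusion model, uniform
  steady states, analytic instability margin + numerical dispersion
  relation, stability curve and patternation test, PDE simulator,
  close-contact patch statistics;
- `fluorescence_model` — Poisson/Gaussian/Gamma photon-count
  likelihoods for free-surface and contact-interface pixels, barrier
  factor, background, 3D membrane-thickness profile;
- `inference` — adaptive Metropolis-within-Gibbs MCMC for the
  unconstrained (per-pixel energies) and constrained (line-imposed)
  fits, Gelman–Rubin diagnostics, slope-unity test, patternation
  posterior, hidden-separation reconstruction;
- `imaging_pipeline` — preprocessing, Richardson–Lucy deconvolution,
  chromatic-shift correction, 3D contour tracking, region extraction,
  channel correlation;
- `synthetic_data` — ground-truth generators for bilayer images,
  NK-like z-stacks and step/PSF phantoms (no microscopy data are
  bundled; everything is generated).

## Worked example

Generate a synthetic bilayer synapse (β = 0.7, α = 1.6, ~2000 interface
pixels, Poisson counts), fit it both ways, and test the patternation
criterion:

```python
import numpy as np
from synergize import (FluorModelSpec, fit_unconstrained, fit_constrained,
                       generate_bilayer, patternation_test)
from synergize.energy_model import RegressionLine
from synergize.imaging_pipeline import TwoChannelImage, channel_correlation
from synergize.inference import patternation_posterior, slope_unity_test

spec = FluorModelSpec()                      # Poisson shot-noise model
counts_small, counts_long, truth = generate_bilayer(seed=42, spec=spec)
print("interface pixels:", int(truth.ci_mask.sum()))
r = channel_correlation(TwoChannelImage(counts_small, counts_long), truth.ci_mask)
print(f"channel correlation (ci): {r:.2f}")

fit = fit_unconstrained(counts_small, counts_long, truth.fs_mask, truth.ci_mask,
                        spec=spec, seed=42)
print(f"TLS slope through posterior-mean SQREs: {fit.line['slope']:.3f} "
      f"(truth -0.700), max R-hat {fit.max_rhat:.2f}")

con = fit_constrained(counts_small, counts_long, truth.fs_mask, truth.ci_mask,
                      spec=spec, seed=42)
b = con.params["beta"]
print(f"beta posterior: {b['mean']:.3f} [{b['ci_low']:.3f}, {b['ci_high']:.3f}]")
print("slope-unity test:", slope_unity_test(con)["one_in_ci"])
print(f"P(patternation possible): {patternation_posterior(con)['p_intersect']:.3f}")
res = patternation_test(RegressionLine(alpha=con.params['alpha']['mean'], beta=b['mean']))
print("unstable segment on the SQRE line:",
      tuple(round(x, 2) for x in res.unstable_segments[0]))
```

Output:

```
interface pixels: 1976
channel correlation (ci): -0.94
TLS slope through posterior-mean SQREs: -0.713 (truth -0.700), max R-hat 1.01
beta posterior: 0.688 [0.667, 0.704]
slope-unity test: False
P(patternation possible): 1.000
unstable segment on the SQRE line: (0.46, 2.07)
```

Reading it: the two channels exclude each other (r = −0.94 in the
shot-noise limit; overdispersed default images land in the −0.4…−0.7
range seen in real synapses); a fit that never assumes the line finds a
straight SQRE relation with slope −0.713; imposing the line gives
β = 0.69 [0.67, 0.70], excluding β = 1 (the springs are asymmetric:
accommodating unbound ICAM1 is cheaper than stretching the bond); and
every posterior draw of the line crosses the instability region, i.e.
there exist ligand densities at which this synapse would pattern by
size exclusion alone — the segment e_C ∈ (0.46, 2.07) of the steady-state
line is the unstable stretch.

A thin CLI mirrors the library: `synergize synth | preprocess |
contour | fit | stability | simulate`, each with `--seed` and a JSON
run-log.

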