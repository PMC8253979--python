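# moltenfit

Fluorescence and circular-dichroism analysis for characterizing
intrinsically disordered proteins (IDPs) and molten globules in solution.

Whether a protein domain is a compact fold, a molten globule, or a
disordered chain is decided in practice by a battery of solution
spectroscopy assays: equilibrium binding by fluorescence anisotropy,
chemical-denaturation transitions followed by the tryptophan emission
maximum, Stern–Volmer quenching, time-correlated single-photon counting
(TCSPC), ANS hydrophobic-probe fluorescence, far-UV CD, and sequence
composition statistics. `moltenfit` implements the quantitative analysis
for every one of these stages as scikit-learn-style estimators (with
`fit`/`predict`, `get_params`, and fitted attributes ending in `_`),
plus seeded synthetic-data generators with the same statistical structure
the analyses assume — so every fit can be validated end to end by
parameter recovery without any instrument files.

## Models at the core

* **Tight-binding (quadratic) isotherm** — for a labeled species A at
  total concentration A₀ titrated with partner T (total T₀), the bound
  fraction is the exact mass-action root
  f_b = [A₀+T₀+K_D − √((A₀+T₀+K_D)² − 4A₀T₀)]/(2A₀), and the
  steady-state anisotropy is r = r_A + (r_AT − r_A)·f_b. Fitting r(T₀)
  yields K_D, with bootstrap uncertainties.
* **Unfolding sigmoid** — λ(D) = λ_N + (λ_U − λ_N)/(1 + e^{(x−D)/a})
  for the emission maximum versus denaturant D; the width `a` (inversely
  proportional to the midpoint slope (λ_U−λ_N)/4a) quantifies unfolding
  cooperativity. A Gaussian-peak model handles non-monotone (ANS-type)
  profiles.
* **Stern–Volmer quenching** — F₀/F = 1 + K_SV[Q] (collisional), or the
  product (1 + K_dyn[Q])(1 + K_static[Q]) when ground-state dark
  complexes add static quenching; comparing intensity- and lifetime-based
  plots classifies the mechanism.
* **TCSPC reconvolution** — I(t) = IRF ⊛ Σᵢ Aᵢ e^{−t/τᵢ}, fitted with
  Poisson (Neyman) weights and reduced χ²; amplitude- and
  intensity-weighted mean lifetimes.
* **Anisotropy decay** — r(t) = (I_VV − G·I_VH)/(I_VV + 2G·I_VH) tail-
  fitted with r(t) = r∞ + Σᵢ Aᵢ e^{−t/θᵢ}; the rotational correlation
  time θ is compared against the hydrated-sphere expectation
  θ = η·M(ν̄+h)/(R·T).
* **Sequence & CD** — disorder-/order-promoting residue fractions
  (A,G,R,D,H,Q,K,S,E,P vs W,F,Y,I,M,L,V,N,C,T), average mass, ε₂₈₀;
  mean residue ellipticity [θ] = θ_mdeg·MRW/(10·l·c) and classification
  on the ([θ]₂₀₀, [θ]₂₂₂) double-wavelength plane.

## Worked example

Simulate an anisotropy titration with a known dissociation constant and
refit it:

```python
import numpy as np
import moltenfit as mf
from moltenfit.simulate import NoiseModel, gen_titration

curve = gen_titration(
    kd=2.5, r_a=0.18, r_at=0.26, a0=1.2,          # μM / anisotropy units
    grid=np.linspace(0, 40, 12),                   # titrant, μM
    noise=NoiseModel(additive_sd=0.004, seed=7),
)
fit = mf.fit_binding(curve, n_bootstrap=200, random_state=7)
print(f"K_D = {fit.kd_:.2f} ± {fit.kd_err_:.2f} µM  "
      f"(r_A={fit.r_a_:.3f}, r_AT={fit.r_at_:.3f})")
```

```
K_D = 2.76 ± 5.74 µM  (r_A=0.180, r_AT=0.260)
```

The recovered K_D (2.76 µM) agrees with the 2.5 µM ground truth within
the noise of a single 12-point curve; the wide bootstrap interval is an
honest statement of how little one noisy titration constrains a
micromolar constant — averaging replicate curves before fitting narrows
it substantially. The same loop exists for every stage: a TCSPC decay
simulated with τ = 2.84 ns and Poisson counting noise refits to within
one percent with reduced χ² ≈ 1, and a denaturation series generated
with a 25 nm red shift returns the shift to a tenth of a nanometre.

The same operations are exposed as CLI subcommands
(`moltenfit simulate | seq-profile | binding-fit | transition-fit |
quench-fit | tcspc-fit | anis-fit | cd-mre | cd-classify`), all reading
the package's `#`-metadata delimited text formats and writing JSON fit
reports that record parameters, uncertainties, goodness of fit, and the
seed.

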