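# enzkin

Kinetic and sequence-level characterization of ester-hydrolyzing enzymes
(lipases/esterases assayed on chromogenic 4-nitrophenyl esters), built as
scikit-learn-style estimators over numpy/scipy, with a synthetic-data
generator that carries its own ground truth.

## Who this is for

Enzymologists and biocatalysis groups who measure initial velocities on
4-nitrophenyl esters and want a reproducible, scriptable path from raw rate
tables to the standard characterization package: Michaelis–Menten constants,
the bell-shaped pH dependence of kcat/Km and kcat, the temperature dependence
decomposed into elementary rate constants, transition-state thermodynamics,
salt-effect summaries, thermostability, and the sequence signatures
(AXXXA repeats, G-X-S-X-G nucleophilic elbow, Ala content, mass, pI) that
accompany a thermostable-lipase report.

## The models

**Michaelis–Menten.** v = V<sub>max</sub>[S]/(K<sub>m</sub>+[S]), fitted by
nonlinear least squares in log-parameter space; kcat = V<sub>max</sub>/[E]
with the active enzyme concentration in nM. Units follow the reporting
convention kcat (s⁻¹), K<sub>m</sub> (mM), kcat/K<sub>m</sub> (M⁻¹ s⁻¹).
A two-regime protocol (zero-intercept slope at low [S], plateau mean at high
[S]) is also provided.

**pH dependence (two-pKa bell).**

    k_obs(pH) = k_lim / (1 + 10^(pKa1 − pH) + 10^(pH − pKa2))

with pKa1 < pKa2 enforced by reparameterization. The analytic pH optimum is
the midpoint (pKa1 + pKa2)/2.

**Temperature dependence.** For the acyl-enzyme scheme
E+S ⇌(k₁/k₋₁) ES →(k₂) E_acyl →(k₃) E+P, each elementary constant follows
k_i(T) = (k_i)₀ exp[−E_i/R (1/T − 1/T₀)], giving
kcat/K<sub>m</sub> = k₁k₂/(k₋₁+k₂) and kcat = k₂k₃/(k₂+k₃). The two observed
profiles are fitted jointly with (k₂)₀ and E₂ shared, with an explicit
identifiability report (only k₁ and the ratio k₋₁/k₂ are identified from the
kcat/K<sub>m</sub> profile alone). A descriptive alternative couples a
reversible-inactivation sigmoid to a single Arrhenius rise.

**Thermodynamics.** Eyring linearization
T·ln(k/T) = T·[ln(k_B/ħ) + ΔS‡/R] − ΔH‡/R solved by ordinary least squares;
reaction energy diagrams from Arrhenius barriers E_a = RT·ln(A/k) under an
assumed pre-exponential A (default 6×10¹² s⁻¹); ground-state levels are
A-invariant.

**Sequence descriptors.** Average mass, Henderson–Hasselbalch pI by
bisection, residue composition, overlap-counted AXXXA motifs, G-X-S-X-G
scan, and precursor→mature cleavage bookkeeping.

## Worked example

```python
import numpy as np
from enzkin import (MichaelisMentenParams, SimulationSpec,
                    simulate_velocity_curve, fit_michaelis_menten,
                    PHProfileModel, simulate_ph_profile, fit_ph_profile)

truth = MichaelisMentenParams("4-nitrophenyl acetate", kcat=1.736e-3, km_mM=0.473)
spec = SimulationSpec(seed=3, grid=(0.05, 0.1, 0.25, 0.5, 1, 2, 3.5, 5),
                      noise_rel_sd=0.03, n_replicates=8)
data = simulate_velocity_curve(truth, enzyme_conc_nM=850.0, spec=spec)
fit = fit_michaelis_menten(data)
print(f"kcat = {fit.kcat:.6g} s^-1, Km = {fit.km_mM:.6g} mM, "
      f"kcat/Km = {fit.kcat_over_km:.6g} M^-1 s^-1")

model = PHProfileModel(k_lim=2.33, pka1=7.42, pka2=8.29)
prof = simulate_ph_profile(model, SimulationSpec(
    seed=3, grid=tuple(np.linspace(6.0, 9.5, 25)), noise_rel_sd=0.03,
    n_replicates=8))
ph = fit_ph_profile(prof)
print(f"pKa1 = {ph.model.pka1:.4f}, pKa2 = {ph.model.pka2:.4f}, "
      f"optimum = {ph.ph_optimum:.4f}")
```

prints

```
kcat = 0.00172689 s^-1, Km = 0.465161 mM, kcat/Km = 3.71246 M^-1 s^-1
pKa1 = 7.4315, pKa2 = 8.2835, optimum = 7.8575
```

The fitted constants recover the generating values to within the 3%
measurement noise: kcat within 0.5%, K<sub>m</sub> within 2%, both pKa's
within ~0.01 pH units, and the pH optimum lands at the pKa midpoint.

The same analyses are available from the shell (`enzkin simulate`,
`enzkin fit-mm`, `enzkin fit-ph`, `enzkin fit-temp`, `enzkin eyring`,
`enzkin thermostability`, `enzkin seqscan`, `enzkin report`); `enzkin report`
runs the whole pipeline from one configuration and writes a deterministic
plain-text report.

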