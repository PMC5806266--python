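# Methods

This note documents the models implemented in `enzkin`, the numerical
choices behind the fits, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Assay model and units

All kinetics are modelled at the initial-velocity level of a chromogenic
4-nitrophenyl-ester assay (release of 4-nitrophenol followed at 405 nm),
with the active enzyme concentration [E] given in nM. Absorbance-to-rate
conversion is out of scope; velocities enter in M s⁻¹ (or any consistent
unit, since kcat is formed as V_max/[E]). Reporting units are the field's
conventions: kcat in s⁻¹, K_m in mM, kcat/K_m in M⁻¹ s⁻¹; the single
mM→M factor of 10³ is applied in exactly one place
(`MichaelisMentenParams.kcat_over_km`), and the efficiency is always derived
from kcat and K_m, never stored separately, so the three numbers cannot
drift apart. Physical constants (R = 8.314 J mol⁻¹ K⁻¹,
k_B/ħ = 2.08366×10¹⁰ K⁻¹ s⁻¹, 1 cal = 4.184 J, water 18.01524 Da) live in
one registry (`constants.py`) that tests pin exactly.

## Michaelis–Menten estimation

The full fit is unweighted nonlinear least squares of
v = V_max[S]/(K_m+[S]) over pooled replicates (pooling, rather than
averaging first, preserves the error structure; an optional relative
weighting is exposed for strongly heteroscedastic data). Positivity is
enforced by optimizing (log V_max, log K_m); initial guesses are
V_max ← max(v) and K_m ← the [S] whose velocity is nearest half-max.
Standard errors are asymptotic (delta method through the log
parameterization). A fit whose K_m exceeds the largest tested [S] is
returned but flagged: the plateau was never approached and kcat is weakly
constrained. The two-regime protocol estimates kcat/K_m as the
zero-intercept regression slope of v on [S] at low [S] divided by [E], and
kcat as the plateau mean at high [S] divided by [E]; K_m follows as their
quotient. The plateau estimate carries a known negative bias
K_m/(K_m+[S]) — below 2% once [S] ≥ 50 K_m — and the low-[S] slope a
positive curvature bias of order max[S]/K_m; both are inherent to the
protocol, not to the implementation. Regime boundaries are the caller's
declaration; overlapping regimes are rejected rather than reinterpreted.

## Two-pKa pH model

k_obs(pH) = k_lim / (1 + 10^(pKa1−pH) + 10^(pH−pKa2)) describes activity
requiring one group deprotonated and another protonated. The curve is
unimodal and log-symmetric about the analytic optimum (pKa1+pKa2)/2. The
fit enforces pKa1 < pKa2 through the reparameterization
(pKa1, pKa1 + e^θ) and takes initial pKa guesses from the half-max
crossings on each flank. Data whose maximum sits on the grid boundary cover
only one flank and are refused (the second pKa would be unbounded). Fitted
separations below 0.3 pH units are returned but flagged: k_lim and the pKa
pair become strongly correlated there. Fewer than six distinct pH points
triggers a warning, not an error.

## Temperature decomposition

For the minimal acyl-enzyme scheme, kcat/K_m = k₁k₂/(k₋₁+k₂) and
kcat = k₂k₃/(k₂+k₃), with each elementary constant Arrhenius-dependent
relative to T₀ (default 313.15 K, the 40 °C assay). The numerator energy of
the efficiency profile is E₁+E₂, the dimensionally and mechanistically
coherent combination. The two profiles are fitted jointly with (k₂)₀ and E₂
shared. Residuals are scaled by each profile's maximum so the two
differently scaled observables contribute comparably; optimization runs in
log space for the rate constants with energies bounded at zero, from 16
seeded multistarts (the joint objective is multimodal).

Identifiability is treated explicitly rather than papered over: the
efficiency equation alone identifies only k₁ and the ratio k₋₁/k₂, and the
kcat equation is symmetric under exchange of (k₂, E₂) and (k₃, E₃). Sharing
(k₂)₀, E₂ helps but does not fully resolve either degeneracy, so the fit
reports the condition number of the Jacobian and names the parameters
dominating any near-null singular directions, and accepts user-fixed
parameters (`fixed={...}`). Pinning k₋₁'s value at T₀ and its activation
energy renders every remaining parameter identifiable — the configuration
used by the constrained-recovery test. Predictions (as opposed to parameter
vectors) are well determined either way: the noiseless self-consistency
test reproduces both profiles to 1e−8 relative.

With all activation energies positive, kcat = k₂k₃/(k₂+k₃) is monotone
increasing in T, so its optimum on a finite range sits at the upper
boundary; an interior kcat/K_m optimum arises when E₋₁ exceeds E₁+E₂. The
packaged reference parameter set (`REFERENCE_RATES`) was chosen once to
give an interior efficiency optimum near 42 °C, a kcat near 1.7×10⁻³ s⁻¹
at 40 °C, and E₃ ≫ E₂ so the kcat profile culminates at higher temperature
than the efficiency profile — the qualitative physiognomy of a
thermotolerant lipase. The descriptive alternative (reversible-inactivation
sigmoid × Arrhenius rise) is fitted the same way; monotone data leave its
inactivation parameters non-identified and the result is flagged.

`temperature_optimum` localizes the argmax on a 0.01 K grid and refines it
by bounded scalar optimization; optima within 0.02 K of a range end are
boundary-flagged. The thermostability summary reports the highest
preincubation temperature whose residual activity meets the threshold
(default 0.95 — "full activity" is not a quantified notion, so the cutoff
is a package choice exposed as a parameter).

## Eyring analysis and energy diagrams

Regressing T·ln(k/T) on T gives ΔS‡ = R(slope − ln(k_B/ħ)) and
ΔH‡ = −R·intercept; ΔG‡(T) = ΔH‡ − TΔS‡. The transform is exact, so
noiseless round trips recover both quantities to machine precision, and
ΔG‡ computed from the line equals RT·ln((k_B T/ħ)/k(T)) identically.
Applying the first-order Eyring form to a second-order constant (kcat/K_m)
makes ΔS‡ standard-state dependent; the package computes it per rate
constant and leaves the standard-state caveat to the caller.

Energy diagrams use Arrhenius barriers E_a = RT·ln(A/k) under an assumed
pre-exponential A (default 6×10¹² s⁻¹). Levels: E+S ≡ 0, TS1 = E_a(k₁),
ES = E_a(k₁) − E_a(k₋₁) (= RT·ln(k₋₁/k₁), the binding free energy),
TS2 = ES + E_a(k₂). Because the reverse of the acylation step is not
modelled, the acyl-enzyme is placed below TS2 by the deacylation barrier
E_a(k₃), which makes TS3 coincide with TS2; the diagram therefore ends at
that barrier and carries no E+products level. Ground-state levels are
invariant to A (it cancels in every difference); barriers shift uniformly
by RT·ln(A′/A). Rates exceeding A are rejected as negative barriers.

## Sequence descriptors

Average masses use the ExPASy residue table plus one water; X residues are
excluded with a warning. The pI solves net charge = 0 by bisection on
[0, 14] to 1e−4, with Henderson–Hasselbalch fractional charges for the
termini and D, E, C, Y, H, K, R; the default pKa set is the Bjellqvist
table behind the common web tools, with an EMBOSS alternative, and the
table is swappable — pI comparisons across tools should therefore carry a
tolerance of a few tenths of a pH unit. AXXXA motifs are counted with
overlaps (an alanine may close one motif and open the next); this is the
permissive reading and the one the planted fixtures verify. The
G-X-S-X-G scan reports 1-based match starts (catalytic serine at
start + 2). Cleavage bookkeeping takes the cleavage index as an input —
signal-peptide prediction is deliberately out of scope.

## Synthetic data: what it emulates, and what it does not

Generators produce exactly what the fits consume — velocity tables, pH and
temperature profiles, residual-activity tables, and proteins with planted
motif inventories — each carrying its generating parameters for recovery
testing. The noise model is multiplicative Gaussian (relative SD 3% by
default) truncated at zero: velocities are positive, and error in this
assay format scales with signal. Replication defaults to 8 per condition,
the usual replication of these measurements; residual-activity values are
modelled as ratios of replicate-averaged activities, so their relative
noise scales as 1/√n_replicates. Determinism is contractual: identical
`SimulationSpec` ⇒ byte-identical output, and zero noise reproduces the
model pointwise.

What the generator does not emulate: absorbance traces, instrument drift,
substrate-solubility ceilings (the real limitation for longer-chain
esters), systematic pH-electrode error, or correlated replicate error.
Passing recovery tests therefore demonstrates estimator correctness and
calibration under the stated noise model, not robustness to those
real-world artifacts.

Motif planting verifies by re-scanning: candidates are drawn (alanine
count exact when a fraction is requested; alanines laid as a chain spaced
four apart when only a motif count is) and accepted only when the AXXXA
and elbow counts re-scan to the request, with bounded retries; infeasible
requests raise rather than silently under-plant.

## Problem sizes

Monte-Carlo recovery studies use 200 seeds with 25-point pH profiles and
8×8 velocity designs (the acceptance script) and 60–100 seeds in the unit
suite; these sizes put the standard error of the recovered means an order
of magnitude below the tolerances being checked while keeping the whole
suite in the tens of seconds. Temperature fits use 12-point grids
(20–75 °C in 5 °C steps), six points more than the minimum the joint fit
will accept.

## Known limitations

- The elementary-rate parameter vector is reported with, not purged of,
  its degeneracies; users who need unique parameters must supply
  constraints (and the identifiability block says which directions are
  flat).
- Second-order Eyring/barrier quantities depend on the 1 M standard state.
- No inhibition, interfacial-activation or three-pKa models; no coupling
  between the pH and temperature dependencies.
- The pI is sequence-only (no structure, no modified residues) and
  pKa-table dependent.
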