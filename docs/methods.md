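# Methods

## The physical model

A ubiquitin-associated (UBA) domain self-associates into a homodimer and,
only in its monomeric state, binds ubiquitin:

    D  ⇌  2 M        K_D,dimer   = [M]²/[D]
    M + P  ⇌  C      K_D,complex = [M][P]/[C]

All concentrations are totals in monomer-equivalent µM — a dimer counts as
two monomers — so the protein mass balance is [M] + 2[D] (+ [C]) = [M]_T.

Two NMR observables constrain the two constants:

**Dilution series (slow exchange).** Monomer and dimer interconvert slowly
relative to their chemical-shift difference, so each residue gives two
resolved peaks whose volumes V_m, V_d report populations directly:

    [M] = [M]_T · V_m/(V_m+V_d),   [D] = [M]_T · V_d/(2(V_m+V_d))

Only the within-spectrum ratio enters, so no inter-spectrum volume
normalization is needed and the volume units are arbitrary. Inverting the
mass balance at a given K gives the closed-form monomer concentration

    [M] = (−K + √(K² + 8[M]_T·K))/4

evaluated internally in the conjugate form 2[M]_T/(1+√(1+8[M]_T/K)), which is
stable in both the K→0 and K→∞ limits.

**CSP titration (fast exchange).** Ligand binding shifts the monomer peak
continuously; the combined amide perturbation is the conventional

    Δδ = [0.5·(ΔδH² + 0.2·ΔδN²)]^0.5

relative to the zero-ligand reference point (not sequential points). The
nitrogen weight 0.2 and prefactor 0.5 are fixed. The titration is fit with
the one-site quadratic (ligand-depletion) isotherm evaluated at the
*available monomer* concentration — [M] from the dimer equilibrium at zero
ligand, held constant across the titration:

    Δδ_obs = Δδ_max·{(M+P+K) − √((M+P+K)² − 4MP)}/(2M)

with P the total ligand concentration (the standard quadratic-depletion
convention; the decoupled treatment does not distinguish total from free P
beyond the depletion term).

## The decoupled approximation and its oracle

Holding [M] at its zero-ligand value ignores the re-equilibration of the
dimer pool as ligand consumes monomer. `ubafit.equilibrium` solves the full
coupled system exactly — eliminating dimer ([D]=[M]²/K_d) and complex
([C]=[M]·L_T/([M]+K_c)) reduces both mass balances to one strictly
increasing scalar equation in [M], bracketed on (0, P_T], solved by Brent's
method with a Newton polish (protein-balance residual ≤ 1e-12 µM; no seed
dependence). Every binding fit reports `decoupling_bias`, the maximum
relative deviation between the decoupled isotherm and the exact curve at the
fitted parameters over the measured ligand grid; under the wild-type-like
conditions used here it is of order 10%, which is why the headline fit
reproduces the decoupled computation and the exact solver is kept as a
diagnostic rather than silently substituted.

At zero ligand the solver must and does reduce to the closed-form [M] to
1e-8 relative tolerance over a 20×20 grid of K_D ∈ [0.1, 10³] µM and
[M]_T ∈ [1, 10³] µM (tested).

## Fitting strategy

**Dimer.** The fitted quantity is the residue-averaged monomer volume
fraction per concentration (the quantity typically plotted with 1 S.D.
across-residue error bars). K_D is obtained by nonlinear least squares of
the closed-form monomer fraction in log K (positivity by construction),
initialized from the median per-point estimate K = 2·T·f²/(1−f). A series
that is entirely monomeric or entirely dimeric (fractions within 1e-9 of the
bounds), or has a single concentration, raises a non-identifiability error
rather than returning a boundary value.

**Binding.** A global fit of one shared K_D,complex and one Δδ_max per
residue, both in log parameters, by Levenberg–Marquardt (lmfit). Initial K
from the median half-saturation ligand concentration; initial Δδ_max at
1.05× the largest observed CSP per residue. Fewer than four titration points
raises a non-identifiability error. When the titration endpoint reaches less
than 80% of fitted saturation the result carries `saturation_warning` — the
fit is returned, flagged, not rejected.

**Uncertainties.** The dimer fit bootstraps over residues, the binding fit
over non-reference titration points (200 seeded resamples by default; 0
disables). This is a documented choice, not necessarily how any particular
published table's ± was produced. ΔG uncertainty is first-order propagation
σ_ΔG = R·T·σ_K/K — applied to a K_D of 6.8 ± 3.7 µM this gives ±1.35 kJ/mol,
matching the conventional tabulated ±1.3.

**Free energies.** ΔG = R·T·ln(K_D·10⁻⁶) kJ/mol with R = 8.314 J mol⁻¹ K⁻¹,
T = 298 K, 1 M standard state; configurable through `Constants`. The inverse
round-trips to 10 significant digits (tested).

## PRE rates

With two time points Δt apart the only available estimator is the log
ratio, R₂ = ln(I_a/I_b)/Δt, and Γ₂ = R₂(para) − R₂(dia); Δt defaults to
0.012 s. Γ₂ is invariant to common intensity rescaling. Negative Γ₂
(diamagnetic decaying faster) is reported with a flag, never clipped, so
ordering comparisons on noisy profiles remain honest. For a common relative
intensity noise cv, first-order propagation gives σ_Γ = 2·cv/Δt; this is
validated against 10⁴ Monte-Carlo draws to within 10% (tested). Converting
Γ₂ to distances is out of scope.

## Synthetic data: what it emulates and what it does not

The generators are forward models of exactly the equilibria the fitters
invert, under the study design: 6 log-spaced dilution points from 20 to
500 µM; titration of 0, 25, 50, 100, 150, 200, 300, 400 µM ligand into
200 µM protein; an 8-residue panel (S399, L402, G405, S407, G411, W412,
T419, G425); wild-type-like defaults K_D,dimer = 6.8 µM,
K_D,complex = 40 µM. Noise structure is the standard NMR one —
multiplicative constant-CV for peak volumes (5%) and intensities (2%),
additive Gaussian per shift dimension (0.005 ppm ≈ half a typical ¹H
digital resolution). Saturation CSPs Δδ_max are spread 0.1–0.3 ppm across
the panel — conventional magnitudes, not measured values. Exchange regimes
are baked in (slow for dimerization, fast for binding), not simulated.

Titration shifts are constructed by moving each residue along a fixed
direction in the (¹H, ¹⁵N) plane scaled so the noiseless combined CSP
equals the decoupled isotherm exactly; the reference point is exactly zero.
Because the generator uses the same decoupled forward model as the fitter,
noiseless recovery is exact by construction — that closed loop verifies the
code, while the coupled oracle (a different model) bounds what the
approximation hides. Passing recovery tests therefore demonstrates correct
inversion under the assumed noise model, not robustness to peak overlap,
assignment errors, baseline distortions, or exchange-regime violations,
none of which are simulated.

Every stochastic call requires a seed; identical config + seed yields
byte-identical tables (17-significant-digit CSV writing, round-trip float
parsing).

## Problem sizes

Recovery statistics use 50 replicate datasets per condition (100 in the
distribution-shape test), 200 bootstrap resamples by default but 0 in bulk
recovery loops where only the point estimate is assessed, and 10⁴
Monte-Carlo draws for the error-propagation validation. These sizes give
Monte-Carlo errors well below the tolerances being checked.

## Known limitations

- The decoupled binding fit inherits the fixed-[M] approximation; its bias
  is quantified per fit, not corrected. Joint fitting of both constants
  from titration data alone is deliberately out of scope.
- Bootstrap-over-residues treats residues as exchangeable replicates of the
  same fraction measurement; systematic per-residue integration biases
  would be invisible to it.
- Monomeric-species CSP weighting in the oracle uses complex/(monomer +
  complex); a dimer-inclusive denominator is available as an option, and
  the two differ whenever the dimer pool is substantial.
- The multi-variant pipeline applies no multiple-testing machinery; it
  reports constants, free energies, fold changes, and the additivity gap
  |(ΔΔG₁+ΔΔG₂) − ΔΔG₁₂| only when exactly four variants are configured
  (reference, two singles, double — double listed last).
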