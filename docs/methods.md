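# Methods

## The model

Electron diffraction probes the electrostatic potential of a crystal, so
the elastic scattering factor of an atom depends on its net charge far more
strongly than in the X-ray case.  `isfac` exploits this: every atom in a
kinematical refinement carries one extra parameter, the fraction ν of an
*ionic* electron scattering factor mixed into its neutral one.  The
structure-factor model is

    F_calc(hkl) = Σ_{non-H j} [ν_j f_j^ionic(s) + (1 − ν_j) f_j^neutral(s)]
                    · exp(−8π² U_j(s)) · exp(−2πi h·x_j)
                + Σ_{H k} ν_k f^{H+}(s)
                    · exp(−8π² U_k(s)) · exp(−2πi h·x_k)

with I_calc = scale·|F_calc|² (kinematical, single scattering).  Hydrogens
are special: the neutral-H electron scattering factor is too weak to
support a stable superposition, so protons contribute solely through the
bare-proton curve scaled by their fraction.  The partial charge of atom j
is

    δq_j = ν_j · ΔZ_j        (electrons, absolute scale)

where ΔZ_j is the integer charge offset of the ionic curve assigned to the
atom, and σ(δq) = |ΔZ|·σ(ν) from the least-squares covariance.

## Scattering factors

Ionic electron scattering factors come from the charge-offset Mott–Bethe
relation

    f_e(s) = K · (Z₀ + ΔZ − f_X(s)) / s²,     K = 1/(8π²a₀) = 0.02393366 Å⁻¹

with s = sinθ/λ and f_X the *neutral* atom's X-ray form factor (the
International Tables four-Gaussian coefficients, taken from gemmi).  Using
the neutral f_X with an integer offset means any species — including
formally nonphysical ones such as C⁺ or O⁺ — has a well-defined curve,
which is exactly what a signed, continuously refinable charge needs.
Charged curves diverge as s→0 with the sign of ΔZ; everything therefore
operates inside a resolution window, by default 15–0.75 Å
(s ∈ [0.033, 0.667] Å⁻¹).

For refinement the curves are parametrized in the conventional
four-Gaussian-plus-constant (Cromer–Mann) form, fitted over 200 evenly
spaced window samples with unit weights by damped least squares
(scipy's trust-region reflective solver with b_i ≥ 0 enforced).  Starting
points are the published five-Gaussian electron-scattering coefficients of
the neutral element collapsed to four terms, plus several log-spaced
Gaussian-width ladders whose amplitudes come from a linear solve; the best
of the refined candidates is kept.  The sharpest ladder rung is what lets
a Gaussian absorb the 1/s² ionic tail.

**Residual convention.**  Ionic curves cross zero inside the window (the
neutral f_X decays through Z₀+ΔZ), so a pointwise relative residual
|Δf/f| is unbounded at the crossing for *any* parametrization.  The fit
report therefore quotes the residual relative to the curve's scale,
max|Δf| / max|f| over the window, alongside the raw max|Δf| and the
(ill-behaved) pointwise maximum.  All fitted species used by the templates
stay below 0.5% on the scale-relative measure at out-of-sample points.

H⁺ is built with Z₀ = 1, ΔZ = +1, consistent with the Si⁴⁺ (ΔZ=+4) and
C⁻ (ΔZ=−1) convention; note this is a modelling convention, not a claim
about the high-s limit of a bare proton.

## Refinement

Full-matrix weighted least squares on intensities: parameters are one
overall scale, then per site the free fractional coordinates, displacement
parameters (U_iso or the six U_ij), and ν.  Weights default to 1/σ²(I);
a SHELX-style two-parameter scheme is available.  Iterations are
Levenberg–Marquardt on the normal equations with analytic derivatives
(∂F/∂x, ∂F/∂U, ∂F/∂ν are all closed-form; finite-difference agreement is
tested to 1e-6 of the gradient scale).  Convergence is declared when
max|shift/esd| < 0.01 on a near-undamped step (λ ≤ 1e-3); a heavily damped
step is small regardless of where the optimum is, so it must not count.
Standard uncertainties are the square roots of the diagonal of the inverse
normal matrix scaled by the goodness of fit; the full covariance is kept
for group-charge sums.

Restraints enter as extra weighted residual rows:

* **Total charge (SUMP).**  (Σ_j c_j ν_j − target)/σ with default
  c_j = ΔZ_j·occupancy_j, target 0, σ = 0.001.  The occupancy factor makes
  the restrained combination the charge of the cell content even when
  special positions carry fractional occupancy; at full occupancy it
  reduces to the familiar signed-unit coefficient list.  It is a soft
  restraint: it damps collective charge drift without forcing exact
  neutrality.
* **Distances.**  (d − target)/σ between labelled pairs, with analytic
  coordinate derivatives; useful as mild support for protons when the
  resolution is cut.

**Protocols between refinement rounds.**  The method does not presume
cation or anion.  A non-H site whose ν refines below −0.01 has its ΔZ
negated and ν reset to |ν| (a wrongly-signed ion reveals itself as a
negative fraction); hydrogens are never flipped, since only the H⁺ species
is used.  A site whose ν keeps changing sign at small magnitude
(< 0.05) across rounds is fixed neutral (ν = 0, parameter removed).  A
round whose solution contains a negative U_iso (or negative anisotropic
diagonal) is rejected as an unphysical false minimum — the ADP can mimic
the smooth 1/s² ionic term — the ADPs are reset to 0.02 Å² and the free
fractions pushed outward before re-refining, with at most three escalating
retries.  This mirrors what a practitioner does on seeing a
non-positive-definite ADP.

**Symmetry.**  Operators are supplied as coordinate-triplet strings plus a
lattice-centering code (positive code = centrosymmetric).  Structure
factors sum over all operators with SHELX-style occupancies, which equals
the merged P1 expansion.  Coordinate components pinned by the site
symmetry (detected from the stabilizer's rotation projector; axis-aligned
cases) are excluded from the parameter vector — otherwise the dead
gradient direction stalls the minimizer.  Symmetry constraints on
anisotropic U_ij of special-position atoms are *not* imposed
automatically; use isotropic ADPs there.  Floating origins (polar axes,
P1) are not auto-detected either: anchor an atom with XFIX/
`coordinates_fixed`, or the refiner will stop with an error naming the
null-space parameters.

**Hydrogen modes.**  Riding mode holds H coordinates and ADPs at their
input values and refines only ν; free mode refines x, U and ν for protons
too (the ionic term gives protons enough scattering contrast to support
this).

## Diagnostics

* **R1 / wR2 / GooF** with |F_obs| = √(max(I,0)/scale); GooF is computed
  from the data rows only.
* **Leave-one-out (R_complete).**  Every reflection is omitted in turn,
  the model re-refined from the converged baseline (warm start, capped
  cycles), the omitted reflection's cross-validated |F| residual and every
  δq recorded.  Per atom the report carries mean, std, min, max of δq over
  omissions *and* the baseline esu.  The stability statement worth making
  is that no single reflection moves any charge outside its ±3 esu band;
  the std of the omission distribution itself is far smaller than the esu
  and its maximum is dominated by the few high-leverage reflections, so a
  band in units of that std is not a meaningful stability measure for any
  least-squares estimator.
* **Resolution scans** repeat the refinement per d_min cut and tabulate
  δq ± esu; esu's grow as data are truncated, and mild distance restraints
  recover some reliability at poor cuts.
* **Merging.**  Charges from replicate datasets of the same structure are
  combined as the inverse-variance weighted mean, q̄ = Σ(qᵢ/σᵢ²)/Σ(1/σᵢ²),
  σ̄ = (Σ1/σᵢ²)^(−1/2); with k consistent replicates the esu shrinks like
  1/√k.  Merging across polymorphs is intentionally not supported.
* **Comparison.**  Pearson correlation against reference (e.g.
  quantum-chemical) charge tables, matched by label with an optional alias
  map, with and without hydrogens.  A control transform appends
  average-hydrogen entries (−Σδq_heavy/n_H each) to a heavy-atom-only set.

## ESP maps

ρ(r) = (1/V)·Σ F(hkl)·exp(−2πi h·x) over the symmetry-expanded,
Friedel-completed reflection list on an FFT grid.  F(000) is ill-defined
under ionic curves and must be supplied explicitly (take it from a
conventional neutral refinement); it only shifts the map by a constant.
The grid must satisfy n ≥ 2·max|h|+1 per axis (checked; aliasing is an
error, not a warning), and the default sampling is three points per
minimum resolution element.  Maps are exported/imported as Gaussian CUBE
text.  Grid-to-grid comparison resamples one field onto the other's
points by trilinear interpolation over the overlap (optionally masked to
a radius around selected atoms) and reports the Pearson coefficient,
which is invariant to the arbitrary crystallographic scale.

## Synthetic data

Four templates with exact ground-truth charges (total cell charge zero in
all of them):

* `one-atom-P1` — a single carbon, origin-anchored;
* `ionic-pair-P1` — a rock-salt-like Na⁺/Cl⁻ pair, ν = 0.5 each, both
  positions fixed (the arrangement is inversion-symmetric);
* `toy-zwitterion-P212121` — a glycine-like molecule on general positions,
  five heavy atoms + five protons, NH₃⁺ protons +0.2 e, carboxylate
  oxygens −0.35 e, bonded distances 0.9–1.8 Å;
* `framework-Pnma` — a tetrahedral Si site (ΔZ=+4, δq=+0.4 e) bridged by
  oxygens, one on the mirror with half occupancy.

Intensities are kinematical |F|² scaled so the mean is ≈100, with Gaussian
noise σ_I = max(noise·I, floor), floor 1.0 intensity unit, plus optional
random completeness thinning.  This emulates the leading error behaviour
of integrated intensities; it does **not** model dynamical scattering,
detector point spread, radiation damage, absorption or scaling model
misfit, so passing recovery tests demonstrates the estimator's
correctness and calibration under the stated noise model, not performance
on real data.  Every dataset derives its random stream from
(seed, replicate) and embeds a hash of its generating parameters, so
regeneration is exact.

Recovery experiments perturb the start (coordinates jittered 0.02 Å on
free components only, ν restarted at 0.1 with the generating sign), run
the full protocol refinement, and report per-atom bias, RMSE and the
coverage of ±3 esu intervals over seeded replicates.  Default study
conditions for the headline experiment: the zwitterion template, 0.75 Å
data, 2% noise, 10 replicates — sizes chosen so the whole acceptance
computation is a desk-scale run.

## Known limitations

* Kinematical only; dynamical effects in thick crystals bias real-data
  charges and are out of scope.
* No twinning, anharmonic ADPs, anomalous scattering, or the full
  330-setting space-group table; symmetry comes from explicit operator
  lists.
* Special-position support covers axis-aligned coordinate constraints and
  isotropic ADPs.
* The instruction dialect is a documented subset, not a full SHELX
  grammar.
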