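# Methods

## The quantity being computed

A dipolar coupling between two nuclear spins k1, k2 factorizes
(separability of fast bond-length fluctuations from slow molecular
rotation) as

    D_k(t) = Dc_k · R_k(t) · P2(cos θ_k(t))

with the prefactor `Dc_k = −μ0 h/(2π r0³) (γ1/2π)(γ2/2π)`, the radial
factor `R_k = (r0/r_k)³` and the second-order Legendre function
`P2(x) = (3x² − 1)/2` of the angle between the internuclear vector and the
magnetic-field direction. Averaged over an isotropic rotational
distribution `⟨P2⟩ = 0`; a slightly anisotropic distribution (an alignment
medium) leaves a Hz-scale residual dipolar coupling (RDC) — three to four
orders of magnitude below the kHz-scale coupling itself. Because the
anisotropic orientation distribution can neither be measured nor simulated
at molecular resolution, every back-calculation scheme *fits* some
representation of that distribution to a set of target couplings; the
calculated values therefore inherit a dependence on the target set. The
package implements the two fitting routes for a rigid structure and the
diagnostics used to compare them.

Internal units: nm, ps, kJ/mol, RDCs in Hz, prefactors in kHz, force
constant in kJ mol⁻¹ Hz⁻². The prefactor constant is evaluated in SI and,
as a unit-consistency check, in the nm/ps/kJ-per-mol system
(−1.2337·10⁻⁶ (kJ/mol)² ps³ e⁻² nm⁻⁴ at r0 = 0.1 nm); both give the same
kHz value to machine precision.

Gyromagnetic ratios γ/2π (MHz/T): 1H +42.577, 13C +10.708, 15N −4.316,
14N +3.077, stored in an editable TSV so other tabulations can be swapped
in. The resulting per-pair prefactors (+24.35 kHz for 15N–1H at 0.1 nm,
−46.65 kHz for 13C–1H at 0.109 nm, −4.243 kHz for 13C–13C at 0.153 nm,
+2.603 kHz for 13C–15N at 0.133 nm) agree with published values to within
0.2%, the precision of the γ tabulation.

Each bond class stores the common reference length r0 = 0.1 nm, so the
radial factors at the rigid bond lengths b0 = 0.1 / 0.109 / 0.153 /
0.133 nm are 1.0 / 0.7722 / 0.2792 / 0.4251. The product `Dc·R` is
independent of the choice of r0.

## Alignment-tensor route (AT)

For a rigid structure, each RDC is linear in the five independent
components of the symmetric traceless order matrix S (Saupe matrix):
`D_k = Dc_k R_k u_kᵀ S u_k`. The fit is an unweighted linear least squares
in the basis (Sxx, Syy, Sxy, Sxz, Syz) over the *restrained* targets only,
solved by SVD pseudo-inverse (singular values below 1e−10 of the largest
treated as zero; rank deficiency warns and returns the minimum-norm
solution). No per-type weighting and no time averaging. Predictions are
evaluated for all couplings, restrained or not. Exact properties verified
by the suite: noise-free self-consistency (generate-then-fit recovers the
tensor to <1e−9), rotation covariance S → QSQᵀ, translation invariance.

## Rotational-sampling route (HRS)

The magnetic-field direction is a two-united-atom "molecule" (two
15.035 u particles, rigid 0.153 nm bond) propagated by Langevin dynamics
at 308 K with friction 2.4 ps⁻¹ and Δt = 2 fs. Its only potential energy
is the flat-bottom RDC restraint evaluated on the exponentially
memory-averaged coupling of each restrained RDC:

* zero within ±ΔD_fb (2 Hz) of the target,
* half-harmonic over the next ΔD_h (1 Hz),
* linear beyond (continuous with continuous first derivative),
* force constant K = 100 kJ mol⁻¹ Hz⁻².

The restraining force on particle h1 is
`Σ_k f_k · Dc_k R_k · (1 − e^(−Δt/τ_θ)) · ∂P_k/∂r_h1` with
`∂P_k/∂r_h1 = 3 cos θ (u_k − cos θ û)/b` (the rigid-bond tangential
gradient) and the opposite force on h2. The factor `(1 − e^(−Δt/τ_θ))` is
the exact derivative of the discrete memory average with respect to the
current sample; at the default Δt/τ_θ = 2·10⁻⁷ it is numerically
indistinguishable from the Δt/τ_θ approximation.

**Memory average.** The restrained coupling uses the weight-normalized
exponential running average

    P̄_n = S_n / W_n,   S_n = P_n + w S_{n−1},  W_n = 1 + w W_{n−1},
    w = e^(−Δt/τ_θ),

the discrete form of
`P̄(t) = (τ(1−e^(−t/τ)))⁻¹ ∫₀ᵗ e^(−(t−t')/τ) P(t') dt'`. The
normalization matters: the bare recursion
`P̄_n = (1−w)P_n + w P̄_{n−1}` started at the initial orientation keeps a
weight e^(−t/τ) on that arbitrary initial value, which for τ_θ = 10 ns
freezes the restraint for several nanoseconds; the normalized form behaves
as a plain running mean while t ≪ τ_θ and decays old history once
t ≳ τ_θ, so the restraining force adapts from the first picoseconds. The
bare recursion is still exposed (`update_exp_average`) as the asymptotic
primitive; engine and primitive agree once t ≫ τ_θ (tested).

**Integrator.** One step is kick(Δt/2) – drift(Δt/2) – exact
Ornstein–Uhlenbeck velocity refresh – drift(Δt/2), followed by SHAKE on
the bond length and a velocity projection onto the constraint surface.
The OU update is exact at any Δt, so the force-free stationary state has
Maxwell velocities at T and an isotropic bond orientation; the constrained
dimer carries 5 degrees of freedom, mean kinetic energy (5/2)kT (verified
within statistical error over 10⁵ steps). The force is evaluated once per
step at the pre-step positions. SHAKE iterates to a relative bond-length
precision of 1e−5 (comfortably below the 1e−4 contract; the per-step
pre-correction error of the tangential drift is ~3·10⁻⁵ relative, so the
iteration converges in at most one pass).

**Reported values.** The restraining force uses the damped average; the
*reported* RDC is the plain arithmetic mean of `Dc R P_k` over all sampled
steps of all runs — the two are never mixed. The plain mean of
`P2(u_k·û(t))` over a trajectory equals `3/2 u_kᵀ M u_k − 1/2` with
`M = ⟨û ûᵀ⟩`, so the engine accumulates only the 3×3 orientation second
moment per run; this is algebraically identical to averaging P_k per step
and O(1) per step in the number of targets. Runs (default 3 × 5·10⁶ steps
= 30 ns) differ only by seed (`seed + run_index`, logged in the output);
per-run values are retained and their standard deviation is the run-spread
diagnostic. Identical seeds reproduce results bit for bit.

## Metrics and diagnostics

* RMSD over all couplings, rRMSD over the restrained subset, urRMSD over
  the unrestrained one, satisfying N·RMSD² = N_r·rRMSD² + N_ur·urRMSD².
* N_dev counts deviations strictly above 3 Hz (deviations within the 2 Hz
  flat bottom plus ~1 Hz are treated as insignificant); N_dev,s counts
  opposite signs, a zero matching either sign (the convention where a
  target is exactly zero is not specified anywhere; matching was chosen
  and is documented here).
* Cross-RMSD compares two calculated sets (method vs method, restraint set
  vs restraint set, structure vs structure).
* θ/sin θ histograms of the sampled field direction against reference
  vectors in the molecule (default: the Cα→Cα endpoint vectors of three
  helices; arbitrary vectors accepted). Samples are weighted by 1/sin θ so
  an isotropic distribution is flat; 2° bins, and a magic-angle flag
  raises when any bin within ±5° of 54.74° or 125.26° exceeds 1.5× the
  mean density. Binning, window and factor are package choices (the
  requirement is only that no magic-angle peaks appear) and are exposed as
  parameters. Orientation distributions concentrating at the magic angles
  indicate that the restraining is reducing couplings by parking vectors
  where P2 = 0 rather than by genuine rotational averaging.
* Kabsch superposition (via scipy's align_vectors) of backbone N, CA, C
  atoms over a residue range (default 3–126), returning the fit RMSD and
  per-residue CA/N displacement profiles; validated against an independent
  quaternion-method implementation.
* Hydrogen bonds by the geometric criterion H···acceptor < 0.25 nm and
  donor–H···acceptor angle > 135°.

## Proton construction

X-ray structures carry no backbone protons. The amide H is placed in the
C′(i−1)–N(i)–CA(i) plane along the negative bisector of that angle at N,
at 0.1 nm (N-terminus and prolines skipped). The virtual Hα is placed at
0.109 nm from CA along −(û_N + û_C′ + û_CB) normalized; for glycine, the
first of the two tetrahedral completion directions over the N and C′
bonds, on the +(û_N × û_C′) side. These are standard constructions, but
other software's exact improper-dihedral geometry may differ slightly;
comparisons against published per-coupling values should carry a few
tenths of a Hz of tolerance from this source alone.

## Synthetic fixtures

`synthetic.make_helix` builds an ideal polyalanine backbone (N, CA, C′,
O, CB) by natural-extension placement from internal coordinates (bond
lengths 0.147/0.153/0.133 nm matching the rigid RDC bond lengths, angles
111/116.2/121.7°, ω = 180°), default φ = −57°, ψ = −47°; the canonical
α-helix reproduces the i→i−4 hydrogen-bond pattern under the package's
own H construction and detector. `synth_targets` generates targets
`Dc R u_kᵀ S u_k + N(0, σ²)` from a known tensor; the default tensor
components (5, −2, 3, −1.5, 2.5)·10⁻⁴ give N–H and Cα–Hα couplings
spanning roughly ±30 Hz, the scale of measured backbone sets.
`invert_sequence` builds the artificial control sets in which the ordered
values of one coupling type are reversed along the chain — targets that
are maximally inconsistent with the structure while preserving the value
distribution.

What the synthetic fixtures do *not* emulate: real alignment-medium
physics, intramolecular motion (the generator emits one rigid
conformation), measurement noise structure beyond i.i.d. Gaussian, and
missing residues/duplicate measurements of real data sets. Passing the
self-consistency tests therefore demonstrates correctness of the
machinery, not agreement with any measured protein data.

## Problem sizes and numerical choices

* Acceptance-level HRS checks run 3 × 1 ns (3 × 5·10⁵ steps) rather than
  the 3 × 10 ns production default; with the normalized memory average the
  restrained averages equilibrate within tens of picoseconds, and the
  looser run-to-run scatter at 1 ns enters the pass condition explicitly.
* The isotropic-limit check accepts |mean P2| < 0.05 per coupling at 1 ns
  sampling; the force-free rotational correlation time of the rotor is
  ~0.5 ps, so the sampling error of the mean is well below that bound.
* Degenerate inputs: zero-length vectors, collinear N–CA–C′ geometry and
  SHAKE non-convergence raise; |cos θ| is clamped at 1 + 1e−12; fitting
  requires ≥ 5 restrained couplings.
* Tie-break on alternate locations with equal occupancy: altloc 'A'.

## Known limitations

* Only the rigid-structure variants are implemented: no time-averaged
  alignment-tensor restraining, no whole-molecule rotational sampling, no
  coupling of the field-vector sampling to a molecular simulation
  (the hybrid scheme's molecular-system force constant is fixed at zero).
* Restraining forces act on the field vector only; the package
  back-calculates RDCs for a fixed structure, it does not refine
  structures.
* Single-chain treatment; insertion codes are read but not used for
  selection.
* DSSP-style secondary-structure assignment is out of scope; the
  hydrogen-bond detector provides the geometric part only.
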