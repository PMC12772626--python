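# Methods

## Problem and model

Enzymes that catalyze cycloadditions can do part of their work
electrostatically: the protein scaffold holds charged residues in place so
that the bound substrate sits in a pre-organized electric field. If that
field is aligned with the electron-rich fragment of the substrate (for a
Diels-Alder substrate, the diene axis), it polarizes the frontier density
toward the bond-forming atoms and lowers the barrier; if the substrate is
bound "upside down", the same field opposes reaction. `enzfield` quantifies
this picture from reactant-state ensembles alone, with two complementary
descriptor families:

1. **Environment electrostatics.** The enzyme (plus any retained solvent)
   is a set of fixed molecular-mechanics point charges `q_i` at positions
   `r_i`. At an evaluation point `p` (a substrate atom, or the midpoint of a
   probe atom pair),

   V(p) = k Σ_i q_i / |p − r_i|,  E(p) = k Σ_i q_i (p − r_i)/|p − r_i|³,

   with k = 332.0637 kcal·Å/(mol·e²). Sums are direct — no cutoff, no
   periodic images, no polarization — which keeps the operation exact,
   linear in the charges, and trivially decomposable: the contribution of a
   residue is the same sum restricted to its atoms, and contributions add
   up to the total field exactly (up to floating point). The scalar
   descriptor of interest is the projection E·û on a unit axis û between
   two named substrate atoms (diene axis C10→C13; bond-forming axes
   C13→C14, C10→C15).

2. **Conceptual-DFT reactivity.** In the frontier-molecular-orbital
   approximation the nucleophilic Fukui function f⁻ is the HOMO density and
   the electrophilic f⁺ the LUMO density. Condensation onto atoms is
   Mulliken-style on the supplied MO vector c and overlap S:
   f(A) = Σ_{μ∈A} Σ_ν c_μ c_ν S_μν, reducing to per-atom sums of squared
   coefficients for an orthonormal basis. Each condensed function carries
   one frontier electron and sums to 1 over atoms. Mulliken condensation is
   the only scheme computable from coefficients and overlap alone;
   grid-based (stockholder) condensation would need electron densities and
   is out of scope. A finite-difference route from N / N±1 atomic charge
   tables is provided for ingesting externally computed (e.g. Hirshfeld-I)
   charges; it is exactly consistent with the orbital route when the
   removed electron is the HOMO density.

Per-frame descriptors become ensemble values by weighted averaging.
MD frames sampled at temperature are already Boltzmann-distributed, so the
default weights are uniform; when per-frame energies are supplied the
weights are w_i ∝ exp(−(E_i − E_min)/k_B T) with
k_B = 0.0019872041 kcal/(mol·K), T defaulting to 300 K. Both modes are
exposed because published ensemble-averaged Fukui analyses do not always
state which convention they used.

## Statistics

* **Weighted SEM.** With weights w summing to 1 and effective sample size
  n_eff = 1/Σw², the standard error of the weighted mean is
  SEM = sqrt( Σ w_i (x_i − m)² / (n_eff − 1) ). This convention reduces
  exactly to s/√n (sample sd, n−1 denominator) for uniform weights, which
  is the property we anchor on; it is reported as NaN when n_eff ≤ 1.
* **KDE.** Gaussian kernels with Scott's-rule bandwidth h = σ̂·n^(−1/5)
  (scipy's `gaussian_kde`), density evaluated on 512 points spanning
  [min − 3h, max + 3h]. Bandwidth is overridable for sensitivity checks.
  Zero-variance samples are rejected with a pointer to histograms.
* **Alignment.** "How well is the field aligned with the axis" is
  operationalized three ways: the fraction of frames with positive
  projection, the mean direction cosine, and the probability mass of the
  modal bin of a 20-bin cosine histogram on [−1, 1] (bin count
  configurable). The modal-bin mass is one reasonable reading of a
  "probability peak" statistic and is labelled as such in outputs.
* **Pose comparison.** Welch's unequal-variance t-test with
  Welch–Satterthwaite degrees of freedom (scipy), all pairwise pairs per
  descriptor. Raw p-values by default; Holm adjustment is available but
  off, matching the common practice of reporting raw pairwise p-values for
  a handful of poses. Degenerate inputs follow explicit conventions: both
  samples constant and equal → p = 1; constant but different → p = 0 with
  a degeneracy flag. Sample variances use n−1 denominators everywhere.

## Numerical choices

* Units are fixed internally: Å, elementary charges, kcal/mol; potentials
  in kcal/(mol·e), fields in kcal/(mol·e·Å). The optional MV/cm reporting
  factor (≈4.3364) and the hartree→eV factor (27.2114) are derived from
  CODATA constants at import, not hard-coded. The Coulomb prefactor and k_B
  are pinned to the Amber convention for bit-stable results.
* Fields for probe projections are evaluated at the **midpoint** of the two
  probe atoms (per-atom records hold fields at atom positions). The
  midpoint is a definite, symmetric choice where tools and papers leave the
  evaluation point ambiguous.
* An environment charge within 1e-6 Å of an evaluation point raises an
  error naming the atom rather than being skipped: coincident atoms mean
  broken input.
* Cosines are flagged undefined (NaN) when |E| < 1e-12 — a directionless
  field has no alignment.
* Frontier orbitals: occupied means occupation > 1e-6 electrons (robust to
  printed rounding); HOMO energy ties break toward the larger MO index,
  LUMO ties toward the smaller. Frontier-MO norms may deviate from 1 by up
  to 1e-3 (renormalized); beyond that the input is rejected as
  unnormalized.
* Frame subsampling takes indices round(i·(n−1)/(k−1)), i = 0..k−1 —
  "equally spaced with both endpoints included"; k = 1 returns the middle
  frame.

## The synthetic generator

The generator emulates the statistical structure of enzyme-bound reactant
ensembles without attempting any real enzyme's geometry or energetics:

* A **charged cage**: six two-atom pseudo-residues on a barrel of radius
  8 Å and height 10 Å. Three "top" residues (GLU19, GLU78, ARG122-like;
  net −1, −1, +1) and two "bottom" residues (ASP26, ARG130-like; net −1,
  +1) give the cavity a net bottom-to-top axial field of ≈3.5
  kcal/(mol·e·Å) at the center; one neutral residue pads the wall. GLU19
  sits 2 Å closer to the axis than the rest, making it the designed
  dominant contributor (rank #1 in up-pose decompositions), and the other
  residues are staggered in height so every |contribution| is distinct and
  rankings are deterministic. Charge magnitudes are single formal charges —
  a clear but far-from-saturating effect.
* A **rigid 6-atom substrate** (C10–C15) on the barrel axis with the
  C10→C13 axis along +z in the "up" pose; "down" is the 180° flip about
  the x-axis. The C10/C13 midpoint coincides with the flip center, so with
  zero noise the diene-axis projection of the down pose is the **exact**
  negation of the up pose. The bond-forming probes' midpoints move under
  the flip, so their projections only approximately negate — the exact
  antisymmetry property is specific to the diene axis, by construction.
* **Noise and energies**: i.i.d. Gaussian displacement (default sd 0.1 Å
  per coordinate, a thermal-fluctuation scale) on every atom and frame;
  per-frame energies are harmonic in the total displacement
  (k = 1 kcal/mol/Å²), so Boltzmann weights rank low-displacement frames
  higher by monotonicity.
* **Orbitals**: exact Hückel chains (α = 0, β = −1) as stand-ins for the
  substrate π system; butadiene's HOMO gives the golden-ratio condensed
  values (0.3618, 0.1382, 0.1382, 0.3618). In the four-pose design
  ("A"/"B" up, "C"/"D" down, distinct noise seeds per pose), each frame's
  HOMO is perturbed toward the terminal atoms by ε = gain·(projected
  field) + jitter and renormalized, so the field/reactivity coupling the
  pipeline should recover is present by construction.
* **Effect size**: defaults gain = 0.003 (per kcal/(mol·e·Å)) and jitter
  sd = 0.02 give an up-vs-down separation in f⁻(C10/C13) of roughly 8–10
  per-pose SEMs at 100 frames per pose. We chose this deliberately strong
  (but still small in absolute terms: f⁻ shifts by ≈0.03 on a base of
  0.36) so that the recovery checks are reproducible for any seed; a
  separation near 2–3 SEM would make the pairwise tests a coin flip from
  seed to seed. With a zero-charge cage (or zero gain) the poses are
  exchangeable — the null behaves as a null.
* One global seed fans out via `numpy.random.SeedSequence(seed,
  spawn_key=(pose_index, component))`, so each pose's frames and orbital
  jitter are individually reproducible.

### What passing on synthetic data does not show

The generator reproduces the *structure* of the real problem (a directed
cavity field, pose-dependent alignment, a field-coupled frontier density,
frame noise), not its *content*: real trajectories have correlated,
anisotropic fluctuations, solvent, conformational substates and
polarization; real frontier densities live in large basis sets with
non-identity overlap. Recovering the designed contrast therefore validates
the machinery (signs, rankings, calibrated tests), not any claim about a
particular enzyme, and no absolute field or f⁻ magnitude from the
synthetic study should be compared with measured or published values.

## Problem sizes

Default study sizes — 100 frames per pose for descriptor statistics,
2000 simulated null pairs (n = 100 each) for the Welch calibration, 10⁴
samples for KDE convergence, 1000 random frames for conservation checks —
are chosen so the full acceptance analysis re-runs from scratch in a few
seconds on one CPU while keeping Monte-Carlo noise well inside the stated
tolerances.

## Known limitations

* Point-charge electrostatics only: no Ewald/periodic sums, no
  polarizable charges, no reaction-field corrections, no QM-derived ESP.
* Condensation is Mulliken-style; stockholder (Hirshfeld-type) condensed
  values from external codes can be ingested as charge tables but not
  recomputed.
* No trajectory alignment/imaging, and no parsing of binary trajectory or
  checkpoint formats (Amber prmtop/NetCDF, DCD, Gaussian chk) — PQR, PDB,
  XYZ, CSV and the orbital JSON schema are the supported carriers.
* Whether solvent belongs in the "environment" is a user decision: the
  default environment is every atom outside the substrate selection, and
  the selection grammar makes solvent-free environments easy to request.
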