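# enzfield

Ensemble electric-field and conceptual-DFT reactivity analysis for enzyme
active sites.

Some enzymes catalyze reactions partly by *electrostatic preorganization*:
charged residues held by the protein scaffold exert a standing electric
field on the bound substrate. For a Diels–Alder substrate, a field aligned
along the diene axis polarizes the frontier density toward the bond-forming
carbons and enhances reactivity; a substrate bound in the inverted pose
feels the same field with the opposite sign. `enzfield` is for
computational enzymologists who have reactant-state ensembles (MD or QM/MM
frames plus point charges) and want to quantify this picture without
running reaction simulations.

It computes, over a conformational ensemble:

* **Electrostatic potential and field** of the environment's point charges
  at substrate atoms, V(p) = k Σ qᵢ/rᵢ and E(p) = k Σ qᵢ(p−rᵢ)/rᵢ³
  (k = 332.0637 kcal·Å/(mol·e²)), as direct sums with no cutoff;
* **Projections** E·û onto atom-pair axes (e.g. the diene axis C10→C13),
  with KDE summaries, alignment statistics, and an exact **per-residue
  decomposition** of the projected field;
* **Atom-condensed Fukui functions** in the frontier-MO approximation,
  f⁻(A) = Σ_{μ∈A} Σ_ν c_μ c_ν S_μν over the HOMO (f⁺ over the LUMO),
  HOMO–LUMO gaps, environment-induced charge shifts, and ensemble averages
  with uniform or Boltzmann weights exp(−ΔE/k_BT)/Z with SEMs;
* **Pose comparisons** by Welch two-sample t-tests across all pose pairs.

A synthetic-data module generates charged-cage ensembles with a known
field direction, pose flips, frame noise, harmonic energies and exact
Hückel-polyene orbitals, so every claim the package makes can be tested
against constructions with known answers. See `docs/methods.md` for the
model and its assumptions, `docs/file_formats.md` for the supported
formats.

## Worked example

Generate the four-pose synthetic study (poses A/B "up", C/D "down",
100 frames each) and run the core analyses:

```python
import numpy as np
from enzfield import (CageSpec, generate_pose_ensembles, probe_projection_series,
                      condense_fukui, welch_t_test, rank_residue_contributions)

ensembles = generate_pose_ensembles(CageSpec(n_frames=100, seed=42))
fminus = {}
for pose, e in ensembles.items():
    proj = probe_projection_series(e.topology, e.frames, e.probes[0], e.substrate)
    c10 = e.diene_atoms["C10"]
    f = np.array([condense_fukui(o, "f-").values[c10] for o in e.orbitals])
    fminus[pose] = f
    print(f"pose {pose}: <E.u(C10->C13)> = {proj.projections.mean():+.3f} "
          f"kcal/(mol e A), frac>0 = {(proj.projections>0).mean():.2f}, "
          f"f-(C10) = {f.mean():.4f} +/- {f.std(ddof=1)/10:.4f}")
r = welch_t_test(fminus["A"], fminus["C"])
print(f"Welch A vs C on f-(C10): t = {r.statistic:.2f}, p = {r.p_value:.2e}")
top = rank_residue_contributions(ensembles["A"].topology, ensembles["A"].frames,
                                 ensembles["A"].probes[0], ensembles["A"].substrate)
print("top contributor (pose A):", top.iloc[0]["residue_name"],
      int(top.iloc[0]["residue_id"]),
      f"({top.iloc[0]['mean_projection']:+.2f} kcal/(mol e A))")
```

prints

```
pose A: <E.u(C10->C13)> = +3.509 kcal/(mol e A), frac>0 = 1.00, f-(C10) = 0.3722 +/- 0.0023
pose B: <E.u(C10->C13)> = +3.496 kcal/(mol e A), frac>0 = 1.00, f-(C10) = 0.3750 +/- 0.0026
pose C: <E.u(C10->C13)> = -3.516 kcal/(mol e A), frac>0 = 0.00, f-(C10) = 0.3472 +/- 0.0024
pose D: <E.u(C10->C13)> = -3.598 kcal/(mol e A), frac>0 = 0.00, f-(C10) = 0.3522 +/- 0.0023
Welch A vs C on f-(C10): t = 7.54, p = 1.70e-12
top contributor (pose A): GLU 19 (+3.45 kcal/(mol e A))
```

Read: in the up poses the cavity field points along the diene axis in
every frame (+3.5 kcal/(mol·e·Å), ≈15 MV/cm) and the condensed
nucleophilic Fukui value on the diene terminus C10 is correspondingly
elevated; flipping the substrate negates the projection and depresses
f⁻(C10), a difference the Welch test resolves decisively. The residue
decomposition attributes the up-pose field chiefly to the glutamate-like
residue sealing the top of the cavity — exactly the designed contrast the
generator builds in, recovered end to end by the pipeline.

The same analyses run from the shell on files:

```sh
enzfield simulate --pose up --frames 100 --seed 7 --outdir fixtures/
enzfield field --topology fixtures/cage.pqr --frames fixtures/traj.pdb \
         --substrate "resid 200" --vector C10:C13 --decompose --out fields.csv
enzfield report --frames 100 --seed 7 --outdir report/   # full pipeline + manifest
```

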