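# File formats and mini-grammars

## PQR (canonical charge carrier)

Whitespace-separated `ATOM`/`HETATM` records:

```
ATOM  serial  name  resname  [chain]  resid  x  y  z  charge  radius
```

The chain column is optional and detected per record from the token count
(10 fields without, 11 with). Coordinates are Angstrom, charges elementary
charges `e`. Radii are parsed but ignored by all analyses. `read_pqr`
reports the offending **line number** on malformed records; `write_pqr`
writes coordinates to 3 decimals and charges to 4.

## Trajectories

Multi-model PDB (`MODEL`/`ENDMDL` blocks) and XYZ trajectories are read
through MDAnalysis. A pre-scan checks that every frame has the same atom
count and raises `frame k: expected N atoms, found M` otherwise. Units are
Angstrom throughout; no imaging or alignment is applied (frames are assumed
pre-imaged with the complex whole).

## Orbital data (JSON)

One file per frame:

```json
{
  "n_basis": 4,
  "mo_coefficients": [[...], ...],
  "mo_energies": [-1.618, -0.618, 0.618, 1.618],
  "occupations": [2, 2, 0, 0],
  "basis_to_atom": [0, 1, 2, 3],
  "overlap": [[...], ...]
}
```

* `mo_coefficients`: one **row per basis function**, one **column per MO**.
* `basis_to_atom`: topology atom index (0-based) of each basis row.
* `overlap`: optional; must be symmetric with unit diagonal (within 1e-8).
  When absent, an orthonormal basis (identity overlap) is assumed — this is
  the documented default, since common wavefunction interchange formats do
  not carry the overlap matrix.
* `n_basis` is optional and cross-checked against the coefficient matrix.

Validation: occupations must be non-negative with at least one occupied
(occupation > 1e-6 electrons) and one virtual MO, otherwise the frontier is
undefined and loading fails.

## CSV tables

* **Charge tables**: columns `atom_index,charge` (charges in `e`); extra
  columns are ignored. One table per electronic-structure context
  ("enzyme", "vacuum", ...).
* **Per-frame energies**: column `energy` (kcal/mol), one row per frame,
  in frame order.

## Selection mini-grammar

Clauses separated by `;` are unioned; each clause is a keyword plus a
comma-separated list:

```
name C10,C13          atoms by name
resid 200             all atoms of a residue id
index 0,2,5           explicit 0-based atom indices
```

Resolution is by atom name / residue id (never list position); unknown
names raise an error listing near-matches.

## Pipeline config (YAML)

```yaml
topology: cage.pqr          # PQR with charges
frames: {A: trajA.pdb, B: trajB.pdb}
substrate: "resid 200"
probes: ["C10:C13", "C13:C14"]
orbitals: {A: [f0.orb.json, f1.orb.json]}   # optional, per pose
energies: {A: energiesA.csv}                # optional, per pose
temperature: 300.0
units: kcalmolea            # or mvcm
subsample: 50               # optional: k equally spaced frames
outdir: out/
seed: 0
```

All referenced paths are validated when the config is constructed.
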