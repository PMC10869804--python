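# protodimer

Quantitative characterization of small intertwined homodimers — the kind of
compact two-chain fold where two α-helices from each protomer pack over and
under a shared antiparallel β-sheet, so that most of each chain participates
in the dimer interface. The package re-implements, as one tested pipeline,
the analyses such a structure study needs:

- **Surface and interface analysis.** Shrake–Rupley solvent-accessible
  surface area (SASA) with deterministic golden-spiral sphere sampling;
  per-residue buried area upon complexation, ΔASA(r) = SASA_alone(r) −
  SASA_complex(r); interface residue census; salt-bridge detection
  (Asp/Glu carboxylate O to Lys/Arg side-chain N ≤ 4.0 Å) annotated with the
  relative side-chain accessibility of the acid against an extended Gly-X-Gly
  reference; backbone hydrogen bonds (N···O ≤ 3.5 Å).
- **NMR-ensemble geometry.** Kabsch superposition; ensemble precision as the
  average RMSD-to-mean after iterative mean-structure superposition;
  dihedral-window secondary-structure assignment with H-bond support for
  strands; helix axes by principal components of the Cα cloud and the
  inter-helix crossing angle.
- **Chemical-shift-perturbation (CSP) mapping.** Weighted amide perturbation
  d = √(½·(Δδ_H² + (0.14·Δδ_N)²)) between free and ligand-bound states,
  significance flagging (d > 0.05 ppm), titration saturation checks, and
  B-factor mapping of CSPs onto coordinates.
- **Binding and denaturation fits.** Fluorescence-polarization isotherms fit
  to the 1:1 protomer-site model P([T]) = P_free + (P_bound − P_free)·[T]/(K_d + [T])
  (with an exact ligand-depletion variant); two-state thermal melts
  (van't Hoff, T_m) and urea denaturation (linear extrapolation,
  C_m = ΔG⁰/m), all with linear baselines and asymptotic standard errors.
- **Conservation profiling.** Per-column class fractions (nonpolar/acidic/
  basic), information content, majority consensus, and >80%-conservation
  flagging over a homolog alignment, mapped to reference numbering.
- **Synthetic data.** Seeded generators for every input — a C2-symmetric toy
  dimer with a real inter-chain H-bond ladder, Gaussian coordinate ensembles,
  shift tables, titrations, melts, and alignments — each with a
  machine-readable ground-truth record, so the full pipeline runs and is
  testable without downloads.

Residue numbering is handled explicitly: coordinate files produced from
tagged expression constructs are shifted by a constant offset (e.g. +14) from
the native sequence, and all user-facing ranges are native numbers translated
through a `NumberingMap`.

## Worked example

Generate a synthetic bundle (structure, ensemble, shift tables, titration,
melts, alignment — each with a truth record) and run every stage:

```
protodimer generate --seed 1 --out demo
protodimer run-all demo/config.yaml
```

The consolidated report (`demo/results/report.txt`):

```
protodimer 0.1.0  seed=1  config=0049eedd82d2ff43
[     ok] surface (1.27 s)
          total_sasa_A2 = 5083
          buried_total_A2 = 699.2
          n_interface_residues = 28
          n_salt_bridges = 0
          n_hbonds = 148
[     ok] ensemble (0.10 s)
          n_models = 20
          backbone_rmsd_to_mean_A = 0.6681
          heavy_rmsd_to_mean_A = 0.8441
[     ok] geometry (0.02 s)
          n_helices = 2
          n_strands = 1
          interhelix_angle_deg = 100.3
[     ok] csp (0.01 s)
          n_residues = 63
          n_significant = 10
[     ok] fit (0.01 s)
[     ok] conservation (0.01 s)
          n_sequences = 200
          n_columns = 40
          consensus = ADSYAVTYMFLPMTMIKDVAMSNDTFGTLFWGYLWPQIDM
          n_flagged = 8
```

Reading the numbers: the toy dimer buries ~700 Å² of accessible surface
across 28 interface residues and forms 148 backbone hydrogen bonds (6 of them
across the inter-chain β-sheet). The 20-model ensemble was generated with
backbone noise σ = 0.4 Å and side-chain noise σ = 0.8 Å; the recovered
RMSD-to-mean values (0.67 / 0.84 Å) sit at the closed-form expectation
σ·√3·√(19/20) for each atom class. Secondary-structure assignment finds the
generator's two helices and one strand per protomer; the 100.3° inter-helix
angle matches the generator's axis records. Ten residues (the declared
binding site 45–54) carry significant CSPs, and the eight alignment columns
built at 85% conservation are exactly the flagged set. The fit block's JSON
(`demo/results/report.json`) carries the fitted K_d, T_m, and C_m with
standard errors; with seed 1 they recover the generated truth (K_d 3.1 µM,
T_m 75 °C, C_m 2.5 M) within their uncertainties.

Each stage can also run alone (`protodimer surface|ensemble|geometry|csp|fit|conserve
config.yaml`), and the library API mirrors the CLI one-to-one
(`protodimer.compute_sasa`, `protodimer.fit_fp_binding`, ...).

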