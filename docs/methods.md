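# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind each stage of the pipeline, and what the synthetic-data
generators do and do not emulate.

## Structures, selections, and numbering

PDB and mmCIF files are parsed with gemmi. Every MODEL record becomes one
model; multi-model files must share chain/residue/atom topology exactly (the
first discrepancy is reported). Alternate locations are resolved to the
highest-occupancy conformer, ties broken by file order. Hydrogens are kept on
read (NMR depositions include them) but excluded from SASA and heavy-atom
statistics.

Expression constructs carry affinity tags, so coordinate-file residue numbers
are offset from the native sequence by a constant (+14 for the study
construct; configurable). Coordinate-file numbering is authoritative on read;
all user-facing ranges are native numbers passed through `NumberingMap`
(`file = native + offset`). The default ordered region is native 12–54 per
protomer: a 63-residue chain minus 11 disordered N-terminal and 9 disordered
C-terminal residues leaves the 43-residue folded core.

Atom classes: backbone = {N, CA, C, O}; heavy = all non-hydrogens;
backbone ⊆ heavy ⊆ all by construction.

## Solvent-accessible surface area

Shrake–Rupley with a probe of 1.4 Å and, by default, 960 test points per
atom. Points are placed on a golden-section spiral — a deterministic
quasi-uniform sphere covering — so areas are bit-reproducible with no RNG.
Per-atom area is `(exposed points / n_points) · 4π(r + r_probe)²`;
per-residue and total areas are exact sums, so additivity holds to machine
precision.

Radii are a Chothia-style heavy-atom table keyed by element, with trigonal
(carbonyl/carboxyl/amide/guanidinium) carbons at 1.76 Å and other carbons at
1.87 Å; N 1.65, O 1.40, S 1.85. A custom table can be supplied per call.
Exact parity with PISA-class tools is not promised — radii sets and reference
states differ between tools — which is why comparisons against published
per-structure areas carry ±10% tolerances.

Orientation sensitivity: with a fixed deterministic point set, rotating the
molecule changes which points are occluded. At 960 points the total varies by
up to ~0.25% across random orientations of the toy dimer; at 4000 points the
variation falls below 0.1%, and invariance checks are run at that density.
The default stays at 960 because interface ΔASA totals at 960 agree with a
10 000-point recomputation to well under 1%.

## Interface decomposition

`ΔASA(residue) = SASA(own chain set alone) − SASA(complex)`, clamped at zero;
a residue is an interface residue when ΔASA exceeds 0.1 Å² (suppresses
sampling noise; configurable). Per-chain buried totals are sums over each
chain set, and swapping the sets only swaps the labels. For a C2-symmetric
dimer the two protomer totals agree to sampling error (<0.1% observed).

## Salt bridges and relative side-chain accessibility

A salt bridge is an Asp/Glu side-chain carboxylate oxygen within 4.0 Å of a
Lys/Arg side-chain nitrogen (His excluded from the basic set by default;
both cutoff and His inclusion configurable). Each bridge reports the minimum
charged-group heavy-atom distance and the acid's relative side-chain
accessibility.

Relative accessibility is side-chain SASA in context divided by the
side-chain SASA of the same residue type in an extended Gly-X-Gly tripeptide,
in percent, clamped at 100. The reference tripeptides are built at run time
(extended backbone, φ = −120°, ψ = 130°, side chain grafted from ideal
residue templates via the N/CA/C frame) and their areas are computed with
this package's own SASA engine and radii, then cached — the ratio never mixes
radii conventions. Published per-residue accessibility percentages may use a
different reference state (whole-residue vs side-chain, different extended
conformation), hence the ±10-percentage-point tolerance on such comparisons.

## Hydrogen bonds

Backbone amide N (donor) to carbonyl O (acceptor) with N···O ≤ 3.5 Å,
excluding same-residue and sequence-adjacent pairs. When the amide proton is
present, H···O ≤ 2.5 Å and N–H···O ≥ 120° are also required; hydrogen-free
coordinate sets fall back to the distance criterion alone.

## Ensemble precision

The reporting convention is the one used for NMR ensemble statistics: all
models are superposed on the ensemble mean (two refinement rounds — the
change in the mean is <0.01 Å per further round on test ensembles), then the
average over models of the RMSD to the final mean is reported. This is
smaller than mean pairwise RMSD by roughly √2; published ensemble numbers
computed under slightly different conventions (per-protomer vs both chains,
superposition set) are compared at ±0.2 Å.

For an ensemble built by displacing every atom by isotropic Gaussian noise σ,
the expected RMSD-to-mean is σ·√3·√((m−1)/m) for m models; superposition
absorbs six rigid-body degrees of freedom, pulling the observed value ~1%
below this for hundreds of atoms. The generator/estimator pair reproduces the
closed form within 5%.

## Secondary structure and helix geometry

Assignment is by dihedral windows, not a DSSP port: helix where
φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°] over ≥4 consecutive residues; strand
where φ ∈ [−180°, −40°] and ψ ∈ [50°, 180°] (or ψ ≤ −170°, the Ramachandran
wrap) over ≥2 residues. A candidate strand run is kept only if at least one
residue forms a backbone H-bond to a partner ≥5 residues away in sequence or
in another chain — this rejects isolated extended stretches and turn
contacts, and keeps helical i→i+4 bonds from counting as sheet support. The
trade-off: the first strand of a very tight hairpin (partner at sequence
distance 3–4) would be missed; inter-chain sheets, the case this package
targets, are unaffected. Chain termini with undefined φ or ψ are coil, so an
ideal helix spanning a whole chain is assigned from its second to its
penultimate residue.

Helix axes are the largest-variance principal component of the segment's Cα
cloud, sign-oriented N→C. The inter-helix angle is arccos of the dot product
of the oriented axes, in [0°, 180°]: antiparallel helices report near 180°,
and the undirected crossing angle is min(θ, 180° − θ). Published inter-helix
angles rarely state the axis definition or residue ranges used, so such
comparisons use this package's own assigned boundaries and ±5°.

## Chemical-shift perturbations

d = √(½·(Δδ_H² + (w·Δδ_N)²)) with w = 0.14, the field-standard weighting that
scales the ¹⁵N shift range onto the ¹H range. Published methods sections
sometimes typeset the weight outside the square (½·(Δδ_H² + w·Δδ_N²));
that reading is dimensionally inconsistent but shipped as variant
`as_printed` so either convention can be reproduced — for Δδ_N = 0.5 ppm the
two give 0.0495 vs 0.1323 ppm, which straddles the 0.05 ppm significance
threshold. Residues present in only one table (prolines, line-broadened
slow-exchange peaks) are reported explicitly, never dropped. Exchange-regime
labels are input annotations; classifying exchange regimes from spectra is
out of scope. Titration saturation is declared when the maximum per-residue
d between the last two titration points falls below 0.01 ppm (configurable).

## Binding and denaturation fits

Binding: the peptide binds each protomer independently, so the 2:1
peptide-per-dimer stoichiometry collapses to a 1:1 protomer-site model and
concentrations are protomer-denominated. The default model is the hyperbola
above; `quadratic_depletion` uses the exact bound fraction of the tracer
(10 nM default) and agrees with the hyperbola to <0.5% in the micromolar-K_d
regime. K_d is parameterized as log K_d internally (no negative excursions);
standard errors are asymptotic (Jacobian), with the delta method mapping
se(log K_d) back to K_d. With 8-point curves, 95% brackets use the t quantile
at n − p = 5 degrees of freedom.

Thermal melts: two-state van't Hoff model with ΔCp = 0 (not estimable from a
single melt), linear folded/unfolded baselines, temperatures in kelvin
internally. Chemical denaturation: linear extrapolation ΔG(u) = ΔG⁰ − m·u at
298.15 K, midpoint C_m = ΔG⁰/m, se(C_m) by the delta method with the
ΔG⁰/m covariance. A fit is rejected as "no transition" when the midpoint
falls outside the data range, the transition amplitude is under five times
the residual scatter, or the two-state model fails to halve the residual sum
of squares of a straight line — this is how a baseline-only trace (an
unfolded variant's melt) is reported rather than fit.

Both midpoints are invariant to affine rescaling of the signal axis, and the
binding fit is scale-equivariant in concentration.

## Conservation

Class sets: nonpolar {A,V,L,I,M,F,W,P,G}, acidic {D,E}, basic {K,R}; His is
in no class by default (configurable). Gaps count in the denominator of class
fractions, so heavily gapped columns cannot be called conserved. A column is
flagged when a single class fraction strictly exceeds 0.80; a per-residue
mode is available where the ">80%" convention refers to single-residue
conservation. Information content is log₂20 − H(non-gap distribution) with no
small-sample correction; sequences are unweighted (UniRef-style inputs are
already partially de-redundant; Henikoff weighting is out of scope).
Consensus is majority-rule over non-gap residues, alphabetic tie-break,
lowercase where the gap fraction exceeds 0.5.

## Synthetic data

Every generator takes one explicit seed, uses its own `numpy` Generator (no
global state), and emits a ground-truth record; recovery tests consume the
truth record, never re-derived constants.

The toy dimer is built from ideal internal coordinates (NeRF chain growth
with Engh–Huber-style bond lengths/angles; helix φ/ψ = −57°/−47°, strand
−120°/130°): per chain, a 12-residue helix, a 5-residue strand, and a second
12-residue helix with short linkers, 37 residues total, full N/CA/C/O
backbone plus ideal side chains. Linker and coil dihedrals sit at positive φ,
outside both assignment windows, so segment boundaries are recoverable
exactly. The two chains are related by a C2 rotation placing the strands as
an antiparallel inter-chain β-sheet (Cα separation 5.1 Å, protomer rolled 45°
about the strand axis); these placement constants were chosen once so the
sheet carries a genuine N···O hydrogen-bond ladder (6 inter-chain bonds) with
no steric clash, and are not fit to any data. A `separation` parameter pulls
the protomers apart for no-contact controls.

Ensembles add isotropic Gaussian displacements with separate backbone and
side-chain σ. Shift tables draw baselines in realistic amide ranges (¹H
7–9.5, ¹⁵N 105–130 ppm) and displace binding-site residues so both weighted
terms contribute equally. Titrations, melts, and urea curves use exactly the
forward models the fits assume; alignments keep the reference residue with a
per-column probability, else draw uniformly from the 20 amino acids.

What the generators do **not** emulate — and therefore what passing tests do
not demonstrate about real data: realistic side-chain rotamers and packing
(toy side chains are ideal-template conformers), correlated ensemble motions
(real NMR ensembles have structured, not isotropic, uncertainty),
ring-current or conformational contributions to chemical shifts, binding
intermediates or cooperativity, ΔCp ≠ 0 melts, irreversible aggregation, and
phylogenetic correlation between homologs. Analyses of real structures remain
subject to radii-set and convention differences discussed above.

Default study conditions baked into the generators: K_d 3.1 µM probed at
0.25–50 µM (8 points, noise 2% of the dynamic range), T_m 75 °C with
ΔH 300 kJ/mol over 20–95 °C, ΔG⁰ 25 kJ/mol with m 10 kJ/mol/M (C_m 2.5 M)
over 0–6 M urea, CSP effect 0.2 ppm on residues 45–54 of a 63-residue chain,
200-sequence alignments with 85%-conserved columns. Monte-Carlo suite sizes
(100 titrations, 40 melts, 40 urea curves) keep the whole recovery suite
around twenty seconds while leaving medians stable to well inside the
acceptance margins.

## Pipeline and reproducibility

The CLI validates the full configuration (unknown keys rejected, input files
checked) before any stage runs; stage failures are recorded in the report and
independent stages still run. Every run writes the resolved configuration and
a config hash next to its outputs; identical configuration and inputs give
identical reports apart from timings. The report JSON validates against the
pydantic schema shipped in `protodimer.pipeline`.
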