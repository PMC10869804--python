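"""Seeded generators for every input the pipeline consumes.

Each generator emits its data together with a machine-readable ground-truth
record, so downstream recovery tests compare against the generator's truth
rather than hard-coded numbers.  All randomness flows through one explicitly
seeded ``numpy.random.Generator`` per call; identical seeds give identical
outputs.

The toy dimer emulates the study system at toy scale: two identical chains,
each two ideal alpha-helices flanking a short extended strand, placed with C2
symmetry so the two strands pair into an antiparallel inter-chain beta-sheet
with a backbone hydrogen-bond ladder.  The placement constants (inter-strand
spacing, roll angle of each protomer about its strand axis, ladder register)
were chosen once so that the sheet geometry is H-bond competent; they are not
fit to any data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._peptide_build import HELIX_PHI_PSI, STRAND_PHI_PSI, build_chain
from .csp import CSPConfig, ShiftRecord, weighted_csp
from .fitting import (
    MeltCurve,
    TitrationCurve,
    UreaCurve,
    chemical_model,
    hyperbolic_model,
    thermal_model,
)
from .conservation import AMINO_ACIDS, MSA
from .structure import Atom, Chain, Residue, Structure
from .surface import BACKBONE_NAMES

__all__ = [
    "GeneratorSpec",
    "make_toy_dimer",
    "perturb_ensemble",
    "simulate_shift_tables",
    "simulate_fp_titration",
    "simulate_melt",
    "simulate_urea",
    "simulate_msa",
]


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for the toy-dimer generator.

    Segment boundaries are residue numbers (1-based, inclusive).  `separation`
    adds extra distance (Å) between the two protomers along the sheet-pairing
    direction; 0 gives the contact dimer, large values pull the chains apart.
    Linker and coil dihedrals sit at positive phi, outside both the helix and
    strand Ramachandran windows, so assigned segments cannot bleed into the
    linkers.
    """

    seed: int = 0
    helix1: tuple[int, int] = (3, 14)
    strand: tuple[int, int] = (17, 21)
    helix2: tuple[int, int] = (24, 35)
    n_residues: int = 37
    separation: float = 0.0
    # placement constants (see module docstring)
    sheet_spacing: float = 5.1  # Å between strand C-alpha traces
    roll_deg: float = 45.0  # rotation of the protomer about its strand axis
    register_shift: float = 0.0  # Å shift along the strand axis
    linker1_phi_psi: tuple[float, float] = (55.0, 70.0)
    linker2_phi_psi: tuple[float, float] = (60.0, 40.0)
    coil_phi_psi: tuple[float, float] = (60.0, 40.0)


def _segment_kind(spec: GeneratorSpec, seq_num: int) -> str:
    for lo, hi in (spec.helix1, spec.helix2):
        if lo <= seq_num <= hi:
            return "helix"
    if spec.strand[0] <= seq_num <= spec.strand[1]:
        return "strand"
    if spec.helix1[1] < seq_num < spec.strand[0]:
        return "linker1"
    if spec.strand[1] < seq_num < spec.helix2[0]:
        return "linker2"
    return "coil"


def _protomer_phi_psi(spec: GeneratorSpec) -> list[tuple[float, float]]:
    table = {
        "helix": HELIX_PHI_PSI,
        "strand": STRAND_PHI_PSI,
        "linker1": spec.linker1_phi_psi,
        "linker2": spec.linker2_phi_psi,
        "coil": spec.coil_phi_psi,
    }
    return [table[_segment_kind(spec, seq)] for seq in range(1, spec.n_residues + 1)]


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _transform_chain(chain: Chain, rot: np.ndarray, trans: np.ndarray, new_id: str) -> Chain:
    residues = []
    for res in chain.residues:
        atoms = [
            Atom(a.name, a.element, rot @ a.coord + trans, a.is_hydrogen) for a in res.atoms
        ]
        residues.append(Residue(new_id, res.seq_num, res.name, atoms))
    return Chain(new_id, residues)


def make_toy_dimer(spec: GeneratorSpec | None = None) -> tuple[Structure, dict]:
    """C2-symmetric toy homodimer with an antiparallel inter-chain beta-sheet.

    Returns ``(structure, truth)``; the truth record holds the generator's
    segment boundaries, helix axis directions, and the contact-based interface
    residue list (residues with a heavy atom within 4.5 Å of the other chain).
    Construction is fully deterministic (the seed only labels the spec).
    """
    spec = spec or GeneratorSpec()
    chain = build_chain("A", _protomer_phi_psi(spec), with_sidechains=True)

    # orient the protomer: strand C-alpha axis along x (N to C), strand
    # centroid at the origin, and helix1 toward negative z — so the C2
    # rotation about z places the partner's helices on the opposite sheet face
    strand_ca = np.array(
        [
            res.atom("CA").coord
            for res in chain.residues
            if spec.strand[0] <= res.seq_num <= spec.strand[1]
        ]
    )
    centroid = strand_ca.mean(axis=0)
    centered = strand_ca - centroid
    _, _, vt = np.linalg.svd(centered)
    x_axis = vt[0]
    if np.dot(x_axis, strand_ca[-1] - strand_ca[0]) < 0:
        x_axis = -x_axis
    helix1_ca = np.array(
        [
            res.atom("CA").coord
            for res in chain.residues
            if spec.helix1[0] <= res.seq_num <= spec.helix1[1]
        ]
    )
    off_axis = helix1_ca.mean(axis=0) - centroid
    off_axis -= np.dot(off_axis, x_axis) * x_axis
    z_axis = -off_axis / np.linalg.norm(off_axis)
    y_axis = np.cross(z_axis, x_axis)
    frame = np.array([x_axis, y_axis, z_axis])  # rows: new basis
    chain = _transform_chain(chain, frame, -frame @ centroid, "A")

    # roll about the strand axis to make the strand's amides/carbonyls face
    # the partner strand, then offset by half the sheet spacing
    roll = _rotation([1.0, 0.0, 0.0], spec.roll_deg)
    half_gap = 0.5 * (spec.sheet_spacing + spec.separation)
    shift_a = np.array([-0.5 * spec.register_shift, -half_gap, 0.0])
    chain_a = _transform_chain(chain, roll, shift_a, "A")
    # C2 partner: 180 degree rotation about z through the origin
    c2 = _rotation([0.0, 0.0, 1.0], 180.0)
    chain_b = _transform_chain(chain_a, c2, np.zeros(3), "B")

    structure = Structure(models=[[chain_a, chain_b]], id="toy_dimer")

    # contact-based interface truth (pure geometry, independent of any SASA engine)
    coords_a = [(r.seq_num, a.coord) for r in chain_a.residues for a in r.heavy_atoms]
    coords_b = np.array([a.coord for r in chain_b.residues for a in r.heavy_atoms])
    contact = sorted(
        {
            seq
            for seq, xyz in coords_a
            if np.min(np.linalg.norm(coords_b - xyz, axis=1)) < 4.5
        }
    )
    helix_axes = {}
    for label, (lo, hi) in (("helix1", spec.helix1), ("helix2", spec.helix2)):
        ca = np.array(
            [r.atom("CA").coord for r in chain_a.residues if lo <= r.seq_num <= hi]
        )
        centered = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        d = vt[0]
        if np.dot(d, ca[-1] - ca[0]) < 0:
            d = -d
        helix_axes[label] = d.tolist()

    truth = {
        "spec": dataclasses.asdict(spec),
        "segments": [
            ["helix", *spec.helix1],
            ["strand", *spec.strand],
            ["helix", *spec.helix2],
        ],
        "helix_axes_chain_a": helix_axes,
        "interface_residues_per_chain": contact,
        "c2_symmetric": True,
    }
    return structure, truth


def perturb_ensemble(
    structure: Structure,
    sigma_backbone: float,
    sigma_sidechain: float,
    n_models: int,
    seed: int,
) -> Structure:
    """Ensemble of `n_models` copies with isotropic Gaussian atom displacements.

    Backbone atoms (N, CA, C, O) get ``sigma_backbone``; all other atoms get
    ``sigma_sidechain`` (Å per coordinate component).
    """
    if structure.n_models != 1:
        raise ValueError("perturb_ensemble expects a single-model input")
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        chains = []
        for chain in structure.models[0]:
            residues = []
            for res in chain.residues:
                atoms = []
                for a in res.atoms:
                    sigma = sigma_backbone if a.name in BACKBONE_NAMES else sigma_sidechain
                    atoms.append(
                        Atom(a.name, a.element, a.coord + rng.normal(0.0, sigma, 3), a.is_hydrogen)
                    )
                residues.append(Residue(chain.chain_id, res.seq_num, res.name, atoms))
            chains.append(Chain(chain.chain_id, residues))
        models.append(chains)
    return Structure(models=models, id=structure.id + "_ensemble")


def simulate_shift_tables(
    n_residues: int = 63,
    binding_site: tuple[int, int] = (45, 54),
    effect_size: float = 0.2,
    noise: float = 0.0,
    seed: int = 0,
    dropped_bound: tuple[int, ...] = (),
    prolines: tuple[int, ...] = (),
) -> tuple[list[ShiftRecord], list[ShiftRecord], dict]:
    """Free and bound amide shift tables with a perturbed binding site.

    Baseline shifts are drawn in realistic amide ranges (1H 7–9.5 ppm, 15N
    105–130 ppm).  Binding-site residues are displaced by `effect_size` ppm in
    1H and ``effect_size / 0.14`` ppm in 15N (so both terms of the weighted
    CSP contribute equally); `dropped_bound` rows are removed from the bound
    table to emulate slow-exchange line broadening, and `prolines` have no
    amide so they appear in neither table.
    """
    rng = np.random.default_rng(seed)
    config = CSPConfig()
    free, bound = [], []
    true_csp = {}
    lo, hi = binding_site
    for num in range(1, n_residues + 1):
        if num in prolines:
            continue
        aa = "P" if num in prolines else AMINO_ACIDS[rng.integers(0, 20)]
        h = rng.uniform(7.0, 9.5)
        n15 = rng.uniform(105.0, 130.0)
        in_site = lo <= num <= hi
        dh = effect_size if in_site else 0.0
        dn = (effect_size / config.nitrogen_weight) if in_site else 0.0
        exchange = "slow" if in_site and effect_size > 0 else "fast"
        free.append(ShiftRecord(num, aa, h + rng.normal(0, noise), n15 + rng.normal(0, noise)))
        if num not in dropped_bound:
            bound.append(
                ShiftRecord(
                    num,
                    aa,
                    h + dh + rng.normal(0, noise),
                    n15 + dn + rng.normal(0, noise),
                    exchange,
                )
            )
        true_csp[num] = weighted_csp(dh, dn, config)
    truth = {
        "binding_site": list(binding_site),
        "effect_size": effect_size,
        "noise": noise,
        "true_csp": true_csp,
        "dropped_bound": list(dropped_bound),
        "prolines": list(prolines),
    }
    return free, bound, truth


def simulate_fp_titration(
    kd: float = 3.1,
    p_free: float = 60.0,
    p_bound: float = 200.0,
    concs: np.ndarray | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[TitrationCurve, dict]:
    """Hyperbolic polarization titration with additive Gaussian noise.

    Defaults mirror the study regime: micromolar affinity probed over a
    0.25–50 µM protomer dilution series with noise at 2% of the dynamic
    range.  ``noise_sd=None`` selects that default; pass 0 for a noiseless
    curve.
    """
    rng = np.random.default_rng(seed)
    if concs is None:
        concs = np.geomspace(0.25, 50.0, 8)
    concs = np.asarray(concs, float)
    if noise_sd is None:
        noise_sd = 0.02 * abs(p_bound - p_free)
    signal = hyperbolic_model(concs, kd, p_free, p_bound)
    signal = signal + rng.normal(0.0, noise_sd, size=concs.shape)
    truth = {
        "kd": kd,
        "p_free": p_free,
        "p_bound": p_bound,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return TitrationCurve(protein_conc=concs, polarization=signal), truth


def simulate_melt(
    tm: float = 75.0,
    dh: float = 300.0,
    baselines: tuple[tuple[float, float], tuple[float, float]] = ((-20.0, 0.02), (-2.0, 0.01)),
    t_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    transition: bool = True,
) -> tuple[MeltCurve, dict]:
    """Two-state thermal melt (°C vs signal); `transition=False` emits baselines only.

    The baseline-only trace emulates an unfolded variant whose melt shows no
    credible transition.
    """
    rng = np.random.default_rng(seed)
    if t_grid is None:
        t_grid = np.arange(20.0, 95.0 + 1e-9, 1.0)
    t_grid = np.asarray(t_grid, float)
    (af, bf), (au, bu) = baselines
    if transition:
        signal = thermal_model(t_grid, tm, dh, af, bf, au, bu)
    else:
        signal = au + bu * t_grid
    signal = signal + rng.normal(0.0, noise_sd, size=t_grid.shape)
    truth = {
        "tm": tm if transition else None,
        "dh": dh if transition else None,
        "baselines": baselines,
        "noise_sd": noise_sd,
        "seed": seed,
        "transition": transition,
    }
    return MeltCurve(temperature=t_grid, signal=signal), truth


def simulate_urea(
    dg0: float = 25.0,
    m: float = 10.0,
    baselines: tuple[tuple[float, float], tuple[float, float]] = ((-20.0, 0.1), (-2.0, 0.05)),
    u_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[UreaCurve, dict]:
    """Two-state urea denaturation curve; midpoint Cm = dg0 / m."""
    rng = np.random.default_rng(seed)
    if u_grid is None:
        u_grid = np.arange(0.0, 6.0 + 1e-9, 0.25)
    u_grid = np.asarray(u_grid, float)
    (af, bf), (au, bu) = baselines
    signal = chemical_model(u_grid, dg0, m, af, bf, au, bu)
    signal = signal + rng.normal(0.0, noise_sd, size=u_grid.shape)
    truth = {
        "dg0": dg0,
        "m": m,
        "cm": dg0 / m,
        "baselines": baselines,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return UreaCurve(urea=u_grid, signal=signal), truth


def simulate_msa(
    reference: str,
    conservation_profile: list[float],
    n_seqs: int = 200,
    seed: int = 0,
    flag_level: float = 0.8,
) -> tuple[MSA, dict]:
    """Alignment where column i keeps the reference residue with probability
    ``conservation_profile[i]`` and otherwise draws uniformly from the 20
    amino acids.

    The truth record lists the columns *intended* to be conserved (profile
    value > `flag_level`), keyed by reference (native) numbering.
    """
    if len(conservation_profile) != len(reference):
        raise ValueError("profile length must match reference length")
    rng = np.random.default_rng(seed)
    seqs = [("ref", reference)]
    for i in range(n_seqs - 1):
        row = []
        for ref_aa, p in zip(reference, conservation_profile):
            if rng.random() < p:
                row.append(ref_aa)
            else:
                row.append(AMINO_ACIDS[rng.integers(0, 20)])
        seqs.append((f"homolog_{i + 1}", "".join(row)))
    truth = {
        "conservation_profile": list(conservation_profile),
        "intended_conserved": [
            i + 1 for i, p in enumerate(conservation_profile) if p > flag_level
        ],
        "n_seqs": n_seqs,
        "seed": seed,
    }
    return MSA(sequences=seqs), truth


def write_truth(truth: dict, path: str | Path) -> None:
    """Write a generator's ground-truth record as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
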