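"""Superposition, ensemble precision, secondary structure, and helix geometry.

Ensemble precision follows the reporting convention of NMR structure
statistics: all models are iteratively superposed on the ensemble mean
coordinates (two refinement rounds) and the average over models of the
RMSD-to-mean for the selected atoms is reported.  This differs from the mean
pairwise RMSD by roughly sqrt(2); the convention is stated so published
ensemble numbers can be compared apples-to-apples.

Secondary structure uses a dihedral-window assignment (not a DSSP port):
helix for >=4 consecutive residues in the alpha region of the Ramachandran
map, strand for >=2 consecutive residues in the beta region supported by an
inter-strand backbone hydrogen bond, coil otherwise.  Helix axes are the
principal direction of the segment's C-alpha cloud, oriented N to C, so the
inter-helix angle distinguishes parallel from antiparallel packing.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from ._peptide_build import dihedral
from .errors import TopologyMismatchError
from .structure import (
    AtomRef,
    NumberingMap,
    Selection,
    Structure,
    apply_selection,
    get_coords,
)
from .surface import find_hbonds

__all__ = [
    "SuperpositionResult",
    "SecondaryStructure",
    "HelixAxis",
    "kabsch_superpose",
    "ensemble_rmsd",
    "assign_secondary_structure",
    "helix_axis",
    "interhelix_angle",
    "compare_structures",
]


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # applied after rotation: x' = R x + t
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclasses.dataclass
class SecondaryStructure:
    # (kind, chain_id, start, end) — start/end in native numbering, inclusive
    segments: list[tuple[str, str, int, int]]

    def of_kind(self, kind: str, chain_id: str | None = None) -> list[tuple[str, str, int, int]]:
        return [
            s for s in self.segments
            if s[0] == kind and (chain_id is None or s[1] == chain_id)
        ]


@dataclasses.dataclass
class HelixAxis:
    origin: np.ndarray
    direction: np.ndarray  # unit vector, oriented N -> C

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        norm = np.linalg.norm(self.direction)
        if not np.isclose(norm, 1.0, atol=1e-6):
            self.direction = self.direction / norm


def kabsch_superpose(coords_ref: np.ndarray, coords_mov: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of mov onto ref.

    Standard Kabsch algorithm via SVD with a determinant correction so the
    returned rotation is always proper (no reflection).
    """
    ref = np.asarray(coords_ref, float)
    mov = np.asarray(coords_mov, float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs for superposition")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    a = ref - ref_c
    b = mov - mov_c
    if np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) coordinate spread")
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_c - rot @ mov_c
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _model_coords(
    structure: Structure, selection: Selection, numbering: NumberingMap | None
) -> np.ndarray:
    """(n_models, n_atoms, 3) coordinate stack for a selection; checks topology."""
    stacks = []
    key_ref = None
    for m in range(structure.n_models):
        refs = apply_selection(structure, m, selection, numbering)
        keys = [(r.chain_id, r.seq_num, r.atom.name) for r in refs]
        if key_ref is None:
            key_ref = keys
        elif keys != key_ref:
            raise TopologyMismatchError("selection differs between models")
        stacks.append(get_coords(refs))
    return np.array(stacks)


def ensemble_rmsd(
    structure: Structure,
    selection: Selection | None = None,
    atom_class: Literal["backbone", "heavy", "ca", "all"] = "backbone",
    numbering: NumberingMap | None = None,
    n_iterations: int = 2,
) -> tuple[float, list[float]]:
    """Average RMSD-to-mean of an ensemble after iterative mean superposition.

    Returns ``(mean_rmsd, per_model_rmsds)``.  Models are superposed on the
    running mean structure for `n_iterations` refinement rounds (the mean is
    recomputed after each round), then each model's RMSD to the final mean is
    reported.
    """
    if structure.n_models < 2:
        raise ValueError("ensemble statistics need at least 2 models")
    if selection is None:
        selection = Selection()
    selection = dataclasses.replace(selection, atom_class=atom_class)
    coords = _model_coords(structure, selection, numbering)  # (m, n, 3)

    work = coords - coords.mean(axis=1, keepdims=True)  # center each model
    mean = work[0].copy()
    for _ in range(n_iterations):
        for m in range(work.shape[0]):
            sup = kabsch_superpose(mean, work[m])
            work[m] = sup.apply(work[m])
        mean = work.mean(axis=0)
    per_model = [
        float(np.sqrt(np.mean(np.sum((work[m] - mean) ** 2, axis=1))))
        for m in range(work.shape[0])
    ]
    return float(np.mean(per_model)), per_model


# ---------------------------------------------------------------------------
# secondary structure

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -40.0)
STRAND_PSI = (50.0, 180.0)
STRAND_PSI_WRAP = -170.0  # psi below this also counts as extended (wraparound)
MIN_HELIX_LEN = 4
MIN_STRAND_LEN = 2


def _phi_psi(chain_residues) -> list[tuple[float | None, float | None]]:
    out = []
    n = len(chain_residues)
    for i, res in enumerate(chain_residues):
        phi = psi = None
        atoms = {a.name: a.coord for a in res.atoms}
        if i > 0 and chain_residues[i - 1].seq_num == res.seq_num - 1:
            prev = {a.name: a.coord for a in chain_residues[i - 1].atoms}
            if "C" in prev and all(k in atoms for k in ("N", "CA", "C")):
                phi = dihedral(prev["C"], atoms["N"], atoms["CA"], atoms["C"])
        if i + 1 < n and chain_residues[i + 1].seq_num == res.seq_num + 1:
            nxt = {a.name: a.coord for a in chain_residues[i + 1].atoms}
            if "N" in nxt and all(k in atoms for k in ("N", "CA", "C")):
                psi = dihedral(atoms["N"], atoms["CA"], atoms["C"], nxt["N"])
        out.append((phi, psi))
    return out


def assign_secondary_structure(
    structure: Structure,
    model_index: int = 0,
    numbering: NumberingMap | None = None,
) -> SecondaryStructure:
    """Dihedral-window helix/strand/coil assignment with H-bond support for strands.

    Residues with missing backbone atoms (or undefined phi/psi at chain
    termini) are coil.  Candidate strand runs are kept only when at least one
    residue forms a backbone H-bond to a non-local partner (sequence distance
    >= 5 or another chain), so isolated extended stretches and turn contacts
    are not called strands; helical i->i+4 bonds are likewise excluded from
    sheet support.  Segment boundaries are reported in native numbering.
    """
    numbering = numbering or NumberingMap(0)
    hbonds = find_hbonds(structure, model_index)
    partnered: set[tuple[str, int]] = set()
    for hb in hbonds:
        d_chain, d_seq, _ = hb.donor
        a_chain, a_seq, _ = hb.acceptor
        if d_chain != a_chain or abs(d_seq - a_seq) >= 5:
            partnered.add((d_chain, d_seq))
            partnered.add((a_chain, a_seq))

    segments: list[tuple[str, str, int, int]] = []
    for chain in structure.models[model_index]:
        phipsi = _phi_psi(chain.residues)
        labels = []
        for (phi, psi), res in zip(phipsi, chain.residues):
            label = "coil"
            if phi is not None and psi is not None:
                if HELIX_PHI[0] <= phi <= HELIX_PHI[1] and HELIX_PSI[0] <= psi <= HELIX_PSI[1]:
                    label = "helix"
                elif STRAND_PHI[0] <= phi <= STRAND_PHI[1] and (
                    STRAND_PSI[0] <= psi <= STRAND_PSI[1] or psi <= STRAND_PSI_WRAP
                ):
                    label = "strand"
            labels.append(label)
        # collapse runs, apply minimum lengths and strand H-bond support
        i = 0
        n = len(labels)
        while i < n:
            j = i
            while j < n and labels[j] == labels[i]:
                j += 1
            kind = labels[i]
            run = chain.residues[i:j]
            length = j - i
            keep = False
            if kind == "helix" and length >= MIN_HELIX_LEN:
                keep = True
            elif kind == "strand" and length >= MIN_STRAND_LEN:
                keep = any((chain.chain_id, r.seq_num) in partnered for r in run)
            if keep:
                segments.append(
                    (
                        kind,
                        chain.chain_id,
                        numbering.to_native(run[0].seq_num),
                        numbering.to_native(run[-1].seq_num),
                    )
                )
            i = j
    return SecondaryStructure(segments=segments)


def helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Principal axis of a helix's C-alpha cloud, oriented from N to C terminus."""
    coords = np.asarray(ca_coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 5:
        raise ValueError("helix axis needs at least 5 C-alpha positions")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    return HelixAxis(origin=centroid, direction=direction)


def interhelix_angle(axis1: HelixAxis, axis2: HelixAxis) -> float:
    """Angle between two oriented helix axes, degrees in [0, 180].

    Orientation (N to C) is preserved, so antiparallel helices report near
    180 rather than near 0.
    """
    cosang = float(np.dot(axis1.direction, axis2.direction))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def helix_axis_for_segment(
    structure: Structure,
    model_index: int,
    chain_id: str,
    start: int,
    end: int,
    numbering: NumberingMap | None = None,
) -> HelixAxis:
    """Helix axis of a native-numbered segment of one chain."""
    sel = Selection(chains=(chain_id,), ranges=((start, end),), atom_class="ca")
    refs = apply_selection(structure, model_index, sel, numbering)
    return helix_axis(get_coords(refs))


def compare_structures(
    structure_a: Structure,
    structure_b: Structure,
    pairing: list[tuple[tuple[str, int], tuple[str, int]]],
    model_a: int = 0,
    model_b: int = 0,
) -> float:
    """C-alpha RMSD between two structures after Kabsch superposition.

    `pairing` lists equivalent residues as ((chain, seq_num), (chain, seq_num))
    tuples in each structure's own coordinate numbering.
    """
    coords_a = []
    coords_b = []
    for (chain_a_id, seq_a), (chain_b_id, seq_b) in pairing:
        ca_a = ca_b = None
        chain_a = structure_a.chain(chain_a_id, model_a)
        chain_b = structure_b.chain(chain_b_id, model_b)
        if chain_a is not None:
            res = chain_a.residue(seq_a)
            ca = res.atom("CA") if res else None
            ca_a = None if ca is None else ca.coord
        if chain_b is not None:
            res = chain_b.residue(seq_b)
            ca = res.atom("CA") if res else None
            ca_b = None if ca is None else ca.coord
        if ca_a is not None and ca_b is not None:
            coords_a.append(ca_a)
            coords_b.append(ca_b)
    if len(coords_a) < 3:
        raise ValueError(f"only {len(coords_a)} paired C-alpha atoms; need at least 3")
    return kabsch_superpose(np.array(coords_a), np.array(coords_b)).rmsd
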