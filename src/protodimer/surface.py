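"""Solvent-accessible surface areas and dimer-interface analysis.

The SASA engine is a Shrake–Rupley implementation with *deterministic* sphere
sampling: test points are placed on a golden-section spiral rather than drawn
at random, so areas are exactly reproducible run to run.  Radii follow a
Chothia/NACCESS-style heavy-atom convention (hydrogens are excluded); exact
parity with PISA-class tools is not promised, only tolerance-level agreement.

Interface analysis decomposes buried area per residue:
``dASA(residue) = SASA(own chain set alone) - SASA(in complex)``, with a
residue counted as an interface residue when its dASA exceeds a small cutoff
that suppresses sampling noise.

Relative side-chain accessibility is reported against an extended Gly-X-Gly
tripeptide reference computed with this same engine and radii, so the ratio
never mixes radii conventions.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache

import numpy as np

from ._peptide_build import build_gxg_tripeptide
from .errors import NoSideChainError, UnknownRadiusError
from .structure import (
    AtomRef,
    NumberingMap,
    Selection,
    Structure,
    apply_selection,
)

__all__ = [
    "SASAParams",
    "SASAResult",
    "InterfaceReport",
    "SaltBridge",
    "HBond",
    "compute_sasa",
    "interface_analysis",
    "find_salt_bridges",
    "relative_sidechain_asa",
    "find_hbonds",
]

# Chothia (1976)-style van der Waals radii, Å.
# Carbonyl/carboxyl carbons are smaller than aliphatic/aromatic ones.
ELEMENT_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.80,
    "SE": 1.90,
}
# residue-specific carbons that are trigonal (carboxyl/amide/guanidinium/ring C=O)
_TRIGONAL_CARBON = {
    ("*", "C"),  # backbone carbonyl
    ("ASP", "CG"),
    ("GLU", "CD"),
    ("ASN", "CG"),
    ("GLN", "CD"),
    ("ARG", "CZ"),
}
TRIGONAL_C_RADIUS = 1.76

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclasses.dataclass(frozen=True)
class SASAParams:
    """Probe radius, sphere sampling density, and radii table."""

    probe_radius: float = 1.4
    n_points: int = 960
    radii: dict | None = None  # optional {(res_name, atom_name) or element: radius}

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 100:
            raise ValueError("n_points must be at least 100")


@dataclasses.dataclass
class SASAResult:
    per_atom: list[float]  # parallel to the input atom list, Å²
    per_residue: dict[tuple[str, int], float]
    total: float


@dataclasses.dataclass
class InterfaceReport:
    per_residue_buried: dict[tuple[str, int], float]
    interface_residues: dict[str, list[int]]  # chain_id -> sorted seq_nums
    buried_total_per_chain: dict[str, float]  # keyed by chain-set label
    buried_total_complexwide: float
    n_interface_residues: int


@dataclasses.dataclass
class SaltBridge:
    acidic: tuple[str, int, str]  # chain, seq_num, res_name
    basic: tuple[str, int, str]
    acidic_atom: str
    basic_atom: str
    distance: float
    asa_ratio: float | None = None  # % relative side-chain accessibility of the acid


@dataclasses.dataclass
class HBond:
    donor: tuple[str, int, str]  # chain, seq_num, atom name
    acceptor: tuple[str, int, str]
    distance: float
    angle: float | None = None  # N-H...O angle when the amide H is present


def _atom_radius(res_name: str, atom: "AtomRef | object", params: SASAParams) -> float:
    name = atom.atom.name if isinstance(atom, AtomRef) else atom.name
    element = (atom.atom.element if isinstance(atom, AtomRef) else atom.element).upper()
    if params.radii:
        if (res_name, name) in params.radii:
            return params.radii[(res_name, name)]
        if element in params.radii:
            return params.radii[element]
    if element == "C":
        if ("*", name) in _TRIGONAL_CARBON or (res_name, name) in _TRIGONAL_CARBON:
            return TRIGONAL_C_RADIUS
        return ELEMENT_RADII["C"]
    if element in ELEMENT_RADII:
        return ELEMENT_RADII[element]
    raise UnknownRadiusError(
        f"no radius for atom {name!r} (element {element!r}) in residue {res_name!r}"
    )


@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(atom_refs: list[AtomRef], params: SASAParams | None = None) -> SASAResult:
    """Shrake–Rupley SASA over heavy atoms.

    Hydrogens in the input are ignored.  Per-atom areas are
    ``(exposed points / n_points) * 4 pi (r + probe)^2``; per-residue areas and
    the total are exact sums of the per-atom areas.
    """
    params = params or SASAParams()
    heavy = [(i, ref) for i, ref in enumerate(atom_refs) if not ref.atom.is_hydrogen]
    if not heavy:
        raise ValueError("SASA requires at least one non-hydrogen atom")
    coords = np.array([ref.atom.coord for _, ref in heavy])
    radii = np.array([_atom_radius(ref.res_name, ref, params) for _, ref in heavy])
    extended = radii + params.probe_radius
    sphere = _sphere_points(params.n_points)
    n_atoms = len(heavy)

    per_atom_full = [0.0] * len(atom_refs)
    per_residue: dict[tuple[str, int], float] = {}
    # neighbour pruning via a coarse distance matrix (fine for <10^4 atoms)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    cutoff2 = (extended[:, None] + extended[None, :]) ** 2
    neighbor_mask = (d2 < cutoff2) & ~np.eye(n_atoms, dtype=bool)

    for k in range(n_atoms):
        idx_orig, ref = heavy[k]
        pts = coords[k] + extended[k] * sphere  # (n_points, 3)
        nbrs = np.nonzero(neighbor_mask[k])[0]
        exposed = np.ones(params.n_points, dtype=bool)
        for j in nbrs:
            dj2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= dj2 > extended[j] ** 2
            if not exposed.any():
                break
        area = exposed.sum() / params.n_points * 4.0 * math.pi * extended[k] ** 2
        per_atom_full[idx_orig] = area
        key = (ref.chain_id, ref.seq_num)
        per_residue[key] = per_residue.get(key, 0.0) + area

    total = float(sum(per_atom_full))
    return SASAResult(per_atom=per_atom_full, per_residue=per_residue, total=total)


def _chain_atoms(structure: Structure, model_index: int, chains: tuple[str, ...]) -> list[AtomRef]:
    sel = Selection(chains=chains, atom_class="heavy")
    return apply_selection(structure, model_index, sel)


def interface_analysis(
    structure: Structure,
    model_index: int,
    chains_a: tuple[str, ...],
    chains_b: tuple[str, ...],
    params: SASAParams | None = None,
    cutoff: float = 0.1,
) -> InterfaceReport:
    """Per-residue buried area upon complexation of chain set A with chain set B.

    dASA is clamped at zero; a residue is an interface residue when its dASA
    exceeds `cutoff` (Å², default 0.1 to suppress sampling noise).
    """
    if set(chains_a) & set(chains_b):
        raise ValueError("chain sets must be disjoint")
    params = params or SASAParams()

    atoms_a = _chain_atoms(structure, model_index, tuple(chains_a))
    atoms_b = _chain_atoms(structure, model_index, tuple(chains_b))
    sasa_a = compute_sasa(atoms_a, params)
    sasa_b = compute_sasa(atoms_b, params)
    sasa_complex = compute_sasa(atoms_a + atoms_b, params)

    per_residue_buried: dict[tuple[str, int], float] = {}
    for alone in (sasa_a, sasa_b):
        for key, area in alone.per_residue.items():
            buried = area - sasa_complex.per_residue.get(key, 0.0)
            per_residue_buried[key] = max(0.0, buried)

    interface_residues: dict[str, list[int]] = {}
    for (chain_id, seq_num), buried in per_residue_buried.items():
        if buried > cutoff:
            interface_residues.setdefault(chain_id, []).append(seq_num)
    for v in interface_residues.values():
        v.sort()

    label_a = "+".join(chains_a)
    label_b = "+".join(chains_b)
    buried_a = sum(
        v for (c, _), v in per_residue_buried.items() if c in chains_a
    )
    buried_b = sum(
        v for (c, _), v in per_residue_buried.items() if c in chains_b
    )
    return InterfaceReport(
        per_residue_buried=per_residue_buried,
        interface_residues=interface_residues,
        buried_total_per_chain={label_a: buried_a, label_b: buried_b},
        buried_total_complexwide=buried_a + buried_b,
        n_interface_residues=sum(len(v) for v in interface_residues.values()),
    )


# ---------------------------------------------------------------------------
# salt bridges

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
BASIC_ATOMS_WITH_HIS = {**BASIC_ATOMS, "HIS": ("ND1", "NE2")}


def find_salt_bridges(
    structure: Structure,
    model_index: int = 0,
    distance_cutoff: float = 4.0,
    include_his: bool = False,
    params: SASAParams | None = None,
    with_asa_ratio: bool = True,
) -> list[SaltBridge]:
    """Asp/Glu carboxylate O to Lys/Arg side-chain N contacts within the cutoff.

    Each bridge reports the minimum charged-group heavy-atom distance and the
    relative side-chain accessibility of the acidic residue in the full
    assembly (``asa_ratio``, percent).
    """
    basic_table = BASIC_ATOMS_WITH_HIS if include_his else BASIC_ATOMS
    acidic_sites = []  # (chain, seq, res_name, atom_name, coord)
    basic_sites = []
    for chain in structure.models[model_index]:
        for res in chain.residues:
            for table, sites in ((ACIDIC_ATOMS, acidic_sites), (basic_table, basic_sites)):
                for atom_name in table.get(res.name, ()):
                    atom = res.atom(atom_name)
                    if atom is not None:
                        sites.append((chain.chain_id, res.seq_num, res.name, atom_name, atom.coord))

    # group by residue, keep the minimum-distance atom pair per residue pair
    best: dict[tuple, SaltBridge] = {}
    for ac, aseq, aname, a_atom, a_xyz in acidic_sites:
        for bc, bseq, bname, b_atom, b_xyz in basic_sites:
            dist = float(np.linalg.norm(a_xyz - b_xyz))
            if dist > distance_cutoff:
                continue
            key = (ac, aseq, bc, bseq)
            if key not in best or dist < best[key].distance:
                best[key] = SaltBridge(
                    acidic=(ac, aseq, aname),
                    basic=(bc, bseq, bname),
                    acidic_atom=a_atom,
                    basic_atom=b_atom,
                    distance=dist,
                )
    bridges = sorted(best.values(), key=lambda b: (b.acidic[0], b.acidic[1], b.basic[0], b.basic[1]))
    if with_asa_ratio:
        for bridge in bridges:
            chain_id, seq_num, _ = bridge.acidic
            try:
                bridge.asa_ratio = relative_sidechain_asa(
                    structure, model_index, chain_id, seq_num, params
                )
            except NoSideChainError:  # pragma: no cover - acids always have side chains
                bridge.asa_ratio = None
    return bridges


# ---------------------------------------------------------------------------
# relative side-chain accessibility

@lru_cache(maxsize=64)
def _gxg_reference_area(res_name: str, probe_radius: float, n_points: int) -> float:
    """Side-chain SASA of residue X in an extended Gly-X-Gly tripeptide."""
    st = build_gxg_tripeptide(res_name)
    refs = apply_selection(st, 0, Selection(atom_class="heavy"))
    params = SASAParams(probe_radius=probe_radius, n_points=n_points)
    result = compute_sasa(refs, params)
    area = 0.0
    for ref, a in zip(refs, result.per_atom):
        if ref.seq_num == 2 and ref.atom.name not in BACKBONE_NAMES:
            area += a
    return area


def relative_sidechain_asa(
    structure: Structure,
    model_index: int,
    chain_id: str,
    seq_num: int,
    params: SASAParams | None = None,
) -> float:
    """Side-chain SASA in context as a percentage of the Gly-X-Gly reference.

    Values above 100 are clamped to 100.  Glycine raises
    :class:`NoSideChainError`.
    """
    params = params or SASAParams()
    chain = structure.chain(chain_id, model_index)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} absent from model {model_index}")
    res = chain.residue(seq_num)
    if res is None:
        raise ValueError(f"residue {chain_id}:{seq_num} not found")
    if res.name == "GLY":
        raise NoSideChainError(f"residue {chain_id}:{seq_num} is glycine (no side chain)")

    all_atoms = apply_selection(structure, model_index, Selection(atom_class="heavy"))
    result = compute_sasa(all_atoms, params)
    sc_area = 0.0
    found_sidechain = False
    for ref, a in zip(all_atoms, result.per_atom):
        if (
            ref.chain_id == chain_id
            and ref.seq_num == seq_num
            and ref.atom.name not in BACKBONE_NAMES
        ):
            sc_area += a
            found_sidechain = True
    if not found_sidechain:
        raise NoSideChainError(f"residue {chain_id}:{seq_num} has no side-chain atoms")
    reference = _gxg_reference_area(res.name, params.probe_radius, params.n_points)
    return min(100.0, 100.0 * sc_area / reference)


# ---------------------------------------------------------------------------
# hydrogen bonds

def find_hbonds(
    structure: Structure,
    model_index: int = 0,
    no_cutoff: float = 3.5,
    ho_cutoff: float = 2.5,
    angle_cutoff: float = 120.0,
    numbering: NumberingMap | None = None,
) -> list[HBond]:
    """Backbone-backbone hydrogen bonds.

    A bond is an amide N (donor) and carbonyl O (acceptor) with N···O <=
    `no_cutoff` Å, excluding pairs within the same or sequence-adjacent
    residues of one chain.  When the amide proton is present, H···O <=
    `ho_cutoff` and an N-H···O angle >= `angle_cutoff` degrees are also
    required.
    """
    donors = []  # (chain, seq, N coord, H coord or None)
    acceptors = []  # (chain, seq, O coord)
    for chain in structure.models[model_index]:
        for res in chain.residues:
            n = res.atom("N")
            if n is not None:
                h = res.atom("H") or res.atom("HN")
                donors.append((chain.chain_id, res.seq_num, n.coord, None if h is None else h.coord))
            o = res.atom("O")
            if o is not None:
                acceptors.append((chain.chain_id, res.seq_num, o.coord))

    bonds = []
    for d_chain, d_seq, n_xyz, h_xyz in donors:
        for a_chain, a_seq, o_xyz in acceptors:
            if d_chain == a_chain and abs(d_seq - a_seq) < 2:
                continue
            dist = float(np.linalg.norm(n_xyz - o_xyz))
            if dist > no_cutoff:
                continue
            angle = None
            if h_xyz is not None:
                ho = float(np.linalg.norm(h_xyz - o_xyz))
                if ho > ho_cutoff:
                    continue
                v1 = n_xyz - h_xyz
                v2 = o_xyz - h_xyz
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < angle_cutoff:
                    continue
            bonds.append(
                HBond(
                    donor=(d_chain, d_seq, "N"),
                    acceptor=(a_chain, a_seq, "O"),
                    distance=dist,
                    angle=angle,
                )
            )
    bonds.sort(key=lambda b: (b.donor[0], b.donor[1], b.acceptor[0], b.acceptor[1]))
    return bonds
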