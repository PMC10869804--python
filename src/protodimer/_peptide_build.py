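"""Ideal-geometry polypeptide backbone construction.

Backbones are grown atom by atom with the natural-extension reference frame
(NeRF): each new atom is placed at a fixed bond length, bond angle, and
torsion relative to the three previously placed atoms.  Bond lengths and
angles are standard Engh–Huber-style values; the caller supplies per-residue
(phi, psi) pairs, so ideal helices, strands, or mixed topologies can be built
deterministically with no randomness.

Side chains (for reference tripeptides) are grafted from ideal residue
coordinates bundled with biotite's chemical component dictionary, superposed
onto the built backbone via their N/CA/C frame.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .structure import Atom, Chain, Residue, Structure

# standard backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0  # trans peptide bond

# canonical (phi, psi) for ideal secondary structures
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom D given A-B-C, |C-D|, angle(B,C,D) and torsion(A,B,C,D) in degrees."""
    angle = np.deg2rad(angle)
    torsion = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O coordinates for a chain with the given (phi, psi) per residue.

    phi of the first residue and psi of the last are used only to orient the
    chain termini and the final carbonyl oxygen.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    coords: list[dict[str, np.ndarray]] = []
    # seed the first three atoms in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        prev = coords[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: in the peptide plane, trans to the next N
    for i in range(n_res):
        res = coords[i]
        if i + 1 < n_res:
            # O lies trans to the next N across the C: torsion N-CA-C-O = psi + 180
            psi = _dihedral(res["N"], res["CA"], res["C"], coords[i + 1]["N"])
        else:
            psi = phi_psi[i][1]
        o = place_atom(res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        res["O"] = o
    return coords


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle in degrees (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


dihedral = _dihedral


@lru_cache(maxsize=32)
def _ccd_residue_heavy(res_name: str) -> tuple[tuple[str, str, tuple[float, float, float]], ...]:
    """Ideal heavy-atom coordinates for a residue type from biotite's CCD subset."""
    import biotite.structure.info as struc_info

    arr = struc_info.residue(res_name)
    out = []
    for name, element, coord in zip(arr.atom_name, arr.element, arr.coord):
        if element.upper() in ("H", "D") or name == "OXT":
            continue
        out.append((str(name), str(element), tuple(float(x) for x in coord)))
    return tuple(out)


def _kabsch_fit(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation + translation moving `mov` onto `ref` (least squares)."""
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, ref_c - rot @ mov_c


def build_chain(
    chain_id: str,
    phi_psi: list[tuple[float, float]],
    res_names: list[str] | None = None,
    first_seq_num: int = 1,
    with_sidechains: bool = False,
) -> Chain:
    """Build a full-backbone chain (N, CA, C, O) with ideal geometry.

    With ``with_sidechains=True``, heavy side-chain atoms are grafted from
    ideal residue templates via the N/CA/C frame of each residue.
    """
    n_res = len(phi_psi)
    if res_names is None:
        res_names = ["ALA"] * n_res
    if len(res_names) != n_res:
        raise ValueError("res_names and phi_psi lengths differ")
    bb = build_backbone(phi_psi)
    residues = []
    for i, (coords, name) in enumerate(zip(bb, res_names)):
        atoms = [
            Atom("N", "N", coords["N"]),
            Atom("CA", "C", coords["CA"]),
            Atom("C", "C", coords["C"]),
            Atom("O", "O", coords["O"]),
        ]
        if with_sidechains and name != "GLY":
            template = _ccd_residue_heavy(name)
            tdict = {n: np.array(c) for n, _, c in template}
            tframe = np.array([tdict["N"], tdict["CA"], tdict["C"]])
            frame = np.array([coords["N"], coords["CA"], coords["C"]])
            rot, trans = _kabsch_fit(frame, tframe)
            for aname, element, coord in template:
                if aname in ("N", "CA", "C", "O"):
                    continue
                atoms.append(Atom(aname, element, rot @ np.array(coord) + trans))
        residues.append(
            Residue(chain_id=chain_id, seq_num=first_seq_num + i, name=name, atoms=atoms)
        )
    return Chain(chain_id=chain_id, residues=residues)


def build_gxg_tripeptide(res_name: str) -> Structure:
    """Extended Gly-X-Gly tripeptide with the X side chain in its ideal conformation.

    Used as the reference state for relative side-chain accessibility.
    """
    phi_psi = [STRAND_PHI_PSI] * 3
    chain = build_chain("A", phi_psi, ["GLY", res_name, "GLY"], with_sidechains=True)
    return Structure(models=[[chain]], id=f"GXG_{res_name}")
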