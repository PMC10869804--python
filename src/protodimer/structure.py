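"""Structure I/O, selections, and residue-numbering maps.

Coordinate files are read with gemmi (PDB and mmCIF) into a small in-memory
model: a :class:`Structure` is an ordered list of models, each a list of
:class:`Chain` objects holding :class:`Residue` and :class:`Atom` records.
Multi-model files (NMR ensembles) are required to share identical topology
across models so that ensemble statistics are well defined.

Residue numbering follows the coordinate file on read.  User-facing residue
ranges use *native* (construct-free) numbering and are translated through a
:class:`NumberingMap` — a constant offset introduced by affinity tags, e.g.
native E36 = file E50 at offset 14.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

from .errors import EmptySelectionError, StructureParseError, TopologyMismatchError

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "NumberingMap",
    "Selection",
    "AtomRef",
    "read_structure",
    "map_numbering",
    "apply_selection",
    "write_annotated_structure",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


@dataclasses.dataclass
class Atom:
    """A single atom: name, element, Cartesian coordinates in Å."""

    name: str
    element: str
    coord: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_num: int
    name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(
                f"residue {self.chain_id}:{self.seq_num} has duplicate atom name {dup!r}"
            )

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def residue(self, seq_num: int) -> Residue | None:
        for r in self.residues:
            if r.seq_num == seq_num:
                return r
        return None


@dataclasses.dataclass
class Structure:
    """A (possibly multi-model) structure; models share topology."""

    models: list[list[Chain]]
    id: str = ""

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chains(self, model_index: int = 0) -> list[Chain]:
        return self.models[model_index]

    def chain(self, chain_id: str, model_index: int = 0) -> Chain | None:
        for c in self.models[model_index]:
            if c.chain_id == chain_id:
                return c
        return None


@dataclasses.dataclass(frozen=True)
class NumberingMap:
    """Constant offset between coordinate-file and native residue numbers.

    ``offset = file_number - native_number``; affinity tags prepended to the
    construct shift the file numbering up (offset 14 for the study construct).
    """

    offset: int = 0

    def to_file(self, native_num: int) -> int:
        return native_num + self.offset

    def to_native(self, file_num: int) -> int:
        return file_num - self.offset


def map_numbering(
    seq_num: int,
    numbering: NumberingMap,
    direction: Literal["native_to_file", "file_to_native"] = "native_to_file",
) -> int:
    """Translate a residue number between native and coordinate-file numbering."""
    if direction == "native_to_file":
        return numbering.to_file(seq_num)
    if direction == "file_to_native":
        return numbering.to_native(seq_num)
    raise ValueError(f"unknown direction {direction!r}")


AtomClass = Literal["backbone", "heavy", "ca", "all"]


@dataclasses.dataclass(frozen=True)
class Selection:
    """Chain / residue-range / atom-class filter.

    Residue ranges are 1-based closed intervals in *native* numbering; they
    must be ordered and non-overlapping.  ``chains=None`` selects all chains.
    """

    chains: tuple[str, ...] | None = None
    ranges: tuple[tuple[int, int], ...] = ()
    atom_class: AtomClass = "all"

    def __post_init__(self) -> None:
        prev_end = None
        for start, end in self.ranges:
            if end < start:
                raise ValueError(f"empty range ({start}, {end})")
            if prev_end is not None and start <= prev_end:
                raise ValueError("ranges must be ordered and non-overlapping")
            prev_end = end

    def contains_native(self, native_num: int) -> bool:
        if not self.ranges:
            return True
        return any(lo <= native_num <= hi for lo, hi in self.ranges)


@dataclasses.dataclass
class AtomRef:
    """An atom together with its residue context."""

    atom: Atom
    chain_id: str
    seq_num: int
    res_name: str


def _atom_in_class(atom: Atom, atom_class: AtomClass) -> bool:
    if atom_class == "all":
        return True
    if atom_class == "heavy":
        return not atom.is_hydrogen
    if atom_class == "ca":
        return atom.name == "CA"
    if atom_class == "backbone":
        return atom.name in BACKBONE_ATOMS
    raise ValueError(f"unknown atom class {atom_class!r}")


def apply_selection(
    structure: Structure,
    model_index: int,
    selection: Selection,
    numbering: NumberingMap | None = None,
) -> list[AtomRef]:
    """Filter one model's atoms by chain, native residue range, and atom class.

    Raises :class:`EmptySelectionError` when nothing matches.
    """
    numbering = numbering or NumberingMap(0)
    out: list[AtomRef] = []
    for chain in structure.models[model_index]:
        if selection.chains is not None and chain.chain_id not in selection.chains:
            continue
        for res in chain.residues:
            native = numbering.to_native(res.seq_num)
            if not selection.contains_native(native):
                continue
            for atom in res.atoms:
                if _atom_in_class(atom, selection.atom_class):
                    out.append(AtomRef(atom, chain.chain_id, res.seq_num, res.name))
    if not out:
        raise EmptySelectionError(
            f"selection matched no atoms in model {model_index} "
            f"(chains={selection.chains}, ranges={selection.ranges}, "
            f"class={selection.atom_class})"
        )
    return out


# ---------------------------------------------------------------------------
# reading


def _convert_gemmi_residue(chain_id: str, gres: gemmi.Residue) -> Residue:
    # alternate locations: keep the highest-occupancy conformer per atom name,
    # ties broken by file order
    best: dict[str, gemmi.Atom] = {}
    for ga in gres:
        prev = best.get(ga.name)
        if prev is None or ga.occ > prev.occ:
            best[ga.name] = ga
    atoms = []
    for ga in best.values():
        element = ga.element.name if ga.element else "X"
        atoms.append(
            Atom(
                name=ga.name,
                element=element,
                coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                is_hydrogen=element.upper() in ("H", "D"),
            )
        )
    return Residue(chain_id=chain_id, seq_num=gres.seqid.num, name=gres.name, atoms=atoms)


def _topology_signature(model: list[Chain]) -> list[tuple]:
    sig = []
    for chain in model:
        for res in chain.residues:
            sig.append(
                (chain.chain_id, res.seq_num, res.name, tuple(a.name for a in res.atoms))
            )
    return sig


def read_structure(path: str | Path, fmt: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Every MODEL record becomes one model; alternate locations are resolved to
    the highest-occupancy conformer.  Multi-model files must have identical
    topology across models.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt not in ("pdb", "mmcif"):
        raise ValueError(f"format must be 'pdb' or 'mmcif', got {fmt!r}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from exc

    models: list[list[Chain]] = []
    for gmodel in st:
        chains = []
        for gchain in gmodel:
            residues = [_convert_gemmi_residue(gchain.name, r) for r in gchain]
            chains.append(Chain(chain_id=gchain.name, residues=residues))
        models.append(chains)
    if not models or not any(c.residues for c in models[0]):
        raise StructureParseError(f"{path.name}: no atoms found")

    ref_sig = _topology_signature(models[0])
    for i, model in enumerate(models[1:], start=2):
        sig = _topology_signature(model)
        if sig != ref_sig:
            detail = "model has different length"
            for a, b in zip(ref_sig, sig):
                if a != b:
                    detail = f"model 1 has {a}, model {i} has {b}"
                    break
            raise TopologyMismatchError(
                f"{path.name}: topology mismatch between model 1 and model {i}: {detail}"
            )
    return Structure(models=models, id=st.name or path.stem)


# ---------------------------------------------------------------------------
# writing


def to_gemmi(
    structure: Structure,
    per_residue_values: dict[tuple[str, int], float] | None = None,
) -> gemmi.Structure:
    """Convert to a gemmi structure, optionally writing values into B-factors."""
    per_residue_values = per_residue_values or {}
    st = gemmi.Structure()
    st.name = structure.id or "MODEL"
    for model_chains in structure.models:
        gmodel = gemmi.Model(len(st) + 1)
        for chain in model_chains:
            gchain = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.seq_num, " ")
                bval = per_residue_values.get((chain.chain_id, res.seq_num), 0.0)
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*atom.coord)
                    ga.occ = 1.0
                    ga.b_iso = bval
                    gres.add_atom(ga)
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    st.setup_entities()
    return st


def write_annotated_structure(
    structure: Structure,
    per_residue_values: dict[tuple[str, int], float],
    path: str | Path,
) -> None:
    """Write a PDB file with per-residue values in the B-factor column.

    Values are keyed by ``(chain_id, seq_num)`` in coordinate-file numbering;
    residues without an entry get 0.00.
    """
    st = to_gemmi(structure, per_residue_values)
    st.write_pdb(str(path))


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a plain PDB file (all B-factors zero)."""
    write_annotated_structure(structure, {}, path)


def get_coords(atom_refs: Sequence[AtomRef]) -> np.ndarray:
    """Stack the coordinates of a selection into an (n, 3) array."""
    return np.array([ref.atom.coord for ref in atom_refs])


def iter_residues(structure: Structure, model_index: int = 0) -> Iterable[Residue]:
    for chain in structure.models[model_index]:
        yield from chain.residues
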