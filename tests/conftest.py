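"""Shared fixtures: synthetic structures and a cached (optional) PDB fetch."""

from __future__ import annotations

import urllib.request
from pathlib import Path

import numpy as np
import pytest

from protodimer import GeneratorSpec, make_toy_dimer
from protodimer.structure import Atom, Chain, Residue, Structure

PDB_ENTRY = "8DSB"


@pytest.fixture(scope="session")
def toy_dimer():
    """Default C2-symmetric toy homodimer with its ground-truth record."""
    return make_toy_dimer(GeneratorSpec(seed=0))


@pytest.fixture(scope="session")
def separated_dimer():
    return make_toy_dimer(GeneratorSpec(seed=0, separation=100.0))


def _make_glu_lys_pair(n_o_distance: float) -> Structure:
    """Minimal Glu/Lys pair with the carboxylate O and amine N at a set distance."""
    glu = Residue(
        "A", 1, "GLU",
        [
            Atom("N", "N", [0.0, 3.0, 0.0]),
            Atom("CA", "C", [0.0, 1.5, 0.0]),
            Atom("C", "C", [1.0, 0.8, 1.0]),
            Atom("O", "O", [1.0, 0.9, 2.2]),
            Atom("CB", "C", [-1.2, 0.8, -0.6]),
            Atom("CG", "C", [-1.2, -0.7, -0.4]),
            Atom("CD", "C", [-0.4, -1.3, 0.7]),
            Atom("OE1", "O", [0.0, -0.6, 1.6]),
            Atom("OE2", "O", [0.0, 0.0, 0.0]),  # reference charged O at origin
        ],
    )
    lys = Residue(
        "B", 1, "LYS",
        [
            Atom("N", "N", [n_o_distance + 3.0, 3.0, 0.0]),
            Atom("CA", "C", [n_o_distance + 3.0, 1.5, 0.0]),
            Atom("C", "C", [n_o_distance + 4.0, 0.8, 1.0]),
            Atom("O", "O", [n_o_distance + 4.0, 0.9, 2.2]),
            Atom("CB", "C", [n_o_distance + 1.8, 0.9, -0.5]),
            Atom("CG", "C", [n_o_distance + 1.6, -0.5, -0.3]),
            Atom("CD", "C", [n_o_distance + 1.0, -1.0, 0.8]),
            Atom("CE", "C", [n_o_distance + 0.6, -0.5, 1.8]),
            Atom("NZ", "N", [n_o_distance, 0.0, 0.0]),  # charged N on the x axis
        ],
    )
    return Structure(models=[[Chain("A", [glu]), Chain("B", [lys])]], id="pair")


@pytest.fixture
def glu_lys_pair_factory():
    return _make_glu_lys_pair


@pytest.fixture(scope="session")
def pdb_ensemble(tmp_path_factory):
    """The deposited NMR ensemble, fetched once and cached; skip when offline.

    The structure-dependent checks are defined to be skipped (not failed) when
    the entry cannot be retrieved, since the suite must run without network
    access.
    """
    cache = Path(__file__).resolve().parent.parent / "scratch" / f"{PDB_ENTRY.lower()}.pdb"
    if not cache.exists():
        url = f"https://files.rcsb.org/download/{PDB_ENTRY}.pdb"
        try:
            cache.parent.mkdir(parents=True, exist_ok=True)
            with urllib.request.urlopen(url, timeout=15) as resp:
                data = resp.read()
            cache.write_bytes(data)
        except Exception:
            pytest.skip(f"PDB entry {PDB_ENTRY} not available (offline)")
    from protodimer import read_structure

    return read_structure(cache)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
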