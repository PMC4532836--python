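"""Synthetic reference structures for the contour-length calculus.

These generators build *synthetic* single-chain models of the two
cupredoxins studied by the pipeline — an azurin-like and a
plastocyanin-like chain — plus small toy fixtures.  They are stand-ins
constructed from published facts about the real proteins, not crystal
structures:

* azurin-like: 128 residues, disulfide Cys-3–Cys-26, Cu site with five
  coordinating residues (Gly-45 carbonyl O, His-46 Nδ1, Cys-112 Sγ,
  His-117 Nδ1, Met-121 Sδ) at the published bond lengths (~3.0, 1.95, 2.1,
  1.95 and 2.9 Å);
* plastocyanin-like: 105 residues, no disulfide, Cu coordinated by
  His-39 Nδ1 (2.2 Å), Cys-89 Sγ (2.1 Å), His-92 Nδ1 (2.0 Å) and
  Met-97 Sδ (2.6 Å).

Key Cα positions (termini, crosslinked cysteines, Cu ligands) are pinned so
that the inter-anchor native spans are geometrically plausible for a
~3 nm β-barrel and the structure-derived ΔL bookkeeping is consistent with
the experimentally reported increments; the remaining residues follow a
deterministic coiled path between pins.  Non-key residues are alanine.
All coordinates are synthetic; only residue numbering, crosslink topology,
ligand identities and Cu–ligand bond lengths reflect the real proteins.
"""

from __future__ import annotations

import io

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "synthetic_azurin_pdb",
    "synthetic_plastocyanin_pdb",
    "toy_tripeptide_pdb",
    "toy_hairpin_pdb",
    "toy_extended_pdb",
    "toy_disulfide_pdb",
    "write_reference_pdbs",
]

_CA_STEP = 3.8  # Å, consecutive Cα spacing along the chain


def _coil(p0: np.ndarray, p1: np.ndarray, n_interior: int, phase: float) -> list[np.ndarray]:
    """Deterministic coiled path of ``n_interior`` points between two pins.

    A straight line from p0 to p1 plus a helical displacement with a
    sine envelope (zero at both ends), with amplitude scaled so the mean
    point spacing approaches the Cα step.  Purely cosmetic: downstream
    geometry uses pinned positions only.
    """
    if n_interior <= 0:
        return []
    k = n_interior + 1
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < 1e-9:
        axis_dir = np.array([0.0, 0.0, 1.0])
    else:
        axis_dir = axis / length
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_dir)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis_dir, ref)
    u /= np.linalg.norm(u)
    w = np.cross(axis_dir, u)
    # path length needed vs straight distance sets the wiggle amplitude
    excess = max(k * _CA_STEP - length, 0.0)
    amp = min(0.6 * np.sqrt(excess), 9.0)
    turns = max(1, int(round(k * _CA_STEP / (2 * np.pi * max(amp, 2.0)))))
    pts = []
    for i in range(1, k):
        t = i / k
        env = amp * np.sin(np.pi * t)
        ang = phase + 2 * np.pi * turns * t
        pts.append(p0 + t * axis + env * (np.cos(ang) * u + np.sin(ang) * w))
    return pts


def _chain_path(pins: dict[int, np.ndarray], first: int, last: int) -> dict[int, np.ndarray]:
    """Cα coordinates for residues first..last through the pinned positions."""
    coords: dict[int, np.ndarray] = {}
    keys = sorted(pins)
    if keys[0] != first or keys[-1] != last:
        raise ValueError("pins must include both termini")
    for a, b in zip(keys, keys[1:]):
        coords[a] = pins[a]
        interior = _coil(pins[a], pins[b], b - a - 1, phase=0.7 * a)
        for off, p in enumerate(interior, start=1):
            coords[a + off] = p
    coords[last] = pins[last]
    return coords


def _push_away(coords: dict[int, np.ndarray], pins: set[int], centre: np.ndarray,
               min_dist: float = 4.2) -> None:
    """Push non-pinned path points radially away from ``centre`` (the metal)."""
    for n, p in coords.items():
        if n in pins:
            continue
        d = np.linalg.norm(p - centre)
        if d < min_dist:
            direction = (p - centre) / d if d > 1e-9 else np.array([0.0, 0.0, 1.0])
            coords[n] = centre + direction * min_dist


def _build_pdb(
    n_res: int,
    ca: dict[int, np.ndarray],
    names: dict[int, str],
    side_atoms: list[tuple[int, str, str, np.ndarray]],
    hetero: list[tuple[str, str, np.ndarray]],
    chain_id: str = "A",
) -> str:
    """Assemble a PDB text from Cα positions, side-chain atoms and hetero atoms."""
    records = []
    for num in range(1, n_res + 1):
        records.append((chain_id, num, names.get(num, "ALA"), "CA", "C", ca[num], False))
    for num, res_name, atom_name, coord in side_atoms:
        elem = atom_name[0]
        records.append((chain_id, num, res_name, atom_name, elem, coord, False))
    for elem, name, coord in hetero:
        records.append((chain_id, n_res + 1, name, name, elem, coord, True))

    arr = struc.AtomArray(len(records))
    for i, (cid, num, res_name, atom_name, elem, coord, het) in enumerate(records):
        arr.chain_id[i] = cid
        arr.res_id[i] = num
        arr.res_name[i] = res_name
        arr.atom_name[i] = atom_name
        arr.element[i] = elem
        arr.coord[i] = coord
        arr.hetero[i] = het
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def _between(origin: np.ndarray, target: np.ndarray, dist_from_origin: float) -> np.ndarray:
    """Point at ``dist_from_origin`` from origin along origin->target."""
    v = target - origin
    return origin + v / np.linalg.norm(v) * dist_from_origin


def synthetic_azurin_pdb(mutations: tuple[str, ...] = ()) -> str:
    """Synthetic azurin-like reference structure (PDB text), chain A.

    128 residues; Cys-3/Cys-26 disulfide (Sγ–Sγ 2.05 Å, Cα–Cα 4.6 Å);
    penta-coordinate Cu site.  ``mutations`` accepts "C112A" and "C26A"
    (residue renamed to ALA, anchor sulfur removed).

    .. note:: synthetic coordinates — see module docstring.
    """
    pins = {
        1: np.array([0.0, 0.0, 0.0]),
        3: np.array([2.0, 3.0, 0.0]),
        26: np.array([2.0, 7.6, 0.0]),
        45: np.array([-1.96, 28.11, 5.0]),
        46: np.array([-4.0, 24.90, 5.0]),
        112: np.array([-2.0, 19.07, 1.0]),
        117: np.array([2.0, 25.0, 5.0]),
        121: np.array([4.0, 24.5, 0.0]),
        128: np.array([10.0, 0.0, 0.0]),
    }
    cu = np.array([-1.0, 23.0, 3.0])
    ca = _chain_path(pins, 1, 128)
    _push_away(ca, set(pins), cu)

    names = {3: "CYS", 26: "CYS", 45: "GLY", 46: "HIS", 112: "CYS",
             117: "HIS", 121: "MET", 128: "LYS"}
    side = [
        (3, "CYS", "SG", np.array([4.49, 4.275, 0.0])),
        (26, "CYS", "SG", np.array([4.49, 6.325, 0.0])),
        (45, "GLY", "O", _between(cu, pins[45], 3.00)),
        (46, "HIS", "ND1", _between(cu, pins[46], 1.95)),
        (112, "CYS", "SG", _between(cu, pins[112], 2.10)),
        (117, "HIS", "ND1", _between(cu, pins[117], 1.95)),
        (121, "MET", "SD", _between(cu, pins[121], 2.90)),
    ]
    for mut in mutations:
        if mut not in ("C112A", "C26A"):
            raise ValueError(f"unsupported mutation {mut!r}")
        res = int(mut[1:-1])
        names[res] = "ALA"
        side = [s for s in side if s[0] != res]
    hetero = [] if "apo" in mutations else [("CU", "CU", cu)]
    return _build_pdb(128, ca, names, side, hetero)


def synthetic_plastocyanin_pdb(apo: bool = False) -> str:
    """Synthetic plastocyanin-like reference structure (PDB text), chain A.

    105 residues, no disulfide; Cu coordinated by His-39, Cys-89, His-92 and
    Met-97 at the published 2.2 / 2.1 / 2.0 / 2.6 Å bond lengths.

    .. note:: synthetic coordinates — see module docstring.
    """
    pins = {
        1: np.array([0.0, 0.0, 0.0]),
        39: np.array([-6.0, 24.61, 4.0]),
        89: np.array([-2.0, 24.096, 1.0]),
        92: np.array([-4.0, 30.0, 2.0]),
        97: np.array([4.5, 27.0, 4.0]),
        105: np.array([15.0, 0.0, 0.0]),
    }
    cu = np.array([-2.0, 27.0, 4.0])
    ca = _chain_path(pins, 1, 105)
    _push_away(ca, set(pins), cu)
    names = {39: "HIS", 89: "CYS", 92: "HIS", 97: "MET"}
    side = [
        (39, "HIS", "ND1", _between(cu, pins[39], 2.20)),
        (89, "CYS", "SG", _between(cu, pins[89], 2.10)),
        (92, "HIS", "ND1", _between(cu, pins[92], 2.00)),
        (97, "MET", "SD", _between(cu, pins[97], 2.60)),
    ]
    hetero = [] if apo else [("CU", "CU", cu)]
    return _build_pdb(105, ca, names, side, hetero)


def toy_tripeptide_pdb() -> str:
    """Three alanines with exact integer-Å coordinates (parser fixture)."""
    ca = {1: np.array([0.0, 0.0, 0.0]),
          2: np.array([3.0, 2.0, 1.0]),
          3: np.array([6.0, 4.0, 2.0])}
    return _build_pdb(3, ca, {}, [], [])


def toy_hairpin_pdb() -> str:
    """12-residue hairpin whose termini Cα are exactly 10 Å apart.

    Full release from the N terminus up to an anchor at residue 12 frees 11
    residues: ΔL = 11 x 0.38 - 1.0 = 3.18 nm.
    """
    ca = {}
    for i in range(6):  # residues 1..6, outbound strand
        ca[i + 1] = np.array([i * _CA_STEP, 0.0, 0.0])
    for i in range(6):  # residues 7..12, return strand
        ca[i + 7] = np.array([(5 - i) * _CA_STEP, 10.0, 0.0])
    return _build_pdb(12, ca, {}, [], [])


def toy_extended_pdb(n: int = 12) -> str:
    """Fully extended straight chain (3.8 Å Cα spacing); near-zero ΔL gain."""
    ca = {i: np.array([(i - 1) * _CA_STEP, 0.0, 0.0]) for i in range(1, n + 1)}
    return _build_pdb(n, ca, {}, [], [])


def toy_disulfide_pdb(ss_distance: float = 2.05) -> str:
    """8-residue peptide with Cys-2 and Cys-7 Sγ at ``ss_distance`` Å."""
    ca = {i: np.array([(i - 1) * _CA_STEP, 0.0, 0.0]) for i in range(1, 9)}
    ca[7] = np.array([3.8, 6.0, 0.0])  # fold residue 7 back near residue 2
    names = {2: "CYS", 7: "CYS"}
    mid_y = 3.0
    side = [
        (2, "CYS", "SG", np.array([3.8, mid_y - ss_distance / 2, 0.0])),
        (7, "CYS", "SG", np.array([3.8, mid_y + ss_distance / 2, 0.0])),
    ]
    return _build_pdb(8, ca, names, side, [])


def write_reference_pdbs(directory) -> dict[str, str]:
    """Write all synthetic reference PDBs into ``directory``; return paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "azurin_synthetic.pdb": synthetic_azurin_pdb(),
        "azurin_C112A_synthetic.pdb": synthetic_azurin_pdb(("C112A",)),
        "azurin_C26A_synthetic.pdb": synthetic_azurin_pdb(("C26A",)),
        "plastocyanin_synthetic.pdb": synthetic_plastocyanin_pdb(),
    }
    out = {}
    for name, content in files.items():
        path = directory / name
        path.write_text(content)
        out[name] = str(path)
    return out
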