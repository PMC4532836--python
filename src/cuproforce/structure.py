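"""Structure-derived contour-length predictions.

Given a protein structure, predicts the contour-length increment expected
when the chain unfolds from one terminus up to an anchor residue (for
cupredoxins, a Cu-coordinating residue), accounting for residues trapped
behind disulfide shortcuts, and extracts metal-site coordination geometry.

Contour-length bookkeeping
--------------------------
A released stretch of n residues contributes ``L_res * n`` of contour
(L_res = 0.38 nm per residue).  The measurable increment ΔL between the
worm-like-chain fit before and after the unfolding step additionally
reflects the folded geometry: before the step the folded domain spans the
Cα-Cα distance between its tether points (the two termini); after unfolding
up to an anchor residue, the still-folded remainder spans the distance from
the anchor to the far terminus.  Hence

    ΔL = L_res * n_released + S_crosslink + d(anchor, far terminus)
         - d(N terminus, C terminus),

where S_crosslink is the Cα-Cα span of any traversed disulfide bridge.  A
disulfide (i, j) wholly contained in the released stretch traps residues
i..j inclusive (they stay behind the covalent shortcut and contribute no
backbone contour); the bridge itself is traversed and contributes its
Cα(i)-Cα(j) span.  The net geometric correction is reported as the
prediction's ``native_span_nm`` (so ΔL = L_res * released - native span).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from cuproforce.polymer import LENGTH_PER_RESIDUE_NM

__all__ = [
    "StructureModel",
    "Residue",
    "DisulfideBond",
    "MetalSite",
    "ContourPrediction",
    "parse_structure",
    "find_disulfides",
    "metal_site_geometry",
    "predict_increment",
]

#: Side-chain atoms that can anchor a metal or crosslink, per residue type.
ANCHOR_ATOMS = {
    "CYS": ("SG",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}

#: Elements considered metal cofactors when scanning HETATM records.
METAL_ELEMENTS = {"CU", "ZN", "FE", "NI", "CO", "MN"}


@dataclass
class Residue:
    """One residue: author number, 3-letter name, Cα and anchor-atom coordinates."""

    number: int
    name: str
    ca: np.ndarray
    atoms: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class StructureModel:
    """Single-chain protein model with hetero (metal) atoms.

    Residues are ordered by author numbering, which must be strictly
    increasing.  Coordinates are in Å, as in the PDB format.
    """

    chain_id: str
    residues: list[Residue]
    hetero: list[tuple[str, str, np.ndarray]]  # (element, name, coord)
    missing_residues: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        for r in self.residues:
            if not np.all(np.isfinite(r.ca)):
                raise ValueError(f"non-finite Cα coordinates at residue {r.number}")
        self._by_number = {r.number: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int) -> Residue:
        try:
            return self._by_number[number]
        except KeyError:
            raise KeyError(f"residue {number} not in chain {self.chain_id}") from None

    def ca_distance(self, i: int, j: int) -> float:
        """Cα-Cα distance between residues i and j, Å."""
        return float(np.linalg.norm(self.residue(i).ca - self.residue(j).ca))

    @property
    def n_terminus(self) -> int:
        return self.residues[0].number

    @property
    def c_terminus(self) -> int:
        return self.residues[-1].number


@dataclass(frozen=True)
class DisulfideBond:
    """Cys-Cys crosslink, residue numbers i < j, Sγ-Sγ distance in Å."""

    residues: tuple[int, int]
    distance: float

    def __post_init__(self) -> None:
        i, j = self.residues
        if not i < j:
            raise ValueError("disulfide residue pair must satisfy i < j")


@dataclass
class MetalSite:
    """Metal cofactor with its coordinating atoms, sorted by distance."""

    element: str
    position: np.ndarray
    ligands: list[dict]  # residue, res_name, atom, distance (Å)


@dataclass
class ContourPrediction:
    """Expected contour-length increment for one unfolding step."""

    construct: str
    pulled_terminus: str  # "N" or "C"
    anchor_residue: int | None  # None = complete unfolding to the far terminus
    released: int
    trapped: int
    native_span_nm: float
    delta_L_nm: float
    crosslink_span_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_L_nm < -1e-9:
            raise ValueError("predicted ΔL must be non-negative")


def parse_structure(pdb_content: str, chain_id: str) -> StructureModel:
    """Parse PDB-format text into a single-chain :class:`StructureModel`.

    Parameters
    ----------
    pdb_content : str
        PDB-format text (ATOM/HETATM/TER records).
    chain_id : str
        Chain to extract; metals are taken from hetero records of the same
        chain or, if that chain carries none, from any chain.

    Returns
    -------
    StructureModel

    Warns
    -----
    UserWarning
        For gaps in the author numbering (missing residues) and for Cys/His/
        Met residues missing their anchor side-chain atom (degraded to Cβ).
    """
    pdb = PDBFile.read(io.StringIO(pdb_content))
    atoms = pdb.get_structure(model=1)
    if chain_id not in set(atoms.chain_id):
        raise ValueError(
            f"chain {chain_id!r} not present; available: {sorted(set(atoms.chain_id))}"
        )
    chain = atoms[atoms.chain_id == chain_id]
    protein = chain[struc.filter_amino_acids(chain)]
    if protein.array_length() == 0:
        raise ValueError(f"chain {chain_id!r} contains no amino-acid residues")

    residues: list[Residue] = []
    for res_id in np.unique(protein.res_id):
        res_atoms = protein[protein.res_id == res_id]
        name = str(res_atoms.res_name[0])
        ca_mask = res_atoms.atom_name == "CA"
        if not np.any(ca_mask):
            warnings.warn(f"residue {res_id} ({name}) has no Cα; skipped")
            continue
        ca = np.array(res_atoms.coord[ca_mask][0], dtype=float)
        keep: dict[str, np.ndarray] = {}
        for atom_name in ANCHOR_ATOMS.get(name, ()) + ("CB", "O"):
            m = res_atoms.atom_name == atom_name
            if np.any(m):
                keep[atom_name] = np.array(res_atoms.coord[m][0], dtype=float)
        if name in ANCHOR_ATOMS and not any(a in keep for a in ANCHOR_ATOMS[name]):
            warnings.warn(
                f"residue {res_id} ({name}) lacks its anchor side-chain atom; "
                "falling back to Cβ"
            )
        residues.append(Residue(number=int(res_id), name=name, ca=ca, atoms=keep))

    numbers = [r.number for r in residues]
    missing = [
        n
        for a, b in zip(numbers, numbers[1:])
        for n in range(a + 1, b)
    ]
    if missing:
        warnings.warn(
            f"chain {chain_id!r}: {len(missing)} residue number(s) missing "
            f"from the author numbering: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )

    hetero: list[tuple[str, str, np.ndarray]] = []
    het = atoms[~struc.filter_amino_acids(atoms) & ~struc.filter_solvent(atoms)]
    if het.array_length():
        same_chain = het[het.chain_id == chain_id]
        source = same_chain if same_chain.array_length() else het
        for k in range(source.array_length()):
            elem = str(source.element[k]).upper()
            hetero.append(
                (elem, str(source.atom_name[k]), np.array(source.coord[k], dtype=float))
            )
    return StructureModel(
        chain_id=chain_id, residues=residues, hetero=hetero, missing_residues=missing
    )


def _sulfur(res: Residue) -> np.ndarray | None:
    if "SG" in res.atoms:
        return res.atoms["SG"]
    return res.atoms.get("CB")


def find_disulfides(model: StructureModel, cutoff: float = 2.5) -> list[DisulfideBond]:
    """All cysteine pairs whose Sγ atoms lie within ``cutoff`` Å.

    The default 2.5 Å comfortably covers the ~2.05 Å S-S covalent bond
    without reaching non-bonded sulfur contacts.
    """
    cys = [r for r in model.residues if r.name == "CYS"]
    bonds = []
    for a in range(len(cys)):
        for b in range(a + 1, len(cys)):
            sa, sb = _sulfur(cys[a]), _sulfur(cys[b])
            if sa is None or sb is None:
                continue
            d = float(np.linalg.norm(sa - sb))
            if d <= cutoff:
                bonds.append(
                    DisulfideBond(residues=(cys[a].number, cys[b].number), distance=d)
                )
    return bonds


def metal_site_geometry(
    model: StructureModel, metal_element: str = "CU", cutoff: float = 3.5
) -> MetalSite:
    """Coordination geometry of a metal cofactor.

    Scans all non-carbon protein atoms retained by the parser (side-chain
    anchors, Cβ, backbone carbonyl O) plus Cα within ``cutoff`` of the metal
    and reports them sorted by distance.

    Raises
    ------
    ValueError
        If no hetero atom of ``metal_element`` is present.
    """
    metal_element = metal_element.upper()
    positions = [coord for elem, _, coord in model.hetero if elem == metal_element]
    if not positions:
        raise ValueError(f"no {metal_element} atom in structure")
    pos = positions[0]
    ligands = []
    for res in model.residues:
        for atom_name, coord in list(res.atoms.items()) + [("CA", res.ca)]:
            if atom_name in ("CB", "CA"):
                continue
            d = float(np.linalg.norm(coord - pos))
            if d <= cutoff:
                ligands.append(
                    {
                        "residue": res.number,
                        "res_name": res.name,
                        "atom": atom_name,
                        "distance": d,
                    }
                )
    ligands.sort(key=lambda lig: lig["distance"])
    return MetalSite(element=metal_element, position=pos, ligands=ligands)


def predict_increment(
    model: StructureModel,
    pulled_terminus: str,
    anchor_residue: int | None,
    disulfides: list[DisulfideBond] | None = None,
    L_res: float = LENGTH_PER_RESIDUE_NM,
    construct: str = "",
) -> ContourPrediction:
    """Expected ΔL for unfolding from a terminus up to an anchor residue.

    Parameters
    ----------
    model : StructureModel
    pulled_terminus : {"N", "C"}
        Terminus from which the chain unravels.
    anchor_residue : int or None
        Residue that stays anchored (e.g. a Cu ligand); the released stretch
        runs from the pulled terminus up to, but excluding, this residue.
        ``None`` releases the whole chain (complete unfolding).
    disulfides : list of DisulfideBond, optional
        Crosslinks in effect (pass ``[]`` to model a reduced/mutant chain);
        defaults to :func:`find_disulfides` on the model.
    L_res : float
        Contour length per residue, nm (default 0.38).

    Returns
    -------
    ContourPrediction

    Raises
    ------
    ValueError
        Unknown terminus, anchor outside the pulled span, or a disulfide
        crossing the anchor.
    """
    if pulled_terminus not in ("N", "C"):
        raise ValueError("pulled_terminus must be 'N' or 'C'")
    if disulfides is None:
        disulfides = find_disulfides(model)
    n_term, c_term = model.n_terminus, model.c_terminus
    near = n_term if pulled_terminus == "N" else c_term
    far = c_term if pulled_terminus == "N" else n_term

    if anchor_residue is None:
        anchor = far
        released_span = [r.number for r in model.residues]
    else:
        anchor = anchor_residue
        model.residue(anchor)  # existence check
        if pulled_terminus == "N":
            if not (n_term <= anchor <= c_term):
                raise ValueError(f"anchor {anchor} outside pulled span")
            released_span = [r.number for r in model.residues if r.number < anchor]
        else:
            if not (n_term <= anchor <= c_term):
                raise ValueError(f"anchor {anchor} outside pulled span")
            released_span = [r.number for r in model.residues if r.number > anchor]

    released_set = set(released_span)
    trapped = 0
    crosslink_span = 0.0
    for bond in disulfides:
        i, j = bond.residues
        inside = {n for n in released_set if i <= n <= j}
        loop = {r.number for r in model.residues if i <= r.number <= j}
        if not inside:
            continue  # loop untouched by this unfolding step
        if inside != loop:
            raise ValueError(
                f"disulfide {bond.residues} crosses the anchor at {anchor}; "
                "the released span must contain the loop entirely or not at all"
            )
        trapped += len(loop)
        released_set -= loop
        crosslink_span += model.ca_distance(i, j) / 10.0  # Å -> nm

    released = len(released_set)
    d_anchor_far = model.ca_distance(anchor, far) / 10.0
    d_termini = model.ca_distance(n_term, c_term) / 10.0
    delta_L = L_res * released + crosslink_span + d_anchor_far - d_termini
    native_span = L_res * released - delta_L
    return ContourPrediction(
        construct=construct or model.chain_id,
        pulled_terminus=pulled_terminus,
        anchor_residue=anchor_residue,
        released=released,
        trapped=trapped,
        native_span_nm=native_span,
        delta_L_nm=delta_L,
        crosslink_span_nm=crosslink_span,
    )
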