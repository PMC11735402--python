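"""Residue-level geometric features of a protein(-DNA) complex.

Distance features interpret fitness scores structurally: mean distance
of each residue to the DNA-binding surface (TOP: residues 248, 273, 277,
280 in the p53 DBD convention), to the opposite pole (BOTTOM: 153, 225,
260) and to the hydrophobic core (CENTER: 195, 236, 253), plus
membership in the protein-DNA / inter-chain interface within a 10 A
heavy-atom cutoff.

The default inter-residue metric is the minimum heavy-atom distance
(contact-map semantics); a Calpha mode is available for speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "StructureModel",
    "interface_residues",
    "load_structure",
    "mean_distance_to_set",
    "residue_distance_matrix",
    "TOP_RESIDUES",
    "BOTTOM_RESIDUES",
    "CENTER_RESIDUES",
]

#: reference residue sets of the p53 DNA-binding domain
TOP_RESIDUES = (248, 273, 277, 280)
BOTTOM_RESIDUES = (153, 225, 260)
CENTER_RESIDUES = (195, 236, 253)


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float
    is_hetatm: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    atoms: list[Atom]

    def __post_init__(self) -> None:
        coords = np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)
        if len(coords) and not np.isfinite(coords).all():
            raise ValueError("non-finite atom coordinates")
        self._index: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._index.setdefault((a.chain, a.resnum), []).append(i)

    @property
    def residue_index(self) -> dict[tuple[str, int], list[int]]:
        return self._index

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def residues(self, chains: Optional[Iterable[str]] = None) -> list[tuple[str, int]]:
        chains = None if chains is None else set(chains)
        return [key for key in self._index if chains is None or key[0] in chains]

    def heavy_coords(self, key: tuple[str, int]) -> np.ndarray:
        idx = [i for i in self._index[key] if self.atoms[i].element != "H"]
        return np.array([[self.atoms[i].x, self.atoms[i].y, self.atoms[i].z] for i in idx])

    def ca_coord(self, key: tuple[str, int]) -> Optional[np.ndarray]:
        for i in self._index[key]:
            if self.atoms[i].name == "CA":
                return self.atoms[i].xyz
        return None

    def translated(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transformed copy (used for invariance checks)."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        atoms = []
        for a in self.atoms:
            x, y, z = rotation @ a.xyz + translation
            atoms.append(
                Atom(a.chain, a.resnum, a.resname, a.name, a.element, x, y, z, a.is_hetatm)
            )
        return StructureModel(atoms)


def load_structure(pdb_text: str) -> StructureModel:
    """Parse PDB-format text; only the first MODEL is loaded.

    HETATM records are retained and flagged (nucleic-acid chains use
    standard residues, so DNA partners parse as ordinary atoms).
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparsable PDB input: {exc}") from exc
    if len(st) == 0:
        raise ValueError("no ATOM records found")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for atom in res:
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name,
                        name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        is_hetatm=res.het_flag == "H",
                    )
                )
    if not atoms:
        raise ValueError("no ATOM records found")
    return StructureModel(atoms)


def residue_distance_matrix(
    structure: StructureModel,
    mode: str = "min_heavy_atom",
    chains: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Symmetric residue-residue distance matrix in Angstrom.

    ``min_heavy_atom`` uses the minimum pairwise heavy-atom distance;
    ``c_alpha`` uses Calpha positions (residues lacking a Calpha are
    dropped with a warning column absent).  The index holds residue
    numbers when a single chain is selected, else (chain, resnum).
    """
    keys = structure.residues(chains)
    if len(keys) < 2:
        raise ValueError("need at least two residues")
    single_chain = len({c for c, _ in keys}) == 1
    labels = [r for _, r in keys] if single_chain else keys

    if mode == "c_alpha":
        coords = []
        kept_labels = []
        for key, lab in zip(keys, labels):
            ca = structure.ca_coord(key)
            if ca is not None:
                coords.append(ca)
                kept_labels.append(lab)
        mat = cdist(np.array(coords), np.array(coords))
        return pd.DataFrame(mat, index=kept_labels, columns=kept_labels)
    if mode != "min_heavy_atom":
        raise ValueError(f"unknown mode {mode!r}")

    coord_sets = [structure.heavy_coords(key) for key in keys]
    n = len(keys)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cdist(coord_sets[i], coord_sets[j]).min()
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def mean_distance_to_set(
    matrix: pd.DataFrame,
    residue,
    reference: Sequence,
) -> float:
    """Arithmetic mean of distances from *residue* to the reference set.

    A residue belonging to the reference set includes its own zero
    self-distance in the mean (documented convention).
    """
    missing = [r for r in reference if r not in matrix.index]
    if missing:
        raise KeyError(f"reference residues missing from structure: {missing}")
    if residue not in matrix.index:
        raise KeyError(f"residue {residue!r} missing from structure")
    return float(matrix.loc[residue, list(reference)].mean())


def interface_residues(
    structure: StructureModel,
    partner_chains: Iterable[str],
    cutoff: float = 10.0,
    chains: Optional[Iterable[str]] = None,
) -> set[tuple[str, int]]:
    """Residues with any heavy atom within *cutoff* of a partner heavy atom."""
    partner_chains = set(partner_chains)
    if not partner_chains & set(structure.chains()):
        raise ValueError(f"partner chains {sorted(partner_chains)} not in structure")
    partner_coords = np.vstack(
        [structure.heavy_coords(k) for k in structure.residues(partner_chains)]
    )
    tree = cKDTree(partner_coords)
    query = structure.residues(chains)
    result = set()
    for key in query:
        if key[0] in partner_chains:
            continue
        coords = structure.heavy_coords(key)
        if len(coords) and float(tree.query(coords)[0].min()) <= cutoff:
            result.add(key)
    return result


def structure_feature_table(
    structure: StructureModel,
    chain: str,
    dna_chains: Iterable[str],
    mode: str = "min_heavy_atom",
    cutoff: float = 10.0,
    top: Sequence[int] = TOP_RESIDUES,
    bottom: Sequence[int] = BOTTOM_RESIDUES,
    center: Sequence[int] = CENTER_RESIDUES,
) -> pd.DataFrame:
    """Per-residue TOP/BOTTOM/CENTER distances and interface membership."""
    matrix = residue_distance_matrix(structure, mode=mode, chains=[chain])
    iface = interface_residues(structure, dna_chains, cutoff=cutoff, chains=[chain])
    iface_nums = {r for c, r in iface}
    rows = []
    for resnum in matrix.index:
        rows.append(
            {
                "resnum": resnum,
                "TOP": mean_distance_to_set(matrix, resnum, list(top)),
                "BOTTOM": mean_distance_to_set(matrix, resnum, list(bottom)),
                "CENTER": mean_distance_to_set(matrix, resnum, list(center)),
                "is_interface": resnum in iface_nums,
                "in_reference_set": resnum in set(top) | set(bottom) | set(center),
            }
        )
    return pd.DataFrame(rows).set_index("resnum")
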