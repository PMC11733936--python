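"""In-memory protein--ligand structure model and a synthetic toy complex builder."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidInputError

#: Protein backbone atom names.
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class StructureModel:
    """Atom table of a prepared protein--ligand complex (coordinates in Angstrom).

    ``ligand_selection`` and ``protein_backbone`` are disjoint atom-index
    arrays identifying the ligand and the protein backbone (N, CA, C, O).
    """

    serials: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    record_types: np.ndarray
    xyz: np.ndarray
    ligand_selection: np.ndarray
    protein_backbone: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.ligand_selection = np.asarray(self.ligand_selection, dtype=int)
        self.protein_backbone = np.asarray(self.protein_backbone, dtype=int)
        n = self.xyz.shape[0]
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise InvalidInputError("xyz must be an (n_atoms, 3) array")
        for name in ("serials", "names", "elements", "resids", "resnames", "chains", "record_types"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"{name} length does not match n_atoms={n}")
        if not np.all(np.isfinite(self.xyz)):
            raise InvalidInputError("coordinates must be finite")
        if np.intersect1d(self.ligand_selection, self.protein_backbone).size:
            raise InvalidInputError("ligand and protein selections must be disjoint")

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return np.array([e.upper() != "H" for e in self.elements])

    @property
    def ligand_heavy(self) -> np.ndarray:
        """Indices of ligand heavy atoms."""
        sel = self.ligand_selection
        return sel[self.heavy_mask[sel]]

    @property
    def protein_indices(self) -> np.ndarray:
        """Indices of all atoms not in the ligand selection."""
        mask = np.ones(self.n_atoms, dtype=bool)
        mask[self.ligand_selection] = False
        return np.flatnonzero(mask)

    def residue_keys(self) -> np.ndarray:
        """Per-atom (chain, resid) identifiers."""
        return np.array([f"{c}:{r}" for c, r in zip(self.chains, self.resids)])

    def with_coordinates(self, xyz: np.ndarray) -> "StructureModel":
        return replace(self, xyz=np.asarray(xyz, dtype=float))


def make_toy_structure(n_residues: int = 12, n_ligand_atoms: int = 5,
                       ligand_resname: str = "LIG") -> StructureModel:
    """Build a small synthetic helix-like protein with a ligand in a shallow pocket.

    Purely geometric plumbing for exercising restraint selection, trajectory
    superposition and RMSD analysis; no chemistry is implied.  The ligand sits
    ~4 A from the middle residues so a 6 A binding-site cutoff frees a few
    residues from restraints.
    """
    names, elements, resids, resnames, chains, records = [], [], [], [], [], []
    coords = []
    # backbone offsets relative to the residue anchor point
    offsets = {
        "N": np.array([-0.8, -0.6, -0.4]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([0.9, 0.5, 0.3]),
        "O": np.array([1.1, 1.5, 0.6]),
    }
    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    for i in range(n_residues):
        anchor = np.array([radius * np.cos(i * turn), radius * np.sin(i * turn), rise * i])
        for name in BACKBONE_NAMES:
            names.append(name)
            elements.append(name[0])
            resids.append(i + 1)
            resnames.append("ALA")
            chains.append("A")
            records.append("ATOM")
            coords.append(anchor + offsets[name])
    # ligand: compact cluster displaced from the helix axis near the middle residue
    mid = n_residues // 2
    center = np.array([4.0, 0.0, rise * mid])
    lig_offsets = np.array([
        [0.0, 0.0, 0.0],
        [1.3, 0.4, 0.2],
        [-0.6, 1.2, -0.3],
        [0.4, -1.1, 0.8],
        [-0.9, -0.5, -0.9],
        [1.0, 1.0, -1.0],
        [-1.2, 0.2, 1.1],
    ])
    for j in range(n_ligand_atoms):
        names.append(f"C{j + 1}")
        elements.append("C")
        resids.append(n_residues + 1)
        resnames.append(ligand_resname)
        chains.append("A")
        records.append("HETATM")
        coords.append(center + lig_offsets[j % len(lig_offsets)])

    n_total = len(names)
    n_prot = n_residues * len(BACKBONE_NAMES)
    return StructureModel(
        serials=np.arange(1, n_total + 1),
        names=np.array(names),
        elements=np.array(elements),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.array(chains),
        record_types=np.array(records),
        xyz=np.array(coords),
        ligand_selection=np.arange(n_prot, n_total),
        protein_backbone=np.arange(n_prot),
    )
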