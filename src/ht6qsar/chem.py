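"""Molecular data model and perception layer.

Everything downstream (descriptor kernels, curation, the published model)
operates on :class:`MoleculeRecord` — a plain-data snapshot of a molecule:
graph, 3D geometry, per-atom partial charges and an optional experimental
affinity.  Records are normally built from SMILES/SDF/MOL2 via
:func:`parse_molecule` (RDKit does the perception work), but can equally be
hand-assembled with assigned coordinates and charges, which is how the unit
fixtures exercise the descriptor semantics without any quantum-chemistry
input.

Partial charges are consumed, never computed ab initio: they either come
from the input file (e.g. semi-empirical charges exported to a MOL2 charge
column or an SDF data field) or, as a fallback, from the Gasteiger scheme.
Records carry ``charge_origin`` so reports can flag that internally
generated charges are not comparable to externally supplied ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

# Average atomic masses (u) for the elements the hand-built fixtures and the
# curated chemical space use; parse_molecule takes masses from RDKit instead.
ATOMIC_MASS = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Se": 78.971, "Br": 79.904, "I": 126.904,
}

HYBRIDIZATIONS = ("sp", "sp2", "sp3", "aromatic", "other")

#: Elements treated as intrinsically lipophilic; a carbon is additionally
#: lipophilic when all of its heavy neighbours are carbons (an added ring
#: methyl is lipophilic, a ring carbon next to nitrogen is not).
LIPOPHILIC_ELEMENTS = frozenset({"Cl", "Br", "I", "S"})

#: Gate for "non-polar" hydrogens: |partial charge| <= 0.200 e.
NONPOLAR_H_WINDOW = 0.200


class ParseError(ValueError):
    """Input text could not be interpreted as a molecule."""


class ChargeSourceError(ValueError):
    """Per-atom charges were required from the input but are absent."""


class GeometryError(ValueError):
    """3D coordinates are missing or could not be generated."""


@dataclass
class Atom:
    """One atom: identity, geometry, charge and perception flags."""

    index: int
    element: str
    mass: float
    coords: np.ndarray          # Å, shape (3,)
    partial_charge: float       # elementary-charge units
    in_ring: bool = False
    hybridization: str = "other"
    n_attached_H: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        if self.n_attached_H < 0:
            raise ValueError(f"atom {self.index}: negative hydrogen count")
        if self.hybridization not in HYBRIDIZATIONS:
            raise ValueError(f"atom {self.index}: unknown hybridization {self.hybridization!r}")


@dataclass
class MoleculeRecord:
    """A molecule with explicit hydrogens, geometry, charges and activity.

    ``bonds`` are (i, j, order) with 0-based atom indices; aromatic bonds
    carry order 1.5.  ``ki_nM`` is the experimental inhibition constant in
    nM; ``pki`` its molar-scale negative log.  ``charge_origin`` records
    where the partial charges came from ("file", "gasteiger" or "assigned").
    """

    mol_id: str
    smiles: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, float]]
    ki_nM: float | None = None
    pki: float | None = None
    charge_origin: str = "assigned"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"{self.mol_id}: bond ({i},{j}) has invalid endpoints")
        if self.ki_nM is not None:
            if self.ki_nM <= 0:
                raise ValueError(f"{self.mol_id}: Ki must be positive")
            expected = -math.log10(self.ki_nM * 1e-9)
            if self.pki is None:
                self.pki = expected
            elif abs(self.pki - expected) > 5e-4:
                raise ValueError(
                    f"{self.mol_id}: pKi {self.pki} inconsistent with Ki {self.ki_nM} nM"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def heavy_neighbors(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.atoms[j].element != "H"]

    def coords_array(self) -> np.ndarray:
        return np.vstack([a.coords for a in self.atoms])

    def translated(self, v) -> "MoleculeRecord":
        v = np.asarray(v, dtype=float)
        atoms = [replace(a, coords=a.coords + v) for a in self.atoms]
        return replace(self, atoms=atoms)


@dataclass(frozen=True)
class AtomClassFlags:
    """Per-atom membership in the descriptor vocabulary's atom classes."""

    is_nonpolar_h: bool     # H with |q| <= 0.200 e
    is_ring_c: bool
    is_lipophilic: bool
    is_donor: bool          # N or O bearing >= 1 hydrogen
    is_sp3_n: bool
    is_sp2_o: bool
    is_ring_n: bool


# ---------------------------------------------------------------------------
# parsing


def _rdkit():
    from rdkit import Chem
    from rdkit.Chem import AllChem
    return Chem, AllChem


def _looks_like_sdf(text: str) -> bool:
    return "M  END" in text or "$$$$" in text


def _looks_like_mol2(text: str) -> bool:
    return "@<TRIPOS>" in text


def _hybridization_of(atom) -> str:
    from rdkit.Chem.rdchem import HybridizationType as HT
    if atom.GetIsAromatic():
        return "aromatic"
    return {HT.SP: "sp", HT.SP2: "sp2", HT.SP3: "sp3"}.get(atom.GetHybridization(), "other")


def _file_charges(mol) -> list[float] | None:
    """Per-atom charges carried by the input, if any.

    MOL2 charge columns surface as the ``_TriposPartialCharge`` atom
    property; SDF inputs may carry a whitespace-separated ``PARTIAL_CHARGES``
    data field (one value per atom, input atom order).
    """
    if mol.HasProp("PARTIAL_CHARGES"):
        vals = [float(t) for t in mol.GetProp("PARTIAL_CHARGES").split()]
        if len(vals) != mol.GetNumAtoms():
            raise ChargeSourceError(
                f"PARTIAL_CHARGES lists {len(vals)} values for {mol.GetNumAtoms()} atoms"
            )
        return vals
    if all(a.HasProp("_TriposPartialCharge") for a in mol.GetAtoms()):
        return [a.GetDoubleProp("_TriposPartialCharge") for a in mol.GetAtoms()]
    return None


def from_rdkit(mol, mol_id: str = "", ki_nM: float | None = None,
               charge_source: str = "auto", embed_seed: int = 42) -> MoleculeRecord:
    """Build a :class:`MoleculeRecord` from an RDKit mol.

    Hydrogens are made explicit; a 3D conformer is ETKDG-embedded (fixed
    seed, so regression tests are stable) when the input had none.
    """
    Chem, AllChem = _rdkit()

    file_q = _file_charges(mol)
    had_conformer = mol.GetNumConformers() > 0
    if mol.GetNumAtoms(onlyExplicit=True) != Chem.AddHs(mol).GetNumAtoms():
        if file_q is not None:
            # adding hydrogens would desynchronise the per-atom charge list
            raise ChargeSourceError(
                f"{mol_id or 'molecule'}: file charges supplied but hydrogens are implicit"
            )
        mol = Chem.AddHs(mol, addCoords=had_conformer)

    if mol.GetNumConformers() == 0:
        params = AllChem.ETKDGv3()
        params.randomSeed = embed_seed
        if AllChem.EmbedMolecule(mol, params) != 0:
            params.useRandomCoords = True
            if AllChem.EmbedMolecule(mol, params) != 0:
                raise GeometryError(f"{mol_id or 'molecule'}: 3D embedding failed")
        AllChem.MMFFOptimizeMolecule(mol, maxIters=200)

    if charge_source == "from-file":
        if file_q is None:
            raise ChargeSourceError(f"{mol_id or 'molecule'}: no per-atom charges in input")
        charges, origin = file_q, "file"
    elif charge_source == "gasteiger" or (charge_source == "auto" and file_q is None):
        from rdkit.Chem import rdPartialCharges
        rdPartialCharges.ComputeGasteigerCharges(mol)
        charges = [a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()]
        origin = "gasteiger"
    elif charge_source == "auto":
        charges, origin = file_q, "file"
    else:
        raise ValueError(f"unknown charge_source {charge_source!r}")

    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        n_h = sum(1 for nb in a.GetNeighbors() if nb.GetSymbol() == "H")
        atoms.append(Atom(
            index=a.GetIdx(),
            element=a.GetSymbol(),
            mass=a.GetMass(),
            coords=np.array([pos.x, pos.y, pos.z]),
            partial_charge=float(charges[a.GetIdx()]),
            in_ring=a.IsInRing(),
            hybridization=_hybridization_of(a),
            n_attached_H=n_h,
        ))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    smiles = Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(mol)))
    return MoleculeRecord(mol_id=mol_id, smiles=smiles, atoms=atoms, bonds=bonds,
                          ki_nM=ki_nM, charge_origin=origin)


def parse_molecule(text: str, charge_source: str = "auto", mol_id: str = "",
                   ki_nM: float | None = None, embed_seed: int = 42) -> MoleculeRecord:
    """Parse a SMILES string, an SDF (V2000) block or a MOL2 block.

    ``charge_source`` is one of ``"from-file"`` (per-atom charges must be in
    the input), ``"gasteiger"`` (always recompute) or ``"auto"`` (file
    charges when present, Gasteiger otherwise).
    """
    Chem, _ = _rdkit()
    text = text.strip("\n")
    if _looks_like_mol2(text):
        mol = Chem.MolFromMol2Block(text, removeHs=False)
        if mol is None:
            raise ParseError(f"unparseable MOL2 block ({mol_id or text[:40]!r})")
    elif _looks_like_sdf(text):
        supplier = Chem.SDMolSupplier()
        supplier.SetData(text if text.endswith("$$$$") else text + "\n\n$$$$\n",
                         removeHs=False)
        mol = next(iter(supplier), None)
        if mol is None:
            raise ParseError(f"unparseable SDF block ({mol_id or text[:40]!r})")
    else:
        mol = Chem.MolFromSmiles(text)
        if mol is None:
            raise ParseError(f"unparseable SMILES {text!r}" + (f" ({mol_id})" if mol_id else ""))
    return from_rdkit(mol, mol_id=mol_id, ki_nM=ki_nM,
                      charge_source=charge_source, embed_seed=embed_seed)


# ---------------------------------------------------------------------------
# geometry / topology


def bond_distance_matrix(mol: MoleculeRecord) -> np.ndarray:
    """Shortest-path bond counts between all atom pairs.

    Symmetric with zero diagonal; disconnected pairs get ``inf`` (flagged
    with a warning) so "within n bonds" predicates simply fail for them.
    """
    n = mol.n_atoms
    if n == 0:
        return np.zeros((0, 0))
    rows, cols = [], []
    for i, j, _ in mol.bonds:
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="BF", unweighted=True, directed=False)
    if np.isinf(dist).any():
        logger.warning("%s: disconnected graph, unreachable pairs set to inf", mol.mol_id)
    return dist


def center_of_mass(mol: MoleculeRecord) -> np.ndarray:
    """Mass-weighted mean position of all atoms, hydrogens included (Å)."""
    masses = np.array([a.mass for a in mol.atoms])
    if masses.sum() <= 0:
        raise GeometryError(f"{mol.mol_id}: non-positive total mass")
    return masses @ mol.coords_array() / masses.sum()


def classify_atoms(mol: MoleculeRecord) -> list[AtomClassFlags]:
    """Assign every atom its descriptor-vocabulary class flags.

    Atoms with hybridization "other" are excluded from the
    hybridization-dependent classes (sp3-N, sp2-O) with a logged warning.
    """
    flags = []
    warned = False
    for a in mol.atoms:
        if a.hybridization == "other" and a.element in ("N", "O") and not warned:
            logger.warning("%s: atom %d has unknown hybridization; excluded from "
                           "hybridization-dependent classes", mol.mol_id, a.index)
            warned = True
        is_c = a.element == "C"
        lipophilic = a.element in LIPOPHILIC_ELEMENTS or (
            is_c and all(mol.atoms[j].element == "C" for j in mol.heavy_neighbors(a.index))
        )
        flags.append(AtomClassFlags(
            is_nonpolar_h=a.element == "H" and abs(a.partial_charge) <= NONPOLAR_H_WINDOW,
            is_ring_c=is_c and a.in_ring,
            is_lipophilic=lipophilic,
            is_donor=a.element in ("N", "O") and a.n_attached_H >= 1,
            is_sp3_n=a.element == "N" and a.hybridization == "sp3",
            is_sp2_o=a.element == "O" and a.hybridization == "sp2",
            is_ring_n=a.element == "N" and a.in_ring,
        ))
    return flags
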