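"""The six descriptors of the published six-parameter binding-affinity model.

Each descriptor is a small counting/summing kernel over atom classes and
shortest-path bond distances (plus one Euclidean gate around the centre of
mass).  Naming convention, decoded once here and used throughout:

* ``nB``  — "within n bonds": shortest-path distance d with 1 <= d <= n
  (the atom itself, d = 0, never qualifies); "exactly n bonds" is d = n.
* ``nBc`` — within n bonds, summing partial charges instead of counting.
* ``f``   — frequency of occurrence of the first-named atom class.

The canonical descriptor names (column order of the published model):

``com_Hhyd_3A``      number of non-polar hydrogens (|q| <= 0.2 e) within
                     3 Å (Euclidean, inclusive) of the centre of mass.
``ringC_S_4Bc``      sum of partial charges over the *set* of ring carbons
                     within four bonds of any sulfur (each carbon once).
``flipo&S_ringN3B``  ring nitrogens whose minimum bond distance to the
                     class {lipophilic atoms plus sulfur} is exactly 3; a ring N
                     with such an atom at two or fewer bonds is neglected.
``KRFPC620``         nitrogens bearing three ethyl (CH3CH2-) substituents
                     (the Klekota-Roth fragment-620 pattern), counted per
                     unique central nitrogen.
``sp3N_sp2O_8B``     sp3 nitrogens within eight bonds of any sp2 oxygen.
``fsp3Cdon1B``       H-bond donor atoms (N/O with >= 1 H) directly bonded
                     to at least one sp3 carbon.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .chem import MoleculeRecord, bond_distance_matrix, center_of_mass, classify_atoms

logger = logging.getLogger(__name__)

MODEL1_DESCRIPTORS = (
    "com_Hhyd_3A",
    "ringC_S_4Bc",
    "flipo&S_ringN3B",
    "KRFPC620",
    "sp3N_sp2O_8B",
    "fsp3Cdon1B",
)


def count_nonpolar_h_near_com(mol: MoleculeRecord, radius: float = 3.0) -> int:
    """``com_Hhyd_3A``: non-polar hydrogens within ``radius`` Å of the com."""
    com = center_of_mass(mol)
    flags = classify_atoms(mol)
    return sum(
        1 for a, f in zip(mol.atoms, flags)
        if f.is_nonpolar_h and np.linalg.norm(a.coords - com) <= radius
    )


def sum_ring_c_charge_near_s(mol: MoleculeRecord, max_bonds: int = 4) -> float:
    """``ringC_S_4Bc``: charge sum over ring carbons within ``max_bonds`` of sulfur.

    Set semantics: a ring carbon near several sulfurs contributes once.
    """
    sulfurs = [a.index for a in mol.atoms if a.element == "S"]
    if not sulfurs:
        return 0.0
    flags = classify_atoms(mol)
    dist = bond_distance_matrix(mol)
    total = 0.0
    for a, f in zip(mol.atoms, flags):
        if not f.is_ring_c:
            continue
        d = min(dist[a.index, s] for s in sulfurs)
        if 1 <= d <= max_bonds:
            total += a.partial_charge
    return total


def count_ring_n_3b_from_lipophilic(mol: MoleculeRecord) -> int:
    """``flipo&S_ringN3B``: ring N at minimum distance exactly 3 from the
    lipophilic-or-sulfur atom class (a closer class member disqualifies)."""
    flags = classify_atoms(mol)
    targets = [a.index for a, f in zip(mol.atoms, flags) if f.is_lipophilic]
    ring_ns = [a.index for a, f in zip(mol.atoms, flags) if f.is_ring_n]
    if not targets or not ring_ns:
        return 0
    dist = bond_distance_matrix(mol)
    count = 0
    for n in ring_ns:
        d = min(dist[n, t] for t in targets if t != n)
        if d == 3:
            count += 1
    return count


def count_triethyl_n(mol: MoleculeRecord) -> int:
    """``KRFPC620``: nitrogens whose three heavy substituents are all ethyls."""

    def is_ethyl_ch2(c: int, n: int) -> bool:
        a = mol.atoms[c]
        if a.element != "C" or a.n_attached_H != 2:
            return False
        heavy = [j for j in mol.heavy_neighbors(c) if j != n]
        if len(heavy) != 1:
            return False
        tip = mol.atoms[heavy[0]]
        return (tip.element == "C" and tip.n_attached_H == 3
                and len(mol.heavy_neighbors(tip.index)) == 1)

    count = 0
    for a in mol.atoms:
        if a.element != "N":
            continue
        heavy = mol.heavy_neighbors(a.index)
        if len(heavy) == 3 and all(is_ethyl_ch2(c, a.index) for c in heavy):
            count += 1
    return count


def count_sp3n_near_sp2o(mol: MoleculeRecord, max_bonds: int = 8) -> int:
    """``sp3N_sp2O_8B``: sp3 nitrogens within ``max_bonds`` of any sp2 oxygen."""
    flags = classify_atoms(mol)
    ns = [a.index for a, f in zip(mol.atoms, flags) if f.is_sp3_n]
    os_ = [a.index for a, f in zip(mol.atoms, flags) if f.is_sp2_o]
    if not ns or not os_:
        return 0
    dist = bond_distance_matrix(mol)
    return sum(1 for n in ns if any(1 <= dist[n, o] <= max_bonds for o in os_))


def count_donor_on_sp3c(mol: MoleculeRecord) -> int:
    """``fsp3Cdon1B``: donor atoms directly bonded to >= 1 sp3 carbon."""
    flags = classify_atoms(mol)
    count = 0
    for a, f in zip(mol.atoms, flags):
        if not f.is_donor:
            continue
        if any(mol.atoms[j].element == "C" and mol.atoms[j].hybridization == "sp3"
               for j in mol.heavy_neighbors(a.index)):
            count += 1
    return count


DESCRIPTOR_FUNCS = {
    "com_Hhyd_3A": count_nonpolar_h_near_com,
    "ringC_S_4Bc": sum_ring_c_charge_near_s,
    "flipo&S_ringN3B": count_ring_n_3b_from_lipophilic,
    "KRFPC620": count_triethyl_n,
    "sp3N_sp2O_8B": count_sp3n_near_sp2o,
    "fsp3Cdon1B": count_donor_on_sp3c,
}


def compute_descriptors(mol: MoleculeRecord) -> dict[str, float]:
    """All six descriptors for one molecule, in model column order."""
    return {name: fn(mol) for name, fn in DESCRIPTOR_FUNCS.items()}


def compute_descriptor_table(mols: list[MoleculeRecord],
                             on_error: str = "drop") -> pd.DataFrame:
    """Descriptor table: one row per molecule, the six model columns.

    Per-molecule failures are collected; with ``on_error="drop"`` the
    offending molecules are excluded with a logged reason, with ``"raise"``
    the first failure propagates.
    """
    rows, ids = [], []
    for mol in mols:
        try:
            rows.append(compute_descriptors(mol))
        except Exception as exc:  # noqa: BLE001 - reported per molecule
            if on_error == "raise":
                raise
            logger.warning("descriptors failed for %s: %s", mol.mol_id, exc)
            continue
        ids.append(mol.mol_id)
    table = pd.DataFrame(rows, index=pd.Index(ids, name="mol_id"),
                         columns=list(MODEL1_DESCRIPTORS))
    return table
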