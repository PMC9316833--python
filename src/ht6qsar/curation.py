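"""Dataset curation for the binding-affinity study.

A raw activity table (structure + Ki in nM) is reduced to a modelling-ready
set by stripping counter-ions, removing metal derivatives, collapsing
duplicates, removing rule-of-five violators and records without a defined
Ki, and converting Ki to the molar-scale pKi = -log10(Ki [M]).

Each removed molecule gets exactly one primary reason, assigned in this
order: invalid structure -> salt/metal -> undefined Ki -> rule-of-five ->
duplicate.  Curation is idempotent: running it on its own output changes
nothing.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass, field, replace

from .chem import MoleculeRecord, parse_molecule

#: Elements allowed in an organic, non-metallic ligand.
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)


def ki_to_pki(ki_nM: float) -> float:
    """pKi = -log10(Ki in molar) for a Ki given in nM."""
    if not ki_nM > 0:
        raise ValueError(f"Ki must be positive, got {ki_nM}")
    return 9.0 - math.log10(ki_nM)


def pki_to_ki(pki: float) -> float:
    """Inverse transform: Ki in nM for a molar-scale pKi."""
    return 10.0 ** (9.0 - pki)


@dataclass
class CurationReport:
    """Bookkeeping of the curation pass.

    ``removal_reasons`` maps mol_id -> primary reason; the count fields
    partition the removals, so n_output = n_input - sum of removals.
    """

    n_input: int = 0
    n_removed_invalid: int = 0
    n_removed_duplicates: int = 0
    n_removed_salts_metals: int = 0
    n_removed_ro5: int = 0
    n_removed_no_ki: int = 0
    n_output: int = 0
    removal_reasons: dict[str, str] = field(default_factory=dict)

    def check(self) -> None:
        removed = (self.n_removed_invalid + self.n_removed_duplicates
                   + self.n_removed_salts_metals + self.n_removed_ro5
                   + self.n_removed_no_ki)
        assert self.n_output == self.n_input - removed, "curation counts do not add up"
        assert removed == len(self.removal_reasons)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _ro5_violations(mol) -> int:
    from rdkit.Chem import Crippen, Descriptors, Lipinski
    return sum([
        Descriptors.MolWt(mol) > 500,
        Crippen.MolLogP(mol) > 5,
        Lipinski.NumHDonors(mol) > 5,
        Lipinski.NumHAcceptors(mol) > 10,
    ])


def _desalted_parent(smiles: str):
    """(parent RDKit mol, canonical parent SMILES) after keeping the largest
    organic fragment, or (None, reason) when nothing organic remains."""
    from rdkit import Chem
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None, "invalid"
    # a metal anywhere in the record makes it a metal derivative (an
    # organometallic complex is not rescued by keeping its organic fragment)
    if any(a.GetSymbol() not in ORGANIC_ELEMENTS for a in mol.GetAtoms()):
        return None, "salt_or_metal"
    frags = Chem.GetMolFrags(mol, asMols=True)
    organic = [f for f in frags
               if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        return None, "salt_or_metal"
    parent = max(organic, key=lambda f: f.GetNumHeavyAtoms())
    if any(a.GetSymbol() not in ORGANIC_ELEMENTS for a in parent.GetAtoms()):
        return None, "salt_or_metal"
    return parent, Chem.MolToSmiles(parent)


def curate(records: list[MoleculeRecord], ro5_strict: bool = False,
           embed_seed: int = 42) -> tuple[list[MoleculeRecord], CurationReport]:
    """Apply the curation rules; removals are reported, never raised.

    A rule-of-five "violator" breaks >= 2 of the four criteria (the classical
    one-violation allowance); ``ro5_strict`` tightens this to >= 1.
    Duplicates (same canonical desalted parent) collapse to one survivor
    whose activity is the median pKi of the group (Ki back-transformed so the
    Ki/pKi invariant holds).
    """
    report = CurationReport(n_input=len(records))
    max_violations = 0 if ro5_strict else 1

    staged: list[tuple[MoleculeRecord, str, bool]] = []  # record, parent smiles, changed
    for rec in records:
        parent, key = _desalted_parent(rec.smiles)
        if parent is None:
            if key == "invalid":
                report.n_removed_invalid += 1
            else:
                report.n_removed_salts_metals += 1
            report.removal_reasons[rec.mol_id] = key
            continue
        if rec.ki_nM is None:
            report.n_removed_no_ki += 1
            report.removal_reasons[rec.mol_id] = "undefined_ki"
            continue
        if _ro5_violations(parent) > max_violations:
            report.n_removed_ro5 += 1
            report.removal_reasons[rec.mol_id] = "rule_of_five"
            continue
        staged.append((rec, key, key != rec.smiles))

    groups: dict[str, list[tuple[MoleculeRecord, bool]]] = {}
    order: list[str] = []
    for rec, key, changed in staged:
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append((rec, changed))

    survivors: list[MoleculeRecord] = []
    for key in order:
        group = groups[key]
        rec, changed = group[0]
        for dup, _ in group[1:]:
            report.n_removed_duplicates += 1
            report.removal_reasons[dup.mol_id] = "duplicate"
        pki = statistics.median(ki_to_pki(r.ki_nM) for r, _ in group)
        ki = pki_to_ki(pki)
        if changed:
            rec = parse_molecule(key, charge_source="gasteiger", mol_id=rec.mol_id,
                                 embed_seed=embed_seed)
        rec = replace(rec, smiles=key, ki_nM=ki, pki=None)  # pki re-derived from ki
        survivors.append(rec)

    report.n_output = len(survivors)
    report.check()
    return survivors, report


def count_potent(records: list[MoleculeRecord], threshold_nM: float = 10.0) -> int:
    """Number of records at or below a Ki potency threshold (defined Ki only)."""
    return sum(1 for r in records if r.ki_nM is not None and r.ki_nM <= threshold_nM)
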