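"""Synthetic inputs that make every pipeline stage testable offline.

Two generators:

* :func:`make_toy_molecules` — a panel of small hand-built molecules with
  deterministic idealized geometry and assigned partial charges, each
  annotated (:data:`EXPECTED_DESCRIPTORS`) with hand-derived values for all
  six model descriptors.  The annotations are worked out from the structure
  diagrams (bond-path counting, charge sums, symmetry arguments), so they
  double as an independent oracle for the descriptor engine.

* :func:`make_feature_matrix` — descriptor-like feature matrices with a
  planted sparse linear signal: count-like integer columns, one charge-like
  real column, near-constant and collinear decoys (so objective feature
  selection has something to prune), and a response rescaled into the
  study's activity span of pKi 4.5-9.3 (an experimental Ki range of about
  0.5 nM to 29 uM).

Hydrogens whose role in a fixture is irrelevant are assigned charges of
+0.25 e — outside the +-0.2 e non-polar window — so the centre-of-mass
hydrogen count for that fixture is exactly zero however the hydrogens are
laid out.  Fixtures probing the centre-of-mass descriptor use symmetric
geometries where the count is unambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ATOMIC_MASS, Atom, MoleculeRecord
from .descriptors import MODEL1_DESCRIPTORS

_QH_NONPOLAR = 0.05   # inside the +-0.2 window
_QH_POLAR = 0.25      # outside the window: never counted near the com


class _Builder:
    """Incremental hand-construction of a MoleculeRecord."""

    def __init__(self) -> None:
        self._atoms: list[tuple] = []
        self._bonds: list[tuple[int, int, float]] = []

    def add(self, element: str, xyz, q: float, hyb: str = "sp3",
            ring: bool = False) -> int:
        self._atoms.append((element, np.asarray(xyz, float), q, hyb, ring))
        return len(self._atoms) - 1

    def bond(self, i: int, j: int, order: float = 1.0) -> None:
        self._bonds.append((i, j, order))

    def h(self, parent: int, xyz, q: float = _QH_POLAR) -> int:
        idx = self.add("H", xyz, q, hyb="other")
        self.bond(parent, idx)
        return idx

    def hs(self, parent: int, n: int, q: float = _QH_POLAR,
           r: float = 1.09) -> None:
        """Attach n hydrogens around the parent on a deterministic fan."""
        base = self._atoms[parent][1]
        dirs = [np.array([0.3, 0.6, 0.74]), np.array([0.3, -0.6, 0.74]),
                np.array([-0.6, 0.3, -0.74]), np.array([0.6, -0.3, -0.74])]
        for k in range(n):
            d = dirs[k % 4] / np.linalg.norm(dirs[k % 4])
            self.h(parent, base + r * d + 0.05 * k, q)

    def build(self, mol_id: str, smiles: str = "") -> MoleculeRecord:
        n_h = [0] * len(self._atoms)
        for i, j, _ in self._bonds:
            if self._atoms[j][0] == "H":
                n_h[i] += 1
            if self._atoms[i][0] == "H":
                n_h[j] += 1
        atoms = [
            Atom(index=idx, element=el, mass=ATOMIC_MASS[el], coords=xyz,
                 partial_charge=q, in_ring=ring, hybridization=hyb,
                 n_attached_H=n_h[idx])
            for idx, (el, xyz, q, hyb, ring) in enumerate(self._atoms)
        ]
        return MoleculeRecord(mol_id=mol_id, smiles=smiles, atoms=atoms,
                              bonds=list(self._bonds), charge_origin="assigned")


def _polygon(n: int, side: float) -> list[np.ndarray]:
    radius = side / (2 * math.sin(math.pi / n))
    return [radius * np.array([math.cos(2 * math.pi * k / n),
                               math.sin(2 * math.pi * k / n), 0.0])
            for k in range(n)]


def _radial(point: np.ndarray, extra: float) -> np.ndarray:
    u = point[:2] / np.linalg.norm(point[:2])
    return point + extra * np.array([u[0], u[1], 0.0])


_TET = [np.array(v) / math.sqrt(3) for v in
        ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]


# --------------------------------------------------------------------------
# individual fixtures


def _methane() -> MoleculeRecord:
    b = _Builder()
    c = b.add("C", (0, 0, 0), -0.20)
    for d in _TET:
        b.h(c, 1.09 * d, _QH_NONPOLAR)
    return b.build("methane", "C")


def _ethane() -> MoleculeRecord:
    b = _Builder()
    c1 = b.add("C", (-0.765, 0, 0), -0.15)
    c2 = b.add("C", (0.765, 0, 0), -0.15)
    b.bond(c1, c2)
    for sign, c in ((-1, c1), (1, c2)):
        for ang in (0, 2 * math.pi / 3, 4 * math.pi / 3):
            off = np.array([sign * 0.51, 0.96 * math.cos(ang), 0.96 * math.sin(ang)])
            b.h(c, b._atoms[c][1] + off, _QH_NONPOLAR)
    return b.build("ethane", "CC")


def _aromatic_ring(b: _Builder, elements: list[str], charges: list[float],
                   side: float = 1.39) -> list[int]:
    pts = _polygon(len(elements), side)
    idx = [b.add(el, pt, q, hyb="aromatic", ring=True)
           for el, pt, q in zip(elements, pts, charges)]
    for k in range(len(idx)):
        b.bond(idx[k], idx[(k + 1) % len(idx)], 1.5)
    return idx


def _benzene() -> MoleculeRecord:
    b = _Builder()
    ring = _aromatic_ring(b, ["C"] * 6, [-0.10] * 6)
    for c in ring:
        b.h(c, _radial(b._atoms[c][1], 1.09), 0.10)
    return b.build("benzene", "c1ccccc1")


def _pyridine() -> MoleculeRecord:
    b = _Builder()
    ring = _aromatic_ring(b, ["N", "C", "C", "C", "C", "C"],
                          [-0.30, 0.06, 0.06, 0.06, 0.06, 0.06])
    for c in ring[1:]:
        b.h(c, _radial(b._atoms[c][1], 1.09), 0.10)
    return b.build("pyridine", "c1ccncc1")


def _thioanisole() -> MoleculeRecord:
    b = _Builder()
    ring = _aromatic_ring(b, ["C"] * 6, [-0.05] * 6)
    for c in ring[1:]:
        b.h(c, _radial(b._atoms[c][1], 1.09), _QH_POLAR)
    s = b.add("S", _radial(b._atoms[ring[0]][1], 1.78), 0.0)
    b.bond(ring[0], s)
    me = b.add("C", b._atoms[s][1] + np.array([1.28, 1.28, 0]), -0.10)
    b.bond(s, me)
    b.hs(me, 3)
    return b.build("thioanisole", "CSc1ccccc1")


def _amine(mol_id: str, smiles: str, arms: list[int]) -> MoleculeRecord:
    """Tertiary amine with arms of the given carbon counts (1=methyl, 2=ethyl)."""
    b = _Builder()
    n = b.add("N", (0, 0, 0), -0.35)
    for arm_no, length in enumerate(arms):
        ang = 2 * math.pi * arm_no / 3
        u = np.array([math.cos(ang), math.sin(ang), 0.0])
        prev = n
        for depth in range(1, length + 1):
            c = b.add("C", (1.47 + 1.53 * (depth - 1)) * u, -0.05)
            b.bond(prev, c)
            b.hs(c, 3 if depth == length else 2)
            prev = c
    return b.build(mol_id, smiles)


def _chain(b: _Builder, spec: list[tuple[str, float, str, int]],
           spacing: float = 1.5) -> list[int]:
    """Zig-zag heavy-atom chain: (element, charge, hybridization, n_H)."""
    idx = []
    for k, (el, q, hyb, n_h) in enumerate(spec):
        pos = np.array([spacing * k, 0.4 * (k % 2), 0.0])
        i = b.add(el, pos, q, hyb=hyb)
        if idx:
            b.bond(idx[-1], i)
        b.hs(i, n_h)
        idx.append(i)
    return idx


def _ethanolamine() -> MoleculeRecord:
    b = _Builder()
    _chain(b, [("O", -0.40, "sp3", 1), ("C", 0.0, "sp3", 2),
               ("C", 0.0, "sp3", 2), ("N", -0.50, "sp3", 2)])
    return b.build("ethanolamine", "NCCO")


def _phenol() -> MoleculeRecord:
    b = _Builder()
    ring = _aromatic_ring(b, ["C"] * 6, [-0.05] * 6)
    for c in ring[1:]:
        b.h(c, _radial(b._atoms[c][1], 1.09), _QH_POLAR)
    o = b.add("O", _radial(b._atoms[ring[0]][1], 1.36), -0.40)
    b.bond(ring[0], o)
    b.h(o, b._atoms[o][1] + np.array([0.6, 0.77, 0]))
    return b.build("phenol", "Oc1ccccc1")


def _aminopentanone() -> MoleculeRecord:
    b = _Builder()
    chain = _chain(b, [("C", -0.10, "sp3", 3), ("C", 0.30, "sp2", 0),
                       ("C", 0.0, "sp3", 2), ("C", 0.0, "sp3", 2),
                       ("C", 0.0, "sp3", 2), ("N", -0.50, "sp3", 2)])
    o = b.add("O", b._atoms[chain[1]][1] + np.array([0, 1.22, 0]), -0.35, hyb="sp2")
    b.bond(chain[1], o, 2.0)
    return b.build("5-amino-2-pentanone", "CC(=O)CCCN")


def _diaminopentanone() -> MoleculeRecord:
    b = _Builder()
    chain = _chain(b, [("N", -0.50, "sp3", 2), ("C", 0.0, "sp3", 2),
                       ("C", 0.0, "sp3", 2), ("C", 0.30, "sp2", 0),
                       ("C", 0.0, "sp3", 2), ("C", 0.0, "sp3", 2),
                       ("N", -0.50, "sp3", 2)])
    o = b.add("O", b._atoms[chain[3]][1] + np.array([0, 1.22, 0]), -0.35, hyb="sp2")
    b.bond(chain[3], o, 2.0)
    return b.build("1,5-diamino-3-pentanone", "NCCC(=O)CCN")


def _imidazole_core(b: _Builder) -> list[int]:
    # ring order: N1(H), C2, N3, C4, C5
    ring = _aromatic_ring(b, ["N", "C", "N", "C", "C"],
                          [-0.25, 0.10, -0.25, 0.05, 0.05], side=1.37)
    b.h(ring[0], _radial(b._atoms[ring[0]][1], 1.01))
    b.h(ring[1], _radial(b._atoms[ring[1]][1], 1.09))
    return ring


def _imidazole() -> MoleculeRecord:
    b = _Builder()
    ring = _imidazole_core(b)
    b.h(ring[3], _radial(b._atoms[ring[3]][1], 1.09))
    b.h(ring[4], _radial(b._atoms[ring[4]][1], 1.09))
    return b.build("imidazole", "c1cnc[nH]1")


def _ethylimidazole() -> MoleculeRecord:
    b = _Builder()
    ring = _imidazole_core(b)
    b.h(ring[4], _radial(b._atoms[ring[4]][1], 1.09))
    ch2 = b.add("C", _radial(b._atoms[ring[3]][1], 1.50), -0.05)
    b.bond(ring[3], ch2)
    b.hs(ch2, 2)
    ch3 = b.add("C", _radial(b._atoms[ring[3]][1], 3.03), -0.10)
    b.bond(ch2, ch3)
    b.hs(ch3, 3)
    return b.build("4-ethylimidazole", "CCc1c[nH]cn1")


def _ethylmethylimidazole() -> MoleculeRecord:
    b = _Builder()
    ring = _imidazole_core(b)
    ch2 = b.add("C", _radial(b._atoms[ring[3]][1], 1.50), -0.05)
    b.bond(ring[3], ch2)
    b.hs(ch2, 2)
    ch3 = b.add("C", _radial(b._atoms[ring[3]][1], 3.03), -0.10)
    b.bond(ch2, ch3)
    b.hs(ch3, 3)
    me = b.add("C", _radial(b._atoms[ring[4]][1], 1.50), -0.10)
    b.bond(ring[4], me)
    b.hs(me, 3)
    return b.build("4-ethyl-5-methylimidazole", "CCc1c(C)[nH]cn1")


def _benzenedithiol() -> MoleculeRecord:
    b = _Builder()
    ring = _aromatic_ring(b, ["C"] * 6, [-0.05] * 6)
    for c in ring[2:]:
        b.h(c, _radial(b._atoms[c][1], 1.09), _QH_POLAR)
    for c in ring[:2]:
        s = b.add("S", _radial(b._atoms[c][1], 1.78), 0.0)
        b.bond(c, s)
        b.h(s, b._atoms[s][1] + np.array([0.5, 0.5, 1.0]))
    return b.build("benzene-1,2-dithiol", "Sc1ccccc1S")


def _piperidine() -> MoleculeRecord:
    b = _Builder()
    pts = _polygon(6, 1.53)
    ring = [b.add("N" if k == 0 else "C", pt, -0.50 if k == 0 else -0.05,
                  hyb="sp3", ring=True) for k, pt in enumerate(pts)]
    for k in range(6):
        b.bond(ring[k], ring[(k + 1) % 6])
    b.h(ring[0], _radial(b._atoms[ring[0]][1], 1.01))
    for c in ring[1:]:
        b.hs(c, 2)
    return b.build("piperidine", "C1CCNCC1")


def _methylphenylsulfone() -> MoleculeRecord:
    b = _Builder()
    ring = _aromatic_ring(b, ["C"] * 6, [-0.05] * 6)
    for c in ring[1:]:
        b.h(c, _radial(b._atoms[c][1], 1.09), _QH_POLAR)
    s = b.add("S", _radial(b._atoms[ring[0]][1], 1.77), 1.0)
    b.bond(ring[0], s)
    for dz in (1.43, -1.43):
        o = b.add("O", b._atoms[s][1] + np.array([0, 0, dz]), -0.45, hyb="sp2")
        b.bond(s, o, 2.0)
    me = b.add("C", b._atoms[s][1] + np.array([1.25, 1.25, 0]), -0.10)
    b.bond(s, me)
    b.hs(me, 3)
    return b.build("methyl-phenyl-sulfone", "CS(=O)(=O)c1ccccc1")


def _sulfonylpiperazine() -> MoleculeRecord:
    b = _Builder()
    pts = _polygon(6, 1.50)
    elements = ["N", "C", "C", "N", "C", "C"]
    ring = [b.add(el, pt, 0.05 if el == "C" else -0.40, hyb="sp3", ring=True)
            for el, pt in zip(elements, pts)]
    for k in range(6):
        b.bond(ring[k], ring[(k + 1) % 6])
    for c in (ring[1], ring[2], ring[4], ring[5]):
        b.hs(c, 2)
    b.h(ring[3], _radial(b._atoms[ring[3]][1], 1.01))
    s = b.add("S", _radial(b._atoms[ring[0]][1], 1.68), 1.0)
    b.bond(ring[0], s)
    for dz in (1.43, -1.43):
        o = b.add("O", b._atoms[s][1] + np.array([0, 0, dz]), -0.45, hyb="sp2")
        b.bond(s, o, 2.0)
    me = b.add("C", _radial(b._atoms[s][1], 1.77), -0.10)
    b.bond(s, me)
    b.hs(me, 3)
    return b.build("1-(methylsulfonyl)piperazine", "CS(=O)(=O)N1CCNCC1")


#: Hand-derived expected values for all six descriptors, per fixture, in
#: MODEL1_DESCRIPTORS order.  Derivations: bond paths counted on the drawn
#: structures, charge sums from the assigned charges, centre-of-mass counts
#: from the symmetric geometries (see module docstring).
EXPECTED_DESCRIPTORS: dict[str, tuple] = {
    "methane": (4, 0.0, 0, 0, 0, 0),
    "ethane": (6, 0.0, 0, 0, 0, 0),
    "benzene": (6, 0.0, 0, 0, 0, 0),
    "pyridine": (5, 0.0, 0, 0, 0, 0),
    "thioanisole": (0, -0.30, 0, 0, 0, 0),
    "triethylamine": (0, 0.0, 0, 1, 0, 0),
    "trimethylamine": (0, 0.0, 0, 0, 0, 0),
    "N,N-diethylmethylamine": (0, 0.0, 0, 0, 0, 0),
    "ethanolamine": (0, 0.0, 0, 0, 0, 2),
    "phenol": (0, 0.0, 0, 0, 0, 0),
    "5-amino-2-pentanone": (0, 0.0, 0, 0, 1, 1),
    "1,5-diamino-3-pentanone": (0, 0.0, 0, 0, 2, 2),
    "imidazole": (0, 0.0, 0, 0, 0, 0),
    "4-ethylimidazole": (0, 0.0, 1, 0, 0, 0),
    "4-ethyl-5-methylimidazole": (0, 0.0, 0, 0, 0, 0),
    "benzene-1,2-dithiol": (0, -0.30, 0, 0, 0, 0),
    "piperidine": (0, 0.0, 0, 0, 0, 1),
    "methyl-phenyl-sulfone": (0, -0.30, 0, 0, 0, 0),
    "1-(methylsulfonyl)piperazine": (0, 0.20, 0, 0, 2, 1),
}


def make_toy_molecules() -> list[MoleculeRecord]:
    """The full fixture panel (deterministic geometry and charges)."""
    return [
        _methane(), _ethane(), _benzene(), _pyridine(), _thioanisole(),
        _amine("triethylamine", "CCN(CC)CC", [2, 2, 2]),
        _amine("trimethylamine", "CN(C)C", [1, 1, 1]),
        _amine("N,N-diethylmethylamine", "CCN(C)CC", [2, 2, 1]),
        _ethanolamine(), _phenol(), _aminopentanone(), _diaminopentanone(),
        _imidazole(), _ethylimidazole(), _ethylmethylimidazole(),
        _benzenedithiol(), _piperidine(), _methylphenylsulfone(),
        _sulfonylpiperazine(),
    ]


def expected_descriptor_table() -> pd.DataFrame:
    """The fixture annotations as a table aligned with the engine output."""
    return pd.DataFrame.from_dict(
        EXPECTED_DESCRIPTORS, orient="index", columns=list(MODEL1_DESCRIPTORS)
    ).rename_axis("mol_id")


def export_fixtures(directory) -> tuple[Path, Path]:
    """Write the fixture panel as an SDF plus a JSON annotation file."""
    from rdkit import Chem
    from rdkit.Chem import rdchem

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sdf_path = directory / "toy_molecules.sdf"
    order_map = {1.0: rdchem.BondType.SINGLE, 2.0: rdchem.BondType.DOUBLE,
                 1.5: rdchem.BondType.AROMATIC}
    with open(sdf_path, "w") as fh:
        for rec in make_toy_molecules():
            rw = Chem.RWMol()
            conf = Chem.Conformer(rec.n_atoms)
            for a in rec.atoms:
                atom = Chem.Atom(a.element)
                atom.SetIsAromatic(a.hybridization == "aromatic")
                atom.SetNoImplicit(True)
                rw.AddAtom(atom)
                conf.SetAtomPosition(a.index, tuple(a.coords))
            for i, j, order in rec.bonds:
                bond_idx = rw.AddBond(i, j, order_map[order]) - 1
                rw.GetBondWithIdx(bond_idx).SetIsAromatic(order == 1.5)
            mol = rw.GetMol()
            mol.AddConformer(conf)
            mol.SetProp("_Name", rec.mol_id)
            block = Chem.MolToMolBlock(mol, kekulize=False)
            charges = " ".join(f"{a.partial_charge:.4f}" for a in rec.atoms)
            fh.write(block)
            fh.write(f">  <PARTIAL_CHARGES>\n{charges}\n\n$$$$\n")
    json_path = directory / "toy_annotations.json"
    json_path.write_text(json.dumps(
        {k: dict(zip(MODEL1_DESCRIPTORS, v)) for k, v in EXPECTED_DESCRIPTORS.items()},
        indent=2))
    return sdf_path, json_path


# --------------------------------------------------------------------------
# planted-signal feature matrices


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted-signal generator.

    Defaults emulate the modelled dataset's statistical shape: a few
    hundred molecules, a few dozen candidate descriptors, a six-descriptor
    true model, activity spanning pKi 4.5-9.3 with ~0.3 pKi-unit noise.
    """

    n_molecules: int = 300
    n_descriptors: int = 40
    true_subset_size: int = 6
    beta: dict | None = None       # named coefficients; default drawn per seed
    noise_sd: float = 0.3          # pKi units, pre-rescaling
    y_range: tuple[float, float] = (4.5, 9.3)
    seed: int = 0
    n_near_constant: int = 2
    n_collinear_pairs: int = 2

    def __post_init__(self) -> None:
        if self.true_subset_size > self.n_descriptors:
            raise ValueError("true_subset_size exceeds n_descriptors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_feature_matrix(spec: SyntheticSpec = SyntheticSpec()
                        ) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Feature matrix with a planted sparse linear signal.

    Columns are count-like integers (small-Poisson mixtures) except one
    charge-like real column, which is always part of the true subset
    (mirroring the published model's single charge-sum descriptor).
    Decoys include near-constant columns and highly correlated pairs; both
    kinds are planted among decoys only, so objective feature selection is
    exercised without making the recovery problem ill-posed.

    The truth record stores the planted subset and the *effective*
    (post-rescaling) coefficients, intercept and noise so that recovery
    checks compare on the reported scale.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_molecules, spec.n_descriptors, spec.true_subset_size
    names = [f"x{i:03d}" for i in range(p)]
    cols = {}
    lam = rng.uniform(1.0, 3.0, size=p)
    for i, name in enumerate(names):
        cols[name] = rng.poisson(lam[i], size=n).astype(float)

    order = rng.permutation(p)
    true_idx = sorted(order[:k])
    decoy_idx = [i for i in order[k:]]
    # the charge-like column joins the true subset
    charge_col = names[true_idx[0]] if k else names[decoy_idx[0]]
    cols[charge_col] = rng.normal(-0.3, 0.15, size=n)

    for i in decoy_idx[:spec.n_near_constant]:
        cols[names[i]] = rng.binomial(1, 0.02, size=n).astype(float)
    remaining = decoy_idx[spec.n_near_constant:]
    for j in range(min(spec.n_collinear_pairs, len(remaining) // 2)):
        a, bcol = remaining[2 * j], remaining[2 * j + 1]
        cols[names[bcol]] = cols[names[a]] + rng.binomial(1, 0.05, size=n)

    X = pd.DataFrame(cols, columns=names,
                     index=pd.Index([f"m{i:04d}" for i in range(n)], name="mol_id"))

    true_names = [names[i] for i in true_idx]
    if spec.beta is not None:
        beta = {nm: float(spec.beta[nm]) for nm in true_names}
    else:
        mags = rng.uniform(0.3, 0.8, size=k)
        signs = rng.choice([-1.0, 1.0], size=k)
        beta = dict(zip(true_names, mags * signs))
    if beta.get(charge_col) is not None:
        # charge-like values are ~10x smaller than counts; scale the
        # coefficient so the term carries comparable signal
        beta[charge_col] *= 4.0

    raw = sum(beta[nm] * X[nm].to_numpy() for nm in true_names) \
        + rng.normal(0, spec.noise_sd, size=n)
    lo, hi = spec.y_range
    span = raw.max() - raw.min()
    scale = (hi - lo) / span if span > 0 else 1.0
    shift = lo - scale * raw.min()
    y = pd.Series(scale * raw + shift, index=X.index, name="pki")

    truth = {
        "subset": tuple(true_names),
        "beta": {nm: scale * b for nm, b in beta.items()},
        "intercept": shift,
        "noise_sd": scale * spec.noise_sd,
        "scale": scale,
        "charge_column": charge_col,
        "near_constant": [names[i] for i in decoy_idx[:spec.n_near_constant]],
        "collinear_pairs": [
            (names[remaining[2 * j]], names[remaining[2 * j + 1]])
            for j in range(min(spec.n_collinear_pairs, len(remaining) // 2))
        ],
    }
    return X, y, truth
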