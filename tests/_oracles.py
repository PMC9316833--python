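"""Independent brute-force oracles for the descriptor kernels.

Deliberately naive: Floyd-Warshall over an explicit adjacency list, python
loops and set logic, and a from-scratch re-derivation of the atom classes.
Nothing here imports the descriptor engine, so agreement is meaningful.
"""

import math

INF = float("inf")


def floyd_warshall(mol):
    n = mol.n_atoms
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for i, j, _ in mol.bonds:
        d[i][j] = d[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def _com(mol):
    total = sum(a.mass for a in mol.atoms)
    return [sum(a.mass * a.coords[c] for a in mol.atoms) / total for c in range(3)]


def _lipophilic(mol, a):
    if a.element in ("Cl", "Br", "I", "S"):
        return True
    if a.element != "C":
        return False
    heavy = [mol.atoms[j] for j in mol.neighbors(a.index)
             if mol.atoms[j].element != "H"]
    return all(nb.element == "C" for nb in heavy)


def oracle_descriptors(mol):
    d = floyd_warshall(mol)
    com = _com(mol)

    com_h = 0
    for a in mol.atoms:
        if a.element == "H" and abs(a.partial_charge) <= 0.200:
            if math.dist(a.coords, com) <= 3.0:
                com_h += 1

    sulfurs = [a.index for a in mol.atoms if a.element == "S"]
    ring_c_sum = 0.0
    for a in mol.atoms:
        if a.element == "C" and a.in_ring:
            if any(1 <= d[a.index][s] <= 4 for s in sulfurs):
                ring_c_sum += a.partial_charge

    lipo = [a.index for a in mol.atoms if _lipophilic(mol, a)]
    flipo = 0
    for a in mol.atoms:
        if a.element == "N" and a.in_ring:
            dists = [d[a.index][t] for t in lipo if t != a.index]
            if dists and min(dists) == 3:
                flipo += 1

    krfpc = 0
    for a in mol.atoms:
        if a.element != "N":
            continue
        heavy = [j for j in mol.neighbors(a.index) if mol.atoms[j].element != "H"]
        if len(heavy) != 3:
            continue
        n_ethyl = 0
        for c in heavy:
            ca = mol.atoms[c]
            others = [j for j in mol.neighbors(c)
                      if mol.atoms[j].element != "H" and j != a.index]
            if ca.element == "C" and ca.n_attached_H == 2 and len(others) == 1:
                tip = mol.atoms[others[0]]
                tip_heavy = [j for j in mol.neighbors(tip.index)
                             if mol.atoms[j].element != "H"]
                if tip.element == "C" and tip.n_attached_H == 3 and len(tip_heavy) == 1:
                    n_ethyl += 1
        if n_ethyl == 3:
            krfpc += 1

    sp2o = [a.index for a in mol.atoms
            if a.element == "O" and a.hybridization == "sp2"]
    sp3n_count = 0
    for a in mol.atoms:
        if a.element == "N" and a.hybridization == "sp3":
            if any(1 <= d[a.index][o] <= 8 for o in sp2o):
                sp3n_count += 1

    fdon = 0
    for a in mol.atoms:
        if a.element in ("N", "O") and a.n_attached_H >= 1:
            if any(mol.atoms[j].element == "C"
                   and mol.atoms[j].hybridization == "sp3"
                   for j in mol.neighbors(a.index)):
                fdon += 1

    return {
        "com_Hhyd_3A": com_h,
        "ringC_S_4Bc": ring_c_sum,
        "flipo&S_ringN3B": flipo,
        "KRFPC620": krfpc,
        "sp3N_sp2O_8B": sp3n_count,
        "fsp3Cdon1B": fdon,
    }


def loo_q2_bruteforce(X, y):
    """Leave-one-out PRESS by n explicit refits (numpy lstsq only)."""
    import numpy as np
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xd = np.column_stack([np.ones(n - 1), X[mask]])
        beta, *_ = np.linalg.lstsq(Xd, y[mask], rcond=None)
        pred = np.concatenate([[1.0], X[i]]) @ beta
        press += (y[i] - pred) ** 2
    tss = ((y - y.mean()) ** 2).sum()
    return 1 - press / tss
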