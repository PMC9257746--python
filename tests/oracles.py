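"""Independent reference implementations used only as test oracles.

Each routine here recomputes a quantity by a different route than the
package (brute-force enumeration, closed forms, direct formula sums) so
the two can be compared without sharing code paths.
"""

from fractions import Fraction
from math import comb

import numpy as np

#: Standard atomic weights (IUPAC conventional values) for formula-mass sums.
ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.067, "Cl": 35.453, "Br": 79.904, "I": 126.904,
}


def formula_mass(smiles: str) -> float:
    """Molecular weight as a plain sum of atomic weights over all atoms."""
    from rdkit import Chem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    return sum(ATOMIC_WEIGHTS[a.GetSymbol()] for a in mol.GetAtoms())


def lipinski_counts(smiles: str) -> tuple[int, int]:
    """(donors, acceptors) by direct atom enumeration: donors are H atoms
    bound to N or O; acceptors are N and O atoms."""
    from rdkit import Chem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    hbd = hba = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("N", "O"):
            hba += 1
            hbd += sum(1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "H")
    return hbd, hba


def fisher_enumeration(tp: int, fp: int, fn: int, tn: int) -> Fraction:
    """One-sided Fisher probability by exhaustive hypergeometric enumeration.

    Sums P(a) over all tables with the observed margins whose top-left
    count a is at least the observed tp.
    """
    n = tp + fp + fn + tn
    row1 = tp + fp
    col1 = tp + fn
    total = Fraction(0)
    a_min = max(0, row1 + col1 - n)
    a_max = min(row1, col1)
    for a in range(a_min, a_max + 1):
        if a >= tp:
            total += Fraction(comb(col1, a) * comb(n - col1, row1 - a), comb(n, row1))
    return total


def svd_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """SVD-based PLS1 in the scaled space: the weight for each latent
    variable is the dominant left singular vector of the residual
    cross-covariance matrix E'f (sign-fixed toward positive covariance).

    Returns (regression_vector, scores) on the autoscaled X / centred y
    scale, computed independently of the package implementation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    E = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    f = y - y.mean()
    p = E.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((X.shape[0], n_components))
    for a in range(n_components):
        cov = (E.T @ f).reshape(-1, 1)
        u, _, _ = np.linalg.svd(cov, full_matrices=False)
        w = u[:, 0]
        if float(w @ cov.ravel()) < 0:
            w = -w
        t = E @ w
        tt = float(t @ t)
        P[:, a] = (E.T @ t) / tt
        q[a] = float(f @ t) / tt
        W[:, a], T[:, a] = w, t
        E = E - np.outer(t, P[:, a])
        f = f - q[a] * t
    b = W @ np.linalg.solve(P.T @ W, q)
    return b, T


def ols_fitted(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares fitted values of y on autoscaled X with intercept."""
    X = np.asarray(X, float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    A = np.column_stack([np.ones(len(y)), Xs])
    beta, *_ = np.linalg.lstsq(A, np.asarray(y, float), rcond=None)
    return A @ beta
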