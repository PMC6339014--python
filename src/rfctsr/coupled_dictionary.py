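"""Sparse representation and coupled dictionary learning.

A patch ``x`` is modelled as a sparse combination of dictionary atoms,
``x = D a`` with few nonzeros in ``a``, found by minimizing

    F(a) = ||x - D a||_2^2 + lambda ||a||_1

with a monotone proximal-gradient (ISTA) scheme. Coupled learning fits a
low-dose dictionary ``D_L`` and a high-dose dictionary ``D_H`` that share
one sparse code matrix ``E`` by alternating minimization of

    (1/D_L)||X_L - D_L E||_F^2 + (1/D_H)||X_H - D_H E||_F^2 + lambda ||E||_1

in the weighted joint signal space (row-stacked, with the dimension
weights folded in as row scalings). The code step is ISTA (monotone) and
the dictionary step is an exact least-squares minimizer (MOD-style), so
the objective is nonincreasing across alternations; column normalization
is applied once at the end with code rows rescaled to keep the joint
product unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = ["Dictionary", "SparseCode", "DegradationOperator", "sparse_code",
           "sparse_code_batch", "learn_coupled_dicts", "reconstruct_from_code",
           "backproject", "CoupledDictResult"]

_NNZ_TOL = 1e-12


@dataclass
class Dictionary:
    """Atoms as columns of a (signal_dim, n_atoms) matrix."""

    atoms: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix")
        if self.normalized:
            norms = np.linalg.norm(self.atoms, axis=0)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normalized dictionary must have unit-norm columns")

    @property
    def signal_dim(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    def normalize(self) -> "Dictionary":
        """Unit-normalize columns; an all-zero atom (which carries no
        signal) is replaced by a standard basis vector so the unit-norm
        invariant holds."""
        atoms = self.atoms.copy()
        norms = np.linalg.norm(atoms, axis=0)
        for j in np.flatnonzero(norms == 0):
            atoms[:, j] = 0.0
            atoms[j % atoms.shape[0], j] = 1.0
            norms[j] = 1.0
        return Dictionary(atoms / norms, normalized=True)


@dataclass
class SparseCode:
    """Coefficients of one signal (vector) or many (matrix, columns=signals)."""

    alpha: np.ndarray
    lam: float
    objective: list[float] = field(default_factory=list)

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(np.abs(self.alpha) > _NNZ_TOL))


@dataclass(frozen=True)
class DegradationOperator:
    """Degradation H relating an HD patch to the observed signal: identity,
    or blur followed by down-sampling by an integer factor."""

    kind: str = "identity"
    blur_kernel: np.ndarray | None = None
    factor: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "blur_downsample"):
            raise ValueError(f"unknown degradation kind: {self.kind}")
        if self.factor < 1:
            raise ValueError("factor must be a positive integer")

    def as_matrix(self, signal_dim: int) -> np.ndarray | None:
        """Dense matrix acting on flattened square patches; None = identity."""
        if self.kind == "identity":
            return None
        from scipy.ndimage import correlate

        p = int(round(np.sqrt(signal_dim)))
        if p * p != signal_dim:
            raise ValueError(f"signal dim {signal_dim} is not a square patch")
        kernel = (np.ones((1, 1)) if self.blur_kernel is None
                  else np.asarray(self.blur_kernel, dtype=np.float64))
        cols = []
        for j in range(signal_dim):
            e = np.zeros(signal_dim)
            e[j] = 1.0
            img = correlate(e.reshape(p, p), kernel, mode="nearest")
            cols.append(img[::self.factor, ::self.factor].ravel())
        return np.array(cols).T


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _ista(D: np.ndarray, Y: np.ndarray, lam: float, max_iter: int, tol: float,
          A0: np.ndarray | None = None) -> tuple[np.ndarray, list[float]]:
    """Monotone proximal gradient for min ||Y - D A||_F^2 + lam ||A||_1.

    Y has signals as columns. Step size 1/L with L = 2 sigma_max(D)^2.
    Returns the code matrix and the per-iteration objective trace.
    """
    smax = np.linalg.norm(D, 2)
    L = 2.0 * smax ** 2 if smax > 0 else 1.0
    step = 1.0 / L
    A = np.zeros((D.shape[1], Y.shape[1])) if A0 is None else A0.copy()

    def obj(A):
        R = Y - D @ A
        return float(np.sum(R ** 2) + lam * np.sum(np.abs(A)))

    trace = [obj(A)]
    for _ in range(max_iter):
        grad = 2.0 * (D.T @ (D @ A - Y))
        A = _soft(A - step * grad, lam * step)
        trace.append(obj(A))
        if trace[-2] - trace[-1] < tol:
            break
    return A, trace


def sparse_code(x: np.ndarray, D: Dictionary, lam: float,
                max_iter: int = 200, tol: float = 1e-10) -> SparseCode:
    """Sparse-code one signal against a normalized dictionary."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input signal")
    if x.shape[0] != D.signal_dim:
        raise ValueError(f"signal dim {x.shape[0]} != dictionary dim {D.signal_dim}")
    A, trace = _ista(D.atoms, x[:, None], lam, max_iter, tol)
    return SparseCode(alpha=A[:, 0], lam=lam, objective=trace)


def sparse_code_batch(X: np.ndarray, D: Dictionary, lam: float,
                      max_iter: int = 200, tol: float = 1e-10,
                      A0: np.ndarray | None = None) -> SparseCode:
    """Sparse-code many signals (columns of X) simultaneously."""
    A, trace = _ista(D.atoms, np.asarray(X, dtype=np.float64), lam,
                     max_iter, tol, A0=A0)
    return SparseCode(alpha=A, lam=lam, objective=trace)


def reconstruct_from_code(D: Dictionary, alpha: SparseCode) -> np.ndarray:
    """Synthesize D @ alpha."""
    return D.atoms @ alpha.alpha


def backproject(y: np.ndarray, D: Dictionary, H: DegradationOperator,
                lam: float, max_iter: int = 200, tol: float = 1e-10) -> SparseCode:
    """Sparse-code an observed signal through a degradation operator,
    minimizing ||y - H D a||_2^2 + lam ||a||_1.

    With ``H = identity`` this is exactly :func:`sparse_code` (same code
    path, bit-for-bit under the same iteration budget).
    """
    y = np.asarray(y, dtype=np.float64)
    Hm = H.as_matrix(D.signal_dim)
    eff = D.atoms if Hm is None else Hm @ D.atoms
    if y.shape[0] != eff.shape[0]:
        raise ValueError(f"observed dim {y.shape[0]} != H(D a) dim {eff.shape[0]}")
    A, trace = _ista(eff, y[:, None], lam, max_iter, tol)
    return SparseCode(alpha=A[:, 0], lam=lam, objective=trace)


class CoupledDictResult(NamedTuple):
    D_L: Dictionary
    D_H: Dictionary
    E: SparseCode
    objective: list[float]


def learn_coupled_dicts(X_L: np.ndarray, X_H: np.ndarray, B: int, lam: float,
                        n_iter: int, seed: int, code_iter: int = 30,
                        tol: float = 1e-10) -> CoupledDictResult:
    """Alternating minimization for the coupled dictionary objective.

    X_L, X_H are column-paired sample matrices (signals as columns).
    Atoms are initialized from a seeded random subset of training columns.
    ``objective`` is the trace of the joint objective recorded after every
    code and dictionary step; it is nonincreasing by construction.
    """
    X_L = np.asarray(X_L, dtype=np.float64)
    X_H = np.asarray(X_H, dtype=np.float64)
    if X_L.shape[1] != X_H.shape[1]:
        raise ValueError("X_L and X_H must be column-paired")
    if B < 2:
        raise ValueError("need at least 2 atoms")
    d_l, n = X_L.shape
    d_h = X_H.shape[0]

    # joint signal space with the 1/D_L, 1/D_H weights folded into the rows
    Z = np.vstack([X_L / np.sqrt(d_l), X_H / np.sqrt(d_h)])

    rng = np.random.default_rng(seed)
    Dj = _init_atoms(Z, B, rng)

    E = np.zeros((B, n))
    if n_iter == 0:
        return _split_joint(Dj, E, d_l, d_h, lam, [])

    def obj(Dm, Em):
        return float(np.sum((Z - Dm @ Em) ** 2) + lam * np.sum(np.abs(Em)))

    trace = [obj(Dj, E)]
    for _ in range(n_iter):
        E, _ = _ista(Dj, Z, lam, code_iter, tol, A0=E)
        trace.append(obj(Dj, E))
        # exact least-squares dictionary update (MOD): D = Z E^T (E E^T)^+
        G = E @ E.T
        Dj_new = np.linalg.lstsq(G, E @ Z.T, rcond=None)[0].T
        # keep atoms that no signal uses unchanged rather than zeroed
        used = np.abs(E).sum(axis=1) > _NNZ_TOL
        Dj = np.where(used[None, :], Dj_new, Dj)
        trace.append(obj(Dj, E))
    return _split_joint(Dj, E, d_l, d_h, lam, trace)


def _init_atoms(Z: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded diverse initialization from training columns.

    The first atom is a random column; each further atom is the column
    least correlated (in absolute value) with the atoms chosen so far.
    This avoids seeding the alternation with near-duplicate atoms, which
    a plain random subset frequently does on structured patch data.
    """
    n = Z.shape[1]
    if n < B:
        import warnings
        warnings.warn(f"fewer samples ({n}) than atoms ({B}); "
                      "initializing with replacement")
    norms = np.linalg.norm(Z, axis=0)
    Zn = Z / np.where(norms > 0, norms, 1.0)
    chosen = [int(rng.integers(n))]
    max_corr = np.abs(Zn.T @ Zn[:, chosen[0]])
    max_corr[norms == 0] = np.inf  # never pick empty columns if avoidable
    while len(chosen) < B:
        max_corr[chosen] = np.inf
        j = int(np.argmin(max_corr)) if np.isfinite(max_corr).any() \
            else int(rng.integers(n))
        chosen.append(j)
        if np.isfinite(max_corr[j]):
            max_corr = np.maximum(max_corr, np.abs(Zn.T @ Zn[:, j]))
    return Zn[:, chosen].copy()


def _split_joint(Dj, E, d_l, d_h, lam, trace) -> CoupledDictResult:
    # normalize joint atoms, compensating the code rows so Dj @ E is unchanged
    norms = np.linalg.norm(Dj, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    Dj_n = Dj / safe
    E_n = E * safe[:, None]
    D_L = Dictionary(Dj_n[:d_l] * np.sqrt(d_l)).normalize()
    D_H = Dictionary(Dj_n[d_l:] * np.sqrt(d_h)).normalize()
    return CoupledDictResult(D_L=D_L, D_H=D_H,
                             E=SparseCode(alpha=E_n, lam=lam, objective=trace),
                             objective=trace)
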