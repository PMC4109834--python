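"""Lasso sparse coding, incoherent per-class dictionary learning, residuals.

A sample ``x`` (a standardized 100-dim layout descriptor) is represented
as a sparse combination of dictionary atoms by solving the lasso

    min_a  1/2 ||x - D a||_2^2 + lambda ||a||_1,

with every atom (column of ``D``) constrained to the unit Euclidean ball.
One dictionary is learned per class by alternating minimization over codes
and atoms; dictionaries of different classes are additionally pushed to be
mutually incoherent through the cross-Gram penalty

    eta * sum_{j1 != j2} || D^(j1)^T D^(j2) ||_F^2,

so that a sample is reconstructed well by its own class's dictionary and
poorly by the others.  Classification later relies on the *per-feature*
squared reconstruction error

    R[i, j, k] = (x_i[k] - (D^(j) a_hat_{j,i})[k])^2,

where the code ``a_hat_{j,i}`` is computed once per (sample, class) from
the full vector; summing R over k recovers the usual squared residual.

The lasso solver is cyclic coordinate descent with a warm start, which
makes the alternating dictionary objective non-increasing by construction;
solutions are validated against the lasso KKT conditions in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_LAMBDA = 0.10
DEFAULT_ETA = 0.05
DEFAULT_ITERS = 30
REL_TOL = 1e-5


@dataclass
class Dictionary:
    """Per-class dictionary: ``K x m`` atom matrix, unit-ball columns."""

    atoms: np.ndarray
    label: str | None = None
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a K x m matrix")

    @property
    def n_features(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]


@dataclass
class SparseCode:
    """Lasso solution: coefficients and the achieved objective value."""

    coef: np.ndarray
    objective: float


@dataclass
class ResidualProfile:
    """``N x C x K`` per-sample, per-class, per-feature squared residuals."""

    R: np.ndarray
    classes: list[str]

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=np.float64)
        if self.R.ndim != 3:
            raise ValueError("R must be N x C x K")

    def total(self) -> np.ndarray:
        """``N x C`` full squared residuals (sum over features)."""
        return self.R.sum(axis=2)


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def lasso_matrix(
    X: np.ndarray,
    D: np.ndarray,
    lam: float,
    init: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> np.ndarray:
    """Coordinate-descent lasso for all columns of ``X`` at once.

    Returns the ``m x n`` coefficient matrix ``A`` minimizing, per column,
    ``1/2 ||x - D a||^2 + lam ||a||_1``.  Cyclic updates; each coordinate
    update never increases the objective, so warm starts (``init``) keep
    outer alternating schemes monotone.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    D = np.asarray(D, dtype=np.float64)
    if D.shape[0] != X.shape[0]:
        raise ValueError(f"dimension mismatch: D is {D.shape}, X is {X.shape}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    K, n = X.shape
    m = D.shape[1]
    G = D.T @ D
    C = D.T @ X
    A = np.zeros((m, n)) if init is None else np.array(init, dtype=np.float64)
    diag = np.diag(G)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(m):
            if diag[j] <= 1e-12:
                continue
            rho = C[j] - G[j] @ A + diag[j] * A[j]
            new = _soft(rho, lam) / diag[j]
            delta = max(delta, float(np.max(np.abs(new - A[j]), initial=0.0)))
            A[j] = new
        if delta < tol:
            break
    return A


def lasso_objective(X: np.ndarray, D: np.ndarray, A: np.ndarray, lam: float) -> float:
    """Summed lasso objective over all columns."""
    R = X - D @ A
    return float(0.5 * np.sum(R * R) + lam * np.sum(np.abs(A)))


def lasso(x: np.ndarray, D: Dictionary | np.ndarray, lam: float) -> SparseCode:
    """Solve the lasso for a single sample against a dictionary."""
    atoms = D.atoms if isinstance(D, Dictionary) else np.asarray(D, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64).ravel()
    A = lasso_matrix(x[:, None], atoms, lam)
    coef = A[:, 0]
    return SparseCode(coef=coef, objective=lasso_objective(x[:, None], atoms, A, lam))


def kkt_violation(x: np.ndarray, D: np.ndarray, coef: np.ndarray, lam: float) -> float:
    """Largest violation of the lasso stationarity conditions.

    At an optimum, ``d_j^T (x - D a)`` equals ``lam * sign(a_j)`` for
    active atoms and lies in ``[-lam, lam]`` for inactive ones.
    """
    grad = D.T @ (np.asarray(x, dtype=np.float64).ravel() - D @ coef)
    active = coef != 0
    v_inactive = float(np.max(np.abs(grad[~active]) - lam, initial=0.0))
    v_active = float(np.max(np.abs(grad[active] - lam * np.sign(coef[active])), initial=0.0))
    return max(v_inactive, v_active, 0.0)


def _project_ball(D: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(D, axis=0)
    scale = np.maximum(norms, 1.0)
    return D / scale


def _init_atoms(X: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[1]
    idx = rng.choice(n, size=m, replace=m > n)
    return _project_ball(X[:, idx].copy())


def _update_atoms(
    D: np.ndarray,
    S: np.ndarray,
    B: np.ndarray,
    eta: float = 0.0,
    P: np.ndarray | None = None,
) -> np.ndarray:
    """Block coordinate descent over atoms, then unit-ball projection.

    With ``eta == 0`` this is the classic surrogate update
    ``d_j <- (b_j - D s_j + S_jj d_j) / S_jj``; with ``eta > 0`` each atom
    instead solves ``(S_jj I + 4 eta P) d = b_j - D s_j + S_jj d_j`` where
    ``P`` is the sum of the other classes' ``D D^T`` (the exact minimizer
    of the incoherence-penalized quadratic in that atom).
    """
    D = D.copy()
    m = D.shape[1]
    if eta > 0 and P is not None:
        evals, evecs = np.linalg.eigh(P)
    for j in range(m):
        sjj = S[j, j]
        if sjj <= 1e-12:
            continue
        r = B[:, j] - D @ S[:, j] + sjj * D[:, j]
        if eta > 0 and P is not None:
            d = evecs @ ((evecs.T @ r) / (sjj + 4.0 * eta * evals))
        else:
            d = r / sjj
        norm = np.linalg.norm(d)
        if norm > 1.0:
            d = d / norm
        D[:, j] = d
    return D


def learn_dictionary(
    X: np.ndarray,
    m: int,
    lam: float = DEFAULT_LAMBDA,
    iters: int = DEFAULT_ITERS,
    seed: int = 0,
    label: str | None = None,
) -> Dictionary:
    """Learn a single dictionary by alternating minimization.

    Atoms are initialized from randomly selected samples (with replacement
    when ``m`` exceeds the sample count) and projected to the unit ball.
    Each outer iteration sparse-codes all samples (warm-started) and then
    updates atoms by block coordinate descent; the recorded objective
    ``(1/n) sum_i (1/2 ||x_i - D a_i||^2 + lam ||a_i||_1)`` is
    non-increasing.  Stops early when the relative improvement falls below
    ``1e-5``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.size == 0:
        raise ValueError("empty sample matrix")
    if m < 1 or iters < 1:
        raise ValueError("m and iters must be >= 1")
    n = X.shape[1]
    rng = np.random.default_rng(seed)
    D = _init_atoms(X, m, rng)
    A = None
    trace = []
    for _ in range(iters):
        A = lasso_matrix(X, D, lam, init=A)
        D = _update_atoms(D, A @ A.T, X @ A.T)
        obj = lasso_objective(X, D, A, lam) / n
        trace.append(obj)
        if len(trace) > 1 and trace[-2] - trace[-1] < REL_TOL * max(abs(trace[-2]), 1e-12):
            break
    return Dictionary(atoms=D, label=label, objective_trace=trace)


def class_seed(seed: int, index: int) -> int:
    """Per-class seed derived from a master seed (stable, below 2**31)."""
    return (seed + 1009 * index) % (2**31)


def learn_class_dictionaries(
    X_by_class: dict[str, np.ndarray],
    m: int,
    lam: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
    iters: int = DEFAULT_ITERS,
    seed: int = 0,
) -> dict[str, Dictionary]:
    """Learn one dictionary per class with a cross-class incoherence penalty.

    With ``eta == 0`` the classes decouple and the result is exactly the
    sequence of independent :func:`learn_dictionary` calls with seeds
    ``class_seed(seed, index)``.  With ``eta > 0`` classes are updated
    cyclically; each class's atom update exactly minimizes its penalized
    quadratic given the other classes' current dictionaries, followed by
    unit-ball projection.
    """
    labels = list(X_by_class.keys())
    mats = {}
    for lab in labels:
        Xc = np.atleast_2d(np.asarray(X_by_class[lab], dtype=np.float64))
        if Xc.size == 0 or Xc.shape[1] == 0:
            raise ValueError(f"class {lab!r} has no samples")
        mats[lab] = Xc
    if eta < 0:
        raise ValueError("eta must be >= 0")
    if eta == 0:
        return {
            lab: learn_dictionary(mats[lab], m, lam, iters, seed=class_seed(seed, i), label=lab)
            for i, lab in enumerate(labels)
        }
    if len(labels) < 2:
        raise ValueError("incoherence penalty needs at least 2 classes")
    dicts = {
        lab: _init_atoms(mats[lab], m, np.random.default_rng(class_seed(seed, i)))
        for i, lab in enumerate(labels)
    }
    codes: dict[str, np.ndarray | None] = {lab: None for lab in labels}
    traces: dict[str, list[float]] = {lab: [] for lab in labels}
    for _ in range(iters):
        for lab in labels:
            X = mats[lab]
            A = lasso_matrix(X, dicts[lab], lam, init=codes[lab])
            codes[lab] = A
            P = np.zeros((X.shape[0], X.shape[0]))
            for other in labels:
                if other != lab:
                    P += dicts[other] @ dicts[other].T
            dicts[lab] = _update_atoms(dicts[lab], A @ A.T, X @ A.T, eta=eta, P=P)
            traces[lab].append(lasso_objective(X, dicts[lab], A, lam) / X.shape[1])
    return {
        lab: Dictionary(atoms=dicts[lab], label=lab, objective_trace=traces[lab])
        for lab in labels
    }


def cross_gram_norm(dicts: dict[str, Dictionary]) -> float:
    """Sum of squared Frobenius cross-Gram norms over ordered class pairs."""
    labels = list(dicts.keys())
    total = 0.0
    for a in labels:
        for b in labels:
            if a != b:
                G = dicts[a].atoms.T @ dicts[b].atoms
                total += float(np.sum(G * G))
    return total


def residual_profile(
    X: np.ndarray,
    dicts: dict[str, Dictionary],
    lam: float = DEFAULT_LAMBDA,
) -> ResidualProfile:
    """Per-feature squared reconstruction errors of samples under each class.

    For sample ``i`` and class ``j``, the code is the lasso solution of
    ``x_i`` against ``D^(j)``; ``R[i, j, k]`` is the squared residual of
    feature ``k`` under that code.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    labels = list(dicts.keys())
    K, n = X.shape
    R = np.zeros((n, len(labels), K))
    for ci, lab in enumerate(labels):
        atoms = dicts[lab].atoms
        if atoms.shape[0] != K:
            raise ValueError(
                f"dimension mismatch: class {lab!r} dictionary has K={atoms.shape[0]}, samples have K={K}"
            )
        A = lasso_matrix(X, atoms, lam)
        E = X - atoms @ A
        R[:, ci, :] = (E**2).T
    return ResidualProfile(R=R, classes=labels)
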