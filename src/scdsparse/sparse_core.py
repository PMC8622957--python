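"""Sparse coding and dictionary learning.

The signal model is ``x ~= D @ alpha`` where ``D`` is an n x m matrix whose
unit-norm columns (atoms) form a — typically overcomplete, m > n — basis for
one class of signals, and ``alpha`` is sparse.  Two algorithms operate on it:

* :func:`omp_code` — error-constrained Orthogonal Matching Pursuit.  Greedily
  selects the atom most correlated with the current residual, re-solves the
  least-squares problem on the selected support, and stops once the residual
  energy fraction drops below ``epsilon`` (or the atom budget is exhausted).
* :func:`ksvd_train` — k-SVD dictionary learning.  Alternates OMP sparse
  coding of a training set with rank-1 SVD updates of each atom (and of the
  coefficients that use it), so the dictionary adapts to the training class.

All randomness is driven by explicit integer seeds; identical seeds give
bit-identical dictionaries and codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular

from .errors import (
    DimensionMismatchError,
    FormatError,
    InvalidArgumentError,
    RankDeficiencyError,
)

# double-precision noise-floor tolerances, shared across the package
ATOL_NORM = 1e-9      # unit-norm / energy bookkeeping
ATOL_ORTHO = 1e-8     # residual-vs-selected-atom orthogonality
ATOL_COEF = 1e-6      # coefficient comparisons

__all__ = [
    "Dictionary",
    "SparseCode",
    "CodingConfig",
    "init_dictionary",
    "omp_code",
    "ksvd_train",
    "reconstruct",
    "save_dictionary",
    "load_dictionary",
]


@dataclass
class Dictionary:
    """An indexed collection of m unit-norm atoms (columns of ``atoms``).

    Parameters
    ----------
    atoms
        n x m real matrix; every column has Euclidean norm 1.
    seed
        Seed the initial random dictionary was drawn from, if any.
    iterations
        Number of k-SVD training iterations this dictionary has undergone
        (0 for an untrained random dictionary).
    class_label
        Signal class the dictionary was trained for, if any.
    history
        Total squared coding residual after each training iteration.
    """

    atoms: np.ndarray
    seed: int | None = None
    iterations: int = 0
    class_label: str | None = None
    history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise InvalidArgumentError("atoms must be a 2-D matrix")
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(norms == 0):
            raise InvalidArgumentError("dictionary contains an all-zero atom")
        if np.any(np.abs(norms - 1.0) > ATOL_NORM):
            raise InvalidArgumentError("every atom must have unit Euclidean norm")

    @property
    def n(self) -> int:
        """Signal length (rows)."""
        return self.atoms.shape[0]

    @property
    def m(self) -> int:
        """Atom count (columns)."""
        return self.atoms.shape[1]

    @property
    def overcomplete(self) -> bool:
        return self.m > self.n


@dataclass
class SparseCode:
    """Result of sparse-coding one signal against a dictionary.

    ``alpha`` is the full length-m coefficient vector (zero off-support),
    ``support`` lists the selected atom indices in selection order,
    ``residual`` is ``x - D @ alpha`` and ``rel_error`` is the residual
    energy divided by the signal energy, in [0, 1].
    """

    alpha: np.ndarray
    support: list[int]
    residual: np.ndarray
    rel_error: float

    @property
    def l1(self) -> float:
        """Sum of absolute coefficients — the classification score."""
        return float(np.sum(np.abs(self.alpha)))


@dataclass(frozen=True)
class CodingConfig:
    """OMP stopping rule: code until the residual energy fraction is below
    ``epsilon`` or ``max_atoms`` atoms have been selected.

    ``epsilon`` lives in (0, 1]; ``max_atoms=None`` means "up to n atoms"
    (an exact representation is then always reachable).
    """

    epsilon: float = 0.05
    max_atoms: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon <= 1.0):
            raise InvalidArgumentError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if self.max_atoms is not None and self.max_atoms < 1:
            raise InvalidArgumentError(f"max_atoms must be >= 1, got {self.max_atoms}")

    def resolved_max_atoms(self, n: int) -> int:
        if self.max_atoms is None:
            return n
        return min(self.max_atoms, n)


def init_dictionary(n: int, m: int, seed: int) -> Dictionary:
    """Random initial dictionary: i.i.d. standard-normal entries, columns
    normalized to unit norm.  Identical seed => identical dictionary."""
    if n < 2 or m < 1:
        raise InvalidArgumentError(f"need n >= 2 and m >= 1, got n={n}, m={m}")
    rng = np.random.default_rng(seed)
    atoms = rng.standard_normal((n, m))
    atoms /= np.linalg.norm(atoms, axis=0, keepdims=True)
    return Dictionary(atoms=atoms, seed=seed, iterations=0)


def _check_signal(D: Dictionary, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != D.n:
        raise DimensionMismatchError(f"signal length {x.shape[0]} != dictionary rows {D.n}")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("signal contains non-finite values")
    if np.dot(x, x) == 0.0:
        raise InvalidArgumentError("signal has zero norm")
    return x


def omp_code(D: Dictionary, x: np.ndarray, cfg: CodingConfig = CodingConfig()) -> SparseCode:
    """Error-constrained OMP.

    Iterates while the residual energy fraction ``e = ||r||^2 / ||x||^2``
    still exceeds ``cfg.epsilon`` and the support is below the atom budget.  Each
    iteration selects the atom with the largest absolute inner product with
    the current residual (ties -> lowest index), then recomputes the
    coefficients as the least-squares solution restricted to the selected
    atoms, so the residual stays orthogonal to every selected atom.

    With ``epsilon=1.0`` the loop never runs: the empty code already
    satisfies the error constraint (``e`` starts at exactly 1), so the
    sparsest feasible solution is all-zero and ``rel_error=1``.

    Greedy selection stops early if the residual becomes numerically
    orthogonal to every unselected atom (no atom can make progress) — the
    degenerate case where the error target is unreachable in ``D``.
    """
    x = _check_signal(D, x)
    n = D.n
    max_atoms = cfg.resolved_max_atoms(n)
    energy = float(np.dot(x, x))

    support: list[int] = []
    selected = np.zeros(D.m, dtype=bool)
    residual = x.copy()
    e = 1.0

    # least squares over the growing support via incremental QR:
    # Q holds an orthonormal basis of the selected atoms, R the triangular
    # factor, qx the entries of Q^T x.  Residual = x - Q Q^T x.
    Q = np.empty((n, max_atoms))
    R = np.zeros((max_atoms, max_atoms))
    qx = np.empty(max_atoms)

    while e > cfg.epsilon and len(support) < max_atoms:
        corr = np.abs(D.atoms.T @ residual)
        corr[selected] = -np.inf  # a selected atom is orthogonal to r anyway
        i = int(np.argmax(corr))  # argmax takes the lowest index on ties
        if corr[i] <= 1e-10 * np.linalg.norm(residual):
            break  # residual numerically orthogonal to every unselected atom
        j = len(support)
        # orthogonalize atom i against the current basis (re-orthogonalized
        # Gram-Schmidt keeps Q orthonormal to the noise floor)
        v = D.atoms[:, i].copy()
        rcol = np.zeros(j)
        for _ in range(2):
            proj = Q[:, :j].T @ v
            rcol += proj
            v -= Q[:, :j] @ proj
        rnorm = float(np.linalg.norm(v))
        if rnorm <= 1e-10:
            raise RankDeficiencyError(support + [i])
        support.append(i)
        selected[i] = True
        Q[:, j] = v / rnorm
        R[:j, j] = rcol
        R[j, j] = rnorm
        qx[j] = float(Q[:, j] @ x)
        residual = residual - Q[:, j] * qx[j]
        e = float(np.dot(residual, residual)) / energy

    alpha = np.zeros(D.m)
    if support:
        k = len(support)
        coef = solve_triangular(R[:k, :k], qx[:k], lower=False)
        alpha[support] = coef
    return SparseCode(alpha=alpha, support=support, residual=residual, rel_error=e)


def reconstruct(D: Dictionary, code: SparseCode | np.ndarray) -> np.ndarray:
    """Synthesis: ``D @ alpha``."""
    alpha = code.alpha if isinstance(code, SparseCode) else np.asarray(code, dtype=float)
    if alpha.shape[0] != D.m:
        raise DimensionMismatchError(f"alpha length {alpha.shape[0]} != atom count {D.m}")
    return D.atoms @ alpha


def _code_matrix(D: np.ndarray, X: np.ndarray, cfg: CodingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sparse-code every column of X; returns (m x M coefficients, per-signal
    squared residual norms)."""
    wrap = Dictionary(atoms=D)
    m, M = D.shape[1], X.shape[1]
    A = np.zeros((m, M))
    res2 = np.zeros(M)
    for t in range(M):
        code = omp_code(wrap, X[:, t], cfg)
        A[:, t] = code.alpha
        res2[t] = float(np.dot(code.residual, code.residual))
    return A, res2


def ksvd_train(
    X: np.ndarray,
    D0: Dictionary,
    K: int = 20,
    cfg: CodingConfig = CodingConfig(),
    class_label: str | None = None,
) -> Dictionary:
    """k-SVD dictionary learning.

    Per iteration: every training signal (column of ``X``) is sparse-coded
    against the current dictionary; then each atom j whose usage set w (the
    signals whose codes involve atom j) is nonempty is updated by a rank-1
    SVD of the residual matrix of those signals computed with atom j's
    coefficient row zeroed — the new atom is the first left singular vector
    and its coefficient row becomes (first singular value) x (first right
    singular vector).  Atoms no signal uses are replaced by the normalized
    training signal with the largest current coding residual, which keeps the
    dictionary free of dead atoms.

    The SVD's sign ambiguity is resolved by flipping so the atom entry of
    largest magnitude is positive, making the result deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InvalidArgumentError("training set must be an n x M matrix with M >= 1")
    if K < 1:
        raise InvalidArgumentError(f"iteration count K must be >= 1, got {K}")
    if X.shape[0] != D0.n:
        raise DimensionMismatchError(f"training rows {X.shape[0]} != dictionary rows {D0.n}")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0) or not np.all(np.isfinite(X)):
        raise InvalidArgumentError("every training signal must be finite with nonzero norm")

    D = D0.atoms.copy()
    m = D.shape[1]
    history: list[float] = []

    for _ in range(K):
        A, res2 = _code_matrix(D, X, cfg)
        history.append(float(res2.sum()))
        replacement_order = list(np.argsort(res2)[::-1])  # worst-coded first

        for j in range(m):
            w = np.flatnonzero(A[j, :] != 0.0)
            if w.size == 0:
                if replacement_order:
                    t = replacement_order.pop(0)
                    v = X[:, t]
                    D[:, j] = v / np.linalg.norm(v)
                continue
            Aw = A[:, w].copy()
            Aw[j, :] = 0.0
            R = X[:, w] - D @ Aw
            U, S, Vt = np.linalg.svd(R, full_matrices=False)
            atom = U[:, 0]
            if atom[np.argmax(np.abs(atom))] < 0:
                atom = -atom
                Vt = -Vt
            D[:, j] = atom
            A[j, w] = S[0] * Vt[0, :]

    # final coding pass to report the residual of the returned dictionary
    _, res2 = _code_matrix(D, X, cfg)
    history.append(float(res2.sum()))

    return Dictionary(
        atoms=D,
        seed=D0.seed,
        iterations=K,
        class_label=class_label if class_label is not None else D0.class_label,
        history=history,
    )


# ---------------------------------------------------------------------------
# serialization: a delimited-text container and a binary (.npz) container,
# both storing the matrix plus its provenance (n, m, class label, seed, K).

_TEXT_MAGIC = "scdsparse-dictionary v1"


def save_dictionary(D: Dictionary, path: str | Path, epsilon: float | None = None) -> None:
    """Write a dictionary to ``path``.

    ``.txt``/``.csv``/``.tsv`` suffixes get the delimited-text container
    (a header line per metadata field, then one tab-delimited row per signal
    sample); anything else gets the versioned binary ``.npz`` container.
    Both round-trip losslessly at double precision.
    """
    path = Path(path)
    meta = {
        "n": D.n,
        "m": D.m,
        "seed": D.seed,
        "iterations": D.iterations,
        "class_label": D.class_label,
        "epsilon": epsilon,
    }
    if path.suffix.lower() in {".txt", ".csv", ".tsv"}:
        with open(path, "w") as fh:
            fh.write(f"# {_TEXT_MAGIC}\n")
            fh.write(f"# meta {json.dumps(meta)}\n")
            for row in D.atoms:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    else:
        np.savez(
            path,
            format=np.array(_TEXT_MAGIC),
            atoms=D.atoms,
            meta=np.array(json.dumps(meta)),
        )


def load_dictionary(path: str | Path) -> Dictionary:
    """Read a dictionary written by :func:`save_dictionary`."""
    path = Path(path)
    if path.suffix.lower() in {".txt", ".csv", ".tsv"}:
        with open(path) as fh:
            magic = fh.readline().strip()
            if magic != f"# {_TEXT_MAGIC}":
                raise FormatError(f"{path}: line 1: not a {_TEXT_MAGIC} file")
            meta_line = fh.readline().strip()
            if not meta_line.startswith("# meta "):
                raise FormatError(f"{path}: line 2: missing metadata header")
            meta = json.loads(meta_line[len("# meta "):])
            atoms = np.loadtxt(fh, delimiter="\t", ndmin=2)
    else:
        with np.load(path) as z:
            if str(z["format"]) != _TEXT_MAGIC:
                raise FormatError(f"{path}: not a {_TEXT_MAGIC} container")
            atoms = z["atoms"]
            meta = json.loads(str(z["meta"]))
    if atoms.shape != (meta["n"], meta["m"]):
        raise FormatError(f"{path}: matrix shape {atoms.shape} disagrees with header")
    return Dictionary(
        atoms=atoms,
        seed=meta["seed"],
        iterations=meta["iterations"],
        class_label=meta["class_label"],
    )
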