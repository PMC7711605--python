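"""Exploratory/confirmatory factor analysis of expression profiles.

The common-factor model writes each z-scored variable as a linear
combination of p latent factors plus a unique term,

    x_i = a_i1 F_1 + ... + a_ip F_p + e_i,

so the population correlation matrix decomposes as
R = A Phi_f A' + Psi^2, with A the pattern loadings, Phi_f the factor
correlation matrix (oblique factors) and Psi^2 the diagonal uniquenesses.
Extraction is principal-axis factoring (iterated communalities on the
reduced correlation matrix), factor count selection follows the Kaiser
rule optionally pruned of factors that attract no variable, and rotation
is promax (varimax followed by an oblique target-power procrustes).
Variables are then assigned to the factor carrying their largest absolute
pattern loading, which partitions genes into candidate regulatory
subgroups.  Factor scores are never estimated; only the generator truth
in synthetic experiments holds them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


class NoStructureError(ValueError):
    """No eigenvalue exceeds one: the data carry no common-factor structure."""


@dataclass
class LoadingMatrix:
    """Factor pattern with factor correlations and per-variable summaries."""

    variables: list[str]
    loadings: np.ndarray              # q x p pattern matrix A
    phi: np.ndarray                   # p x p factor correlations
    uniquenesses: np.ndarray          # Psi^2, length q
    communalities: np.ndarray         # h^2, length q
    eigenvalues: np.ndarray           # of the full correlation matrix
    rotation: str = "none"
    converged: bool = True

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        p = self.n_factors
        q = len(self.variables)
        if p >= q:
            raise ValueError("need fewer factors than variables")
        if not np.allclose(self.phi, self.phi.T, atol=atol):
            raise ValueError("factor correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.phi), 1.0, atol=1e-6):
            raise ValueError("factor correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.phi).min() < -1e-8:
            raise ValueError("factor correlation matrix must be PSD")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"f{j + 1}" for j in range(self.n_factors)]
        df = pd.DataFrame(self.loadings, index=self.variables, columns=cols)
        df.insert(0, "communality", self.communalities)
        return df


@dataclass
class GroupAssignment:
    """Variable -> factor partition by maximal absolute pattern loading."""

    factor: pd.Series          # variable -> 1-based factor index
    winning_loading: pd.Series

    @property
    def sizes(self) -> pd.Series:
        return self.factor.value_counts().sort_index()

    def members(self, k: int) -> list[str]:
        return list(self.factor.index[self.factor == k])


def _as_variable_matrix(data) -> tuple[np.ndarray, list[str]]:
    """Return (variables x samples array, variable names)."""
    if isinstance(data, ExpressionMatrix):
        return data.values, data.variables
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.index)
    arr = np.asarray(data, dtype=float)
    return arr, [f"v{i + 1}" for i in range(arr.shape[0])]


def correlation_matrix(data) -> tuple[np.ndarray, list[str]]:
    vals, names = _as_variable_matrix(data)
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in input")
    sds = vals.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = names[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"zero-variance variable {bad!r}")
    return np.corrcoef(vals), names


def correlation_eigenvalues(data) -> np.ndarray:
    """Eigenvalues of the variable correlation matrix, descending.

    For z-scored data the covariance and correlation matrices coincide,
    so the Kaiser rule applied here matches the covariance-matrix form.
    """
    corr, _ = correlation_matrix(data)
    ev = np.linalg.eigvalsh(corr)[::-1]
    return ev


def scree_elbow(eigenvalues: np.ndarray) -> int:
    """Elbow by maximal second difference; diagnostic only."""
    ev = np.asarray(eigenvalues, dtype=float)
    if len(ev) < 3:
        return len(ev)
    second = np.diff(ev, 2)
    return int(np.argmax(second)) + 1


def select_n_factors(eigenvalues, strategy: str = "kaiser",
                     corr: np.ndarray | None = None, kappa: float = 4.0,
                     max_iter: int = 200, tol: float = 1e-6) -> int:
    """Number of factors by the Kaiser rule, optionally pruned.

    ``"kaiser"`` counts eigenvalues > 1.  ``"kaiser-then-prune"`` starts
    from the Kaiser count and reduces it one at a time while the rotated
    solution leaves some factor with no variable's maximal absolute
    loading (the Kaiser rule tends to overestimate; empty factors are
    regarded as ineffective).  Pruning requires the correlation matrix.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-10):
        raise ValueError("eigenvalues must be sorted descending")
    p = int(np.sum(ev > 1.0))
    if p == 0:
        raise NoStructureError("no eigenvalue exceeds 1; no factor structure")
    if strategy == "kaiser":
        return p
    if strategy != "kaiser-then-prune":
        raise ValueError(f"unknown strategy {strategy!r}")
    if corr is None:
        raise ValueError("kaiser-then-prune requires the correlation matrix")
    while p > 1:
        lm = principal_axis_factoring(corr, p, max_iter=max_iter, tol=tol)
        if p > 1:
            lm = promax_rotate(lm, kappa=kappa)
        winners = np.argmax(np.abs(lm.loadings), axis=1)
        n_empty = p - len(np.unique(winners))
        if n_empty == 0:
            break
        p -= 1
        logger.info("pruning to %d factors (%d attracted no variable)",
                    p, n_empty)
    return p


def squared_multiple_correlations(corr: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """SMC initial communalities, 1 - 1/diag(R^-1), ridged if near-singular."""
    q = corr.shape[0]
    try:
        inv = linalg.inv(corr)
        if not np.all(np.isfinite(inv)):
            raise linalg.LinAlgError
    except linalg.LinAlgError:
        inv = linalg.inv(corr + ridge * np.eye(q))
    d = np.diag(inv)
    if np.any(d <= 0):
        inv = linalg.inv(corr + max(ridge, 1e-6) * np.eye(q))
        d = np.diag(inv)
    return np.clip(1.0 - 1.0 / d, 0.0, 1.0)


def _fix_column_signs(A: np.ndarray) -> np.ndarray:
    """Orient each factor so its dominant loading is positive."""
    A = A.copy()
    for j in range(A.shape[1]):
        i = int(np.argmax(np.abs(A[:, j])))
        if A[i, j] < 0:
            A[:, j] = -A[:, j]
    return A


def principal_axis_factoring(corr: np.ndarray, p: int, max_iter: int = 200,
                             tol: float = 1e-6,
                             variables: list[str] | None = None) -> LoadingMatrix:
    """Iterated-communality principal-axis extraction (unrotated).

    The diagonal of R is replaced by current communality estimates
    (initialised at the squared multiple correlations), the reduced
    matrix is eigendecomposed, loadings are the top-p eigenvectors
    scaled by sqrt(eigenvalue), and the cycle repeats until the largest
    communality change falls below ``tol``.
    """
    corr = np.asarray(corr, dtype=float)
    q = corr.shape[0]
    if corr.shape != (q, q) or not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be square symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    if not 0 < p < q:
        raise ValueError("need 0 < p < q factors")
    if variables is None:
        variables = [f"v{i + 1}" for i in range(q)]

    eigenvalues = np.linalg.eigvalsh(corr)[::-1]
    h2 = squared_multiple_correlations(corr)
    reduced = corr.copy()
    converged = False
    A = np.zeros((q, p))
    for _ in range(max_iter):
        np.fill_diagonal(reduced, h2)
        w, V = np.linalg.eigh(reduced)
        w, V = w[::-1][:p], V[:, ::-1][:, :p]
        A = V * np.sqrt(np.clip(w, 0.0, None))
        new_h2 = np.sum(A ** 2, axis=1)
        if np.any(new_h2 > 1.0):
            over = new_h2 > 1.0
            if np.any(new_h2 > 1.0 + 1e-8):
                warnings.warn("Heywood case: communality > 1 clipped")
            new_h2 = np.where(over, 1.0, new_h2)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            converged = True
            break
        h2 = new_h2
    if not converged:
        warnings.warn(f"PAF did not converge in {max_iter} iterations")
    A = _fix_column_signs(A)
    lm = LoadingMatrix(
        variables=list(variables), loadings=A, phi=np.eye(p),
        uniquenesses=1.0 - h2, communalities=h2, eigenvalues=eigenvalues,
        rotation="none", converged=converged)
    lm.validate()
    return lm


def _varimax(A: np.ndarray, max_iter: int = 500, tol: float = 1e-10,
             normalize: bool = True) -> np.ndarray:
    q, p = A.shape
    if p == 1:
        return A.copy()
    h = np.sqrt(np.sum(A ** 2, axis=1))
    h[h == 0] = 1.0
    X = A / h[:, None] if normalize else A.copy()
    T = np.eye(p)
    d = 0.0
    for _ in range(max_iter):
        L = X @ T
        B = X.T @ (L ** 3 - L @ np.diag(np.sum(L ** 2, axis=0)) / q)
        U, s, Vt = np.linalg.svd(B)
        T = U @ Vt
        d_new = float(np.sum(s))
        if d_new < d * (1.0 + tol):
            break
        d = d_new
    L = X @ T
    if normalize:
        L = L * h[:, None]
    return L


def promax_rotate(lm: LoadingMatrix | np.ndarray, kappa: float = 4.0,
                  variables: list[str] | None = None) -> LoadingMatrix:
    """Oblique promax rotation of an unrotated loading matrix.

    Varimax pre-rotation, element-wise power-``kappa`` target, least
    squares procrustes transform, and column normalisation so the factor
    correlation matrix has unit diagonal.  The reproduced common part
    A_rot Phi_f A_rot' equals A A' exactly (oblique rotations preserve
    the common covariance).
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if isinstance(lm, LoadingMatrix):
        A = lm.loadings
        variables = lm.variables
        eigenvalues = lm.eigenvalues
        h2 = lm.communalities
    else:
        A = np.asarray(lm, dtype=float)
        if variables is None:
            variables = [f"v{i + 1}" for i in range(A.shape[0])]
        eigenvalues = np.array([])
        h2 = np.sum(A ** 2, axis=1)
    q, p = A.shape
    if p == 1:
        return LoadingMatrix(
            variables=list(variables), loadings=A.copy(), phi=np.eye(1),
            uniquenesses=1.0 - h2, communalities=h2,
            eigenvalues=eigenvalues, rotation=f"promax({kappa:g})")

    V = _varimax(A)
    target = np.sign(V) * np.abs(V) ** kappa
    U, *_ = np.linalg.lstsq(V, target, rcond=None)
    d = np.diag(linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    phi = linalg.inv(U.T @ U)
    phi = (phi + phi.T) / 2.0
    pattern = _fix_column_signs(pattern)
    # re-orienting a factor flips the corresponding row/column of phi
    signs = np.ones(p)
    raw = V @ U
    for j in range(p):
        i = int(np.argmax(np.abs(raw[:, j])))
        if raw[i, j] < 0:
            signs[j] = -1.0
    phi = phi * np.outer(signs, signs)
    h2_obl = np.einsum("ij,jk,ik->i", pattern, phi, pattern)
    out = LoadingMatrix(
        variables=list(variables), loadings=pattern, phi=phi,
        uniquenesses=1.0 - h2_obl, communalities=h2_obl,
        eigenvalues=eigenvalues, rotation=f"promax({kappa:g})")
    out.validate()
    return out


def communalities(lm: LoadingMatrix) -> np.ndarray:
    """Common variance per variable: h2 = a Phi_f a' (sum of squares when
    the factors are orthogonal)."""
    return np.einsum("ij,jk,ik->i", lm.loadings, lm.phi, lm.loadings)


def explained_variance_proportion(lm: LoadingMatrix) -> float:
    """Cumulative squared-loading proportion tr(A Phi A') / q."""
    return float(np.sum(communalities(lm)) / len(lm.variables))


def assign_groups(lm: LoadingMatrix) -> GroupAssignment:
    """Assign every variable to the factor with its largest |loading|.

    Ties break toward the lowest factor index (logged).
    """
    absA = np.abs(lm.loadings)
    winners = np.argmax(absA, axis=1)
    for i in range(absA.shape[0]):
        best = absA[i, winners[i]]
        if np.sum(absA[i] == best) > 1:
            logger.info("tie for variable %s broken toward factor %d",
                        lm.variables[i], winners[i] + 1)
    factor = pd.Series(winners + 1, index=lm.variables, name="factor")
    winning = pd.Series(
        lm.loadings[np.arange(len(winners)), winners], index=lm.variables,
        name="loading")
    return GroupAssignment(factor=factor, winning_loading=winning)


class PrincipalAxisFactorAnalysis:
    """Principal-axis factor analysis with promax rotation (sklearn style).

    Parameters
    ----------
    n_factors : int or {"kaiser", "kaiser-then-prune"}
        Fixed factor count or a selection strategy.
    rotation : {"promax", "none"}
    kappa : float
        Promax power (4 is conventional).
    max_iter, tol : PAF iteration controls.

    Attributes (after :meth:`fit`)
    ------------------------------
    eigenvalues_, n_factors_, loadings_, factor_corr_, communalities_,
    uniquenesses_, groups_ (GroupAssignment), loading_matrix_,
    explained_variance_proportion_, scree_elbow_.
    """

    def __init__(self, n_factors="kaiser-then-prune", rotation="promax",
                 kappa: float = 4.0, max_iter: int = 200, tol: float = 1e-6):
        self.n_factors = n_factors
        self.rotation = rotation
        self.kappa = kappa
        self.max_iter = max_iter
        self.tol = tol

    # -- sklearn plumbing ------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"n_factors": self.n_factors, "rotation": self.rotation,
                "kappa": self.kappa, "max_iter": self.max_iter,
                "tol": self.tol}

    def set_params(self, **params) -> "PrincipalAxisFactorAnalysis":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # --------------------------------------------------------------------
    def fit(self, X, y=None) -> "PrincipalAxisFactorAnalysis":
        """Fit to an (n_samples, n_variables) array/DataFrame, or to an
        ExpressionMatrix / variables-by-samples DataFrame."""
        if isinstance(X, ExpressionMatrix):
            data = X
        elif isinstance(X, pd.DataFrame):
            # sklearn convention: rows are samples, columns are variables
            data = ExpressionMatrix(X.T)
        else:
            arr = np.asarray(X, dtype=float)
            data = ExpressionMatrix(pd.DataFrame(
                arr.T, index=[f"v{i + 1}" for i in range(arr.shape[1])]))
        corr, names = correlation_matrix(data)
        self.eigenvalues_ = np.linalg.eigvalsh(corr)[::-1]
        self.scree_elbow_ = scree_elbow(self.eigenvalues_)
        if isinstance(self.n_factors, int):
            p = self.n_factors
        else:
            p = select_n_factors(self.eigenvalues_, strategy=self.n_factors,
                                 corr=corr, kappa=self.kappa,
                                 max_iter=self.max_iter, tol=self.tol)
        lm = principal_axis_factoring(corr, p, max_iter=self.max_iter,
                                      tol=self.tol, variables=names)
        if self.rotation == "promax" and p > 1:
            lm = promax_rotate(lm, kappa=self.kappa)
        elif self.rotation not in ("promax", "none"):
            raise ValueError(f"unknown rotation {self.rotation!r}")
        self.loading_matrix_ = lm
        self.n_factors_ = p
        self.loadings_ = lm.loadings
        self.factor_corr_ = lm.phi
        self.communalities_ = lm.communalities
        self.uniquenesses_ = lm.uniquenesses
        self.explained_variance_proportion_ = explained_variance_proportion(lm)
        self.groups_ = assign_groups(lm)
        return self
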