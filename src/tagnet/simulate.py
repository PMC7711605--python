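"""Seeded synthetic-data generators with retained ground truth.

Three generators cover every pipeline input:

* factor-structured expression  X = A F + E  with F ~ N(0, Phi_f) and
  independent errors of variance Psi^2, so the population covariance is
  A Phi_f A' + Psi^2;
* path-model samples  x = (I - Lambda)^-1 eps  with eps ~ N(0, Phi_e),
  whose population covariance is the model-implied Sigma(theta);
* phenotype time series built by inverting the oil-productivity formula,
  so the noiseless series recovers prescribed per-cell increments
  exactly.

All randomness flows through one ``numpy.random.Generator`` derived from
an explicit seed; regenerating with the same seed is bit-identical.
The ``table1_like`` scenario mimics the 9-group / 89-variable structure
of the study (group sizes 24, 21, 16, 9, 5, 6, 1, 3, 4, primary loading
0.8) at the study's sample count of 210.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import OIL_PRODUCTIVITY, ExpressionMatrix, PhenotypeSeries
from .sem import PathModel, implied_covariance

TABLE1_GROUP_SIZES = (24, 21, 16, 9, 5, 6, 1, 3, 4)


@dataclass
class SyntheticTruth:
    """Ground truth retained by a generator for recovery tests."""

    seed: int
    loadings: np.ndarray | None = None      # A
    factor_corr: np.ndarray | None = None   # Phi_f
    uniquenesses: np.ndarray | None = None  # Psi^2 (diagonal)
    factor_scores: np.ndarray | None = None  # F, n x p
    errors: np.ndarray | None = None         # E
    model: PathModel | None = None
    theta: np.ndarray | None = None
    groups: pd.Series | None = None


def gen_factor_data(A: np.ndarray, phi: np.ndarray, psi2: np.ndarray,
                    n: int, seed: int,
                    variables: list[str] | None = None,
                    standardize: bool = False
                    ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw n samples of q variables from the common-factor model.

    With ``standardize=True`` the rows of A and psi2 are rescaled so the
    population covariance A Phi_f A' + Psi^2 has a unit diagonal.
    """
    A = np.asarray(A, dtype=float)
    phi = np.asarray(phi, dtype=float)
    psi2 = np.asarray(psi2, dtype=float).copy()
    q, p = A.shape
    if phi.shape != (p, p):
        raise ValueError("Phi_f order must match the factor count")
    if psi2.shape != (q,):
        raise ValueError("psi2 must have one variance per variable")
    if np.any(psi2 < 0):
        raise ValueError("psi2 must be non-negative")
    w = np.linalg.eigvalsh(phi)
    if w.min() < -1e-10:
        raise ValueError("Phi_f must be positive semi-definite")
    if standardize:
        diag = np.einsum("ij,jk,ik->i", A, phi, A) + psi2
        scale = np.sqrt(diag)
        A = A / scale[:, None]
        psi2 = psi2 / diag

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(phi + 1e-12 * np.eye(p))
    F = rng.standard_normal((n, p)) @ L.T
    E = rng.standard_normal((n, q)) * np.sqrt(psi2)
    X = F @ A.T + E                      # n x q
    if variables is None:
        variables = [f"v{i + 1}" for i in range(q)]
    expr = ExpressionMatrix(pd.DataFrame(
        X.T, index=variables,
        columns=[f"s{i + 1}" for i in range(n)]))
    truth = SyntheticTruth(seed=seed, loadings=A, factor_corr=phi,
                           uniquenesses=psi2, factor_scores=F, errors=E)
    return expr, truth


def gen_sem_data(model: PathModel, theta: np.ndarray, n: int, seed: int
                 ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw n samples from a path model at the parameter point theta.

    Returns an (n, q) DataFrame with columns in model node order; the
    sample covariance converges to Sigma(theta).
    """
    sigma = implied_covariance(model, theta)  # also validates (I - Lambda)
    lam, phi = model.matrices(theta)
    w = np.linalg.eigvalsh((phi + phi.T) / 2.0)
    if w.min() <= 0:
        raise ValueError("Phi_e must be positive definite")
    q = model.q
    rng = np.random.default_rng(seed)
    eps = rng.multivariate_normal(np.zeros(q), phi, size=n,
                                  method="cholesky")
    B = np.linalg.solve(np.eye(q) - lam, np.eye(q))
    X = eps @ B.T
    df = pd.DataFrame(X, columns=model.nodes)
    truth = SyntheticTruth(seed=seed, model=model.copy(),
                           theta=np.asarray(theta, dtype=float),
                           errors=eps)
    return df, truth


def gen_phenotype_series(per_cell_oil: np.ndarray, cell: np.ndarray,
                         seed: int = 0, noise_sd: float = 0.0,
                         series_id: str = "sim", strain: str = "synthetic",
                         t: np.ndarray | None = None) -> PhenotypeSeries:
    """Build a phenotype series whose oil-productivity values equal the
    successive differences of ``per_cell_oil`` (units 1e-11 g/cell).

    OIL(t) = per_cell_oil(t) * Cell(t) / 1e3, optionally with Gaussian
    measurement noise on the oil titre.
    """
    per_cell_oil = np.asarray(per_cell_oil, dtype=float)
    cell = np.asarray(cell, dtype=float)
    if per_cell_oil.shape != cell.shape:
        raise ValueError("per_cell_oil and cell must have equal length")
    if len(per_cell_oil) < 2:
        raise ValueError("need at least two time points")
    if np.any(per_cell_oil <= 0) or np.any(cell <= 0):
        raise ValueError("trajectories must be positive")
    if t is None:
        t = 24.0 * np.arange(len(cell))
    oil = per_cell_oil * cell / 1e3
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        oil = np.clip(oil + rng.normal(0.0, noise_sd, size=oil.shape), 0.0,
                      None)
    return PhenotypeSeries(series_id=series_id, strain=strain, t=t,
                           oil=oil, cell=cell)


def six_node_truth() -> tuple[PathModel, np.ndarray]:
    """A 6-node benchmark path model for structure-recovery tests.

    Every edge lies in a v-structure (x2 <- {x1, x3}; y <- {x2, x4, x5}),
    so the model is its own covariance-equivalence class and directed
    recovery is statistically identifiable.  Effects sit in the range of
    strong standardized regulatory weights.
    """
    m = PathModel(nodes=["x1", "x2", "x3", "x4", "x5", "y"])
    edges = [("x1", "x2", 0.7), ("x3", "x2", 0.6), ("x2", "y", 0.7),
             ("x4", "y", 0.6), ("x5", "y", 0.6)]
    for s, t, _ in edges:
        m.add_edge(s, t)
    theta = np.array([w for *_, w in edges] + [1.0] * 6)
    return m, theta


def group_network_truth() -> tuple[PathModel, np.ndarray]:
    """A 9-factor path model used by the ``table1_network`` scenario.

    Six edges, all pointing into colliders (Group3 <- {Group2, Group9},
    Group5 <- {Group2, Group8}, Group9 <- {Group6, Group4}), so every
    direction is identifiable from the covariance structure.
    """
    nodes = [f"Group{k}" for k in range(1, 10)]
    m = PathModel(nodes=nodes)
    edges = [("Group2", "Group3", 0.7), ("Group9", "Group3", 0.6),
             ("Group2", "Group5", 0.7), ("Group8", "Group5", 0.6),
             ("Group6", "Group9", 0.6), ("Group4", "Group9", 0.6)]
    for s, t, _ in edges:
        m.add_edge(s, t)
    theta = np.array([w for *_, w in edges] + [1.0] * 9)
    return m, theta


def table1_like_scenario(n: int = 210, loading: float = 0.8, seed: int = 0,
                         factor_corr: float = 0.3,
                         group_model: PathModel | None = None,
                         group_theta: np.ndarray | None = None
                         ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """89-variable, 9-group scenario mirroring the study's group sizes.

    Each variable loads ``loading`` on its group's factor and 0 elsewhere;
    factors are mildly oblique (pairwise correlation ``factor_corr``), or,
    when a ``group_model`` is given, correlated through that path model's
    implied covariance (standardized to unit factor variances).  One
    variable in group 3 is named ``oil_productivity``.
    """
    sizes = TABLE1_GROUP_SIZES
    q, p = sum(sizes), len(sizes)
    if group_model is not None:
        sigma_f = implied_covariance(group_model, group_theta)
        d = np.sqrt(np.diag(sigma_f))
        factor_cov = sigma_f / np.outer(d, d)
    else:
        factor_cov = None
    A = np.zeros((q, p))
    names, groups = [], []
    i = 0
    for g, size in enumerate(sizes):
        for j in range(size):
            A[i, g] = loading
            if g == 2 and j == size - 1:
                names.append(OIL_PRODUCTIVITY)
            else:
                names.append(f"g{g + 1}_v{j + 1}")
            groups.append(g + 1)
            i += 1
    if factor_cov is not None:
        phi = factor_cov
    else:
        phi = np.full((p, p), factor_corr)
        np.fill_diagonal(phi, 1.0)
    psi2 = np.ones(q)
    expr, truth = gen_factor_data(A, phi, psi2, n, seed, variables=names,
                                  standardize=True)
    truth.groups = pd.Series(groups, index=names, name="factor")
    if group_model is not None:
        truth.model = group_model.copy()
        truth.theta = np.asarray(group_theta, dtype=float)
    return expr, truth


def table1_network_scenario(n: int = 500, loading: float = 0.8, seed: int = 0
                            ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """table1_like with the factors coupled through a known path model."""
    m, theta = group_network_truth()
    return table1_like_scenario(n=n, loading=loading, seed=seed,
                                group_model=m, group_theta=theta)


SCENARIOS = {"table1_like": table1_like_scenario,
             "table1_network": table1_network_scenario}
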