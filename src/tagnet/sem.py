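"""Covariance-structure SEM over observed variables (path analysis).

A path model on q observed variables collects linear coefficients in a
q x q matrix Lambda (row = child/target, column = parent/source) and
error (co)variances in Phi_e.  The model-implied covariance is

    Sigma(theta) = (I - Lambda)^-1 Phi_e (I - Lambda)^-T,

fitted to the sample covariance S by minimising the maximum-likelihood
discrepancy

    F_ML = log|Sigma(theta)| - log|S| + tr(Sigma(theta)^-1 S) - q,

which is zero iff Sigma(theta) = S.  The chi-square statistic is
(n - 1) * F_ML (Wishart convention; switchable to n).  Standard errors
come from the observed information, the Hessian of (n - 1)/2 * F_ML at
the optimum; modification indices are one-degree-of-freedom score
statistics built on the expected information.  Cyclic (non-recursive)
models are permitted whenever (I - Lambda) is invertible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger(__name__)


class SingularModelError(ValueError):
    """(I - Lambda) is singular: the feedback structure admits no solution."""


class IdentificationError(ValueError):
    """The model's free parameters are not identified by the covariances."""


class MatrixDomainError(ValueError):
    """A covariance input is not symmetric positive definite."""


# ---------------------------------------------------------------------------
# model specification


@dataclass
class PathModel:
    """Directed path model: free/fixed edges, error variances/covariances.

    ``edges`` maps (source, target) to {"free": bool, "value": float};
    error covariances are fixed at zero unless declared in
    ``error_covariances`` (keyed by a sorted node pair).  Every node's
    error variance is free.
    """

    nodes: list[str]
    edges: dict = field(default_factory=dict)
    error_covariances: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        for (s, t) in self.edges:
            self._check_pair(s, t)
        for pair in self.error_covariances:
            a, b = pair
            self._check_pair(a, b)

    def _check_pair(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-edge on {a!r} not allowed")
        for x in (a, b):
            if x not in self.nodes:
                raise KeyError(f"unknown node {x!r}")

    # -- construction helpers -------------------------------------------
    def add_edge(self, source: str, target: str, free: bool = True,
                 value: float = 0.0) -> None:
        self._check_pair(source, target)
        if (source, target) in self.edges:
            raise ValueError(f"edge {source}->{target} already present")
        self.edges[(source, target)] = {"free": free, "value": float(value)}

    def remove_edge(self, source: str, target: str) -> None:
        del self.edges[(source, target)]

    def add_error_covariance(self, a: str, b: str, free: bool = True,
                             value: float = 0.0) -> None:
        self._check_pair(a, b)
        key = tuple(sorted((a, b)))
        if key in self.error_covariances:
            raise ValueError(f"error covariance {a}~~{b} already present")
        self.error_covariances[key] = {"free": free, "value": float(value)}

    def remove_error_covariance(self, a: str, b: str) -> None:
        del self.error_covariances[tuple(sorted((a, b)))]

    def copy(self) -> "PathModel":
        return PathModel(nodes=list(self.nodes),
                         edges={k: dict(v) for k, v in self.edges.items()},
                         error_covariances={k: dict(v) for k, v in
                                            self.error_covariances.items()})

    # -- parameter bookkeeping ------------------------------------------
    @property
    def q(self) -> int:
        return len(self.nodes)

    def free_parameters(self) -> list[tuple[str, object]]:
        """Ordered free-parameter descriptors: ("edge", (s, t)),
        ("cov", (a, b)), then ("var", node)."""
        out: list[tuple[str, object]] = []
        for key, spec in self.edges.items():
            if spec["free"]:
                out.append(("edge", key))
        for key, spec in self.error_covariances.items():
            if spec["free"]:
                out.append(("cov", key))
        for node in self.nodes:
            out.append(("var", node))
        return out

    def parameter_labels(self) -> list[str]:
        labels = []
        for kind, key in self.free_parameters():
            if kind == "edge":
                labels.append(f"{key[0]}->{key[1]}")
            elif kind == "cov":
                labels.append(f"{key[0]}~~{key[1]}")
            else:
                labels.append(f"var({key})")
        if len(set(labels)) != len(labels):
            raise ValueError("free parameter labels are not unique")
        return labels

    @property
    def n_free(self) -> int:
        return len(self.free_parameters())

    def degrees_of_freedom(self) -> int:
        return self.q * (self.q + 1) // 2 - self.n_free

    def is_saturated(self) -> bool:
        if self.edges:
            return False
        pairs = {tuple(sorted((a, b)))
                 for i, a in enumerate(self.nodes)
                 for b in self.nodes[i + 1:]}
        free = {k for k, v in self.error_covariances.items() if v["free"]}
        return free == pairs

    # -- matrix assembly -------------------------------------------------
    def matrices(self, theta: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
        """(Lambda, Phi_e) at a parameter point; fixed values filled in."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        q = self.q
        lam = np.zeros((q, q))
        phi = np.zeros((q, q))
        for (s, t), spec in self.edges.items():
            if not spec["free"]:
                lam[idx[t], idx[s]] = spec["value"]
        for (a, b), spec in self.error_covariances.items():
            if not spec["free"]:
                phi[idx[a], idx[b]] = phi[idx[b], idx[a]] = spec["value"]
        if theta is not None:
            for value, (kind, key) in zip(theta, self.free_parameters()):
                if kind == "edge":
                    s, t = key
                    lam[idx[t], idx[s]] = value
                elif kind == "cov":
                    a, b = key
                    phi[idx[a], idx[b]] = phi[idx[b], idx[a]] = value
                else:
                    phi[idx[key], idx[key]] = value
        return lam, phi

    # -- serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [(s, t, "free" if v["free"] else "fixed", v["value"])
                for (s, t), v in self.edges.items()]
        return pd.DataFrame(rows, columns=["source", "target", "status", "value"])

    @classmethod
    def from_frame(cls, nodes: list[str], df: pd.DataFrame) -> "PathModel":
        m = cls(nodes=list(nodes))
        for _, row in df.iterrows():
            m.add_edge(row["source"], row["target"],
                       free=str(row["status"]) == "free",
                       value=float(row.get("value", 0.0)))
        return m


# ---------------------------------------------------------------------------
# core covariance algebra


def _check_spd(M: np.ndarray, name: str) -> None:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise MatrixDomainError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-8):
        raise MatrixDomainError(f"{name} must be symmetric")
    try:
        linalg.cholesky(M, lower=True)
    except linalg.LinAlgError as exc:
        raise MatrixDomainError(f"{name} is not positive definite") from exc


def implied_covariance(model: PathModel, theta: np.ndarray | None = None
                       ) -> np.ndarray:
    """Sigma(theta) = (I - Lambda)^-1 Phi_e (I - Lambda)^-T."""
    lam, phi = model.matrices(theta)
    q = model.q
    ImL = np.eye(q) - lam
    det = np.linalg.det(ImL)
    if abs(det) < 1e-12:
        cyc = [model.nodes[i] for i in range(q) if np.any(lam[i] != 0)]
        raise SingularModelError(
            f"(I - Lambda) is singular; feedback among {cyc} admits no "
            "reduced form")
    B = linalg.solve(ImL, np.eye(q))
    sigma = B @ phi @ B.T
    return (sigma + sigma.T) / 2.0


def ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """Maximum-likelihood discrepancy between sample and implied covariance."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if S.shape != sigma.shape:
        raise MatrixDomainError("covariance matrices must have equal order")
    _check_spd(S, "sample covariance")
    _check_spd(sigma, "implied covariance")
    q = S.shape[0]
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    f = logdet_m - logdet_s + float(np.trace(linalg.solve(sigma, S))) - q
    return max(f, 0.0)


# ---------------------------------------------------------------------------
# derivative machinery


def _dsigma(model: PathModel, B: np.ndarray, sigma: np.ndarray,
            params: list[tuple[str, object]]) -> list[np.ndarray]:
    """dSigma/dtheta for each descriptor, at the point giving (B, sigma)."""
    idx = {n: i for i, n in enumerate(model.nodes)}
    q = model.q
    out = []
    for kind, key in params:
        if kind == "edge":
            s, t = key
            # dSigma = B E_{t,s} Sigma + (B E_{t,s} Sigma)'
            X = np.outer(B[:, idx[t]], sigma[idx[s], :])
            out.append(X + X.T)
        elif kind == "cov":
            a, b = key
            X = np.outer(B[:, idx[a]], B[:, idx[b]])
            out.append(X + X.T)
        else:
            col = B[:, idx[key]]
            out.append(np.outer(col, col))
    return out


def _fml_and_grad(model: PathModel, theta: np.ndarray, S: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    lam, phi = model.matrices(theta)
    q = model.q
    ImL = np.eye(q) - lam
    det = np.linalg.det(ImL)
    if not np.isfinite(det) or abs(det) < 1e-12:
        return np.inf, np.zeros_like(theta)
    B = linalg.solve(ImL, np.eye(q))
    sigma = B @ phi @ B.T
    sigma = (sigma + sigma.T) / 2.0
    w, _ = np.linalg.eigh(sigma)
    if w.min() <= 1e-10:
        return np.inf, np.zeros_like(theta)
    W = linalg.inv(sigma)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    f = logdet_m - logdet_s + float(np.sum(W * S)) - q
    M = W - W @ S @ W  # dF/dSigma
    grad = np.array([float(np.sum(M * d))
                     for d in _dsigma(model, B, sigma, model.free_parameters())])
    return f, grad


def start_values(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Deterministic starting point: stored edge/cov values (default 0),
    error variances at the sample variances."""
    idx = {n: i for i, n in enumerate(model.nodes)}
    theta0 = []
    for kind, key in model.free_parameters():
        if kind == "edge":
            theta0.append(model.edges[key]["value"])
        elif kind == "cov":
            theta0.append(model.error_covariances[key]["value"])
        else:
            theta0.append(S[idx[key], idx[key]])
    return np.array(theta0, dtype=float)


# ---------------------------------------------------------------------------
# fit indices


UNDEFINED = None  # marker for AGFI/RMSEA when df = 0


@dataclass
class FitReport:
    """Fit indices of a model plus its saturated/independence baselines."""

    chi2: float
    df: int
    p: float | None
    gfi: float
    agfi: float | None
    cfi: float
    rmsea: float | None
    aic: float
    n: int
    saturated: dict = field(default_factory=dict)
    independence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "GFI": self.gfi, "AGFI": self.agfi, "CFI": self.cfi,
                "RMSEA": self.rmsea, "AIC": self.aic, "n": self.n,
                "saturated": self.saturated,
                "independence": self.independence}


def fit_indices(chi2: float, df: int, n: int, chi2_indep: float,
                df_indep: int, n_free_params: int, q: int,
                S: np.ndarray | None = None,
                implied: np.ndarray | None = None) -> FitReport:
    """Assemble CMIN p, GFI, AGFI, CFI, RMSEA and AIC.

    GFI = 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2] requires the
    sample and implied covariances; with chi2 = 0 it is 1 by definition.
    AGFI and RMSEA are reported as ``None`` when df = 0.  AIC uses
    chi2 + 2 * (free parameters), so the saturated model scores
    q(q + 1).
    """
    if df < 0:
        raise IdentificationError("negative degrees of freedom")
    chi2 = float(chi2)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else None
    if S is not None and implied is not None:
        A = linalg.solve(implied, S)
        Iq = np.eye(q)
        gfi = 1.0 - np.trace((A - Iq) @ (A - Iq)) / np.trace(A @ A)
        gfi = float(gfi)
    elif chi2 == 0.0:
        gfi = 1.0
    else:
        warnings.warn("GFI requires S and the implied covariance; reporting NaN")
        gfi = float("nan")
    if df > 0:
        agfi = 1.0 - (q * (q + 1) / (2.0 * df)) * (1.0 - gfi)
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    else:
        agfi = UNDEFINED
        rmsea = UNDEFINED
    denom = max(chi2_indep - df_indep, chi2 - df, 0.0)
    cfi = 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0
    aic = chi2 + 2.0 * n_free_params

    n_moments = q * (q + 1) // 2
    saturated = {"chi2": 0.0, "df": 0, "p": None, "GFI": 1.0, "AGFI": None,
                 "CFI": 1.0, "RMSEA": None, "AIC": float(2 * n_moments)}
    df0 = int(df_indep)
    indep_rmsea = (float(np.sqrt(max(chi2_indep - df0, 0.0) / (df0 * (n - 1))))
                   if df0 > 0 else None)
    independence = {"chi2": float(chi2_indep), "df": df0,
                    "p": float(stats.chi2.sf(chi2_indep, df0)) if df0 > 0 else None,
                    "CFI": 0.0 if chi2_indep > df0 else 1.0,
                    "RMSEA": indep_rmsea,
                    "AIC": float(chi2_indep + 2 * q)}
    return FitReport(chi2=chi2, df=int(df), p=p, gfi=gfi, agfi=agfi, cfi=cfi,
                     rmsea=rmsea, aic=float(aic), n=int(n),
                     saturated=saturated, independence=independence)


def independence_chi2(S: np.ndarray, n: int, bias: str = "n-1"
                      ) -> tuple[float, int]:
    """Chi-square and df of the all-covariances-zero baseline.

    With Sigma = diag(S) the discrepancy reduces to -log|R| for the
    correlation matrix R.
    """
    S = np.asarray(S, dtype=float)
    q = S.shape[0]
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    mult = (n - 1) if bias == "n-1" else n
    return float(-logdet * mult), q * (q - 1) // 2


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class FittedModel:
    """Result of maximum-likelihood estimation of a PathModel."""

    model: PathModel
    S: np.ndarray
    n: int
    theta: pd.Series                 # label -> estimate
    implied: np.ndarray
    se: pd.Series
    wald_p: pd.Series
    chi2: float
    df: int
    fit_report: FitReport
    converged: bool
    fml: float

    @property
    def param_descriptors(self) -> list[tuple[str, object]]:
        return self.model.free_parameters()

    def standardized_weights(self) -> pd.DataFrame:
        """Edge table with standardized weights w = b * sd(source)/sd(target),
        using model-implied standard deviations."""
        sd = np.sqrt(np.diag(self.implied))
        idx = {node: i for i, node in enumerate(self.model.nodes)}
        rows = []
        for (kind, key), label in zip(self.param_descriptors,
                                      self.model.parameter_labels()):
            if kind != "edge":
                continue
            s, t = key
            b = self.theta[label]
            rows.append({"source": s, "target": t, "estimate": b,
                         "standardized_weight": b * sd[idx[s]] / sd[idx[t]],
                         "se": self.se[label], "p_value": self.wald_p[label]})
        return pd.DataFrame(
            rows, columns=["source", "target", "estimate",
                           "standardized_weight", "se", "p_value"])

    def structural_pvalues(self) -> dict[tuple[str, object], float]:
        """Wald p per free edge and free error covariance."""
        out = {}
        for (kind, key), label in zip(self.param_descriptors,
                                      self.model.parameter_labels()):
            if kind in ("edge", "cov"):
                out[(kind, key)] = float(self.wald_p[label])
        return out

    def to_report_dict(self) -> dict:
        return {"parameters": self.theta.to_dict(),
                "se": self.se.to_dict(),
                "wald_p": self.wald_p.to_dict(),
                "fit": self.fit_report.to_dict(),
                "converged": self.converged}


def _observed_information(model: PathModel, theta: np.ndarray, S: np.ndarray,
                          n: int, bias: str, step: float = 1e-6
                          ) -> np.ndarray:
    """Hessian of (n-1)/2 * F_ML via central differences of the gradient."""
    m = len(theta)
    H = np.zeros((m, m))
    for j in range(m):
        h = step * max(1.0, abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        _, gp = _fml_and_grad(model, tp, S)
        _, gm = _fml_and_grad(model, tm, S)
        H[:, j] = (gp - gm) / (2 * h)
    H = (H + H.T) / 2.0
    mult = (n - 1) if bias == "n-1" else n
    return H * mult / 2.0


def expected_information(model: PathModel, theta: np.ndarray, S: np.ndarray,
                         n: int, bias: str = "n-1",
                         extra: list[tuple[str, object]] | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Expected information over free params (+ optional extra descriptors)
    and the score vector of (n-1)/2 * F_ML at theta."""
    params = model.free_parameters() + list(extra or [])
    lam, phi = model.matrices(theta)
    q = model.q
    B = linalg.solve(np.eye(q) - lam, np.eye(q))
    sigma = B @ phi @ B.T
    sigma = (sigma + sigma.T) / 2.0
    W = linalg.inv(sigma)
    derivs = _dsigma(model, B, sigma, params)
    mult = (n - 1) if bias == "n-1" else n
    Y = np.stack([(W @ d @ W).ravel() for d in derivs])
    D = np.stack([d.ravel() for d in derivs])
    info = (mult / 2.0) * (Y @ D.T)
    info = (info + info.T) / 2.0
    M = W - W @ S @ W
    score = (mult / 2.0) * D @ M.ravel()
    return info, score


def fit_model(model: PathModel, S: np.ndarray, n: int, bias: str = "n-1",
              ridge: float = 0.0, check_identification: bool = True,
              compute_se: bool = True, max_iter: int = 1000) -> FittedModel:
    """Estimate a path model by ML against the sample covariance S.

    Quasi-Newton (L-BFGS-B) minimisation of F_ML with an analytic
    gradient, starting from zero edges and sample variances.  A ridge
    can stabilise a near-singular S.  Identification is checked from the
    rank of the expected information at the optimum.
    """
    S = np.asarray(S, dtype=float)
    q = model.q
    if S.shape != (q, q):
        raise ValueError("S order does not match the model's node count")
    if n <= q:
        raise ValueError("need more observations than variables")
    if ridge > 0:
        S = S + ridge * np.eye(q)
    _check_spd(S, "sample covariance")
    df = model.degrees_of_freedom()
    if df < 0:
        raise IdentificationError(
            f"{model.n_free} free parameters exceed {q * (q + 1) // 2} moments")
    labels = model.parameter_labels()
    mult = (n - 1) if bias == "n-1" else n

    if model.is_saturated():
        idx = {node: i for i, node in enumerate(model.nodes)}
        vals = []
        for kind, key in model.free_parameters():
            if kind == "cov":
                vals.append(S[idx[key[0]], idx[key[1]]])
            else:
                vals.append(S[idx[key], idx[key]])
        theta = np.array(vals, dtype=float)
        fml, converged = 0.0, True
    else:
        theta0 = start_values(model, S)

        def objective(th):
            return _fml_and_grad(model, th, S)

        res = optimize.minimize(
            objective, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9})
        theta, fml = res.x, float(res.fun)
        # L-BFGS-B can stop on a tiny relative reduction while far from
        # stationarity (struggling line search near the PD boundary);
        # polish with full BFGS whenever the gradient is not flat
        if np.isfinite(fml) and np.abs(res.jac).max() > 1e-7:
            start = theta if np.isfinite(fml) else theta0
            res2 = optimize.minimize(
                objective, start, jac=True, method="BFGS",
                options={"maxiter": max_iter, "gtol": 1e-9})
            if np.isfinite(res2.fun) and res2.fun <= fml:
                theta, fml = res2.x, float(res2.fun)
        if not np.isfinite(fml):
            raise SingularModelError("optimizer left the feasible region")
        grad_norm = np.abs(_fml_and_grad(model, theta, S)[1]).max()
        converged = grad_norm < 1e-5 or fml < 1e-12
        if not converged:
            warnings.warn("SEM optimizer did not report convergence; "
                          "returning last iterate")

    fml = max(fml, 0.0)
    chi2 = mult * fml
    implied = implied_covariance(model, theta)

    lamv, _ = model.matrices(theta)
    if np.max(np.abs(np.linalg.eigvals(lamv))) >= 1.0:
        warnings.warn("spectral radius of Lambda >= 1: non-stationary "
                      "feedback interpretation")

    if check_identification and model.n_free > 0 and not model.is_saturated():
        info, _ = expected_information(model, theta, S, n, bias=bias)
        w = np.linalg.eigvalsh(info)
        if w.min() < 1e-10 * max(w.max(), 1.0):
            raise IdentificationError(
                "expected information is rank deficient: model not identified")

    if compute_se and model.n_free > 0:
        H = _observed_information(model, theta, S, n, bias)
        try:
            cov = linalg.pinvh(H)
            var = np.diag(cov)
            # a non-positive variance marks a parameter the information
            # cannot pin down: report an infinite SE so its Wald p is 1
            se = np.where(var > 0, np.sqrt(np.abs(var)), np.inf)
        except linalg.LinAlgError:
            warnings.warn("observed information not invertible; SEs undefined")
            se = np.full(len(theta), np.inf)
    else:
        se = np.full(len(theta), np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), theta / se,
                     np.where(np.isinf(se), 0.0, np.inf))
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    chi2_0, df_0 = independence_chi2(S, n, bias=bias)
    report = fit_indices(chi2, df, n, chi2_0, df_0, model.n_free, q,
                         S=S, implied=implied)
    return FittedModel(model=model, S=S, n=n,
                       theta=pd.Series(theta, index=labels),
                       implied=implied,
                       se=pd.Series(se, index=labels),
                       wald_p=pd.Series(pvals, index=labels),
                       chi2=float(chi2), df=int(df), fit_report=report,
                       converged=converged, fml=fml)


def modification_indices(fm: FittedModel,
                         candidates: list[tuple[str, tuple[str, str]]],
                         bias: str = "n-1") -> list[tuple[tuple[str, tuple[str, str]], float]]:
    """Score-test modification index for each fixed-at-zero candidate.

    Candidates are ("edge", (source, target)) or ("cov", (a, b)).  The MI
    approximates the chi-square drop from freeing that one parameter:
    MI = U_c^2 / (I_cc - I_ct I_tt^-1 I_tc), with U the score and I the
    expected information over free parameters plus the candidate.
    """
    model = fm.model
    for kind, key in candidates:
        if kind == "edge":
            if key in model.edges and model.edges[key]["free"]:
                raise ValueError(f"candidate edge {key} is already free")
        elif kind == "cov":
            k = tuple(sorted(key))
            if k in model.error_covariances and model.error_covariances[k]["free"]:
                raise ValueError(f"candidate covariance {key} is already free")
        else:
            raise ValueError(f"unknown candidate kind {kind!r}")
        if key[0] == key[1]:
            raise ValueError("self-referential candidate")
    if not candidates:
        return []
    theta = fm.theta.to_numpy()
    info, score = expected_information(model, theta, fm.S, fm.n, bias=bias,
                                       extra=list(candidates))
    m = model.n_free
    I_tt = info[:m, :m]
    out = []
    for j, cand in enumerate(candidates):
        c = m + j
        u = score[c]
        i_tc = info[:m, c]
        try:
            sol = linalg.solve(I_tt, i_tc, assume_a="sym")
            denom = info[c, c] - float(i_tc @ sol)
        except linalg.LinAlgError:
            denom = 0.0
        mi = (u * u / denom) if denom > 1e-12 else 0.0
        out.append((cand, max(float(mi), 0.0)))
    return out


# ---------------------------------------------------------------------------
# sklearn-style wrapper


class StructuralEquationModel:
    """Path-analytic SEM estimator (sklearn style).

    Parameters
    ----------
    model : PathModel
        The structural specification to estimate.
    bias : {"n-1", "n"}
        Multiplier convention for the chi-square statistic.
    ridge : float
        Added to diag(S) when the sample covariance is near singular.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_, se_, wald_p_, implied_cov_, chi2_, df_, fit_report_,
    standardized_weights_, fitted_ (the full :class:`FittedModel`).
    """

    def __init__(self, model: PathModel, bias: str = "n-1",
                 ridge: float = 0.0):
        self.model = model
        self.bias = bias
        self.ridge = ridge

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "bias": self.bias, "ridge": self.ridge}

    def set_params(self, **params) -> "StructuralEquationModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "StructuralEquationModel":
        """Fit from an (n_samples, n_variables) array or DataFrame whose
        columns match the model's nodes."""
        if isinstance(X, pd.DataFrame):
            X = X[self.model.nodes]
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
        S = np.cov(arr, rowvar=False, ddof=1)
        return self.fit_cov(S, arr.shape[0])

    def fit_cov(self, S: np.ndarray, n: int) -> "StructuralEquationModel":
        fm = fit_model(self.model, S, n, bias=self.bias, ridge=self.ridge)
        self.fitted_ = fm
        self.params_ = fm.theta
        self.se_ = fm.se
        self.wald_p_ = fm.wald_p
        self.implied_cov_ = fm.implied
        self.chi2_ = fm.chi2
        self.df_ = fm.df
        self.fit_report_ = fm.fit_report
        self.standardized_weights_ = fm.standardized_weights()
        return self
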