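"""Stepwise structural model search.

The search starts from a star model (one free edge from every candidate
regulator into the objective variable, regulators mutually independent),
then alternates two moves, one modification per refit:

* prune: while any free structural parameter has Wald p >= alpha,
  delete the single one with the largest p and refit;
* add: free the absent parameter with the highest modification index,
  provided it exceeds the MI threshold.

The alternation runs over directed path edges first, then over error
covariances.  An edge deleted in a phase enters a tabu list for the rest
of that phase, preventing oscillation and guaranteeing termination.  A
candidate model is accepted when CMIN p > 0.01, GFI >= 0.90,
CFI >= 0.90 and RMSEA below the hard cap 0.10 (below 0.05 preferred,
flagged separately); failing acceptance, the search restarts from a
seeded random perturbation of the initial edge set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import OIL_PRODUCTIVITY, AnalysisDataset, standardize_dataset
from .factor import GroupAssignment, PrincipalAxisFactorAnalysis
from .sem import (FittedModel, IdentificationError, PathModel,
                  SingularModelError, fit_model, modification_indices)

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Knobs of the stepwise search."""

    alpha: float = 0.01              # Wald retention threshold per edge
    mi_threshold: float = 3.84       # chi2(1) at 0.05
    cmin_p_min: float = 0.01
    gfi_min: float = 0.90
    cfi_min: float = 0.90
    rmsea_good: float = 0.05
    rmsea_max: float = 0.10
    max_iter: int = 200
    restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mi_threshold <= 0:
            raise ValueError("MI threshold must be positive")


@dataclass
class TraceAction:
    action: str                      # delete | add | phase | restart
    kind: str = ""                   # edge | cov
    key: tuple = ()
    statistic: float = float("nan")  # Wald p for deletions, MI for additions
    chi2: float = float("nan")
    df: int = -1


@dataclass
class SearchTrace:
    """Ordered action log; replaying it reproduces the final model."""

    initial: PathModel
    actions: list[TraceAction] = field(default_factory=list)

    def log(self, **kw) -> None:
        self.actions.append(TraceAction(**kw))

    def replay(self) -> PathModel:
        model = self.initial.copy()
        for act in self.actions:
            if act.action == "restart":
                model = self.initial.copy()
                for k in list(model.edges):
                    if k not in act.key:
                        model.remove_edge(*k)
            elif act.action == "delete" and act.kind == "edge":
                model.remove_edge(*act.key)
            elif act.action == "delete" and act.kind == "cov":
                model.remove_error_covariance(*act.key)
            elif act.action == "add" and act.kind == "edge":
                model.add_edge(*act.key)
            elif act.action == "add" and act.kind == "cov":
                model.add_error_covariance(*act.key)
        return model

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.actions])


@dataclass
class AcceptanceFlags:
    cmin_p: bool
    gfi: bool
    cfi: bool
    rmsea_hard: bool
    rmsea_preferred: bool
    all_significant: bool

    @property
    def accepted(self) -> bool:
        return self.cmin_p and self.gfi and self.cfi and self.rmsea_hard


def star_initial_model(objective: str, parents: list[str]) -> PathModel:
    """Star model: one free edge from each parent into the objective,
    parents mutually independent (error covariances fixed at zero)."""
    if not parents:
        raise ValueError("parent set must not be empty")
    if objective in parents:
        raise ValueError("objective must not be among the parents")
    model = PathModel(nodes=list(parents) + [objective])
    for p in parents:
        model.add_edge(p, objective)
    return model


def acceptance_flags(fm: FittedModel, cfg: SearchConfig) -> AcceptanceFlags:
    rep = fm.fit_report
    p_ok = True if rep.p is None else rep.p > cfg.cmin_p_min
    rmsea = rep.rmsea
    rmsea_hard = True if rmsea is None else rmsea < cfg.rmsea_max
    rmsea_pref = True if rmsea is None else rmsea < cfg.rmsea_good
    sig = all(p < cfg.alpha for p in fm.structural_pvalues().values())
    return AcceptanceFlags(cmin_p=p_ok, gfi=rep.gfi >= cfg.gfi_min,
                           cfi=rep.cfi >= cfg.cfi_min,
                           rmsea_hard=rmsea_hard, rmsea_preferred=rmsea_pref,
                           all_significant=sig)


def prune_step(fm: FittedModel, alpha: float
               ) -> tuple[PathModel, tuple[str, tuple] | None, float]:
    """Delete the free structural parameter with the largest Wald p if it
    is >= alpha; otherwise return the model unchanged.

    Returns (model, deleted descriptor or None, its p)."""
    pvals = fm.structural_pvalues()
    if not pvals:
        return fm.model, None, float("nan")
    (kind, key), worst_p = max(pvals.items(), key=lambda kv: kv[1])
    if not np.isfinite(worst_p):
        worst_p = 1.0
    if worst_p < alpha:
        return fm.model, None, worst_p
    model = fm.model.copy()
    if kind == "edge":
        model.remove_edge(*key)
        remaining = [s for (s, t) in model.edges if t == key[1]]
        if key[1] == model.nodes[-1] and not remaining:
            logger.warning("objective %r lost its last regulator", key[1])
    else:
        model.remove_error_covariance(*key)
    return model, (kind, key), worst_p


def _candidates(model: PathModel, phase: str, tabu: set) -> list:
    if phase == "paths":
        out = [("edge", (s, t))
               for s in model.nodes for t in model.nodes
               if s != t and (s, t) not in model.edges
               and ("edge", (s, t)) not in tabu]
    elif phase == "error_covariances":
        # a covariance between a directly connected pair is not identified
        # alongside the edge (two parameters, one moment) and is skipped
        out = []
        for i, a in enumerate(model.nodes):
            for b in model.nodes[i + 1:]:
                key = tuple(sorted((a, b)))
                if ((a, b) in model.edges or (b, a) in model.edges
                        or key in model.error_covariances
                        or ("cov", key) in tabu):
                    continue
                out.append(("cov", key))
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return out


def add_step(fm: FittedModel, phase: str, mi_threshold: float,
             tabu: set | None = None
             ) -> tuple[PathModel, tuple[str, tuple] | None, float]:
    """Free the highest-MI absent parameter of the phase if its MI exceeds
    the threshold; otherwise return the model unchanged."""
    tabu = tabu or set()
    cands = _candidates(fm.model, phase, tabu)
    if not cands:
        return fm.model, None, float("nan")
    if fm.model.degrees_of_freedom() <= 0:
        return fm.model, None, float("nan")
    scored = modification_indices(fm, cands)
    scored.sort(key=lambda cm: -cm[1])
    (kind, key), mi = scored[0]
    if mi <= mi_threshold:
        return fm.model, None, mi
    model = fm.model.copy()
    if kind == "edge":
        model.add_edge(*key)
    else:
        model.add_error_covariance(*key)
    return model, (kind, key), mi


def _search_once(initial: PathModel, S: np.ndarray, n: int, cfg: SearchConfig,
                 trace: SearchTrace) -> FittedModel:
    fm = fit_model(initial, S, n, check_identification=False)
    actions = 0
    for phase in ("paths", "error_covariances"):
        trace.log(action="phase", kind=phase)
        tabu: set = set()
        while actions < cfg.max_iter:
            # prune to all-significant
            while actions < cfg.max_iter:
                model, deleted, p = prune_step(fm, cfg.alpha)
                if deleted is None:
                    break
                tabu.add(deleted)
                fm = fit_model(model, S, n, check_identification=False)
                actions += 1
                trace.log(action="delete", kind=deleted[0], key=deleted[1],
                          statistic=p, chi2=fm.chi2, df=fm.df)
            # additions exist to reach an acceptably fitting model; once
            # every edge is significant and the fit thresholds are met,
            # adding further parameters only chases noise
            if acceptance_flags(fm, cfg).accepted:
                return fm
            # best addition, skipping candidates that break the fit
            added = None
            skip = set(tabu)
            while actions < cfg.max_iter:
                model, added, mi = add_step(fm, phase, cfg.mi_threshold, skip)
                if added is None:
                    break
                try:
                    # additions must keep the model identified
                    fm_new = fit_model(model, S, n)
                except (SingularModelError, IdentificationError) as exc:
                    logger.info("candidate %s rejected: %s", added, exc)
                    skip.add(added)
                    added = None
                    continue
                fm = fm_new
                actions += 1
                trace.log(action="add", kind=added[0], key=added[1],
                          statistic=mi, chi2=fm.chi2, df=fm.df)
                break
            if added is None:
                break
    if actions >= cfg.max_iter:
        warnings.warn("model search hit the iteration cap; returning "
                      "best-so-far")
    return fm


def _perturb(initial: PathModel, rng: np.random.Generator
             ) -> tuple[PathModel, tuple]:
    """Randomly drop ~30% of the initial free edges (at least one kept)."""
    model = initial.copy()
    free = [k for k, v in model.edges.items() if v["free"]]
    keep = [k for k in free if rng.random() > 0.3]
    if not keep and free:
        keep = [free[rng.integers(len(free))]]
    for k in free:
        if k not in keep:
            model.remove_edge(*k)
    return model, tuple(keep)


def optimize(initial: PathModel, S: np.ndarray, n: int,
             cfg: SearchConfig | None = None
             ) -> tuple[FittedModel, SearchTrace, AcceptanceFlags]:
    """Run the stepwise search, restarting from seeded perturbations of
    the initial model until the fit thresholds are met.

    Returns the accepted model with the best AIC (or the best-effort
    model with its acceptance flags when no restart reaches acceptance).
    """
    cfg = cfg or SearchConfig()
    trace = SearchTrace(initial=initial.copy())
    rng = np.random.default_rng(cfg.seed)
    best: tuple[FittedModel, AcceptanceFlags] | None = None
    start = initial
    # every restart is explored; among accepted models the lowest AIC wins
    for attempt in range(cfg.restarts + 1):
        if attempt > 0:
            start, kept = _perturb(initial, rng)
            trace.log(action="restart", kind="edge", key=kept)
        fm = _search_once(start, S, n, cfg, trace)
        flags = acceptance_flags(fm, cfg)
        if best is None:
            best = (fm, flags)
        else:
            b_fm, b_flags = best
            better = ((flags.accepted and not b_flags.accepted)
                      or (flags.accepted == b_flags.accepted
                          and fm.fit_report.aic < b_fm.fit_report.aic))
            if better:
                best = (fm, flags)
    fm, flags = best
    if not flags.all_significant:
        warnings.warn("returned model retains a non-significant parameter")
    return fm, trace, flags


class StepwiseSEMSearch:
    """Stepwise SEM structure learner (sklearn style).

    Parameters mirror :class:`SearchConfig` plus the objective variable.
    ``fit(X)`` expects an (n_samples, n_variables) DataFrame whose
    columns include the objective; every other column starts as a parent
    in the star initial model.

    Attributes (after :meth:`fit`)
    ------------------------------
    best_model_, fitted_, trace_, flags_, edges_ (standardized edge table).
    """

    def __init__(self, objective: str, alpha: float = 0.01,
                 mi_threshold: float = 3.84, max_iter: int = 200,
                 restarts: int = 3, seed: int = 0):
        self.objective = objective
        self.alpha = alpha
        self.mi_threshold = mi_threshold
        self.max_iter = max_iter
        self.restarts = restarts
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"objective": self.objective, "alpha": self.alpha,
                "mi_threshold": self.mi_threshold, "max_iter": self.max_iter,
                "restarts": self.restarts, "seed": self.seed}

    def set_params(self, **params) -> "StepwiseSEMSearch":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> SearchConfig:
        return SearchConfig(alpha=self.alpha, mi_threshold=self.mi_threshold,
                            max_iter=self.max_iter, restarts=self.restarts,
                            seed=self.seed)

    def fit(self, X: pd.DataFrame, y=None) -> "StepwiseSEMSearch":
        if self.objective not in X.columns:
            raise ValueError(f"objective {self.objective!r} not in columns")
        parents = [c for c in X.columns if c != self.objective]
        initial = star_initial_model(self.objective, parents)
        arr = X[parents + [self.objective]].to_numpy(dtype=float)
        S = np.cov(arr, rowvar=False, ddof=1)
        fm, trace, flags = optimize(initial, S, arr.shape[0], self._config())
        self.best_model_ = fm.model
        self.fitted_ = fm
        self.trace_ = trace
        self.flags_ = flags
        self.edges_ = fm.standardized_weights()
        return self


# ---------------------------------------------------------------------------
# 5-step pipeline


@dataclass
class PipelineResult:
    factor_analysis: PrincipalAxisFactorAnalysis
    groups: GroupAssignment
    oil_group: int
    group_model: FittedModel
    group_trace: SearchTrace
    group_flags: AcceptanceFlags
    pseudo_profiles: pd.DataFrame
    pseudo_model: FittedModel
    pseudo_trace: SearchTrace
    pseudo_flags: AcceptanceFlags


def run_stepwise_pipeline(dataset: AnalysisDataset,
                          cfg: SearchConfig | None = None,
                          n_factors="kaiser-then-prune",
                          kappa: float = 4.0) -> PipelineResult:
    """Factor grouping, then within-group and between-group SEM search.

    STEP 1-2: star initial model over the oil-productivity group and
    stepwise optimization.  STEP 3: per-group average profiles (pseudo
    variables).  STEP 4-5: star model with the oil-containing group as
    objective over the pseudo variables, optimized the same way.
    """
    from .network import pseudo_variables  # local import avoids a cycle

    cfg = cfg or SearchConfig()
    if OIL_PRODUCTIVITY not in dataset.data.index:
        raise ValueError(f"dataset lacks the {OIL_PRODUCTIVITY!r} row")
    ds = standardize_dataset(dataset)
    fa = PrincipalAxisFactorAnalysis(n_factors=n_factors, kappa=kappa)
    fa.fit(ds.data.T)
    groups = fa.groups_
    oil_group = int(groups.factor[OIL_PRODUCTIVITY])

    members = groups.members(oil_group)
    parents = [m for m in members if m != OIL_PRODUCTIVITY]
    if not parents:
        raise ValueError("oil productivity is alone in its group")
    X_group = ds.data.T[parents + [OIL_PRODUCTIVITY]]
    initial = star_initial_model(OIL_PRODUCTIVITY, parents)
    S = np.cov(X_group.to_numpy(dtype=float), rowvar=False, ddof=1)
    group_fm, group_trace, group_flags = optimize(
        initial, S, X_group.shape[0], cfg)

    pseudo = pseudo_variables(ds, groups)
    profiles = pseudo.profiles
    objective = f"Group{oil_group}"
    others = [g for g in profiles.index if g != objective]
    Xp = profiles.T[others + [objective]]
    Sp = np.cov(Xp.to_numpy(dtype=float), rowvar=False, ddof=1)
    initial_p = star_initial_model(objective, others)
    pseudo_fm, pseudo_trace, pseudo_flags = optimize(
        initial_p, Sp, Xp.shape[0], cfg)

    return PipelineResult(
        factor_analysis=fa, groups=groups, oil_group=oil_group,
        group_model=group_fm, group_trace=group_trace,
        group_flags=group_flags, pseudo_profiles=profiles,
        pseudo_model=pseudo_fm, pseudo_trace=pseudo_trace,
        pseudo_flags=pseudo_flags)
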