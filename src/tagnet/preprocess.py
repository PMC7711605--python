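"""Expression preprocessing and phenotype-derived oil productivity.

Raw microarray intensities are log2-transformed and z-scored per gene.
Oil productivity at time t is the change in oil mass per cell between
consecutive sampling points,

    oil_productivity(t) = OIL(t+1) * 1e3 / Cell(t+1) - OIL(t) * 1e3 / Cell(t)

with OIL in g/L and Cell in 1e8 cells/mL, so the value is in units of
1e-11 g per cell.  Expression measured at time t is paired with the
productivity realised over (t, t+1); the final time point of every series
therefore carries no productivity and is dropped from the analysis set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OIL_PRODUCTIVITY = "oil_productivity"


class ZeroVarianceError(ValueError):
    """A gene row has zero variance and cannot be z-scored."""


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression grid.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are variables (genes, optionally ``oil_productivity``),
        columns are sample ids.
    normalized : bool
        True once rows are log2 z-scores (mean 0, sample sd 1).
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate variable id: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")

    @property
    def variables(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def validate(self, atol: float = 1e-9) -> None:
        if self.normalized:
            vals = self.values
            means = vals.mean(axis=1)
            sds = vals.std(axis=1, ddof=1)
            if not (np.allclose(means, 0.0, atol=atol)
                    and np.allclose(sds, 1.0, atol=atol)):
                raise ValueError("normalized matrix rows must have mean 0, sd 1")


@dataclass
class PhenotypeSeries:
    """One strain's time course of oil titre and cell density."""

    series_id: str
    strain: str
    t: np.ndarray          # hours, strictly increasing
    oil: np.ndarray        # g/L
    cell: np.ndarray       # 1e8 cells/mL

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.oil = np.asarray(self.oil, dtype=float)
        self.cell = np.asarray(self.cell, dtype=float)
        if not (len(self.t) == len(self.oil) == len(self.cell)):
            raise ValueError("t, oil and cell must have equal length")
        if len(self.t) < 1:
            raise ValueError("series must contain at least one time point")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.oil < 0):
            raise ValueError("OIL must be non-negative")
        if np.any(self.cell <= 0):
            raise ValueError("Cell must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class AnalysisDataset:
    """Normalized expression plus oil productivity over retained samples.

    ``sample_map`` maps each retained sample id to its (series_id, t)
    origin.  Samples from the last time point of each series are absent.
    """

    expression: ExpressionMatrix
    sample_map: pd.DataFrame = field(repr=False)  # index=sample, cols series_id, t

    @property
    def data(self) -> pd.DataFrame:
        return self.expression.data

    @property
    def n_samples(self) -> int:
        return self.expression.data.shape[1]


def log2_zscore(raw: ExpressionMatrix, on_zero_variance: str = "error") -> ExpressionMatrix:
    """Per-gene log2 transform followed by z-scoring (sample sd, n-1).

    Parameters
    ----------
    raw : ExpressionMatrix
        Positive raw intensities.
    on_zero_variance : {"error", "drop"}
        Constant rows abort by default; ``"drop"`` removes them with a
        warning instead (changing the downstream variable count).
    """
    vals = raw.data.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise ValueError(
            f"non-finite value at gene {raw.variables[bad[0]]!r}, "
            f"sample {raw.samples[bad[1]]!r}")
    if np.any(vals <= 0):
        bad = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive expression value at gene {raw.variables[bad[0]]!r}, "
            f"sample {raw.samples[bad[1]]!r}: {vals[bad[0], bad[1]]}")
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score")

    logged = np.log2(vals)
    sds = logged.std(axis=1, ddof=1)
    zero = sds == 0.0
    if np.any(zero):
        names = [raw.variables[i] for i in np.flatnonzero(zero)]
        if on_zero_variance == "drop":
            warnings.warn(f"dropping zero-variance genes: {names}")
            keep = ~zero
            logged = logged[keep]
            sds = sds[keep]
            index = [v for v, k in zip(raw.variables, keep) if k]
        else:
            raise ZeroVarianceError(f"zero variance for gene {names[0]!r}")
    else:
        index = raw.variables

    z = (logged - logged.mean(axis=1, keepdims=True)) / sds[:, None]
    out = ExpressionMatrix(
        pd.DataFrame(z, index=index, columns=raw.samples), normalized=True)
    out.validate()
    return out


def oil_productivity(series: PhenotypeSeries) -> list[tuple[float, float]]:
    """Per-cell oil production rate between consecutive time points.

    Returns ``(t_i, value_i)`` for every time point except the last;
    a length-1 series yields an empty list with a logged warning.
    """
    if len(series) < 2:
        logger.warning("series %s has a single time point; no productivity",
                       series.series_id)
        return []
    per_cell = series.oil * 1e3 / series.cell
    values = np.diff(per_cell)
    return list(zip(series.t[:-1].tolist(), values.tolist()))


def assemble_dataset(expr: ExpressionMatrix,
                     series_set: list[PhenotypeSeries],
                     sample_map: pd.DataFrame,
                     normalize: str = "after") -> AnalysisDataset:
    """Join expression with per-sample oil productivity, dropping each
    series' final time point.

    Parameters
    ----------
    expr : ExpressionMatrix
        Raw (positive) or already-normalized expression over all samples.
    series_set : list of PhenotypeSeries
    sample_map : DataFrame
        Index = sample ids of ``expr``; columns ``series_id`` and ``t``.
    normalize : {"after", "before"}
        Z-score over retained samples only ("after", default) or over all
        samples prior to deletion ("before").
    """
    if normalize not in ("after", "before"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    missing = [s for s in expr.samples if s not in sample_map.index]
    if missing:
        raise KeyError(f"sample {missing[0]!r} has no (series, t) mapping")
    pairs = list(zip(sample_map.loc[expr.samples, "series_id"],
                     sample_map.loc[expr.samples, "t"]))
    if len(set(pairs)) != len(pairs):
        dup = next(p for p in pairs if pairs.count(p) > 1)
        raise ValueError(f"duplicate (series, t) pair: {dup}")

    prod: dict[tuple[str, float], float] = {}
    for series in series_set:
        for t, v in oil_productivity(series):
            prod[(series.series_id, float(t))] = v

    if normalize == "before" and not expr.normalized:
        expr = log2_zscore(expr)

    keep, values = [], []
    for sample, (sid, t) in zip(expr.samples, pairs):
        key = (sid, float(t))
        if key in prod:
            keep.append(sample)
            values.append(prod[key])
    expected = sum(max(len(s) - 1, 0) for s in series_set)
    data = expr.data[keep]
    if normalize == "after" and not expr.normalized:
        data = log2_zscore(ExpressionMatrix(data)).data
    prod_row = pd.DataFrame([values], index=[OIL_PRODUCTIVITY], columns=keep)
    joined = pd.concat([data, prod_row])
    if joined.shape[1] != expected:
        logger.warning("retained %d samples, expected %d from series lengths",
                       joined.shape[1], expected)
    out_expr = ExpressionMatrix(joined, normalized=False)
    return AnalysisDataset(expression=out_expr,
                           sample_map=sample_map.loc[keep])


def standardize_dataset(ds: AnalysisDataset) -> AnalysisDataset:
    """Z-score every row of an assembled dataset (incl. oil productivity)."""
    vals = ds.data.to_numpy(dtype=float)
    sds = vals.std(axis=1, ddof=1)
    if np.any(sds == 0):
        bad = ds.data.index[int(np.flatnonzero(sds == 0)[0])]
        raise ZeroVarianceError(f"zero variance for variable {bad!r}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sds[:, None]
    expr = ExpressionMatrix(
        pd.DataFrame(z, index=ds.data.index, columns=ds.data.columns),
        normalized=True)
    return AnalysisDataset(expression=expr, sample_map=ds.sample_map)
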