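"""Packaged fixtures: the study's printed factor-loading and edge tables.

``table1_loadings`` holds the 89-variable pattern matrix with
communalities and printed group labels; ``table3_edges`` the 46-edge
within-group regulatory model; ``table5_edges`` the 21-edge group-level
model.  In the edge tables a p-value printed as ``***`` (below 0.001)
is parsed as NaN, with the raw token kept in ``p_label``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .factor import LoadingMatrix
from .network import RegulatoryGraph

import numpy as np


def _data_path(name: str):
    return resources.files("tagnet.data").joinpath(name)


def load_table1_loadings() -> pd.DataFrame:
    with resources.as_file(_data_path("table1_loadings.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df


def table1_loading_matrix() -> LoadingMatrix:
    """The printed pattern as a LoadingMatrix (factor correlations are not
    printed; an identity placeholder is used, so only the pattern-based
    operations — assignment, strong loadings — are meaningful)."""
    df = load_table1_loadings()
    cols = [f"f{j}" for j in range(1, 10)]
    A = df[cols].to_numpy(dtype=float)
    h2 = df["communality"].to_numpy(dtype=float)
    return LoadingMatrix(
        variables=list(df["variable"]), loadings=A, phi=np.eye(9),
        uniquenesses=1.0 - h2, communalities=h2,
        eigenvalues=np.array([]), rotation="promax(4)")


def table1_printed_groups() -> pd.Series:
    df = load_table1_loadings()
    return pd.Series(df["group"].to_numpy(), index=df["variable"],
                     name="factor")


def _load_edges(name: str) -> RegulatoryGraph:
    with resources.as_file(_data_path(name)) as p:
        df = pd.read_csv(p, sep="\t", dtype={"p_value": str})
    df = df.rename(columns={"p_value": "p_label"})
    df["p_value"] = pd.to_numeric(df["p_label"], errors="coerce")
    g = RegulatoryGraph.from_edges(df, provenance="fixture")
    for (_, row) in df.iterrows():
        g.graph.edges[row["source"], row["target"]]["p_label"] = row["p_label"]
    return g


def load_table3_edges() -> RegulatoryGraph:
    return _load_edges("table3_edges.tsv")


def load_table5_edges() -> RegulatoryGraph:
    return _load_edges("table5_edges.tsv")
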