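"""Table and configuration plumbing.

TSV dialects:

* expression: first column ``variable``, remaining columns sample ids;
* metadata: ``sample_id, series_id, strain, time_h, oil_g_per_L,
  cells_1e8_per_mL``;
* edge list: ``source, target, standardized_weight, p_value``.

Configuration is YAML with strict key validation; every run writes a
manifest carrying the resolved config and its hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

METADATA_COLUMNS = ["sample_id", "series_id", "strain", "time_h",
                    "oil_g_per_L", "cells_1e8_per_mL"]


class TableFormatError(ValueError):
    pass


def read_table(path: str | Path, columns: list[str] | None = None,
               numeric: list[str] | None = None) -> pd.DataFrame:
    """Strict TSV reader: header required, consistent column counts,
    declared columns present, declared numeric columns parseable.
    Errors cite the offending 1-based line number."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TableFormatError(f"{path}: empty file, header required")
    header = lines[0].split("\t")
    ncol = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise TableFormatError(
                f"{path}:{lineno}: expected {ncol} columns, got {len(parts)}")
        rows.append(parts)
    df = pd.DataFrame(rows, columns=header)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise TableFormatError(f"{path}: missing column {missing[0]!r}")
    for col in numeric or []:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise TableFormatError(
                f"{path}: column {col!r} is not numeric: {exc}") from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False
                ) -> Path:
    """Full-precision, locale-independent TSV output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_expression_tsv(path: str | Path):
    from .preprocess import ExpressionMatrix

    df = read_table(path)
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "variable"
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric expression value: "
                               f"{exc}") from exc
    return ExpressionMatrix(df)


def read_metadata_tsv(path: str | Path):
    """Returns (sample_map DataFrame, list of PhenotypeSeries)."""
    from .preprocess import PhenotypeSeries

    df = read_table(path, columns=METADATA_COLUMNS,
                    numeric=["time_h", "oil_g_per_L", "cells_1e8_per_mL"])
    sample_map = df.set_index("sample_id")[["series_id", "time_h"]].rename(
        columns={"time_h": "t"})
    series = []
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("time_h")
        series.append(PhenotypeSeries(
            series_id=str(sid), strain=str(grp["strain"].iloc[0]),
            t=grp["time_h"].to_numpy(),
            oil=grp["oil_g_per_L"].to_numpy(),
            cell=grp["cells_1e8_per_mL"].to_numpy()))
    return sample_map, series


@dataclass
class PipelineConfig:
    """Validated run configuration (YAML-backed)."""

    expression: str = ""
    metadata: str = ""
    out_dir: str = "tagnet_out"
    seed: int = 0
    n_factors: str | int = "kaiser-then-prune"
    kappa: float = 4.0
    alpha: float = 0.01
    mi_threshold: float = 3.84
    max_iter: int = 200
    restarts: int = 3
    normalize: str = "after"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = set(cls().__dict__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: PipelineConfig,
                   steps: list[str], failed_stage: str | None = None) -> Path:
    import tagnet

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tagnet_version": tagnet.__version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "completed_steps": steps,
        "status": "failed" if failed_stage else "ok",
        "failed_stage": failed_stage,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return path
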