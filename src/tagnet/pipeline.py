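"""End-to-end orchestration of the 5-step analysis from files on disk."""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as tio
from .network import RegulatoryGraph, enumerate_cycles, export_graph
from .preprocess import assemble_dataset
from .search import SearchConfig, run_stepwise_pipeline

logger = logging.getLogger(__name__)

STEPS = ["preprocess", "factor_analysis", "group_model", "pseudo_variables",
         "pseudo_model"]


def run(config: tio.PipelineConfig) -> Path:
    """Execute preprocess -> factor analysis -> within-group search ->
    pseudo variables -> group-level search, writing artifacts and a
    manifest to ``config.out_dir``.

    On a stage failure the manifest records the failed stage and partial
    artifacts are retained; the exception propagates.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    try:
        expr = tio.read_expression_tsv(config.expression)
        sample_map, series = tio.read_metadata_tsv(config.metadata)
        dataset = assemble_dataset(expr, series, sample_map,
                                   normalize=config.normalize)
        tio.write_table(dataset.data.reset_index(), out / "analysis_dataset.tsv")
        completed.append("preprocess")

        cfg = SearchConfig(alpha=config.alpha,
                           mi_threshold=config.mi_threshold,
                           max_iter=config.max_iter,
                           restarts=config.restarts, seed=config.seed)
        result = run_stepwise_pipeline(dataset, cfg,
                                       n_factors=config.n_factors,
                                       kappa=config.kappa)
        lm = result.factor_analysis.loading_matrix_
        loadings = lm.to_frame().reset_index(names="variable")
        loadings["group"] = result.groups.factor.to_numpy()
        tio.write_table(loadings, out / "loadings.tsv")
        completed.append("factor_analysis")

        for tag, fm, trace in (("group", result.group_model,
                                result.group_trace),
                               ("pseudo", result.pseudo_model,
                                result.pseudo_trace)):
            g = RegulatoryGraph.from_fitted(fm)
            export_graph(g, out / f"{tag}_edges.tsv", "tsv")
            (out / f"{tag}_fit.json").write_text(
                json.dumps(fm.to_report_dict(), indent=2, default=str) + "\n")
            tio.write_table(trace.to_frame(), out / f"{tag}_trace.tsv")
            (out / f"{tag}_cycles.txt").write_text(
                "\n".join(" -> ".join(c) for c in enumerate_cycles(g)) + "\n")
        completed.append("group_model")
        tio.write_table(result.pseudo_profiles.reset_index(names="group"),
                        out / "pseudo_profiles.tsv")
        completed.append("pseudo_variables")
        completed.append("pseudo_model")
        tio.write_manifest(out, config, completed)
        return out
    except Exception:
        failed = STEPS[len(completed)] if len(completed) < len(STEPS) else "?"
        tio.write_manifest(out, config, completed, failed_stage=failed)
        raise
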