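"""End-to-end pipeline: load inputs, survey ranks, score genes, benchmark.

``run_pipeline`` wires the stages together and writes the standard run
artifacts (rank_metrics.tsv, consensus matrices, gene_scores.tsv,
labeling.json, de_table.tsv, enrichment_table.tsv, summary.json, a log
file) into an output directory.  All randomness flows from one top-level
seed expanded deterministically per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .consensus import consensus_run, rank_survey
from .enrichment import (
    DEFAULT_THRESHOLD_GRID,
    EnrichmentReport,
    matched_comparison,
    parse_threshold_specs,
    simple_de_test,
)
from .matrix import ExpressionMatrix, filter_low_expression
from .nmf import assign_clusters
from .scoring import label_clusters, score_genes

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Unreadable or invalid input (CLI exit code 2)."""


class ComputationError(RuntimeError):
    """A pipeline stage failed during computation (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Flat pipeline configuration; round-trips through ``key = value`` text."""

    matrix: str = ""
    labels: str = ""
    reference: str = ""
    de_table: str = ""          # optional; empty -> built-in Welch/BH test
    out_dir: str = "nmfmarker_run"
    scale_tag: str = "tpm"
    ranks: str = "2:5"          # "lo:hi" inclusive, or single "2"
    score_rank: int = 2
    n_runs: int = 100
    seed: int = 42
    min_expressed_samples: int = 5
    specs: str = "0.05:;0.05:1;0.01:;0.01:1;0.05:0.5;0.05:1.5;0.01:0.5;0.01:1.5"
    universe_size: int = 0      # 0 -> number of genes after filtering
    disease_name: str = "glaucoma"
    normal_name: str = "normal"
    max_iter: int = 2000
    tol: float = 1e-6
    survey: bool = True

    def rank_list(self) -> list[int]:
        text = self.ranks.strip()
        if ":" in text:
            lo, hi = text.split(":")
            return list(range(int(lo), int(hi) + 1))
        return [int(text)]

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float, "str": str,
                 "bool": lambda s: str(s).strip().lower() in ("1", "true", "yes")}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise InputError(f"unknown config key {key!r} in {path}")
            kwargs[key] = casts[types[key]](value)
        return cls(**kwargs)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig) -> EnrichmentReport:
    """Run the full analysis described by ``config``; returns the enrichment
    report and leaves all artifacts in ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("nmfmarker")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _require_file(path: str, what: str) -> str:
    if not path:
        raise InputError(f"missing required input: {what}")
    if not Path(path).is_file():
        raise InputError(f"{what} file not found: {path}")
    return path


def _run(config: RunConfig, out: Path) -> EnrichmentReport:
    survey_seed, score_seed, de_seed, _ = _stage_seeds(config.seed)

    # --- inputs -----------------------------------------------------------
    matrix = io.read_expression_matrix(
        _require_file(config.matrix, "expression matrix"), scale_tag=config.scale_tag
    )
    labels = io.read_sample_labels(
        _require_file(config.labels, "sample labels"),
        disease_name=config.disease_name, normal_name=config.normal_name,
    )
    io.check_labels(labels, matrix)
    reference = io.read_gene_list(_require_file(config.reference, "reference gene list"))
    matrix = filter_low_expression(matrix, config.min_expressed_samples)
    labeled = [s for s in matrix.sample_ids if s in labels]
    if len(labeled) < matrix.n_samples:
        logger.info("excluding %d unlabeled samples", matrix.n_samples - len(labeled))
        matrix = ExpressionMatrix(matrix.data[labeled], scale_tag=matrix.scale_tag)
    logger.info("matrix: %d genes x %d samples", matrix.n_genes, matrix.n_samples)

    try:
        # --- rank survey --------------------------------------------------
        if config.survey:
            survey = rank_survey(
                matrix, config.rank_list(), n_runs=config.n_runs,
                base_seed=survey_seed, max_iter=config.max_iter, tol=config.tol,
            )
            survey.to_frame().to_csv(out / "rank_metrics.tsv", sep="\t", index=False)
            for res in survey.results:
                pd.DataFrame(res.consensus, index=matrix.sample_ids,
                             columns=matrix.sample_ids).to_csv(
                    out / f"consensus_rank{res.rank}.tsv", sep="\t")
            logger.info("rank survey selected rank %d", survey.selected_rank)
            if survey.selected_rank != config.score_rank:
                logger.warning(
                    "survey selected rank %d but scoring uses rank %d "
                    "(two-group scoring is rank-2 only)",
                    survey.selected_rank, config.score_rank,
                )

        # --- scoring ------------------------------------------------------
        res2 = consensus_run(
            matrix, rank=config.score_rank, n_runs=config.n_runs,
            base_seed=score_seed, max_iter=config.max_iter, tol=config.tol,
        )
        labeling = label_clusters(
            assign_clusters(res2.best_run), labels, sample_ids=matrix.sample_ids
        )
        scores = score_genes(res2.best_run, labeling, gene_ids=matrix.gene_ids)
        scores.to_csv(out / "gene_scores.tsv", sep="\t", index=False,
                      float_format="%.10g")
        with open(out / "labeling.json", "w") as fh:
            json.dump(labeling.to_dict(), fh, indent=1)
        logger.info("disease cluster %d, precision %.4f",
                    labeling.disease_cluster, labeling.precision)

        # --- DEG comparison -----------------------------------------------
        if config.de_table:
            de_table = io.read_de_table(_require_file(config.de_table, "DE table"))
        else:
            de_table = simple_de_test(matrix, labels)
        de_table.to_csv(out / "de_table.tsv", sep="\t", index=False,
                        float_format="%.10g")
        specs = (parse_threshold_specs(config.specs) if config.specs
                 else list(DEFAULT_THRESHOLD_GRID))
        N = config.universe_size or matrix.n_genes
        report = matched_comparison(scores, de_table, specs, reference, N)
        report.to_frame().to_csv(out / "enrichment_table.tsv", sep="\t",
                                 index=False, float_format="%.10g")
        summary = {
            "n_genes": matrix.n_genes,
            "n_samples": matrix.n_samples,
            "universe_size": N,
            "reference_size": report.G,
            "precision": labeling.precision,
            "disease_cluster": labeling.disease_cluster,
            "mean_ratio_deg": report.mean_ratio_deg,
            "mean_ratio_nmf": report.mean_ratio_nmf,
            "t_test_p": report.t_test_p,
            "seed": config.seed,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        logger.info("mean enrichment ratio DEG %.3f vs NMF %.3f (p=%.4g)",
                    report.mean_ratio_deg, report.mean_ratio_nmf, report.t_test_p)
        return report
    except (InputError, ComputationError):
        raise
    except Exception as exc:  # computation failures get a stage-tagged error
        raise ComputationError(f"pipeline computation failed: {exc}") from exc
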