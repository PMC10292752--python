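"""Enrichment-ratio benchmarking of ranked gene lists against a reference set.

For a selected list of ``n`` genes of which ``g`` belong to a reference set
of size ``G`` drawn from a universe of ``N`` genes, the enrichment ratio is

    ER = (g / n) / (G / N)

i.e. the over-representation of the reference set relative to chance.  A
grid of DEG significance thresholds (adjusted p and |log2 fold-change|)
defines list sizes ``n``; for each threshold the top-``n`` NMF-scored genes
are compared at matched ``n``, and the two ratio columns are summarized by
their means and Welch's unequal-variance t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DISEASE, NORMAL
from .matrix import SCALE_LOG2, ExpressionMatrix, normalize_gene_id
from .scoring import _labels_per_sample, top_genes


@dataclass(frozen=True)
class ThresholdSpec:
    """A DEG significance threshold: adjusted p < ``max_adjusted_p`` and,
    when set, |log2FC| > ``min_abs_logfc`` (both strict, matching the usual
    "<" / ">" convention)."""

    max_adjusted_p: float
    min_abs_logfc: float | None = None

    def __post_init__(self):
        if not 0.0 < self.max_adjusted_p <= 1.0:
            raise ValueError("max_adjusted_p must be in (0, 1]")
        if self.min_abs_logfc is not None and self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")

    def __str__(self) -> str:
        base = f"FDR<{self.max_adjusted_p:g}"
        if self.min_abs_logfc is not None:
            base += f" & |logFC|>{self.min_abs_logfc:g}"
        return base


#: The standard 8-threshold grid.
DEFAULT_THRESHOLD_GRID: tuple[ThresholdSpec, ...] = (
    ThresholdSpec(0.05),
    ThresholdSpec(0.05, 1.0),
    ThresholdSpec(0.01),
    ThresholdSpec(0.01, 1.0),
    ThresholdSpec(0.05, 0.5),
    ThresholdSpec(0.05, 1.5),
    ThresholdSpec(0.01, 0.5),
    ThresholdSpec(0.01, 1.5),
)


def parse_threshold_specs(text: str) -> list[ThresholdSpec]:
    """Parse a ``"0.05:;0.05:1;0.01:0.5"``-style grid string."""
    specs = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        p_part, _, f_part = chunk.partition(":")
        specs.append(
            ThresholdSpec(float(p_part), float(f_part) if f_part.strip() else None)
        )
    if not specs:
        raise ValueError(f"no threshold specs in {text!r}")
    return specs


def filter_de_table(de_table: pd.DataFrame, spec: ThresholdSpec) -> list[str]:
    """Genes passing a significance threshold, in table order."""
    mask = de_table["adj_p"] < spec.max_adjusted_p
    if spec.min_abs_logfc is not None:
        mask &= de_table["logFC"].abs() > spec.min_abs_logfc
    return de_table.loc[mask, "gene"].astype(str).tolist()


def enrichment_ratio(g: int, n: int, G: int, N: int) -> float:
    """Enrichment ratio ``(g/n) / (G/N)`` of a selected gene list."""
    if n < 1 or G < 1 or N < 1:
        raise ValueError("n, G and N must be >= 1")
    if g < 0 or g > min(n, G):
        raise ValueError(f"g must be in [0, min(n, G)] = [0, {min(n, G)}], got {g}")
    if n > N or G > N:
        raise ValueError("n and G cannot exceed the universe size N")
    return (g / n) / (G / N)


def overlap_count(list_a, reference) -> int:
    """Size of the intersection of two gene lists under id normalization."""
    a = {normalize_gene_id(g) for g in list_a}
    b = {normalize_gene_id(g) for g in reference}
    return len(a & b)


@dataclass
class EnrichmentRow:
    threshold: ThresholdSpec
    n: int
    g_deg: int
    ratio_deg: float
    g_nmf: int
    ratio_nmf: float
    excluded: bool = False


@dataclass
class EnrichmentReport:
    """Per-threshold DEG-vs-NMF enrichment ratios plus the summary comparison."""

    rows: list[EnrichmentRow]
    G: int
    N: int
    mean_ratio_deg: float = field(default=float("nan"))
    mean_ratio_nmf: float = field(default=float("nan"))
    t_test_p: float = field(default=float("nan"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": [str(r.threshold) for r in self.rows],
                "n": [r.n for r in self.rows],
                "g_deg": [r.g_deg for r in self.rows],
                "ratio_deg": [r.ratio_deg for r in self.rows],
                "g_nmf": [r.g_nmf for r in self.rows],
                "ratio_nmf": [r.ratio_nmf for r in self.rows],
                "excluded": [r.excluded for r in self.rows],
            }
        )


def _summarize(report: EnrichmentReport) -> EnrichmentReport:
    used = [r for r in report.rows if not r.excluded]
    if used:
        deg = np.array([r.ratio_deg for r in used])
        nmf = np.array([r.ratio_nmf for r in used])
        report.mean_ratio_deg = float(deg.mean())
        report.mean_ratio_nmf = float(nmf.mean())
        if len(used) >= 2 and (np.ptp(deg) > 0 or np.ptp(nmf) > 0):
            report.t_test_p = float(
                stats.ttest_ind(nmf, deg, equal_var=False).pvalue
            )
        else:
            warnings.warn("degenerate ratio columns: t-test undefined",
                          UserWarning, stacklevel=3)
    return report


def report_from_counts(
    counts: list[tuple[ThresholdSpec | str, int, int, int]], G: int, N: int
) -> EnrichmentReport:
    """Build a report from per-threshold overlap counts ``(spec, n, g_deg,
    g_nmf)`` — e.g. when replaying published tables — recomputing every ratio
    and the summary statistics."""
    rows = [
        EnrichmentRow(
            threshold=spec, n=n,
            g_deg=g_deg, ratio_deg=enrichment_ratio(g_deg, n, G, N),
            g_nmf=g_nmf, ratio_nmf=enrichment_ratio(g_nmf, n, G, N),
        )
        for spec, n, g_deg, g_nmf in counts
    ]
    return _summarize(EnrichmentReport(rows=rows, G=G, N=N))


def matched_comparison(
    score_table: pd.DataFrame,
    de_table: pd.DataFrame,
    specs,
    reference,
    N: int,
) -> EnrichmentReport:
    """Compare DEG threshold lists with matched-size top NMF lists.

    For each threshold: ``n`` is the DEG list size, the DEG ratio uses the
    overlap of that list with the reference set, and the NMF ratio uses the
    top-``n`` genes of the score table.  Thresholds yielding ``n == 0`` are
    flagged and excluded from the means with a warning; ``n`` larger than
    the score table is capped with a warning.  Means use unrounded ratios;
    the two ratio columns are compared by Welch's t-test.
    """
    ref = list(reference)
    G = len({normalize_gene_id(g) for g in ref})
    rows: list[EnrichmentRow] = []
    for spec in specs:
        deg_genes = filter_de_table(de_table, spec)
        n = len(deg_genes)
        if n == 0:
            warnings.warn(f"threshold {spec} selected no genes; row excluded",
                          UserWarning, stacklevel=2)
            rows.append(EnrichmentRow(spec, 0, 0, float("nan"), 0, float("nan"),
                                      excluded=True))
            continue
        n_top = n
        if n_top > len(score_table):
            warnings.warn(
                f"threshold {spec}: n={n} exceeds score table "
                f"({len(score_table)} genes); capping", UserWarning, stacklevel=2,
            )
            n_top = len(score_table)
        g_deg = overlap_count(deg_genes, ref)
        g_nmf = overlap_count(top_genes(score_table, n_top), ref)
        rows.append(
            EnrichmentRow(
                threshold=spec, n=n,
                g_deg=g_deg, ratio_deg=enrichment_ratio(g_deg, n, G, N),
                g_nmf=g_nmf, ratio_nmf=enrichment_ratio(g_nmf, n_top, G, N),
            )
        )
    return _summarize(EnrichmentReport(rows=rows, G=G, N=N))


def simple_de_test(m: ExpressionMatrix, labels) -> pd.DataFrame:
    """Per-gene two-group Welch t-test with Benjamini-Hochberg correction.

    A convenience differential-expression comparator, NOT limma-voom: on the
    ``log2(x + 1)`` scale (applied unless the matrix is already log2),
    ``logFC`` is mean(disease) - mean(normal) and the p-value is Welch's
    unequal-variance two-sample t-test, BH-adjusted across genes.  Genes with
    zero variance in both groups get p = 1 and are flagged with a warning.

    Returns a DataFrame with columns ``gene``, ``logFC``, ``p``, ``adj_p``.
    """
    groups = _labels_per_sample(labels, m.sample_ids)
    dis = np.array([g == DISEASE for g in groups])
    if dis.sum() < 2 or (~dis).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    X = m.values
    if m.scale_tag != SCALE_LOG2:
        X = np.log2(X + 1.0)
    a, b = X[:, dis], X[:, ~dis]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance genes assigned p = 1",
            UserWarning, stacklevel=2,
        )
        p[degenerate] = 1.0
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"gene": m.gene_ids, "logFC": logfc, "p": p, "adj_p": adj}
    )
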