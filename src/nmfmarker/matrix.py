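"""Expression-matrix container and preprocessing.

The central object is :class:`ExpressionMatrix`, a validated non-negative
gene-by-sample matrix with an explicit scale tag (``counts``, ``tpm`` or
``log2_tpm_plus1``).  Preprocessing follows the standard bulk RNA-seq recipe:
length-normalised TPM, ``log2(TPM + 1)`` rescaling, and removal of genes not
expressed in a minimum number of samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_COUNTS = "counts"
SCALE_TPM = "tpm"
SCALE_LOG2 = "log2_tpm_plus1"
VALID_SCALES = (SCALE_COUNTS, SCALE_TPM, SCALE_LOG2)


def normalize_gene_id(gene_id: str) -> str:
    """Normalize a gene identifier for cross-file matching.

    Identifiers are stripped of surrounding whitespace and case-folded so
    that e.g. mouse symbol ``Lyz2`` matches ``LYZ2`` from a human-centric
    reference list.
    """
    return str(gene_id).strip().casefold()


def _check_unique(ids, what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen[i] = seen.get(i, 0) + 1
    if dupes:
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dupes))}")


@dataclass
class ExpressionMatrix:
    """A non-negative gene-by-sample expression matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes as rows (index = gene identifiers), samples as columns.
    scale_tag : str
        One of ``counts``, ``tpm``, ``log2_tpm_plus1``.
    """

    data: pd.DataFrame
    scale_tag: str = SCALE_TPM

    def __post_init__(self) -> None:
        if self.scale_tag not in VALID_SCALES:
            raise ValueError(
                f"scale_tag must be one of {VALID_SCALES}, got {self.scale_tag!r}"
            )
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(list(self.data.index), "gene")
        _check_unique(list(self.data.columns), "sample")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.isnan(values).any():
            rows, cols = np.nonzero(np.isnan(values))
            raise ValueError(
                "missing values at "
                f"{[(self.data.index[r], self.data.columns[c]) for r, c in zip(rows[:5], cols[:5])]}"
            )
        if (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            raise ValueError(
                "negative entries at "
                f"{[(self.data.index[r], self.data.columns[c]) for r, c in zip(rows[:5], cols[:5])]}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray, scale_tag: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns),
            scale_tag=scale_tag,
        )


def tpm_transform(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Convert raw read counts to transcripts per million (TPM).

    For each sample, ``rate_i = count_i / (length_i / 1000)`` and
    ``TPM_i = rate_i / sum_j rate_j * 1e6``.  Non-degenerate columns of the
    result sum to one million; all-zero columns stay all-zero and trigger a
    warning.

    Parameters
    ----------
    counts : ExpressionMatrix
        Raw counts (``scale_tag == "counts"``).
    gene_lengths : mapping of gene id to length in bases
        Must cover every gene in ``counts``; lengths must be positive.
    """
    if counts.scale_tag != SCALE_COUNTS:
        raise ValueError(f"expected counts matrix, got scale_tag={counts.scale_tag!r}")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing[:10]}")
    lengths = np.array([float(gene_lengths[g]) for g in counts.gene_ids])
    if (lengths <= 0).any():
        bad = [g for g, L in zip(counts.gene_ids, lengths) if L <= 0]
        raise ValueError(f"non-positive gene lengths for: {bad[:10]}")

    rate = counts.values / (lengths[:, None] / 1000.0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        warnings.warn(
            f"all-zero sample columns left as zero: "
            f"{[counts.sample_ids[i] for i in np.nonzero(zero_cols)[0]]}",
            UserWarning,
            stacklevel=2,
        )
    safe = np.where(zero_cols, 1.0, colsum)
    tpm = rate / safe[None, :] * 1e6
    tpm[:, zero_cols] = 0.0
    return counts.with_values(tpm, SCALE_TPM)


def log2_rescale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise ``log2(x + 1)`` rescaling of a TPM matrix."""
    if m.scale_tag != SCALE_TPM:
        raise ValueError(f"expected tpm matrix, got scale_tag={m.scale_tag!r}")
    return m.with_values(np.log2(m.values + 1.0), SCALE_LOG2)


def filter_low_expression(m: ExpressionMatrix, min_samples: int = 5) -> ExpressionMatrix:
    """Keep genes expressed (value strictly > 0) in at least ``min_samples`` samples.

    The sample set is unchanged.  Idempotent.  The number of removed genes is
    logged at INFO level.
    """
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    n_positive = (m.values > 0).sum(axis=1)
    keep = n_positive >= min_samples
    removed = int((~keep).sum())
    logger.info(
        "filter_low_expression: removed %d of %d genes (min_samples=%d)",
        removed, m.n_genes, min_samples,
    )
    return ExpressionMatrix(m.data.loc[keep], scale_tag=m.scale_tag)
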