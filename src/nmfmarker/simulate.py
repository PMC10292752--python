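"""Synthetic two-group expression data with planted marker structure.

The generator emulates a bulk RNA-seq case/control design (disease vs
normal) through a planted rank-2 factorization ``A = noise(W_true H_true)``:

* ``H_true`` has a two-block structure — each sample predominantly expresses
  either the normal or the disease metagene.  ``mislabel_fraction`` blends
  in ambiguous samples on both sides (disease-labeled samples with a
  normal-like profile and vice versa), emulating cohorts where the disease
  phenotype is not yet fully expressed.
* ``W_true`` plants the ground truth where the basis-matrix gene score
  looks: marker (reference) genes receive high baseline weights in both
  metagenes (disease-associated genes tend to be well expressed in the
  affected tissue) and a multiplicative elevation ``marker_effect`` in the
  disease metagene.  A fraction of markers (``null_marker_fraction``) keeps
  effect 1 — disease-associated but with negligible fold change, the kind
  of gene a hard DEG threshold cannot see.
* ``n_bystander_genes`` non-marker genes receive strong disease-metagene
  fold changes (secondary/downstream expression shifts); they are
  differentially expressed but not part of the reference set, so DEG
  threshold lists are diluted the way real reference-set benchmarks are.

Noise is multiplicative gamma (mean 1, continuous, TPM-like) by default;
Poisson sampling gives count-like data.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import simple_de_test
from .io import DISEASE, NORMAL
from .matrix import SCALE_COUNTS, SCALE_TPM, ExpressionMatrix

NOISE_MODELS = ("gamma", "poisson", "none")


@dataclass
class SyntheticSpec:
    """Parameters of the planted two-group design.

    Defaults mirror a mid-sized two-group bulk RNA-seq cohort with a
    reference set of 50 planted markers at a three-fold disease elevation
    and 10% multiplicative noise.
    """

    n_genes: int = 2000
    n_samples: int = 60
    n_disease_samples: int = 20
    n_marker_genes: int = 50
    marker_effect: float = 3.0
    noise_model: str = "gamma"
    noise_scale: float = 0.1
    mislabel_fraction: float = 0.0
    seed: int = 0
    # Marker realism: disease genes are well expressed in the affected
    # tissue, and a fraction shows no fold change at all.
    marker_baseline_boost: float = 4.0
    null_marker_fraction: float = 0.4
    # Non-reference genes with genuine secondary fold changes.
    n_bystander_genes: int = 200
    bystander_logfc_shape: float = 2.0
    bystander_logfc_scale: float = 0.6
    bystander_down_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_marker_genes > self.n_genes:
            raise ValueError("n_marker_genes must be <= n_genes")
        if not 0 < self.n_disease_samples < self.n_samples:
            raise ValueError("need 0 < n_disease_samples < n_samples")
        if self.marker_effect < 1:
            raise ValueError("marker_effect must be >= 1")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if not 0.0 <= self.mislabel_fraction < 1.0:
            raise ValueError("mislabel_fraction must be in [0, 1)")
        if not 0.0 <= self.null_marker_fraction <= 1.0:
            raise ValueError("null_marker_fraction must be in [0, 1]")
        if self.n_marker_genes + self.n_bystander_genes > self.n_genes:
            raise ValueError("markers + bystanders exceed n_genes")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    matrix: ExpressionMatrix
    labels: dict[str, str]
    markers: list[str]          # the planted reference set
    de_markers: list[str]       # markers with a real disease elevation
    bystanders: list[str]       # non-reference genes with real fold changes
    ambiguous_samples: list[str]
    spec: SyntheticSpec

    def ground_truth(self) -> dict:
        return {
            "markers": self.markers,
            "de_markers": self.de_markers,
            "bystanders": self.bystanders,
            "ambiguous_samples": self.ambiguous_samples,
            "spec": asdict(self.spec),
        }

    def write_ground_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.ground_truth(), fh, indent=1)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Build the planted dataset; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_g, n_s, n_d = spec.n_genes, spec.n_samples, spec.n_disease_samples
    gene_ids = [f"g{i:05d}" for i in range(n_g)]
    sample_ids = [f"s{j:03d}" for j in range(n_s)]

    # TPM-like heavy-tailed baseline expression.
    baseline = rng.lognormal(mean=1.5, sigma=1.2, size=n_g)

    order = rng.permutation(n_g)
    marker_idx = order[: spec.n_marker_genes]
    bystander_idx = order[spec.n_marker_genes:
                          spec.n_marker_genes + spec.n_bystander_genes]
    baseline[marker_idx] *= spec.marker_baseline_boost

    # W_true: column 0 = normal metagene, column 1 = disease metagene.
    W = np.column_stack([baseline, baseline.copy()])
    n_null = int(round(spec.null_marker_fraction * spec.n_marker_genes))
    de_marker_idx = marker_idx[n_null:]
    W[de_marker_idx, 1] *= spec.marker_effect

    if len(bystander_idx):
        mag = rng.gamma(spec.bystander_logfc_shape,
                        spec.bystander_logfc_scale, size=len(bystander_idx))
        sign = np.where(rng.uniform(size=len(bystander_idx))
                        < spec.bystander_down_fraction, -1.0, 1.0)
        W[bystander_idx, 1] *= 2.0 ** (sign * mag)

    # H_true: block structure with per-sample activity jitter; a fraction of
    # samples on each side carries the other group's profile (ambiguous
    # phenotype), so cluster composition can be impure in both directions.
    cross = 0.04
    is_disease = np.zeros(n_s, dtype=bool)
    is_disease[:n_d] = True
    profile_disease = is_disease.copy()
    flip_d = int(round(spec.mislabel_fraction * n_d))
    flip_n = int(round(spec.mislabel_fraction * (n_s - n_d)))
    flipped = []
    if flip_d:
        idx = rng.choice(np.nonzero(is_disease)[0], size=flip_d, replace=False)
        profile_disease[idx] = False
        flipped.extend(idx.tolist())
    if flip_n:
        idx = rng.choice(np.nonzero(~is_disease)[0], size=flip_n, replace=False)
        profile_disease[idx] = True
        flipped.extend(idx.tolist())

    activity = rng.uniform(0.8, 1.2, size=n_s)
    H = np.empty((2, n_s))
    H[0] = np.where(profile_disease, cross, activity)
    H[1] = np.where(profile_disease, activity, cross)

    A = W @ H
    if spec.noise_model == "gamma" and spec.noise_scale > 0:
        cv2 = spec.noise_scale**2
        A = A * rng.gamma(shape=1.0 / cv2, scale=cv2, size=A.shape)
        tag = SCALE_TPM
    elif spec.noise_model == "poisson":
        A = rng.poisson(A).astype(float)
        tag = SCALE_COUNTS
    else:
        tag = SCALE_TPM

    matrix = ExpressionMatrix(
        pd.DataFrame(A, index=gene_ids, columns=sample_ids), scale_tag=tag
    )
    labels = {
        s: (DISEASE if d else NORMAL) for s, d in zip(sample_ids, is_disease)
    }
    return SyntheticDataset(
        matrix=matrix,
        labels=labels,
        markers=sorted(gene_ids[i] for i in marker_idx),
        de_markers=sorted(gene_ids[i] for i in de_marker_idx),
        bystanders=sorted(gene_ids[i] for i in bystander_idx),
        ambiguous_samples=sorted(sample_ids[i] for i in flipped),
        spec=spec,
    )


def generate_de_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """Differential-expression table for a generated dataset (Welch t + BH
    via :func:`nmfmarker.enrichment.simple_de_test`)."""
    return simple_de_test(dataset.matrix, dataset.labels)
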