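"""Projection of perturbed transcriptomes onto a developmental axis.

A developmental reference study (e.g. liver maturation stages) defines the
axis: after a location-only, reference-anchored batch adjustment — each
study's control condition is matched to the reference's adult stage — PCA in
covariance form (no unit-variance scaling) is fitted on the reference
samples alone, and all other samples are projected as supplementary
individuals onto the first principal component. The sign convention puts
the reference's adult samples at positive coordinates, so lower PC1 values
read as less mature (dedifferentiated) states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BatchedExpression",
    "Projection",
    "combine_studies",
    "align_batches",
    "fit_project",
]


@dataclass
class BatchedExpression:
    """A pooled genes x samples matrix with batch/condition annotations.

    ``anchor_condition_map`` names, per batch, the condition treated as
    equivalent to the reference batch's adult stage (for the reference batch
    itself, its adult-stage label).
    """

    matrix: pd.DataFrame
    batch: Mapping[str, str]
    condition: Mapping[str, str]
    reference_batch: str
    anchor_condition_map: Mapping[str, str]

    def __post_init__(self) -> None:
        batches = {self.batch[s] for s in self.matrix.columns}
        if self.reference_batch not in batches:
            raise ValueError(f"reference batch {self.reference_batch!r} absent")
        missing = batches - set(self.anchor_condition_map)
        if missing:
            raise ValueError(f"batches without an anchor condition: {sorted(missing)}")

    def samples_of(self, batch: str) -> list[str]:
        return [s for s in self.matrix.columns if self.batch[s] == batch]

    def anchor_samples_of(self, batch: str) -> list[str]:
        anchor = self.anchor_condition_map[batch]
        return [s for s in self.samples_of(batch) if self.condition[s] == anchor]


@dataclass
class Projection:
    pc1_loadings: pd.Series  # unit-norm, per gene
    pc1_var_fraction: float
    coords: pd.Series  # per sample
    orientation: int  # +1 (unchanged) or -1 (flipped)


def combine_studies(studies: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Column-concatenate studies on their common genes.

    Genes missing from any study are dropped, with a warning when the
    intersection loses genes.
    """
    common: pd.Index | None = None
    for df in studies.values():
        common = df.index if common is None else common.intersection(df.index)
    assert common is not None
    n_total = max(len(df.index) for df in studies.values())
    if len(common) < n_total:
        warnings.warn(
            f"dropping {n_total - len(common)} genes absent from some study",
            stacklevel=2,
        )
    return pd.concat([df.loc[common] for df in studies.values()], axis=1)


def align_batches(be: BatchedExpression, eb_shrink: bool = False) -> pd.DataFrame:
    """Location-only batch adjustment anchored on matched conditions.

    Per gene, every non-reference batch is shifted so the mean of its
    anchor-condition samples equals the mean of the reference batch's
    anchor-stage samples; the reference batch is returned unchanged.
    ``eb_shrink`` applies empirical-Bayes shrinkage of the per-gene shifts
    toward the batch-wide mean shift (normal prior, method-of-moments
    hyperparameters); off by default.
    """
    batches = sorted({be.batch[s] for s in be.matrix.columns})
    if len(batches) < 2:
        raise ValueError("need at least two batches to adjust")
    ref_anchor = be.anchor_samples_of(be.reference_batch)
    if not ref_anchor:
        raise ValueError("reference batch lacks anchor-condition samples")
    ref_means = be.matrix[ref_anchor].mean(axis=1)

    corrected = be.matrix.copy()
    for b in batches:
        if b == be.reference_batch:
            continue
        anchors = be.anchor_samples_of(b)
        if not anchors:
            raise ValueError(f"batch {b!r} has no anchor-condition samples")
        shift = ref_means - be.matrix[anchors].mean(axis=1)
        if eb_shrink:
            shift = _shrink_shifts(be, b, anchors, ref_anchor, shift)
        cols = be.samples_of(b)
        corrected[cols] = be.matrix[cols].add(shift, axis=0)
    return corrected


def _shrink_shifts(
    be: BatchedExpression,
    batch: str,
    anchors: list[str],
    ref_anchor: list[str],
    shift: pd.Series,
) -> pd.Series:
    """Normal-prior shrinkage of per-gene shifts toward their mean.

    Posterior mean with prior N(mean shift, tau^2) and per-gene sampling
    variance estimated from the anchor replicates (pooled when a batch has a
    single anchor sample); tau^2 by method of moments.
    """
    def _noise(cols: list[str]) -> float:
        if len(cols) < 2:
            return float(be.matrix.to_numpy().var(ddof=1))
        return float(be.matrix[cols].var(axis=1, ddof=1).mean())

    se2 = _noise(ref_anchor) / max(len(ref_anchor), 1) + _noise(anchors) / max(
        len(anchors), 1
    )
    tau2 = max(float(shift.var(ddof=1)) - se2, 0.0)
    if se2 + tau2 == 0:
        return shift
    b_weight = se2 / (se2 + tau2)  # in [0, 1]
    return (1 - b_weight) * shift + b_weight * float(shift.mean())


def fit_project(corrected: pd.DataFrame, be: BatchedExpression) -> Projection:
    """Covariance-form PCA on the reference batch; others as supplementary.

    The first principal component is fitted on reference-batch samples only
    (centered by reference gene means, no unit-variance scaling).
    Non-reference samples are centered by the same gene means and projected
    onto the PC1 loadings. Orientation is flipped if needed so that the
    reference's adult (anchor-stage) samples average a positive coordinate.
    """
    ref_cols = be.samples_of(be.reference_batch)
    if len(ref_cols) < 3:
        raise ValueError("reference batch needs at least 3 samples")
    X = corrected[ref_cols].to_numpy(dtype=float).T  # samples x genes
    gene_means = X.mean(axis=0)
    Xc = X - gene_means
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0 or np.allclose(Xc, 0):
        raise ValueError("reference samples are not distinct; PC1 undefined")
    loadings = vt[0]
    var_fraction = float(s[0] ** 2 / np.sum(s**2))

    all_cols = list(corrected.columns)
    A = corrected[all_cols].to_numpy(dtype=float).T - gene_means
    coords = A @ loadings

    orientation = 1
    adult = be.anchor_samples_of(be.reference_batch)
    adult_idx = [all_cols.index(s_) for s_ in adult]
    if adult_idx and float(np.mean(coords[adult_idx])) < 0:
        orientation = -1
        loadings = -loadings
        coords = -coords
    return Projection(
        pc1_loadings=pd.Series(loadings, index=corrected.index, name="pc1_loading"),
        pc1_var_fraction=var_fraction,
        coords=pd.Series(coords, index=all_cols, name="pc1_coord"),
        orientation=orientation,
    )
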