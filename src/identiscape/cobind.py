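"""Transcription-factor co-binding stratification and cistrome enrichment.

Enhancers are scored for occupancy by each TF cistrome (>= 1 bp overlap),
giving a binary enhancer x TF matrix. Enhancers are then split by binding of
a focal TF and by the number of additionally co-bound TFs, and each stratum
is summarized by the percentage of its enhancers falling in inactivated
(DOWN) regions. Cistrome enrichment within region classes is quantified with
2x2 Fisher tables and Haldane-corrected log odds ratios, and the resulting
log-odds matrix is clustered hierarchically (Euclidean distance, Ward /
ward.D2 linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .intervals import GenomicInterval, overlap_any

__all__ = [
    "BindingMatrix",
    "EnrichmentCell",
    "build_binding_matrix",
    "cobinding_strata_fraction",
    "overlap_enrichment",
    "cluster_enrichment",
]


@dataclass
class BindingMatrix:
    enhancer_ids: list[str]
    tf_names: list[str]
    occupancy: np.ndarray  # (n_enhancers, n_tfs), values in {0, 1}

    def degree(self, exclude: str | None = None) -> np.ndarray:
        """Number of bound TFs per enhancer, optionally excluding one TF."""
        occ = self.occupancy
        if exclude is not None:
            j = self.tf_names.index(exclude)
            occ = np.delete(occ, j, axis=1)
        return occ.sum(axis=1)


@dataclass
class EnrichmentCell:
    query_set: str
    region_class: str
    log_odds: float
    pvalue: float
    counts: tuple[tuple[int, int], tuple[int, int]]


def build_binding_matrix(
    enhancers: Sequence[GenomicInterval],
    cistromes: Mapping[str, Sequence[GenomicInterval]],
) -> BindingMatrix:
    """occupancy[e, t] = 1 iff enhancer e overlaps any site of TF t (>=1 bp)."""
    tf_names = list(cistromes)
    if len(set(tf_names)) != len(tf_names):
        raise ValueError("duplicate TF names")
    if not tf_names:
        raise ValueError("need at least one TF cistrome")
    occ = np.zeros((len(enhancers), len(tf_names)), dtype=np.int8)
    for j, tf in enumerate(tf_names):
        occ[:, j] = overlap_any(enhancers, cistromes[tf]).astype(np.int8)
    ids = [
        e.name if e.name is not None else f"{e.chrom}:{e.start}-{e.end}"
        for e in enhancers
    ]
    if len(set(ids)) != len(ids):
        raise ValueError("enhancer ids are not unique")
    return BindingMatrix(enhancer_ids=ids, tf_names=tf_names, occupancy=occ)


def cobinding_strata_fraction(
    bm: BindingMatrix,
    enhancers: Sequence[GenomicInterval],
    focal_tf: str,
    down_regions: Sequence[GenomicInterval],
    strata: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Percent of enhancers overlapping DOWN regions, by focal binding x degree.

    Enhancers are split by whether the focal TF binds them, then by the count
    of *additional* bound TFs (focal excluded) falling in each closed integer
    stratum (default [0-2], [3-5], [6-8] for nine TFs). Cell values are
    100 x fraction of the stratum overlapping any DOWN region; empty strata
    are NaN (missing, not zero). Strata must tile 0..n_tfs-1 exactly.
    """
    if focal_tf not in bm.tf_names:
        raise ValueError(f"unknown focal TF {focal_tf!r}")
    n_extra = len(bm.tf_names) - 1
    if strata is None:
        if n_extra == 8:
            strata = [(0, 2), (3, 5), (6, 8)]
        else:
            edges = np.linspace(0, n_extra + 1, 4).astype(int)
            strata = [(int(edges[i]), int(edges[i + 1] - 1)) for i in range(3)]
    covered = sorted(k for lo, hi in strata for k in range(lo, hi + 1))
    if covered != list(range(n_extra + 1)):
        raise ValueError(
            f"strata {strata} do not tile the co-binding range 0..{n_extra}"
        )

    focal_col = bm.occupancy[:, bm.tf_names.index(focal_tf)].astype(bool)
    degree = bm.degree(exclude=focal_tf)
    if degree.max(initial=0) > n_extra:
        raise ValueError("co-binding degree exceeds the top stratum bound")
    in_down = overlap_any(enhancers, down_regions)

    cols = [f"{lo}-{hi}" for lo, hi in strata]
    table = pd.DataFrame(index=["bound", "unbound"], columns=cols, dtype=float)
    for (lo, hi), col in zip(strata, cols):
        for row, sel_focal in (("bound", focal_col), ("unbound", ~focal_col)):
            sel = sel_focal & (degree >= lo) & (degree <= hi)
            n = int(sel.sum())
            table.loc[row, col] = (
                100.0 * in_down[sel].mean() if n else np.nan
            )
    return table


def overlap_enrichment(
    query: Sequence[GenomicInterval],
    target_sets: Mapping[str, Sequence[GenomicInterval]],
    universe: Sequence[GenomicInterval],
    query_name: str = "query",
) -> list[EnrichmentCell]:
    """Fisher-exact enrichment of each target set in query vs rest of universe.

    Universe regions are partitioned into query members (matched by exact
    coordinates) and the rest; each is tested for >= 1 bp overlap with the
    target set, giving the 2x2 table (query&set, query&!set, rest&set,
    rest&!set). log_odds is the natural log of the odds ratio with Haldane's
    +0.5 applied to every cell iff any cell is zero; the p-value is always
    from the uncorrected exact test.
    """
    if not universe:
        raise ValueError("empty universe")
    key = lambda iv: (iv.chrom, iv.start, iv.end)  # noqa: E731
    query_keys = {key(iv) for iv in query}
    in_query = np.asarray([key(iv) in query_keys for iv in universe])
    cells: list[EnrichmentCell] = []
    for name, regions in target_sets.items():
        hit = overlap_any(universe, regions)
        a = int(np.sum(in_query & hit))
        b = int(np.sum(in_query & ~hit))
        c = int(np.sum(~in_query & hit))
        d = int(np.sum(~in_query & ~hit))
        _, p = stats.fisher_exact([[a, b], [c, d]])
        if a + b == 0 or c + d == 0:
            # no contrast between query and rest (e.g. query = universe)
            lo = 0.0
        elif min(a, b, c, d) == 0:
            lo = float(np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))))
        else:
            lo = float(np.log((a * d) / (b * c)))
        cells.append(
            EnrichmentCell(
                query_set=name,
                region_class=query_name,
                log_odds=lo,
                pvalue=float(p),
                counts=((a, b), (c, d)),
            )
        )
    return cells


def cluster_enrichment(
    log_odds: pd.DataFrame, n_clusters: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Hierarchical clustering of log-odds rows (Euclidean, Ward linkage).

    scipy's ``ward`` on raw observations reproduces R hclust's ward.D2
    agglomeration on Euclidean distances. Missing values are imputed as 0
    with a warning. Returns the scipy linkage matrix and flat cluster labels
    (1-based) at the requested cut.
    """
    mat = log_odds.to_numpy(dtype=float, copy=True)
    if mat.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    if np.isnan(mat).any():
        warnings.warn("imputing missing log-odds values as 0", stacklevel=2)
        mat = np.nan_to_num(mat, nan=0.0)
    linkage = hierarchy.linkage(mat, method="ward")
    labels = hierarchy.fcluster(linkage, t=n_clusters, criterion="maxclust")
    return linkage, labels
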