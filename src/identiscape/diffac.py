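"""Differential H3K27ac region classification from bin-level statistics.

The upstream differential engine (window-based count testing) is consumed as
a table of bins with log2 fold change and p-value. Bins are BH-adjusted
genome-wide, labelled UP/DOWN/NS at an FDR threshold, grouped under their
covering acetylation peak (>= 75 bp overlap by default), and each peak's
merged region is classified by the ratio of UP to DOWN bins: UP iff
ratio >= 2, DOWN iff ratio <= 0.5, MIXED in between, UNCHANGED when no bin
is significant. Regions are linked to genes by TSS overlap or a provided
distal-link table, and gene-class association is quantified by odds ratios
against the OTHER gene class.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, TSSRecord, assign_tss

__all__ = [
    "BinStat",
    "DiffRegion",
    "DiffacConfig",
    "bh_adjust",
    "label_bins",
    "group_bins_by_peak",
    "classify_regions",
    "regions_to_genes",
    "direction_class_association",
    "read_bin_table",
]

UP = "UP"
DOWN = "DOWN"
NS = "NS"
MIXED = "MIXED"
UNCHANGED = "UNCHANGED"


@dataclass
class BinStat:
    interval: GenomicInterval
    log2fc: float
    pvalue: float
    fdr: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


@dataclass
class DiffRegion:
    interval: GenomicInterval
    n_up: int
    n_down: int
    direction: str
    peak_id: str


@dataclass(frozen=True)
class DiffacConfig:
    fdr_threshold: float = 0.05
    ratio_up: float = 2.0
    ratio_down: float = 0.5
    min_bin_peak_overlap: int = 75

    def __post_init__(self) -> None:
        if not (self.ratio_down <= 1.0 <= self.ratio_up):
            raise ValueError("need ratio_down <= 1 <= ratio_up")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def label_bins(
    bins: Sequence[BinStat], cfg: DiffacConfig = DiffacConfig()
) -> list[str]:
    """UP iff fdr <= threshold and log2fc > 0; DOWN for log2fc < 0; else NS.

    A significant bin with log2fc exactly 0 has no sign and stays NS.
    """
    labels: list[str] = []
    for b in bins:
        if b.fdr is None:
            raise ValueError("bins must carry FDR; run bh_adjust first")
        if b.fdr <= cfg.fdr_threshold and b.log2fc > 0:
            labels.append(UP)
        elif b.fdr <= cfg.fdr_threshold and b.log2fc < 0:
            labels.append(DOWN)
        else:
            labels.append(NS)
    return labels


def _peak_id(peak: GenomicInterval, i: int) -> str:
    return peak.name if peak.name is not None else f"peak_{i:05d}"


def group_bins_by_peak(
    bins: Sequence[BinStat],
    peaks: Sequence[GenomicInterval],
    cfg: DiffacConfig = DiffacConfig(),
) -> dict[str, list[int]]:
    """Assign bins to covering peaks requiring >= ``min_bin_peak_overlap`` bp.

    Peaks must be non-overlapping (pre-merged). A bin reaching the overlap
    threshold on several peaks goes to the one with the largest overlap
    (tie -> leftmost peak); bins covering no peak at threshold are dropped.
    """
    # verify peaks disjoint per chromosome
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end, i))
    for chrom, triples in by_chrom.items():
        triples.sort()
        for (s1, e1, _), (s2, _, _) in zip(triples, triples[1:]):
            if s2 < e1:
                raise ValueError(
                    f"peaks overlap on {chrom}; merge them before grouping"
                )

    groups: dict[str, list[int]] = {}
    for bi, b in enumerate(bins):
        triples = by_chrom.get(b.interval.chrom)
        if not triples:
            continue
        starts = [t[0] for t in triples]
        # candidate peaks: those starting before the bin ends
        hi = bisect.bisect_left(starts, b.interval.end)
        best: tuple[int, int] | None = None  # (overlap, peak original index)
        for s, e, pi in triples[:hi]:
            ov = min(e, b.interval.end) - max(s, b.interval.start)
            if ov >= cfg.min_bin_peak_overlap:
                # strict > keeps the leftmost peak on ties (triples sorted)
                if best is None or ov > best[0]:
                    best = (ov, pi)
        if best is not None:
            pid = _peak_id(peaks[best[1]], best[1])
            groups.setdefault(pid, []).append(bi)
    return groups


def classify_regions(
    groups: Mapping[str, Sequence[int]],
    bins: Sequence[BinStat],
    bin_labels: Sequence[str],
    cfg: DiffacConfig = DiffacConfig(),
) -> list[DiffRegion]:
    """Classify each peak's merged bins by the UP:DOWN ratio rule.

    With u UP and d DOWN bins: no significant bin -> UNCHANGED; d = 0 with
    u >= 1 -> UP; u = 0 with d >= 1 -> DOWN (the ratio's limit convention);
    otherwise r = u/d gives UP iff r >= ratio_up, DOWN iff r <= ratio_down,
    MIXED in between. The region interval spans min start to max end of the
    member bins. Output order follows sorted peak ids.
    """
    regions: list[DiffRegion] = []
    for pid in sorted(groups):
        idxs = list(groups[pid])
        if not idxs:
            raise ValueError(f"empty bin group for peak {pid}")
        u = sum(bin_labels[i] == UP for i in idxs)
        d = sum(bin_labels[i] == DOWN for i in idxs)
        if u == 0 and d == 0:
            direction = UNCHANGED
        elif d == 0:
            direction = UP
        elif u == 0:
            direction = DOWN
        else:
            r = u / d
            if r >= cfg.ratio_up:
                direction = UP
            elif r <= cfg.ratio_down:
                direction = DOWN
            else:
                direction = MIXED
        chrom = bins[idxs[0]].interval.chrom
        start = min(bins[i].interval.start for i in idxs)
        end = max(bins[i].interval.end for i in idxs)
        regions.append(
            DiffRegion(
                interval=GenomicInterval(chrom, start, end, name=pid),
                n_up=u,
                n_down=d,
                direction=direction,
                peak_id=pid,
            )
        )
    return regions


def run_diffac(
    bins: Sequence[BinStat],
    peaks: Sequence[GenomicInterval],
    cfg: DiffacConfig = DiffacConfig(),
) -> list[DiffRegion]:
    """Bin table to classified regions: BH-adjust, label, group, classify."""
    fdrs = bh_adjust([b.pvalue for b in bins])
    for b, q in zip(bins, fdrs):
        b.fdr = float(q)
    labels = label_bins(bins, cfg)
    groups = group_bins_by_peak(bins, peaks, cfg)
    return classify_regions(groups, bins, labels, cfg)


def regions_to_genes(
    regions: Sequence[DiffRegion],
    tss: Sequence[TSSRecord],
    distal_links: pd.DataFrame | None = None,
) -> dict[str, list[str]]:
    """Link genes to region directions by TSS overlap and distal links.

    ``distal_links`` is a table with columns ``region_id`` and ``gene_id``
    (e.g. a precomputed enhancer-gene link table). Each gene maps to the
    multiset of directions of its linked regions; unlinked genes are absent.
    """
    gene_dirs: dict[str, list[str]] = {}
    hits = assign_tss(tss, [r.interval for r in regions])
    for gene, idxs in hits.items():
        gene_dirs.setdefault(gene, []).extend(regions[i].direction for i in idxs)
    if distal_links is not None:
        known = {r.peak_id: r for r in regions}
        unknown = set(distal_links["region_id"]) - set(known)
        if unknown:
            raise ValueError(
                f"distal link table references unknown region ids: {sorted(unknown)[:5]}"
            )
        for row in distal_links.itertuples(index=False):
            gene_dirs.setdefault(row.gene_id, []).append(
                known[row.region_id].direction
            )
    return gene_dirs


def direction_class_association(
    gene_regions: Mapping[str, Sequence[str]],
    calls: Sequence["IdentityCall"],  # noqa: F821 - identity.IdentityCall
    categories: Sequence[str] = (UP, DOWN, UNCHANGED),
) -> pd.DataFrame:
    """Odds of ID/UBQ genes versus OTHER genes within each region category.

    For each category and gene class c (ID, UBQ), a 2x2 table counts genes of
    class c versus OTHER genes, inside versus outside the category (a gene is
    "in" a category iff at least one linked region has that direction).
    Fisher's exact test p-values are BH-corrected across all rows. Degenerate
    tables (a zero margin) report NaN odds ratio and p-value.
    """
    from .identity import ID as _ID, OTHER as _OTHER, UBQ as _UBQ

    klass_of = {c.gene_id: c.klass for c in calls}
    shared = [g for g in gene_regions if g in klass_of]
    if not shared and gene_regions:
        raise ValueError("gene namespaces of regions and identity calls are disjoint")

    genes_by_class: dict[str, set[str]] = {_ID: set(), _UBQ: set(), _OTHER: set()}
    for g, k in klass_of.items():
        genes_by_class.setdefault(k, set()).add(g)
    in_cat: dict[str, set[str]] = {
        cat: {g for g, dirs in gene_regions.items() if cat in dirs}
        for cat in categories
    }

    rows = []
    for cat in categories:
        for klass in (_ID, _UBQ):
            a = len(genes_by_class[klass] & in_cat[cat])
            b = len(genes_by_class[klass] - in_cat[cat])
            c = len(genes_by_class[_OTHER] & in_cat[cat])
            d = len(genes_by_class[_OTHER] - in_cat[cat])
            if min(a + b, c + d, a + c, b + d) == 0:
                oratio, p = math.nan, math.nan
            else:
                oratio, p = stats.fisher_exact([[a, c], [b, d]])
            rows.append(
                {
                    "category": cat,
                    "klass": klass,
                    "n_class_in": a,
                    "n_class_out": b,
                    "n_other_in": c,
                    "n_other_out": d,
                    "odds_ratio": oratio,
                    "pvalue": p,
                }
            )
    table = pd.DataFrame(rows)
    ok = table["pvalue"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_adjust(table.loc[ok, "pvalue"].to_numpy())
    table["qvalue"] = q
    return table


def read_bin_table(path: str) -> list[BinStat]:
    """Read a bin table TSV with columns chrom, start, end, log2fc, pvalue."""
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "log2fc", "pvalue"}
    if not need.issubset(df.columns):
        raise ValueError(f"bin table must have columns {sorted(need)}")
    return [
        BinStat(
            interval=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            log2fc=float(r.log2fc),
            pvalue=float(r.pvalue),
        )
        for r in df.itertuples(index=False)
    ]
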