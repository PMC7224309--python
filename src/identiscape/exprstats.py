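"""Expression-side statistics of identity loss.

Covers: median-of-ratios size factors for count normalization; global
z-scaling with a bottom-baseline gene filter and scaled log2 fold changes;
Tukey-depth bagplots (bivariate boxplots) for comparing the breadth of
transcriptomic changes; repression-quartile enrichment of gene classes; the
weighted Kolmogorov-Smirnov-style gene-set enrichment running statistic with
gene-set permutations; and per-cell gene-set score projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull

from .diffac import bh_adjust

__all__ = [
    "size_factors",
    "scale_and_fc",
    "tukey_depth",
    "Bagplot",
    "bagplot",
    "QuartileEnrichment",
    "quartile_enrichment",
    "GseaResult",
    "gsea_es",
    "rank_by_class_difference",
    "gene_set_score",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over genes g (restricted to genes with a positive
    geometric mean, i.e. positive counts in every sample) of
    counts[g, j] / geometric_mean_g(counts).
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    positive = np.all(mat > 0, axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    logm = np.log(mat[positive])
    loggeo = logm.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logm - loggeo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def scale_and_fc(
    expr: pd.DataFrame,
    design: Mapping[str, str],
    baseline_cond: str,
    perturbed_cond: str | None = None,
    drop_fraction: float = 0.2,
) -> pd.DataFrame:
    """Baseline-filtered, globally z-scaled log2 fold changes.

    Steps: (1) drop the lowest ``drop_fraction`` of genes ranked by their
    mean baseline-condition expression (ties broken by gene id order);
    (2) z-scale the whole retained matrix with one global mean and one
    global standard deviation (ddof=1) over all retained values;
    (3) scaled_fc = per-gene mean of scaled perturbed samples minus mean of
    scaled baseline samples. Returns a table indexed by gene with columns
    ``baseline`` (unscaled baseline mean), ``raw_fc`` and ``scaled_fc``.
    """
    if not (0 <= drop_fraction < 1):
        raise ValueError("drop_fraction must be in [0, 1)")
    samples = [s for s in expr.columns if s in design]
    conds = {design[s] for s in samples}
    if baseline_cond not in conds:
        raise ValueError(f"baseline condition {baseline_cond!r} absent from design")
    if perturbed_cond is None:
        others = sorted(conds - {baseline_cond})
        if len(others) != 1:
            raise ValueError(
                "perturbed_cond must be given when more than two conditions exist"
            )
        perturbed_cond = others[0]
    base_cols = [s for s in samples if design[s] == baseline_cond]
    pert_cols = [s for s in samples if design[s] == perturbed_cond]

    baseline_mean = expr[base_cols].mean(axis=1)
    n_drop = int(np.floor(drop_fraction * len(expr) + 1e-9))
    order = sorted(expr.index, key=lambda g: (baseline_mean[g], g))
    kept = sorted(order[n_drop:], key=list(expr.index).index)
    sub = expr.loc[kept, base_cols + pert_cols]

    values = sub.to_numpy(dtype=float)
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("zero global standard deviation; cannot scale")
    scaled = (sub - mu) / sd

    out = pd.DataFrame(
        {
            "baseline": baseline_mean.loc[kept],
            "raw_fc": sub[pert_cols].mean(axis=1) - sub[base_cols].mean(axis=1),
            "scaled_fc": scaled[pert_cols].mean(axis=1)
            - scaled[base_cols].mean(axis=1),
        }
    )
    out.attrs["global_mean"] = mu
    out.attrs["global_sd"] = sd
    out.attrs["n_dropped"] = n_drop
    return out


# ---------------------------------------------------------------------------
# Tukey depth & bagplot


def tukey_depth(
    points: np.ndarray,
    max_exact: int = 5000,
    n_directions: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Halfspace (Tukey) depth of every data point, as an integer count.

    depth(p) = min over closed halfplanes with p on the boundary of the
    number of data points (p included) in the halfplane. Exact for
    n <= ``max_exact`` via the angular rotating-halfplane method; larger
    inputs are approximated with ``n_directions`` seeded random directions.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    depths = np.empty(n, dtype=int)
    if n > max_exact:
        rng = np.random.default_rng(seed)
        phis = rng.uniform(0, 2 * np.pi, size=n_directions)
        dirs = np.column_stack([np.cos(phis), np.sin(phis)])
        proj = pts @ dirs.T  # (n, n_directions)
        for i in range(n):
            counts = (proj >= proj[i] - 1e-12).sum(axis=0)
            counts_rev = (proj <= proj[i] + 1e-12).sum(axis=0)
            depths[i] = int(min(counts.min(), counts_rev.min()))
        return depths

    for i in range(n):
        diff = pts - pts[i]
        coincident = np.all(np.abs(diff) == 0, axis=1)
        base = int(coincident.sum())  # includes the point itself
        rest = diff[~coincident]
        m = rest.shape[0]
        if m == 0:
            depths[i] = base
            continue
        beta = np.sort(np.arctan2(rest[:, 1], rest[:, 0]))
        ext = np.concatenate([beta, beta + 2 * np.pi])
        # max count over half-open arcs (t - pi, t]; candidates t at each
        # angle and each angle + pi (where the open-semicircle count jumps)
        cands = np.concatenate([beta + 2 * np.pi, beta + np.pi])
        hi = np.searchsorted(ext, cands, side="right")
        lo = np.searchsorted(ext, cands - np.pi, side="right")
        max_open = int((hi - lo).max())
        depths[i] = base + m - max_open
    return depths


@dataclass
class Bagplot:
    """A bivariate boxplot: depth median, bag and loop polygons, outliers."""

    depth_median: np.ndarray  # (2,)
    bag: np.ndarray  # (k, 2) polygon vertices, counter-clockwise
    loop: np.ndarray  # (k, 2)
    outliers: list[int]
    depths: np.ndarray  # per-point integer Tukey depth
    in_bag: np.ndarray  # boolean mask, inside-or-on the bag


def _polygon_gauge(
    points: np.ndarray, center: np.ndarray, vertices: np.ndarray
) -> np.ndarray:
    """Minkowski gauge of each point w.r.t. a convex polygon about ``center``.

    gauge(p) = ||p - c|| / r where r is the distance from c to the polygon
    boundary along the ray c -> p; gauge <= 1 iff p is inside-or-on.
    """
    out = np.empty(points.shape[0])
    v = vertices - center
    edges = list(zip(v, np.roll(v, -1, axis=0)))
    for i, p in enumerate(points):
        d = p - center
        norm = np.hypot(*d)
        if norm == 0:
            out[i] = 0.0
            continue
        u = d / norm
        r = np.inf
        for a, b in edges:
            e = b - a
            denom = u[0] * (-e[1]) - u[1] * (-e[0])
            if abs(denom) < 1e-300:
                continue
            t = (a[0] * (-e[1]) - a[1] * (-e[0])) / denom
            s_num = u[0] * a[1] - u[1] * a[0]
            s = s_num / denom
            if t > 0 and -1e-12 <= s <= 1 + 1e-12:
                r = min(r, t)
        out[i] = norm / r if np.isfinite(r) else np.inf
    return out


def bagplot(points: np.ndarray, loop_factor: float = 3.0) -> Bagplot:
    """Construct a bagplot from an (n, 2) point cloud.

    The depth median is the deepest point (centroid of the deepest set on
    ties). The bag is the convex hull of the ceil(n/2) deepest points,
    shrunk about the depth median — via the polygon gauge — to the largest
    size at which exactly ceil(n/2) points are inside-or-on (depth ties can
    otherwise leave extra equal-depth points inside the raw hull). The loop
    is the bag inflated by ``loop_factor`` about the depth median; points
    outside the loop are outliers.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points for a bagplot")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError(
            "points are collinear; use a univariate summary instead"
        )
    depths = tukey_depth(pts)
    dmax = depths.max()
    center = pts[depths == dmax].mean(axis=0)

    k = int(np.ceil(n / 2))
    dist = np.hypot(*(pts - center).T)
    order = sorted(range(n), key=lambda i: (-depths[i], dist[i], i))
    selected = np.asarray(order[:k])
    hull = ConvexHull(pts[selected])
    vertices = pts[selected][hull.vertices]

    gauges = _polygon_gauge(pts, center, vertices)
    lam = float(np.sort(gauges)[k - 1])
    if lam <= 0:
        lam = float(np.sort(gauges)[np.sort(gauges) > 0][0]) if (gauges > 0).any() else 1.0
    bag = center + lam * (vertices - center)
    loop = center + loop_factor * lam * (vertices - center)
    tol = 1e-9
    in_bag = gauges <= lam * (1 + tol) + tol
    outliers = [int(i) for i in np.nonzero(gauges > loop_factor * lam * (1 + tol))[0]]
    return Bagplot(
        depth_median=center,
        bag=bag,
        loop=loop,
        outliers=outliers,
        depths=depths,
        in_bag=in_bag,
    )


# ---------------------------------------------------------------------------
# quartile enrichment


@dataclass
class QuartileEnrichment:
    table: pd.DataFrame  # quartile, n, n_id, id_fraction, relative, pvalue, qvalue
    chi2_pvalue: float
    relative_is_absolute: bool  # True when Q1 has no ID genes


def quartile_enrichment(
    fc: pd.DataFrame,
    calls: Sequence["IdentityCall"],  # noqa: F821
    repressed_mask: pd.Series | None = None,
    klass: str = "ID",
) -> QuartileEnrichment:
    """Identity-gene enrichment across repression quartiles.

    Repressed genes (default scaled_fc < 0) are ranked by increasing
    repression, so Q4 holds the most repressed genes; quartiles are
    near-equal with remainder genes going to the earlier quartiles. Each
    quartile's fraction of ``klass`` genes is reported relative to Q1
    (Q1 = 1); when Q1 has no class genes the absolute fractions are returned
    with a flag. A chi-square test of class x quartile summarizes the table;
    per-quartile Fisher tests against Q1 are BH-corrected.
    """
    if repressed_mask is None:
        repressed_mask = fc["scaled_fc"] < 0
    rep = fc.loc[repressed_mask]
    if len(rep) < 4:
        raise ValueError("need at least 4 repressed genes for quartiles")
    klass_of = {c.gene_id: c.klass for c in calls}
    # Q1 = least repressed ... Q4 = most repressed (most negative scaled_fc)
    ordered = rep.sort_values("scaled_fc", ascending=False, kind="stable")
    n = len(ordered)
    base, r = divmod(n, 4)
    sizes = [base + 1] * r + [base] * (4 - r)
    bounds = np.cumsum([0] + sizes)

    rows = []
    is_klass_all = []
    for q in range(4):
        genes = ordered.index[bounds[q] : bounds[q + 1]]
        flags = np.asarray([klass_of.get(g) == klass for g in genes])
        is_klass_all.append(flags)
        rows.append(
            {
                "quartile": f"Q{q + 1}",
                "n": len(genes),
                "n_class": int(flags.sum()),
                "class_fraction": float(flags.mean()) if len(genes) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    q1_frac = table.loc[0, "class_fraction"]
    relative_is_absolute = q1_frac == 0
    table["relative"] = (
        table["class_fraction"]
        if relative_is_absolute
        else table["class_fraction"] / q1_frac
    )

    cont = np.array([[f.sum(), len(f) - f.sum()] for f in is_klass_all]).T
    if cont.min() >= 0 and (cont.sum(axis=0) > 0).all() and cont.sum(axis=1).min() > 0:
        chi2_p = float(stats.chi2_contingency(cont)[1])
    else:
        chi2_p = float("nan")

    pvals = [np.nan]
    for q in range(1, 4):
        t = [
            [int(is_klass_all[q].sum()), int(len(is_klass_all[q]) - is_klass_all[q].sum())],
            [int(is_klass_all[0].sum()), int(len(is_klass_all[0]) - is_klass_all[0].sum())],
        ]
        pvals.append(float(stats.fisher_exact(t)[1]))
    table["pvalue"] = pvals
    qvals = np.full(4, np.nan)
    qvals[1:] = bh_adjust(pvals[1:])
    table["qvalue"] = qvals
    return QuartileEnrichment(
        table=table, chi2_pvalue=chi2_p, relative_is_absolute=bool(relative_is_absolute)
    )


# ---------------------------------------------------------------------------
# GSEA


@dataclass
class GseaResult:
    es: float
    nes: float
    fdr: float
    running_sum: np.ndarray
    perm_es: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def gsea_es(
    ranked: pd.Series,
    gene_set: Iterable[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> GseaResult:
    """Weighted running-sum enrichment score with gene-set permutations.

    ``ranked`` maps genes (index) to the ranking metric, already ordered
    from most positively to most negatively associated. At each hit the sum
    gains |score|^weight / sum over hits of |score|^weight; at each miss it
    loses 1/(N - m). ES is the signed extremum. The null is built from
    ``n_perm`` random same-size gene sets; NES divides ES by the mean
    absolute value of same-sign permutation scores and FDR is the fraction
    of same-sign permutation scores at least as extreme.
    """
    genes = list(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    gs = set(gene_set)
    hit = np.asarray([g in gs for g in genes])
    m = int(hit.sum())
    N = len(genes)
    if m == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if m == N:
        raise ValueError("gene set covers the whole ranked list; ES undefined")

    def _es(hit_mask: np.ndarray) -> tuple[float, np.ndarray]:
        w = np.abs(scores) ** weight
        denom = w[hit_mask].sum()
        steps = np.where(
            hit_mask,
            (w / denom) if denom > 0 else (1.0 / hit_mask.sum()),
            -1.0 / (N - hit_mask.sum()),
        )
        run = np.cumsum(steps)
        i = int(np.argmax(np.abs(run)))
        return float(run[i]), run

    es, running = _es(hit)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        mask = np.zeros(N, dtype=bool)
        mask[rng.choice(N, size=m, replace=False)] = True
        perm[b], _ = _es(mask)
    same_sign = perm[np.sign(perm) == np.sign(es)] if es != 0 else perm
    if same_sign.size:
        nes = es / float(np.mean(np.abs(same_sign)))
        fdr = float(np.mean(np.abs(same_sign) >= abs(es)))
    else:
        nes, fdr = np.nan, 0.0
    return GseaResult(es=es, nes=float(nes), fdr=fdr, running_sum=running, perm_es=perm)


def rank_by_class_difference(
    expr: pd.DataFrame, design: Mapping[str, str], cond_a: str, cond_b: str
) -> pd.Series:
    """Difference-of-classes ranking metric: mean(cond_a) - mean(cond_b).

    Returns genes sorted by descending metric, ready for :func:`gsea_es`.
    """
    a = [s for s in expr.columns if design.get(s) == cond_a]
    b = [s for s in expr.columns if design.get(s) == cond_b]
    if not a or not b:
        raise ValueError("both conditions need at least one sample")
    metric = expr[a].mean(axis=1) - expr[b].mean(axis=1)
    return metric.sort_values(ascending=False, kind="stable")


def gene_set_score(norm_expr: pd.DataFrame, gene_set: Iterable[str]) -> pd.Series:
    """Per-cell (or per-sample) mean normalized expression over a gene set."""
    gs = list(dict.fromkeys(gene_set))
    if not gs:
        raise ValueError("empty gene set")
    missing = [g for g in gs if g not in norm_expr.index]
    if missing:
        raise ValueError(f"gene set members absent from matrix: {missing[:5]}")
    return norm_expr.loc[gs].mean(axis=0).rename("gene_set_score")
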