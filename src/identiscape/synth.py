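"""Synthetic fixtures with the statistical structure each pipeline stage assumes.

Every generator is a pure function of :class:`SynthConfig` (byte-identical
outputs per seed) and emits ground-truth tables alongside the data:

* multi-tissue H3K4me3-like peak sets with planted focal-specific broad
  domains over identity-gene TSS and shared broad domains over
  housekeeping-gene TSS;
* per-peak bin tables with planted UP/DOWN differential-signal regions and
  z-test p-values;
* per-TF cistromes whose co-binding degree carries an exactly logistic link
  to membership in the inactivated (DOWN) region set;
* a developmental reference expression matrix interpolating newborn to
  adult profiles, perturbation studies with planted identity-gene
  repression and batch offsets, partially dedifferentiated samples, and
  Poisson single-cell counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffac import BinStat
from .intervals import GenomicInterval, TSSRecord, write_bed, write_tss

__all__ = [
    "SynthConfig",
    "SynthTissueData",
    "SynthBins",
    "SynthExpression",
    "gen_tissue_peaks",
    "make_peak_grid",
    "gen_bins",
    "gen_cistromes",
    "gen_expression",
    "write_fixture_tree",
]


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic study conditions (see docs/methods.md)."""

    seed: int = 0
    # tissue peak sets
    n_tissues: int = 10
    n_genes: int = 2000
    n_id_genes: int = 200
    n_ubq_genes: int = 200
    n_peaks_per_tissue: int = 3000
    broad_length_factor: float = 5.0
    gene_spacing: int = 50_000
    chrom: str = "chr1"
    peak_length_median: float = 700.0
    peak_length_sigma: float = 0.45
    # differential bins
    n_bins_per_peak: int = 10
    effect_size: float = 1.0
    noise_sd: float = 0.4
    frac_up: float = 0.25
    frac_down: float = 0.25
    # cistromes
    n_tfs: int = 9
    cobind_logistic_slope: float = 1.0
    cobind_base_p: float = 0.35
    # expression
    n_stages: int = 7
    n_reps: int = 2
    dediff_weights: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    dediff_weight: float = 0.5
    n_maturation_genes: int = 400
    maturation_effect: float = 2.0
    expr_noise_sd: float = 0.3
    batch_offset_sd: float = 1.0
    n_induced_genes: int = 200
    n_cells: int = 300

    def __post_init__(self) -> None:
        if self.n_id_genes > self.n_genes:
            raise ValueError("n_id_genes cannot exceed n_genes")
        if self.n_id_genes + self.n_ubq_genes > self.n_genes:
            raise ValueError("identity + ubiquitous gene counts exceed n_genes")
        for name in ("n_tissues", "n_genes", "n_peaks_per_tissue", "n_tfs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _gene_ids(cfg: SynthConfig) -> list[str]:
    return [f"gene_{i:04d}" for i in range(cfg.n_genes)]


def _gene_classes(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, str]:
    """Shuffled ID/UBQ/OTHER assignment; first rng draw of each generator,
    so generators sharing a seed agree on gene classes."""
    genes = _gene_ids(cfg)
    perm = rng.permutation(cfg.n_genes)
    classes = {g: "OTHER" for g in genes}
    for i in perm[: cfg.n_id_genes]:
        classes[genes[i]] = "ID"
    for i in perm[cfg.n_id_genes : cfg.n_id_genes + cfg.n_ubq_genes]:
        classes[genes[i]] = "UBQ"
    return classes


@dataclass
class SynthTissueData:
    peaks: dict[str, list[GenomicInterval]]
    tss: list[TSSRecord]
    truth: dict[str, str]  # gene -> ID/UBQ/OTHER
    focal: str


def gen_tissue_peaks(cfg: SynthConfig) -> SynthTissueData:
    """Multi-tissue peak sets with planted broad identity/housekeeping domains.

    Background peak lengths are lognormal. Broad domains (length =
    ``broad_length_factor`` x the tissue's median background length, jittered
    upward) are planted over identity-gene TSS in the focal tissue only and
    over housekeeping-gene TSS in every tissue, so identity domains are
    focal-specific and housekeeping domains are fully shared.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = _gene_classes(cfg, rng)
    genes = _gene_ids(cfg)
    genome_len = cfg.n_genes * cfg.gene_spacing

    tss = [
        TSSRecord(
            gene_id=g,
            chrom=cfg.chrom,
            position=cfg.gene_spacing // 2 + i * cfg.gene_spacing,
            strand="+" if rng.random() < 0.5 else "-",
        )
        for i, g in enumerate(genes)
    ]
    pos_of = {t.gene_id: t.position for t in tss}
    id_genes = [g for g in genes if classes[g] == "ID"]
    ubq_genes = [g for g in genes if classes[g] == "UBQ"]

    focal = "liver"
    tissues = [focal] + [f"tissue_{i:02d}" for i in range(1, cfg.n_tissues)]
    peaks: dict[str, list[GenomicInterval]] = {}
    for tissue in tissues:
        planted_genes = (id_genes + ubq_genes) if tissue == focal else ubq_genes
        n_bg = max(cfg.n_peaks_per_tissue - len(planted_genes), 1)
        lengths = np.maximum(
            rng.lognormal(
                mean=np.log(cfg.peak_length_median),
                sigma=cfg.peak_length_sigma,
                size=n_bg,
            ).astype(int),
            50,
        )
        starts = rng.integers(0, genome_len - int(lengths.max()), size=n_bg)
        median_bg = float(np.median(lengths))
        planted: list[GenomicInterval] = []
        for g in planted_genes:
            broad_len = int(
                cfg.broad_length_factor * median_bg * rng.uniform(1.0, 1.3)
            )
            broad_len = max(broad_len, 51)
            center = pos_of[g]
            start = max(0, center - broad_len // 2)
            planted.append(GenomicInterval(cfg.chrom, start, start + broad_len))
        background = [
            GenomicInterval(cfg.chrom, int(s), int(s + ln))
            for s, ln in zip(starts, lengths)
        ]
        peaks[tissue] = planted + background
    return SynthTissueData(peaks=peaks, tss=tss, truth=classes, focal=focal)


def make_peak_grid(
    n: int, length: int = 1500, spacing: int = 10_000, chrom: str = "chr1"
) -> list[GenomicInterval]:
    """Named, equal-length, non-overlapping peaks on a regular grid."""
    return [
        GenomicInterval(
            chrom, i * spacing, i * spacing + length, name=f"peak_{i:05d}"
        )
        for i in range(n)
    ]


@dataclass
class SynthBins:
    bins: list[BinStat]
    truth: dict[str, str]  # peak_id -> UP/DOWN/UNCHANGED


def gen_bins(cfg: SynthConfig, peaks: Sequence[GenomicInterval]) -> SynthBins:
    """Bin-level differential statistics with planted UP/DOWN peaks.

    Each peak is tiled with ``n_bins_per_peak`` equal bins. Planted UP/DOWN
    peaks draw bin log2 fold changes from Normal(+-effect_size, noise_sd),
    null peaks from Normal(0, noise_sd); p-values come from the two-sided
    z-test with known standard deviation, so null p-values are uniform.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(peaks)
    n_up = int(round(cfg.frac_up * n))
    n_down = int(round(cfg.frac_down * n))
    perm = rng.permutation(n)
    direction = np.array(["UNCHANGED"] * n, dtype=object)
    direction[perm[:n_up]] = "UP"
    direction[perm[n_up : n_up + n_down]] = "DOWN"

    bins: list[BinStat] = []
    truth: dict[str, str] = {}
    for i, peak in enumerate(peaks):
        pid = peak.name if peak.name is not None else f"peak_{i:05d}"
        truth[pid] = str(direction[i])
        edges = np.linspace(peak.start, peak.end, cfg.n_bins_per_peak + 1).astype(int)
        mean = {"UP": cfg.effect_size, "DOWN": -cfg.effect_size, "UNCHANGED": 0.0}[
            str(direction[i])
        ]
        fcs = rng.normal(mean, cfg.noise_sd, size=cfg.n_bins_per_peak)
        pvals = 2.0 * stats.norm.sf(np.abs(fcs) / cfg.noise_sd)
        for j in range(cfg.n_bins_per_peak):
            if edges[j + 1] <= edges[j]:
                raise ValueError("peak too short for the requested bin count")
            bins.append(
                BinStat(
                    interval=GenomicInterval(
                        peak.chrom, int(edges[j]), int(edges[j + 1])
                    ),
                    log2fc=float(fcs[j]),
                    pvalue=float(min(pvals[j], 1.0)),
                )
            )
    return SynthBins(bins=bins, truth=truth)


def gen_cistromes(
    cfg: SynthConfig,
    enhancers: Sequence[GenomicInterval],
    down_truth: Sequence[bool],
) -> tuple[dict[str, list[GenomicInterval]], np.ndarray]:
    """Per-TF binding-site sets with a logistic degree-inactivation link.

    Co-binding degree k (bound TFs out of ``n_tfs``) is drawn from
    Binomial(n_tfs, p1) for DOWN enhancers and Binomial(n_tfs, p0)
    otherwise, with log[(p1/(1-p1)) / (p0/(1-p0))] = ``cobind_logistic_slope``.
    By the binomial likelihood-ratio identity this makes the log-odds of
    DOWN membership exactly linear in k with that slope. Bound TFs are
    chosen uniformly given k; each site is a 200-bp interval inside the
    enhancer. Returns (cistromes, per-enhancer degrees).
    """
    if len(enhancers) != len(down_truth):
        raise ValueError("down_truth must align with enhancers")
    rng = np.random.default_rng(cfg.seed)
    p0 = cfg.cobind_base_p
    odds1 = (p0 / (1 - p0)) * np.exp(cfg.cobind_logistic_slope)
    p1 = odds1 / (1 + odds1)
    tf_names = [f"TF_{j:02d}" for j in range(cfg.n_tfs)]
    cistromes: dict[str, list[GenomicInterval]] = {t: [] for t in tf_names}
    degrees = np.empty(len(enhancers), dtype=int)
    for i, (enh, down) in enumerate(zip(enhancers, down_truth)):
        k = int(rng.binomial(cfg.n_tfs, p1 if down else p0))
        degrees[i] = k
        bound = rng.choice(cfg.n_tfs, size=k, replace=False)
        width = min(200, enh.length)
        lo = enh.start
        hi = max(enh.end - width, lo + 1)
        for j in np.sort(bound):
            start = int(rng.integers(lo, hi))
            cistromes[tf_names[j]].append(
                GenomicInterval(enh.chrom, start, start + width)
            )
    return cistromes, degrees


@dataclass
class SynthExpression:
    reference: pd.DataFrame  # genes x stage samples
    ref_condition: dict[str, str]
    ref_stage: dict[str, float]  # sample -> maturation s in [0, 1]
    injury: pd.DataFrame  # genes x injury-batch samples
    injury_condition: dict[str, str]
    injury_w: dict[str, float]  # sample -> dedifferentiation weight
    perturb: pd.DataFrame  # genes x ERS-study samples
    perturb_condition: dict[str, str]
    sc_counts: pd.DataFrame  # genes x cells, integer counts
    classes: dict[str, str]
    repressed_genes: list[str]
    induced_genes: list[str]


def gen_expression(cfg: SynthConfig) -> SynthExpression:
    """Developmental reference, perturbation studies and single-cell counts.

    Expression follows b_g + (s - 1) * v_g + noise where s in [0, 1] is the
    maturation stage: identity genes rise with maturation
    (v = +maturation_effect), a planted set of fetal genes falls, other
    genes are flat. The injury batch carries a per-gene batch offset and
    samples at dedifferentiation weights w (stage s = 1 - w). The ERS-like
    perturbation batch represses identity genes by ``effect_size`` and
    induces a planted stress-response set. Single-cell counts are Poisson
    around size-scaled adult means.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = _gene_classes(cfg, rng)
    genes = _gene_ids(cfg)
    n = cfg.n_genes

    baseline = rng.normal(7.0, 1.5, size=n)
    v = np.zeros(n)
    other_idx = [i for i, g in enumerate(genes) if classes[g] == "OTHER"]
    fetal_idx = rng.choice(
        other_idx, size=min(cfg.n_maturation_genes, len(other_idx) // 2), replace=False
    )
    for i, g in enumerate(genes):
        if classes[g] == "ID":
            v[i] = cfg.maturation_effect
    v[fetal_idx] = -0.75 * cfg.maturation_effect
    induced_pool = [i for i in other_idx if i not in set(fetal_idx)]
    induced_idx = rng.choice(
        induced_pool,
        size=min(cfg.n_induced_genes, len(induced_pool)),
        replace=False,
    )

    def profile(s: float) -> np.ndarray:
        return baseline + (s - 1.0) * v

    def noisy(mean: np.ndarray) -> np.ndarray:
        return mean + rng.normal(0.0, cfg.expr_noise_sd, size=n)

    # reference developmental study
    stages = np.linspace(0.0, 1.0, cfg.n_stages)
    ref_cols, ref_cond, ref_stage = [], {}, {}
    ref_data = []
    for j, s in enumerate(stages):
        cond = "adult" if j == cfg.n_stages - 1 else f"stage_{j:02d}"
        for r in range(cfg.n_reps):
            name = f"ref_{cond}_r{r}"
            ref_cols.append(name)
            ref_cond[name] = cond
            ref_stage[name] = float(s)
            ref_data.append(noisy(profile(float(s))))
    reference = pd.DataFrame(np.column_stack(ref_data), index=genes, columns=ref_cols)

    # injury batch: controls (w = 0, adult-like) + dedifferentiated samples
    inj_offset = rng.normal(0.0, cfg.batch_offset_sd, size=n)
    inj_cols, inj_cond, inj_w = [], {}, {}
    inj_data = []
    for r in range(cfg.n_reps):
        name = f"inj_control_r{r}"
        inj_cols.append(name)
        inj_cond[name] = "control"
        inj_w[name] = 0.0
        inj_data.append(noisy(profile(1.0)) + inj_offset)
    for w in cfg.dediff_weights:
        for r in range(cfg.n_reps):
            name = f"inj_w{int(round(100 * w)):03d}_r{r}"
            inj_cols.append(name)
            inj_cond[name] = f"injured_w{int(round(100 * w)):03d}"
            inj_w[name] = float(w)
            inj_data.append(noisy(profile(1.0 - w)) + inj_offset)
    injury = pd.DataFrame(np.column_stack(inj_data), index=genes, columns=inj_cols)

    # ERS-like perturbation batch: identity repression + induced stress genes
    ers_offset = rng.normal(0.0, cfg.batch_offset_sd, size=n)
    delta = np.zeros(n)
    delta[[i for i, g in enumerate(genes) if classes[g] == "ID"]] = -cfg.effect_size
    delta[induced_idx] = cfg.effect_size
    pert_cols, pert_cond = [], {}
    pert_data = []
    for r in range(cfg.n_reps):
        name = f"ers_control_r{r}"
        pert_cols.append(name)
        pert_cond[name] = "control"
        pert_data.append(noisy(profile(1.0)) + ers_offset)
    for r in range(cfg.n_reps):
        name = f"ers_stress_r{r}"
        pert_cols.append(name)
        pert_cond[name] = "stress"
        pert_data.append(noisy(profile(1.0) + delta) + ers_offset)
    perturb = pd.DataFrame(np.column_stack(pert_data), index=genes, columns=pert_cols)

    # single-cell counts: Poisson around size-scaled adult-profile means
    cell_sizes = rng.lognormal(0.0, 0.3, size=cfg.n_cells)
    mu = np.power(2.0, profile(1.0)) / 50.0
    lam = np.outer(mu, cell_sizes)
    sc = rng.poisson(lam)
    sc_counts = pd.DataFrame(
        sc, index=genes, columns=[f"cell_{c:04d}" for c in range(cfg.n_cells)]
    )

    return SynthExpression(
        reference=reference,
        ref_condition=ref_cond,
        ref_stage=ref_stage,
        injury=injury,
        injury_condition=inj_cond,
        injury_w=inj_w,
        perturb=perturb,
        perturb_condition=pert_cond,
        sc_counts=sc_counts,
        classes=classes,
        repressed_genes=[g for g in genes if classes[g] == "ID"],
        induced_genes=[genes[i] for i in sorted(induced_idx)],
    )


def write_fixture_tree(cfg: SynthConfig, outdir: str | Path) -> None:
    """Write the full fixture tree (BEDs, TSVs, truth JSON) for a config."""
    out = Path(outdir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    tissue_data = gen_tissue_peaks(cfg)
    for tissue, peaks in tissue_data.peaks.items():
        write_bed(out / "peaks" / f"{tissue}.bed", peaks)
    write_tss(out / "tss.tsv", tissue_data.tss)

    grid = make_peak_grid(60)
    sb = gen_bins(cfg, grid)
    rows = [
        {
            "chrom": b.interval.chrom,
            "start": b.interval.start,
            "end": b.interval.end,
            "log2fc": b.log2fc,
            "pvalue": b.pvalue,
        }
        for b in sb.bins
    ]
    pd.DataFrame(rows).to_csv(out / "bins.tsv", sep="\t", index=False)
    write_bed(out / "diff_peaks.bed", grid)

    down_mask = [sb.truth[p.name] == "DOWN" for p in grid]
    cistromes, _ = gen_cistromes(cfg, grid, down_mask)
    (out / "cistromes").mkdir(exist_ok=True)
    for tf, sites in cistromes.items():
        write_bed(out / "cistromes" / f"{tf}.bed", sites)

    se = gen_expression(cfg)
    se.reference.round(4).to_csv(out / "reference_expression.tsv", sep="\t")
    se.injury.round(4).to_csv(out / "injury_expression.tsv", sep="\t")
    se.perturb.round(4).to_csv(out / "perturb_expression.tsv", sep="\t")
    se.sc_counts.to_csv(out / "sc_counts.tsv", sep="\t")

    truth = {
        "gene_classes": tissue_data.truth,
        "focal_tissue": tissue_data.focal,
        "diff_peak_directions": sb.truth,
        "repressed_genes": se.repressed_genes,
        "induced_genes": se.induced_genes,
        "injury_weights": se.injury_w,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
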