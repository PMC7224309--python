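"""Broad H3K4me3 domain calling and identity-gene classification.

Broad H3K4me3 domains mark cell-identity genes: within each tissue, enriched
regions spanning more than a multiple (default 3x) of the tissue's median
peak size are "broad". Broad domains of the focal tissue are split into
identity (ID) domains — detected in fewer than a threshold fraction (default
25%) of the other tissues — and ubiquitous (UBQ) domains. Genes inherit the
label of the domain overlapping their TSS, ID taking precedence over UBQ;
genes under no broad domain are OTHER.

"Detected in" another tissue means >=1 bp overlap between the focal broad
domain and any *broad domain* of that tissue (sharing is judged against the
other tissues' broad-domain sets, not their raw peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, TSSRecord, assign_tss, overlap_any

__all__ = [
    "IdentityConfig",
    "TissuePeakCollection",
    "BroadDomain",
    "IdentityCall",
    "select_broad_domains",
    "domain_specificity",
    "classify_genes",
    "specificity_index",
    "calls_to_frame",
]

ID = "ID"
UBQ = "UBQ"
OTHER = "OTHER"


@dataclass(frozen=True)
class IdentityConfig:
    """Thresholds of the identity-calling rules.

    broad_multiplier: a peak is broad iff its length is strictly greater
        than this multiple of the tissue's median peak length.
    specificity_threshold: a broad domain is ID iff its shared fraction
        across other tissues is strictly below this value.
    """

    broad_multiplier: float = 3.0
    specificity_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.broad_multiplier <= 0:
            raise ValueError("broad_multiplier must be > 0")
        if not (0 < self.specificity_threshold <= 1):
            raise ValueError("specificity_threshold must be in (0, 1]")


@dataclass
class TissuePeakCollection:
    tissue: str
    peaks: list[GenomicInterval]


@dataclass
class BroadDomain:
    interval: GenomicInterval
    tissue: str
    shared_fraction: float
    label: str  # ID or UBQ


@dataclass
class IdentityCall:
    gene_id: str
    klass: str  # ID, UBQ or OTHER
    evidence: list[BroadDomain] = field(default_factory=list)


def select_broad_domains(
    coll: TissuePeakCollection, cfg: IdentityConfig = IdentityConfig()
) -> list[GenomicInterval]:
    """Peaks strictly longer than ``broad_multiplier`` x median peak length.

    The median of an even count is the mean of the two central values
    (numpy convention).
    """
    if not coll.peaks:
        raise ValueError(f"tissue {coll.tissue!r} has no peaks")
    lengths = np.asarray([p.length for p in coll.peaks], dtype=float)
    threshold = cfg.broad_multiplier * float(np.median(lengths))
    return [p for p, ln in zip(coll.peaks, lengths) if ln > threshold]


def domain_specificity(
    focal: Sequence[GenomicInterval],
    others: Sequence[TissuePeakCollection],
    cfg: IdentityConfig = IdentityConfig(),
    *,
    focal_tissue: str = "focal",
) -> list[BroadDomain]:
    """Label each focal broad domain ID or UBQ by cross-tissue sharing.

    ``others`` must already hold each tissue's *broad domains*. The shared
    fraction is the number of other tissues overlapping the domain by >=1 bp
    divided by the number of other tissues; label is ID iff strictly below
    ``specificity_threshold``.
    """
    if not others:
        raise ValueError("need at least one other tissue")
    n_other = len(others)
    shared_counts = np.zeros(len(focal), dtype=int)
    for coll in others:
        shared_counts += overlap_any(focal, coll.peaks).astype(int)
    out: list[BroadDomain] = []
    for iv, c in zip(focal, shared_counts):
        frac = c / n_other
        label = ID if frac < cfg.specificity_threshold else UBQ
        out.append(
            BroadDomain(
                interval=iv, tissue=focal_tissue, shared_fraction=frac, label=label
            )
        )
    return out


def classify_genes(
    domains: Sequence[BroadDomain], tss: Sequence[TSSRecord]
) -> list[IdentityCall]:
    """Assign every annotated gene exactly one class: ID, UBQ or OTHER.

    A gene is ID if any of its TSS falls in an ID domain (ID takes precedence
    over UBQ when both are hit), UBQ if only UBQ domains are hit, OTHER
    otherwise. The partition over the annotation is exhaustive and exclusive.
    """
    gene_regions = assign_tss(tss, [d.interval for d in domains])
    gene_order: list[str] = []
    seen: set[str] = set()
    for rec in tss:
        if rec.gene_id not in seen:
            seen.add(rec.gene_id)
            gene_order.append(rec.gene_id)

    calls: list[IdentityCall] = []
    for gene in gene_order:
        idxs = gene_regions.get(gene, [])
        evidence = [domains[i] for i in idxs]
        if any(d.label == ID for d in evidence):
            klass = ID
        elif evidence:
            klass = UBQ
        else:
            klass = OTHER
        calls.append(IdentityCall(gene_id=gene, klass=klass, evidence=evidence))
    return calls


def specificity_index(
    expr: pd.DataFrame, tissue_of: Mapping[str, str], focal: str
) -> pd.Series:
    """Tissue-specificity expression index, log2 units.

    index(g) = mean over focal replicates of expr[g] minus the mean over
    control tissues of each tissue's replicate mean (a mean of means, so
    unbalanced replicate counts do not weight tissues unequally).
    ``expr`` is genes x samples, already log2-normalized; ``tissue_of`` maps
    sample name -> tissue label.
    """
    missing = [s for s in expr.columns if s not in tissue_of]
    if missing:
        raise ValueError(f"samples without tissue labels: {missing}")
    focal_cols = [s for s in expr.columns if tissue_of[s] == focal]
    if not focal_cols:
        raise ValueError(f"no replicates labelled with focal tissue {focal!r}")
    control_tissues = sorted(
        {tissue_of[s] for s in expr.columns if tissue_of[s] != focal}
    )
    if not control_tissues:
        raise ValueError("need at least one control tissue")
    focal_mean = expr[focal_cols].mean(axis=1)
    tissue_means = pd.concat(
        {
            t: expr[[s for s in expr.columns if tissue_of[s] == t]].mean(axis=1)
            for t in control_tissues
        },
        axis=1,
    )
    return (focal_mean - tissue_means.mean(axis=1)).rename("specificity_index")


def call_identity(
    peaks: Mapping[str, Sequence[GenomicInterval]],
    focal: str,
    tss: Sequence[TSSRecord],
    cfg: IdentityConfig = IdentityConfig(),
) -> tuple[list[BroadDomain], list[IdentityCall]]:
    """End-to-end identity calling from per-tissue peak sets.

    Selects broad domains per tissue, labels the focal tissue's broad
    domains by cross-tissue sharing, and classifies all annotated genes.
    """
    if focal not in peaks:
        raise ValueError(f"focal tissue {focal!r} not among peak sets")
    broad = {
        t: select_broad_domains(TissuePeakCollection(t, list(p)), cfg)
        for t, p in peaks.items()
    }
    others = [TissuePeakCollection(t, broad[t]) for t in peaks if t != focal]
    domains = domain_specificity(broad[focal], others, cfg, focal_tissue=focal)
    return domains, classify_genes(domains, tss)


def calls_to_frame(calls: Sequence[IdentityCall]) -> pd.DataFrame:
    """Per-gene table: gene_id, klass, n_ID_domains, n_UBQ_domains."""
    rows = [
        {
            "gene_id": c.gene_id,
            "klass": c.klass,
            "n_ID_domains": sum(d.label == ID for d in c.evidence),
            "n_UBQ_domains": sum(d.label == UBQ for d in c.evidence),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["gene_id", "klass", "n_ID_domains", "n_UBQ_domains"])
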