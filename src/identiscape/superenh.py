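"""Rank-ordering super-enhancer identification and identity-domain overlap.

Enhancer peaks within a stitching distance (default 12,500 bp) are joined
into stitched enhancers whose signal is the sum of member peak scores.
Stitched enhancers are sorted by ascending signal; both rank and signal are
min-max scaled to [0, 1] and the super-enhancer cutoff is the signal at the
first point where the discrete slope of the scaled curve reaches 1 (the
geometric tangent rule). Enhancers with signal strictly above the cutoff are
super-enhancers. Identity domains are then classed by whether they share a
base with any super-enhancer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GenomicInterval, TSSRecord, assign_tss, merge_intervals, overlap_any

__all__ = [
    "StitchConfig",
    "RankedEnhancer",
    "stitch_peaks",
    "stitched_signal",
    "rose_cutoff",
    "rank_enhancers",
    "id_domains_by_se",
    "gene_se_classes",
]

ID_SE = "ID+SE"
ID_NOSE = "ID-SE"


@dataclass(frozen=True)
class StitchConfig:
    stitch_distance: int = 12500
    tss_exclusion: int = 0

    def __post_init__(self) -> None:
        if self.stitch_distance < 0 or self.tss_exclusion < 0:
            raise ValueError("distances must be >= 0")


@dataclass
class RankedEnhancer:
    interval: GenomicInterval
    signal: float
    rank: int  # 1..n, ascending signal
    is_super: bool


def stitch_peaks(
    peaks: Sequence[GenomicInterval],
    cfg: StitchConfig = StitchConfig(),
    tss: Sequence[TSSRecord] | None = None,
) -> list[GenomicInterval]:
    """Join peaks whose gap is at most ``stitch_distance`` bp.

    With ``tss_exclusion > 0`` and a TSS annotation provided, peaks lying
    entirely within that distance of an annotated TSS are removed before
    stitching; the default (0) applies no masking.
    """
    kept = list(peaks)
    if cfg.tss_exclusion > 0 and tss:
        windows = [
            GenomicInterval(
                t.chrom,
                max(0, t.position - cfg.tss_exclusion),
                t.position + cfg.tss_exclusion,
            )
            for t in tss
        ]
        contained = np.zeros(len(kept), dtype=bool)
        merged = merge_intervals(windows, max_gap=0)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for w in merged:
            by_chrom.setdefault(w.chrom, []).append(w)
        for i, p in enumerate(kept):
            for w in by_chrom.get(p.chrom, []):
                if w.start <= p.start and p.end <= w.end:
                    contained[i] = True
                    break
        kept = [p for i, p in enumerate(kept) if not contained[i]]
    return merge_intervals(kept, max_gap=cfg.stitch_distance)


def stitched_signal(
    stitched: Sequence[GenomicInterval], peaks: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per stitched region, the sum of scores of member peaks.

    Peaks without a score contribute their length instead, so unscored BED3
    input still yields a usable (coverage-proportional) signal.
    """
    signal = np.zeros(len(stitched), dtype=float)
    for j, region in enumerate(stitched):
        for p in peaks:
            if p.overlaps(region):
                signal[j] += p.score if p.score is not None else p.length
    return signal


def rose_cutoff(signals: Sequence[float]) -> tuple[float, np.ndarray]:
    """Tangent-rule super-enhancer cutoff over a signal vector.

    Signals are sorted ascending; rank and signal are min-max scaled to
    [0, 1]. Scanning from the low end, the cutoff is the (unscaled) signal at
    the first index whose forward finite-difference slope on the scaled curve
    reaches 1. Returns ``(cutoff_signal, is_super)`` with flags in the input
    order; ``is_super`` uses strict inequality (ties at the cutoff are not
    super). All-equal signals yield zero super-enhancers.
    """
    s = np.asarray(signals, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two enhancers to rank")
    if np.any(s < 0):
        raise ValueError("signals must be >= 0")
    order = np.argsort(s, kind="stable")
    srt = s[order]
    if srt[0] == srt[-1]:
        return float(srt[-1]), np.zeros(s.size, dtype=bool)
    n = s.size
    x = np.arange(n, dtype=float) / (n - 1)
    y = (srt - srt[0]) / (srt[-1] - srt[0])
    slopes = np.diff(y) / np.diff(x)
    # mean slope is 1, so at least one forward difference reaches it
    idx = int(np.argmax(slopes >= 1.0))
    cutoff = float(srt[idx])
    return cutoff, s > cutoff


def rank_enhancers(
    stitched: Sequence[GenomicInterval], signals: Sequence[float]
) -> list[RankedEnhancer]:
    """Attach ascending-signal ranks and super flags to stitched enhancers."""
    cutoff, flags = rose_cutoff(signals)
    order = np.argsort(np.asarray(signals, dtype=float), kind="stable")
    ranks = np.empty(len(stitched), dtype=int)
    ranks[order] = np.arange(1, len(stitched) + 1)
    return [
        RankedEnhancer(
            interval=iv, signal=float(sig), rank=int(r), is_super=bool(f)
        )
        for iv, sig, r, f in zip(stitched, signals, ranks, flags)
    ]


def id_domains_by_se(
    id_domains: Sequence[GenomicInterval], se: Sequence[RankedEnhancer]
) -> list[str]:
    """Label each identity domain ID+SE or ID-SE by super-enhancer overlap."""
    supers = [e.interval for e in se if e.is_super]
    mask = overlap_any(id_domains, supers)
    return [ID_SE if m else ID_NOSE for m in mask]


def gene_se_classes(
    id_domains: Sequence[GenomicInterval],
    domain_labels: Sequence[str],
    tss: Sequence[TSSRecord],
) -> dict[str, str]:
    """Genes inherit their domain's ID+SE / ID-SE label via TSS overlap.

    A gene hit by both classes of domain is ID+SE (super-enhancer support
    takes precedence).
    """
    hits = assign_tss(tss, id_domains)
    out: dict[str, str] = {}
    for gene, idxs in hits.items():
        labels = {domain_labels[i] for i in idxs}
        out[gene] = ID_SE if ID_SE in labels else ID_NOSE
    return out
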