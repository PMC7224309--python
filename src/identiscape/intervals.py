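"""Genomic interval algebra and BED/TSS I/O.

All coordinates are BED-convention 0-based half-open ``[start, end)``.
Chromosome names are compared by exact string match; strand is carried on
TSS records but ignored by overlap tests.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "TSSRecord",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_tss",
    "write_tss",
    "merge_intervals",
    "overlap_any",
    "assign_tss",
]


class BedParseError(ValueError):
    """Raised for malformed BED / TSS lines; message names the offending line."""


@dataclass
class GenomicInterval:
    """A genomic region on one chromosome, 0-based half-open.

    ``score`` maps to BED column 5, ``name`` to column 4; both optional.
    """

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"end <= start for {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TSSRecord:
    """One annotated transcription start site. A gene may own several."""

    gene_id: str
    chrom: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative TSS position for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be +/- (got {self.strand!r})")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED5 (tab-separated, no header).

    Scores are parsed from column 5 when present, names from column 4.
    Malformed lines (fewer than 3 columns, non-integer coordinates,
    ``end <= start``) raise :class:`BedParseError` naming the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: non-numeric score"
                    ) from exc
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, score=score, name=name)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    """Write BED; emits exactly the columns needed (3, 4 or 5)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score) if iv.score % 1 else str(int(iv.score)))
            fh.write("\t".join(cols) + "\n")


def read_tss(path: str | Path) -> list[TSSRecord]:
    """Read a TSS annotation TSV with header gene_id, chrom, position, strand."""
    records: list[TSSRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        want = ["gene_id", "chrom", "position", "strand"]
        try:
            idx = [header.index(c) for c in want]
        except ValueError as exc:
            raise BedParseError(f"{path}: header must contain {want}") from exc
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            try:
                records.append(
                    TSSRecord(
                        gene_id=fields[idx[0]],
                        chrom=fields[idx[1]],
                        position=int(fields[idx[2]]),
                        strand=fields[idx[3]],
                    )
                )
            except (ValueError, IndexError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_tss(path: str | Path, records: Iterable[TSSRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tposition\tstrand\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.position}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# interval algebra


def _group_by_chrom(
    ivs: Sequence[GenomicInterval],
) -> dict[str, list[tuple[int, int, int]]]:
    """chrom -> [(start, end, original_index), ...]"""
    groups: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for i, iv in enumerate(ivs):
        groups[iv.chrom].append((iv.start, iv.end, i))
    return groups


def merge_intervals(
    ivs: Sequence[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is at most ``max_gap`` bases.

    Two intervals with gap ``next.start - cur.end <= max_gap`` are joined
    (gap 0 means touching). Output is sorted by (chrom, start) and
    non-overlapping; merging is transitive. Scores and names are dropped.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in ivs}):
        spans = sorted(
            (iv.start, iv.end) for iv in ivs if iv.chrom == chrom
        )
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def _merged_arrays(
    b: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """chrom -> (starts, ends) of the merged cover of ``b`` (sorted, disjoint)."""
    cover: dict[str, list[list[int]]] = defaultdict(lambda: [[], []])
    for iv in merge_intervals(b, max_gap=0):
        cover[iv.chrom][0].append(iv.start)
        cover[iv.chrom][1].append(iv.end)
    return {
        c: (np.asarray(se[0], dtype=np.int64), np.asarray(se[1], dtype=np.int64))
        for c, se in cover.items()
    }


def overlap_any(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask over ``a``: does each interval share >=1 bp with ``b``?

    Merging ``b`` first is safe because merging with gap 0 preserves the
    covered base set exactly (half-open adjacency bridges no bases).
    """
    mask = np.zeros(len(a), dtype=bool)
    if not len(a) or not len(b):
        return mask
    cover = _merged_arrays(b)
    for i, iv in enumerate(a):
        se = cover.get(iv.chrom)
        if se is None:
            continue
        starts, ends = se
        j = int(np.searchsorted(starts, iv.end, side="left")) - 1
        if j >= 0 and ends[j] > iv.start:
            mask[i] = True
    return mask


def assign_tss(
    tss: Sequence[TSSRecord], regions: Sequence[GenomicInterval]
) -> dict[str, list[int]]:
    """Map each gene to the indices of all regions containing one of its TSS.

    A TSS at position ``p`` hits region ``[start, end)`` iff
    ``start <= p < end`` (half-open). Genes with no hit are absent from the
    mapping; region indices are sorted and unique per gene.
    """
    by_chrom = _group_by_chrom(regions)
    # sort candidates by start; sweep each TSS over regions with start <= p
    sorted_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.asarray([t[0] for t in triples], dtype=np.int64)
        ends = np.asarray([t[1] for t in triples], dtype=np.int64)
        orig = np.asarray([t[2] for t in triples], dtype=np.int64)
        sorted_chrom[chrom] = (starts, ends, orig)

    hits: dict[str, set[int]] = defaultdict(set)
    for rec in tss:
        entry = sorted_chrom.get(rec.chrom)
        if entry is None:
            continue
        starts, ends, orig = entry
        k = int(np.searchsorted(starts, rec.position, side="right"))
        if k == 0:
            continue
        sel = ends[:k] > rec.position
        for idx in orig[:k][sel]:
            hits[rec.gene_id].add(int(idx))
    return {g: sorted(s) for g, s in hits.items()}
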