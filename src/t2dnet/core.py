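"""Genomic domain types, interval arithmetic, and plain-text I/O.

Coordinates are 0-based half-open (BED convention) everywhere. Chromosome
names are taken verbatim; no "chr" normalisation is attempted.

Chromatin states follow an 8-label vocabulary derived from a 9-state
histone-mark segmentation in which the two low-signal quiescent states are
merged into a single ``Quies/low`` catch-all.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Fixed chromatin-state vocabulary used throughout the package.
CHROMATIN_STATES: tuple[str, ...] = (
    "CTCF",
    "Txn",
    "TssA",
    "TssFlnk",
    "EnhWk",
    "EnhA1",
    "EnhA2",
    "Quies/low",
)

#: States counted as islet enhancers / promoters in cumulative-PPA analyses.
ENHANCER_STATES: tuple[str, ...] = ("EnhA1", "EnhA2", "EnhWk")
PROMOTER_STATES: tuple[str, ...] = ("TssA", "TssFlnk")

#: Label given to site fragments that fall outside the state segmentation.
DEFAULT_STATE = "Quies/low"


class BedParseError(ValueError):
    """Raised when a BED-like file contains a malformed line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located genomic region, 0-based half-open.

    Parameters
    ----------
    chrom
        Chromosome name, taken verbatim.
    start
        First base of the interval (inclusive, >= 0).
    end
        One past the last base (exclusive, > start).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> float:
        """Gap in bases between two intervals; 0 if they touch or overlap."""
        if self.chrom != other.chrom:
            return float("inf")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def expanded(self, slop: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, max(0, self.start - slop), self.end + slop)


@dataclass(frozen=True)
class AnnotatedSite:
    """An accessible-chromatin element carrying a chromatin-state label and
    the number of samples supporting the call."""

    interval: GenomicInterval
    state: str = DEFAULT_STATE
    support: int = 1

    def __post_init__(self) -> None:
        if self.state not in CHROMATIN_STATES:
            raise ValueError(
                f"unknown chromatin state {self.state!r}; "
                f"expected one of {CHROMATIN_STATES}"
            )
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: TSS position, strand and biotype."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


#: Biotypes retained for all downstream analyses.
ANALYSIS_BIOTYPES = frozenset({"protein_coding", "lncRNA"})


@dataclass(frozen=True)
class Tad:
    """A topologically associating domain."""

    interval: GenomicInterval


# ---------------------------------------------------------------------------
# Interval arithmetic


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or touching intervals into a minimal sorted set."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered by a set of intervals."""
    return sum(iv.width for iv in merge_intervals(intervals))


def jaccard(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> float:
    """Jaccard index of base-level overlap between two interval sets.

    Raises
    ------
    ValueError
        If both sets are empty (the index is undefined).
    """
    if not a and not b:
        raise ValueError("Jaccard index undefined for two empty interval sets")
    ma, mb = merge_intervals(a) if a else [], merge_intervals(b) if b else []
    union = total_bases(list(ma) + list(mb))
    inter = 0
    bb: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in mb:
        bb[iv.chrom].append(iv)
    for iv in ma:
        for other in bb.get(iv.chrom, ()):
            lo = max(iv.start, other.start)
            hi = min(iv.end, other.end)
            if hi > lo:
                inter += hi - lo
    return inter / union


class IntervalIndex:
    """Per-chromosome sorted merged intervals supporting fast vectorised
    "does [s, e) overlap anything" queries via binary search."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        merged = merge_intervals(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
        for iv in merged:
            by_chrom[iv.chrom].append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def overlaps_any(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Boolean vector: does each query interval overlap the index?"""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._starts:
            return np.zeros(starts.shape, dtype=bool)
        s, e = self._starts[chrom], self._ends[chrom]
        # first indexed interval whose end is past the query start
        idx = np.searchsorted(e, starts, side="right")
        hit = idx < len(s)
        out = np.zeros(starts.shape, dtype=bool)
        out[hit] = s[idx[hit]] < ends[hit]
        return out


# ---------------------------------------------------------------------------
# Site splitting by chromatin state


def split_sites_by_state(
    sites: Sequence[GenomicInterval],
    segments: Sequence[AnnotatedSite],
    support: int | None = None,
) -> list[AnnotatedSite]:
    """Partition accessible sites along a chromatin-state segmentation.

    A site overlapping several state segments is split into one element per
    segment, so each output element carries exactly one state and the
    elements tile the input site base-for-base. Bases not covered by any
    segment are labelled ``Quies/low``.

    Parameters
    ----------
    sites
        Un-labelled accessible-chromatin intervals.
    segments
        Non-overlapping state segmentation (validated).
    support
        Sample-support count copied onto every output element (default 1).
    """
    seg_by_chrom: dict[str, list[AnnotatedSite]] = defaultdict(list)
    for seg in segments:
        seg_by_chrom[seg.interval.chrom].append(seg)
    seg_arrays: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom, segs in seg_by_chrom.items():
        segs.sort(key=lambda s: s.interval.start)
        starts = np.array([s.interval.start for s in segs], dtype=np.int64)
        ends = np.array([s.interval.end for s in segs], dtype=np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"state segments overlap on {chrom}")
        seg_arrays[chrom] = (starts, ends, [s.state for s in segs])

    sup = 1 if support is None else support
    out: list[AnnotatedSite] = []
    for site in sites:
        chrom = site.chrom
        if chrom not in seg_arrays:
            out.append(AnnotatedSite(site, DEFAULT_STATE, sup))
            continue
        starts, ends, states = seg_arrays[chrom]
        pos = site.start
        while pos < site.end:
            i = int(np.searchsorted(ends, pos, side="right"))
            if i >= len(starts) or starts[i] >= site.end:
                # remainder is outside every segment
                out.append(
                    AnnotatedSite(
                        GenomicInterval(chrom, pos, site.end), DEFAULT_STATE, sup
                    )
                )
                break
            if starts[i] > pos:
                # gap before the next segment
                out.append(
                    AnnotatedSite(
                        GenomicInterval(chrom, pos, int(starts[i])),
                        DEFAULT_STATE,
                        sup,
                    )
                )
                pos = int(starts[i])
            hi = min(site.end, int(ends[i]))
            out.append(
                AnnotatedSite(GenomicInterval(chrom, pos, hi), states[i], sup)
            )
            pos = hi
    return out


# ---------------------------------------------------------------------------
# I/O: BED, gene tables, TADs


def read_bed(path: str | Path) -> list[AnnotatedSite]:
    """Read a 3-5 column BED file of annotated sites.

    Column 4 (optional) is the chromatin-state label, column 5 (optional)
    the sample-support count. Missing labels default to ``Quies/low``.
    """
    sites: list[AnnotatedSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            state = fields[3] if len(fields) > 3 and fields[3] else DEFAULT_STATE
            sup = int(fields[4]) if len(fields) > 4 and fields[4] else 1
            try:
                sites.append(
                    AnnotatedSite(GenomicInterval(fields[0], start, end), state, sup)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_bed(sites: Iterable[AnnotatedSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.state}\t{s.support}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene table TSV with header: gene_id, chrom, tss, strand, biotype."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("gene_id", "chrom", "tss", "strand", "biotype"):
            if name not in idx:
                raise BedParseError(f"{path}: missing column {name!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            try:
                genes.append(
                    GeneModel(
                        gene_id=f[idx["gene_id"]],
                        chrom=f[idx["chrom"]],
                        tss=int(f[idx["tss"]]),
                        strand=f[idx["strand"]],
                        biotype=f[idx["biotype"]],
                    )
                )
            except (ValueError, IndexError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tbiotype\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.biotype}\n")


def read_tads(path: str | Path) -> list[Tad]:
    return [Tad(s.interval) for s in read_bed(path)]


def write_tads(tads: Iterable[Tad], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tads:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
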