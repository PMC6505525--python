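"""Chromatin-loop merging and regulatory-element enrichment at loop anchors.

Loop calls arrive from several contact maps (individual samples plus a
pooled map) at 5/10/25 kb resolutions. Calls are unified by clustering loops
whose corresponding anchor midpoints lie within a tolerance (20 kb by
default) and keeping, per cluster, the highest-resolution call — ties broken
by the deepest source map. Enrichment of chromatin-state classes at anchors
is measured against a size-matched permutation null, and co-localization of
state pairs across the two anchors of a loop with Fisher's exact test.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import AnnotatedSite, GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

VALID_RESOLUTIONS = (5000, 10000, 25000)


@dataclass(frozen=True)
class Loop:
    """An intra-chromosomal chromatin loop between two anchors.

    ``anchor1`` precedes ``anchor2`` in genome order; anchor widths equal
    the calling resolution. ``depth`` is the total contact count of the
    source map and is used only for merge tie-breaking. ``support`` lists
    every input loop set in which a matching call was found.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    source: str = "pooled"
    depth: float = 0.0
    support: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loops must be intra-chromosomal")
        if self.anchor1.start > self.anchor2.start:
            raise ValueError("anchor1 must precede anchor2 in genome order")
        if self.resolution not in VALID_RESOLUTIONS:
            raise ValueError(f"resolution must be one of {VALID_RESOLUTIONS}")

    @property
    def span(self) -> float:
        """Distance between anchor midpoints."""
        return self.anchor2.midpoint - self.anchor1.midpoint


@dataclass(frozen=True)
class EnrichmentResult:
    """Permutation enrichment of one chromatin state at loop anchors."""

    state: str
    observed: float
    null_mean: float
    fold: float
    empirical_p: float
    n_perm: int


@dataclass(frozen=True)
class PairEnrichment:
    """Fisher-exact enrichment for one unordered state pair across anchors."""

    state_a: str
    state_b: str
    odds_ratio: float
    p_value: float
    counts: tuple[tuple[int, int], tuple[int, int]]


# ---------------------------------------------------------------------------
# Loop-set merging


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_loop_sets(
    loop_sets: Sequence[Sequence[Loop]], tolerance: int = 20_000
) -> list[Loop]:
    """Unify loop calls across samples and resolutions.

    Two loops match when both anchor-midpoint distances (anchor1 to anchor1
    and anchor2 to anchor2, after genome ordering) are within ``tolerance``.
    Matching is closed transitively; each resulting cluster contributes one
    representative: the smallest-resolution call, ties broken by the largest
    source depth. The representative's ``support`` records every source
    whose loop set contained a matching call.
    """
    loops: list[Loop] = [lp for ls in loop_sets for lp in ls]
    if not loops:
        return []
    n = len(loops)
    uf = _UnionFind(n)
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, lp in enumerate(loops):
        by_chrom[lp.anchor1.chrom].append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: loops[i].anchor1.midpoint)
        m1 = np.array([loops[i].anchor1.midpoint for i in idxs])
        m2 = np.array([loops[i].anchor2.midpoint for i in idxs])
        for a in range(len(idxs)):
            # candidates limited to anchor1 midpoints within tolerance
            b = a + 1
            while b < len(idxs) and m1[b] - m1[a] <= tolerance:
                if abs(m2[b] - m2[a]) <= tolerance:
                    uf.union(idxs[a], idxs[b])
                b += 1
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        clusters[uf.find(i)].append(i)
    merged: list[Loop] = []
    for members in clusters.values():
        rep_i = min(
            members, key=lambda i: (loops[i].resolution, -loops[i].depth)
        )
        rep = loops[rep_i]
        support = tuple(sorted({loops[i].source for i in members}))
        merged.append(
            Loop(
                rep.anchor1,
                rep.anchor2,
                rep.resolution,
                rep.source,
                rep.depth,
                support,
            )
        )
    merged.sort(key=lambda lp: (lp.anchor1.chrom, lp.anchor1.start, lp.anchor2.start))
    return merged


# ---------------------------------------------------------------------------
# Anchor signal profile


def anchor_signal_profile(
    loops: Sequence[Loop],
    coverage: Mapping[str, np.ndarray],
    half_window: int,
) -> np.ndarray:
    """Mean per-base signal around anchor midpoints, max-normalised to 1.

    ``coverage`` maps chromosome name to a per-base signal vector. The
    returned profile has length ``2 * half_window + 1`` with offset 0 at the
    anchor midpoint; positions falling outside a coverage vector contribute
    zero signal.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    width = 2 * half_window + 1
    acc = np.zeros(width)
    n_anchors = 0
    for lp in loops:
        for anchor in (lp.anchor1, lp.anchor2):
            track = coverage.get(anchor.chrom)
            if track is None:
                continue
            mid = int(anchor.midpoint)
            lo, hi = mid - half_window, mid + half_window + 1
            src_lo, src_hi = max(0, lo), min(len(track), hi)
            if src_hi > src_lo:
                acc[src_lo - lo : src_hi - lo] += track[src_lo:src_hi]
            n_anchors += 1
    if n_anchors:
        acc /= n_anchors
    peak = acc.max()
    if peak > 0:
        acc = acc / peak
    return acc


# ---------------------------------------------------------------------------
# Permutation enrichment at anchors


def _anchor_index(loops: Sequence[Loop], window: int) -> IntervalIndex:
    anchors = [
        a.expanded(window) if window else a
        for lp in loops
        for a in (lp.anchor1, lp.anchor2)
    ]
    return IntervalIndex(anchors)


def anchor_enrichment(
    sites: Sequence[AnnotatedSite],
    loops: Sequence[Loop],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 7000,
    window: int = 25_000,
    mode: str = "within_window",
    rng_seed: int | None = None,
) -> list[EnrichmentResult]:
    """Permutation enrichment of each chromatin state at loop anchors.

    For each state the observed statistic is the proportion of that state's
    sites overlapping an anchor directly (``mode="direct_overlap"``) or
    within ``window`` bases (``mode="within_window"``). The null re-places
    every site uniformly on its own chromosome preserving its length
    (a size-matched null), ``n_perm`` times. Fold is observed over the null
    mean; the empirical p-value uses the add-one convention
    ``(1 + #{null >= observed}) / (1 + n_perm)`` so it is never zero.
    """
    if mode not in ("direct_overlap", "within_window"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eff_window = window if mode == "within_window" else 0
    index = _anchor_index(loops, eff_window)
    rng = np.random.default_rng(rng_seed)

    by_state: dict[str, list[AnnotatedSite]] = defaultdict(list)
    for s in sites:
        by_state[s.state].append(s)

    results: list[EnrichmentResult] = []
    for state in sorted(by_state):
        group = by_state[state]
        if not group:
            warnings.warn(f"state {state} has no sites; omitted")
            continue
        chroms = [s.interval.chrom for s in group]
        starts = np.array([s.interval.start for s in group], dtype=np.int64)
        ends = np.array([s.interval.end for s in group], dtype=np.int64)
        lengths = ends - starts

        hits = np.zeros(len(group), dtype=bool)
        null_hits = np.zeros((n_perm, len(group)), dtype=bool)
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for i, c in enumerate(chroms):
            by_chrom[c].append(i)
        for chrom, idxs in by_chrom.items():
            ii = np.array(idxs)
            hits[ii] = index.overlaps_any(chrom, starts[ii], ends[ii])
            size = chrom_sizes.get(chrom)
            if size is None:
                raise ValueError(f"no chromosome size for {chrom}")
            max_start = np.maximum(size - lengths[ii], 1)
            rand_starts = (
                rng.random((n_perm, len(ii))) * max_start[None, :]
            ).astype(np.int64)
            flat_s = rand_starts.ravel()
            flat_e = flat_s + np.tile(lengths[ii], n_perm)
            null_hits[:, ii] = index.overlaps_any(chrom, flat_s, flat_e).reshape(
                n_perm, len(ii)
            )
        observed = hits.mean()
        null_props = null_hits.mean(axis=1)
        null_mean = float(null_props.mean())
        fold = observed / null_mean if null_mean > 0 else np.inf
        emp_p = (1 + int((null_props >= observed).sum())) / (1 + n_perm)
        results.append(
            EnrichmentResult(state, float(observed), null_mean, float(fold), emp_p, n_perm)
        )
    return results


# ---------------------------------------------------------------------------
# Pairwise co-localization across anchors


def _states_at_anchors(
    sites: Sequence[AnnotatedSite], loops: Sequence[Loop]
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """For each loop, the set of states overlapping each anchor."""
    per_state_index = {
        state: IntervalIndex([s.interval for s in sites if s.state == state])
        for state in {s.state for s in sites}
    }
    out = []
    for lp in loops:
        sets = []
        for anchor in (lp.anchor1, lp.anchor2):
            present = frozenset(
                state
                for state, idx in per_state_index.items()
                if idx.overlaps_any(
                    anchor.chrom,
                    np.array([anchor.start]),
                    np.array([anchor.end]),
                )[0]
            )
            sets.append(present)
        out.append((sets[0], sets[1]))
    return out


def pair_colocalization(
    sites: Sequence[AnnotatedSite], loops: Sequence[Loop]
) -> list[PairEnrichment]:
    """Fisher-exact enrichment for every unordered pair of chromatin states
    connected across loop anchors.

    Each loop contributes its two oriented anchor pairs. For states (A, B)
    the 2x2 table cross-classifies oriented pairs by "A present at the
    first anchor" and "B present at the second"; a positive odds ratio >1
    means A-anchors preferentially connect to B-anchors. Pairs involving a
    state present at no anchor are skipped.
    """
    anchor_states = _states_at_anchors(sites, loops)
    all_states = sorted({s.state for s in sites})
    present_somewhere = {
        st
        for st in all_states
        if any(st in a or st in b for a, b in anchor_states)
    }
    results: list[PairEnrichment] = []
    for i, sa in enumerate(all_states):
        for sb in all_states[i:]:
            if sa not in present_somewhere or sb not in present_somewhere:
                logger.info("state pair (%s, %s) not estimable; skipped", sa, sb)
                continue
            n11 = n10 = n01 = n00 = 0
            for left, right in anchor_states:
                for first, second in ((left, right), (right, left)):
                    x, y = sa in first, sb in second
                    if x and y:
                        n11 += 1
                    elif x:
                        n10 += 1
                    elif y:
                        n01 += 1
                    else:
                        n00 += 1
            table = np.array([[n11, n10], [n01, n00]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                logger.info(
                    "state pair (%s, %s) has a degenerate table; skipped", sa, sb
                )
                continue
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            results.append(
                PairEnrichment(sa, sb, float(odds), float(p), ((n11, n10), (n01, n00)))
            )
    return results


# ---------------------------------------------------------------------------
# BEDPE I/O with metadata columns


BEDPE_HEADER = (
    "chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tresolution\tsource\tdepth\tsupport"
)


def read_bedpe(path: str | Path) -> list[Loop]:
    """Read loops from a BEDPE file with resolution/source/depth/support
    metadata columns (header optional)."""
    loops: list[Loop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom1\t"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            a1 = GenomicInterval(f[0], int(f[1]), int(f[2]))
            a2 = GenomicInterval(f[3], int(f[4]), int(f[5]))
            resolution = int(f[6]) if len(f) > 6 else a1.width
            source = f[7] if len(f) > 7 else "pooled"
            depth = float(f[8]) if len(f) > 8 else 0.0
            support = tuple(f[9].split(",")) if len(f) > 9 and f[9] else ()
            loops.append(Loop(a1, a2, resolution, source, depth, support))
    return loops


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(BEDPE_HEADER + "\n")
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t{a2.chrom}\t{a2.start}\t{a2.end}"
                f"\t{lp.resolution}\t{lp.source}\t{lp.depth:g}\t{','.join(lp.support)}\n"
            )
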