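"""Candidate target-gene assignment for islet enhancers.

Enhancers (active-enhancer chromatin-state elements) are linked to gene
promoters either through a chromatin loop — enhancer at one anchor, promoter
at the opposite anchor of the same loop, each optionally within a flanking
window of the anchor — or by direct promoter proximity. Alternate, much
looser gene sets based on a +/-1 Mb window or the containing TAD are
provided for comparison.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import AnnotatedSite, GeneModel, GenomicInterval, Tad
from .loops import Loop

PROMOTER_UPSTREAM = 5000
PROMOTER_DOWNSTREAM = 2000


@dataclass(frozen=True)
class PromoterRegion:
    """Gene promoter window: 5 kb upstream to 2 kb downstream of the TSS,
    oriented by strand and clamped at the chromosome start."""

    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class EnhancerGeneEdge:
    """A candidate regulatory link between an enhancer element and a gene.

    ``loop_id`` is the index of the witnessing loop in the merged loop list,
    or -1 for promoter-proximal edges. ``distance`` separates enhancer and
    promoter midpoints.
    """

    enhancer: AnnotatedSite
    gene_id: str
    loop_id: int
    distance: float

    @property
    def via_loop(self) -> bool:
        return self.loop_id >= 0


def promoter_regions(
    genes: Sequence[GeneModel], strand_aware: bool = True
) -> list[PromoterRegion]:
    """Promoter windows (-5 kb / +2 kb of the TSS).

    With ``strand_aware`` (default) the 5 kb arm extends upstream with
    respect to the gene's strand; otherwise all genes are treated as
    plus-strand.
    """
    out = []
    for g in genes:
        if strand_aware and g.strand == "-":
            lo, hi = g.tss - PROMOTER_DOWNSTREAM, g.tss + PROMOTER_UPSTREAM
        else:
            lo, hi = g.tss - PROMOTER_UPSTREAM, g.tss + PROMOTER_DOWNSTREAM
        out.append(PromoterRegion(g.gene_id, GenomicInterval(g.chrom, max(0, lo), hi)))
    return out


def _overlaps_with_flank(iv: GenomicInterval, anchor: GenomicInterval, flank: int) -> bool:
    if iv.chrom != anchor.chrom:
        return False
    return iv.start < anchor.end + flank and anchor.start - flank < iv.end


def map_enhancer_targets(
    enhancers: Sequence[AnnotatedSite],
    promoters: Sequence[PromoterRegion],
    loops: Sequence[Loop],
    flank: int = 0,
) -> list[EnhancerGeneEdge]:
    """Loop-mediated enhancer-gene edges.

    An edge (enhancer, gene) exists when the enhancer overlaps one anchor
    (expanded by ``flank``) and the gene's promoter overlaps the opposite
    anchor (same flank) of the same loop. Same-anchor co-occupancy is not an
    edge. Edges are deduplicated on (enhancer, gene, loop).
    """
    prom_by_chrom: dict[str, list[PromoterRegion]] = defaultdict(list)
    for p in promoters:
        prom_by_chrom[p.interval.chrom].append(p)
    enh_by_chrom: dict[str, list[AnnotatedSite]] = defaultdict(list)
    for e in enhancers:
        enh_by_chrom[e.interval.chrom].append(e)

    edges: set[EnhancerGeneEdge] = set()
    for loop_id, lp in enumerate(loops):
        chrom = lp.anchor1.chrom
        cand_enh = enh_by_chrom.get(chrom, ())
        cand_prom = prom_by_chrom.get(chrom, ())
        if not cand_enh or not cand_prom:
            continue
        for a_enh, a_prom in ((lp.anchor1, lp.anchor2), (lp.anchor2, lp.anchor1)):
            hits_e = [
                e for e in cand_enh if _overlaps_with_flank(e.interval, a_enh, flank)
            ]
            if not hits_e:
                continue
            hits_p = [
                p for p in cand_prom if _overlaps_with_flank(p.interval, a_prom, flank)
            ]
            for e in hits_e:
                for p in hits_p:
                    edges.add(
                        EnhancerGeneEdge(
                            e,
                            p.gene_id,
                            loop_id,
                            abs(e.interval.midpoint - p.interval.midpoint),
                        )
                    )
    return sorted(
        edges,
        key=lambda ed: (
            ed.enhancer.interval.chrom,
            ed.enhancer.interval.start,
            ed.gene_id,
            ed.loop_id,
        ),
    )


def degree_counts(
    edges: Iterable[EnhancerGeneEdge],
) -> tuple[dict[str, int], dict[GenomicInterval, int], dict[str, int]]:
    """Per-gene and per-enhancer connection counts from an edge list.

    Returns
    -------
    genes_to_enhancers
        Distinct enhancer elements looped to each gene.
    enhancers_to_genes
        Distinct genes looped to each enhancer (keyed by enhancer interval).
    genes_to_loops
        Distinct loops carrying at least one enhancer per gene (the
        multi-loop analysis).
    """
    gene_enh: dict[str, set] = defaultdict(set)
    enh_gene: dict[GenomicInterval, set] = defaultdict(set)
    gene_loops: dict[str, set] = defaultdict(set)
    for ed in edges:
        gene_enh[ed.gene_id].add(ed.enhancer.interval)
        enh_gene[ed.enhancer.interval].add(ed.gene_id)
        if ed.via_loop:
            gene_loops[ed.gene_id].add(ed.loop_id)
    return (
        {g: len(v) for g, v in gene_enh.items()},
        {e: len(v) for e, v in enh_gene.items()},
        {g: len(v) for g, v in gene_loops.items()},
    )


def window_gene_set(
    variant_chrom: str,
    variant_pos: int,
    promoters: Sequence[PromoterRegion],
    half_window: int = 1_000_000,
) -> set[str]:
    """Genes whose promoter overlaps a +/-``half_window`` window around the
    variant position."""
    lo, hi = max(0, variant_pos - half_window), variant_pos + half_window
    return {
        p.gene_id
        for p in promoters
        if p.interval.chrom == variant_chrom
        and p.interval.start < hi
        and lo < p.interval.end
    }


def tad_gene_set(
    variant_chrom: str,
    variant_pos: int,
    tads: Sequence[Tad],
    promoters: Sequence[PromoterRegion],
) -> set[str]:
    """Genes whose promoter overlaps the TAD containing the variant.

    An empty set (with a warning) is returned when the variant falls in no
    TAD.
    """
    containing = [
        t
        for t in tads
        if t.interval.chrom == variant_chrom
        and t.interval.start <= variant_pos < t.interval.end
    ]
    if not containing:
        warnings.warn(
            f"variant {variant_chrom}:{variant_pos} falls in no TAD; empty gene set"
        )
        return set()
    out: set[str] = set()
    for t in containing:
        for p in promoters:
            if p.interval.overlaps(t.interval):
                out.add(p.gene_id)
    return out


def assign_signal_targets(
    signal_enhancers: Sequence[AnnotatedSite],
    promoters: Sequence[PromoterRegion],
    loops: Sequence[Loop],
    flank: int = 25_000,
) -> set[str]:
    """Candidate target genes of a GWAS signal's enhancer variants.

    A gene qualifies when, for any of the signal's enhancer elements,
    (a) enhancer and promoter are each within ``flank`` of the opposite
    anchors of one loop, or (b) the enhancer lies within ``flank`` of the
    promoter region itself.

    Raises
    ------
    ValueError
        If the signal carries no enhancer element (callers must pre-filter).
    """
    if not signal_enhancers:
        raise ValueError("signal has no enhancer variants; pre-filter signals")
    genes: set[str] = set()
    loop_edges = map_enhancer_targets(signal_enhancers, promoters, loops, flank=flank)
    genes.update(ed.gene_id for ed in loop_edges)
    for e in signal_enhancers:
        for p in promoters:
            if (
                p.interval.chrom == e.interval.chrom
                and e.interval.distance_to(p.interval) <= flank
            ):
                genes.add(p.gene_id)
    return genes


def promoters_by_gene(
    promoters: Sequence[PromoterRegion],
) -> Mapping[str, PromoterRegion]:
    return {p.gene_id: p for p in promoters}
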