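"""Promoter-swap detection and expression asymmetry.

A promoter swap places the complete coding sequence of a partner gene under
the regulatory region of another gene (e.g. ELF1 driven by the FRS2 or TP53
promoter). Detection works from consensus DNA structural variants plus a
gene model: one breakend must fall inside the promoter-donor gene just
downstream of its promoter (intron 1 by default) with the junction
retaining the 5' part, while the mate breakend must land upstream of the
partner gene's CDS with the junction retaining everything 3', so that the
partner's full coding sequence is transcribed from the donated promoter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Breakend, SVCall

__all__ = [
    "GeneModel",
    "PromoterSwapEvent",
    "detect_swaps",
    "exon_asymmetry",
    "cohort_rank",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """Minimal transcript model.

    ``exons`` are genomic (start, end) intervals listed in transcription
    order (5'->3'), so for '-' strand genes coordinates decrease along the
    list. ``promoter`` is the regulatory interval immediately upstream of
    exon 1; ``cds_start`` is the genomic coordinate of the translation
    start (the 5'-most CDS base in transcription direction).
    """

    name: str
    chrom: str
    strand: str
    promoter: tuple[int, int]
    exons: tuple[tuple[int, int], ...]
    cds_start: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        starts = [e[0] for e in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else \
            starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(f"{self.name}: exons not in transcription order")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def tx_start(self) -> int:
        """Genomic coordinate of the transcription start (5' end)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[0][1]

    @property
    def tx_interval(self) -> tuple[int, int]:
        lo = min(e[0] for e in self.exons)
        hi = max(e[1] for e in self.exons)
        return lo, hi

    @property
    def locus(self) -> tuple[int, int]:
        """Gene body plus promoter; the unit of amplification bookkeeping."""
        lo, hi = self.tx_interval
        return min(lo, self.promoter[0]), max(hi, self.promoter[1])

    def intron(self, i: int) -> tuple[int, int]:
        """Genomic interval of intron ``i`` (1-based, after exon i)."""
        if not 1 <= i < self.n_exons:
            raise ValueError(f"{self.name} has no intron {i}")
        a, b = self.exons[i - 1], self.exons[i]
        if self.strand == "+":
            return a[1], b[0]
        return b[1], a[0]

    def exons_upstream_of(self, pos: int) -> set[int]:
        """1-based exon indices lying fully 5' of a genomic position."""
        out = set()
        for idx, (s, e) in enumerate(self.exons, start=1):
            if (self.strand == "+" and e <= pos) or \
               (self.strand == "-" and s >= pos):
                out.add(idx)
        return out

    def exons_downstream_of(self, pos: int) -> set[int]:
        """1-based exon indices lying fully 3' of a genomic position."""
        return {i for i in range(1, self.n_exons + 1)
                if i not in self.exons_upstream_of(pos)
                and self._fully_3prime(i, pos)}

    def _fully_3prime(self, idx: int, pos: int) -> bool:
        s, e = self.exons[idx - 1]
        return s >= pos if self.strand == "+" else e <= pos


@dataclass
class PromoterSwapEvent:
    """A detected promoter swap, optionally chained (three-way fusions)."""

    promoter_gene: str
    partner_gene: str
    dna_breakpoints: tuple[Breakend, Breakend]
    promoter_included_exons: frozenset[int]
    promoter_excluded_exons: frozenset[int]
    partner_fused_exons: frozenset[int] = frozenset()
    chain: tuple[str, ...] = ()
    asymmetry_ratio: float | None = None
    partner_rank: int | None = None
    n_cohort: int | None = None


def _promoter_side_hit(gene: GeneModel, bnd: Breakend,
                       intron_index: int) -> bool:
    """Breakend inside the acceptance intron with the 5' part retained."""
    if bnd.chrom != gene.chrom or gene.n_exons <= intron_index:
        return False
    lo, hi = gene.intron(intron_index)
    if not lo <= bnd.pos < hi:
        return False
    # Retaining the 5' flank means the junction faces 3': for '+' genes the
    # right flank is lost (side "right"), for '-' genes the left flank.
    return bnd.side == ("right" if gene.strand == "+" else "left")


def _partner_side_hit(gene: GeneModel, bnd: Breakend) -> bool:
    """Breakend upstream of the CDS with the complete CDS retained 3'."""
    if bnd.chrom != gene.chrom:
        return False
    if gene.strand == "+":
        lo, hi = min(gene.tx_start, gene.promoter[0]), gene.cds_start
        if not lo <= bnd.pos < hi:
            return False
        return bnd.side == "left"
    lo, hi = gene.cds_start, max(gene.tx_start, gene.promoter[1])
    if not lo < bnd.pos <= hi:
        return False
    return bnd.side == "right"


def detect_swaps(consensus_svs: list[SVCall],
                 gene_models: dict[str, GeneModel],
                 intron_index: int = 1) -> list[PromoterSwapEvent]:
    """Scan consensus SVs for promoter-swap junctions.

    The result is independent of SV input order. Events sharing a gene such
    that one event's partner donates its 5' part in another event are
    chained into a single multi-gene record (three-way fusions of the
    ALDH2::PLEKHA5::ATF7 kind).
    """
    genes = sorted(gene_models.values(), key=lambda g: g.name)
    raw: list[PromoterSwapEvent] = []
    for sv in sorted(consensus_svs, key=lambda s: s.key()):
        for bp, bq in ((sv.bnd1, sv.bnd2), (sv.bnd2, sv.bnd1)):
            pgenes = [g for g in genes if _promoter_side_hit(g, bp, intron_index)]
            qgenes = [g for g in genes
                      if _partner_side_hit(g, bq) and g not in pgenes]
            if not pgenes and not qgenes:
                log.debug("breakends %s / %s in unannotated territory", bp, bq)
            for pg in pgenes:
                for qg in qgenes:
                    if pg.name == qg.name:
                        continue
                    included = frozenset(pg.exons_upstream_of(
                        bp.pos + (1 if pg.strand == "+" else 0)))
                    excluded = frozenset(range(1, pg.n_exons + 1)) - included
                    fused = frozenset(qg.exons_downstream_of(bq.pos))
                    raw.append(PromoterSwapEvent(
                        promoter_gene=pg.name, partner_gene=qg.name,
                        dna_breakpoints=(bp, bq),
                        promoter_included_exons=included,
                        promoter_excluded_exons=excluded,
                        partner_fused_exons=fused,
                        chain=(pg.name, qg.name)))
    # Deduplicate identical events (the same junction can be listed once
    # per supporting direction).
    seen = {}
    for ev in raw:
        key = (ev.promoter_gene, ev.partner_gene, ev.dna_breakpoints)
        seen.setdefault(key, ev)
    events = list(seen.values())
    return _chain_events(events)


def _chain_events(events: list[PromoterSwapEvent]) -> list[PromoterSwapEvent]:
    """Merge X->Y and Y->Z events into one chained X->Y->Z record."""
    by_promoter = {}
    for ev in events:
        by_promoter.setdefault(ev.promoter_gene, []).append(ev)
    consumed = set()
    out = []
    for ev in events:
        if id(ev) in consumed:
            continue
        chain = list(ev.chain)
        tail = ev
        while True:
            nxts = [e for e in by_promoter.get(tail.partner_gene, [])
                    if id(e) not in consumed and e is not ev]
            if not nxts:
                break
            nxt = nxts[0]
            consumed.add(id(nxt))
            chain.append(nxt.partner_gene)
            tail = nxt
        consumed.add(id(ev))
        if len(chain) > 2:
            out.append(PromoterSwapEvent(
                promoter_gene=chain[0], partner_gene=chain[-1],
                dna_breakpoints=ev.dna_breakpoints,
                promoter_included_exons=ev.promoter_included_exons,
                promoter_excluded_exons=ev.promoter_excluded_exons,
                partner_fused_exons=tail.partner_fused_exons,
                chain=tuple(chain)))
        else:
            out.append(ev)
    return out


def exon_asymmetry(exon_expr: np.ndarray | list[float],
                   included: set[int] | frozenset[int]) -> float:
    """Mean expression of fusion-included exons over excluded exons.

    Exon indices are 1-based. Scale-invariant; an excluded mean of zero
    yields +inf as a flagged sentinel.
    """
    expr = np.asarray(exon_expr, dtype=float)
    idx = sorted(included)
    if not idx or len(idx) == len(expr):
        raise ValueError("both exon partitions must be non-empty")
    mask = np.zeros(len(expr), dtype=bool)
    mask[[i - 1 for i in idx]] = True
    inc_mean = expr[mask].mean()
    exc_mean = expr[~mask].mean()
    if exc_mean == 0:
        return float("inf")
    return float(inc_mean / exc_mean)


def cohort_rank(gene: str, sample_id: str,
                expression: pd.DataFrame) -> tuple[int, int]:
    """Dense descending rank of a sample's expression among the cohort.

    Ties share the better (smaller) rank; 1 = highest expression.
    """
    if gene not in expression.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = expression.loc[gene]
    if sample_id not in row.index:
        raise KeyError(f"sample {sample_id!r} not in expression matrix")
    ranks = row.rank(method="dense", ascending=False)
    return int(ranks[sample_id]), int(row.size)
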