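"""Cross-caller structural-variant consensus and RNA-fusion noise filtering.

DNA structural variants are considered true when identified by at least two
of the callers (single-linkage clustering of cross-caller matches within a
breakpoint tolerance). RNA fusion candidates are considered noise if
identified by only one of the two fusion programs, or if no consensus DNA
structural variant links the two gene loci — mirroring automatic RNA/DNA
fusion matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median_low

from .genome import Breakend, SVCall
from .promoter_swap import GeneModel

__all__ = [
    "ConsensusSV",
    "FusionCandidate",
    "match_breakpoints",
    "consensus_filter",
    "filter_fusions",
    "DEFAULT_DNA_TOL",
    "DEFAULT_RNA_TOL",
]

DEFAULT_DNA_TOL = 1000
DEFAULT_RNA_TOL = 10_000


@dataclass
class ConsensusSV:
    """A structural variant supported by >= min_callers independent callers.

    The representative breakend positions are per-end medians of the
    supporting calls.
    """

    bnd1: Breakend
    bnd2: Breakend
    orientation: str
    supporting_callers: frozenset[str]
    calls: tuple[SVCall, ...] = ()

    def as_svcall(self) -> SVCall:
        return SVCall(self.bnd1, self.bnd2, self.orientation,
                      caller_id="consensus",
                      quality=float(len(self.supporting_callers)))


@dataclass
class FusionCandidate:
    """RNA-level fusion candidate with program provenance.

    ``breakpoint5``/``breakpoint3`` are the genomic projections of the RNA
    breakpoints (exon-edge coordinates) of the 5' and 3' genes.
    """

    gene5: str
    gene3: str
    breakpoint5: tuple[str, int]
    breakpoint3: tuple[str, int]
    programs: frozenset[str]
    dna_supported: bool = False
    matched_sv: ConsensusSV | None = None

    def __post_init__(self):
        if self.gene5 == self.gene3:
            raise ValueError("5' and 3' fusion genes must differ")


def match_breakpoints(a: SVCall, b: SVCall, tol: int,
                      require_orientation: bool = True) -> bool:
    """True iff two calls describe the same junction within tolerance.

    Same chromosome pair, same orientation class (optional), and both
    breakend distances <= tol.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if (a.bnd1.chrom, a.bnd2.chrom) != (b.bnd1.chrom, b.bnd2.chrom):
        return False
    if require_orientation and a.orientation != b.orientation:
        return False
    return (abs(a.bnd1.pos - b.bnd1.pos) <= tol
            and abs(a.bnd2.pos - b.bnd2.pos) <= tol)


def consensus_filter(callsets: list[list[SVCall]], min_callers: int = 2,
                     tol: int = DEFAULT_DNA_TOL,
                     require_orientation: bool = True) -> list[ConsensusSV]:
    """Single-linkage clustering of matching calls across callers.

    Clusters supported by >= min_callers distinct callers are emitted with
    per-end median representative positions. Processing order is fixed by
    sorting, so permuting the caller list or within-caller order leaves the
    output unchanged.
    """
    if len(callsets) < min_callers:
        raise ValueError("need at least min_callers call sets")
    calls = sorted((c for cs in callsets for c in cs),
                   key=lambda c: (c.key(), c.caller_id))
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if match_breakpoints(calls[i], calls[j], tol,
                                 require_orientation):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[SVCall]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(calls[i])

    out = []
    for root in sorted(clusters):
        members = clusters[root]
        callers = frozenset(c.caller_id for c in members)
        if len(callers) < min_callers:
            continue
        rep = members[0]
        pos1 = median_low(sorted(c.bnd1.pos for c in members))
        pos2 = median_low(sorted(c.bnd2.pos for c in members))
        out.append(ConsensusSV(
            bnd1=Breakend(rep.bnd1.chrom, pos1, rep.bnd1.side),
            bnd2=Breakend(rep.bnd2.chrom, pos2, rep.bnd2.side),
            orientation=rep.orientation,
            supporting_callers=callers,
            calls=tuple(members)))
    out.sort(key=lambda c: (c.bnd1.chrom, c.bnd1.pos, c.bnd2.chrom,
                            c.bnd2.pos))
    return out


def _sv_links_fusion(sv: ConsensusSV, bp5: tuple[str, int],
                     bp3: tuple[str, int], tol: int) -> bool:
    for end5, end3 in ((sv.bnd1, sv.bnd2), (sv.bnd2, sv.bnd1)):
        if (end5.chrom == bp5[0] and abs(end5.pos - bp5[1]) <= tol
                and end3.chrom == bp3[0] and abs(end3.pos - bp3[1]) <= tol):
            return True
    return False


def filter_fusions(candidates: list[FusionCandidate],
                   consensus_svs: list[ConsensusSV],
                   gene_models: dict[str, GeneModel],
                   tol: int = DEFAULT_RNA_TOL,
                   n_programs_required: int = 2) -> list[FusionCandidate]:
    """Remove fusion-candidate noise.

    A candidate is retained only if called by both fusion programs AND a
    consensus DNA structural variant links the two gene loci within ``tol``
    of the genomic projections of the RNA breakpoints. Retained candidates
    carry the matched SV for the RNA/DNA pairing report.
    """
    retained = []
    for cand in candidates:
        for gene in (cand.gene5, cand.gene3):
            if gene not in gene_models:
                raise KeyError(f"gene {gene!r} absent from gene model")
        if len(cand.programs) < n_programs_required:
            continue
        match = next((sv for sv in consensus_svs
                      if _sv_links_fusion(sv, cand.breakpoint5,
                                          cand.breakpoint3, tol)), None)
        cand.dna_supported = match is not None
        cand.matched_sv = match
        if cand.dna_supported:
            retained.append(cand)
    return retained
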