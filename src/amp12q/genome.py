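"""Coordinate-aware data model for rearranged cancer genomes.

Segments, copy-number profiles, breakends and derivative chromosomes with
exact integer copy-number bookkeeping. Internal coordinates are 0-based
half-open; external formats (VCF, SEG) are converted at the I/O boundary.

Breakend ``side`` denotes the flank of the position that faces the junction
(the flank lost at this end of the join). The four intrachromosomal junction
classes follow read-pair mapping conventions:

====================  ============================
(side1, side2)        orientation class
====================  ============================
(right, left)         D   deletion-type
(left, right)         TD  tandem-duplication-type
(right, right)        HH  head-to-head inversion
(left, left)          TT  tail-to-tail inversion
====================  ============================

where breakends of an intrachromosomal call are ordered by position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "GenomeSpec",
    "Segment",
    "CNSegment",
    "CNProfile",
    "Breakend",
    "SVCall",
    "DerivativeChromosome",
    "orientation_of",
    "cn_from_derivative",
    "sv_from_derivative",
    "apply_cn_events",
    "expected_ploidy",
    "default_genome",
    "INTERCHROM",
]

INTERCHROM = "interchromosomal"

_ORIENTATION = {
    ("right", "left"): "D",
    ("left", "right"): "TD",
    ("right", "right"): "HH",
    ("left", "left"): "TT",
}

# hg19 chromosome lengths scaled 1:1000 (bp). Relative structure is what
# matters for the amplicon mechanisms; the reduced scale keeps per-base
# oracles tractable.
_HG19_KB = {
    "chr1": 249250, "chr2": 243199, "chr3": 198022, "chr4": 191154,
    "chr5": 180915, "chr6": 171115, "chr7": 159138, "chr8": 146364,
    "chr9": 141213, "chr10": 135534, "chr11": 135006, "chr12": 133851,
    "chr13": 115169, "chr14": 107349, "chr15": 102531, "chr16": 90354,
    "chr17": 81195, "chr18": 78077, "chr19": 59128, "chr20": 63025,
    "chr21": 48129, "chr22": 51304, "chrX": 155270, "chrY": 59373,
}


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome catalogue with lengths and sex.

    Centromeres are modelled as single midpoints, which is all that is
    needed to flag dicentric derivatives.
    """

    chromosomes: tuple[tuple[str, int], ...]
    sex: str = "female"

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def autosome_count(self) -> int:
        return sum(1 for c, _ in self.chromosomes if c not in ("chrX", "chrY"))

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def centromere(self, chrom: str) -> int:
        """Centromere position, modelled as the chromosome midpoint."""
        return self.length(chrom) // 2


def default_genome(sex: str = "female") -> GenomeSpec:
    """24-chromosome human-like toy genome, hg19 lengths scaled 1:1000."""
    return GenomeSpec(tuple(_HG19_KB.items()), sex=sex)


def expected_ploidy(genome: GenomeSpec, chrom: str) -> int:
    """Expected germline copy number: 2 for autosomes, sex-dependent for X/Y."""
    if chrom == "chrX":
        return 2 if genome.sex == "female" else 1
    if chrom == "chrY":
        return 1 if genome.sex == "male" else 0
    return 2


@dataclass(frozen=True)
class Segment:
    """Oriented reference interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def flipped(self) -> "Segment":
        return replace(self, strand="-" if self.strand == "+" else "+")

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= start and end <= self.end


@dataclass(frozen=True)
class CNSegment:
    """Strandless interval with integer total copy number.

    ``log2ratio`` is derived presentation metadata (rounded on export) and
    does not participate in equality.
    """

    chrom: str
    start: int
    end: int
    cn: int
    log2ratio: float = field(default=0.0, compare=False)

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.cn < 0:
            raise ValueError("copy number must be >= 0")


def _log2ratio(cn: int, ploidy: int) -> float:
    if ploidy <= 0:
        return 0.0
    if cn == 0:
        return float("-inf")
    return math.log2(cn / ploidy)


class CNProfile:
    """Genome-wide copy-number profile for one sample.

    Segments fully tile every chromosome (gaps forbidden) and adjacent
    segments with equal copy number are merged on construction, so the
    number of segments per chromosome is minimal and "visible copy number
    shift" counting is well defined.
    """

    def __init__(self, sample_id: str, genome: GenomeSpec,
                 segments: list[CNSegment]):
        self.sample_id = sample_id
        self.genome = genome
        by_chrom: dict[str, list[CNSegment]] = {c: [] for c in genome.names}
        for seg in segments:
            if seg.chrom not in by_chrom:
                raise ValueError(f"segment on unknown chromosome {seg.chrom}")
            if seg.end > genome.length(seg.chrom):
                raise ValueError(
                    f"segment [{seg.start},{seg.end}) exceeds {seg.chrom} "
                    f"length {genome.length(seg.chrom)}")
            by_chrom[seg.chrom].append(seg)
        self.segments: dict[str, list[CNSegment]] = {}
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            pos = 0
            merged: list[CNSegment] = []
            for seg in segs:
                if seg.start != pos:
                    raise ValueError(
                        f"{chrom}: coverage gap/overlap at {pos} vs "
                        f"segment start {seg.start}")
                if merged and merged[-1].cn == seg.cn:
                    prev = merged.pop()
                    seg = CNSegment(chrom, prev.start, seg.end, seg.cn,
                                    prev.log2ratio)
                merged.append(seg)
                pos = seg.end
            if pos != genome.length(chrom):
                raise ValueError(f"{chrom}: coverage ends at {pos}, expected "
                                 f"{genome.length(chrom)}")
            self.segments[chrom] = merged

    @classmethod
    def flat(cls, sample_id: str, genome: GenomeSpec) -> "CNProfile":
        """Unrearranged profile at expected ploidy everywhere."""
        segs = []
        for chrom, length in genome.chromosomes:
            ploidy = expected_ploidy(genome, chrom)
            segs.append(CNSegment(chrom, 0, length, ploidy,
                                  _log2ratio(ploidy, ploidy)))
        return cls(sample_id, genome, segs)

    def all_segments(self) -> list[CNSegment]:
        return [s for chrom in self.genome.names for s in self.segments[chrom]]

    def cn_at(self, chrom: str, pos: int) -> int:
        for seg in self.segments[chrom]:
            if seg.start <= pos < seg.end:
                return seg.cn
        raise ValueError(f"position {chrom}:{pos} outside profile")

    def max_cn(self, chrom: str, start: int, end: int) -> int:
        """Maximum copy number over an interval."""
        vals = [s.cn for s in self.segments[chrom]
                if s.start < end and start < s.end]
        if not vals:
            raise ValueError(f"interval {chrom}:{start}-{end} outside profile")
        return max(vals)

    def min_cn(self, chrom: str, start: int, end: int) -> int:
        vals = [s.cn for s in self.segments[chrom]
                if s.start < end and start < s.end]
        if not vals:
            raise ValueError(f"interval {chrom}:{start}-{end} outside profile")
        return min(vals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CNProfile):
            return NotImplemented
        return (self.sample_id == other.sample_id
                and self.genome == other.genome
                and self.segments == other.segments)


@dataclass(frozen=True, order=True)
class Breakend:
    """One end of a junction: position plus the junction-facing flank."""

    chrom: str
    pos: int
    side: str  # "left" or "right": flank of pos facing the junction

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left or right, got {self.side!r}")
        if self.pos < 0:
            raise ValueError("position must be >= 0")


def orientation_of(side1: str, side2: str, same_chrom: bool = True) -> str:
    """Junction orientation class from the two junction-facing flanks.

    Interchromosomal junctions are not assigned an intrachromosomal class.
    """
    if side1 not in ("left", "right") or side2 not in ("left", "right"):
        raise ValueError("sides must be 'left' or 'right'")
    if not same_chrom:
        return INTERCHROM
    return _ORIENTATION[(side1, side2)]


@dataclass(frozen=True)
class SVCall:
    """Breakend pair with orientation class and caller provenance.

    Intrachromosomal breakends are stored position-sorted; ``orientation``
    is always consistent with (bnd1.side, bnd2.side).
    """

    bnd1: Breakend
    bnd2: Breakend
    orientation: str
    caller_id: str = "unknown"
    quality: float = 0.0

    @classmethod
    def make(cls, bnd1: Breakend, bnd2: Breakend, caller_id: str = "unknown",
             quality: float = 0.0) -> "SVCall":
        """Canonical constructor: sorts breakends, derives orientation."""
        if (bnd1.chrom, bnd1.pos) > (bnd2.chrom, bnd2.pos):
            bnd1, bnd2 = bnd2, bnd1
        same = bnd1.chrom == bnd2.chrom
        return cls(bnd1, bnd2, orientation_of(bnd1.side, bnd2.side, same),
                   caller_id, quality)

    def key(self) -> tuple:
        return (self.bnd1.chrom, self.bnd1.pos, self.bnd1.side,
                self.bnd2.chrom, self.bnd2.pos, self.bnd2.side)


@dataclass
class DerivativeChromosome:
    """Ordered, oriented reference segments forming one derivative.

    Models supernumerary ring/marker chromosomes and dicentrics. ``history``
    records every stochastic operation applied, so a derivative is fully
    reproducible from its generating configuration and seed.
    """

    genome: GenomeSpec
    blocks: list[Segment] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)

    def __post_init__(self):
        for b in self.blocks:
            if b.chrom not in self.genome.lengths:
                raise ValueError(f"block on unknown chromosome {b.chrom}")
            if b.end > self.genome.length(b.chrom):
                raise ValueError(f"block [{b.start},{b.end}) outside "
                                 f"{b.chrom}")

    @property
    def centromere_count(self) -> int:
        """Number of blocks spanning a centromere midpoint."""
        n = 0
        for b in self.blocks:
            mid = self.genome.centromere(b.chrom)
            if b.start <= mid < b.end:
                n += 1
        return n

    def total_length(self) -> int:
        return sum(len(b) for b in self.blocks)

    def locus_copies(self, chrom: str, start: int, end: int) -> int:
        """Number of blocks fully containing a locus interval."""
        return sum(1 for b in self.blocks if b.contains(chrom, start, end))

    def record(self, op: str, **params) -> None:
        self.history.append({"op": op, **params})


def _block_junction_ends(prev: Segment, nxt: Segment) -> tuple[Breakend, Breakend]:
    """Breakends of the junction between two adjacent derivative blocks.

    The trailing end of a '+' block faces right of its last base; of a '-'
    block, left of its reference start. Leading ends mirror this.
    """
    if prev.strand == "+":
        b1 = Breakend(prev.chrom, prev.end - 1, "right")
    else:
        b1 = Breakend(prev.chrom, prev.start, "left")
    if nxt.strand == "+":
        b2 = Breakend(nxt.chrom, nxt.start, "left")
    else:
        b2 = Breakend(nxt.chrom, nxt.end - 1, "right")
    return b1, b2


def _contiguous(prev: Segment, nxt: Segment) -> bool:
    if prev.chrom != nxt.chrom or prev.strand != nxt.strand:
        return False
    if prev.strand == "+":
        return prev.end == nxt.start
    return nxt.end == prev.start


def sv_from_derivative(der: DerivativeChromosome,
                       caller_id: str = "truth") -> list[SVCall]:
    """Junctions implied by a derivative: one call per non-contiguous
    adjacent block pair. Splitting a block into contiguous sub-blocks does
    not change the output."""
    if not der.blocks:
        raise ValueError("derivative has no blocks")
    calls = []
    for prev, nxt in zip(der.blocks, der.blocks[1:]):
        if _contiguous(prev, nxt):
            continue
        b1, b2 = _block_junction_ends(prev, nxt)
        calls.append(SVCall.make(b1, b2, caller_id=caller_id))
    return calls


def apply_cn_events(baseline: CNProfile,
                    events: list[tuple[str, int, int, int]],
                    sample_id: str | None = None) -> CNProfile:
    """Add integer copy-number deltas over intervals to a baseline profile.

    ``events`` are (chrom, start, end, delta) with 0-based half-open
    coordinates; the result is re-segmented minimally. Negative resulting
    copy numbers indicate an inconsistent event list and raise.
    """
    genome = baseline.genome
    sample = sample_id if sample_id is not None else baseline.sample_id
    out: list[CNSegment] = []
    ev_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, start, end, delta in events:
        if chrom not in genome.lengths:
            raise ValueError(f"event on unknown chromosome {chrom}")
        if not 0 <= start < end <= genome.length(chrom):
            raise ValueError(f"event [{start},{end}) outside {chrom}")
        ev_by_chrom.setdefault(chrom, []).append((start, end, delta))
    for chrom, length in genome.chromosomes:
        ploidy = expected_ploidy(genome, chrom)
        cuts = {0, length}
        for seg in baseline.segments[chrom]:
            cuts.add(seg.start)
            cuts.add(seg.end)
        deltas: dict[int, int] = {}
        for start, end, delta in ev_by_chrom.get(chrom, []):
            cuts.add(start)
            cuts.add(end)
            deltas[start] = deltas.get(start, 0) + delta
            deltas[end] = deltas.get(end, 0) - delta
        bounds = sorted(cuts)
        running = 0
        for lo, hi in zip(bounds, bounds[1:]):
            running += deltas.get(lo, 0)
            cn = baseline.cn_at(chrom, lo) + running
            if cn < 0:
                raise ValueError(f"negative copy number at {chrom}:{lo}")
            out.append(CNSegment(chrom, lo, hi, cn, _log2ratio(cn, ploidy)))
    return CNProfile(sample, genome, out)


def cn_from_derivative(der: DerivativeChromosome, baseline: CNProfile,
                       sample_id: str | None = None) -> CNProfile:
    """Copy-number profile of baseline plus one copy of the derivative.

    For every reference base, cn = baseline cn + multiplicity of the base
    across derivative blocks; strand does not affect dosage.
    """
    events = [(b.chrom, b.start, b.end, 1) for b in der.blocks]
    return apply_cn_events(baseline, events, sample_id=sample_id)
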