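"""Synthetic-data engine for 12q13-15 amplicon mechanisms.

Generates ground-truth tumour genomes for the four case groups:

* chromothripsis of a chromosome 12 copy followed by breakage-fusion-bridge
  (BFB) amplification of selected loci (CDK4, MDM2, HMGA2) — groups A-C,
  with increasing genome-wide background alteration;
* disruption of the TP53 locus creating a dicentric chromosome whose
  break-repair cycles co-amplify CDK4 with a TP53-promoter gene fusion —
  group D;

plus imperfect observations: three DNA structural-variant callers with
per-caller sensitivity, breakpoint jitter and Poisson false positives, two
RNA fusion programs, and log-normal expression with copy-number dosage and
promoter-swap effects at gene and exon level.

All randomness flows through one seeded :class:`numpy.random.Generator`;
each stochastic operation is recorded in the derivative's history.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    Breakend,
    CNProfile,
    DerivativeChromosome,
    GenomeSpec,
    SVCall,
    Segment,
    apply_cn_events,
    cn_from_derivative,
    default_genome,
    expected_ploidy,
    sv_from_derivative,
)
from .promoter_swap import GeneModel

__all__ = [
    "SimConfig",
    "CallerModel",
    "ExpressionModel",
    "SwapTruth",
    "SimulatedCase",
    "toy_gene_models",
    "simulate_chromothripsis",
    "simulate_bfb",
    "simulate_tp53_dicentric",
    "observe_callers",
    "observe_fusions",
    "simulate_expression",
    "generate_case",
    "generate_cohort",
    "rna_cohort_labels",
    "simulate_swap_cohort",
    "default_caller_models",
    "GROUP_SIZES",
]

MAX_ATTEMPTS = 1000

# Study design: per-group case counts of the four-group scheme.
GROUP_SIZES = {"A": 3, "B": 10, "C": 7, "D": 5}

# RNA cohort composition: subtype sample counts, plus three additional
# profiles from multi-sampled 12q-amplified cases.
RNA_SUBTYPE_COUNTS = (
    ("OS_Conv", 69),
    ("OS_DDPar", 3),
    ("OS_Par", 4),
    ("OS_LGC", 3),
    ("OB", 13),
    ("OS_12q_multi", 3),
)


def _plus_gene(name: str, chrom: str, anchor: int) -> GeneModel:
    """Toy '+'-strand gene: 500 bp promoter, five 200 bp exons, 500 bp
    introns; CDS starts at exon 2 (exon 1 is 5' UTR)."""
    a = anchor
    exons = tuple((a + i * 700, a + i * 700 + 200) for i in range(5))
    return GeneModel(name=name, chrom=chrom, strand="+",
                     promoter=(a - 500, a), exons=exons, cds_start=a + 700)


def _minus_gene(name: str, chrom: str, anchor: int) -> GeneModel:
    """Toy '-'-strand gene; ``anchor`` is the transcription start (high
    coordinate), promoter immediately above it."""
    a = anchor
    exons = tuple((a - i * 700 - 200, a - i * 700) for i in range(5))
    return GeneModel(name=name, chrom=chrom, strand="-",
                     promoter=(a, a + 500), exons=exons, cds_start=a - 700)


def toy_gene_models() -> dict[str, GeneModel]:
    """Gene panel on the 1:1000 toy genome.

    Anchors follow the genes' proportional hg19 positions; bodies are
    enlarged (3 kb) so exon/intron structure survives realistic breakpoint
    jitter. FRS2 is nudged clear of MDM2.
    """
    genes = [
        _plus_gene("EPS8", "chr12", 15_700),
        _plus_gene("PLEKHA5", "chr12", 19_300),
        _plus_gene("ATF7", "chr12", 54_000),
        _plus_gene("CDK4", "chr12", 58_100),
        _plus_gene("HMGA2", "chr12", 64_000),
        _plus_gene("MDM2", "chr12", 69_200),
        _plus_gene("FRS2", "chr12", 73_500),
        _plus_gene("ALDH2", "chr12", 112_000),
        _plus_gene("ELF1", "chr13", 41_500),
        _plus_gene("ADAM32", "chr8", 39_000),
        _minus_gene("TP53", "chr17", 7_590),
    ]
    return {g.name: g for g in genes}


@dataclass
class SimConfig:
    """Per-case simulation parameters.

    ``selected_loci`` are (chrom, start, end, label) intervals under
    selection during BFB; ``genome_noise_rate`` is the expected number of
    background copy-number alterations per genome.
    """

    mechanism: str = "chromothripsis_bfb"  # or "tp53_dicentric", "none"
    group_label: str = "A"
    n_fragments: int = 40
    retention_prob: float = 0.6
    n_bfb_cycles: int = 4
    selected_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    genome_noise_rate: float = 0.0
    min_noise_events: int = 0
    template: str = "extra_copy"  # or "normal_homologue"
    swap_prob: float = 0.0
    swap_promoter_genes: tuple[str, ...] = ("FRS2", "PLEKHA5")
    tp53_mode: str = "promoter_fusion"  # or "homozygous_loss"
    cn_cap: int = 8  # array saturation level for observed copy numbers
    sex: str | None = None  # None -> drawn at random

    def __post_init__(self):
        if self.mechanism == "chromothripsis_bfb" and self.n_fragments < 2:
            raise ValueError("chromothripsis requires n_fragments >= 2")
        if not 0 < self.retention_prob <= 1:
            raise ValueError("retention_prob must be in (0, 1]")
        if self.n_bfb_cycles > 0 and self.mechanism == "chromothripsis_bfb" \
                and not self.selected_loci:
            raise ValueError("selected_loci required when n_bfb_cycles > 0")


@dataclass(frozen=True)
class CallerModel:
    """Abstract behaviour of one imperfect SV caller."""

    caller_id: str
    sensitivity: float = 0.9
    fp_rate: float = 2.0
    jitter_sd: float = 50.0

    def __post_init__(self):
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.fp_rate < 0 or self.jitter_sd < 0:
            raise ValueError("fp_rate and jitter_sd must be >= 0")


def default_caller_models() -> list[CallerModel]:
    return [CallerModel("caller1"), CallerModel("caller2"),
            CallerModel("caller3")]


@dataclass(frozen=True)
class ExpressionModel:
    """Log-normal expression with copy-number dosage and swap effects.

    Expression (log2) = gene baseline + dosage_exponent * log2(cn/2) +
    sample effect + exon noise; exons driven by a swapped promoter gain
    log2(swap_fold).
    """

    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 0.5
    dosage_exponent: float = 1.0
    swap_fold: float = 8.0
    noise_sd: float = 0.3

    def __post_init__(self):
        if self.swap_fold <= 1:
            raise ValueError("swap_fold must be > 1")
        if self.baseline_log_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class SwapTruth:
    """Ground-truth promoter swap inserted into a simulated genome."""

    promoter_gene: str
    partner_gene: str
    breakpoints: tuple[Breakend, Breakend]
    promoter_included_exons: frozenset[int]
    partner_fused_exons: frozenset[int]


@dataclass
class SimulatedCase:
    """One simulated tumour: exact truth plus imperfect observations.

    ``true_cn`` is the exact copy-number bookkeeping of the derivative over
    its baseline; ``observed_cn`` is the same profile after array-style
    saturation of very high copy numbers.
    """

    case_id: str
    group_label: str
    sex: str
    genome: GenomeSpec
    config: SimConfig
    derivative: DerivativeChromosome | None
    true_svs: list[SVCall]
    true_swaps: list[SwapTruth]
    true_cn: CNProfile
    observed_cn: CNProfile
    callsets: dict[str, list[SVCall]]
    fusion_candidates: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# mechanism simulators
# ---------------------------------------------------------------------------

def simulate_chromothripsis(genome: GenomeSpec, chrom: str, n_fragments: int,
                            retention_prob: float,
                            rng: np.random.Generator,
                            protected_loci: list[tuple[int, int]] = (),
                            ) -> tuple[DerivativeChromosome,
                                       list[tuple[int, int]]]:
    """Shatter one chromosome copy and re-ligate retained fragments.

    The copy is cut at ``n_fragments - 1`` uniform positions; each fragment
    is independently retained with ``retention_prob``, retained fragments
    are uniformly permuted and each flipped with probability 1/2.
    ``protected_loci`` (selection for tumour-driving genes) are never cut
    and fragments containing them are always retained. Returns the
    derivative and the list of lost fragment intervals.

    Raises after a bounded number of all-fragments-lost retries.
    """
    if n_fragments < 2:
        raise ValueError("n_fragments must be >= 2")
    length = genome.length(chrom)
    forbidden = sorted(protected_loci)
    allowed = np.ones(length - 1, dtype=bool)  # cut between pos and pos+1
    for lo, hi in forbidden:
        allowed[max(lo - 1, 0):hi] = False
    candidates = np.flatnonzero(allowed) + 1
    if candidates.size < n_fragments - 1:
        raise ValueError("not enough cuttable positions")
    for attempt in range(MAX_ATTEMPTS):
        cuts = np.sort(rng.choice(candidates, size=n_fragments - 1,
                                  replace=False))
        bounds = [0, *cuts.tolist(), length]
        frags = [(a, b) for a, b in zip(bounds, bounds[1:])]
        keep_draw = rng.random(len(frags)) < retention_prob
        keep = [k or any(a <= lo and hi <= b for lo, hi in forbidden)
                for k, (a, b) in zip(keep_draw, frags)]
        retained = [f for f, k in zip(frags, keep) if k]
        if retained:
            break
    else:
        raise RuntimeError("chromothripsis retained zero fragments "
                           f"after {MAX_ATTEMPTS} attempts")
    order = rng.permutation(len(retained))
    flips = rng.random(len(retained)) < 0.5
    blocks = []
    for idx in order:
        a, b = retained[idx]
        strand = "-" if flips[idx] else "+"
        blocks.append(Segment(chrom, a, b, strand))
    der = DerivativeChromosome(genome, blocks)
    der.record("chromothripsis", chrom=chrom, cuts=[int(c) for c in cuts],
               retained=[list(f) for f in retained],
               order=[int(i) for i in order],
               flips=[bool(f) for f in flips])
    lost = [f for f, k in zip(frags, keep) if not k]
    return der, lost


def _flip_blocks(blocks: list[Segment]) -> list[Segment]:
    return [b.flipped() for b in reversed(blocks)]


def _split_blocks(blocks: list[Segment], offset: int
                  ) -> tuple[list[Segment], list[Segment]]:
    """Split a block list at a derivative-coordinate offset."""
    total = sum(len(b) for b in blocks)
    if not 0 < offset < total:
        raise ValueError("split offset must be interior")
    prefix, suffix = [], []
    pos = 0
    for i, b in enumerate(blocks):
        if pos + len(b) <= offset:
            prefix.append(b)
            pos += len(b)
            continue
        cut = offset - pos
        if cut == 0:
            suffix = blocks[i:]
        else:
            if b.strand == "+":
                prefix.append(Segment(b.chrom, b.start, b.start + cut, "+"))
                suffix = [Segment(b.chrom, b.start + cut, b.end, "+"),
                          *blocks[i + 1:]]
            else:
                prefix.append(Segment(b.chrom, b.end - cut, b.end, "-"))
                suffix = [Segment(b.chrom, b.start, b.end - cut, "-"),
                          *blocks[i + 1:]]
        break
    return prefix, suffix


def _locus_copies(blocks: list[Segment], chrom: str, lo: int, hi: int) -> int:
    return sum(1 for b in blocks if b.contains(chrom, lo, hi))


def _junction_keys(blocks: list[Segment]) -> list[frozenset]:
    from .genome import _block_junction_ends, _contiguous
    keys = []
    for prev, nxt in zip(blocks, blocks[1:]):
        if _contiguous(prev, nxt):
            continue
        b1, b2 = _block_junction_ends(prev, nxt)
        keys.append(frozenset([(b1.chrom, b1.pos, b1.side),
                               (b2.chrom, b2.pos, b2.side)]))
    return keys


def simulate_bfb(der: DerivativeChromosome,
                 selected_loci: list[tuple[str, int, int, str]],
                 n_cycles: int, rng: np.random.Generator,
                 min_copies: dict[str, int] | None = None,
                 required_junctions: list[frozenset] = (),
                 fallback_min: dict[str, int] | None = None,
                 ) -> DerivativeChromosome:
    """Breakage-fusion-bridge amplification under locus selection.

    Per cycle the derivative fuses with its inverted sister copy, the
    palindrome breaks at a uniform position, and one of the two products
    survives. A surviving product must contain at least one copy of every
    selected locus (``min_copies`` can raise individual requirements) and
    every ``required_junctions`` adjacency; among the copy-richer and
    copy-poorer valid products, survival probability is proportional to the
    product's selected-locus copy count (selection favours amplification).
    Fold-back junctions emitted at fusion points are of HH/TT type.

    A cycle whose break yields no valid product is a die-out and is
    resampled up to a bound; if ``fallback_min`` is given the cycle is then
    retried once under those weaker requirements (a geometrically
    over-constrained selection target), otherwise an error names the
    failing locus.
    """
    if not der.blocks:
        raise ValueError("derivative must be non-empty")
    if n_cycles == 0:
        return der
    if min_copies is None:
        min_copies = {}

    def attempt_cycle(blocks, floors):
        doubled = blocks + _flip_blocks(blocks)
        total = sum(len(b) for b in doubled)
        for attempt in range(MAX_ATTEMPTS):
            offset = int(rng.integers(1, total))
            prefix, suffix = _split_blocks(doubled, offset)
            valid, weights = [], []
            for product in (prefix, suffix):
                ok = all(
                    _locus_copies(product, c, lo, hi)
                    >= floors.get(label, 1)
                    for c, lo, hi, label in selected_loci)
                if ok and required_junctions:
                    keys = _junction_keys(product)
                    ok = all(k in keys for k in required_junctions)
                if ok:
                    valid.append(product)
                    weights.append(sum(
                        _locus_copies(product, c, lo, hi)
                        for c, lo, hi, label in selected_loci))
            if valid:
                w = np.asarray(weights, dtype=float)
                pick = int(rng.choice(len(valid), p=w / w.sum())) \
                    if len(valid) > 1 else 0
                return valid[pick]
        return None

    blocks = list(der.blocks)
    for cycle in range(n_cycles):
        chosen = attempt_cycle(blocks, min_copies)
        if chosen is None and fallback_min is not None:
            chosen = attempt_cycle(blocks, fallback_min)
        if chosen is None:
            missing = next(
                (label for c, lo, hi, label in selected_loci
                 if _locus_copies(blocks, c, lo, hi)
                 < min_copies.get(label, 1)),
                selected_loci[0][3] if selected_loci else "junction")
            raise RuntimeError(
                f"BFB cycle {cycle} died out {MAX_ATTEMPTS} times "
                f"(locus {missing})")
        blocks = chosen
    out = DerivativeChromosome(der.genome, blocks, list(der.history))
    out.record("bfb", n_cycles=n_cycles,
               loci=[label for *_, label in selected_loci])
    return out


def _amplification_ring(der: DerivativeChromosome,
                        selected_loci: list[tuple[str, int, int, str]],
                        rng: np.random.Generator) -> DerivativeChromosome:
    """Compact circularisable sub-derivative around the selected loci.

    Fragments of the shattered derivative containing selected loci are
    trimmed to the loci plus a random flank, permuted and re-oriented;
    BFB cycles then amplify this ring rather than the whole derivative.
    """
    groups: dict[int, tuple[Segment, list[tuple[int, int]]]] = {}
    for chrom, lo, hi, _ in selected_loci:
        block = next((b for b in der.blocks if b.contains(chrom, lo, hi)),
                     None)
        if block is None:
            raise RuntimeError(f"no derivative block contains locus "
                               f"{chrom}:{lo}-{hi}")
        entry = groups.setdefault(id(block), (block, []))
        entry[1].append((lo, hi))
    sub_blocks = []
    for block, intervals in groups.values():
        lo = min(l for l, _ in intervals)
        hi = max(h for _, h in intervals)
        margin = int(rng.integers(600, 1500))
        start = max(block.start, lo - margin)
        end = min(block.end, hi + margin)
        strand = "+" if rng.random() < 0.5 else "-"
        sub_blocks.append(Segment(block.chrom, start, end, strand))
    order = rng.permutation(len(sub_blocks))
    ring = DerivativeChromosome(der.genome,
                                [sub_blocks[i] for i in order])
    ring.record("amplification_ring", n_blocks=len(sub_blocks))
    return ring


def simulate_tp53_dicentric(genome: GenomeSpec, genes: dict[str, GeneModel],
                            n_cycles: int, rng: np.random.Generator,
                            partner_gene: str = "ELF1",
                            ) -> tuple[DerivativeChromosome, SwapTruth,
                                       list[tuple[str, int, int, int]]]:
    """TP53-disruption mechanism of group D.

    Chromosome 17 breaks inside TP53 between promoter and CDS; the
    promoter-bearing (centromeric) arm fuses to a partner chromosome arm
    that carries its own centromere, creating a dicentric and placing the
    partner gene's complete CDS under the TP53 promoter. A fragment of a
    chromosome 12 homologue containing CDK4 (but not MDM2 or HMGA2) is then
    captured, and break-repair cycles amplify CDK4 while retaining the
    TP53-promoter junction.

    Returns the derivative, the true TP53 fusion record, and baseline
    copy-number events for the donor homologues (whole-homologue losses
    that manifest as the chromosome 12 deletions seen in these cases).
    """
    tp53 = genes["TP53"]
    partner = genes[partner_gene]
    if partner.strand != "+":
        raise ValueError("partner gene must be '+' strand in this model")
    cdk4 = genes["CDK4"]
    intron_lo, intron_hi = tp53.intron(1)
    split = int(rng.integers(intron_lo + 20, intron_hi - 20))
    bq = int(rng.integers(partner.tx_start + 10, partner.cds_start - 10))
    len17 = genome.length(tp53.chrom)
    lenq = genome.length(partner.chrom)
    blocks = [Segment(tp53.chrom, split, len17, "-"),
              Segment(partner.chrom, bq, lenq, "+")]
    der = DerivativeChromosome(genome, blocks)
    der.record("tp53_dicentric_fusion", split=split, partner=partner_gene,
               partner_break=bq)
    assert der.centromere_count == 2, "fusion must create a dicentric"
    fusion_keys = _junction_keys(der.blocks)

    # Capture of a CDK4-bearing chromosome 12 fragment.
    lo, hi = cdk4.locus
    cap_lo = int(rng.integers(lo - 6000, lo - 500))
    cap_hi = int(rng.integers(hi + 500, hi + 6000))
    strand = "+" if rng.random() < 0.5 else "-"
    frag = Segment("chr12", cap_lo, cap_hi, strand)
    total = der.total_length()
    for attempt in range(MAX_ATTEMPTS):
        offset = int(rng.integers(1, total))
        prefix, suffix = _split_blocks(der.blocks, offset)
        new_blocks = prefix + [frag] + suffix
        if all(k in _junction_keys(new_blocks) for k in fusion_keys):
            break
    else:
        raise RuntimeError("chr12 capture destroyed the TP53 junction "
                           f"{MAX_ATTEMPTS} times")
    der = DerivativeChromosome(genome, new_blocks, list(der.history))
    der.record("chr12_capture", start=cap_lo, end=cap_hi, strand=strand)

    loci = [("chr12", lo, hi, "CDK4")]
    if n_cycles > 0:
        # Selection tightens after the first cycle: the surviving clone
        # keeps at least two, then at least three CDK4 copies, encoding
        # co-amplification of CDK4 with the TP53-promoter junction.
        der = simulate_bfb(der, loci, 1, rng, min_copies={"CDK4": 2},
                           required_junctions=fusion_keys)
        if n_cycles > 1:
            der = simulate_bfb(der, loci, n_cycles - 1, rng,
                               min_copies={"CDK4": 3},
                               required_junctions=fusion_keys,
                               fallback_min={"CDK4": 2})

    truth = SwapTruth(
        promoter_gene="TP53", partner_gene=partner_gene,
        breakpoints=(Breakend(tp53.chrom, split, "left"),
                     Breakend(partner.chrom, bq, "left")),
        promoter_included_exons=frozenset(tp53.exons_upstream_of(split)),
        partner_fused_exons=frozenset(partner.exons_downstream_of(bq)))
    baseline_events = [
        (tp53.chrom, 0, len17, -1),       # broken homologue 17 consumed
        (partner.chrom, 0, lenq, -1),     # partner donor arm consumed
        ("chr12", 0, genome.length("chr12"), -1),  # chr12 donor homologue
    ]
    return der, truth, baseline_events


def insert_swap(der: DerivativeChromosome, pgene: GeneModel,
                qgene: GeneModel, rng: np.random.Generator) -> SwapTruth:
    """Append a promoter-swap junction to a derivative (in place).

    A block ending inside the promoter gene's intron 1 is followed by a
    block starting upstream of the partner gene's CDS, transposing the 5'
    promoter part onto the intact partner coding sequence.
    """
    if pgene.strand != "+" or qgene.strand != "+":
        raise ValueError("swap insertion implemented for '+' strand genes")
    intron_lo, intron_hi = pgene.intron(1)
    bp = int(rng.integers(intron_lo + 20, intron_hi - 20))
    bq = int(rng.integers(qgene.tx_start + 10, qgene.cds_start - 10))
    p_block = Segment(pgene.chrom, max(pgene.promoter[0] - 100, 0), bp, "+")
    q_hi = min(qgene.tx_interval[1] + 500, der.genome.length(qgene.chrom))
    q_block = Segment(qgene.chrom, bq, q_hi, "+")
    der.blocks.extend([p_block, q_block])
    der.record("promoter_swap", promoter=pgene.name, partner=qgene.name,
               bp=bp, bq=bq)
    return SwapTruth(
        promoter_gene=pgene.name, partner_gene=qgene.name,
        breakpoints=(Breakend(pgene.chrom, bp - 1, "right"),
                     Breakend(qgene.chrom, bq, "left")),
        promoter_included_exons=frozenset(pgene.exons_upstream_of(bp)),
        partner_fused_exons=frozenset(qgene.exons_downstream_of(bq)))


# ---------------------------------------------------------------------------
# observation models
# ---------------------------------------------------------------------------

def saturate_profile(profile: CNProfile, cap: int) -> CNProfile:
    """Array-style saturation: copy numbers above ``cap`` read as ``cap``.

    High-level amplifications are not resolved by segmentation of array
    log-ratios; adjacent saturated segments merge.
    """
    from .genome import CNSegment, _log2ratio
    segs = []
    for seg in profile.all_segments():
        cn = min(seg.cn, cap)
        ploidy = expected_ploidy(profile.genome, seg.chrom)
        segs.append(CNSegment(seg.chrom, seg.start, seg.end, cn,
                              _log2ratio(cn, ploidy)))
    return CNProfile(profile.sample_id, profile.genome, segs)

def observe_callers(true_svs: list[SVCall], models: list[CallerModel],
                    genome: GenomeSpec, rng: np.random.Generator
                    ) -> dict[str, list[SVCall]]:
    """Imperfect caller outputs: per-caller detection, jitter, FPs."""
    if not models:
        raise ValueError("at least one caller model required")
    chrom_names = list(genome.names)
    lengths = genome.lengths
    out: dict[str, list[SVCall]] = {}
    for model in models:
        calls = []
        for sv in true_svs:
            if rng.random() >= model.sensitivity:
                continue
            bnds = []
            for bnd in (sv.bnd1, sv.bnd2):
                jitter = int(round(rng.normal(0, model.jitter_sd))) \
                    if model.jitter_sd > 0 else 0
                pos = min(max(bnd.pos + jitter, 0),
                          lengths[bnd.chrom] - 1)
                bnds.append(Breakend(bnd.chrom, pos, bnd.side))
            calls.append(SVCall.make(bnds[0], bnds[1],
                                     caller_id=model.caller_id,
                                     quality=float(rng.integers(20, 100))))
        for _ in range(rng.poisson(model.fp_rate)):
            bnds = []
            for _ in range(2):
                chrom = chrom_names[rng.integers(len(chrom_names))]
                pos = int(rng.integers(0, lengths[chrom]))
                side = "left" if rng.random() < 0.5 else "right"
                bnds.append(Breakend(chrom, pos, side))
            if (bnds[0].chrom, bnds[0].pos) == (bnds[1].chrom, bnds[1].pos):
                continue
            calls.append(SVCall.make(bnds[0], bnds[1],
                                     caller_id=model.caller_id,
                                     quality=float(rng.integers(5, 40))))
        out[model.caller_id] = calls
    return out


def _rna_breakpoints(truth: SwapTruth, genes: dict[str, GeneModel]
                     ) -> tuple[tuple[str, int], tuple[str, int]]:
    """Exon-edge genomic coordinates of the RNA-level fusion breakpoints."""
    pg, qg = genes[truth.promoter_gene], genes[truth.partner_gene]
    last_inc = max(truth.promoter_included_exons)
    s, e = pg.exons[last_inc - 1]
    bp5 = (pg.chrom, e if pg.strand == "+" else s)
    first_fused = min(truth.partner_fused_exons)
    s, e = qg.exons[first_fused - 1]
    bp3 = (qg.chrom, s if qg.strand == "+" else e)
    return bp5, bp3


def observe_fusions(true_swaps: list[SwapTruth],
                    genes: dict[str, GeneModel], rng: np.random.Generator,
                    sensitivity: float = 0.9, fp_rate: float = 0.5,
                    programs: tuple[str, str] = ("prog1", "prog2")) -> list:
    """Two imperfect RNA fusion callers over the true swap events."""
    from .consensus import FusionCandidate
    gene_names = sorted(genes)
    raw: dict[tuple, set[str]] = {}
    for prog in programs:
        for truth in true_swaps:
            if rng.random() >= sensitivity:
                continue
            bp5, bp3 = _rna_breakpoints(truth, genes)
            key = (truth.promoter_gene, truth.partner_gene, bp5, bp3)
            raw.setdefault(key, set()).add(prog)
        for _ in range(rng.poisson(fp_rate)):
            g5, g3 = rng.choice(gene_names, size=2, replace=False)
            m5, m3 = genes[g5], genes[g3]
            bp5 = (m5.chrom, m5.exons[int(rng.integers(m5.n_exons))][1])
            bp3 = (m3.chrom, m3.exons[int(rng.integers(m3.n_exons))][0])
            raw.setdefault((g5, g3, bp5, bp3), set()).add(prog)
    out = []
    for (g5, g3, bp5, bp3), progs in sorted(raw.items()):
        out.append(FusionCandidate(gene5=g5, gene3=g3, breakpoint5=bp5,
                                   breakpoint3=bp3,
                                   programs=frozenset(progs)))
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(sample_ids: list[str],
                        genes: dict[str, GeneModel],
                        gene_cn: dict[str, dict[str, int]],
                        swaps: dict[str, list[SwapTruth]],
                        model: ExpressionModel,
                        rng: np.random.Generator,
                        extra_genes: tuple[str, ...] = (),
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort expression matrices (log2 scale), gene- and exon-level.

    Gene-level values are the mean over the gene's exons. ``gene_cn`` maps
    sample -> gene -> total copy number (missing entries are diploid);
    ``swaps`` lists each sample's true promoter-swap events, whose included
    exons gain log2(swap_fold).
    """
    all_genes = sorted(genes) + sorted(extra_genes)
    offsets = {g: float(rng.normal(0, 1.0)) for g in all_genes}
    exon_rows = [f"{g}:exon{i}" for g in sorted(genes)
                 for i in range(1, genes[g].n_exons + 1)]
    exon_mat = pd.DataFrame(0.0, index=exon_rows, columns=sample_ids)
    gene_mat = pd.DataFrame(0.0, index=all_genes, columns=sample_ids)
    for sample in sample_ids:
        cn_map = gene_cn.get(sample, {})
        swap_list = swaps.get(sample, [])
        boost: dict[tuple[str, int], float] = {}
        for truth in swap_list:
            for i in truth.partner_fused_exons:
                boost[(truth.partner_gene, i)] = math.log2(model.swap_fold)
            for i in truth.promoter_included_exons:
                boost[(truth.promoter_gene, i)] = math.log2(model.swap_fold)
        for g in all_genes:
            cn = cn_map.get(g, 2)
            dosage = model.dosage_exponent * math.log2(max(cn, 0.1) / 2)
            sample_eff = float(rng.normal(0, model.baseline_log_sd))
            base = model.baseline_log_mean + offsets[g] + dosage + sample_eff
            if g in genes:
                vals = []
                for i in range(1, genes[g].n_exons + 1):
                    v = base + boost.get((g, i), 0.0) \
                        + float(rng.normal(0, model.noise_sd))
                    exon_mat.at[f"{g}:exon{i}", sample] = v
                    vals.append(v)
                gene_mat.at[g, sample] = float(np.mean(vals))
            else:
                gene_mat.at[g, sample] = base \
                    + float(rng.normal(0, model.noise_sd))
    return gene_mat, exon_mat


def rna_cohort_labels() -> list[tuple[str, str]]:
    """(sample_id, subtype) pairs of the RNA expression cohort."""
    out = []
    i = 1
    for subtype, count in RNA_SUBTYPE_COUNTS:
        for _ in range(count):
            out.append((f"S{i:03d}", subtype))
            i += 1
    return out


def simulate_swap_cohort(rng: np.random.Generator,
                         model: ExpressionModel = ExpressionModel(),
                         n_swap_cases: int = 1,
                         promoter_gene: str = "FRS2",
                         partner_gene: str = "ELF1",
                         ) -> tuple[pd.DataFrame, pd.DataFrame,
                                    dict[str, SwapTruth]]:
    """RNA cohort with promoter-swap cases among otherwise diploid samples.

    The cohort has the study's sample composition; the first
    ``n_swap_cases`` osteosarcoma samples carry a promoter swap driving
    ``partner_gene``, with both partner and promoter loci amplified (the
    fused copies sit inside the amplicon).
    """
    genes = toy_gene_models()
    labels = rna_cohort_labels()
    sample_ids = [s for s, _ in labels]
    swaps: dict[str, list[SwapTruth]] = {}
    gene_cn: dict[str, dict[str, int]] = {}
    truths: dict[str, SwapTruth] = {}
    pg, qg = genes[promoter_gene], genes[partner_gene]
    for sample in sample_ids[:n_swap_cases]:
        bp = int(rng.integers(*pg.intron(1)))
        bq = int(rng.integers(qg.tx_start + 10, qg.cds_start - 10))
        truth = SwapTruth(
            promoter_gene=promoter_gene, partner_gene=partner_gene,
            breakpoints=(Breakend(pg.chrom, bp, "right"),
                         Breakend(qg.chrom, bq, "left")),
            promoter_included_exons=frozenset(pg.exons_upstream_of(bp)),
            partner_fused_exons=frozenset(qg.exons_downstream_of(bq)))
        swaps[sample] = [truth]
        truths[sample] = truth
        amp = int(rng.integers(4, 9))
        gene_cn[sample] = {promoter_gene: amp, partner_gene: amp,
                           "CDK4": amp, "MDM2": amp}
    gene_mat, exon_mat = simulate_expression(
        sample_ids, genes, gene_cn, swaps, model, rng)
    return gene_mat, exon_mat, truths


# ---------------------------------------------------------------------------
# case and cohort generation
# ---------------------------------------------------------------------------

def _selected_loci(genes: dict[str, GeneModel],
                   labels: tuple[str, ...]) -> list[tuple[str, int, int, str]]:
    out = []
    for label in labels:
        g = genes[label]
        lo, hi = g.locus
        out.append((g.chrom, lo, hi, label))
    return out


def group_config(group: str, rng: np.random.Generator) -> SimConfig:
    """Default per-group simulation parameters.

    A: chromothripsis+BFB of an extra chr12 copy, no background noise.
    B: same with a little background noise and optional promoter swap.
    C: chromothripsis+BFB of a normal chr12 homologue (hence chr12
       deletions) with genome-wide noise.
    D: TP53 dicentric with genome-wide noise; HMGA2 never under selection.
    """
    genes = toy_gene_models()
    n_fragments = int(rng.integers(20, 61))
    n_cycles = int(rng.integers(3, 7))
    base = dict(n_fragments=n_fragments, n_bfb_cycles=n_cycles,
                retention_prob=0.6)
    abc_loci = _selected_loci(genes, ("CDK4", "MDM2", "HMGA2"))
    if group == "A":
        return SimConfig(mechanism="chromothripsis_bfb", group_label="A",
                         selected_loci=abc_loci, genome_noise_rate=0.0,
                         template="extra_copy", **base)
    if group == "B":
        return SimConfig(mechanism="chromothripsis_bfb", group_label="B",
                         selected_loci=abc_loci, genome_noise_rate=2.5,
                         min_noise_events=1, template="extra_copy",
                         swap_prob=0.5, **base)
    if group == "C":
        return SimConfig(mechanism="chromothripsis_bfb", group_label="C",
                         selected_loci=abc_loci, genome_noise_rate=45.0,
                         template="normal_homologue", swap_prob=0.4,
                         swap_promoter_genes=("FRS2",), **base)
    if group == "D":
        mode = "homozygous_loss" if rng.random() < 0.2 else "promoter_fusion"
        return SimConfig(mechanism="tp53_dicentric", group_label="D",
                         selected_loci=_selected_loci(genes, ("CDK4",)),
                         genome_noise_rate=45.0, tp53_mode=mode, **base)
    raise ValueError(f"unknown group {group!r}")


def _noise_events(genome: GenomeSpec, rate: float, min_events: int,
                  rng: np.random.Generator,
                  exclude: tuple[str, ...] = ("chr12", "chrX", "chrY"),
                  ) -> list[tuple[str, int, int, int]]:
    """Background CNAs: whole-chromosome aneuploidies and interval events.

    Losses never stack on losses (double deletion of the same region is a
    distinct biology not modelled here); chr12 and sex chromosomes are
    exempt so mechanism-specific chr12 signatures stay interpretable.
    """
    if rate <= 0 and min_events <= 0:
        return []
    chroms = [c for c in genome.names if c not in exclude]
    count = max(int(rng.poisson(rate)), min_events)
    events: list[tuple[str, int, int, int]] = []
    losses: dict[str, list[tuple[int, int]]] = {}
    for _ in range(count):
        for attempt in range(50):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = genome.length(chrom)
            if rng.random() < 0.2:
                lo, hi = 0, length
            else:
                span = int(length * rng.uniform(0.05, 0.4))
                lo = int(rng.integers(0, length - span))
                hi = lo + span
            delta = 1 if rng.random() < 0.6 else -1
            if delta == -1:
                clash = any(a < hi and lo < b
                            for a, b in losses.get(chrom, []))
                if clash:
                    continue
                losses.setdefault(chrom, []).append((lo, hi))
            events.append((chrom, lo, hi, delta))
            break
    return events


def generate_case(case_id: str, config: SimConfig,
                  rng: np.random.Generator,
                  caller_models: list[CallerModel] | None = None,
                  ) -> SimulatedCase:
    """Simulate one tumour genome and its imperfect observations."""
    genes = toy_gene_models()
    sex = config.sex or ("male" if rng.random() < 0.5 else "female")
    genome = default_genome(sex=sex)
    if caller_models is None:
        caller_models = default_caller_models()
    baseline_events: list[tuple[str, int, int, int]] = []
    swaps: list[SwapTruth] = []
    der: DerivativeChromosome | None = None

    if config.mechanism == "chromothripsis_bfb":
        # The 12q13-15 amplicon is one contiguous region: the span covering
        # all selected loci is shielded from shattering cuts (with a flank
        # so the amplification ring always has breakable margins).
        chr12_loci = [(lo, hi) for c, lo, hi, _ in config.selected_loci
                      if c == "chr12"]
        protected = [(min(lo for lo, _ in chr12_loci) - 600,
                      max(hi for _, hi in chr12_loci) + 600)]
        der, lost = simulate_chromothripsis(
            genome, "chr12", config.n_fragments, config.retention_prob,
            rng, protected_loci=protected)
        if config.template == "normal_homologue":
            baseline_events.append(("chr12", 0,
                                    genome.length("chr12"), -1))
        # Selective amplification: BFB cycles act on a compact ring built
        # from the selected-locus fragments, so amplification stays focal
        # while the shattered backbone remains a uniform single-copy gain
        # (the oscillating two-state pattern of the mechanism).
        ring = _amplification_ring(der, config.selected_loci, rng)
        # Selection pressure escalates per cycle: the surviving clone is
        # always among the most amplified products of the bridge break.
        for cycle in range(config.n_bfb_cycles):
            floor = min(2 ** (cycle + 1), 6)
            ring = simulate_bfb(ring, config.selected_loci, 1, rng,
                                min_copies={label: floor for *_, label
                                            in config.selected_loci},
                                fallback_min={label: 1 for *_, label
                                              in config.selected_loci})
        der = DerivativeChromosome(genome, der.blocks + ring.blocks,
                                   der.history + ring.history)
        if config.swap_prob > 0 and rng.random() < config.swap_prob:
            pname = config.swap_promoter_genes[
                int(rng.integers(len(config.swap_promoter_genes)))]
            swaps.append(insert_swap(der, genes[pname], genes["ELF1"], rng))
    elif config.mechanism == "tp53_dicentric":
        if config.tp53_mode == "promoter_fusion":
            der, truth, baseline_events = simulate_tp53_dicentric(
                genome, genes, config.n_bfb_cycles, rng)
            swaps.append(truth)
        else:
            # Homozygous TP53 loss: both alleles deleted; the CDK4 amplicon
            # arises from an independently captured chr12 fragment.
            cdk4 = genes["CDK4"]
            clo, chi = cdk4.locus
            cap_lo = int(rng.integers(clo - 6000, clo - 500))
            cap_hi = int(rng.integers(chi + 500, chi + 6000))
            der = DerivativeChromosome(
                genome, [Segment("chr12", cap_lo, cap_hi, "+")])
            der.record("chr12_capture", start=cap_lo, end=cap_hi)
            der = simulate_bfb(der, config.selected_loci, 1, rng,
                               min_copies={"CDK4": 2})
            if config.n_bfb_cycles > 1:
                der = simulate_bfb(der, config.selected_loci,
                                   config.n_bfb_cycles - 1, rng,
                                   min_copies={"CDK4": 3},
                                   fallback_min={"CDK4": 2})
            baseline_events.append(("chr12", 0, genome.length("chr12"), -1))
    elif config.mechanism != "none":
        raise ValueError(f"unknown mechanism {config.mechanism!r}")

    noise = _noise_events(genome, config.genome_noise_rate,
                          config.min_noise_events, rng)
    baseline = apply_cn_events(CNProfile.flat(case_id, genome),
                               baseline_events + noise)
    if (config.mechanism == "tp53_dicentric"
            and config.tp53_mode == "homozygous_loss"):
        # Both TP53 alleles lost regardless of background events.
        tp53 = genes["TP53"]
        lo, hi = tp53.locus
        zero = [(tp53.chrom, max(s.start, lo), min(s.end, hi), -s.cn)
                for s in baseline.segments[tp53.chrom]
                if s.start < hi and lo < s.end and s.cn > 0]
        if zero:
            baseline = apply_cn_events(baseline, zero)
    true_cn = cn_from_derivative(der, baseline) if der else baseline
    observed = saturate_profile(true_cn, config.cn_cap)
    true_svs = sv_from_derivative(der) if der and der.blocks else []
    callsets = observe_callers(true_svs, caller_models, genome, rng)
    fusions = observe_fusions(swaps, genes, rng)
    return SimulatedCase(
        case_id=case_id, group_label=config.group_label, sex=sex,
        genome=genome, config=config, derivative=der, true_svs=true_svs,
        true_swaps=swaps, true_cn=true_cn, observed_cn=observed,
        callsets=callsets, fusion_candidates=fusions)


def generate_cohort(seed: int, group_sizes: dict[str, int] | None = None,
                    ) -> list[SimulatedCase]:
    """Deterministic cohort of simulated cases, study-sized by default."""
    if group_sizes is None:
        group_sizes = dict(GROUP_SIZES)
    for g in group_sizes:
        if g not in GROUP_SIZES:
            raise ValueError(f"unknown group {g!r}")
        if group_sizes[g] < 0:
            raise ValueError("group sizes must be >= 0")
    master = np.random.default_rng(seed)
    cases = []
    i = 1
    for group in sorted(group_sizes):
        for _ in range(group_sizes[group]):
            case_rng = np.random.default_rng(
                int(master.integers(0, 2**31)))
            config = group_config(group, case_rng)
            cases.append(generate_case(f"case{i:02d}", config, case_rng))
            i += 1
    return cases
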