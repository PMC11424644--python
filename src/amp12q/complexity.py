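"""Genomic complexity scoring and the four-group case classifier.

A chromosome counts as affected by a copy-number alteration if it shows a
visible copy-number shift in the segmentation or a non-diploid copy number;
the X and Y chromosomes count as one pair in males. The genomic complexity
score (GCS) used here is a shift-point surrogate: the number of copy-number
shift points across the genome plus the number of whole-chromosome
aneuploidies (the score it stands in for is defined elsewhere and is
config-replaceable).

Cases split into a low-complexity cluster (< half of chromosomes affected)
and a high-complexity cluster; together with MDM2 status and TP53
alterations this yields the A/B/C/D grouping:

* A — MDM2-amplified, no alterations outside chromosome 12;
* B — MDM2-amplified, low complexity, some alterations outside chr12;
* C — MDM2-amplified, genome-wide alterations;
* D — CDK4 without MDM2 amplification, TP53 altered, genome-wide
  alterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources

from scipy import stats

from .genome import CNProfile, expected_ploidy

__all__ = [
    "CaseFeatures",
    "GroupAssignment",
    "count_affected_chromosomes",
    "genomic_complexity_score",
    "complexity_cluster",
    "assign_group",
    "mutual_exclusivity",
    "load_study_cases",
    "TP53_MUTATED_STATES",
]

TP53_MUTATED_STATES = frozenset({"promoter_fusion", "homozygous_loss", "snv"})


@dataclass
class CaseFeatures:
    """Per-tumour flags feeding the group classifier."""

    case_id: str
    cdk4_amp: bool
    mdm2_amp: bool
    hmga2_amp: bool
    tp53_status: str  # wildtype | promoter_fusion | snv | homozygous_loss
    chr12_deletions: bool
    n_chrom_altered: int
    n_chrom_total: int = 23
    gcs: float | None = None
    subtype: str | None = None  # annotation only

    def __post_init__(self):
        if not 0 <= self.n_chrom_altered <= self.n_chrom_total:
            raise ValueError("n_chrom_altered out of range")
        if self.tp53_status not in TP53_MUTATED_STATES | {"wildtype"}:
            raise ValueError(f"unknown tp53_status {self.tp53_status!r}")

    @property
    def tp53_mutated(self) -> bool:
        return self.tp53_status in TP53_MUTATED_STATES


@dataclass
class GroupAssignment:
    case_id: str
    group: str  # A, B, C, D or unclassified
    rationale: list[str] = field(default_factory=list)


def _chromosome_units(profile: CNProfile) -> list[list[str]]:
    """Chromosomes as counting units: X/Y merged into one pair in males,
    Y dropped in females (expected copy number zero)."""
    genome = profile.genome
    units: list[list[str]] = []
    sex_unit: list[str] = []
    for chrom, _ in genome.chromosomes:
        if chrom in ("chrX", "chrY"):
            if genome.sex == "male":
                sex_unit.append(chrom)
            elif chrom == "chrX":
                units.append([chrom])
        else:
            units.append([chrom])
    if sex_unit:
        units.append(sex_unit)
    return units


def _chrom_affected(profile: CNProfile, chrom: str) -> bool:
    segs = profile.segments[chrom]
    if len(segs) >= 2:
        return True  # visible copy-number shift
    return segs[0].cn != expected_ploidy(profile.genome, chrom)


def count_affected_chromosomes(profile: CNProfile) -> int:
    """Number of chromosome units carrying a copy-number alteration."""
    return sum(
        1 for unit in _chromosome_units(profile)
        if any(_chrom_affected(profile, c) for c in unit))


def total_chromosome_units(profile: CNProfile) -> int:
    return len(_chromosome_units(profile))


def genomic_complexity_score(profile: CNProfile) -> float:
    """Shift-point surrogate GCS: copy-number shift points plus
    whole-chromosome aneuploidies."""
    score = 0
    for chrom, _ in profile.genome.chromosomes:
        segs = profile.segments[chrom]
        score += len(segs) - 1
        if len(segs) == 1 and segs[0].cn != expected_ploidy(
                profile.genome, chrom):
            score += 1
    return float(score)


def complexity_cluster(features: CaseFeatures) -> str:
    """'low' iff fewer than half the chromosome units are affected."""
    frac = features.n_chrom_altered / features.n_chrom_total
    return "low" if frac < 0.5 else "high"


def assign_group(features: CaseFeatures,
                 cluster: str | None = None) -> GroupAssignment:
    """Deterministic A/B/C/D assignment from case features.

    Assumes chromosome 12 is itself altered in every in-scope case (all
    carry the 12q13-15 amplicon), so alterations outside chromosome 12
    number ``n_chrom_altered - 1``.
    """
    if cluster is None:
        cluster = complexity_cluster(features)
    rationale = [f"complexity cluster = {cluster}"]
    if not features.cdk4_amp:
        rationale.append("CDK4 amplification absent: out of scope")
        return GroupAssignment(features.case_id, "unclassified", rationale)
    outside = max(features.n_chrom_altered - 1, 0)
    if (not features.mdm2_amp and features.tp53_mutated
            and cluster == "high"):
        rationale.append("CDK4 without MDM2, TP53 altered, genome-wide CNAs")
        return GroupAssignment(features.case_id, "D", rationale)
    if features.mdm2_amp and cluster == "high":
        rationale.append("MDM2 amplified with genome-wide CNAs")
        return GroupAssignment(features.case_id, "C", rationale)
    if features.mdm2_amp and outside == 0:
        rationale.append("MDM2 amplified, no CNAs outside chromosome 12")
        return GroupAssignment(features.case_id, "A", rationale)
    if features.mdm2_amp and cluster == "low" and outside >= 1:
        rationale.append("MDM2 amplified, low complexity, some CNAs "
                         "outside chromosome 12")
        return GroupAssignment(features.case_id, "B", rationale)
    rationale.append("no rule matched")
    return GroupAssignment(features.case_id, "unclassified", rationale)


def mutual_exclusivity(cases: list[CaseFeatures]) -> tuple[int, float]:
    """Co-occurrence of HMGA2 amplification and TP53 mutation.

    Returns the co-occurrence count and a one-sided Fisher exact p-value
    for under-representation of co-occurrence in the 2x2 table.
    """
    if not cases:
        raise ValueError("at least one case required")
    both = sum(1 for c in cases if c.hmga2_amp and c.tp53_mutated)
    a_only = sum(1 for c in cases if c.hmga2_amp and not c.tp53_mutated)
    b_only = sum(1 for c in cases if not c.hmga2_amp and c.tp53_mutated)
    neither = len(cases) - both - a_only - b_only
    _, p = stats.fisher_exact([[both, a_only], [b_only, neither]],
                              alternative="less")
    return both, float(p)


def load_study_cases() -> list[CaseFeatures]:
    """The bundled 25-case feature table.

    Encodes only per-case attributes printed in the study (amplification
    and TP53 flags, subtype counts, chromosome 12 deletion statements);
    unprinted numeric fields carry group-consistent defaults and are marked
    as such in the JSON.
    """
    text = resources.files("amp12q").joinpath(
        "data/study_cases.json").read_text()
    payload = json.loads(text)
    return [CaseFeatures(**{k: v for k, v in row.items()
                            if k not in ("notes",)})
            for row in payload["cases"]]
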