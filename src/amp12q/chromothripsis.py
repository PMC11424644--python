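"""Per-chromosome chromothripsis evidence scoring.

Chromothripsis — a single catastrophic shattering with random re-ligation —
leaves three measurable footprints on a chromosome: copy number oscillating
between few states, breakpoints clustered relative to a uniform layout, and
the four junction orientation classes (HH/TT/TD/D) occurring at roughly
equal frequency. Breakage-fusion-bridge amplification, by contrast, leaves
fold-back (HH/TT-only) junctions and step-wise copy-number gains, so the
orientation test discriminates the two mechanisms.

The composite call requires all four criteria; two or three met is reported
as "inconclusive", fewer as "absent".
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy import stats

from .genome import CNProfile, SVCall, expected_ploidy

__all__ = [
    "Thresholds",
    "ChromothripsisReport",
    "TemplateInference",
    "cn_oscillation",
    "orientation_equiprobability",
    "breakpoint_clustering",
    "call_chromothripsis",
    "score_chromosome",
    "infer_template",
]

ORIENTATION_CLASSES = ("HH", "TT", "TD", "D")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the composite chromothripsis call.

    min_breakpoints: breakends on the chromosome required for a clustered
        rearrangement burst; max_states: dominant copy-number states allowed
        (oscillation between few states); min_oscillation: fraction of CN
        transitions returning to the preceding state; min_orientation_p:
        equiprobability of junction orientations must not be rejected below
        this level.
    """

    min_breakpoints: int = 10
    max_states: int = 3
    min_oscillation: float = 0.6
    min_orientation_p: float = 0.05
    exact_test_below: int = 20  # totals below this use the exact multinomial


@dataclass
class ChromothripsisReport:
    chrom: str
    n_breakpoints: int
    cn_states: dict[int, int]
    oscillation_fraction: float | None
    dominant_state_count: int | None
    orientation_counts: tuple[int, int, int, int]
    orientation_p: float
    clustering_stat: float | None
    verdict: str = "absent"
    criteria: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class TemplateInference:
    """Which chromosome 12 copy was shattered.

    No deletions on the chromosome means an extra copy was the template
    (every fragment loss would otherwise dip below germline ploidy); any
    deletion implicates one of the normal homologues.
    """

    chrom: str
    deletions_present: bool
    template: str  # "extra_copy" or "normal_homologue"


def cn_oscillation(profile: CNProfile,
                   chrom: str) -> tuple[float | None, int | None]:
    """Oscillation fraction and dominant-state count of a chromosome.

    Oscillation fraction: of the interior copy-number transitions, the
    share that return to the immediately preceding state (2,3,2 counts;
    2,3,4 does not). Dominant-state count: minimal number of CN states
    covering >= 80% of the segments. Both undefined with < 3 segments.
    """
    states = [s.cn for s in profile.segments[chrom]]
    n = len(states)
    if n < 3:
        return None, None
    returns = sum(1 for i in range(1, n - 1) if states[i + 1] == states[i - 1])
    frac = returns / (n - 2)
    counts = sorted(np.unique(states, return_counts=True)[1], reverse=True)
    covered, k = 0, 0
    for c in counts:
        covered += c
        k += 1
        if covered >= 0.8 * n:
            break
    return frac, k


def _exact_multinomial_p(counts: np.ndarray) -> float:
    """Exact multinomial goodness-of-fit p against uniform(1/4 x 4).

    Sums the probability of all outcomes no more likely than the observed
    one. Feasible for the small totals it is applied to.
    """
    n = int(counts.sum())
    logp_obs = stats.multinomial.logpmf(counts, n, [0.25] * 4)
    p = 0.0
    for a in range(n + 1):
        for b in range(n - a + 1):
            for c in range(n - a - b + 1):
                d = n - a - b - c
                lp = stats.multinomial.logpmf([a, b, c, d], n, [0.25] * 4)
                if lp <= logp_obs + 1e-9:
                    p += float(np.exp(lp))
    return min(p, 1.0)


def orientation_equiprobability(counts, exact_below: int = 0
                                ) -> tuple[float, float]:
    """Chi-square goodness-of-fit of (HH, TT, TD, D) counts vs uniform.

    3 degrees of freedom, no continuity correction; totals below
    ``exact_below`` use the exact multinomial test instead (statistic still
    reported as chi-square).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (4,):
        raise ValueError("counts must have four entries (HH, TT, TD, D)")
    total = obs.sum()
    if total < 1:
        raise ValueError("at least one junction required")
    expected = np.full(4, total / 4)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    if 0 < total < exact_below:
        p = _exact_multinomial_p(obs.astype(int))
    else:
        p = float(stats.chi2.sf(chi2, df=3))
    return chi2, p


def breakpoint_clustering(positions, chrom_length: int) -> float:
    """Kolmogorov-Smirnov distance of breakpoints vs uniform placement."""
    pos = np.asarray(sorted(positions), dtype=float)
    if pos.size < 2:
        raise ValueError("at least two positions required")
    return float(stats.kstest(pos / chrom_length, "uniform").statistic)


def score_chromosome(profile: CNProfile, svs: list[SVCall], chrom: str,
                     thresholds: Thresholds = Thresholds()
                     ) -> ChromothripsisReport:
    """Assemble all evidence for one chromosome and call the verdict."""
    bnds = [b for sv in svs for b in (sv.bnd1, sv.bnd2) if b.chrom == chrom]
    counts = {c: 0 for c in ORIENTATION_CLASSES}
    for sv in svs:
        if sv.bnd1.chrom == chrom and sv.bnd2.chrom == chrom:
            counts[sv.orientation] += 1
    ori = tuple(counts[c] for c in ORIENTATION_CLASSES)
    total_junc = sum(ori)
    if total_junc >= 1:
        _, ori_p = orientation_equiprobability(
            ori, exact_below=thresholds.exact_test_below)
    else:
        ori_p = 0.0
    frac, k = cn_oscillation(profile, chrom)
    clustering = None
    if len(bnds) >= 2:
        clustering = breakpoint_clustering(
            [b.pos for b in bnds], profile.genome.length(chrom))
    states: dict[int, int] = {}
    for seg in profile.segments[chrom]:
        states[seg.cn] = states.get(seg.cn, 0) + 1
    report = ChromothripsisReport(
        chrom=chrom, n_breakpoints=len(bnds), cn_states=states,
        oscillation_fraction=frac, dominant_state_count=k,
        orientation_counts=ori, orientation_p=ori_p,
        clustering_stat=clustering)
    report.verdict, report.criteria = call_chromothripsis(report, thresholds)
    return report


def call_chromothripsis(report: ChromothripsisReport,
                        thresholds: Thresholds = Thresholds()
                        ) -> tuple[str, dict[str, bool]]:
    """Composite verdict: all four criteria -> chromothripsis, at least two
    -> inconclusive, otherwise absent. Undefined oscillation (too few
    segments) forces absent."""
    if report.oscillation_fraction is None or report.n_breakpoints == 0:
        return "absent", {}
    criteria = {
        "breakpoints": report.n_breakpoints >= thresholds.min_breakpoints,
        "few_states": report.dominant_state_count <= thresholds.max_states,
        "oscillation":
            report.oscillation_fraction >= thresholds.min_oscillation,
        "orientation": report.orientation_p >= thresholds.min_orientation_p,
    }
    met = sum(criteria.values())
    if met == 4:
        return "chromothripsis", criteria
    if met >= 2:
        return "inconclusive", criteria
    return "absent", criteria


def infer_template(profile: CNProfile, chrom: str = "chr12"
                   ) -> TemplateInference:
    """Infer which copy of the chromosome the rearrangement affected."""
    ploidy = expected_ploidy(profile.genome, chrom)
    deletions = any(s.cn < ploidy for s in profile.segments[chrom])
    return TemplateInference(
        chrom=chrom, deletions_present=deletions,
        template="normal_homologue" if deletions else "extra_copy")
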