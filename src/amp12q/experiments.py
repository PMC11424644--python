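"""Canned validation experiments over the simulators and analysis chain.

Each experiment regenerates its inputs from a seed, runs the package's own
methods, and measures recovery of the simulated ground truth. These back
both the validation test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .chromothripsis import Thresholds, score_chromosome
from .complexity import assign_group, load_study_cases, mutual_exclusivity
from .consensus import consensus_filter, match_breakpoints
from .genome import Breakend, SVCall, default_genome
from .pipeline import analyse_case
from .promoter_swap import cohort_rank, exon_asymmetry
from .simulate import (
    default_caller_models,
    generate_case,
    generate_cohort,
    group_config,
    observe_callers,
    rna_cohort_labels,
    simulate_swap_cohort,
)

__all__ = [
    "study_fixture_summary",
    "chromothripsis_recovery",
    "consensus_recovery",
    "swap_recovery",
    "group_recovery",
]


def study_fixture_summary() -> dict:
    """Group counts and HMGA2/TP53 exclusivity of the bundled 25 cases."""
    cases = load_study_cases()
    counts: dict[str, int] = {}
    for feat in cases:
        g = assign_group(feat).group
        counts[g] = counts.get(g, 0) + 1
    co, p = mutual_exclusivity(cases)
    return {"group_counts": counts, "n_cases": len(cases),
            "cooccurrence": co, "fisher_p": p}


def _chr12_verdict(case, tol=500) -> str:
    consensus = consensus_filter(list(case.callsets.values()), tol=tol)
    report = score_chromosome(case.observed_cn,
                              [c.as_svcall() for c in consensus], "chr12",
                              Thresholds())
    return report.verdict


def chromothripsis_recovery(seed: int, n_each: int = 100) -> dict:
    """Sensitivity/specificity of the chr12 chromothripsis call on
    simulated chromothripsis+BFB vs TP53-dicentric cases."""
    master = np.random.default_rng(seed)
    hits = {"pos": 0, "neg": 0}
    for kind, group in (("pos", "A"), ("neg", "D")):
        for i in range(n_each):
            rng = np.random.default_rng(int(master.integers(0, 2**31)))
            config = group_config(group, rng)
            case = generate_case(f"{kind}{i}", config, rng)
            verdict = _chr12_verdict(case)
            if kind == "pos" and verdict == "chromothripsis":
                hits["pos"] += 1
            if kind == "neg" and verdict != "chromothripsis":
                hits["neg"] += 1
    return {"sensitivity": hits["pos"] / n_each,
            "specificity": hits["neg"] / n_each,
            "n_each": n_each}


def _random_svs(rng, genome, n):
    chroms = list(genome.names)
    lengths = genome.lengths
    out = []
    while len(out) < n:
        c1, c2 = (chroms[rng.integers(len(chroms))] for _ in range(2))
        b1 = Breakend(c1, int(rng.integers(0, lengths[c1])),
                      "left" if rng.random() < 0.5 else "right")
        b2 = Breakend(c2, int(rng.integers(0, lengths[c2])),
                      "left" if rng.random() < 0.5 else "right")
        if (b1.chrom, b1.pos) == (b2.chrom, b2.pos):
            continue
        out.append(SVCall.make(b1, b2, caller_id="truth"))
    return out


def _single_linkage_bruteforce(callsets, min_callers, tol):
    """Independent enumeration of all cross-caller pairwise matches."""
    calls = [c for cs in callsets for c in cs]
    n = len(calls)
    seen = [False] * n
    clusters = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if not seen[v] and match_breakpoints(calls[u], calls[v],
                                                     tol):
                    seen[v] = True
                    stack.append(v)
        clusters.append(comp)
    out = set()
    for comp in clusters:
        if len({calls[i].caller_id for i in comp}) >= min_callers:
            out.add(frozenset(calls[i].key() for i in comp))
    return out


def consensus_recovery(seed: int, n_runs: int = 100, n_svs: int = 50,
                       tol: int = 500) -> dict:
    """Consensus filtering vs oracle enumeration and truth recovery.

    Callers at sensitivity 0.9, 2 expected false positives, 50 bp jitter.
    """
    master = np.random.default_rng(seed)
    genome = default_genome()
    models = default_caller_models()  # sens 0.9, fp 2, jitter 50
    recalls, false_counts, agreements = [], [], 0
    for _ in range(n_runs):
        rng = np.random.default_rng(int(master.integers(0, 2**31)))
        truth = _random_svs(rng, genome, n_svs)
        callsets = list(observe_callers(truth, models, genome,
                                        rng).values())
        consensus = consensus_filter(callsets, min_callers=2, tol=tol)
        got = {frozenset(c.key() for c in cons.calls)
               for cons in consensus}
        if got == _single_linkage_bruteforce(callsets, 2, tol):
            agreements += 1
        matched = sum(1 for t in truth
                      if any(match_breakpoints(t, c.as_svcall(), tol)
                             for c in consensus))
        false = sum(1 for c in consensus
                    if not any(match_breakpoints(t, c.as_svcall(), tol)
                               for t in truth))
        recalls.append(matched / n_svs)
        false_counts.append(false)
    return {"recall": float(np.mean(recalls)),
            "false_consensus_mean": float(np.mean(false_counts)),
            "oracle_agreement": agreements / n_runs,
            "n_runs": n_runs}


def swap_recovery(seed: int, n_runs: int = 100) -> dict:
    """Promoter-swap expression behaviour across seeded cohorts.

    Single-swap cohorts: fraction where the partner gene ranks 1st and the
    included/excluded exon asymmetry exceeds 1. Dual-swap cohorts (two
    independent events driving the same partner): fraction occupying the
    two top ranks.
    """
    master = np.random.default_rng(seed)
    rank1 = asym = 0
    for _ in range(n_runs):
        rng = np.random.default_rng(int(master.integers(0, 2**31)))
        gene_mat, exon_mat, truths = simulate_swap_cohort(rng)
        sample, truth = next(iter(truths.items()))
        if cohort_rank(truth.partner_gene, sample, gene_mat)[0] == 1:
            rank1 += 1
        exon_rows = [f"{truth.partner_gene}:exon{i}"
                     for i in range(1, 6)]
        linear = np.power(2.0, exon_mat.loc[exon_rows, sample].values)
        if exon_asymmetry(linear, truth.partner_fused_exons) > 1:
            asym += 1
    top2 = 0
    for _ in range(n_runs):
        rng = np.random.default_rng(int(master.integers(0, 2**31)))
        gene_mat, _, truths = simulate_swap_cohort(rng, n_swap_cases=2)
        ranks = sorted(cohort_rank("ELF1", s, gene_mat)[0]
                       for s in truths)
        if ranks[0] == 1 and ranks[1] <= 2:
            top2 += 1
    return {"partner_rank1_fraction": rank1 / n_runs,
            "asymmetry_gt1_fraction": asym / n_runs,
            "dual_swap_top2_fraction": top2 / n_runs,
            "n_runs": n_runs}


def group_recovery(seed: int, n_cases: int = 200) -> dict:
    """Classifier recovery of simulated group labels."""
    master = np.random.default_rng(seed)
    per_group = n_cases // 4
    correct = total = 0
    for group in "ABCD":
        for i in range(per_group):
            rng = np.random.default_rng(int(master.integers(0, 2**31)))
            config = group_config(group, rng)
            case = generate_case(f"{group}{i}", config, rng)
            result = analyse_case(case)
            total += 1
            correct += result["assigned_group"] == group
    return {"accuracy": correct / total, "n_cases": total}
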