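"""Cross-caller SV consensus and RNA fusion noise filtering."""

import numpy as np
import pytest

from amp12q.consensus import (
    ConsensusSV,
    FusionCandidate,
    consensus_filter,
    filter_fusions,
    match_breakpoints,
)
from amp12q.genome import Breakend, SVCall, default_genome
from amp12q.simulate import default_caller_models, observe_callers, \
    toy_gene_models


def _sv(pos1, pos2, side1="right", side2="left", chrom1="chr12",
        chrom2="chr12", caller="c1"):
    return SVCall.make(Breakend(chrom1, pos1, side1),
                       Breakend(chrom2, pos2, side2), caller_id=caller)


def _random_svs(rng, genome, n):
    chroms = list(genome.names)
    lengths = genome.lengths
    out = []
    while len(out) < n:
        c1, c2 = (chroms[rng.integers(24)] for _ in range(2))
        b1 = Breakend(c1, int(rng.integers(0, lengths[c1])),
                      "left" if rng.random() < 0.5 else "right")
        b2 = Breakend(c2, int(rng.integers(0, lengths[c2])),
                      "left" if rng.random() < 0.5 else "right")
        if (b1.chrom, b1.pos) == (b2.chrom, b2.pos):
            continue
        out.append(SVCall.make(b1, b2, caller_id="truth"))
    return out


class TestMatchBreakpoints:
    def test_identical_calls_zero_tolerance(self):
        assert match_breakpoints(_sv(100, 500), _sv(100, 500), tol=0)

    def test_orientation_mismatch(self):
        a = _sv(100, 500, "right", "left")   # D
        b = _sv(100, 500, "left", "right")   # TD
        assert not match_breakpoints(a, b, tol=100)
        assert match_breakpoints(a, b, tol=100, require_orientation=False)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_breakpoints(_sv(1, 2), _sv(1, 2), tol=-1)

    def test_random_pairs_match_definition(self, genome, rng):
        svs = _random_svs(rng, genome, 60)
        tol = 500
        for _ in range(1000):
            a, b = (svs[rng.integers(len(svs))] for _ in range(2))
            expected = (
                (a.bnd1.chrom, a.bnd2.chrom) == (b.bnd1.chrom, b.bnd2.chrom)
                and a.orientation == b.orientation
                and abs(a.bnd1.pos - b.bnd1.pos) <= tol
                and abs(a.bnd2.pos - b.bnd2.pos) <= tol)
            assert match_breakpoints(a, b, tol) == expected


def _brute_force_consensus(callsets, min_callers, tol):
    """Independent oracle: single-linkage over all pairwise matches."""
    calls = [c for cs in callsets for c in cs]
    n = len(calls)
    adj = [[match_breakpoints(calls[i], calls[j], tol)
            for j in range(n)] for i in range(n)]
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
                if not seen[v] and adj[u][v]:
                    seen[v] = True
                    stack.append(v)
        clusters.append(comp)
    out = set()
    for comp in clusters:
        callers = {calls[i].caller_id for i in comp}
        if len(callers) >= min_callers:
            out.add(frozenset(calls[i].key() for i in comp))
    return out


class TestConsensusFilter:
    def test_single_caller_support_excluded(self):
        sets = [[_sv(100, 500, caller="c1")], [], []]
        assert consensus_filter(sets, min_callers=2, tol=100) == []

    def test_three_caller_agreement(self):
        sets = [[_sv(100, 500, caller=c)] for c in ("c1", "c2", "c3")]
        out = consensus_filter(sets, min_callers=2, tol=100)
        assert len(out) == 1
        assert out[0].supporting_callers == frozenset({"c1", "c2", "c3"})

    def test_median_representative_position(self):
        sets = [[_sv(100, 500, caller="c1")], [_sv(110, 520, caller="c2")],
                [_sv(130, 540, caller="c3")]]
        out = consensus_filter(sets, tol=100)
        assert (out[0].bnd1.pos, out[0].bnd2.pos) == (110, 520)

    def test_too_few_callsets_rejected(self):
        with pytest.raises(ValueError):
            consensus_filter([[_sv(1, 2)]], min_callers=2, tol=10)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_pairwise_oracle_on_simulated_callers(self, genome,
                                                         seed):
        rng = np.random.default_rng(seed)
        truth = _random_svs(rng, genome, 30)
        callsets = observe_callers(truth, default_caller_models(), genome,
                                   rng)
        out = consensus_filter(list(callsets.values()), tol=500)
        got = {frozenset(c.key() for c in cons.calls) for cons in out}
        assert got == _brute_force_consensus(list(callsets.values()), 2, 500)

    def test_permuting_caller_order_invariant(self, genome, rng):
        truth = _random_svs(rng, genome, 20)
        callsets = list(observe_callers(truth, default_caller_models(),
                                        genome, rng).values())
        ref = [(c.bnd1, c.bnd2) for c in
               consensus_filter(callsets, tol=500)]
        perm = [callsets[2], callsets[0], callsets[1]]
        assert [(c.bnd1, c.bnd2)
                for c in consensus_filter(perm, tol=500)] == ref

    def test_idempotent_on_own_output(self, genome, rng):
        truth = _random_svs(rng, genome, 20)
        callsets = list(observe_callers(truth, default_caller_models(),
                                        genome, rng).values())
        first = consensus_filter(callsets, tol=500)
        replicated = [
            [ConsensusSV(c.bnd1, c.bnd2, c.orientation,
                         frozenset([f"r{k}"])).as_svcall()
             for c in first] for k in range(3)]
        for k, calls in enumerate(replicated):
            for c in calls:
                object.__setattr__(c, "caller_id", f"r{k}")
        again = consensus_filter(replicated, tol=500)
        assert [(c.bnd1.pos, c.bnd2.pos) for c in again] == \
            [(c.bnd1.pos, c.bnd2.pos) for c in first]

    def test_monotone_adding_support(self, genome, rng):
        truth = _random_svs(rng, genome, 20)
        callsets = list(observe_callers(truth, default_caller_models(),
                                        genome, rng).values())
        before = {(c.bnd1.chrom, c.bnd2.chrom, c.orientation)
                  for c in consensus_filter(callsets, tol=500)}
        extra = SVCall(truth[0].bnd1, truth[0].bnd2, truth[0].orientation,
                       "caller1", 50.0)
        callsets[0] = callsets[0] + [extra]
        after = {(c.bnd1.chrom, c.bnd2.chrom, c.orientation)
                 for c in consensus_filter(callsets, tol=500)}
        assert before <= after


def _cands(programs, g5="FRS2", g3="ELF1"):
    genes = toy_gene_models()
    bp5 = (genes[g5].chrom, genes[g5].exons[0][1])
    bp3 = (genes[g3].chrom, genes[g3].exons[1][0])
    return FusionCandidate(gene5=g5, gene3=g3, breakpoint5=bp5,
                           breakpoint3=bp3, programs=frozenset(programs))


class TestFusionFilter:
    def _matching_sv(self):
        genes = toy_gene_models()
        return ConsensusSV(
            Breakend(genes["FRS2"].chrom, genes["FRS2"].exons[0][1] + 50,
                     "right"),
            Breakend(genes["ELF1"].chrom, genes["ELF1"].exons[1][0] - 50,
                     "left"),
            "interchromosomal", frozenset({"c1", "c2"}))

    def test_both_programs_with_dna_support_retained(self):
        cand = _cands({"prog1", "prog2"})
        kept = filter_fusions([cand], [self._matching_sv()],
                              toy_gene_models())
        assert kept == [cand]
        assert cand.dna_supported
        assert cand.matched_sv is not None

    def test_both_programs_without_dna_removed(self):
        cand = _cands({"prog1", "prog2"})
        assert filter_fusions([cand], [], toy_gene_models()) == []

    def test_single_program_with_dna_removed(self):
        cand = _cands({"prog1"})
        assert filter_fusions([cand], [self._matching_sv()],
                              toy_gene_models()) == []

    def test_unknown_gene_rejected(self):
        cand = FusionCandidate(gene5="NOSUCH", gene3="ELF1",
                               breakpoint5=("chr1", 1),
                               breakpoint3=("chr13", 1),
                               programs=frozenset({"prog1", "prog2"}))
        with pytest.raises(KeyError):
            filter_fusions([cand], [], toy_gene_models())

    def test_same_gene_fusion_rejected(self):
        with pytest.raises(ValueError):
            FusionCandidate(gene5="FRS2", gene3="FRS2",
                            breakpoint5=("chr12", 1),
                            breakpoint3=("chr12", 2),
                            programs=frozenset({"prog1"}))
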