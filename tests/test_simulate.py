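"""Mechanism simulators: chromothripsis, BFB, TP53 dicentric, observers."""

import numpy as np
import pytest

from amp12q.genome import (
    CNProfile,
    DerivativeChromosome,
    Segment,
    cn_from_derivative,
    sv_from_derivative,
)
from amp12q.simulate import (
    CallerModel,
    ExpressionModel,
    GROUP_SIZES,
    SimConfig,
    generate_cohort,
    observe_callers,
    rna_cohort_labels,
    simulate_bfb,
    simulate_chromothripsis,
    simulate_expression,
    simulate_tp53_dicentric,
    toy_gene_models,
)


class TestChromothripsis:
    def test_full_retention_conserves_content(self, genome, rng):
        der, lost = simulate_chromothripsis(genome, "chr12", 25, 1.0, rng)
        assert lost == []
        assert der.total_length() == genome.length("chr12")
        profile = cn_from_derivative(der, CNProfile.flat("s", genome))
        assert [s.cn for s in profile.segments["chr12"]] == [3]

    def test_identity_permutation_gives_intact_chromosome(self, genome):
        # search seeds for the draw with identity order and no flips
        for seed in range(20000):
            rng = np.random.default_rng(seed)
            der, _ = simulate_chromothripsis(genome, "chr12", 3, 1.0, rng)
            if all(b.strand == "+" for b in der.blocks) and \
                    [b.start for b in der.blocks] == \
                    sorted(b.start for b in der.blocks):
                assert sv_from_derivative(der) == []
                return
        pytest.fail("no identity draw found in seed search")

    def test_fragment_count_too_small_rejected(self, genome, rng):
        with pytest.raises(ValueError):
            simulate_chromothripsis(genome, "chr12", 1, 0.5, rng)

    def test_history_records_draws(self, genome, rng):
        der, _ = simulate_chromothripsis(genome, "chr12", 10, 0.5, rng)
        rec = der.history[0]
        assert rec["op"] == "chromothripsis"
        assert len(rec["cuts"]) == 9
        assert len(rec["order"]) == len(der.blocks)

    def test_protected_locus_never_cut_and_retained(self, genome):
        locus = (58_000, 61_000)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            der, _ = simulate_chromothripsis(
                genome, "chr12", 40, 0.3, rng, protected_loci=[locus])
            assert any(b.contains("chr12", *locus) for b in der.blocks)

    def test_junction_orientations_equiprobable(self, genome):
        # random permutation and flips make the four classes equally
        # likely: each frequency within 3 binomial sds of 1/4
        counts = {"HH": 0, "TT": 0, "TD": 0, "D": 0}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            der, _ = simulate_chromothripsis(genome, "chr12", 200, 0.6, rng)
            for call in sv_from_derivative(der):
                counts[call.orientation] += 1
        total = sum(counts.values())
        sd = np.sqrt(total * 0.25 * 0.75)
        for cls, n in counts.items():
            assert abs(n - total / 4) < 3 * sd, (cls, counts)


def _toy_ring(toy_genome):
    return DerivativeChromosome(toy_genome, [
        Segment("chr12", 100, 1300, "+"),
        Segment("chr12", 4000, 5800, "+"),
        Segment("chr12", 7000, 8000, "-")])


LOCUS = ("chr12", 4500, 5200, "G")


class TestBFB:
    def test_zero_cycles_identity(self, toy_genome, rng):
        der = _toy_ring(toy_genome)
        assert simulate_bfb(der, [LOCUS], 0, rng) is der

    def test_doubling_bound(self, toy_genome):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            der = simulate_bfb(_toy_ring(toy_genome), [LOCUS], 4, rng)
            assert der.locus_copies(*LOCUS[:3]) <= 2 ** 4

    def test_fold_back_junctions_only_for_pure_bfb(self, genome):
        # BFB of an intact chromosome emits exclusively HH/TT junctions,
        # so the orientation equiprobability test rejects
        from amp12q.chromothripsis import orientation_equiprobability
        rng = np.random.default_rng(5)
        der = DerivativeChromosome(
            genome, [Segment("chr12", 0, genome.length("chr12"))])
        der = simulate_bfb(der, [("chr12", 58_000, 61_000, "CDK4")], 60,
                           rng)
        classes = [c.orientation for c in sv_from_derivative(der)]
        assert len(classes) >= 20
        assert set(classes) <= {"HH", "TT"}
        counts = [classes.count(c) for c in ("HH", "TT", "TD", "D")]
        _, p = orientation_equiprobability(counts)
        assert p < 0.01

    def test_die_out_raises_with_locus_name(self, toy_genome, rng):
        # a locus absent from the derivative can never be retained
        with pytest.raises(RuntimeError, match="GHOST"):
            simulate_bfb(_toy_ring(toy_genome),
                         [("chr12", 9000, 9500, "GHOST")], 1, rng)

    def test_copy_distribution_matches_enumeration(self, toy_genome):
        """Two BFB cycles on a small grid: Monte-Carlo locus copy counts
        match exhaustive enumeration of break positions and survivals."""
        blocks = [("chr12", 100, 115, "+"), ("chr12", 120, 135, "+"),
                  ("chr12", 140, 150, "-")]
        locus = ("chr12", 122, 130)

        def flip(bs):
            return [(c, s, e, "-" if st == "+" else "+")
                    for c, s, e, st in reversed(bs)]

        def split(bs, off):
            pre, pos = [], 0
            for i, (c, s, e, st) in enumerate(bs):
                ln = e - s
                if pos + ln <= off:
                    pre.append((c, s, e, st))
                    pos += ln
                    continue
                cut = off - pos
                if cut == 0:
                    return pre, bs[i:]
                if st == "+":
                    return pre + [(c, s, s + cut, st)], \
                        [(c, s + cut, e, st)] + bs[i + 1:]
                return pre + [(c, e - cut, e, st)], \
                    [(c, s, e - cut, st)] + bs[i + 1:]

        def copies(bs):
            return sum(1 for c, s, e, _ in bs
                       if c == locus[0] and s <= locus[1]
                       and locus[2] <= e)

        def step(bs):
            """Distribution over products of one cycle (conditioned on
            validity, product chosen proportional to copy count)."""
            doubled = bs + flip(bs)
            total = sum(e - s for _, s, e, _ in doubled)
            outcomes = {}
            weight_per_offset = 1.0 / (total - 1)
            valid_offsets = []
            for off in range(1, total):
                pre, suf = split(doubled, off)
                prods = [p for p in (pre, suf) if copies(p) >= 1]
                if prods:
                    valid_offsets.append((off, prods))
            norm = len(valid_offsets)
            for off, prods in valid_offsets:
                ws = [copies(p) for p in prods]
                for p, w in zip(prods, ws):
                    key = tuple(p)
                    outcomes[key] = outcomes.get(key, 0.0) \
                        + (w / sum(ws)) / norm
            return outcomes

        # exact distribution of copy number after two cycles
        dist = {}
        for state1, p1 in step(blocks).items():
            for state2, p2 in step(list(state1)).items():
                c = copies(list(state2))
                dist[c] = dist.get(c, 0.0) + p1 * p2

        # Monte-Carlo through the production implementation
        der0 = DerivativeChromosome(
            toy_genome, [Segment(c, s, e, st) for c, s, e, st in blocks])
        sim_counts = {}
        n_mc = 3000
        for seed in range(n_mc):
            rng = np.random.default_rng(seed)
            der = simulate_bfb(der0, [(*locus, "G")], 2, rng)
            c = der.locus_copies(*locus)
            sim_counts[c] = sim_counts.get(c, 0) + 1
        for c in set(dist) | set(sim_counts):
            expected = dist.get(c, 0.0)
            observed = sim_counts.get(c, 0) / n_mc
            sd = np.sqrt(max(expected * (1 - expected), 1e-6) / n_mc)
            assert abs(observed - expected) < max(5 * sd, 0.02), \
                (c, observed, expected)


class TestTP53Dicentric:
    def test_dicentric_by_construction(self, genome, rng):
        der, truth, _ = simulate_tp53_dicentric(genome, toy_gene_models(),
                                                0, rng)
        assert der.centromere_count == 2
        assert truth.promoter_gene == "TP53"

    def test_junction_and_cdk4_retained_through_cycles(self, genome):
        genes = toy_gene_models()
        cdk4 = genes["CDK4"].locus
        for seed in range(10):
            rng = np.random.default_rng(seed)
            der, truth, _ = simulate_tp53_dicentric(genome, genes, 3, rng)
            assert der.locus_copies("chr12", *cdk4) >= 2
            # the TP53-promoter junction breakends appear among junctions
            keys = {frozenset([(c.bnd1.chrom, c.bnd1.pos, c.bnd1.side),
                               (c.bnd2.chrom, c.bnd2.pos, c.bnd2.side)])
                    for c in sv_from_derivative(der)}
            jt = frozenset([(truth.breakpoints[0].chrom,
                             truth.breakpoints[0].pos,
                             truth.breakpoints[0].side),
                            (truth.breakpoints[1].chrom,
                             truth.breakpoints[1].pos,
                             truth.breakpoints[1].side)])
            assert jt in keys

    def test_partner_cds_fully_fused(self, genome, rng):
        genes = toy_gene_models()
        _, truth, _ = simulate_tp53_dicentric(genome, genes, 0, rng)
        # CDS exons (2..5) of the partner are always retained
        assert {2, 3, 4, 5} <= set(truth.partner_fused_exons)
        assert truth.promoter_included_exons == {1}


class TestObserveCallers:
    def _truth(self, genome, rng, n=20):
        from amp12q.genome import Breakend, SVCall
        out = []
        while len(out) < n:
            pos = sorted(rng.integers(0, genome.length("chr12"),
                                      size=2).tolist())
            if pos[0] == pos[1]:
                continue
            out.append(SVCall.make(
                Breakend("chr12", int(pos[0]), "right"),
                Breakend("chr12", int(pos[1]), "left"), "truth"))
        return out

    def test_perfect_caller_reproduces_truth(self, genome, rng):
        truth = self._truth(genome, rng)
        model = CallerModel("perfect", sensitivity=1.0, fp_rate=0.0,
                            jitter_sd=0.0)
        calls = observe_callers(truth, [model], genome, rng)["perfect"]
        assert [c.key() for c in calls] == [t.key() for t in truth]

    def test_blind_caller_emits_only_false_positives(self, genome, rng):
        truth = self._truth(genome, rng)
        model = CallerModel("blind", sensitivity=0.0, fp_rate=3.0)
        calls = observe_callers(truth, [model], genome, rng)["blind"]
        truth_keys = {t.key() for t in truth}
        assert all(c.key() not in truth_keys for c in calls)

    def test_no_models_rejected(self, genome, rng):
        with pytest.raises(ValueError):
            observe_callers([], [], genome, rng)


class TestExpression:
    def test_dosage_closed_form(self, rng):
        genes = toy_gene_models()
        model = ExpressionModel(baseline_log_sd=0.0, noise_sd=0.0,
                                dosage_exponent=1.0)
        gmat, _ = simulate_expression(
            ["amp", "dip"], genes, {"amp": {"CDK4": 8}}, {}, model, rng)
        assert gmat.at["CDK4", "amp"] - gmat.at["CDK4", "dip"] == \
            pytest.approx(2.0)

    def test_no_swap_no_exon_asymmetry(self, rng):
        genes = toy_gene_models()
        model = ExpressionModel(baseline_log_sd=0.2, noise_sd=0.2)
        diffs = []
        for s in range(40):
            r = np.random.default_rng(s)
            _, emat = simulate_expression(["x"], genes, {}, {}, model, r)
            ex = emat.loc[[f"ELF1:exon{i}" for i in range(1, 6)], "x"]
            diffs.append(ex.iloc[0] - ex.iloc[1:].mean())
        assert abs(np.mean(diffs)) < 0.1

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            ExpressionModel(swap_fold=0.5)


class TestCohort:
    def test_default_cohort_size(self):
        cases = generate_cohort(1)
        assert len(cases) == sum(GROUP_SIZES.values()) == 25

    def test_same_seed_identical_outputs(self):
        a, b = generate_cohort(42), generate_cohort(42)
        for ca, cb in zip(a, b):
            assert ca.observed_cn == cb.observed_cn
            assert [s.key() for s in ca.true_svs] == \
                [s.key() for s in cb.true_svs]
            assert ca.sex == cb.sex

    def test_rna_cohort_composition(self):
        labels = rna_cohort_labels()
        assert len(labels) == 95
        from collections import Counter
        counts = Counter(subtype for _, subtype in labels)
        assert counts["OS_Conv"] == 69
        assert counts["OB"] == 13

    def test_cohort_invariants(self):
        from amp12q.chromothripsis import infer_template
        for case in generate_cohort(9):
            # exact CN bookkeeping: true profile reproducible from truth
            if case.derivative is not None:
                assert case.true_cn.cn_at("chr12", 0) >= 0
            dels = [s for s in case.true_cn.segments["chr12"] if s.cn < 2]
            if case.group_label == "A":
                # extra-copy template: never a chr12 deletion
                assert dels == []
            if case.group_label == "D":
                assert dels, "dicentric cases always delete chr12 material"
                t = infer_template(case.observed_cn, "chr12")
                assert t.template == "normal_homologue"

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, {"E": 2})
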