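"""Genome-pair comparison and the binomial conservation model."""

import math

import numpy as np
import pytest
from scipy import stats

from paleovir import conserve as ck
from paleovir import synthgen as sg
from paleovir.io import Gene, GenomeRecord


def _mutate(seq: str, positions, offset=1):
    out = list(seq)
    for pos in positions:
        out[pos] = "ACGT"[("ACGT".index(out[pos]) + offset) % 4]
    return "".join(out)


class TestAlignPair:
    def test_identical_sequences(self):
        aln = ck.align_pair("ACGTACGTAC", "ACGTACGTAC")
        assert aln.identity == 100.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_deletion_toy(self):
        aln = ck.align_pair("ACGT", "AGT")
        assert len(aln) == 4
        matches = sum(x == y for x, y in zip(aln.aligned_a, aln.aligned_b))
        assert matches == 3
        assert aln.aligned_b.count("-") == 1

    def test_toy_score_matches_exhaustive_dp(self):
        """Spot-check the affine score against a brute-force DP over all
        alignments of tiny strings."""
        sc = ck.AlignmentScoring()

        def brute(a, b):
            # plain recursive DP with affine state, memoized
            from functools import lru_cache

            @lru_cache(maxsize=None)
            def go(i, j, state):
                if i == len(a) and j == len(b):
                    return 0.0
                best = -math.inf
                if i < len(a) and j < len(b):
                    s = sc.match if a[i] == b[j] else sc.mismatch
                    best = max(best, s + go(i + 1, j + 1, 0))
                if i < len(a):
                    gap = sc.gap_extend if state == 1 else sc.gap_open
                    best = max(best, gap + go(i + 1, j, 1))
                if j < len(b):
                    gap = sc.gap_extend if state == 2 else sc.gap_open
                    best = max(best, gap + go(i, j + 1, 2))
                return best

            return go(0, 0, 0)

        for a, b in [("ACGT", "AGT"), ("AAAA", "TTTT"), ("ACGTAC", "ACTAC"), ("A", "ACGT")]:
            aln = ck.align_pair(a, b)
            assert aln.score == pytest.approx(brute(a, b))

    def test_score_symmetric_under_swap(self):
        a = sg.simulate_genome(800, 0.5, seed=1).sequence
        b = _mutate(a, np.random.default_rng(2).choice(800, 20, replace=False))
        assert ck.align_pair(a, b).score == pytest.approx(ck.align_pair(b, a).score)

    def test_banded_matches_unbanded(self):
        rng = np.random.default_rng(3)
        a = sg.simulate_genome(5_000, 0.5, seed=4).sequence
        b = list(_mutate(a, rng.choice(5_000, 115, replace=False)))  # ~2.3% divergence
        del b[1200:1203]
        b.insert(3000, "G")
        b = "".join(b)
        full = ck.align_pair(a, b)
        band = ck.align_pair(a, b, band=500)
        assert abs(full.identity - band.identity) < 0.05
        assert band.score <= full.score + 1e-9

    def test_band_infeasible(self):
        with pytest.raises(ValueError):
            ck.align_pair("A" * 100, "A" * 10, band=50)


class TestTrimFlanks:
    def test_planted_flanks_recovered(self):
        rng_core = sg.simulate_genome(3_000, 0.5, seed=31).sequence
        left = sg.simulate_genome(241, 0.5, seed=32).sequence
        right = sg.simulate_genome(119, 0.5, seed=33).sequence
        query = left + rng_core + right
        alignments = []
        for seed in (34, 35, 36):
            rel = _mutate(rng_core, np.random.default_rng(seed).choice(3_000, 30, replace=False))
            alignments.append(ck.align_pair(query, rel))
        start, end, (lf, rf) = ck.trim_flanks(alignments, min_presence=2)
        assert lf == pytest.approx(241, abs=2)
        assert rf == pytest.approx(119, abs=2)
        assert end - start + 1 == pytest.approx(3_000, abs=4)

    def test_no_flanks_core_is_everything(self):
        a = sg.simulate_genome(1_000, 0.5, seed=41).sequence
        aln = ck.align_pair(a, a)
        start, end, flanks = ck.trim_flanks([aln], min_presence=1)
        assert (start, end, flanks) == (1, 1_000, (0, 0))

    def test_min_presence_exceeding_relatives_raises(self):
        a = sg.simulate_genome(100, 0.5, seed=42).sequence
        with pytest.raises(ValueError):
            ck.trim_flanks([ck.align_pair(a, a)], min_presence=2)


class TestCallSnvs:
    def test_identical_pair(self):
        a = sg.simulate_genome(500, 0.5, seed=51).sequence
        table = ck.call_snvs(ck.align_pair(a, a))
        assert table.n_snvs == 0 and table.indels == []

    @pytest.mark.parametrize("k", [0, 1, 5, 50, 842])
    def test_exact_on_planted_substitutions(self, k):
        n = 36_630 if k == 842 else 2_000
        a = sg.simulate_genome(n, 0.5, seed=52 + k).sequence
        pos = np.random.default_rng(53 + k).choice(n, k, replace=False)
        b = _mutate(a, pos)
        aln = ck.PairwiseAlignment("a", "b", a, b)  # gapless pair
        table = ck.call_snvs(aln)
        assert table.n_snvs == k
        assert sorted(p for p, _, _ in table.snvs) == sorted(int(p) + 1 for p in pos)

    def test_planted_substitutions_and_deletion(self):
        a = sg.simulate_genome(2_000, 0.5, seed=61).sequence
        pos = [100, 400, 800, 1200, 1600]
        b = list(_mutate(a, pos))
        del b[999:1002]  # 3-bp deletion
        aln = ck.align_pair(a, "".join(b))
        table = ck.call_snvs(aln)
        assert table.n_snvs == 5
        assert [(length, kind) for _, length, kind in table.indels] == [(3, "deletion")]


class TestWindowIdentity:
    def test_identical_alignment_not_flagged(self):
        a = sg.simulate_genome(5_000, 0.5, seed=71).sequence
        track = ck.window_identity(ck.align_pair(a, a))
        assert all(v == 100.0 for v in track.identities)
        assert not any(track.flagged)

    def test_planted_hypervariable_region_flagged(self):
        n = 36_000
        a = sg.simulate_genome(n, 0.5, seed=72).sequence
        rng = np.random.default_rng(73)
        background = rng.choice(n, int(n * 0.005), replace=False)
        hyper = 18_000 + rng.choice(600, 120, replace=False)  # 20% divergence
        b = _mutate(_mutate(a, background), hyper, offset=2)
        aln = ck.PairwiseAlignment("a", "b", a, b)
        track = ck.window_identity(aln, window=200, step=100)
        flagged_cols = {
            s for s, f in zip(track.window_starts, track.flagged) if f
        }
        assert flagged_cols  # the DGR-like region is detected
        for s in flagged_cols:
            assert 17_000 <= s <= 19_000

    def test_short_alignment_single_window(self):
        a = sg.simulate_genome(80, 0.5, seed=74).sequence
        track = ck.window_identity(ck.align_pair(a, a), window=100)
        assert track.window_starts == [1]
        assert len(track.identities) == 1


class TestPerGeneIdentity:
    def test_identical_genes(self):
        g = sg.simulate_genome(4_000, 0.5, seed=81)
        annotated, genes, _ = sg.plant_genes(g, 5, 300, seed=82)
        aln = ck.align_pair(annotated.sequence, annotated.sequence)
        per_gene, mean = ck.per_gene_identity(aln, genes, level="amino_acid")
        assert all(v == 100.0 for _, v in per_gene)
        assert mean == 100.0

    def test_two_substitutions_in_100aa_gene(self):
        g = sg.simulate_genome(1_000, 0.5, seed=83)
        annotated, genes, proteins = sg.plant_genes(g, 1, 300, seed=84)
        gene = genes[0]
        # two non-synonymous codon edits inside the gene
        seq = list(annotated.sequence)
        for codon_idx in (10, 50):
            start = gene.start - 1 + 3 * codon_idx
            seq[start : start + 3] = "TGG" if seq[start : start + 3] != list("TGG") else "TAC"
        b = "".join(seq)
        aln = ck.PairwiseAlignment("a", "b", annotated.sequence, b)
        per_gene, mean = ck.per_gene_identity(aln, genes, level="amino_acid")
        assert per_gene[0][1] == pytest.approx(98.0, abs=1e-6)

    def test_unweighted_mean_semantics(self):
        """One depressed gene against nine conserved ones: the mean is
        the plain average of per-gene identities."""
        n = 10_000
        a = sg.simulate_genome(n, 0.5, seed=85).sequence
        genes = [Gene(f"g{i}", "a", 1 + i * 1000, (i + 1) * 1000) for i in range(10)]
        b = list(a)
        rng = np.random.default_rng(86)
        # gene 0: 918/1000 matches; genes 1..9: 989/1000
        b[:0] = []
        b = _mutate("".join(b), rng.choice(1000, 82, replace=False))
        for i in range(1, 10):
            b = _mutate(b, 1000 * i + rng.choice(1000, 11, replace=False))
        aln = ck.PairwiseAlignment("a", "b", a, b)
        per_gene, mean = ck.per_gene_identity(aln, genes, level="nucleotide")
        assert per_gene[0][1] == pytest.approx(91.8)
        assert per_gene[1][1] == pytest.approx(98.9)
        assert mean == pytest.approx((91.8 + 9 * 98.9) / 10)

    def test_fully_deleted_gene_reported_missing(self):
        a = "ATGAAACCCGGGTTTTAA" + "ACGT" * 10
        # gene interval aligned only to gaps in the partner genome
        aln = ck.PairwiseAlignment("a", "b", a, "-" * 18 + "ACGT" * 10)
        genes = [Gene("g1", "a", 1, 18)]
        per_gene, mean = ck.per_gene_identity(aln, genes, level="amino_acid")
        assert per_gene[0][1] is None
        assert mean is None


class TestConservationModel:
    def test_zero_rate_or_time_gives_certainty(self):
        for params in (
            ck.ConservationParams(rate_r=0.0),
            ck.ConservationParams(years_t=0.0),
        ):
            prob, log10p = ck.prob_conserved(params)
            assert prob == 1.0 and log10p == 0.0

    def test_small_case_closed_form(self):
        # n=10, m=2, p=0.1: P(X<=2) = 0.9^10 + 10*0.1*0.9^9 + 45*0.01*0.9^8
        params = ck.ConservationParams(n=10, q=0.8, rate_r=0.1, years_t=1.0, compounding="linear")
        expected = 0.9**10 + 10 * 0.1 * 0.9**9 + 45 * 0.01 * 0.9**8
        prob, _ = ck.prob_conserved(params)
        assert prob == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.9298, abs=5e-5)

    def test_matches_scipy_cdf_on_grid(self):
        """Log-space accumulation agrees with the independent scipy
        binomial CDF to 1e-10 relative in log10."""
        for n in (10, 100, 1000):
            for p in (0.001, 0.02, 0.3):
                for q in (0.9, 0.977):
                    params = ck.ConservationParams(n=n, q=q, rate_r=p, years_t=1.0,
                                                   compounding="linear")
                    _, log10p = ck.prob_conserved(params)
                    oracle = stats.binom.logcdf(params.m, n, p) / math.log(10)
                    assert abs(log10p - oracle) <= max(1e-10 * abs(oracle), 1e-12)

    def test_log_probability_collapses_at_1300_years(self):
        _, log10p = ck.prob_conserved(ck.ConservationParams(years_t=1300.0))
        assert log10p < -300

    def test_monotone_decreasing_in_time_and_rate(self):
        probs_t = [
            ck.prob_conserved(ck.ConservationParams(years_t=t))[0] for t in (50, 100, 200, 400)
        ]
        # both endpoints sit within float noise of 1 at small t, so allow
        # an epsilon while requiring a real decrease overall
        for a, b in zip(probs_t, probs_t[1:]):
            assert b <= a + 1e-9
        assert probs_t[-1] < probs_t[0]
        probs_r = [
            ck.prob_conserved(ck.ConservationParams(rate_r=r, years_t=200.0))[0]
            for r in (1e-5, 1.154e-4, 1.976e-4, 4.69e-3)
        ]
        for a, b in zip(probs_r, probs_r[1:]):
            assert b <= a + 1e-9
        assert probs_r[-1] < probs_r[0]

    def test_compound_linear_gap_small_at_temperate_scale(self):
        c = ck.ConservationParams(rate_r=1.154e-4, years_t=200.0, compounding="compound")
        l = ck.ConservationParams(rate_r=1.154e-4, years_t=200.0, compounding="linear")
        assert abs(c.p_site - l.p_site) < 3e-4


class TestYearsToThreshold:
    def test_matches_direct_scan(self):
        n, q, r = 2_000, 0.99, 5e-4
        t_bisect = ck.years_to_threshold(n, q, r, prob_target=1e-3)
        t_scan = next(
            t for t in range(1, 10_000)
            if ck.prob_conserved(
                ck.ConservationParams(n=n, q=q, rate_r=r, years_t=float(t))
            )[0] < 1e-3
        )
        assert t_bisect == t_scan

    def test_zero_rate_never_decays(self):
        assert ck.years_to_threshold(36_630, 0.977, 0.0) is None

    def test_target_above_one_returns_zero(self):
        assert ck.years_to_threshold(36_630, 0.977, 1e-4, prob_target=1.0) == 0

    def test_temperate_rate_lands_just_past_two_centuries(self):
        t = ck.years_to_threshold(36_630, 0.977, 1.154e-4, prob_target=1e-3)
        assert 201 <= t <= 260
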