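"""Tests of the peak-comparison suite: interval ops vs brute-force oracles,
PWM threshold vs exhaustive enumeration, rank tests, annotation, metagene
and codon classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chipwin import synthetic
from chipwin.features import (PWM, FeatureDistribution, GeneModel, MotifHit,
                              annotate_peaks, average_conservation,
                              classify_codon_reads, count_motifs_in_peaks,
                              ctcf_like_pwm, intersect_peaks, linear_r2,
                              metagene_profile, peak_coverage, pwm_threshold,
                              pwm_tail_probability, scan_motifs,
                              score_distribution, wilcoxon_rank_sum)
from chipwin.peakcalling import Peak, PeakSet, TagTrack


def random_peakset(rng, label, n, chroms=("chr1", "chr2"), span=100_000):
    """Random sorted non-overlapping peaks."""
    peaks = []
    for chrom in chroms:
        pos = 0
        for _ in range(n // len(chroms)):
            pos += int(rng.integers(50, span // n))
            width = int(rng.integers(20, 400))
            peaks.append(Peak(chrom, pos, pos + width, 7.0))
            pos += width
    return PeakSet(label, peaks)


# ---------------------------------------------------------------------------
# interval operations vs brute force


class TestIntersectPeaks:
    def test_self_intersection_is_complete(self):
        rng = np.random.default_rng(0)
        a = random_peakset(rng, "a", 40)
        shared, frac = intersect_peaks(a, a)
        assert frac == 1.0 and len(shared) == len(a)

    def test_disjoint_sets_share_nothing(self):
        a = PeakSet("a", [Peak("chr1", 0, 100, 7)])
        b = PeakSet("b", [Peak("chr1", 200, 300, 7)])
        shared, frac = intersect_peaks(a, b)
        assert frac == 0.0 and len(shared) == 0

    def test_empty_query_flagged_undefined(self):
        a = PeakSet("a", [])
        b = PeakSet("b", [Peak("chr1", 0, 100, 7)])
        _, frac = intersect_peaks(a, b)
        assert np.isnan(frac)

    def test_matches_allpairs_oracle_on_random_sets(self):
        rng = np.random.default_rng(1)
        for rep in range(30):
            a = random_peakset(rng, "a", 30)
            b = random_peakset(rng, "b", 24)
            shared, frac = intersect_peaks(a, b)
            oracle = [p for p in a
                      if any(p.chrom == q.chrom and p.start < q.end
                             and p.end > q.start for q in b)]
            assert [(p.chrom, p.start) for p in shared] == \
                [(p.chrom, p.start) for p in oracle]
            assert frac == len(oracle) / len(a)


class TestPeakCoverage:
    def test_zero_track_all_zero(self):
        t = TagTrack({"chr1": np.zeros(1000, dtype=np.int64)})
        cov = peak_coverage(t, [Peak("chr1", 10, 500, 7)])
        assert cov.tolist() == [0]

    def test_whole_chromosome_peak_conserves_total(self):
        rng = np.random.default_rng(2)
        arr = rng.poisson(2.0, 5000).astype(np.int64)
        t = TagTrack({"chr1": arr})
        cov = peak_coverage(t, [Peak("chr1", 0, 5000, 7)])
        assert cov[0] == arr.sum() == t.total_tags

    def test_matches_perbase_oracle(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(1.5, 20_000).astype(np.int64)
        t = TagTrack({"chr1": arr})
        peaks = random_peakset(rng, "p", 40, chroms=("chr1",), span=20_000)
        cov = peak_coverage(t, peaks)
        for c, p in zip(cov, peaks):
            assert c == arr[p.start:p.end].sum()

    def test_unknown_chromosome_named_in_error(self):
        t = TagTrack({"chr1": np.zeros(100, dtype=np.int64)})
        with pytest.raises(KeyError, match="chrX"):
            peak_coverage(t, [Peak("chrX", 0, 10, 7)])


class TestCountMotifs:
    def test_no_motifs_all_zero(self):
        peaks = [Peak("chr1", 0, 100, 7), Peak("chr1", 200, 300, 7)]
        assert count_motifs_in_peaks([], peaks).tolist() == [0, 0]

    def test_single_contained_motif(self):
        peaks = [Peak("chr1", 0, 100, 7), Peak("chr1", 200, 300, 7)]
        hits = [MotifHit("chr1", 50, 65, "+", 10.0)]
        assert count_motifs_in_peaks(hits, peaks).tolist() == [1, 0]

    def test_straddling_motif_counts_for_both_peaks(self):
        peaks = [Peak("chr1", 0, 100, 7), Peak("chr1", 100, 200, 7)]
        hits = [MotifHit("chr1", 95, 110, "+", 10.0)]
        assert count_motifs_in_peaks(hits, peaks).tolist() == [1, 1]

    def test_matches_allpairs_oracle(self):
        rng = np.random.default_rng(4)
        for rep in range(30):
            peaks = random_peakset(rng, "p", 30)
            hits = []
            for _ in range(60):
                chrom = f"chr{rng.integers(1, 3)}"
                s = int(rng.integers(0, 100_000))
                hits.append(MotifHit(chrom, s, s + 15, "+", 9.0))
            got = count_motifs_in_peaks(hits, peaks)
            for g, p in zip(got, peaks):
                oracle = sum(h.chrom == p.chrom and h.start < p.end
                             and h.end > p.start for h in hits)
                assert g == oracle


class TestAverageConservation:
    def test_constant_track(self):
        track = {"chr1": np.full(1000, 0.37)}
        out = average_conservation(track, [Peak("chr1", 10, 200, 7)])
        assert out[0] == pytest.approx(0.37)

    def test_half_covered_interval_uses_covered_half(self):
        arr = np.full(100, np.nan)
        arr[:50] = 2.0
        out = average_conservation({"chr1": arr}, [Peak("chr1", 0, 100, 7)])
        assert out[0] == pytest.approx(2.0)

    def test_uncovered_interval_flagged_missing(self):
        arr = np.full(100, np.nan)
        out = average_conservation({"chr1": arr}, [Peak("chr1", 0, 100, 7)])
        assert np.isnan(out[0])

    def test_matches_perbase_oracle(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=5000)
        arr[rng.random(5000) < 0.3] = np.nan
        peaks = random_peakset(rng, "p", 20, chroms=("chr1",), span=5000)
        out = average_conservation({"chr1": arr}, peaks)
        for o, p in zip(out, peaks):
            seg = arr[p.start:p.end]
            seg = seg[~np.isnan(seg)]
            if len(seg) == 0:
                assert np.isnan(o)
            else:
                assert o == pytest.approx(seg.mean())


# ---------------------------------------------------------------------------
# R² and rank-sum


class TestLinearR2:
    def test_exact_line_gives_one(self):
        x = np.arange(10.0)
        assert linear_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_constant_response_flagged(self):
        assert np.isnan(linear_r2(np.arange(5.0), np.full(5, 3.0)))

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.7])
        # closed-form OLS with intercept
        b = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        a = y.mean() - b * x.mean()
        ss_res = np.sum((y - (a + b * x)) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert linear_r2(x, y) == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            linear_r2([1, 2, 3], [1, 2])


class TestWilcoxon:
    def test_fully_separated_triples_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.u == 0.0
        assert res.pvalue == pytest.approx(0.1, abs=1e-12)

    def test_exact_path_equals_full_enumeration_small_n(self):
        rng = np.random.default_rng(6)
        for rep in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=4)
            res = wilcoxon_rank_sum(a, b)
            assert res.method == "exact"
            # enumerate all rank assignments of the combined sample
            ranks = np.argsort(np.argsort(np.concatenate([a, b]))) + 1
            u_obs = ranks[:4].sum() - 4 * 5 / 2
            us = []
            for comb in itertools.combinations(range(8), 4):
                us.append(sum(sorted(range(1, 9))[i] for i in comb) - 10)
            us = np.array(us)
            p = min(1.0, np.mean(us <= min(u_obs, 16 - u_obs))
                    + np.mean(us >= max(u_obs, 16 - u_obs)))
            assert res.pvalue == pytest.approx(p, abs=1e-9)

    def test_identical_samples_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 7.0], [1.0, 2.0, 7.0])
        assert res.pvalue == pytest.approx(1.0)

    def test_ties_or_large_n_use_asymptotic_path(self):
        a = np.arange(15.0)
        b = np.arange(15.0) + 0.5
        assert wilcoxon_rank_sum(a, b).method == "asymptotic"
        assert wilcoxon_rank_sum([1, 1, 2], [2, 3, 4]).method == "asymptotic"

    def test_asymptotic_close_to_exact_at_n10(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=10)
        b = rng.normal(0.5, size=10)
        exact = wilcoxon_rank_sum(a, b)
        assert exact.method == "exact"
        from scipy.stats import mannwhitneyu
        approx = mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
        assert abs(exact.pvalue - approx.pvalue) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# PWM threshold and scanning


class TestPWMThreshold:
    def test_tail_matches_exhaustive_enumeration(self, small_pwm):
        grid = 1e-3
        t = pwm_threshold(small_pwm, 3e-5, grid=grid)
        s_int = np.rint(small_pwm.log_odds / grid).astype(np.int64)
        t_int = int(round(t / grid))
        tail = 0.0
        for word in itertools.product(range(4), repeat=8):
            score = sum(s_int[j, b] for j, b in enumerate(word))
            if score >= t_int:
                tail += float(np.prod([small_pwm.background[b] for b in word]))
        assert tail == pytest.approx(pwm_tail_probability(small_pwm, t),
                                     abs=1e-12)
        assert tail <= 3e-5
        # minimality: one grid step lower exceeds the cutoff
        assert pwm_tail_probability(small_pwm, t - grid) > 3e-5

    def test_tail_nonincreasing_in_threshold(self, small_pwm):
        ts = np.linspace(-5, 12, 40)
        tails = [pwm_tail_probability(small_pwm, t) for t in ts]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_distribution_sums_to_one(self, small_pwm):
        _, probs = score_distribution(small_pwm)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_background_pwm_threshold_admits_no_hits(self):
        flat = PWM(np.full((6, 4), 0.25))
        with pytest.warns(UserWarning):
            t = pwm_threshold(flat, 1e-3)
        assert t > 0
        assert len(scan_motifs("ACGT" * 100, flat, t)) == 0

    def test_bad_cutoff_rejected(self, small_pwm):
        with pytest.raises(ValueError):
            pwm_threshold(small_pwm, 0.0)


class TestScanMotifs:
    def test_planted_consensus_is_found(self, pwm):
        rng = np.random.default_rng(8)
        seq = list("".join(rng.choice(list("ACGT"), size=500)))
        cons = pwm.consensus()
        seq[100:100 + pwm.width] = cons
        t = pwm_threshold(pwm, 3e-5)
        hits = scan_motifs("".join(seq), pwm, t)
        assert any(h.start == 100 and h.end == 100 + pwm.width and h.strand == "+"
                   for h in hits)

    def test_matches_naive_rescan(self, small_pwm):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGTN"), size=3000,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        lo = small_pwm.log_odds
        t = 6.0
        hits = scan_motifs(seq, small_pwm, t, both_strands=False)
        got = {(h.start, round(h.score, 9)) for h in hits}
        code = {"A": 0, "C": 1, "G": 2, "T": 3}
        naive = set()
        for i in range(len(seq) - 8 + 1):
            word = seq[i:i + 8]
            if "N" in word:
                continue
            s = sum(lo[j, code[c]] for j, c in enumerate(word))
            if s >= t:
                naive.add((i, round(s, 9)))
        assert got == naive

    def test_palindromic_pwm_hits_both_strands(self):
        probs = np.full((6, 4), 0.01)
        for j, b in enumerate("ACGCGT"):  # reverse complement of itself
            probs[j, "ACGT".index(b)] = 0.97
        pwm = PWM(probs / probs.sum(axis=1, keepdims=True))
        hits = scan_motifs("TTTACGCGTTTT", pwm, threshold=5.0)
        strands = {h.strand for h in hits if h.start == 3}
        assert strands == {"+", "-"}

    def test_hit_count_nonincreasing_in_threshold(self, small_pwm):
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        counts = [len(scan_motifs(seq, small_pwm, t)) for t in (0.0, 3.0, 6.0, 9.0)]
        assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# annotation


def make_gene(chrom="chr1", strand="+", tx=(10_000, 18_000),
              cds=(10_500, 17_500), exons=None):
    exons = exons or [(10_000, 11_000), (13_000, 14_000), (17_000, 18_000)]
    return GeneModel(chrom, strand, tx[0], tx[1], cds[0], cds[1], exons)


class TestAnnotatePeaks:
    def test_no_genes_all_intergenic(self):
        peaks = [Peak("chr1", 100, 300, 7)]
        dist, bg = annotate_peaks(peaks, [], chrom_lengths={"chr1": 10_000})
        assert dist.fractions["intergenic"] == 1.0
        assert bg.fractions["intergenic"] == 1.0

    def test_promoter_priority_beats_exon(self):
        g = make_gene()
        # midpoint 10_200: inside first exon AND within 1 kb of the TSS
        dist, _ = annotate_peaks([Peak("chr1", 10_100, 10_300, 7)], [g])
        assert dist.fractions["promoter"] == 1.0

    def test_categories_by_construction(self):
        g = make_gene()
        cases = {
            "utr5": Peak("chr1", 10_440, 10_460, 7),    # mid 10450: exon, pre-CDS
            "intron": Peak("chr1", 12_000, 12_100, 7),
            "exon": Peak("chr1", 13_400, 13_600, 7),
            "utr3": Peak("chr1", 17_600, 17_800, 7),
            "downstream": Peak("chr1", 18_100, 18_300, 7),
            "intergenic": Peak("chr1", 50_000, 50_100, 7),
        }
        # avoid promoter window around the TSS for the utr5 case
        for cat, peak in cases.items():
            if cat == "utr5":
                g2 = make_gene(cds=(10_470, 17_500))
                dist, _ = annotate_peaks([peak], [g2], promoter_bp=400)
            else:
                dist, _ = annotate_peaks([peak], [g], promoter_bp=400)
            assert dist.fractions[cat] == 1.0, cat

    def test_fractions_sum_to_one_and_order_invariant(self):
        rng = np.random.default_rng(11)
        genome = synthetic.GenomeModel(["chr1"], [200_000])
        genes = synthetic.simulate_genes(genome, 8, seed=11)
        peaks = [Peak("chr1", s, s + 200, 7.0) for s in range(500, 190_000, 4800)]
        dist, _ = annotate_peaks(peaks, genes)
        assert sum(dist.fractions.values()) == pytest.approx(1.0)
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        dist2, _ = annotate_peaks(shuffled, genes)
        assert dist.fractions == dist2.fractions

    def test_empty_peakset_rejected(self):
        with pytest.raises(ValueError):
            annotate_peaks([], [make_gene()])


# ---------------------------------------------------------------------------
# metagene


class TestMetagene:
    def test_constant_coverage_flat_profile(self):
        cov = {"chr1": np.full(40_000, 3.0)}
        g = make_gene(tx=(20_000, 26_000), cds=(20_500, 25_500),
                      exons=[(20_000, 26_000)])
        prof, skipped = metagene_profile(cov, [g], n_body_bins=10,
                                         flank_bp=1000, flank_bins=5)
        assert skipped == 0
        assert np.allclose(prof, 3.0)

    def test_upstream_signal_confined_to_left_flank(self):
        cov = {"chr1": np.zeros(40_000)}
        cov["chr1"][19_000:20_000] = 5.0  # strictly upstream of the TSS
        g = make_gene(tx=(20_000, 26_000), cds=(20_500, 25_500),
                      exons=[(20_000, 26_000)])
        prof, _ = metagene_profile(cov, [g], n_body_bins=10,
                                   flank_bp=1000, flank_bins=5)
        assert np.all(prof[:5] > 0) and np.allclose(prof[5:], 0.0)

    def test_minus_strand_gene_reversed(self):
        cov = {"chr1": np.zeros(40_000)}
        cov["chr1"][26_000:27_000] = 5.0  # upstream of a minus-strand gene
        g = make_gene(strand="-", tx=(20_000, 26_000), cds=(20_500, 25_500),
                      exons=[(20_000, 26_000)])
        prof, _ = metagene_profile(cov, [g], n_body_bins=10,
                                   flank_bp=1000, flank_bins=5)
        assert np.all(prof[:5] > 0) and np.allclose(prof[5:], 0.0)

    def test_two_gene_hand_binned_means(self):
        cov = {"chr1": np.arange(60_000, dtype=float)}
        g1 = make_gene(tx=(20_000, 26_000), cds=(20_500, 25_500),
                       exons=[(20_000, 26_000)])
        g2 = make_gene(tx=(40_000, 46_000), cds=(40_500, 45_500),
                       exons=[(40_000, 46_000)])
        prof, _ = metagene_profile(cov, [g1, g2], n_body_bins=6,
                                   flank_bp=600, flank_bins=3)
        arr = cov["chr1"]
        rows = []
        for g in (g1, g2):
            row = []
            for k in range(3):
                s = g.tx_start - 600 + k * 200
                row.append(arr[s:s + 200].mean())
            for k in range(6):
                row.append(arr[g.tx_start + k * 1000:g.tx_start + (k + 1) * 1000].mean())
            for k in range(3):
                row.append(arr[g.tx_end + k * 200:g.tx_end + (k + 1) * 200].mean())
            rows.append(row)
        assert np.allclose(prof, np.mean(rows, axis=0))

    def test_short_gene_skipped_with_count(self):
        cov = {"chr1": np.zeros(10_000)}
        g = GeneModel("chr1", "+", 100, 140, 100, 140, [(100, 140)])
        prof, skipped = metagene_profile(cov, [g], n_body_bins=60)
        assert skipped == 1 and np.all(np.isnan(prof))


# ---------------------------------------------------------------------------
# codon classification


class TestCodonReads:
    def test_all_serine_reference_zero_glutamate(self):
        tally = classify_codon_reads(["TCC"] * 20)
        assert tally.glutamate_fraction == 0.0
        assert tally.counts.loc["T", "pos1"] == 20

    def test_fifteen_gag_in_hundred(self):
        tally = classify_codon_reads(["GAG"] * 15 + ["TCC"] * 85)
        assert tally.glutamate_fraction == pytest.approx(0.15)

    def test_gaa_also_counts_as_glutamate_and_n_excluded(self):
        tally = classify_codon_reads(["GAA", "GAG", "TCC", "GNG"])
        assert tally.glutamate_fraction == pytest.approx(2 / 3)
        assert tally.counts.loc["N", "pos2"] == 1

    def test_column_sums_equal_read_count(self):
        reads = synthetic.simulate_codon_reads(500, 0.2, 0.01, seed=12)
        tally = classify_codon_reads(reads)
        assert (tally.counts.sum(axis=0) == 500).all()

    def test_simulated_fraction_within_binomial_ci(self):
        reads = synthetic.simulate_codon_reads(5000, 0.14, 0.0, seed=13)
        tally = classify_codon_reads(reads)
        # deterministic allocation, zero error: exactly round(5000*0.14)
        assert tally.glutamate_fraction == pytest.approx(700 / 5000)
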