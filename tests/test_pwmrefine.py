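import numpy as np
import pytest
from scipy import stats

from lacicode._seq import ALPHABET, revcomp_matrix
from lacicode.footprint import GibbsConfig, gibbs_search
from lacicode.pwmrefine import (
    NullDistribution,
    PWM,
    build_pwm,
    null_scores,
    refine,
    scan,
    suppress_overlaps,
    zscore_filter,
)
from lacicode.seqio import make_site_table
from lacicode.synthetic import PlantedCode, generate_family, generate_regions


def _brute_force_score(freqs, background, window):
    total = 0.0
    for j, base in enumerate(window):
        total += np.log2(freqs[j, ALPHABET.index(base)] / background[ALPHABET.index(base)])
    return total


class TestBuildPWM:
    def test_uniform_column_zero_log_odds(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
        assert np.allclose(pwm.frequencies[0], 0.25)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_constant_pseudocount_arithmetic(self):
        pwm = build_pwm(["GGTGTGACGTCACA"], pseudocount=1.0)
        # each observed cell: (1 + 1/4) / (1 + 1) = 0.625
        cols = np.arange(14)
        codes = [ALPHABET.index(b) for b in "GGTGTGACGTCACA"]
        assert np.allclose(pwm.frequencies[cols, codes], 0.625)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            build_pwm([])

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])

    def test_palindromic_flag_symmetrizes(self):
        pwm = build_pwm(["AAAAAAAAAAAAAA"], palindromic=True)
        assert np.allclose(pwm.counts, revcomp_matrix(pwm.counts))


class TestScan:
    def test_embedded_consensus_found_once(self, rng):
        sites = ["TGTGAACGTTCACA", "TGTGATCGATCACA", "TGTGACCGGTCACA"]
        pwm = build_pwm(sites)
        consensus = "TGTGAACGTTCACA"
        region = "A" * 30 + consensus + "A" * 30
        hits = scan(pwm, ("r", region), min_score=pwm.score(consensus))
        assert list(hits["start"]) == [30]

    def test_min_score_neg_inf_returns_all_windows(self):
        pwm = build_pwm(["TGTGAACGTTCACA"])
        region = "ACGT" * 20
        hits = scan(pwm, ("r", region), min_score=-np.inf)
        assert len(hits) == len(region) - 14 + 1

    def test_brute_force_equivalence(self, rng):
        sites = ["".join(rng.choice(list(ALPHABET), size=14)) for _ in range(6)]
        pwm = build_pwm(sites)
        bg = np.full(4, 0.25)
        for _ in range(5):
            region = "".join(rng.choice(list(ALPHABET), size=60))
            hits = scan(pwm, ("r", region), min_score=-np.inf)
            for row in hits[hits.strand == "+"].itertuples():
                expected = _brute_force_score(pwm.frequencies, bg, row.sequence)
                assert abs(row.score - expected) < 1e-9


class TestNullScores:
    def test_zero_log_odds_pwm_gives_zero_scores(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
        null = null_scores(pwm, [("r", "ACGT" * 100)], n_null=1000, seed=1)
        assert np.allclose(null.scores, 0.0)

    def test_deterministic_given_seed(self):
        pwm = build_pwm(["TGTGAACGTTCACA", "TGTGATCGATCACA"])
        regions = [("r", "ACGTTGCA" * 40)]
        a = null_scores(pwm, regions, n_null=2000, seed=9)
        b = null_scores(pwm, regions, n_null=2000, seed=9)
        assert np.array_equal(a.scores, b.scores)

    def test_planted_consensus_is_extreme(self, rng):
        sites = ["TGTGAACGTTCACA", "TGTGATCGATCACA", "TGTGACCGGTCACA"]
        pwm = build_pwm(sites)
        regions = [("r%d" % i, "".join(rng.choice(list(ALPHABET), size=200)))
                   for i in range(5)]
        null = null_scores(pwm, regions, n_null=100_000, seed=2)
        p = null.pvalues(pwm.score("TGTGAACGTTCACA"))[0]
        assert p < 0.001

    def test_null_on_null_pvalues_superuniform(self, rng):
        # empirical p-values of null draws against their own null must pass a
        # KS test against uniform at alpha=0.01
        sites = ["TGTGAACGTTCACA", "TGTGATCGATCACA", "TGTGACCGGTCACA"]
        pwm = build_pwm(sites)
        regions = [("r%d" % i, "".join(rng.choice(list(ALPHABET), size=200)))
                   for i in range(5)]
        null = null_scores(pwm, regions, n_null=20_000, seed=3)
        fresh = null_scores(pwm, regions, n_null=2_000, seed=4)
        pvals = null.pvalues(fresh.scores)
        # heavy score ties make the p-values conservative (discrete, below
        # the diagonal); super-uniformity is the one-sided anti-conservative
        # KS check
        ks = stats.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01

    def test_small_n_null_rejected(self):
        pwm = build_pwm(["ACGT"])
        with pytest.raises(ValueError):
            null_scores(pwm, [("r", "ACGTACGT")], n_null=10, seed=0)


class TestRefine:
    @staticmethod
    def _setup(seed, tfs=10):
        code = PlantedCode.simple({"KA": "TG"})
        _, class_map = generate_family(1, tfs, code, seed=seed)
        regions, truth = generate_regions(class_map, code, site_rate=0.8,
                                          region_len=150, seed=seed + 1)
        strict = [(r.region_id, r.strict_seq) for r in regions]
        extended = [(r.region_id, r.extended_seq) for r in regions]
        seeds = gibbs_search(strict, GibbsConfig(seed=seed + 2))
        return regions, truth, seeds, extended

    @pytest.fixture
    def planted_setup(self):
        return self._setup(41)

    def test_planted_recovery(self):
        # 20-regulator class, 80% of regions carrying a planted site: the
        # refined, Z-filtered set must track the planted count and location
        n_planted = n_found = n_matched = 0
        for seed in (41, 61, 81, 101, 121):
            regions, truth, seeds, extended = self._setup(seed, tfs=20)
            res = refine(seeds, extended, n_null=20_000, seed=seed + 3)
            final = zscore_filter(res.sites, z_min=4.0)
            offsets = {r.region_id: r.strict_offset for r in regions}
            planted = {
                (t.region_id, t.start + offsets[t.region_id])
                for t in truth.itertuples()
            }
            n_planted += len(planted)
            n_found += len(final)
            n_matched += sum(
                any(rid == s.region_id and abs(s.start - st) <= 1
                    for rid, st in planted)
                for s in final.itertuples()
            )
        assert abs(n_found - n_planted) <= 0.1 * n_planted
        assert n_matched >= 0.9 * n_found  # seed-aggregated precision

    def test_alpha_one_keeps_all_candidates(self, planted_setup):
        _, _, seeds, extended = planted_setup
        res = refine(seeds, extended, n_null=20_000, alpha=1.0, seed=45)
        assert res.n_iterations <= 50
        assert len(res.sites) >= len(seeds)

    def test_deterministic(self, planted_setup):
        _, _, seeds, extended = planted_setup
        a = refine(seeds, extended, n_null=5000, seed=46)
        b = refine(seeds, extended, n_null=5000, seed=46)
        assert a.sites.equals(b.sites)
        assert a.trace == b.trace

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError):
            refine(make_site_table(), [("r", "ACGT" * 10)])


class TestFilters:
    def test_zscore_filter_oracle(self, rng):
        rows = [
            {"tf_id": "t", "region_id": "r", "start": i * 20, "end": i * 20 + 14,
             "strand": "+", "sequence": "TGTGAACGTTCACA", "score": 1.0,
             "zscore": float(z), "confidence": 0.5}
            for i, z in enumerate(rng.normal(4, 2, size=30))
        ]
        df = make_site_table(rows)
        kept = zscore_filter(df, z_min=4.0)
        assert set(kept["zscore"]) == {z for z in df["zscore"] if z >= 4.0}
        assert len(zscore_filter(df, z_min=-np.inf)) == len(df)
        assert len(zscore_filter(df, z_min=99.0)) == 0

    def test_overlap_suppression_keeps_best(self):
        rows = [
            {"tf_id": "t", "region_id": "r", "start": s, "end": s + 14,
             "strand": "+", "sequence": "TGTGAACGTTCACA", "score": sc,
             "zscore": 0.0, "confidence": 0.5}
            for s, sc in [(10, 5.0), (12, 8.0), (40, 3.0)]
        ]
        kept = suppress_overlaps(make_site_table(rows))
        assert sorted(kept["start"]) == [12, 40]
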