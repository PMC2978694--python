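import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lacicode.degeneracy import quartet_of
from lacicode.synthetic import (
    CodeEntry,
    DegeneracySpec,
    PlantedCode,
    generate_degeneracy_bs_sets,
    generate_family,
    generate_regions,
    shuffle_region,
)


class TestGenerateFamily:
    def test_specificity_columns_forced(self, small_code):
        records, class_map = generate_family(1, 3, small_code, seed=7)
        assert len(records) == 3
        for rec in records:
            assert rec.aligned_seq[14:20] == "KATVSR"
            assert rec.aligned_seq[50] == "A" and rec.aligned_seq[53] == "L"

    def test_row_and_column_counts(self, small_code):
        records, _ = generate_family(2, 5, small_code, seed=1)
        assert len(records) == 10
        assert all(len(r.aligned_seq) == 71 for r in records)

    def test_deterministic(self, small_code):
        a, _ = generate_family(2, 4, small_code, seed=9)
        b, _ = generate_family(2, 4, small_code, seed=9)
        assert [r.aligned_seq for r in a] == [r.aligned_seq for r in b]

    def test_code_must_cover_classes(self, small_code):
        with pytest.raises(ValueError):
            generate_family(3, 2, small_code, seed=0)


class TestGenerateRegions:
    def test_zero_site_rate(self, small_code):
        _, class_map = generate_family(2, 4, small_code, seed=3)
        regions, truth = generate_regions(class_map, small_code, site_rate=0.0,
                                          region_len=100, seed=5)
        assert len(truth) == 0
        assert all(len(r.strict_seq) == 100 for r in regions)
        assert all(len(r.extended_seq) == 250 for r in regions)

    def test_nondegenerate_class_plants_one_palindrome(self):
        code = PlantedCode.simple({"KA": "TG"})
        _, class_map = generate_family(1, 100, code, seed=2)
        _, truth = generate_regions(class_map, code, site_rate=1.0,
                                    region_len=60, seed=8)
        quartets = {quartet_of(s).pair for s in truth.site_seq}
        assert quartets == {("TG", "TG")}

    def test_truth_matches_region_slice(self, small_code):
        _, class_map = generate_family(2, 10, small_code, seed=4)
        regions, truth = generate_regions(class_map, small_code, site_rate=0.9,
                                          region_len=150, seed=6)
        by_id = {r.region_id: r for r in regions}
        for t in truth.itertuples():
            r = by_id[t.region_id]
            assert r.strict_seq[t.start:t.start + 14] == t.site_seq
            ext = r.strict_offset + t.start
            assert r.extended_seq[ext:ext + 14] == t.site_seq

    def test_asym_dominant_fraction_binomial(self):
        # dominant-palindrome fraction must sit within 3 SE of dominant_prob
        p = 0.8
        n = 10_000
        code = PlantedCode(
            entries=[CodeEntry("KA", "TG")],
            degeneracy={"KA": DegeneracySpec("asym_intrinsic", dominant="TG",
                                             minor="TA", dominant_prob=p)},
        )
        _, class_map = generate_family(1, n, code, seed=13)
        _, truth = generate_regions(class_map, code, site_rate=1.0,
                                    region_len=50, seed=17)
        frac = np.mean([quartet_of(s).pair == ("TG", "TG") for s in truth.site_seq])
        se = np.sqrt(p * (1 - p) / len(truth))
        assert abs(frac - p) < 3 * se

    def test_site_longer_than_region_rejected(self, small_code):
        _, class_map = generate_family(1, 2, small_code, seed=1)
        with pytest.raises(ValueError):
            generate_regions(class_map, small_code, region_len=10, seed=0)

    def test_quartet_frequencies_match_code_weights(self):
        # chi-square goodness of fit of planted quartets vs the code's
        # half-site pairing law (symmetric intrinsic: 1/4, 1/4, 1/2)
        code = PlantedCode(
            entries=[CodeEntry("KA", "TG", 0.5), CodeEntry("KA", "CA", 0.5)],
            degeneracy={"KA": DegeneracySpec("sym_intrinsic")},
        )
        _, class_map = generate_family(1, 10_000, code, seed=19)
        _, truth = generate_regions(class_map, code, site_rate=1.0,
                                    region_len=50, seed=23)
        obs = {("TG", "TG"): 0, ("CA", "CA"): 0, ("CA", "TG"): 0}
        for s in truth.site_seq:
            obs[quartet_of(s).pair] += 1
        n = sum(obs.values())
        expected = [n * 0.25, n * 0.25, n * 0.5]
        chi2 = stats.chisquare(
            [obs[("TG", "TG")], obs[("CA", "CA")], obs[("CA", "TG")]], expected
        )
        assert chi2.pvalue > 0.01


class TestDegeneracyScenarios:
    def test_exclusive_has_no_mixtures(self):
        sites = generate_degeneracy_bs_sets("exclusive", 100, ("TG", "CA"), seed=3)
        quartets = [quartet_of(s) for s in sites]
        assert all(q.palindromic for q in quartets)
        assert {q.pair for q in quartets} == {("TG", "TG"), ("CA", "CA")}

    def test_both_high_affinity_mixture_fraction(self):
        # independent equiprobable half sites: the two ordered mixtures
        # jointly carry probability 1/2
        sites = generate_degeneracy_bs_sets(
            "both_high_affinity", 10_000, ("TG", "CA"), seed=5
        )
        mix = np.mean([not quartet_of(s).palindromic for s in sites])
        se = np.sqrt(0.25 / len(sites))
        assert abs(mix - 0.5) < 4 * se

    def test_preferential_limit_is_exclusive(self):
        sites = generate_degeneracy_bs_sets(
            "preferential", 50, ("TG", "CA"), dominant_prob=1.0, seed=7
        )
        quartets = [quartet_of(s) for s in sites]
        assert all(q.palindromic for q in quartets)
        assert not any(q.pair == ("CA", "TG") for q in quartets)

    def test_identical_semiseqs_rejected(self):
        with pytest.raises(ValueError):
            generate_degeneracy_bs_sets("exclusive", 10, ("TG", "TG"), seed=1)


class TestShuffle:
    def test_single_letter(self):
        assert shuffle_region("AAAA", seed=1) == "AAAA"

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200),
           st.integers(0, 2**31 - 1))
    def test_permutation_and_determinism(self, seq, seed):
        out = shuffle_region(seq, seed)
        assert sorted(out) == sorted(seq)
        assert out == shuffle_region(seq, seed)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shuffle_region("", seed=0)


class TestPlantedCode:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PlantedCode(entries=[CodeEntry("KA", "TG", 0.5)])

    def test_dominant_prob_bounds(self):
        with pytest.raises(ValueError):
            DegeneracySpec("asym_intrinsic", dominant="TG", minor="TA",
                           dominant_prob=0.4)
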