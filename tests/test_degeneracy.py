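import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from lacicode._seq import revcomp
from lacicode.degeneracy import (
    COMBINATIONS,
    DINUCLEOTIDES,
    CombinationMatrixF,
    build_F,
    classify,
    classify_sites,
    quartet_of,
    scenario_label,
    significant_combos,
)
from lacicode.synthetic import generate_degeneracy_bs_sets, make_site


def _site(left, right):
    rng = np.random.default_rng(0)
    return make_site(rng, left, right, identity=1.0)


class TestQuartet:
    def test_palindrome(self):
        q = quartet_of(_site("TG", "TG"))
        assert q.pair == ("TG", "TG") and q.palindromic

    def test_mixture_unordered(self):
        q = quartet_of(_site("TG", "CA"))
        assert q.pair == ("CA", "TG") and not q.palindromic

    def test_reverse_complement_invariance(self):
        for left, right in [("TG", "CA"), ("AA", "GT"), ("CC", "CC")]:
            site = _site(left, right)
            assert quartet_of(site).pair == quartet_of(revcomp(site)).pair

    def test_central_insertion_removed(self):
        site = _site("TG", "TG")
        with_bis = site[:7] + "A" + site[7:]  # 15-bp NT-2bis variant
        assert quartet_of(with_bis).pair == ("TG", "TG")

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            quartet_of("ACGTACGTACGT")


class TestBuildF:
    def test_cell_space_is_136(self):
        F = build_F([_site("TG", "TG")])
        assert len(F.counts) == 136
        assert len(COMBINATIONS) == len(DINUCLEOTIDES) + (16 * 15) // 2

    def test_identical_palindromes_one_cell(self):
        F = build_F([_site("TG", "TG")] * 3)
        assert F[("TG", "TG")] == 3
        assert F.total == 3

    def test_exhaustive_enumeration_oracle(self, rng):
        # independent oracle: count quartets by direct string arithmetic
        sites = [
            _site("".join(rng.choice(list("ACGT"), 2)),
                  "".join(rng.choice(list("ACGT"), 2)))
            for _ in range(5000)
        ]
        F = build_F(sites)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        oracle = Counter()
        for s in sites:
            left = s[2] + s[3]
            right = comp[s[11]] + comp[s[10]]
            oracle[tuple(sorted((left, right)))] += 1
        for cell in COMBINATIONS:
            assert F.counts[cell] == oracle.get(cell, 0)

    def test_strand_invariance(self, rng):
        sites = [
            _site("".join(rng.choice(list("ACGT"), 2)),
                  "".join(rng.choice(list("ACGT"), 2)))
            for _ in range(200)
        ]
        assert build_F(sites).counts == build_F([revcomp(s) for s in sites]).counts


class TestSignificantCombos:
    def test_concentrated_cell_significant(self):
        F = build_F([_site("TG", "TG")] * 100)
        S = significant_combos(F)
        assert ("TG", "TG") in S
        assert len(S.cells) == 1

    def test_counts_at_expectation_not_significant(self):
        # one site in each palindromic cell and uniform mixtures: close to
        # the background law, nothing should stand out
        sites = []
        for a, b in COMBINATIONS:
            sites.append(_site(a, b))
        S = significant_combos(build_F(sites))
        assert len(S.cells) == 0

    def test_single_site_is_low_power(self):
        S = significant_combos(build_F([_site("TG", "TG")]))
        assert len(S.cells) == 0 and S.low_power

    def test_bad_background_rejected(self):
        F = build_F([_site("TG", "TG")])
        with pytest.raises(ValueError):
            significant_combos(F, {d: 1.0 for d in DINUCLEOTIDES})


class TestClassify:
    @pytest.mark.parametrize("scenario,expected", [
        ("both_high_affinity", "both_high_affinity"),
        ("preferential", "preferential"),
        ("exclusive", "exclusive"),
    ])
    def test_scenario_recovery(self, scenario, expected):
        correct = 0
        for rep in range(25):
            sites = generate_degeneracy_bs_sets(
                scenario, 40, ("TG", "CA"), seed=7000 + rep
            )
            _, _, rels = classify_sites(sites)
            correct += scenario_label(rels) == expected
        assert correct >= 22

    def test_preferential_dominant_is_correct(self):
        sites = generate_degeneracy_bs_sets(
            "preferential", 60, ("TG", "CA"), dominant_prob=0.85, seed=99
        )
        _, _, rels = classify_sites(sites)
        asym = [r for r in rels if r.kind == "asym_intrinsic"]
        assert asym and all(r.semiseq_b == "TG" for r in asym)

    def test_never_both_extrinsic_and_intrinsic_for_one_pair(self):
        for rep in range(30):
            for scenario in ("both_high_affinity", "preferential", "exclusive"):
                sites = generate_degeneracy_bs_sets(
                    scenario, 40, ("TG", "CA"), seed=300 + rep
                )
                _, _, rels = classify_sites(sites)
                by_pair = {}
                for r in rels:
                    key = tuple(sorted((r.semiseq_a, r.semiseq_b)))
                    by_pair.setdefault(key, set()).add(
                        "extrinsic" if r.kind == "extrinsic" else "intrinsic"
                    )
                assert all(len(kinds) == 1 for kinds in by_pair.values())

    def test_power_monotonic_for_effect_scenarios(self):
        rates = {}
        for scenario in ("preferential", "exclusive"):
            rates[scenario] = []
            for n in (10, 40, 160):
                ok = sum(
                    scenario_label(classify_sites(
                        generate_degeneracy_bs_sets(
                            scenario, n, ("TG", "CA"), seed=5000 + 13 * rep + n
                        )
                    )[2]) == scenario
                    for rep in range(40)
                )
                rates[scenario].append(ok / 40)
        for scenario, r in rates.items():
            assert r[0] <= r[1] + 1e-9 and r[1] <= r[2] + 1e-9, (scenario, r)

    def test_relation_rendering(self):
        sites = generate_degeneracy_bs_sets("exclusive", 60, ("TG", "CA"), seed=5)
        _, _, rels = classify_sites(sites)
        assert any(r.render() == "CA>-<TG" for r in rels)
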