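"""Planted-truth benchmarks of the whole pipeline.

These routines generate synthetic studies at the package's standard
conditions, run the analysis, and score it against the planted ground truth.
They back both the acceptance checks and the reproducibility script.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import ALPHABET
from .degeneracy import build_F, classify_sites, scenario_label
from .mi import mi_matrix
from .pipeline import DEFAULT_CODE_MAP, PipelineConfig, run_synthetic
from .pwmrefine import build_pwm, null_scores, scan
from .synthetic import (
    PlantedCode,
    generate_degeneracy_bs_sets,
    generate_family,
    generate_regions,
)

PLANTED_AA_COLUMNS = {14, 15}  # alignment columns 15/16, 0-based
PLANTED_NT_COLUMNS = {2, 3, 10, 11}  # NT-5/NT-4 of both half sites


@dataclass
class PlantedCodeResult:
    n_planted: int = 0
    n_found: int = 0
    n_matched: int = 0  # found sites within +/-1 bp of a planted start
    n_recovered: int = 0  # planted sites matched by a found site
    n_seeds: int = 0
    n_exact_codes: int = 0
    per_seed: list[dict] = field(default_factory=list)

    @property
    def recovery(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else 0.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_found if self.n_found else 0.0

    @property
    def code_exact_fraction(self) -> float:
        return self.n_exact_codes / self.n_seeds if self.n_seeds else 0.0


def planted_code_benchmark(seeds, **config_overrides) -> PlantedCodeResult:
    """Full footprint+refine pipeline vs planted truth, seed-swept.

    Standard conditions: 6 recognition classes x 8 TFs, site rate 0.8,
    150-bp strict regions, uniform background.
    """
    out = PlantedCodeResult()
    for seed in seeds:
        cfg = PipelineConfig(seed=int(seed), **config_overrides)
        res = run_synthetic(cfg)
        offsets = {r.tf_id: r.strict_offset for r in res.regions}
        planted = [
            (t.region_id, t.start + offsets[t.tf_id])
            for t in res.truth.itertuples()
        ]
        found = [(s.region_id, s.start) for s in res.refined_sites.itertuples()]
        matched = sum(
            any(rid == frid and abs(fst - st) <= 1 for frid, fst in found)
            for rid, st in planted
        )
        precision_hits = sum(
            any(rid == frid and abs(fst - st) <= 1 for rid, st in planted)
            for frid, fst in found
        )
        recovered_code = {
            row.aa_pair: sorted(a.split(":")[0]
                                for a in row.associations.split(",") if a)
            for row in res.code_table.itertuples()
        }
        exact = recovered_code == {k: [v] for k, v in cfg.code_map.items()}
        out.n_planted += len(planted)
        out.n_found += len(found)
        out.n_matched += precision_hits
        out.n_recovered += matched
        out.n_seeds += 1
        out.n_exact_codes += exact
        out.per_seed.append(
            {"seed": int(seed), "planted": len(planted), "found": len(found),
             "recovered": matched, "exact_code": bool(exact)}
        )
    return out


def scenario_benchmark(n_sites: int, n_reps: int, seed: int) -> dict[str, float]:
    """Fraction of replicates in which each degeneracy scenario is labelled
    correctly from its site set."""
    rng = np.random.default_rng(seed)
    rates = {}
    for scenario in ("both_high_affinity", "preferential", "exclusive"):
        correct = 0
        for _ in range(n_reps):
            sites = generate_degeneracy_bs_sets(
                scenario, n_sites, ("TG", "CA"),
                seed=int(rng.integers(2**31 - 1)),
            )
            _, _, rels = classify_sites(sites)
            correct += scenario_label(rels) == scenario
        rates[scenario] = correct / n_reps
    return rates


def mi_benchmark(n_seeds: int, seed: int, tfs_per_class: int = 60) -> float:
    """Fraction of seeds in which the planted (AA-15, AA-16) <-> (NT-5, NT-4)
    covariation is the top-ranked mutual-information cell."""
    rng = np.random.default_rng(seed)
    code = PlantedCode.simple(DEFAULT_CODE_MAP)
    hits = 0
    for _ in range(n_seeds):
        records, class_map = generate_family(
            6, tfs_per_class, code, seed=int(rng.integers(2**31 - 1))
        )
        _, truth = generate_regions(
            class_map, code, site_rate=1.0, region_len=60,
            seed=int(rng.integers(2**31 - 1)),
        )
        dom = {r.id: r.aligned_seq for r in records}
        bs = {f"s{i}": t.site_seq for i, t in enumerate(truth.itertuples())}
        pairing = {f"s{i}": t.tf_id for i, t in enumerate(truth.itertuples())}
        top_aa, top_nt, _ = mi_matrix(dom, bs, pairing).ranked_cells()[0]
        hits += top_aa in PLANTED_AA_COLUMNS and top_nt in PLANTED_NT_COLUMNS
    return hits / n_seeds


def scan_vs_brute_force(seed: int, n_regions: int = 5) -> float:
    """Max absolute difference between the vectorized scanner and naive
    per-window log-odds summation."""
    rng = np.random.default_rng(seed)
    sites = ["".join(rng.choice(list(ALPHABET), size=14)) for _ in range(6)]
    pwm = build_pwm(sites)
    freqs = pwm.frequencies
    worst = 0.0
    for i in range(n_regions):
        region = "".join(rng.choice(list(ALPHABET), size=60))
        hits = scan(pwm, (f"r{i}", region), min_score=-np.inf)
        for row in hits[hits.strand == "+"].itertuples():
            brute = sum(
                np.log2(freqs[j, ALPHABET.index(b)] / 0.25)
                for j, b in enumerate(row.sequence)
            )
            worst = max(worst, abs(row.score - brute))
    return worst


def f_matrix_vs_enumeration(seed: int, n_sites: int = 5000) -> bool:
    """Compare build_F against direct per-site string enumeration."""
    rng = np.random.default_rng(seed)
    from .synthetic import make_site

    sites = [
        make_site(rng, "".join(rng.choice(list(ALPHABET), 2)),
                  "".join(rng.choice(list(ALPHABET), 2)))
        for _ in range(n_sites)
    ]
    F = build_F(sites)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    oracle: dict[tuple[str, str], int] = {}
    for s in sites:
        left = s[2] + s[3]
        right = comp[s[11]] + comp[s[10]]
        key = tuple(sorted((left, right)))
        oracle[key] = oracle.get(key, 0) + 1
    return all(F.counts[c] == oracle.get(c, 0) for c in F.counts)


def null_pvalue_uniformity(seed: int) -> float:
    """One-sided KS p-value that null-on-null empirical p-values are not
    anti-conservative (super-uniformity check)."""
    rng = np.random.default_rng(seed)
    sites = ["TGTGAACGTTCACA", "TGTGATCGATCACA", "TGTGACCGGTCACA"]
    pwm = build_pwm(sites)
    regions = [
        (f"r{i}", "".join(rng.choice(list(ALPHABET), size=200)))
        for i in range(5)
    ]
    null = null_scores(pwm, regions, n_null=20_000,
                       seed=int(rng.integers(2**31 - 1)))
    fresh = null_scores(pwm, regions, n_null=2_000,
                        seed=int(rng.integers(2**31 - 1)))
    pvals = null.pvalues(fresh.scores)
    return float(stats.kstest(pvals, "uniform", alternative="greater").pvalue)


def combination_space_size() -> int:
    """Number of cells of the half-site combination matrix, by construction
    of an actual F matrix."""
    from .synthetic import make_site

    rng = np.random.default_rng(0)
    return len(build_F([make_site(rng, "TG", "TG")]).counts)
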