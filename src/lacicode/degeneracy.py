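"""Intrinsic/extrinsic degeneracy classification of a class's binding sites.

Each 14-bp site is reduced to its specificity quartet: the (NT-5, NT-4)
dinucleotide of the left half site read on the sense strand and that of the
right half site read on the complementary strand, kept as an unordered pair.
Counts over the 136 possible unordered dinucleotide combinations (16
palindromic + 120 mixed) form the triangular matrix F; cells significantly
over-represented against the genomic background form the matrix S.

Classification logic: a significant *absence* of the mixture of two
significant palindromes (against the independent half-site pairing
expectation) signals an extrinsic degeneracy -- two sub-populations of TFs
each locked to its own palindrome. Extrinsic relations partition the
half-site types into blocks; within a block, a palindrome significantly
exceeding the block-uniform expectation marks an asymmetric intrinsic
degeneracy with that dominant palindrome, otherwise the block is a
symmetric intrinsic degeneracy.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import ALPHABET, complement

DINUCLEOTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)
COMBINATIONS = tuple(
    tuple(sorted(c))
    for c in itertools.combinations_with_replacement(DINUCLEOTIDES, 2)
)
N_COMBINATIONS = len(COMBINATIONS)  # 136 = 16 palindromic + 120 mixed

SITE_WIDTH = 14
_LEFT = (2, 3)  # NT-5, NT-4 of the left half site
_RIGHT = (11, 10)  # NT-5, NT-4 of the right half site (sense indices)


@dataclass(frozen=True)
class HalfSiteQuartet:
    d_left: str
    d_right: str

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.d_left, self.d_right)))

    @property
    def palindromic(self) -> bool:
        return self.d_left == self.d_right


@dataclass
class CombinationMatrixF:
    counts: dict[tuple[str, str], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, pair) -> int:
        return self.counts[tuple(sorted(pair))]


@dataclass
class SignificanceMatrixS:
    cells: dict[tuple[str, str], float]  # significant cell -> p-value
    pvalues: dict[tuple[str, str], float]  # all tested cells
    low_power: bool = False

    def __contains__(self, pair) -> bool:
        return tuple(sorted(pair)) in self.cells

    @property
    def palindromes(self) -> list[str]:
        return sorted(a for a, b in self.cells if a == b)

    @property
    def half_types(self) -> list[str]:
        return sorted({h for cell in self.cells for h in cell})


@dataclass(frozen=True)
class DegeneracyRelation:
    kind: Literal["sym_intrinsic", "asym_intrinsic", "extrinsic"]
    semiseq_a: str  # asym: the minor semisequence
    semiseq_b: str  # asym: the dominant semisequence
    pvalue: float = float("nan")

    def render(self) -> str:
        arrow = {
            "asym_intrinsic": "->",  # minor -> dominant
            "sym_intrinsic": "<->",
            "extrinsic": ">-<",
        }[self.kind]
        return f"{self.semiseq_a}{arrow}{self.semiseq_b}"


def quartet_of(site: str) -> HalfSiteQuartet:
    """Specificity quartet of a site; 15-bp sites carrying the central
    inserted base (NT-2bis) are normalized by deleting it first."""
    site = site.upper()
    if len(site) == SITE_WIDTH + 1:
        site = site[:7] + site[8:]
    if len(site) != SITE_WIDTH:
        raise ValueError(f"site must be 14 bp after normalization: {site!r}")
    d_left = site[_LEFT[0]] + site[_LEFT[1]]
    d_right = complement(site[_RIGHT[0]]) + complement(site[_RIGHT[1]])
    return HalfSiteQuartet(d_left, d_right)


def build_F(bs_set: Sequence[str]) -> CombinationMatrixF:
    """Triangular count matrix over the 136 unordered dinucleotide pairs."""
    if not bs_set:
        raise ValueError("need at least one site")
    counts = {cell: 0 for cell in COMBINATIONS}
    for site in bs_set:
        counts[quartet_of(site).pair] += 1
    return CombinationMatrixF(counts)


def significant_combos(
    F: CombinationMatrixF,
    background_dinuc_probs: dict[str, float] | None = None,
    alpha_fdr: float = 0.05,
) -> SignificanceMatrixS:
    """Cells of F over-represented against the genomic background.

    Expected cell probability under the background is q_a^2 for a palindromic
    cell and 2 q_a q_b for a mixed one; per-cell binomial upper-tail p-values
    are controlled with Benjamini-Hochberg at ``alpha_fdr``.
    """
    if background_dinuc_probs is None:
        background_dinuc_probs = {d: 1.0 / 16.0 for d in DINUCLEOTIDES}
    q = background_dinuc_probs
    total_q = sum(q.values())
    if abs(total_q - 1.0) > 1e-9:
        raise ValueError("background dinucleotide probabilities must sum to 1")
    n = F.total
    # the BH family is the full 136-cell combination space (empty cells get
    # p = 1), so a lone site in an otherwise empty cell cannot reach
    # significance by escaping the multiplicity correction
    pvals = {}
    for a, b in COMBINATIONS:
        p = q[a] ** 2 if a == b else 2 * q[a] * q[b]
        pvals[(a, b)] = float(stats.binom.sf(F.counts[(a, b)] - 1, n, p))
    keys = list(pvals)
    reject, _, _, _ = multipletests(
        [pvals[k] for k in keys], alpha=alpha_fdr, method="fdr_bh"
    )
    sig = {k: pvals[k] for k, r in zip(keys, reject) if r}
    return SignificanceMatrixS(sig, pvals, low_power=not sig)


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def classify(
    S: SignificanceMatrixS,
    F: CombinationMatrixF,
    alpha_fdr: float = 0.05,
) -> list[DegeneracyRelation]:
    """Resolve the degeneracy relations of one recognition class."""
    relations: list[DegeneracyRelation] = []
    palins = S.palindromes
    n = F.total

    # 1. extrinsic: mixtures of significant palindrome pairs that are
    #    significantly under-represented vs independent half-site pairing
    extrinsic_pairs: set[tuple[str, str]] = set()
    if len(palins) >= 2:
        pal_total = sum(F[(c, c)] for c in palins)
        r = {c: F[(c, c)] / pal_total for c in palins}
        tests = []
        for a, b in itertools.combinations(palins, 2):
            p_mix = 2 * r[a] * r[b]
            obs = F[(a, b)]
            tests.append(((a, b), float(stats.binom.cdf(obs, n, p_mix))))
        reject, _, _, _ = multipletests(
            [p for _, p in tests], alpha=alpha_fdr, method="fdr_bh"
        )
        for (pair, p), rej in zip(tests, reject):
            if rej:
                extrinsic_pairs.add(pair)
                relations.append(
                    DegeneracyRelation("extrinsic", pair[0], pair[1], p)
                )

    # 2. blocks: half types joined by significant mixtures and by
    #    non-extrinsic significant palindrome pairs
    half_types = S.half_types
    if not half_types:
        return relations
    dsu = _DSU(half_types)
    for a, b in S.cells:
        if a != b and tuple(sorted((a, b))) not in extrinsic_pairs:
            dsu.union(a, b)
    for a, b in itertools.combinations(palins, 2):
        if (a, b) not in extrinsic_pairs:
            dsu.union(a, b)
    blocks: dict[str, list[str]] = {}
    for h in half_types:
        blocks.setdefault(dsu.find(h), []).append(h)

    # 3. intrinsic resolution within each block
    for members in blocks.values():
        members = sorted(members)
        k = len(members)
        if k < 2:
            continue
        mset = set(members)
        n_block = sum(
            F.counts[cell] for cell in COMBINATIONS
            if cell[0] in mset and cell[1] in mset
        )
        if n_block == 0:
            continue
        tests = [
            (c, float(stats.binom.sf(F[(c, c)] - 1, n_block, 1.0 / k**2)))
            for c in members
        ]
        reject, _, _, _ = multipletests(
            [p for _, p in tests], alpha=alpha_fdr, method="fdr_bh"
        )
        dominant_hits = [
            (c, p) for (c, p), rej in zip(tests, reject) if rej
        ]
        if dominant_hits:
            dominant, pval = max(
                dominant_hits, key=lambda cp: (F[(cp[0], cp[0])], cp[0])
            )
            for m in members:
                if m == dominant:
                    continue
                if tuple(sorted((m, dominant))) in extrinsic_pairs:
                    continue
                relations.append(
                    DegeneracyRelation("asym_intrinsic", m, dominant, pval)
                )
        else:
            for a, b in itertools.combinations(members, 2):
                if (a, b) in extrinsic_pairs:
                    continue
                relations.append(DegeneracyRelation("sym_intrinsic", a, b))
    return relations


def classify_sites(
    sites: Sequence[str],
    background_dinuc_probs: dict[str, float] | None = None,
    alpha_fdr: float = 0.05,
) -> tuple[CombinationMatrixF, SignificanceMatrixS, list[DegeneracyRelation]]:
    """Convenience wrapper: F matrix, S matrix and relations for a site set."""
    F = build_F(sites)
    S = significant_combos(F, background_dinuc_probs, alpha_fdr)
    return F, S, classify(S, F, alpha_fdr)


def scenario_label(relations: Sequence[DegeneracyRelation]) -> str:
    """Map a relation set onto the canonical two-half-site scenarios."""
    kinds = {r.kind for r in relations}
    if "extrinsic" in kinds:
        return "exclusive"
    if "asym_intrinsic" in kinds:
        return "preferential"
    if "sym_intrinsic" in kinds:
        return "both_high_affinity"
    return "none"
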