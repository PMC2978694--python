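"""Second binding-site search: iterative PWM refinement with an empirical null.

From the seed sites of the first (footprinting) scan, a pseudocounted PWM is
built and slid over the extended intergenic regions; every window scoring at
least the minimum seed-site score becomes a candidate. The refinement loop
then iterates: (i) draw a null score set by sliding the current PWM over
mononucleotide-shuffled regions, (ii) keep candidates whose empirical
p-value beats alpha, (iii) rebuild the PWM from the kept sites, and
(iv) rescore all candidates -- until the kept set stops changing. Multiple
sites per region and sites inside the coding zone are allowed at this stage.
Final sites carry Z-scores against the final null.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import decode, encode, revcomp_matrix
from .seqio import make_site_table
from .synthetic import shuffle_region

logger = logging.getLogger(__name__)


@dataclass
class PWM:
    counts: np.ndarray  # (width, 4) raw site counts
    pseudocount: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    palindromic: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (width x 4)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.palindromic:
            self.counts = 0.5 * (self.counts + revcomp_matrix(self.counts))

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> float:
        return float(self.counts[0].sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Constant-pseudocount frequencies: (count + B/4) / (N + B)."""
        b = self.pseudocount
        return (self.counts + b / 4.0) / (self.n_sites + b)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(frequency / background), the per-cell scoring matrix."""
        bg = np.asarray(self.background, dtype=float)
        return np.log2(self.frequencies) - np.log2(bg)[None, :]

    def score(self, site: str) -> float:
        codes = encode(site.upper())
        if len(codes) != self.width or (codes < 0).any():
            raise ValueError(f"site {site!r} incompatible with PWM width")
        return float(self.log_odds[np.arange(self.width), codes].sum())


@dataclass
class NullDistribution:
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.sort(np.asarray(self.scores, dtype=float))

    @property
    def size(self) -> int:
        return len(self.scores)

    @property
    def mean(self) -> float:
        return float(self.scores.mean())

    @property
    def sd(self) -> float:
        return float(self.scores.std(ddof=1))

    def pvalues(self, scores) -> np.ndarray:
        """Add-one empirical upper-tail p-values: (1 + #null >= s)/(1 + N)."""
        s = np.atleast_1d(np.asarray(scores, dtype=float))
        n_ge = self.size - np.searchsorted(self.scores, s, side="left")
        return (1.0 + n_ge) / (1.0 + self.size)

    def zscores(self, scores) -> np.ndarray:
        s = np.atleast_1d(np.asarray(scores, dtype=float))
        return (s - self.mean) / self.sd


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = 1.0,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    palindromic: bool = False,
) -> PWM:
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("site width mismatch")
    counts = np.zeros((w, 4))
    cols = np.arange(w)
    for s in sites:
        counts[cols, encode(s.upper())] += 1
    return PWM(counts, pseudocount, background, palindromic)


def _window_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Log-odds score of every window of an encoded region (sense strand)."""
    w = pwm.width
    if len(codes) < w:
        return np.empty(0)
    W = np.lib.stride_tricks.sliding_window_view(codes, w)
    return pwm.log_odds[np.arange(w)[None, :], W].sum(axis=1)


def scan(
    pwm: PWM,
    region: tuple[str, str],
    min_score: float,
    tf_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """All windows of one (region_id, sequence) scoring >= min_score.

    Both strands are scanned; a palindromic PWM scores the two strands
    identically, so reverse-strand duplicates are collapsed to sense.
    """
    rid, seq = region
    codes = encode(seq.upper())
    if len(codes) < pwm.width:
        raise ValueError(f"region {rid} shorter than PWM width")
    sense = _window_scores(pwm, codes)
    if pwm.palindromic:
        best, strands = sense, np.full(len(sense), "+")
    else:
        # one candidate per window: the better-scoring strand (tie -> sense)
        anti = _window_scores(pwm, 3 - codes[::-1])[::-1]
        best = np.maximum(sense, anti)
        strands = np.where(anti > sense, "-", "+")
    tf = (tf_map or {}).get(rid, rid)
    rows = []
    for s in np.flatnonzero(best >= min_score):
        site = seq[s:s + pwm.width]
        strand = strands[s]
        rows.append(
            {"tf_id": tf, "region_id": rid, "start": int(s),
             "end": int(s) + pwm.width, "strand": str(strand),
             "sequence": site if strand == "+" else decode(3 - encode(site)[::-1]),
             "score": float(best[s]), "zscore": float("nan"),
             "confidence": float("nan")}
        )
    return make_site_table(rows)


def null_scores(
    pwm: PWM,
    regions: Sequence[tuple[str, str]],
    n_null: int = 100_000,
    seed: int = 0,
) -> NullDistribution:
    """Empirical null: PWM scores over mononucleotide-shuffled regions.

    Whole regions are shuffled (per-region composition preserved) and every
    window scored; shuffle rounds accumulate until ``n_null`` scores are
    collected.
    """
    if n_null < 1000:
        raise ValueError("n_null must be >= 1000")
    usable = [(rid, s) for rid, s in regions if len(s) >= pwm.width]
    if not usable:
        raise ValueError("no region long enough to scan")
    rng = np.random.default_rng(seed)
    pool: list[np.ndarray] = []
    total = 0
    while total < n_null:
        for rid, seq in usable:
            shuffled = shuffle_region(seq, int(rng.integers(2**31 - 1)))
            sc = _window_scores(pwm, encode(shuffled))
            pool.append(sc)
            total += len(sc)
    scores = np.concatenate(pool)[:n_null]
    return NullDistribution(scores)


def suppress_overlaps(df: pd.DataFrame, min_overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Greedy best-score-first removal of candidates overlapping an already
    kept site in the same region by >= the given fraction of the width."""
    if len(df) == 0:
        return df
    keep_idx = []
    for rid, group in df.groupby("region_id", sort=False):
        g = group.sort_values(["score", "start"], ascending=[False, True])
        taken: list[tuple[int, int]] = []
        for idx, row in g.iterrows():
            w = row.end - row.start
            ok = True
            for s, e in taken:
                overlap = min(e, row.end) - max(s, row.start)
                if overlap >= min_overlap_fraction * w:
                    ok = False
                    break
            if ok:
                taken.append((row.start, row.end))
                keep_idx.append(idx)
    return df.loc[sorted(keep_idx)]


@dataclass
class RefineResult:
    sites: pd.DataFrame
    pwm: PWM
    null: NullDistribution | None
    n_iterations: int
    trace: list[int] = field(default_factory=list)  # kept-set size per iteration


def refine(
    seed_sites: pd.DataFrame,
    extended_regions: Sequence[tuple[str, str]],
    pseudocount: float = 1.0,
    n_null: int = 100_000,
    alpha: float = 1e-3,
    max_iter: int = 50,
    seed: int = 0,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    palindromic: bool = True,
    tf_map: dict[str, str] | None = None,
    min_score: float | None = None,
    site_filter=None,
) -> RefineResult:
    """Iterate null generation / p-value selection / PWM rebuild to a fixed
    point. The candidate pool is fixed by the seed-set minimum score and is
    never re-tightened across iterations.

    ``site_filter`` is an optional user hook, a predicate over site
    sequences applied to the final set (e.g. a spurious-nucleotide filter);
    it does not participate in the iteration.
    """
    if len(seed_sites) == 0:
        raise ValueError("seed_sites must be non-empty")
    pwm = build_pwm(
        list(seed_sites["sequence"]), pseudocount, background, palindromic
    )
    if min_score is None:
        min_score = min(pwm.score(s) for s in seed_sites["sequence"])
    cands = [scan(pwm, reg, min_score, tf_map) for reg in extended_regions]
    candidates = pd.concat([c for c in cands if len(c)], ignore_index=True) \
        if any(len(c) for c in cands) else make_site_table()
    if len(candidates) == 0:
        warnings.warn("no candidates above the seed minimum score")
        return RefineResult(make_site_table(), pwm, None, 0, [])

    rng = np.random.default_rng(seed)
    prev_keys = {
        (r.region_id, r.start) for r in seed_sites.itertuples()
    }
    trace: list[int] = []
    null = None
    kept = candidates
    for it in range(1, max_iter + 1):
        null = null_scores(
            pwm, extended_regions, n_null, int(rng.integers(2**31 - 1))
        )
        pvals = null.pvalues(candidates["score"].to_numpy())
        kept = candidates[pvals < alpha]
        kept = suppress_overlaps(kept)
        trace.append(len(kept))
        if len(kept) == 0:
            warnings.warn("kept-site set became empty; refinement terminated")
            return RefineResult(make_site_table(), pwm, null, it, trace)
        keys = {(r.region_id, r.start) for r in kept.itertuples()}
        pwm = build_pwm(list(kept["sequence"]), pseudocount, background, palindromic)
        candidates = candidates.assign(
            score=[pwm.score(s) for s in candidates["sequence"]]
        )
        if keys == prev_keys:
            break
        prev_keys = keys
    n_iterations = it
    final = kept.copy()
    final["score"] = [pwm.score(s) for s in final["sequence"]]
    final["zscore"] = null.zscores(final["score"].to_numpy())
    if site_filter is not None:
        final = final[[bool(site_filter(s)) for s in final["sequence"]]]
    final = final.reset_index(drop=True)
    return RefineResult(final, pwm, null, n_iterations, trace)


def zscore_filter(sites: pd.DataFrame, z_min: float = 4.0) -> pd.DataFrame:
    """Keep sites whose Z-score is at least ``z_min``."""
    if len(sites) == 0:
        return sites
    return sites[sites["zscore"] >= z_min].reset_index(drop=True)
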