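"""First binding-site scan: a palindromic Gibbs motif sampler.

One recognition class at a time, the sampler searches the pooled strict
intergenic regions of the class for a shared 14-bp palindromic motif. The
occupancy model is zero-or-one site per region with a Bernoulli prior chosen
so that the expected number of sites equals the configured total (by default
the number of regions). The motif model is constrained palindromic: the
count matrix is averaged with its reverse complement before every use, so
the model matrix always equals its own reverse complement.

The per-site confidence is the fraction of post-burn-in Gibbs samples
(pooled across chains) that place the region's site within +/-2 bp of the
reported start; sites below the confidence cutoff (default 40%) are
discarded.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import encode, revcomp_matrix
from .seqio import make_site_table

logger = logging.getLogger(__name__)


@dataclass
class GibbsConfig:
    seed: int
    width: int = 14
    palindromic: bool = True
    one_site_per_region_max: bool = True
    expected_sites: int | None = None  # default: number of regions
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    confidence_cutoff: float = 0.40
    n_chains: int = 4
    iters: int = 1600
    burn_in: int = 400
    pseudocount: float = 1.0
    confidence_window: int = 2
    shift_every: int = 25
    # per-site max-statistic check: a reported site must beat the best
    # window of shuffled copies of its own region (0 disables)
    site_null_shuffles: int = 25
    site_null_alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.confidence_cutoff <= 1):
            raise ValueError("confidence_cutoff must be in (0, 1]")
        if self.palindromic and self.width % 2:
            raise ValueError("palindromic motifs need an even width")
        if self.burn_in >= self.iters:
            raise ValueError("burn_in must be below iters")


@dataclass
class _Chain:
    starts: np.ndarray  # current start per region, -1 = absent
    counts: np.ndarray  # raw base counts of currently assigned sites
    n_assigned: int = 0
    samples: list[np.ndarray] = field(default_factory=list)


def _model_logratio(counts: np.ndarray, n_assigned: int, bg: np.ndarray,
                    pseudocount: float, palindromic: bool) -> np.ndarray:
    c = counts
    if palindromic:
        c = 0.5 * (c + revcomp_matrix(c))
    freq = (c + pseudocount * bg[None, :]) / (n_assigned + pseudocount)
    return np.log(freq) - np.log(bg)[None, :]


def gibbs_search(
    regions: Sequence[tuple[str, str]],
    cfg: GibbsConfig,
    tf_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Run the sampler over (region_id, sequence) pairs; return a site table.

    Regions shorter than the motif width are skipped with a warning. At
    least two usable regions are required.
    """
    w = cfg.width
    usable: list[tuple[str, np.ndarray]] = []
    for rid, seq in regions:
        if len(seq) < w:
            warnings.warn(f"region {rid} shorter than width {w}; skipped")
            continue
        usable.append((rid, encode(seq.upper())))
    n = len(usable)
    if n < 2:
        raise ValueError("need at least 2 regions of usable length")
    seqs = {rid: s for rid, s in usable}
    ids = [rid for rid, _ in usable]
    bg = np.asarray(cfg.background, dtype=float)
    # window index matrices: windows[r][p, j] = base code at position p + j
    windows = {
        rid: np.lib.stride_tricks.sliding_window_view(s, w) for rid, s in seqs.items()
    }
    expected = cfg.expected_sites if cfg.expected_sites is not None else n
    pi = min(expected / n, 0.999)
    log_absent = np.log1p(-pi)
    cols = np.arange(w)

    root = np.random.default_rng(cfg.seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=cfg.n_chains)
    tallies = {rid: {} for rid in ids}  # start -> pooled post-burn-in count
    total_samples = 0

    for cseed in chain_seeds:
        rng = np.random.default_rng(int(cseed))
        counts = np.zeros((w, 4))
        starts = np.full(n, -1, dtype=int)
        for r, rid in enumerate(ids):
            npos = windows[rid].shape[0]
            s = int(rng.integers(npos))
            starts[r] = s
            counts[cols, windows[rid][s]] += 1
        n_assigned = n

        for it in range(cfg.iters):
            for r, rid in enumerate(ids):
                W = windows[rid]
                npos = W.shape[0]
                if starts[r] >= 0:
                    counts[cols, W[starts[r]]] -= 1
                    n_assigned -= 1
                logratio = _model_logratio(
                    counts, n_assigned, bg, cfg.pseudocount, cfg.palindromic
                )
                site_scores = logratio[cols[None, :], W].sum(axis=1)
                full = np.empty(npos + 1)
                full[:npos] = site_scores + np.log(pi / npos)
                full[npos] = log_absent
                full -= full.max()
                p = np.exp(full)
                cum = np.cumsum(p)
                k = int(np.searchsorted(cum, rng.random() * cum[-1]))
                if k == npos:
                    starts[r] = -1
                else:
                    starts[r] = k
                    counts[cols, W[k]] += 1
                    n_assigned += 1
            if cfg.shift_every and (it + 1) % cfg.shift_every == 0:
                starts, counts, n_assigned = _phase_shift(
                    rng, ids, windows, starts, counts, n_assigned, cfg, bg
                )
            if it >= cfg.burn_in:
                total_samples += 1
                for r, rid in enumerate(ids):
                    s = int(starts[r])
                    tallies[rid][s] = tallies[rid].get(s, 0) + 1

    return _report(ids, seqs, tallies, total_samples, tf_map, cfg, bg)


def _phase_shift(rng, ids, windows, starts, counts, n_assigned, cfg, bg):
    """Jointly shift all assigned sites by one offset up to half the motif
    width, sampled in proportion to the joint motif score; escapes the
    shifted-phase local optima palindromic motifs are prone to."""
    w = cfg.width
    cols = np.arange(w)
    half = w // 2
    deltas = [d for d in range(-half, half + 1)]
    log_joint = []
    shifted_valid = []
    for d in deltas:
        new_counts = np.zeros_like(counts)
        ok = True
        for r, rid in enumerate(ids):
            if starts[r] < 0:
                continue
            s = starts[r] + d
            if not (0 <= s < windows[rid].shape[0]):
                ok = False
                break
            new_counts[cols, windows[rid][s]] += 1
        if not ok:
            log_joint.append(-np.inf)
            shifted_valid.append(None)
            continue
        logratio = _model_logratio(
            new_counts, n_assigned, bg, cfg.pseudocount, cfg.palindromic
        )
        log_joint.append(float((logratio * new_counts).sum()))
        shifted_valid.append(new_counts)
    lj = np.array(log_joint)
    lj -= lj.max()
    p = np.exp(lj)
    p /= p.sum()
    pick = rng.choice(len(deltas), p=p)
    d = deltas[pick]
    if d == 0 or shifted_valid[pick] is None:
        return starts, counts, n_assigned
    new_starts = starts.copy()
    new_starts[starts >= 0] += d
    return new_starts, shifted_valid[pick], n_assigned


def _greedy_realign(kept: list[tuple[str, int]], seqs, cfg, bg,
                    max_rounds: int = 20) -> tuple[list[tuple[str, int]], float]:
    """Leave-one-out greedy realignment within half a motif width.

    Returns the realigned (region_id, start) list and the joint model log
    likelihood ratio of the final configuration.
    """
    w = cfg.width
    cols = np.arange(w)
    radius = w // 2
    starts = dict(kept)
    counts = np.zeros((w, 4))
    for rid, s in kept:
        counts[cols, seqs[rid][s:s + w]] += 1
    n = len(kept)
    for _ in range(max_rounds):
        changed = False
        for rid, _ in kept:
            s = starts[rid]
            counts[cols, seqs[rid][s:s + w]] -= 1
            logratio = _model_logratio(
                counts, n - 1, bg, cfg.pseudocount, cfg.palindromic
            )
            npos = len(seqs[rid]) - w + 1
            cand = list(range(max(0, s - radius), min(npos, s + radius + 1)))
            scores = [logratio[cols, seqs[rid][c:c + w]].sum() for c in cand]
            # ties favor the smallest move, then the leftmost start
            best = max(
                zip(scores, [-abs(c - s) for c in cand], [-c for c in cand], cand)
            )[3]
            if best != s:
                starts[rid] = best
                changed = True
            counts[cols, seqs[rid][starts[rid]:starts[rid] + w]] += 1
        if not changed:
            break
    logratio = _model_logratio(
        counts, n, bg, cfg.pseudocount, cfg.palindromic
    )
    return [(rid, starts[rid]) for rid, _ in kept], float((logratio * counts).sum())


def _polish_phases(kept: list[tuple[str, int]], seqs, cfg, bg) -> list[tuple[str, int]]:
    """Phase realignment of the kept sites.

    A palindromic motif admits self-consistent shifted states (a coherent
    +/-1 drift and its strand mirror, the half-site swap at +/-7), and a
    greedy realignment started inside such a state stays in it because the
    blurred model it induces is locally optimal. Restarting the greedy
    realignment from every global shift of the configuration and keeping the
    maximum-likelihood result snaps mixed-phase sets onto the single
    maximum-information phase.
    """
    w = cfg.width
    best_cfg, best_ll = _greedy_realign(kept, seqs, cfg, bg)
    for delta in range(-(w // 2), w // 2 + 1):
        if delta == 0:
            continue
        shifted = []
        for rid, s in kept:
            npos = len(seqs[rid]) - w + 1
            shifted.append((rid, min(max(s + delta, 0), npos - 1)))
        cfg_d, ll_d = _greedy_realign(shifted, seqs, cfg, bg)
        if ll_d > best_ll + 1e-9:
            best_cfg, best_ll = cfg_d, ll_d
    return best_cfg


def _report(ids, seqs, tallies, total_samples, tf_map, cfg, bg) -> pd.DataFrame:
    w = cfg.width
    prelim = []
    for rid in ids:
        tally = {s: c for s, c in tallies[rid].items() if s >= 0}
        if not tally:
            continue
        best = max(tally, key=lambda s: (tally[s], -s))
        win = cfg.confidence_window
        conf = sum(
            c for s, c in tally.items() if abs(s - best) <= win
        ) / total_samples
        if conf < cfg.confidence_cutoff:
            continue
        prelim.append((rid, best, conf))
    if not prelim:
        return make_site_table()
    polished = _polish_phases([(rid, s) for rid, s, _ in prelim], seqs, cfg, bg)
    rows = []
    kept_sites = []
    for (rid, _, conf), (_, best) in zip(prelim, polished):
        seq_codes = seqs[rid][best:best + w]
        kept_sites.append(seq_codes)
        rows.append((rid, best, conf, seq_codes))
    # score the reported sites under the PWM of the kept set
    counts = np.zeros((w, 4))
    cols = np.arange(w)
    for sc in kept_sites:
        counts[cols, sc] += 1
    logratio = _model_logratio(
        counts, len(kept_sites), bg, cfg.pseudocount, cfg.palindromic
    ) / np.log(2)  # bits
    if cfg.site_null_shuffles:
        rows = _site_max_filter(rows, seqs, logratio, cfg)
    out = []
    from ._seq import decode

    for rid, best, conf, sc in rows:
        out.append(
            {
                "tf_id": (tf_map or {}).get(rid, rid),
                "region_id": rid,
                "start": best,
                "end": best + w,
                "strand": "+",
                "sequence": decode(sc),
                "score": float(logratio[cols, sc].sum()),
                "zscore": float("nan"),
                "confidence": conf,
            }
        )
    return make_site_table(out)


def _site_max_filter(rows, seqs, logratio, cfg):
    """Max-statistic significance check of each reported site.

    A motif fitted to the regions it was searched in makes even chance sites
    look strong against ordinary window nulls; the honest per-site null is
    the *best* window score in shuffled (composition-preserving) copies of
    the site's own region. Sites whose score does not beat that max-of-
    windows distribution at ``site_null_alpha`` are discarded.
    """
    w = cfg.width
    cols = np.arange(w)
    k = cfg.site_null_shuffles
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    kept = []
    for rid, best, conf, sc in rows:
        score = logratio[cols, sc].sum()
        region = seqs[rid].copy()
        beaten = 0
        for _ in range(k):
            rng.shuffle(region)
            W = np.lib.stride_tricks.sliding_window_view(region, w)
            if logratio[cols[None, :], W].sum(axis=1).max() >= score:
                beaten += 1
        if (1 + beaten) / (1 + k) <= cfg.site_null_alpha:
            kept.append((rid, best, conf, sc))
    return kept


def site_logo(sites: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column base frequencies and information content (bits).

    IC_j = 2 + sum_b f_bj log2 f_bj with plug-in frequencies.
    """
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("ragged site set")
    counts = np.zeros((w, 4))
    cols = np.arange(w)
    for s in sites:
        counts[cols, encode(s.upper())] += 1
    freq = counts / len(sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return freq, ic
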