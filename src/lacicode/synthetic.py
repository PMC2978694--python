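"""Synthetic families, intergenic regions and planted binding sites.

The generator emulates the statistical structure the analysis assumes for a
helix-turn-helix regulator family with local (auto-)regulation:

* a fixed 71-column domain alignment whose columns 15/16 carry the
  specificity pair, columns 17-20 the invariant recognition-helix sequence
  TVSR, and columns 51/54 the structural hinge residues A/L;
* per-regulator upstream regions in a "strict" (non-coding, <=200 bp) and an
  "extended" (250 bp, including 50 bp of coding sequence) version;
* planted 14-bp palindromic or mixed operators over the conserved backbone
  T G . . A . C | revcomp (conserved NT-6 = G and central CG), whose
  (NT-5, NT-4) half-site dinucleotides follow a planted amino-acid ->
  nucleotide code with configurable degeneracy per recognition class.

Half-site coordinates: position NT-k of the left half site sits at site
index 7-k; the right half site occupies indices 7..13 as the reverse
complement of a half site in the same coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._seq import ALPHABET, revcomp
from .domains import DomainRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

ALIGNMENT_WIDTH = 71
SITE_WIDTH = 14
HALF_WIDTH = 7

# left half-site backbone, NT-7..NT-1; None marks the variable NT-2 slot and
# the (NT-5, NT-4) specificity slots filled from the planted code
_BACKBONE = ("T", "G", None, None, "A", None, "C")
_CONSERVED = {1: "G", 6: "C"}  # NT-6 and the central NT-1 (CG dyad)
_SOFT = {0: "T", 4: "A"}  # matched with per-position identity probability
SPECIFICITY_SLOTS = (2, 3)  # (NT-5, NT-4) within the half site


# ---------------------------------------------------------------------------
# Planted code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegeneracySpec:
    """How a recognition class distributes its half-site dinucleotides.

    kind:
      none            -- a single palindrome.
      sym_intrinsic   -- both half sites drawn independently from the class
                         entries (palindromes and mixtures all populated).
      asym_intrinsic  -- monomers prefer ``dominant``; the dominant-palindrome
                         fraction equals ``dominant_prob``.
      extrinsic       -- each TF of the class is wedded to one palindrome of
                         ``partition``; no mixtures ever occur.
    """

    kind: Literal["none", "sym_intrinsic", "asym_intrinsic", "extrinsic"] = "none"
    dominant: str | None = None
    minor: str | None = None
    dominant_prob: float = 1.0
    partition: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind == "asym_intrinsic":
            if not (0.5 < self.dominant_prob <= 1.0):
                raise ValueError("dominant_prob must be in (0.5, 1]")
            if not self.dominant or not self.minor:
                raise ValueError("asym_intrinsic needs dominant and minor")
        if self.kind == "extrinsic" and len(self.partition) < 2:
            raise ValueError("extrinsic needs a partition of >= 2 semisequences")


@dataclass(frozen=True)
class CodeEntry:
    aa_pair: str
    semiseq: str  # (NT-5, NT-4) dinucleotide of the left half site
    weight: float = 1.0

    def __post_init__(self):
        if len(self.aa_pair) != 2:
            raise ValueError(f"aa_pair must be 2 letters: {self.aa_pair!r}")
        if len(self.semiseq) != 2 or any(b not in ALPHABET for b in self.semiseq):
            raise ValueError(f"semiseq must be a dinucleotide: {self.semiseq!r}")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass
class PlantedCode:
    """Ground-truth (AA-15, AA-16) -> (NT-5, NT-4) associations."""

    entries: list[CodeEntry]
    degeneracy: dict[str, DegeneracySpec] = field(default_factory=dict)

    def __post_init__(self):
        for pair in self.aa_pairs():
            total = sum(e.weight for e in self.entries if e.aa_pair == pair)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"weights for {pair} sum to {total}, not 1")

    def aa_pairs(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.aa_pair, None)
        return list(seen)

    def class_entries(self, aa_pair: str) -> list[CodeEntry]:
        return [e for e in self.entries if e.aa_pair == aa_pair]

    def spec_for(self, aa_pair: str) -> DegeneracySpec:
        return self.degeneracy.get(aa_pair, DegeneracySpec("none"))

    @classmethod
    def simple(cls, mapping: dict[str, str]) -> "PlantedCode":
        """A non-degenerate code: one palindrome per recognition class."""
        return cls([CodeEntry(aa, nt) for aa, nt in mapping.items()])


@dataclass
class Region:
    tf_id: str
    region_id: str
    strict_seq: str
    extended_seq: str
    strict_offset: int  # start of the strict slice within the extended region


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

def generate_family(
    n_classes: int,
    tfs_per_class: int,
    code: PlantedCode,
    seed: int,
    conservation: float = 0.7,
) -> tuple[list[DomainRecord], dict[str, str]]:
    """Domain alignment for ``n_classes`` recognition classes.

    Columns (1-based, fixed frame): 15/16 = class aa_pair, 17-20 = TVSR,
    51 = A, 54 = L. Every other column has a random consensus residue that
    each sequence matches with probability ``conservation``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    pairs = code.aa_pairs()
    if len(pairs) < n_classes:
        raise ValueError(f"code covers {len(pairs)} aa_pairs, need {n_classes}")
    if len(set(pairs)) != len(pairs):  # pragma: no cover - aa_pairs dedups
        raise ValueError("duplicate aa_pairs across classes")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ALPHABET))
    consensus = rng.choice(aa, size=ALIGNMENT_WIDTH)
    fixed = {15: None, 16: None, 17: "T", 18: "V", 19: "S", 20: "R",
             51: "A", 54: "L"}
    records: list[DomainRecord] = []
    class_map: dict[str, str] = {}
    for ci in range(n_classes):
        pair = pairs[ci]
        for ti in range(tfs_per_class):
            cols = consensus.copy()
            noise = rng.random(ALIGNMENT_WIDTH) >= conservation
            cols[noise] = rng.choice(aa, size=int(noise.sum()))
            for col, res in fixed.items():
                cols[col - 1] = res if res is not None else pair[col - 15]
            tf_id = f"tf_{pair}_{ti:03d}"
            seq = "".join(cols)
            records.append(
                DomainRecord(id=tf_id, organism="synthetic", raw_seq=seq,
                             aligned_seq=seq, has_core_domain=True)
            )
            class_map[tf_id] = pair
    return records, class_map


# ---------------------------------------------------------------------------
# Site construction
# ---------------------------------------------------------------------------

def _half_site(rng: np.random.Generator, semiseq: str,
               identity: float = 0.9) -> str:
    """One 7-bp half site (NT-7..NT-1) over the conserved backbone."""
    out = []
    for i in range(HALF_WIDTH):
        if i in _CONSERVED:
            out.append(_CONSERVED[i])
        elif i in SPECIFICITY_SLOTS:
            out.append(semiseq[i - SPECIFICITY_SLOTS[0]])
        elif i in _SOFT:
            if rng.random() < identity:
                out.append(_SOFT[i])
            else:
                out.append(rng.choice([b for b in ALPHABET if b != _SOFT[i]]))
        else:  # variable NT-2
            out.append(ALPHABET[rng.integers(4)])
    return "".join(out)


def make_site(rng: np.random.Generator, left_semiseq: str, right_semiseq: str,
              identity: float = 0.9) -> str:
    """A 14-bp site; the right half is a reverse-complemented half site whose
    (NT-5, NT-4), read on the complementary strand, equal ``right_semiseq``."""
    left = _half_site(rng, left_semiseq, identity)
    right = _half_site(rng, right_semiseq, identity)
    return left + revcomp(right)


def _draw_semiseq_pair(rng: np.random.Generator, code: PlantedCode,
                       aa_pair: str, tf_index: int = 0) -> tuple[str, str]:
    """Half-site dinucleotide pair for one planted site of a class."""
    spec = code.spec_for(aa_pair)
    entries = code.class_entries(aa_pair)
    if spec.kind == "none":
        weights = np.array([e.weight for e in entries])
        s = entries[rng.choice(len(entries), p=weights / weights.sum())].semiseq
        return s, s
    if spec.kind == "sym_intrinsic":
        weights = np.array([e.weight for e in entries])
        weights = weights / weights.sum()
        i, j = rng.choice(len(entries), size=2, p=weights)
        return entries[i].semiseq, entries[j].semiseq
    if spec.kind == "asym_intrinsic":
        # monomer-level preference q with q^2 = dominant_prob, so the
        # dominant-palindrome fraction equals dominant_prob
        q = float(np.sqrt(spec.dominant_prob))
        halves = tuple(
            spec.dominant if rng.random() < q else spec.minor for _ in range(2)
        )
        return halves  # type: ignore[return-value]
    if spec.kind == "extrinsic":
        s = spec.partition[tf_index % len(spec.partition)]
        return s, s
    raise ValueError(f"unknown degeneracy kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Region generation
# ---------------------------------------------------------------------------

def generate_regions(
    class_map: dict[str, str],
    code: PlantedCode,
    site_rate: float = 0.8,
    region_len: int = 150,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    identity: float = 0.9,
    revcomp_fraction: float = 0.0,
) -> tuple[list[Region], pd.DataFrame]:
    """Strict/extended upstream regions with planted sites and their truth.

    Strict regions are ``region_len`` bp of background (<= 200, the
    non-coding truncation limit); extended regions are 250 bp (padding +
    strict slice + 50 bp of "coding" background). Each TF's region carries a
    planted site with probability ``site_rate``; truth offsets are 0-based
    half-open starts on the sense strand of the strict region.
    """
    if not (0 <= site_rate <= 1):
        raise ValueError("site_rate must be in [0, 1]")
    if region_len < 50:
        raise ValueError("region_len must be >= 50")
    if region_len > 200:
        raise ValueError("strict regions are truncated at 200 bp")
    if region_len < SITE_WIDTH:
        raise ValueError("site longer than region")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-9 or (bg < 0).any():
        raise ValueError("background must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list(ALPHABET))

    def bg_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n, p=bg))

    regions: list[Region] = []
    truth_rows: list[dict] = []
    tf_counter: dict[str, int] = {}
    for tf_id, aa_pair in class_map.items():
        idx = tf_counter.setdefault(aa_pair, 0)
        tf_counter[aa_pair] += 1
        strict = bg_seq(region_len)
        region_id = f"{tf_id}|up"
        if rng.random() < site_rate:
            left, right = _draw_semiseq_pair(rng, code, aa_pair, idx)
            site = make_site(rng, left, right, identity)
            start = int(rng.integers(0, region_len - SITE_WIDTH + 1))
            strand = "+"
            planted = site
            if revcomp_fraction and rng.random() < revcomp_fraction:
                strand = "-"
                planted = revcomp(site)
            strict = strict[:start] + planted + strict[start + SITE_WIDTH:]
            truth_rows.append(
                {"tf_id": tf_id, "region_id": region_id, "start": start,
                 "strand": strand, "site_seq": site}
            )
        pad = bg_seq(200 - region_len)
        coding = bg_seq(50)
        extended = pad + strict + coding
        regions.append(
            Region(tf_id=tf_id, region_id=region_id, strict_seq=strict,
                   extended_seq=extended, strict_offset=len(pad))
        )
    truth = pd.DataFrame(
        truth_rows, columns=["tf_id", "region_id", "start", "strand", "site_seq"]
    )
    if len(truth):
        truth = truth.astype({"start": np.int64})
    return regions, truth


# ---------------------------------------------------------------------------
# Degeneracy scenario sets (pure site sets, no regions)
# ---------------------------------------------------------------------------

def generate_degeneracy_bs_sets(
    scenario: Literal["both_high_affinity", "preferential", "exclusive"],
    n_sites: int,
    semiseqs: tuple[str, str],
    mix_energy_ratio: float = 1.0,
    dominant_prob: float = 0.85,
    seed: int = 0,
    identity: float = 0.9,
) -> list[str]:
    """Binding-site sets for the three degeneracy scenarios.

    ``both_high_affinity``: each half site drawn independently from the two
    dinucleotides (mixtures weighted by ``mix_energy_ratio`` relative to
    palindromes). ``preferential``: every monomer binds ``semiseqs[0]`` with
    probability ``dominant_prob`` (at 1.0 this degenerates to pure
    palindromes with zero mixtures). ``exclusive``: two pseudo-TFs, each
    locked to its own palindrome; no mixtures.
    """
    a, b = semiseqs
    if a == b:
        raise ValueError("semiseqs must differ")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    if scenario == "both_high_affinity":
        options = [(a, a), (b, b), (a, b), (b, a)]
        w = np.array([1.0, 1.0, mix_energy_ratio, mix_energy_ratio])
        w = w / w.sum()
        for k in rng.choice(4, size=n_sites, p=w):
            pairs.append(options[k])
    elif scenario == "preferential":
        if not (0.5 < dominant_prob <= 1.0):
            raise ValueError("dominant_prob must be in (0.5, 1]")
        for _ in range(n_sites):
            halves = tuple(
                a if rng.random() < dominant_prob else b for _ in range(2)
            )
            pairs.append(halves)  # type: ignore[arg-type]
    elif scenario == "exclusive":
        for i in range(n_sites):
            s = a if i < (n_sites + 1) // 2 else b
            pairs.append((s, s))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return [make_site(rng, l, r, identity) for l, r in pairs]


def shuffle_region(seq: str, seed: int) -> str:
    """Mononucleotide shuffle: a composition-preserving permutation."""
    if not seq:
        raise ValueError("empty sequence")
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq))
    rng.shuffle(letters)
    return "".join(letters)
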