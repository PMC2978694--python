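"""Per-class consensus, the class-weighted consensus logo, and the
recognition-code table (amino-acid pair -> significant nucleotide pairs,
degeneracy relations, class triads)."""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import ALPHABET, encode
from .degeneracy import DegeneracyRelation, classify_sites
from .footprint import site_logo

logger = logging.getLogger(__name__)

CODE_COLUMNS = [
    "aa_pair",
    "n_tfs_in_class",
    "n_tfs_with_bs",
    "n_bs",
    "associations",
    "degeneracies",
]


def class_consensus(sites: Sequence[str]) -> str:
    """Per-column majority-base consensus; ties go to the alphabetically
    first base among the tied maxima (logged)."""
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("ragged site set")
    counts = np.zeros((w, 4), dtype=int)
    cols = np.arange(w)
    for s in sites:
        counts[cols, encode(s.upper())] += 1
    out = []
    for j in range(w):
        m = counts[j].max()
        winners = [ALPHABET[b] for b in range(4) if counts[j, b] == m]
        if len(winners) > 1:
            logger.info("consensus tie at column %d among %s", j, winners)
        out.append(winners[0])
    return "".join(out)


def consensus_logo(class_consensuses: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Frequency/IC matrix over one consensus per class.

    Weighting is per class, not per site: a class contributes one sequence
    however many binding sites it has, so heavily populated classes cannot
    dominate the logo.
    """
    return site_logo(list(class_consensuses))


def assemble(
    classes: dict[str, list[str]],
    site_tables: dict[str, pd.DataFrame],
    relations: dict[str, list[DegeneracyRelation]],
    background_dinuc_probs: dict[str, float] | None = None,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Recognition-code table: one row per recognition class.

    ``classes`` maps aa_pair -> member tf_ids; ``site_tables`` maps aa_pair
    -> final site table; ``relations`` maps aa_pair -> degeneracy relations.
    Significant associations are the S-matrix palindromic cells of the
    class's site set, reported as "semiseq:count".
    """
    missing = sorted(set(site_tables) - set(classes))
    if missing:
        raise KeyError(f"site tables reference unknown classes: {missing}")
    rows = []
    for aa_pair in sorted(classes):
        members = classes[aa_pair]
        sites = site_tables.get(aa_pair)
        if sites is None or len(sites) == 0:
            rows.append(
                {"aa_pair": aa_pair, "n_tfs_in_class": len(members),
                 "n_tfs_with_bs": 0, "n_bs": 0, "associations": "",
                 "degeneracies": ""}
            )
            continue
        F, S, _ = classify_sites(
            list(sites["sequence"]), background_dinuc_probs, alpha_fdr
        )
        assoc = ",".join(
            f"{c}:{F[(c, c)]}" for c in S.palindromes
        )
        rels = ",".join(r.render() for r in relations.get(aa_pair, []))
        rows.append(
            {
                "aa_pair": aa_pair,
                "n_tfs_in_class": len(members),
                "n_tfs_with_bs": int(sites["tf_id"].nunique()),
                "n_bs": int(len(sites)),
                "associations": assoc,
                "degeneracies": rels,
            }
        )
    return pd.DataFrame(rows, columns=CODE_COLUMNS)


def summarize(code_table: pd.DataFrame,
              relations: dict[str, list[DegeneracyRelation]] | None = None) -> dict:
    """Tallies over the code table: classes with sites, degeneracy counts,
    TF and site totals."""
    relations = relations or {}
    flat = [r for rels in relations.values() for r in rels]
    if len(code_table) == 0:
        return {
            "n_classes": 0, "n_classes_with_bs": 0, "n_intrinsic": 0,
            "n_extrinsic": 0, "n_tfs_with_bs": 0, "n_bs_total": 0,
        }
    return {
        "n_classes": int(len(code_table)),
        "n_classes_with_bs": int((code_table["n_bs"] > 0).sum()),
        "n_intrinsic": sum(r.kind.endswith("intrinsic") for r in flat),
        "n_extrinsic": sum(r.kind == "extrinsic" for r in flat),
        "n_tfs_with_bs": int(code_table["n_tfs_with_bs"].sum()),
        "n_bs_total": int(code_table["n_bs"].sum()),
    }
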