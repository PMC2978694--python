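"""Mutual information between paired protein and binding-site alignments.

Each row of the domain alignment is paired with one binding-site row through
a tf_id map; the plug-in (maximum-likelihood) mutual information, in bits, is
computed for every (amino-acid column, nucleotide column) pair. Pairs with a
gap in either column are dropped before estimation. Highly conserved columns
carry no covariation signal: a constant column gives exactly 0 bits.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

GAPS = {"-", "."}


@dataclass
class MIMatrix:
    values: np.ndarray  # (n_aa_columns, n_nt_columns), bits
    counts: np.ndarray  # usable pairs per cell

    def ranked_cells(self) -> list[tuple[int, int, float]]:
        """Cells as (aa_col0, nt_col0, mi) sorted by decreasing MI; ties
        broken by (aa index, nt index)."""
        n_aa, n_nt = self.values.shape
        cells = [
            (i, j, float(self.values[i, j]))
            for i in range(n_aa) for j in range(n_nt)
        ]
        return sorted(cells, key=lambda c: (-c[2], c[0], c[1]))


def column_mi(aa_column, nt_column, bias_corrected: bool = False) -> float:
    """Plug-in mutual information (bits) between two paired symbol columns.

    ``bias_corrected`` subtracts the first-order Miller-Madow term
    (|A|-1)(|N|-1)/(2 N ln 2); the default matches the plain estimator.
    """
    if len(aa_column) != len(nt_column):
        raise ValueError("columns must be paired (equal length)")
    pairs = [
        (a, n) for a, n in zip(aa_column, nt_column)
        if a not in GAPS and n not in GAPS
    ]
    n = len(pairs)
    if n == 0:
        raise ValueError("no usable (gap-free) pairs")
    joint = Counter(pairs)
    fa = Counter(a for a, _ in pairs)
    fn = Counter(b for _, b in pairs)
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / n
        mi += p * np.log2(p * n * n / (fa[a] * fn[b]))
    if bias_corrected:
        mi -= (len(fa) - 1) * (len(fn) - 1) / (2 * n * np.log(2))
    return max(float(mi), 0.0)


def mi_matrix(
    domain_rows: dict[str, str],
    bs_rows: dict[str, str],
    pairing: dict[str, str] | None = None,
    bias_corrected: bool = False,
) -> MIMatrix:
    """MI over all (AA column, NT column) pairs.

    ``domain_rows`` maps tf_id -> aligned AA sequence, ``bs_rows`` maps
    site_id -> aligned site sequence, and ``pairing`` maps site_id -> tf_id
    (identity by default). Every site row must map to exactly one domain row.
    """
    if pairing is None:
        pairing = {sid: sid for sid in bs_rows}
    missing = [sid for sid, tid in pairing.items() if tid not in domain_rows]
    if missing:
        raise KeyError(f"site rows with no matching domain row: {missing}")
    site_ids = sorted(pairing)
    if len(site_ids) < 2:
        raise ValueError("need at least 2 paired rows")
    aa_mat = [domain_rows[pairing[s]] for s in site_ids]
    nt_mat = [bs_rows[s] for s in site_ids]
    n_aa = len(aa_mat[0])
    n_nt = len(nt_mat[0])
    if any(len(r) != n_aa for r in aa_mat) or any(len(r) != n_nt for r in nt_mat):
        raise ValueError("ragged alignment rows")
    values = np.zeros((n_aa, n_nt))
    counts = np.zeros((n_aa, n_nt), dtype=int)
    for i in range(n_aa):
        aa_col = [r[i] for r in aa_mat]
        for j in range(n_nt):
            nt_col = [r[j] for r in nt_mat]
            usable = sum(
                a not in GAPS and b not in GAPS for a, b in zip(aa_col, nt_col)
            )
            counts[i, j] = usable
            if usable:
                values[i, j] = column_mi(aa_col, nt_col, bias_corrected)
    return MIMatrix(values=values, counts=counts)
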