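"""Readers and writers for every on-disk format the pipeline touches.

FASTA (plain and aligned) goes through Biopython; site tables are TSV via
pandas; motifs use a minimal text matrix format. All coordinates are 0-based
half-open on the sense strand of the named region.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


logger = logging.getLogger(__name__)

SITE_COLUMNS = [
    "tf_id",
    "region_id",
    "start",
    "end",
    "strand",
    "sequence",
    "score",
    "zscore",
    "confidence",
]


class AlignmentLengthError(ValueError):
    """Raised when an alignment that must be rectangular is ragged."""


class MotifFormatError(ValueError):
    """Raised on a malformed motif file."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, aligned: bool = False) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs.

    Sequences are normalized to uppercase (lowercase input is logged).
    With ``aligned=True`` all sequences must share one length.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("normalized lowercase letters in record %s", rec.id)
            seq = seq.upper()
        records.append((rec.id, seq))
    if aligned and records:
        lengths = {len(s) for _, s in records}
        if len(lengths) > 1:
            raise AlignmentLengthError(
                f"ragged alignment in {path}: lengths {sorted(lengths)}"
            )
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Motif (minimal text matrix: one row per position, columns A C G T)
# ---------------------------------------------------------------------------

def write_motif(freqs: np.ndarray, path: str | Path, name: str = "motif") -> None:
    """Write a (width x 4) frequency matrix as a minimal text motif."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 2 or freqs.shape[1] != 4:
        raise MotifFormatError(f"expected a (width x 4) matrix, got {freqs.shape}")
    if (freqs < 0).any():
        raise MotifFormatError("negative matrix entries")
    with open(path, "w") as fh:
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {freqs.shape[0]}\n")
        for row in freqs:
            fh.write(" ".join(f"{v:.10f}" for v in row) + "\n")


def read_motif(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in open(path) if ln.strip()]
    if len(lines) < 3 or not lines[0].startswith("MOTIF"):
        raise MotifFormatError(f"not a motif file: {path}")
    header = lines[1]
    try:
        width = int(header.split("w=")[1].split()[0])
    except (IndexError, ValueError) as exc:
        raise MotifFormatError(f"bad motif header: {header!r}") from exc
    rows = lines[2:]
    if len(rows) != width:
        raise MotifFormatError(
            f"motif declares width {width} but has {len(rows)} rows"
        )
    mat = np.array([[float(v) for v in row.split()] for row in rows])
    if mat.shape != (width, 4):
        raise MotifFormatError(f"expected {width} rows of 4 values")
    if (mat < 0).any():
        raise MotifFormatError("negative matrix entries")
    return mat


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

def make_site_table(rows: Sequence[dict] = ()) -> pd.DataFrame:
    """Build a validated site table (one row per binding site)."""
    df = pd.DataFrame(list(rows), columns=SITE_COLUMNS)
    df = df.astype(
        {
            "tf_id": str,
            "region_id": str,
            "start": np.int64,
            "end": np.int64,
            "strand": str,
            "sequence": str,
            "score": float,
            "zscore": float,
            "confidence": float,
        }
    )
    _validate_sites(df)
    return df


def _validate_sites(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]]
        raise ValueError(f"start >= end for rows: {bad.index.tolist()}")
    widths = df["end"] - df["start"]
    if (widths != df["sequence"].str.len()).any():
        raise ValueError("end - start must equal sequence length")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")


def write_sites(df: pd.DataFrame, path: str | Path) -> None:
    _validate_sites(df)
    out = df.loc[:, SITE_COLUMNS].copy()
    # fixed float formatting keeps reruns byte-identical
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"tf_id": str, "region_id": str, "strand": str, "sequence": str},
    )
    if len(df) == 0:
        df = make_site_table()
    else:
        df = df.astype({"start": np.int64, "end": np.int64})
        _validate_sites(df)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """BED6 export: chrom=region_id, name=tf_id, score scaled to [0,1000]."""
    _validate_sites(df)
    with open(path, "w") as fh:
        if len(df) == 0:
            return
        smax = max(abs(df["score"]).max(), 1e-12)
        for _, row in df.iterrows():
            bed_score = int(round(min(max(row.score / smax, 0.0), 1.0) * 1000))
            fh.write(
                f"{row.region_id}\t{row.start}\t{row.end}\t{row.tf_id}"
                f"\t{bed_score}\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# Truth tables (synthetic ground truth)
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["tf_id", "region_id", "start", "strand", "site_seq"]


def write_truth(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"tf_id": str, "region_id": str, "strand": str, "site_seq": str},
    )
    if len(df):
        df = df.astype({"start": np.int64})
    return df
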