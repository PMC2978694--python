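"""Domain-set curation and recognition-class partitioning.

All operations work in a fixed alignment coordinate frame (columns are
1-based; the reference frame is 71 columns wide). Recognition classes group
regulators by the residues at the specificity columns 15 and 16, optionally
restricted to the dominant subgroup whose recognition-helix columns 17-20
read TVSR.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

GAP = "-"
SPECIFICITY_COLUMNS = (15, 16)
HELIX_COLUMNS = (17, 18, 19, 20)
RECOGNITION_COLUMNS = (5, 15, 16, 17, 18, 19, 20, 51, 54, 55)


@dataclass
class DomainRecord:
    id: str
    organism: str
    raw_seq: str
    aligned_seq: str
    has_core_domain: bool = True

    def __post_init__(self):
        if self.raw_seq != self.aligned_seq.replace(GAP, ""):
            raise ValueError(
                f"{self.id}: raw_seq does not match aligned_seq minus gaps"
            )


@dataclass
class RecognitionClass:
    aa_pair: str
    members: list[str] = field(default_factory=list)
    restricted_group_tag: str | None = None


def filter_domains(
    records: list[DomainRecord],
    length_range: tuple[int, int] = (45, 75),
    require_core: bool = True,
) -> list[DomainRecord]:
    """Keep domains whose ungapped length falls inside the (inclusive) range
    and, if required, that carry the core HTH domain annotation."""
    lo, hi = length_range
    if lo > hi:
        raise ValueError(f"bad length range ({lo}, {hi})")
    kept = [
        r for r in records
        if lo <= len(r.raw_seq) <= hi and (r.has_core_domain or not require_core)
    ]
    logger.info("filter_domains kept %d of %d", len(kept), len(records))
    return kept


def dedupe_domains(records: list[DomainRecord]) -> list[DomainRecord]:
    """Collapse exact-duplicate domain sequences (strain variants) to one
    representative each, the first by sorted id."""
    by_seq: dict[str, DomainRecord] = {}
    for rec in sorted(records, key=lambda r: r.id):
        by_seq.setdefault(rec.raw_seq, rec)
    kept = [r for r in records if by_seq[r.raw_seq] is r]
    logger.info("dedupe_domains removed %d duplicates", len(records) - len(kept))
    return kept


def drop_gappy_columns(
    rows: list[str], max_gap_fraction: float = 0.80
) -> tuple[list[str], dict[int, int]]:
    """Remove columns with a gap fraction strictly above the threshold.

    Returns the reduced rows and a 1-based old->new column map for the kept
    columns; the reduced frame is the fixed coordinate system downstream.
    """
    if not rows:
        return [], {}
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment is ragged")
    n = len(rows)
    keep = [
        j for j in range(width)
        if sum(r[j] == GAP for r in rows) / n <= max_gap_fraction
    ]
    colmap = {old + 1: new + 1 for new, old in enumerate(keep)}
    reduced = ["".join(r[j] for j in keep) for r in rows]
    return reduced, colmap


def recognition_residues(
    record: DomainRecord, columns: tuple[int, ...] = RECOGNITION_COLUMNS
) -> dict[int, str]:
    """Residues at the recognition/structural columns (1-based). A gap at a
    requested column is reported as the gap symbol."""
    width = len(record.aligned_seq)
    out = {}
    for col in columns:
        if not (1 <= col <= width):
            raise IndexError(f"column {col} outside frame of width {width}")
        out[col] = record.aligned_seq[col - 1]
    return out


def partition_classes(
    records: list[DomainRecord], restrict: str | None = "TVSR"
) -> list[RecognitionClass]:
    """Partition records into recognition classes by (column-15, column-16).

    With ``restrict`` set, only records whose columns 17-20 equal it are
    partitioned (the dominant-subgroup restriction); classes are returned in
    lexicographic aa_pair order.
    """
    classes: dict[str, RecognitionClass] = {}
    for rec in records:
        helix = "".join(rec.aligned_seq[c - 1] for c in HELIX_COLUMNS)
        if restrict is not None and helix != restrict:
            continue
        pair = "".join(rec.aligned_seq[c - 1] for c in SPECIFICITY_COLUMNS)
        cls = classes.setdefault(
            pair, RecognitionClass(aa_pair=pair, restricted_group_tag=restrict)
        )
        cls.members.append(rec.id)
    return [classes[k] for k in sorted(classes)]
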