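"""Shared configuration of the analysis scripts (run 01..06 in order)."""
from pathlib import Path

from lacicode.pipeline import PipelineConfig

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

CONFIG = PipelineConfig(seed=SEED)


def load_regions():
    """Rebuild Region objects from the simulated FASTA files."""
    from lacicode.seqio import read_fasta
    from lacicode.synthetic import Region

    strict = dict(read_fasta(DATA / "regions_strict.fasta"))
    extended = dict(read_fasta(DATA / "regions_extended.fasta"))
    regions = []
    for rid, sseq in strict.items():
        regions.append(
            Region(
                tf_id=rid.split("|")[0], region_id=rid, strict_seq=sseq,
                extended_seq=extended[rid],
                strict_offset=200 - len(sseq),
            )
        )
    return regions


def load_classes():
    import pandas as pd

    df = pd.read_csv(DATA / "classes.tsv", sep="\t",
                     keep_default_na=False, na_values=[""])
    classes: dict[str, list[str]] = {}
    for row in df.itertuples():
        classes.setdefault(row.aa_pair, []).append(row.tf_id)
    return classes
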