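"""Simulate the study inputs: a six-class TVSR-like regulator family with a
planted recognition code, and per-regulator strict/extended upstream regions
carrying planted 14-bp palindromic operators."""
import numpy as np
import pandas as pd

from common import CONFIG, DATA
from lacicode import seqio, synthetic
from lacicode.domains import partition_classes

DATA.mkdir(parents=True, exist_ok=True)
rng = np.random.default_rng(CONFIG.seed)
code = synthetic.PlantedCode.simple(dict(sorted(CONFIG.code_map.items())))

records, class_map = synthetic.generate_family(
    CONFIG.n_classes, CONFIG.tfs_per_class, code,
    seed=int(rng.integers(2**31 - 1)),
)
regions, truth = synthetic.generate_regions(
    class_map, code, CONFIG.site_rate, CONFIG.region_len, CONFIG.background,
    seed=int(rng.integers(2**31 - 1)), identity=CONFIG.identity,
)

seqio.write_fasta([(r.id, r.aligned_seq) for r in records], DATA / "domains.fasta")
seqio.write_fasta([(r.region_id, r.strict_seq) for r in regions],
                  DATA / "regions_strict.fasta")
seqio.write_fasta([(r.region_id, r.extended_seq) for r in regions],
                  DATA / "regions_extended.fasta")
seqio.write_truth(truth, DATA / "truth.tsv")

classes = partition_classes(records, restrict=CONFIG.restrict)
pd.DataFrame(
    [(c.aa_pair, m) for c in classes for m in c.members],
    columns=["aa_pair", "tf_id"],
).to_csv(DATA / "classes.tsv", sep="\t", index=False)

print(f"{len(records)} domains in {len(classes)} recognition classes "
      f"(restriction: {CONFIG.restrict})")
print(f"{len(regions)} regions, {len(truth)} planted sites "
      f"(site rate {CONFIG.site_rate})")
print(f"planted code: {dict(sorted(CONFIG.code_map.items()))}")
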