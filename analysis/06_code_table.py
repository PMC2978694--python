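"""Assemble the recognition-code table: per class, the significant
(NT-5, NT-4) associations, the degeneracy relations, the class triad, and
the class-weighted consensus logo."""
import json

import pandas as pd

from common import CONFIG, RESULTS, load_classes
from lacicode.codetable import assemble, class_consensus, consensus_logo, summarize
from lacicode.degeneracy import DegeneracyRelation

classes = load_classes()
sites = pd.read_csv(RESULTS / "refined_sites.tsv", sep="\t",
                    keep_default_na=False, na_values=[""])
rels_df = pd.read_csv(RESULTS / "relations.tsv", sep="\t",
                      keep_default_na=False, na_values=[""])

site_tables = {aa: g.drop(columns="aa_pair") for aa, g in sites.groupby("aa_pair")}
relations = {
    aa: [DegeneracyRelation(r.kind, r.semiseq_a, r.semiseq_b, r.pvalue)
         for r in g.itertuples()]
    for aa, g in rels_df.groupby("aa_pair")
}

table = assemble(classes, site_tables, relations, alpha_fdr=CONFIG.alpha_fdr)
table.to_csv(RESULTS / "code_table.tsv", sep="\t", index=False)
print(table.to_string(index=False))

consensuses = [class_consensus(list(g.sequence)) for _, g in
               sites.groupby("aa_pair")]
freq, ic = consensus_logo(consensuses)
pd.DataFrame({"position": range(1, len(ic) + 1), "ic_bits": ic.round(3)}).to_csv(
    RESULTS / "consensus_logo_ic.tsv", sep="\t", index=False
)
print("\nconsensus-logo information content (bits):",
      " ".join(f"{v:.2f}" for v in ic))

summary = summarize(table, relations)
with open(RESULTS / "summary.json", "w") as fh:
    json.dump(summary, fh, indent=2, sort_keys=True)
print("\nsummary:", json.dumps(summary, sort_keys=True))
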