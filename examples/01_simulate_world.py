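"""Generate a synthetic mutant-line study and write every standard format.

Builds a 500 kb annotated reference, a wild-type parent and six mutant
lines (one causal mutation each, spanning SNV, 1-bp frameshift, 3-bp
in-frame and multi-kb deletion classes), then writes FASTA, GFF3,
per-line VCF, the cross-line evidence table and a truth summary into
./sim_out/.  Every downstream example can be re-run against these files.
"""

import json
import os

import mutline as m
from mutline import io as mio

OUT = "sim_out"
os.makedirs(OUT, exist_ok=True)

bundle = m.default_fixture(seed=0)

mio.write_fasta(bundle.genome, f"{OUT}/reference.fa")
mio.write_gff3(bundle.gene_models, f"{OUT}/genes.gff3")
for line, records in bundle.calls.items():
    mio.write_vcf(
        records, f"{OUT}/{line}.vcf", line, contigs=bundle.genome.lengths
    )
mio.write_evidence_tsv(
    bundle.truth.cross_line_evidence, f"{OUT}/evidence.tsv"
)

truth_summary = {}
for line, causal in bundle.truth.causal.items():
    if isinstance(causal, m.VariantRecord):
        truth_summary[line] = {
            "class": causal.notes["class"],
            "site": f"{causal.seq_name}:{causal.pos + 1}",
            "ref": causal.ref,
            "alt": causal.alt,
        }
    else:
        truth_summary[line] = {
            "class": "large_deletion",
            "interval_1based": [causal.start + 1, causal.end],
            "deleted_genes": causal.deleted_genes,
        }
with open(f"{OUT}/truth.json", "w") as fh:
    json.dump(truth_summary, fh, indent=2)

print(f"wrote reference ({len(bundle.genome['chr1']):,} bp), "
      f"{len(bundle.gene_models)} genes, "
      f"{len(bundle.calls)} per-line VCFs into {OUT}/")
print("planted causal mutations (the ground truth the pipeline must find):")
for line, info in truth_summary.items():
    print(f"  {line}: {info}")
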