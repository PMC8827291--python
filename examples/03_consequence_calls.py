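"""Classify a frameshift in a four-exon gene and report domain loss.

The fixture mimics the candidate gene of the worked study: a 2889 nt
spliced CDS over four exons with an upstream DNA-binding domain
(RWP-RK, aa 520-580) and a downstream protein-interaction domain (PB1,
aa 790-860).  A single-base deletion at spliced CDS position 2189
(CAA -> CA_) shifts the frame between the two domains: the upstream
domain survives, the downstream one is lost — exactly the molecular
lesion that separates a nodulating from a non-nodulating plant.
"""

import mutline as m

genome, gene, variant, domains = m.nin_like_gene_fixture()
call = m.classify_variant(variant, gene, genome, domains)

print(f"gene: {gene.gene_id} ({len(gene.exons)} exons, "
      f"spliced CDS {gene.spliced_cds_length} nt)")
print(f"variant: {variant.seq_name}:{variant.pos + 1} "
      f"{variant.ref}>{variant.alt}")
print(f"effect: {call.effect} at CDS position {call.cds_pos}")
print(f"reference protein: {len(call.ref_protein)} aa; "
      f"mutant protein: {len(call.alt_protein)} aa")
print(f"domains lost: {call.lost_domains}")

# a synonymous edit in the same gene, for contrast
p = m.simulate.genomic_position(gene, 6)  # third base of codon 2
ref = genome["chr1"][p]
for alt in "ACGT":
    if alt == ref:
        continue
    try:
        other = m.classify_variant(
            m.VariantRecord("demo", "chr1", p, ref, alt), gene, genome
        )
    except Exception:
        continue
    if other.effect == "synonymous":
        print(f"for contrast, {ref}>{alt} at CDS position 6 is "
              f"{other.effect}: same protein, no phenotype expected")
        break
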