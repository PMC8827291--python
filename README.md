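# mutline

**Causal-mutation identification in induced mutant lines.**

`mutline` is a Python library for the classic forward-genetics problem:
several mutagenized lines (γ-irradiation, EMS, ...) derived from one
wild-type parent each show a phenotype — here, loss of root nodulation in
chickpea — and the task is to find the one induced lesion per line that
causes it. The package implements the full desk side of that workflow on
the standard file formats the upstream tools emit (VCF, GFF3, FASTA, PAF,
depth TSV), plus a synthetic-data generator with planted ground truth so
every stage is testable without sequencing data.

## What it computes

**Staged variant filtration.** Per-line variant calls pass through a
fixed filter cascade, with survivor counts reported after each stage:

> all calls → in coding sequence → unique to the line (parent included)
> → biallelic → DP ≥ 2 → alt-allele fraction ≥ 0.9 → no alt-supporting
> reads in any other line

Homozygous induced mutations have alt fraction near 1 and are private to
one line; each stage removes a characteristic error mode (shared
parental polymorphism, caller noise, cross-contamination).

**Variant consequences.** Candidates are mapped into spliced-CDS
coordinates of single-transcript gene models and classified as
synonymous / missense / stop gain / stop loss / in-frame indel /
frameshift by rebuilding and translating the mutant CDS (standard
nuclear code). Frameshift is decided by net coding-length change mod 3.
User-supplied protein-domain intervals are reported lost when their
amino-acid stretch is no longer present in the mutant protein.

**Deletion scanning.** Multi-kb deletions invisible to SNP callers are
found by depth contrast: windows where the mutant's coverage falls below
`ceiling × mutant median` while the wild type stays above
`floor × WT median` (shared gaps are thereby excluded). Breakpoints are
refined to the base from split long-read alignments — a deletion-spanning
read aligns in two query-adjacent blocks flanking the gap — taking the
modal inner edges over supporting reads. A collinearity check over a
contig's PAF blocks flags putative reference misassembly, and genes
inside the final interval are reported deleted or truncated.

**F2 linkage.** Recombination frequency between loci is estimated by the
two-gametes-per-plant counting rule: r̂ = recombinant gametes / 2n.
A plant heterozygous at one locus and homozygous at the other counts one
recombinant gamete; opposite homozygotes count two; double heterozygotes
are phase-ambiguous and counted parental. Against a phenotype-defined
locus with a dominant wild-type allele, only recessive-phenotype plants
are informative (their causal genotype is inferred homozygous mutant).

## Worked example

The package ships the published 19-plant chickpea F2 genotype table
(markers `Ca_06500`, the candidate nodulation gene, and `Ca_06416`,
~900 kb away). Running `python examples/05_linkage_analysis.py` prints:

```
phenotype segregation: 14 nodulating : 5 non-nodulating (chi2 vs 3:1 = 0.018, p = 0.89) — consistent with a single recessive locus
Ca_06500 vs Ca_06416: 3 recombinant gametes / 38 = 0.079 (recombinant plants: 3, 7, 19)
phenotype locus vs Ca_06416: 1 / 38 = 0.026 (informative denominator: 1/10 = 0.100)
phenotype locus vs Ca_06500: 0 / 38 = 0.000 — no recombination: the candidate gene cosegregates with the trait
```

Read: the two markers are ~8 cM apart; the distal marker recombines with
the trait once, excluding it as causal, while the candidate gene itself
never separates from the phenotype in 38 gametes.

The other examples each exercise one capability end to end and print the
planted truth next to what the pipeline recovered:

| script | shows |
|---|---|
| `examples/01_simulate_world.py` | generate a 500 kb annotated reference, WT + 6 mutant lines, write all formats |
| `examples/02_filter_pipeline.py` | per-stage survivor table; every planted causal variant among final candidates |
| `examples/03_consequence_calls.py` | a frameshift at spliced CDS position 2189 that removes the downstream PB1 domain |
| `examples/04_deletion_scan.py` | 35 kb deletion found by depth, refined exactly by 3 split reads, collinearity flag |

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the encoded F2 table, the two headline recombination
frequencies (marker–marker by the gamete-counting rule, and
marker–phenotype under the dominant-wild-type rule with the all-plants
denominator) and writes them as JSON, each with the number of gametes
used.

## Layout

```
src/mutline/       model.py (types) · io.py · simulate.py · filters.py
                   consequence.py · deletions.py · linkage.py · datasets.py
examples/          one narrative script per capability
tests/             pytest suite incl. independent brute-force oracles
docs/methods.md    models, assumptions, parameter defaults, limitations
```
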