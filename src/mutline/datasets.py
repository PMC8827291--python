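"""Small published datasets encoded as package data.

These are printed tables, transcribed here so the worked examples and
the acceptance checks can run with no external files.
"""

from __future__ import annotations

from .model import F2Plant

CAUSAL_MARKER = "Ca_06500"
LINKED_MARKER = "Ca_06416"


def chickpea_f2_table() -> list[F2Plant]:
    """The 19-plant chickpea F2 population segregating for nodulation.

    Genotypes at the candidate gene Ca_06500 (allele-specific PCR) and
    the nearby marker Ca_06416 (restriction digest), as published:
    fourteen plants nodulated and five did not; the five complete-
    digestion plants were homozygous wild type at both markers; of the
    ten partial-digestion (het at Ca_06416) plants, seven were het at
    Ca_06500 while plants 3, 7 and 19 were homozygous; plant 19 was
    non-nodulating and het at Ca_06416, the other four non-nodulating
    plants were homozygous mutant at both markers.
    """

    def plant(pid: int, phenotype: str, g500: str, g416: str) -> F2Plant:
        return F2Plant(
            plant_id=str(pid),
            phenotype=phenotype,
            genotypes={CAUSAL_MARKER: g500, LINKED_MARKER: g416},
        )

    plants = [
        # nodulating, hom-WT at both markers (complete digestion)
        plant(2, "nodulating", "hom_wt", "hom_wt"),
        plant(4, "nodulating", "hom_wt", "hom_wt"),
        plant(5, "nodulating", "hom_wt", "hom_wt"),
        plant(8, "nodulating", "hom_wt", "hom_wt"),
        plant(9, "nodulating", "hom_wt", "hom_wt"),
        # nodulating recombinants: hom-WT at Ca_06500, het at Ca_06416
        plant(3, "nodulating", "hom_wt", "het"),
        plant(7, "nodulating", "hom_wt", "het"),
        # nodulating, het at both markers
        plant(6, "nodulating", "het", "het"),
        plant(12, "nodulating", "het", "het"),
        plant(13, "nodulating", "het", "het"),
        plant(14, "nodulating", "het", "het"),
        plant(15, "nodulating", "het", "het"),
        plant(16, "nodulating", "het", "het"),
        plant(17, "nodulating", "het", "het"),
        # non-nodulating, hom-mut at both markers (no digestion)
        plant(1, "non_nodulating", "hom_mut", "hom_mut"),
        plant(10, "non_nodulating", "hom_mut", "hom_mut"),
        plant(11, "non_nodulating", "hom_mut", "hom_mut"),
        plant(18, "non_nodulating", "hom_mut", "hom_mut"),
        # non-nodulating recombinant: het at Ca_06416
        plant(19, "non_nodulating", "hom_mut", "het"),
    ]
    return sorted(plants, key=lambda p: int(p.plant_id))
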