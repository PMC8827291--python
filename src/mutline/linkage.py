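"""F2 marker-trait analysis by direct gamete counting.

Genotypes come from allele-specific PCR band patterns or restriction
digests; recombination frequency between two loci is estimated by the
simple two-gametes-per-plant counting rule: a plant heterozygous at one
locus and homozygous at the other contributes one recombinant gamete,
opposite homozygotes contribute two, and double heterozygotes are
counted as parental (their phase is ambiguous and, as in the original
counting, ignored — this is not a maximum-likelihood estimator).

Against a phenotype-defined locus with a dominant wild-type allele,
recombination is only detectable in recessive-phenotype plants (their
causal genotype is inferred homozygous mutant); by the published
convention the denominator nonetheless remains two gametes per *scored*
plant, and the informative-only denominator is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .model import F2Plant, LinkageResult, MutlineError


@dataclass(frozen=True)
class BandObservation:
    """Allele-specific PCR outcome: which primer pairs gave a product."""

    wt_band: bool
    mut_band: bool


@dataclass(frozen=True)
class DigestObservation:
    """Restriction-digest outcome where only the WT allele is cut."""

    digested: str  # 'complete', 'partial' or 'none'


def call_genotype(obs: BandObservation | DigestObservation) -> str:
    """Genotype class from one assay observation.

    Bands: WT-only -> hom_wt, mutant-only -> hom_mut, both -> het,
    neither -> missing.  Digest (WT allele cut): complete -> hom_wt,
    none -> hom_mut, partial -> het.
    """
    if isinstance(obs, BandObservation):
        if obs.wt_band and obs.mut_band:
            return "het"
        if obs.wt_band:
            return "hom_wt"
        if obs.mut_band:
            return "hom_mut"
        return "missing"
    if isinstance(obs, DigestObservation):
        table = {"complete": "hom_wt", "none": "hom_mut", "partial": "het"}
        try:
            return table[obs.digested]
        except KeyError:
            raise ValueError(
                f"unknown digest outcome {obs.digested!r}"
            ) from None
    raise TypeError(f"unsupported observation {obs!r}")


def recombinant_gametes(g_a: str, g_b: str) -> int | None:
    """Recombinant gametes implied by one plant's two-locus genotypes.

    Same class -> 0; het vs homozygote -> 1; opposite homozygotes -> 2
    (both gametes must have recombined); any missing -> None, the plant
    is excluded.
    """
    if "missing" in (g_a, g_b):
        return None
    if g_a == g_b:
        return 0
    if "het" in (g_a, g_b):
        return 1
    return 2  # hom_wt vs hom_mut


def marker_pair_rf(
    plants: list[F2Plant], marker_a: str, marker_b: str
) -> LinkageResult:
    """Recombination frequency between two genotyped markers."""
    events = 0
    scored, recombinant = [], []
    for p in plants:
        n = recombinant_gametes(
            p.genotypes.get(marker_a, "missing"),
            p.genotypes.get(marker_b, "missing"),
        )
        if n is None:
            continue
        scored.append(p.plant_id)
        events += n
        if n:
            recombinant.append(p.plant_id)
    return LinkageResult(
        loci=(marker_a, marker_b),
        events=events,
        total_gametes=2 * len(scored),
        plant_ids=scored,
        recombinant_plant_ids=recombinant,
        informative_gametes=2 * len(scored),
    )


def marker_phenotype_rf(
    plants: list[F2Plant],
    marker: str,
    dominance: str = "wt_dominant",
    phenotype_locus: str = "phenotype",
) -> LinkageResult:
    """Recombination frequency between a marker and the phenotype-defined
    causal locus when the wild-type allele is dominant.

    Only recessive-phenotype plants are informative (causal genotype
    inferred hom_mut; marker het -> 1 event, marker hom_wt -> 2);
    dominant-phenotype plants contribute no detectable events.  The
    reported denominator is two gametes per scored plant (the published
    convention); ``informative_gametes`` carries the recessive-only
    denominator.
    """
    if dominance != "wt_dominant":
        raise MutlineError("only a dominant wild-type allele is modelled")
    events = 0
    scored, recombinant, informative = [], [], 0
    for p in plants:
        g = p.genotypes.get(marker, "missing")
        if g == "missing" or p.phenotype == "unknown":
            continue
        scored.append(p.plant_id)
        if p.phenotype != "non_nodulating":
            continue
        informative += 2
        n = recombinant_gametes("hom_mut", g)
        events += n
        if n:
            recombinant.append(p.plant_id)
    return LinkageResult(
        loci=(phenotype_locus, marker),
        events=events,
        total_gametes=2 * len(scored),
        plant_ids=scored,
        recombinant_plant_ids=recombinant,
        informative_gametes=informative,
    )


def segregation_check(
    plants: list[F2Plant],
) -> tuple[int, int, float, float]:
    """Phenotype counts with a Pearson chi-square against the 3:1
    single-recessive-locus expectation.

    Returns (n_dominant, n_recessive, chi2, p_value).
    """
    n_dom = sum(1 for p in plants if p.phenotype == "nodulating")
    n_rec = sum(1 for p in plants if p.phenotype == "non_nodulating")
    total = n_dom + n_rec
    if total == 0:
        raise MutlineError("no phenotyped plants to test")
    chi2, pval = stats.chisquare(
        [n_dom, n_rec], f_exp=[0.75 * total, 0.25 * total]
    )
    return n_dom, n_rec, float(chi2), float(pval)
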