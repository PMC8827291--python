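"""Core domain objects shared across the pipeline.

All interval arithmetic inside the package uses 0-based, half-open
coordinates on the forward strand.  Conversion to the 1-based inclusive
conventions of VCF and GFF3 happens only at the I/O boundary
(:mod:`mutline.io`); PAF and BED are already half-open and pass through
unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

#: bases accepted in reference sequences (IUPAC nucleotide codes)
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

PHENOTYPES = ("nodulating", "non_nodulating", "unknown")
GENOTYPES = ("hom_wt", "het", "hom_mut", "missing")

#: ordered filter-stage names of the candidate-identification pipeline
STAGES = (
    "total",
    "cds",
    "unique",
    "two_alleles",
    "read_depth",
    "min_allele_frequency",
    "cross_line_check",
)

EFFECTS = (
    "synonymous",
    "missense",
    "stop_gain",
    "stop_loss",
    "inframe_deletion",
    "inframe_insertion",
    "frameshift",
    "non_coding",
)


class MutlineError(Exception):
    """Base class for errors raised by this package."""


class ParseError(MutlineError):
    """A file did not conform to the expected dialect."""


@dataclass
class GenomeRef:
    """A reference assembly held in memory as plain nucleotide strings."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ParseError(f"sequence {name!r} is empty")
            bad = set(seq.upper()) - IUPAC_NUCLEOTIDES
            if bad:
                pos = next(
                    i for i, b in enumerate(seq) if b.upper() in bad
                )
                raise ParseError(
                    f"sequence {name!r} contains illegal character "
                    f"{seq[pos]!r} at position {pos + 1}"
                )

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}


@dataclass
class GeneModel:
    """One protein-coding gene: strand, exon and CDS intervals.

    ``exons`` and ``cds`` are sorted, non-overlapping half-open intervals
    in reference coordinates; ``cds`` intervals must lie inside exons.
    One transcript per gene is assumed throughout.
    """

    gene_id: str
    seq_name: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s, e), (s2, e2) in zip(ivs, ivs[1:]):
                if not (s < e <= s2 < e2):
                    raise ValueError(
                        f"{self.gene_id}: {name} intervals must be sorted "
                        "and non-overlapping"
                    )
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"{self.gene_id}: CDS interval ({s},{e}) outside exons"
                )
        if self.spliced_cds_length < 3:
            raise ValueError(f"{self.gene_id}: spliced CDS shorter than 3 nt")

    @property
    def spliced_cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class VariantRecord:
    """A single called variant in a single line.

    ``pos`` is the 0-based position of the first REF base.  ``depth`` is
    the DP field (``None`` when the caller omitted it); ``allele_depths``
    is the ``(ref_count, alt_count)`` pair from AD.  Records decomposed
    from a multi-allelic VCF line carry ``multiallelic=True``.
    """

    line_id: str
    seq_name: str
    pos: int
    ref: str
    alt: str
    depth: int | None = None
    allele_depths: tuple[int, int] | None = None
    multiallelic: bool = False
    passed_stages: set = field(default_factory=set)
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("REF and ALT alleles must differ")
        if self.pos < 0:
            raise ValueError("position must be non-negative")
        if self.allele_depths is not None and min(self.allele_depths) < 0:
            raise ValueError("allele depths must be non-negative")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant across lines (normalized records)."""
        return (self.seq_name, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def alt_af(self) -> float | None:
        if self.allele_depths is None:
            return None
        r, a = self.allele_depths
        return a / (r + a) if (r + a) > 0 else None

    def altered_interval(self) -> tuple[int, int]:
        """Reference interval of bases actually changed by this variant.

        The shared anchor base of a left-anchored indel is excluded; a
        pure insertion yields an empty interval at the insertion point.
        """
        if len(self.ref) == len(self.alt):
            return (self.pos, self.end)
        if self.ref[0] == self.alt[0]:
            return (self.pos + 1, self.end)
        return (self.pos, self.end)


@dataclass
class DepthTrack:
    """Per-base read depth for one line on one reference sequence."""

    line_id: str
    seq_name: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")

    def __eq__(self, other) -> bool:  # array-aware equality
        return (
            isinstance(other, DepthTrack)
            and self.line_id == other.line_id
            and self.seq_name == other.seq_name
            and np.array_equal(self.depth, other.depth)
        )


@dataclass(frozen=True)
class PafAlignment:
    """One alignment block of a long read or contig against the reference.

    Query and target intervals are half-open, exactly as in the PAF
    mandatory columns.
    """

    query_name: str
    query_len: int
    qstart: int
    qend: int
    strand: str
    target_name: str
    target_len: int
    tstart: int
    tend: int
    matches: int
    block_len: int
    mapq: int

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.query_len):
            raise ValueError(f"{self.query_name}: bad query interval")
        if not (0 <= self.tstart < self.tend <= self.target_len):
            raise ValueError(f"{self.query_name}: bad target interval")
        if self.strand not in "+-":
            raise ValueError(f"{self.query_name}: bad strand {self.strand!r}")


@dataclass
class F2Plant:
    """One F2 progeny individual: phenotype plus per-marker genotypes."""

    plant_id: str
    phenotype: str
    genotypes: dict[str, str]

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        for marker, g in self.genotypes.items():
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype {g!r} at {marker!r}")


@dataclass
class RunConfig:
    """Tunable thresholds for every pipeline stage.

    Defaults follow the published filter (depth >= 2, alternate-allele
    frequency >= 0.9, zero tolerated cross-line alt reads); the depth-scan
    parameters are this package's own, chosen to resolve a multi-kb event
    at ~20x coverage with a 1 kb window.
    """

    min_depth: int = 2
    min_alt_af: float = 0.9
    cross_line_max_alt_reads: int = 0
    depth_window_bp: int = 1000
    deletion_min_len: int = 5000
    deletion_mutant_ceiling: float = 0.05
    deletion_wt_floor: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.cross_line_max_alt_reads < 0:
            raise ValueError("count thresholds must be non-negative")
        if not (0.0 <= self.min_alt_af <= 1.0):
            raise ValueError("min_alt_af must lie in [0, 1]")
        if self.depth_window_bp < 1 or self.deletion_min_len < 1:
            raise ValueError("window and minimum length must be positive")
        if not (0.0 <= self.deletion_mutant_ceiling <= 1.0):
            raise ValueError("deletion_mutant_ceiling must lie in [0, 1]")
        if not (0.0 <= self.deletion_wt_floor <= 1.0):
            raise ValueError("deletion_wt_floor must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class DeletionTruth:
    """Ground truth for a planted multi-kb deletion in one line."""

    line_id: str
    seq_name: str
    start: int
    end: int
    deleted_genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Everything the generator planted, for downstream verification.

    ``causal`` maps each mutant line to its planted causal event (a
    :class:`VariantRecord` or a :class:`DeletionTruth`); ``background``
    variants are shared by every line (parent-vs-reference polymorphism);
    ``noise`` records are per-line spurious calls; ``cross_line_evidence``
    maps ``(seq_name, pos, alt)`` to per-line counts of sub-threshold
    alt-supporting reads that were *not* called as variants.
    """

    causal: dict[str, object]
    background: list[VariantRecord]
    noise: dict[str, list[VariantRecord]]
    cross_line_evidence: dict[tuple[str, int, str], dict[str, int]]


@dataclass
class FilterReport:
    """Per-line outcome of the staged filter: counts and survivors."""

    line_id: str
    counts: dict[str, int]
    candidates: list[VariantRecord]

    def __post_init__(self) -> None:
        ordered = [self.counts[s] for s in STAGES if s in self.counts]
        if any(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("stage counts must be non-increasing")
        if "cross_line_check" in self.counts and self.counts[
            "cross_line_check"
        ] != len(self.candidates):
            raise ValueError("final count must equal surviving candidates")


@dataclass
class ConsequenceCall:
    """Predicted effect of one variant on one gene model."""

    gene_id: str | None
    effect: str
    cds_pos: int | None = None
    ref_protein: str | None = None
    alt_protein: str | None = None
    lost_domains: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass
class DeletionCall:
    """A candidate large deletion in one line."""

    line_id: str
    seq_name: str
    start: int
    end: int
    source: str  # 'depth_only' or 'split_refined'
    mutant_mean_depth: float
    wt_mean_depth: float
    n_split_mutant: int = 0
    n_contiguous_mutant: int = 0
    n_split_wt: int = 0
    n_contiguous_wt: int = 0
    deleted_genes: list[str] = field(default_factory=list)
    truncated_genes: list[str] = field(default_factory=list)
    unique_to_line: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval_1based(self) -> tuple[int, int]:
        """The call interval as 1-based inclusive coordinates (reports)."""
        return (self.start + 1, self.end)


@dataclass
class LinkageResult:
    """Two-point recombination estimate by direct gamete counting."""

    loci: tuple[str, str]
    events: int
    total_gametes: int
    plant_ids: list[str] = field(default_factory=list)
    recombinant_plant_ids: list[str] = field(default_factory=list)
    informative_gametes: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.events <= self.total_gametes):
            raise ValueError("events must lie in [0, total_gametes]")

    @property
    def frequency(self) -> float:
        return self.events / self.total_gametes if self.total_gametes else 0.0

    @property
    def informative_frequency(self) -> float | None:
        """events over informative gametes only (``None`` if not tracked)."""
        if not self.informative_gametes:
            return None
        return self.events / self.informative_gametes
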