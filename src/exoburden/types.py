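"""Core domain types shared by every stage of the burden-analysis pipeline.

All coordinates are 1-based inclusive (VCF/GTF convention). Downstream modules
operate exclusively on these types; file formats are handled in :mod:`exoburden.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ValidationError(ValueError):
    """An input value violates a domain-type invariant."""


class Consequence(str, Enum):
    """Functional consequence of a variant on its canonical transcript."""

    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_CANONICAL = "splice_canonical"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INFRAME = "inframe"
    OTHER = "other"


#: Consequences that truncate the protein and are candidate loss-of-function.
TRUNCATING = frozenset(
    {Consequence.STOP_GAINED, Consequence.FRAMESHIFT, Consequence.SPLICE_CANONICAL}
)


class VariantClass(str, Enum):
    """Burden-test variant class (three tested models plus a discard bin)."""

    LOF = "LoF"
    DAMAGING_MISSENSE = "damaging_missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: The three classes actually tested exome-wide.
TESTED_CLASSES = (VariantClass.LOF, VariantClass.DAMAGING_MISSENSE, VariantClass.SYNONYMOUS)


@dataclass
class GenotypeCall:
    """One sample's genotype at one variant site.

    Parameters
    ----------
    sample_id : str
        Opaque sample identifier.
    allele_count : int
        Count of alternate alleles, in {0, 1, 2}.
    depth_DP : int
        Read depth at the site for this sample.
    alt_fraction : float or None
        Fraction of reads supporting the alternate allele; must be defined
        when ``allele_count > 0``.
    genotype_quality_GQ : float
        Phred-scaled genotype quality.
    """

    sample_id: str
    allele_count: int
    depth_DP: int
    alt_fraction: Optional[float]
    genotype_quality_GQ: float

    def __post_init__(self) -> None:
        if self.allele_count not in (0, 1, 2):
            raise ValidationError(
                f"allele_count must be 0, 1 or 2 (sample {self.sample_id})"
            )
        if self.depth_DP < 0:
            raise ValidationError(f"depth_DP must be >= 0 (sample {self.sample_id})")
        if self.allele_count > 0 and self.alt_fraction is None:
            raise ValidationError(
                f"alt_fraction required for carrier genotype (sample {self.sample_id})"
            )
        if self.alt_fraction is not None and not 0.0 <= self.alt_fraction <= 1.0:
            raise ValidationError(
                f"alt_fraction outside [0,1] (sample {self.sample_id})"
            )


@dataclass
class AnnotatedVariant:
    """One biallelic variant with site-level QC metrics and carrier genotypes.

    ``variant_id`` is ``chrom:pos:ref:alt`` with a 1-based position. Site-level
    mean metrics (``mean_DP``, ``mean_QD``, ``mean_QUAL``) are taken as provided
    by the annotation input; mean alternate-read fraction and mean GQ are
    derived from the carrier genotypes on demand.
    """

    variant_id: str
    gene: str
    transcript_id: str
    consequence: Consequence
    predictor_flags: Optional[tuple[bool, bool, bool]]
    mean_QD: float
    mean_QUAL: float
    mean_DP: float
    internal_af_by_cohort: dict[str, float] = field(default_factory=dict)
    external_af_by_db: dict[str, float] = field(default_factory=dict)
    genotypes: list[GenotypeCall] = field(default_factory=list)
    cds_ptc_position: Optional[int] = None

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        for label, af in {**self.internal_af_by_cohort, **self.external_af_by_db}.items():
            if not 0.0 <= af <= 1.0:
                raise ValidationError(
                    f"allele frequency {af!r} for source {label!r} outside [0,1] "
                    f"({self.variant_id})"
                )

    @property
    def carriers(self) -> list[str]:
        """Sample ids carrying at least one alternate allele."""
        return [g.sample_id for g in self.genotypes if g.allele_count > 0]

    def mean_alt_fraction(self) -> float:
        """Mean alternate-read fraction over carrier genotypes."""
        fracs = [g.alt_fraction for g in self.genotypes if g.allele_count > 0]
        if not fracs:
            raise ValidationError(f"no carrier genotypes for {self.variant_id}")
        return float(sum(fracs) / len(fracs))

    def mean_GQ(self) -> float:
        """Mean genotype quality over carrier genotypes."""
        gqs = [g.genotype_quality_GQ for g in self.genotypes if g.allele_count > 0]
        if not gqs:
            raise ValidationError(f"no carrier genotypes for {self.variant_id}")
        return float(sum(gqs) / len(gqs))


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one canonical transcript.

    ``exons`` are (start, end) genomic intervals, 1-based inclusive, ordered in
    transcription order (ascending on '+', descending on '-'). ``cds_length_nt``
    includes the stop codon, so the encoded protein has
    ``cds_length_nt / 3 - 1`` amino acids.
    """

    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-' ({self.transcript_id})")
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        for start, end in self.exons:
            if end < start:
                raise ValidationError(
                    f"exon end < start in {self.transcript_id}: ({start},{end})"
                )
        genomic_order = sorted(self.exons)
        expected = genomic_order if self.strand == "+" else genomic_order[::-1]
        if self.exons != expected:
            raise ValidationError(
                f"exons of {self.transcript_id} not in transcription order"
            )
        prev_end = None
        for start, end in genomic_order:
            if prev_end is not None and start <= prev_end:
                raise ValidationError(f"overlapping exons in {self.transcript_id}")
            prev_end = end
        if self.cds_length_nt % 3 != 0:
            raise ValidationError(
                f"CDS length {self.cds_length_nt} of {self.transcript_id} "
                "not divisible by 3"
            )
        if self.protein_length_aa < 1:
            raise ValidationError(f"CDS of {self.transcript_id} too short")

    def cds_lengths_by_exon(self) -> list[int]:
        """Number of CDS nucleotides in each exon, transcription order.

        Exons without CDS overlap contribute 0 and are dropped from the ends;
        internal exons of a coding transcript always overlap the CDS.
        """
        lo, hi = min(self.cds_start, self.cds_end), max(self.cds_start, self.cds_end)
        lengths = []
        for start, end in self.exons:
            ov = min(end, hi) - max(start, lo) + 1
            lengths.append(max(ov, 0))
        # trim leading/trailing non-coding exons
        while lengths and lengths[0] == 0:
            lengths.pop(0)
        while lengths and lengths[-1] == 0:
            lengths.pop()
        return lengths

    @property
    def cds_length_nt(self) -> int:
        return sum(self.cds_lengths_by_exon())

    @property
    def protein_length_aa(self) -> int:
        return self.cds_length_nt // 3 - 1


@dataclass
class Sample:
    """One registered cohort member."""

    sample_id: str
    status: str  # "case" | "control"
    sex: str = "F"  # "F" | "M" | "unknown"
    cohort_label: str = ""
    mean_coding_depth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(f"status must be case/control ({self.sample_id})")
        if self.sex not in ("F", "M", "unknown"):
            raise ValidationError(f"sex must be F/M/unknown ({self.sample_id})")


@dataclass
class CohortDesign:
    """Case/control sample registry with QC exclusion bookkeeping."""

    samples: list[Sample]
    qc_excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample_ids in cohort")
        self._by_id = {s.sample_id: s for s in self.samples}

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def sample(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    def exclude(self, sample_id: str, reason: str) -> None:
        if sample_id not in self._by_id:
            raise ValidationError(f"unknown sample {sample_id}")
        self.qc_excluded.setdefault(sample_id, reason)

    def passing(self, status: Optional[str] = None) -> list[Sample]:
        """Samples surviving QC, optionally restricted to one status."""
        return [
            s
            for s in self.samples
            if s.sample_id not in self.qc_excluded
            and (status is None or s.status == status)
        ]

    @property
    def n_cases(self) -> int:
        return len(self.passing("case"))

    @property
    def n_controls(self) -> int:
        return len(self.passing("control"))


@dataclass
class KinshipPair:
    """KING-style pairwise kinship coefficient."""

    sample_a: str
    sample_b: str
    kinship_coefficient: float

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValidationError(f"kinship pair with identical samples {self.sample_a}")


@dataclass
class GeneBurdenResult:
    """Carrier 2x2 table and Fisher P for one gene in one variant class."""

    gene: str
    variant_class: VariantClass
    case_carriers: int
    case_noncarriers: int
    control_carriers: int
    control_noncarriers: int
    p_value: float
    exome_wide_significant: bool = False

    def __post_init__(self) -> None:
        for v in (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        ):
            if v < 0:
                raise ValidationError(f"negative cell count for {self.gene}")
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError(f"p_value outside (0,1] for {self.gene}")

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (
            self.case_carriers,
            self.case_noncarriers,
            self.control_carriers,
            self.control_noncarriers,
        )


@dataclass
class CalibrationResult:
    """Observed vs permutation-expected P distribution and inflation factor."""

    variant_class: VariantClass
    observed_p: list[float]
    expected_p: list[float]
    lambda_inflation: float
    n_excluded_from_lambda: int

    def __post_init__(self) -> None:
        if len(self.observed_p) != len(self.expected_p):
            raise ValidationError("observed/expected P lists differ in length")
        if self.lambda_inflation <= 0:
            raise ValidationError("lambda must be positive")


@dataclass
class PrevalenceEstimate:
    """Carrier frequency with an exact binomial confidence interval."""

    source_label: str
    carriers: int
    denominator: int
    frequency: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.denominator:
            raise ValidationError(
                f"carriers outside [0, n] for {self.source_label}"
            )
        if not self.ci_low <= self.frequency <= self.ci_high:
            raise ValidationError(f"CI does not cover frequency ({self.source_label})")


@dataclass
class PcaProjection:
    """Principal-component scores for one sample with its retention flag."""

    sample_id: str
    pc_scores: list[float]
    retained: bool

    def __post_init__(self) -> None:
        if len(self.pc_scores) < 2:
            raise ValidationError(f"need >= 2 PC scores ({self.sample_id})")


@dataclass
class DatabaseCount:
    """Carrier count and denominator for one population source."""

    source_label: str
    carriers: int
    denominator: int
    carriers_by_sex: Optional[tuple[int, int]] = None  # (female, male)

    def __post_init__(self) -> None:
        if self.carriers > self.denominator:
            raise ValidationError(f"carriers > denominator ({self.source_label})")
        if self.carriers_by_sex is not None:
            kf, km = self.carriers_by_sex
            if kf + km != self.carriers:
                raise ValidationError(
                    f"sex-split carriers do not sum to total ({self.source_label})"
                )
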