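"""Core domain types shared by every stage of the pipeline.

All genomic coordinates are 0-based half-open throughout the package;
external dialects (VCF, GFF3, BLAST tabular) are converted at the I/O
boundary in :mod:`homeocollapse.formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_STRANDS = {"+", "-", "."}
VALID_SEXES = {"male", "female", "unknown"}
VALID_PLOIDY = {"diploid", "doubled_haploid"}
IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
REGIONS = ("exon", "intron", "upstream", "downstream", "intergenic")
FUNCTIONAL_CLASSES = ("nonsense", "missense", "silent", "none")


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("Interval.seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"Interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise local alignment between two assembly sequences."""

    query: Interval
    subject: Interval
    pct_identity: float
    aln_length: int
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity must lie in [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


@dataclass
class EffectAnnotation:
    """A single predicted variant effect on one gene/transcript.

    Mirrors the subset of a snpEff ``ANN`` entry this pipeline consumes:
    gene, impact class and the nonsense/missense/silent trichotomy.
    """

    gene_id: str
    impact: str
    region: str
    functional_class: str = "none"
    transcript_id: Optional[str] = None
    effect_term: str = ""

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact {self.impact!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")


Genotype = Optional[tuple[int, int]]  # allele index pair; None when missing


@dataclass
class VariantSite:
    """One variant locus with per-sample genotypes and depths.

    ``pos`` is 0-based internally (1-based in VCF). ``genotypes[i]`` is a
    pair of allele indices into ``[ref] + alts`` or ``None`` when the call
    is missing; ``depths[i]`` is the sample read depth or ``None``.
    ``raw`` preserves the verbatim VCF record for bit-exact re-emission.
    """

    seq_id: str
    pos: int
    ref: str
    alts: list[str]
    genotypes: list[Genotype]
    depths: list[Optional[int]]
    ann: list[EffectAnnotation] = field(default_factory=list)
    site_id: str = "."
    qual: Optional[float] = None
    raw: Optional[str] = None

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    def is_heterozygous(self, i: int) -> bool:
        gt = self.genotypes[i]
        return gt is not None and gt[0] != gt[1]

    def is_missing(self, i: int) -> bool:
        return self.genotypes[i] is None

    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
            and self.ref.upper() != self.alts[0].upper()
        )

    def allele_counts(self) -> list[int]:
        """Counts of each allele index over called genotypes only."""
        counts = [0] * self.n_alleles
        for gt in self.genotypes:
            if gt is not None:
                counts[gt[0]] += 1
                counts[gt[1]] += 1
        return counts

    def minor_allele_frequency(self) -> float:
        """MAF over called alleles (VCFtools convention); 0 when no calls."""
        counts = self.allele_counts()
        total = sum(counts)
        if total == 0:
            return 0.0
        return min(counts) / total if len(counts) > 1 else 0.0

    def mean_depth(self) -> Optional[float]:
        dps = [d for d in self.depths if d is not None]
        if not dps:
            return None
        return sum(dps) / len(dps)


@dataclass
class CDSSegment:
    interval: Interval
    phase: int = 0


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    cds: list[CDSSegment] = field(default_factory=list)

    def coding_length(self) -> int:
        return sum(len(seg.interval) for seg in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    span: Interval
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def length(self) -> int:
        """Annotation span length (introns included)."""
        return len(self.span)


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: str = "unknown"
    site: str = ""
    ploidy_class: str = "diploid"

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.ploidy_class not in VALID_PLOIDY:
            raise ValueError(f"unknown ploidy class {self.ploidy_class!r}")


@dataclass
class OntologyTerm:
    term_id: str
    name: str = ""
    namespace: str = "biological_process"
    parents: list[tuple[str, str]] = field(default_factory=list)  # (term_id, relation)
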