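"""Variant effect classification and per-gene impact statistics.

A minimal coding-effect annotator stands in where snpEff output is not
supplied: for a biallelic SNP inside a CDS it translates the reference
and alternate codons on the coding strand (stop gained/lost or start
lost -> HIGH/nonsense, amino-acid change -> MODERATE/missense, same
amino acid -> LOW/silent); inside a gene span but outside CDS ->
intron/MODIFIER; within the flank (5 kbp by default, the snpEff
convention) -> upstream/downstream/MODIFIER; otherwise
intergenic/MODIFIER. One annotation is produced per gene/transcript a
site touches, so a site can carry several.

Downstream statistics follow the published per-gene analysis: counts
per impact class, the moderate-impact density (moderate annotations per
kbp of annotation span, introns included), and 2-standard-deviation
outlier gene sets over either the density or the raw moderate count,
computed over genes with at least one moderate annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .types import (
    EffectAnnotation,
    GeneModel,
    Transcript,
    VariantSite,
)

log = logging.getLogger(__name__)

_FUNC_TO_TERM = {
    "nonsense": "stop_gained",
    "missense": "missense_variant",
    "silent": "synonymous_variant",
}


class EffectAnnotator:
    """Annotates variant sites against gene models and the assembly."""

    def __init__(
        self,
        gene_models: list[GeneModel],
        assembly: dict[str, str],
        flank_bp: int = 5_000,
    ) -> None:
        self.assembly = assembly
        self.flank_bp = flank_bp
        self._trees: dict[str, IntervalTree] = {}
        self._skipped_transcripts: set[str] = set()
        for gene in gene_models:
            span = gene.span
            tree = self._trees.setdefault(span.seq_id, IntervalTree())
            lo = max(0, span.start - flank_bp)
            tree.addi(lo, span.end + flank_bp, gene)
        # per-transcript coding maps: genomic pos -> coding index
        self._coding_maps: dict[str, dict[int, int]] = {}
        self._coding_pos: dict[str, list[int]] = {}
        for gene in gene_models:
            for tr in gene.transcripts:
                total = tr.coding_length()
                if total % 3 != 0:
                    log.warning(
                        "transcript %s CDS length %d not a codon multiple; skipped",
                        tr.transcript_id, total,
                    )
                    self._skipped_transcripts.add(tr.transcript_id)
                    continue
                pos = _coding_positions(tr)
                self._coding_pos[tr.transcript_id] = pos
                self._coding_maps[tr.transcript_id] = {p: k for k, p in enumerate(pos)}

    def annotate(self, site: VariantSite) -> list[EffectAnnotation]:
        if not site.is_biallelic_snp():
            raise ValueError("annotator requires a biallelic SNP")
        tree = self._trees.get(site.seq_id)
        hits = tree[site.pos] if tree is not None else set()
        if not hits:
            return [EffectAnnotation("", "MODIFIER", "intergenic",
                                     effect_term="intergenic_region")]
        out: list[EffectAnnotation] = []
        for hit in sorted(hits, key=lambda h: h.data.gene_id):
            gene: GeneModel = hit.data
            out.extend(self._annotate_gene(site, gene))
        return out

    def _annotate_gene(self, site: VariantSite, gene: GeneModel) -> list[EffectAnnotation]:
        span = gene.span
        pos = site.pos
        if pos < span.start or pos >= span.end:
            # flank: orientation depends on the gene's strand
            before = pos < span.start
            strand = span.strand if span.strand in "+-" else "+"
            if strand == "+":
                region = "upstream" if before else "downstream"
            else:
                region = "downstream" if before else "upstream"
            return [EffectAnnotation(gene.gene_id, "MODIFIER", region,
                                     effect_term=f"{region}_gene_variant")]
        anns: list[EffectAnnotation] = []
        for tr in gene.transcripts:
            if tr.transcript_id in self._skipped_transcripts:
                continue
            cmap = self._coding_maps.get(tr.transcript_id)
            if cmap is not None and pos in cmap:
                anns.append(self._coding_effect(site, gene, tr, cmap[pos]))
            else:
                anns.append(
                    EffectAnnotation(gene.gene_id, "MODIFIER", "intron",
                                     transcript_id=tr.transcript_id,
                                     effect_term="intron_variant")
                )
        if not anns:  # gene without usable transcripts
            anns.append(EffectAnnotation(gene.gene_id, "MODIFIER", "intron",
                                         effect_term="intron_variant"))
        return anns

    def _coding_effect(
        self, site: VariantSite, gene: GeneModel, tr: Transcript, k: int
    ) -> EffectAnnotation:
        seq = self.assembly[site.seq_id]
        coding_pos = self._coding_pos[tr.transcript_id]
        ci, off = divmod(k, 3)
        codon_pos = coding_pos[3 * ci:3 * ci + 3]
        codon = "".join(seq[p].upper() for p in codon_pos)
        alt_base = site.alts[0].upper()
        ref_base = site.ref.upper()
        if tr.strand == "-":
            codon = str(Seq(codon).complement())
            alt_base = str(Seq(alt_base).complement())
            ref_base = str(Seq(ref_base).complement())
        if codon[off] != ref_base:
            log.warning("reference mismatch at %s:%d (assembly %s, VCF ref %s)",
                        site.seq_id, site.pos, codon[off], ref_base)
        alt_codon = codon[:off] + alt_base + codon[off + 1:]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        start_lost = ci == 0 and aa_ref == "M" and aa_alt != "M"
        if aa_alt == "*" and aa_ref != "*":
            impact, func, term = "HIGH", "nonsense", "stop_gained"
        elif aa_ref == "*" and aa_alt != "*":
            impact, func, term = "HIGH", "nonsense", "stop_lost"
        elif start_lost:
            impact, func, term = "HIGH", "nonsense", "start_lost"
        elif aa_ref != aa_alt:
            impact, func, term = "MODERATE", "missense", "missense_variant"
        else:
            impact, func, term = "LOW", "silent", "synonymous_variant"
        return EffectAnnotation(
            gene_id=gene.gene_id,
            impact=impact,
            region="exon",
            functional_class=func,
            transcript_id=tr.transcript_id,
            effect_term=term,
        )


def _coding_positions(tr: Transcript) -> list[int]:
    segs = sorted(tr.cds, key=lambda s: s.interval.start)
    pos: list[int] = []
    for seg in segs:
        pos.extend(range(seg.interval.start, seg.interval.end))
    if tr.strand == "-":
        pos.reverse()
    return pos


def annotate_variant(
    site: VariantSite,
    gene_models: list[GeneModel],
    assembly: dict[str, str],
    flank_bp: int = 5_000,
) -> list[EffectAnnotation]:
    """One-shot convenience wrapper around :class:`EffectAnnotator`."""
    return EffectAnnotator(gene_models, assembly, flank_bp).annotate(site)


def parse_or_annotate(
    sites: Iterable[VariantSite],
    gene_models: list[GeneModel],
    assembly: dict[str, str],
    prefer_ann: bool = True,
    flank_bp: int = 5_000,
) -> list[VariantSite]:
    """Attach effect annotations to every site.

    When ``prefer_ann`` and a site already carries parsed ANN entries
    those are used verbatim; otherwise the minimal annotator runs. The
    fallback is per site, so mixed VCFs are handled; counts are logged.
    """
    annotator = EffectAnnotator(gene_models, assembly, flank_bp)
    out = []
    n_ann, n_self = 0, 0
    for site in sites:
        if prefer_ann and site.ann:
            n_ann += 1
        else:
            site.ann = annotator.annotate(site)
            n_self += 1
        out.append(site)
    log.info("annotations: %d from ANN fields, %d self-annotated", n_ann, n_self)
    return out


# ---------------------------------------------------------------------------
# per-gene impact statistics
# ---------------------------------------------------------------------------

@dataclass
class GeneImpactProfile:
    gene_id: str
    gene_length: int
    counts: dict[str, int] = field(default_factory=dict)        # annotations
    site_counts: dict[str, int] = field(default_factory=dict)   # distinct sites

    @property
    def moderate_density(self) -> float:
        """Moderate annotations per kbp of annotation span (introns in)."""
        return 1000.0 * self.counts.get("MODERATE", 0) / self.gene_length


@dataclass
class OutlierThreshold:
    metric: str
    mean: float
    sd: float
    cutoff: float
    qualifying_genes: set[str]
    population_size: int
    ddof: int = 1


def gene_impact_profiles(
    annotated_sites: Iterable[VariantSite], gene_models: list[GeneModel]
) -> list[GeneImpactProfile]:
    """Per-gene annotation counts by impact class plus the moderate
    density; genes with no annotations are included with zero counts."""
    profiles = {
        g.gene_id: GeneImpactProfile(g.gene_id, g.length,
                                     {k: 0 for k in ("HIGH", "MODERATE", "LOW", "MODIFIER")},
                                     {k: 0 for k in ("HIGH", "MODERATE", "LOW", "MODIFIER")})
        for g in gene_models
    }
    for site in annotated_sites:
        seen_site: set[tuple[str, str]] = set()
        for ann in site.ann:
            prof = profiles.get(ann.gene_id)
            if prof is None:
                continue
            prof.counts[ann.impact] += 1
            key = (ann.gene_id, ann.impact)
            if key not in seen_site:
                prof.site_counts[ann.impact] += 1
                seen_site.add(key)
    return list(profiles.values())


def outlier_genes(
    profiles: list[GeneImpactProfile],
    metric: str = "density",
    k_sd: float = 2.0,
    ddof: int = 1,
) -> OutlierThreshold:
    """2-SD outlier gene set over the moderate-impact metric.

    ``metric`` is ``density`` (moderate annotations / kbp) or ``count``
    (raw moderate annotation count). The reference population is genes
    with at least one moderate annotation, matching the published mean
    of moderate annotations per *qualifying* gene. Cutoff is
    mean + k_sd * sd (sample sd by default); genes at or above the
    cutoff qualify.
    """
    if metric not in ("density", "count"):
        raise ValueError("metric must be 'density' or 'count'")
    pop = [p for p in profiles if p.counts.get("MODERATE", 0) >= 1]
    if not pop:
        return OutlierThreshold(metric, 0.0, 0.0, 0.0, set(), 0, ddof)
    vals = np.array([
        p.moderate_density if metric == "density" else p.counts["MODERATE"]
        for p in pop
    ], dtype=float)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0
    cutoff = mean + k_sd * sd
    if sd == 0.0:
        log.warning("degenerate outlier threshold: zero variance in %s metric", metric)
    qualifying = {p.gene_id for p, v in zip(pop, vals) if v >= cutoff}
    return OutlierThreshold(metric, mean, sd, cutoff, qualifying, len(pop), ddof)


def per_individual_heterozygosity(
    sites: Iterable[VariantSite], samples: list[str]
) -> dict[str, Optional[float]]:
    """Percent heterozygous genotypes per sample over its called sites;
    None for a sample with no called genotypes."""
    n_het = np.zeros(len(samples), dtype=np.int64)
    n_called = np.zeros(len(samples), dtype=np.int64)
    for site in sites:
        for i, gt in enumerate(site.genotypes):
            if gt is not None:
                n_called[i] += 1
                if gt[0] != gt[1]:
                    n_het[i] += 1
    out: dict[str, Optional[float]] = {}
    for i, name in enumerate(samples):
        out[name] = 100.0 * n_het[i] / n_called[i] if n_called[i] else None
    return out


@dataclass
class CohortSummary:
    n_sites: int
    n_annotations: int
    impact_totals: dict[str, int]
    functional_totals: dict[str, int]
    region_totals: dict[str, int]
    genes_per_impact: dict[str, int]
    moderate_sites: int
    annotations_per_snp: float


def cohort_summary(annotated_sites: Iterable[VariantSite]) -> CohortSummary:
    """Cohort-wide annotation totals.

    ``annotations_per_snp`` is total annotations / total sites (a site
    can annotate several genes/transcripts). Moderate impact is totalled
    both per annotation (``impact_totals``) and per distinct site
    (``moderate_sites``), since the two countings differ and both are
    informative.
    """
    impact = {k: 0 for k in ("HIGH", "MODERATE", "LOW", "MODIFIER")}
    functional = {k: 0 for k in ("nonsense", "missense", "silent")}
    region = {k: 0 for k in ("exon", "intron", "upstream", "downstream", "intergenic")}
    genes: dict[str, set[str]] = {k: set() for k in impact}
    n_sites = 0
    n_ann = 0
    moderate_sites = 0
    for site in annotated_sites:
        n_sites += 1
        site_has_moderate = False
        for a in site.ann:
            n_ann += 1
            impact[a.impact] += 1
            region[a.region] += 1
            if a.functional_class in functional:
                functional[a.functional_class] += 1
            if a.gene_id:
                genes[a.impact].add(a.gene_id)
            if a.impact == "MODERATE":
                site_has_moderate = True
        if site_has_moderate:
            moderate_sites += 1
    if n_sites == 0:
        log.warning("cohort summary over zero sites; ratio reported as 0")
    return CohortSummary(
        n_sites=n_sites,
        n_annotations=n_ann,
        impact_totals=impact,
        functional_totals=functional,
        region_totals=region,
        genes_per_impact={k: len(v) for k, v in genes.items()},
        moderate_sites=moderate_sites,
        annotations_per_snp=(n_ann / n_sites if n_sites else 0.0),
    )


def annotations_per_snp(n_annotations: int, n_sites: int) -> float:
    """Mean annotations per SNP (the genome-overview headline ratio)."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    return n_annotations / n_sites


def mean_per_gene(n_annotations: int, n_genes: int) -> float:
    """Mean annotations per qualifying gene."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return n_annotations / n_genes
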