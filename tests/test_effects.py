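"""Coding-effect classification (against an independent codon-table
oracle over the full 64-codon grid, both strands), per-gene impact
profiles, 2-SD outlier thresholds and cohort summaries."""

import numpy as np
import pytest

from homeocollapse import effects
from homeocollapse.types import (
    CDSSegment,
    EffectAnnotation,
    GeneModel,
    Interval,
    Transcript,
    VariantSite,
)
from tests.test_synthio import _ORACLE, _RC


def _snp(seq_id, pos, ref, alt):
    return VariantSite(seq_id, pos, ref, [alt], [(0, 1)], [30])


def _single_exon_gene(seq_id, gene_id, start, n_codons, strand):
    end = start + 3 * n_codons
    tr = Transcript(f"t_{gene_id}", strand, [CDSSegment(Interval(seq_id, start, end, strand), 0)])
    return GeneModel(gene_id, Interval(seq_id, start, end, strand), [tr])


def _expected_class(old_codon, new_codon, codon_index):
    old_aa, new_aa = _ORACLE[old_codon], _ORACLE[new_codon]
    if old_aa == "*":
        return None  # generator never mutates within a stop codon
    if new_aa == "*":
        return ("HIGH", "nonsense")
    if codon_index == 0 and old_aa == "M" and new_aa != "M":
        return ("HIGH", "nonsense")  # start lost
    if new_aa != old_aa:
        return ("MODERATE", "missense")
    return ("LOW", "silent")


@pytest.mark.parametrize("strand", ["+", "-"])
def test_full_codon_grid_matches_oracle(strand):
    """Every codon x position x alternate base, on both strands, against
    the hand-written translation-table oracle. The probe codon sits at
    codon index 1 so start-codon special-casing stays out of scope."""
    bases = "ACGT"
    codons = [a + b + c for a in bases for b in bases for c in bases]
    gap = 20
    glen = 9
    chrom = []
    genes = []
    starts = []
    for i, codon in enumerate(codons):
        start = i * (glen + gap)
        coding = "ATG" + codon + "GGG"
        genomic = coding if strand == "+" else "".join(_RC[b] for b in reversed(coding))
        chrom.append("T" * gap + genomic)
        # gene CDS occupies the last glen bases of the block
        gstart = start + gap
        genes.append(_single_exon_gene("chrT", f"g{i:03d}", gstart, 3, strand))
        starts.append(gstart)
    assembly = {"chrT": "".join(chrom)}
    annotator = effects.EffectAnnotator(genes, assembly, flank_bp=0)

    n_checked = 0
    for i, codon in enumerate(codons):
        if _ORACLE[codon] == "*":
            continue
        for off in range(3):
            # genomic position of coding base (codon index 1, offset off)
            k = 3 + off  # coding index
            if strand == "+":
                gpos = starts[i] + k
            else:
                gpos = starts[i] + glen - 1 - k
            ref_genomic = assembly["chrT"][gpos]
            for alt_coding in bases:
                if alt_coding == codon[off]:
                    continue
                alt_genomic = alt_coding if strand == "+" else _RC[alt_coding]
                site = _snp("chrT", gpos, ref_genomic, alt_genomic)
                anns = [a for a in annotator.annotate(site) if a.region == "exon"]
                assert len(anns) == 1
                new_codon = codon[:off] + alt_coding + codon[off + 1:]
                want = _expected_class(codon, new_codon, 1)
                assert (anns[0].impact, anns[0].functional_class) == want, (
                    codon, off, alt_coding, strand
                )
                n_checked += 1
    assert n_checked == 61 * 9  # 61 non-stop codons x 3 positions x 3 alts


class TestRegions:
    assembly = {"chrR": "A" * 30_000}
    gene_plus = _single_exon_gene("chrR", "gp", 10_000, 100, "+")  # [10000,10300)
    gene_minus = _single_exon_gene("chrR", "gm", 20_000, 100, "-")

    def _ann(self, pos):
        a = effects.EffectAnnotator([self.gene_plus, self.gene_minus], self.assembly)
        return a.annotate(_snp("chrR", pos, "A", "T"))

    def test_upstream_downstream_respect_strand(self):
        (up,) = self._ann(9_000)
        assert (up.gene_id, up.region, up.impact) == ("gp", "upstream", "MODIFIER")
        (down,) = self._ann(10_500)
        assert (down.gene_id, down.region) == ("gp", "downstream")
        (m_down,) = self._ann(19_000)
        assert (m_down.gene_id, m_down.region) == ("gm", "downstream")
        (m_up,) = self._ann(20_500)
        assert (m_up.gene_id, m_up.region) == ("gm", "upstream")

    def test_intergenic(self):
        (a,) = self._ann(0)
        assert (a.region, a.impact, a.gene_id) == ("intergenic", "MODIFIER", "")

    def test_intron(self):
        seq = {"chrI": "A" * 2000}
        tr = Transcript("t1", "+", [
            CDSSegment(Interval("chrI", 100, 400, "+"), 0),
            CDSSegment(Interval("chrI", 700, 1000, "+"), 0),
        ])
        gene = GeneModel("gi", Interval("chrI", 100, 1000, "+"), [tr])
        a = effects.EffectAnnotator([gene], seq)
        (ann,) = a.annotate(_snp("chrI", 500, "A", "T"))
        assert (ann.region, ann.impact) == ("intron", "MODIFIER")

    def test_non_codon_multiple_transcript_skipped(self):
        tr = Transcript("tbad", "+", [CDSSegment(Interval("chrR", 100, 104, "+"), 0)])
        gene = GeneModel("gb", Interval("chrR", 100, 104, "+"), [tr])
        a = effects.EffectAnnotator([gene], self.assembly)
        (ann,) = a.annotate(_snp("chrR", 102, "A", "T"))
        assert ann.region == "intron"  # falls back to non-coding within the span


def test_parse_or_annotate_prefers_existing_ann(sim_small):
    site = sim_small.sites[0]
    pre = EffectAnnotation("geneX", "HIGH", "exon", "nonsense")
    site_with = VariantSite(site.seq_id, site.pos, site.ref, site.alts,
                            site.genotypes, site.depths, ann=[pre])
    out = effects.parse_or_annotate([site_with], sim_small.genes, sim_small.assembly,
                                    prefer_ann=True)
    assert out[0].ann == [pre]
    out2 = effects.parse_or_annotate([site_with], sim_small.genes, sim_small.assembly,
                                     prefer_ann=False)
    assert out2[0].ann != [pre]


def test_annotator_reproduces_truth_ledger_everywhere(sim_small):
    """100% agreement with the generator's planted impact classes, both
    strands and all codon positions."""
    ann = effects.EffectAnnotator(sim_small.genes, sim_small.assembly)
    by_pos = {(s.seq_id, s.pos): s for s in sim_small.sites}
    n = 0
    for key, entry in sim_small.truth.gene_effect_ledger.items():
        annots = ann.annotate(by_pos[key])
        hit = [a for a in annots
               if a.gene_id == entry.gene_id
               and a.impact == entry.impact
               and a.functional_class == entry.functional_class]
        assert hit, (key, entry, annots)
        n += 1
    assert n == len(sim_small.truth.gene_effect_ledger) > 50


class TestProfiles:
    def _profiles(self):
        gene = GeneModel("g1", Interval("c", 0, 2000, "+"))
        other = GeneModel("g2", Interval("c", 5000, 6000, "+"))
        sites = []
        for pos in range(4):
            sites.append(VariantSite("c", pos, "A", ["T"], [(0, 1)], [30], ann=[
                EffectAnnotation("g1", "MODERATE", "exon", "missense")
            ]))
        return effects.gene_impact_profiles(sites, [gene, other])

    def test_density_formula(self):
        profs = {p.gene_id: p for p in self._profiles()}
        assert profs["g1"].moderate_density == pytest.approx(2.0)  # 4 / 2 kbp
        assert profs["g2"].counts["MODERATE"] == 0
        assert profs["g2"].moderate_density == 0.0

    def test_density_scaling_and_shift_invariance(self):
        short = GeneModel("s", Interval("c", 100, 1100, "+"))
        long = GeneModel("l", Interval("c", 5000, 9000, "+"))
        def ann(g):
            return EffectAnnotation(g, "MODERATE", "exon", "missense")
        sites = [
            VariantSite("c", 200, "A", ["T"], [(0, 1)], [30], ann=[ann("s")]),
            VariantSite("c", 6000, "A", ["T"], [(0, 1)], [30], ann=[ann("l")]),
        ]
        profs = {p.gene_id: p for p in effects.gene_impact_profiles(sites, [short, long])}
        assert profs["s"].moderate_density == pytest.approx(4 * profs["l"].moderate_density)

    def test_annotation_conservation(self, sim_small):
        annotated = effects.parse_or_annotate(
            list(sim_small.sites[:500]), sim_small.genes, sim_small.assembly, prefer_ann=False
        )
        profs = effects.gene_impact_profiles(annotated, sim_small.genes)
        total_in_genes = sum(sum(p.counts.values()) for p in profs)
        total_gene_anns = sum(
            1 for s in annotated for a in s.ann if a.gene_id
        )
        assert total_in_genes == total_gene_anns


class TestOutliers:
    def _make(self, counts):
        profs = []
        for i, c in enumerate(counts):
            p = effects.GeneImpactProfile(f"g{i}", 1000, {"MODERATE": c, "HIGH": 0, "LOW": 0, "MODIFIER": 0})
            profs.append(p)
        return profs

    def test_count_metric_sample_sd_oracle(self):
        profs = self._make([1, 1, 1, 1, 16])
        thr = effects.outlier_genes(profs, "count")
        assert thr.mean == pytest.approx(4.0)
        assert thr.sd == pytest.approx(np.std([1, 1, 1, 1, 16], ddof=1))
        assert thr.sd == pytest.approx(6.708, abs=0.001)
        # cutoff 4 + 2*6.708 = 17.42 > 16: no gene qualifies
        assert thr.cutoff == pytest.approx(17.417, abs=0.001)
        assert thr.qualifying_genes == set()

    def test_population_excludes_zero_moderate_genes(self):
        profs = self._make([0, 0, 3, 5])
        thr = effects.outlier_genes(profs, "count")
        assert thr.population_size == 2
        assert thr.mean == pytest.approx(4.0)

    def test_degenerate_equal_metric(self):
        profs = self._make([3, 3, 3])
        thr = effects.outlier_genes(profs, "count")
        assert thr.sd == 0.0 and thr.qualifying_genes == {"g0", "g1", "g2"}

    def test_density_metric(self):
        profs = self._make([1, 1, 10])
        thr = effects.outlier_genes(profs, "density")
        vals = [1.0, 1.0, 10.0]  # per kbp with 1000 bp genes
        assert thr.cutoff == pytest.approx(np.mean(vals) + 2 * np.std(vals, ddof=1))

    def test_population_sd_option(self):
        profs = self._make([1, 1, 1, 1, 16])
        thr = effects.outlier_genes(profs, "count", ddof=0)
        assert thr.sd == pytest.approx(6.0)


class TestHeterozygosity:
    def test_fraction_of_called_sites(self):
        sites = [
            VariantSite("c", i, "A", ["T"], gts, [30, 30])
            for i, gts in enumerate([
                [(0, 1), None], [(0, 0), None], [(1, 1), None], [(0, 0), None],
            ])
        ]
        het = effects.per_individual_heterozygosity(sites, ["S1", "S2"])
        assert het["S1"] == pytest.approx(25.0)
        assert het["S2"] is None

    def test_dh_zero_after_dh_filter(self, sim_small, sample_ids):
        from homeocollapse import varfilter
        kept, _ = varfilter.filter_dh_heterozygotes(sim_small.sites, sample_ids, "DH01")
        het = effects.per_individual_heterozygosity(kept, sample_ids)
        assert het["DH01"] == 0.0
        assert any(v > 0 for k, v in het.items() if k != "DH01" and v is not None)


class TestCohortSummary:
    def test_headline_ratios(self):
        assert effects.annotations_per_snp(28_683_938, 8_383_963) == pytest.approx(3.42, abs=0.005)
        assert round(effects.annotations_per_snp(28_683_938, 8_383_963), 1) == 3.4
        assert effects.mean_per_gene(73_405, 22_914) == pytest.approx(3.20, abs=0.005)

    def test_summary_counts(self):
        sites = [
            VariantSite("c", 0, "A", ["T"], [(0, 1)], [30], ann=[
                EffectAnnotation("g1", "MODERATE", "exon", "missense"),
                EffectAnnotation("g2", "MODIFIER", "intron"),
            ]),
            VariantSite("c", 5, "A", ["T"], [(0, 1)], [30], ann=[
                EffectAnnotation("g1", "MODERATE", "exon", "missense"),
            ]),
        ]
        s = effects.cohort_summary(sites)
        assert s.n_sites == 2 and s.n_annotations == 3
        assert s.annotations_per_snp == pytest.approx(1.5)
        assert s.impact_totals["MODERATE"] == 2
        assert s.moderate_sites == 2
        assert s.genes_per_impact["MODERATE"] == 1
        assert s.functional_totals["missense"] == 2

    def test_empty_input(self):
        s = effects.cohort_summary([])
        assert s.annotations_per_snp == 0.0 and s.n_sites == 0
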