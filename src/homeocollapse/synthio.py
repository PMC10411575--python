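"""Deterministic generator of a post-whole-genome-duplication test dataset.

The generator emulates the salient structure of a salmonid-style genome
that retains homeologous chromosome pairs from an ancestral duplication:

* each homeolog pair is an ancestral sequence duplicated, with the second
  copy diverged by point substitution at a configurable rate (~9%
  divergence, i.e. ~91% identity, typical of residually tetraploid
  regions);
* selected spans are *collapsed*: the assembly carries a single copy and
  the sister haplotype survives only as doubled read depth plus
  paralogous sequence variants (PSVs) that genotype as heterozygous in
  every sample — including a doubled haploid, where true heterozygosity
  is impossible;
* a diploid cohort with Beta-distributed allele frequencies, one doubled
  haploid, per-sample windowed depth tracks;
* multi-exon genes on both strands with planted coding variants of known
  impact (missense / synonymous / stop-gain), a tandem block of
  "hotspot" genes dense in missense variants, and a small GO DAG in
  which one term is truly enriched among the hotspot genes;
* a male-specific contig (the sdY model: covered and genotyped in males,
  absent in females) and autosomal windows carrying an exact copy of a
  male-specific repeat, which show male-biased depth and sex-correlated
  PSV-like genotypes — the classic false-positive mode of a sex GWAS.

Everything is drawn from a single numpy Generator seeded from the
config, and files are emitted in fixed order, so identical configs give
byte-identical outputs. Depth is simulated per window rather than per
read: the downstream collapse detector only ever sees windowed means, so
read placement would add an aligner dependency without adding testable
structure.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import formats
from .types import (
    AlignmentRecord,
    CDSSegment,
    GeneModel,
    Interval,
    OntologyTerm,
    Sample,
    Transcript,
    VariantSite,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SexConfig:
    n_males: int = 10
    n_females: int = 10
    sdy_contig_length: int = 100_000
    n_repeat_windows: int = 2


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset (defaults are desk scale:
    4 homeolog pairs x 10 Mbp, one 3 Mbp collapsed span, 20 diploids + 1
    doubled haploid, mean depth 30)."""

    seed: int = 2023
    n_homeolog_pairs: int = 4
    chrom_length: int = 10_000_000
    diverged_rate: float = 0.09
    collapsed_psv_rate: float = 0.01
    collapsed_spans: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(0, 2_000_000, 5_000_000)]
    )
    n_diploids: int = 20
    include_dh: bool = True
    mean_depth: float = 30.0
    allele_freq_shape: tuple[float, float] = (0.5, 1.5)
    allelic_snp_rate: float = 0.0005
    genes_per_chrom: int = 25
    moderate_hotspot_genes: int = 6
    hotspot_min_moderate: int = 13
    background_moderate_mean: float = 2.0
    missing_rate: float = 0.02
    depth_window_bp: int = 10_000
    aln_chunk_bp: int = 100_000
    mask_fraction: float = 0.30
    repeat_unit_bp: int = 2_000
    n_sdy_markers: int = 20
    sex: SexConfig = field(default_factory=SexConfig)

    def __post_init__(self) -> None:
        if self.n_homeolog_pairs < 1:
            raise ValueError("need at least one homeolog pair")
        if not (0.0 < self.diverged_rate < 1.0 and 0.0 < self.collapsed_psv_rate < 1.0):
            raise ValueError("substitution rates must lie in (0, 1)")
        if self.n_diploids < 2:
            raise ValueError("n_diploids < 2: cohort frequency estimates undefined")
        if self.sex.n_males + self.sex.n_females != self.n_diploids:
            raise ValueError("sex counts must sum to n_diploids")
        spans_by_pair: dict[int, list[tuple[int, int]]] = {}
        for pair, start, end in self.collapsed_spans:
            if not (0 <= pair < self.n_homeolog_pairs):
                raise ValueError(f"collapsed span on unknown pair {pair}")
            if not (0 <= start < end <= self.chrom_length):
                raise ValueError("collapsed span outside chromosome bounds")
            spans_by_pair.setdefault(pair, []).append((start, end))
        for spans in spans_by_pair.values():
            spans.sort()
            for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise ValueError("collapsed spans overlap")


@dataclass
class LedgerEntry:
    gene_id: str
    impact: str
    functional_class: str
    freq: float
    ref: str
    alt: str


@dataclass
class SimTruth:
    """Machine-readable ground truth for every planted feature.

    Each planted variant appears in exactly one ledger: ``psv_sites``
    (paralogous, heterozygous in everyone), ``allelic_sites`` (neutral
    cohort SNPs with their true frequencies), ``gene_effect_ledger``
    (coding variants with their true impact), ``sdy_sites`` or
    ``repeat_snps`` (the sex system).
    """

    collapsed_intervals: list[Interval] = field(default_factory=list)
    psv_sites: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)
    allelic_sites: dict[tuple[str, int], float] = field(default_factory=dict)
    gene_effect_ledger: dict[tuple[str, int], LedgerEntry] = field(default_factory=dict)
    sdy_sites: list[tuple[str, int]] = field(default_factory=list)
    repeat_snps: list[tuple[str, int]] = field(default_factory=list)
    sex_of_sample: dict[str, str] = field(default_factory=dict)
    sdy_contig: str = ""
    planted_repeat_windows: list[Interval] = field(default_factory=list)
    hotspot_genes: list[str] = field(default_factory=list)
    hotspot_term: str = ""

    def to_json(self) -> str:
        def iv(i: Interval) -> dict:
            return {"seq_id": i.seq_id, "start": i.start, "end": i.end}

        payload = {
            "collapsed_intervals": [iv(i) for i in self.collapsed_intervals],
            "psv_sites": [
                {"seq_id": k[0], "pos": k[1], "ref": v[0], "alt": v[1]}
                for k, v in sorted(self.psv_sites.items())
            ],
            "allelic_sites": [
                {"seq_id": k[0], "pos": k[1], "freq": v}
                for k, v in sorted(self.allelic_sites.items())
            ],
            "gene_effect_ledger": [
                {"seq_id": k[0], "pos": k[1], **dataclasses.asdict(v)}
                for k, v in sorted(self.gene_effect_ledger.items())
            ],
            "sdy_sites": [{"seq_id": s, "pos": p} for s, p in self.sdy_sites],
            "repeat_snps": [{"seq_id": s, "pos": p} for s, p in self.repeat_snps],
            "sex_of_sample": self.sex_of_sample,
            "sdy_contig": self.sdy_contig,
            "planted_repeat_windows": [iv(i) for i in self.planted_repeat_windows],
            "hotspot_genes": self.hotspot_genes,
            "hotspot_term": self.hotspot_term,
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]

def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Point-substitute a copy of ``seq`` at the given per-base rate."""
    out = seq.copy()
    pos = np.flatnonzero(rng.random(seq.size) < rate)
    if pos.size:
        # shift each hit base by 1-3 in A,C,G,T order: always a different base
        idx = np.searchsorted(_BASES, out[pos])
        out[pos] = _BASES[(idx + rng.integers(1, 4, size=pos.size)) % 4]
    return out

def _seq_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")

def _pair_names(i: int) -> tuple[str, str]:
    return f"LG{2 * i + 1:02d}", f"LG{2 * i + 2:02d}"

def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def simulate_assembly(
    cfg: SimConfig,
) -> tuple[dict[str, np.ndarray], SimTruth, list[AlignmentRecord]]:
    """Build the assembly, collapse truth and the homeolog alignment table.

    Returns sequences as uint8 numpy arrays (ASCII codes); use
    :func:`finalize_assembly` to apply soft-masking and obtain strings.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = SimTruth()
    assembly: dict[str, np.ndarray] = {}
    alignments: list[AlignmentRecord] = []

    spans_by_pair: dict[int, list[tuple[int, int]]] = {}
    for pair, start, end in cfg.collapsed_spans:
        spans_by_pair.setdefault(pair, []).append((start, end))
    for spans in spans_by_pair.values():
        spans.sort()

    sexcfg = cfg.sex
    repeat_pair = cfg.n_homeolog_pairs - 1
    repeat_unit = _random_seq(rng, cfg.repeat_unit_bp)
    repeat_positions: list[int] = []
    if sexcfg.n_repeat_windows:
        if repeat_pair in spans_by_pair:
            raise ValueError("repeat windows and collapsed spans share a pair; "
                             "use >=2 homeolog pairs when planting repeats")
        step = cfg.chrom_length // (sexcfg.n_repeat_windows + 2)
        wbp = cfg.depth_window_bp
        for k in range(sexcfg.n_repeat_windows):
            wstart = ((k + 1) * step // wbp) * wbp
            repeat_positions.append(wstart)

    for i in range(cfg.n_homeolog_pairs):
        name_a, name_b = _pair_names(i)
        anc = _random_seq(rng, cfg.chrom_length)
        if i == repeat_pair:
            for wstart in repeat_positions:
                off = wstart + (cfg.depth_window_bp - cfg.repeat_unit_bp) // 2
                anc[off:off + cfg.repeat_unit_bp] = repeat_unit
                truth.planted_repeat_windows.append(
                    Interval(name_a, wstart, wstart + cfg.depth_window_bp)
                )
        div = _mutate(rng, anc, cfg.diverged_rate)
        spans = spans_by_pair.get(i, [])

        # PSVs: within collapsed spans the unassembled sister haplotype
        # differs from the carried copy at collapsed_psv_rate
        for s, e in spans:
            pos = np.flatnonzero(rng.random(e - s) < cfg.collapsed_psv_rate) + s
            shift = rng.integers(1, 4, size=pos.size)
            for p, sh in zip(pos.tolist(), shift.tolist()):
                ref = chr(anc[p])
                alt = _BASE_STR[(_BASE_STR.index(ref) + int(sh)) % 4]
                truth.psv_sites[(name_a, int(p))] = (ref, alt)
            truth.collapsed_intervals.append(Interval(name_a, s, e))

        # copy b: diverged copy with collapsed spans deleted
        keep = np.ones(cfg.chrom_length, dtype=bool)
        for s, e in spans:
            keep[s:e] = False
        copy_b = div[keep]

        # alignment table over non-collapsed regions, chunked
        bounds = [0]
        for s, e in spans:
            bounds.extend([s, e])
        bounds.append(cfg.chrom_length)
        for rs, re_ in zip(bounds[0::2], bounds[1::2]):
            region_len = re_ - rs
            if region_len <= 0:
                continue
            deleted = sum(e - s for s, e in spans if e <= rs)
            n_chunks = max(1, region_len // cfg.aln_chunk_bp)
            edges = [rs + k * cfg.aln_chunk_bp for k in range(n_chunks)] + [re_]
            for cs, ce in zip(edges, edges[1:]):
                ident = 100.0 * float(np.mean(anc[cs:ce] == div[cs:ce]))
                alignments.append(
                    AlignmentRecord(
                        query=Interval(name_a, cs, ce, "+"),
                        subject=Interval(name_b, cs - deleted, ce - deleted, "+"),
                        pct_identity=round(ident, 2),
                        aln_length=ce - cs,
                        bitscore=float(ce - cs),
                    )
                )

        assembly[name_a] = anc
        assembly[name_b] = copy_b

    # male-specific contig carrying one exact copy of the repeat unit
    sdy_name = "contig_sdY"
    sdy = _random_seq(rng, sexcfg.sdy_contig_length)
    if repeat_positions:
        off = sexcfg.sdy_contig_length // 2
        sdy[off:off + cfg.repeat_unit_bp] = repeat_unit
    assembly[sdy_name] = sdy
    truth.sdy_contig = sdy_name
    return assembly, truth, alignments


def finalize_assembly(
    assembly: dict[str, np.ndarray], truth: SimTruth, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Apply lowercase soft-masking (random blocks at ``mask_fraction``
    plus the planted repeat windows) and return sequences as strings."""
    masked: dict[str, str] = {}
    block = 5_000
    for name, arr in assembly.items():
        lower = np.zeros(arr.size, dtype=bool)
        n_blocks = int(cfg.mask_fraction * arr.size / block)
        if n_blocks and arr.size > block:
            starts = rng.integers(0, arr.size - block, size=n_blocks)
            for s in starts.tolist():
                lower[s:s + block] = True
        for iv in truth.planted_repeat_windows:
            if iv.seq_id == name:
                lower[iv.start:iv.end] = True
        out = arr.copy()
        out[lower] += 32  # ASCII lowercase
        masked[name] = _seq_str(out)
    return masked


# ---------------------------------------------------------------------------
# gene models, coding variants, GO
# ---------------------------------------------------------------------------

_EXON_OFFSETS = [(200, 500), (1_500, 1_800), (3_200, 3_500)]  # 900 bp CDS
_GENE_SPAN = 4_000


def _coding_positions(tr: Transcript) -> list[int]:
    """Genomic position of each coding base, in translation order."""
    segs = sorted(tr.cds, key=lambda s: s.interval.start)
    pos: list[int] = []
    for seg in segs:
        pos.extend(range(seg.interval.start, seg.interval.end))
    if tr.strand == "-":
        pos.reverse()
    return pos


def _plant_variant(
    rng: np.random.Generator,
    seq: np.ndarray,
    tr: Transcript,
    coding_pos: list[int],
    used: set[int],
    want: str,
) -> tuple[int, str, str] | None:
    """Find a coding position and alt base producing the wanted class
    (missense/silent/nonsense). Returns (genomic pos, ref, alt) on the
    forward genomic strand, or None after bounded retries."""
    n = len(coding_pos)
    for _ in range(80):
        k = int(rng.integers(0, n))
        gpos = coding_pos[k]
        if gpos in used:
            continue
        ci, off = divmod(k, 3)
        codon_gpos = coding_pos[3 * ci:3 * ci + 3]
        codon = "".join(chr(seq[p]).upper() for p in codon_gpos)
        if tr.strand == "-":
            codon = "".join(_COMPLEMENT[b] for b in codon)
        aa = _CODON_TABLE[codon]
        if aa == "*":
            continue
        choices = [b for b in _BASE_STR if b != codon[off]]
        rng.shuffle(choices)
        for alt_coding in choices:
            new_codon = codon[:off] + alt_coding + codon[off + 1:]
            new_aa = _CODON_TABLE[new_codon]
            cls = (
                "nonsense" if new_aa == "*" else "silent" if new_aa == aa else "missense"
            )
            if cls != want:
                continue
            ref = chr(seq[gpos]).upper()
            alt = _COMPLEMENT[alt_coding] if tr.strand == "-" else alt_coding
            used.add(gpos)
            return gpos, ref, alt
    return None


def simulate_annotations(
    assembly: dict[str, np.ndarray],
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[GeneModel], dict[str, set[str]], list[OntologyTerm]]:
    """Tile multi-exon genes on both strands, plant coding variants of
    known effect (ledger-recorded), and build a small GO DAG with one
    term truly enriched among the missense-hotspot genes."""
    genes: list[GeneModel] = []
    impact_of = {"missense": "MODERATE", "silent": "LOW", "nonsense": "HIGH"}
    chrom_names = [n for n in assembly if n != truth.sdy_contig]
    all_gene_entries: list[tuple[GeneModel, Transcript, str]] = []
    for name in chrom_names:
        seq = assembly[name]
        L = seq.size
        spacing = L // (cfg.genes_per_chrom + 1)
        if spacing < 2 * _GENE_SPAN:
            raise ValueError("chromosome too short for requested gene count")
        for gi in range(cfg.genes_per_chrom):
            g0 = (gi + 1) * spacing
            strand = "+" if gi % 2 == 0 else "-"
            gene_id = f"g_{name}_{gi:03d}"
            tid = f"t_{name}_{gi:03d}"
            segs = [
                CDSSegment(Interval(name, g0 + a, g0 + b, strand), 0)
                for a, b in _EXON_OFFSETS
            ]
            tr = Transcript(tid, strand, segs)
            gene = GeneModel(gene_id, Interval(name, g0, g0 + _GENE_SPAN, strand), [tr])
            genes.append(gene)
            all_gene_entries.append((gene, tr, name))

    # hotspot genes: a tandem block on the first chromosome
    n_hot = min(cfg.moderate_hotspot_genes, cfg.genes_per_chrom)
    hot_ids = {e[0].gene_id for e in all_gene_entries[:n_hot]}
    truth.hotspot_genes = sorted(hot_ids)

    used_positions: set[int] = set()
    used_by_seq: dict[str, set[int]] = {}
    for gene, tr, name in all_gene_entries:
        seq = assembly[name]
        used = used_by_seq.setdefault(name, set(
            p for (s, p) in truth.psv_sites if s == name
        ))
        coding_pos = _coding_positions(tr)
        if gene.gene_id in hot_ids:
            n_mis = cfg.hotspot_min_moderate + int(rng.poisson(3))
        else:
            n_mis = int(rng.poisson(cfg.background_moderate_mean))
        n_sil = int(rng.poisson(1.0))
        n_non = int(rng.random() < 0.10)
        wants = ["missense"] * n_mis + ["silent"] * n_sil + ["nonsense"] * n_non
        for want in wants:
            planted = _plant_variant(rng, seq, tr, coding_pos, used, want)
            if planted is None:
                continue
            gpos, ref, alt = planted
            if gene.gene_id in hot_ids and want == "missense":
                # intermediate-frequency haploblock variants, as seen in
                # tandem immune-gene clusters
                freq = float(np.clip(rng.beta(2.0, 2.0), 0.15, 0.85))
            else:
                a, b = cfg.allele_freq_shape
                freq = float(np.clip(rng.beta(a, b), 0.08, 0.95))
            truth.gene_effect_ledger[(name, gpos)] = LedgerEntry(
                gene_id=gene.gene_id,
                impact=impact_of[want],
                functional_class=want,
                freq=freq,
                ref=ref,
                alt=alt,
            )

    gene2go, terms = _build_ontology(truth, [g.gene_id for g in genes], rng)
    return genes, gene2go, terms


def _build_ontology(
    truth: SimTruth, gene_ids: list[str], rng: np.random.Generator
) -> tuple[dict[str, set[str]], list[OntologyTerm]]:
    root = OntologyTerm("GO:0000001", "biological_process", "biological_process", [])
    mids = [
        OntologyTerm(f"GO:00000{10 + i}", f"process_group_{i}", "biological_process",
                     [("GO:0000001", "is_a")])
        for i in range(4)
    ]
    leaves = []
    for i in range(16):
        parent = mids[i % 4].term_id
        rel = "is_a" if i % 3 else "part_of"
        leaves.append(
            OntologyTerm(f"GO:00001{i:02d}", f"leaf_process_{i}", "biological_process",
                         [(parent, rel)])
        )
    hotspot_term = "GO:0000100"
    truth.hotspot_term = hotspot_term
    mapping: dict[str, set[str]] = {}
    leaf_ids = [t.term_id for t in leaves]
    for g in gene_ids:
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(leaf_ids), size=k, replace=False)
        mapping[g] = {leaf_ids[int(p)] for p in picks}
        # keep the planted-enrichment term rare outside the hotspot block
        if g not in truth.hotspot_genes:
            mapping[g].discard(hotspot_term)
    for g in truth.hotspot_genes:
        mapping[g].add(hotspot_term)
    # a couple of background genes share the term (K > k)
    others = [g for g in gene_ids if g not in truth.hotspot_genes]
    for idx in rng.choice(len(others), size=min(3, len(others)), replace=False):
        mapping[others[int(idx)]].add(hotspot_term)
    return mapping, [root] + mids + leaves


def write_obo(terms: list[OntologyTerm], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for t in terms:
            fh.write(f"\n[Term]\nid: {t.term_id}\nname: {t.name}\n")
            fh.write(f"namespace: {t.namespace}\n")
            for parent, rel in t.parents:
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! {parent}\n")


# ---------------------------------------------------------------------------
# cohort: genotypes and depth
# ---------------------------------------------------------------------------

def _make_samples(cfg: SimConfig) -> list[Sample]:
    samples = []
    for i in range(cfg.sex.n_males):
        samples.append(Sample(f"M{i + 1:02d}", "male", "SiteA" if i % 2 == 0 else "SiteB"))
    for i in range(cfg.sex.n_females):
        samples.append(Sample(f"F{i + 1:02d}", "female", "SiteA" if i % 2 == 0 else "SiteB"))
    if cfg.include_dh:
        samples.append(Sample("DH01", "female", "InchCreek", "doubled_haploid"))
    return samples


def simulate_cohort(
    assembly: dict[str, np.ndarray],
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[VariantSite], list[Sample], dict[str, dict[str, list[tuple[int, int, float]]]]]:
    """Draw cohort genotypes and per-sample windowed depth tracks.

    Allelic sites: Beta(a,b) frequencies, binomial diploid genotypes, the
    doubled haploid homozygous. PSV sites: every sample heterozygous with
    depth around 2*lambda. sdY contig: called in males, missing in
    females. Planted repeat windows: male-biased depth and male-correlated
    heterozygosity.
    """
    samples = _make_samples(cfg)
    truth.sex_of_sample = {s.sample_id: s.sex for s in samples}
    n = len(samples)
    is_male = np.array([s.sex == "male" for s in samples])
    dh_idx = next((i for i, s in enumerate(samples) if s.ploidy_class == "doubled_haploid"), None)
    lam = cfg.mean_depth

    collapsed_by_seq: dict[str, list[tuple[int, int]]] = {}
    for iv in truth.collapsed_intervals:
        collapsed_by_seq.setdefault(iv.seq_id, []).append((iv.start, iv.end))

    taken: dict[str, set[int]] = {}
    for (s, p) in truth.psv_sites:
        taken.setdefault(s, set()).add(p)
    for (s, p) in truth.gene_effect_ledger:
        taken.setdefault(s, set()).add(p)

    # --- allelic background sites (outside collapsed spans) -----------------
    a_shape, b_shape = cfg.allele_freq_shape
    for name in sorted(k for k in assembly if k != truth.sdy_contig):
        L = assembly[name].size
        pos = np.flatnonzero(rng.random(L) < cfg.allelic_snp_rate)
        spans = collapsed_by_seq.get(name, [])
        keep = []
        t = taken.get(name, set())
        for p in pos.tolist():
            if any(s <= p < e for s, e in spans) or p in t:
                continue
            keep.append(p)
        freqs = rng.beta(a_shape, b_shape, size=len(keep))
        for p, f in zip(keep, freqs.tolist()):
            truth.allelic_sites[(name, int(p))] = float(f)

    sites: list[VariantSite] = []

    def depth_vec(mean: float) -> list[int]:
        return [int(d) for d in rng.poisson(mean, size=n)]

    def build_allelic(name: str, p: int, freq: float, ref: str, alt: str) -> VariantSite:
        alleles = rng.random((n, 2)) < freq
        miss = rng.random(n) < cfg.missing_rate
        gts: list = []
        for i in range(n):
            if miss[i]:
                gts.append(None)
            elif i == dh_idx:
                x = int(alleles[i, 0])
                gts.append((x, x))
            else:
                a, b = int(alleles[i, 0]), int(alleles[i, 1])
                gts.append((min(a, b), max(a, b)))
        dps = depth_vec(lam)
        depths = [None if gts[i] is None else dps[i] for i in range(n)]
        return VariantSite(name, p, ref, [alt], gts, depths)

    for (name, p), freq in sorted(truth.allelic_sites.items()):
        ref = chr(assembly[name][p]).upper()
        alt = _BASE_STR[(_BASE_STR.index(ref) + int(rng.integers(1, 4))) % 4]
        sites.append(build_allelic(name, p, freq, ref, alt))

    for (name, p), entry in sorted(truth.gene_effect_ledger.items()):
        sites.append(build_allelic(name, p, entry.freq, entry.ref, entry.alt))

    # --- PSV sites: heterozygous in everyone, doubled depth -----------------
    for (name, p), (ref, alt) in sorted(truth.psv_sites.items()):
        gts = [(0, 1)] * n
        depths = depth_vec(2 * lam)
        sites.append(VariantSite(name, p, ref, [alt], gts, depths))

    # --- sdY contig markers --------------------------------------------------
    sdy = truth.sdy_contig
    sdy_len = assembly[sdy].size
    marker_pos = sorted(
        int(p) for p in rng.choice(sdy_len // 4, size=cfg.n_sdy_markers, replace=False)
    )  # first quarter: away from the planted repeat copy in the middle
    for p in marker_pos:
        ref = chr(assembly[sdy][p]).upper()
        alt = _BASE_STR[(_BASE_STR.index(ref) + int(rng.integers(1, 4))) % 4]
        gts: list = []
        depths: list = []
        dps = rng.poisson(lam, size=n)
        for i in range(n):
            if is_male[i]:
                x = int(rng.random() < 0.3)
                gts.append((x, x))
                depths.append(int(dps[i]))
            else:
                gts.append(None)
                depths.append(0)
        sites.append(VariantSite(sdy, p, ref, [alt], gts, depths))
        truth.sdy_sites.append((sdy, p))

    # --- repeat-window sex-correlated PSV-like sites ------------------------
    for iv in truth.planted_repeat_windows:
        p = (iv.start + iv.end) // 2
        ref = chr(assembly[iv.seq_id][p]).upper()
        alt = _BASE_STR[(_BASE_STR.index(ref) + 1) % 4]
        gts = [(0, 1) if is_male[i] else (0, 0) for i in range(n)]
        dps_m = rng.poisson(2 * lam, size=n)
        dps_f = rng.poisson(lam, size=n)
        depths = [int(dps_m[i]) if is_male[i] else int(dps_f[i]) for i in range(n)]
        sites.append(VariantSite(iv.seq_id, p, ref, [alt], gts, depths))
        truth.repeat_snps.append((iv.seq_id, p))

    sites.sort(key=lambda s: (s.seq_id, s.pos))

    # --- depth tracks --------------------------------------------------------
    wbp = cfg.depth_window_bp
    repeat_windows = {(iv.seq_id, iv.start) for iv in truth.planted_repeat_windows}
    tracks: dict[str, dict[str, list[tuple[int, int, float]]]] = {}
    for si, sample in enumerate(samples):
        track: dict[str, list[tuple[int, int, float]]] = {}
        for name in sorted(assembly):
            L = assembly[name].size
            starts = np.arange(0, L, wbp)
            base = lam
            if name == sdy:
                base = lam if is_male[si] else 0.0
            means = np.full(starts.size, float(base))
            for s, e in collapsed_by_seq.get(name, []):
                inside = (starts >= s) & (starts < e)
                means[inside] = 2 * lam
            for k, ws in enumerate(starts.tolist()):
                if (name, ws) in repeat_windows and is_male[si]:
                    means[k] = 10 * lam
            vals = np.where(means > 0, rng.poisson(np.maximum(means, 1e-9)), 0.0)
            track[name] = [
                (int(ws), int(min(ws + wbp, L)), float(v))
                for ws, v in zip(starts.tolist(), vals.tolist())
            ]
        tracks[sample.sample_id] = track
    return sites, samples, tracks


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    assembly: dict[str, str]
    truth: SimTruth
    alignments: list[AlignmentRecord]
    genes: list[GeneModel]
    gene2go: dict[str, set[str]]
    ontology: list[OntologyTerm]
    sites: list[VariantSite]
    samples: list[Sample]
    depth_tracks: dict[str, dict[str, list[tuple[int, int, float]]]]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.assembly.items()}

    def write(self, outdir: str | os.PathLike) -> dict[str, str]:
        """Write every artefact; returns a name -> path map."""
        outdir = os.fspath(outdir)
        os.makedirs(outdir, exist_ok=True)
        depth_dir = os.path.join(outdir, "depth")
        os.makedirs(depth_dir, exist_ok=True)
        paths = {
            "assembly": os.path.join(outdir, "assembly.fasta"),
            "alignments": os.path.join(outdir, "homeolog_alignments.tsv"),
            "vcf": os.path.join(outdir, "cohort.vcf"),
            "gff3": os.path.join(outdir, "genes.gff3"),
            "gene2go": os.path.join(outdir, "gene2go.tsv"),
            "obo": os.path.join(outdir, "ontology.obo"),
            "samples": os.path.join(outdir, "samples.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        formats.write_fasta(self.assembly, paths["assembly"])
        formats.write_alignments_blast6(self.alignments, paths["alignments"])
        formats.write_vcf(
            self.sites, [s.sample_id for s in self.samples], paths["vcf"],
            contigs=self.contig_lengths,
        )
        formats.write_gff3(self.genes, paths["gff3"])
        formats.write_gene2go(self.gene2go, paths["gene2go"])
        write_obo(self.ontology, paths["obo"])
        formats.write_sample_sheet(self.samples, paths["samples"])
        with open(paths["truth"], "w") as fh:
            fh.write(self.truth.to_json())
        for sample_id, track in self.depth_tracks.items():
            p = os.path.join(depth_dir, f"{sample_id}.bedgraph")
            formats.write_bedgraph(track, p)
            paths[f"depth:{sample_id}"] = p
        return paths


def simulate(cfg: SimConfig | None = None) -> SimResult:
    """Run the full generator: assembly, annotations, cohort, depth."""
    cfg = cfg or SimConfig()
    raw_assembly, truth, alignments = simulate_assembly(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    genes, gene2go, ontology = simulate_annotations(raw_assembly, truth, cfg, rng)
    sites, samples, tracks = simulate_cohort(raw_assembly, truth, cfg, rng)
    assembly = finalize_assembly(raw_assembly, truth, cfg, rng)
    return SimResult(
        config=cfg,
        assembly=assembly,
        truth=truth,
        alignments=alignments,
        genes=genes,
        gene2go=gene2go,
        ontology=ontology,
        sites=sites,
        samples=samples,
        depth_tracks=tracks,
    )
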