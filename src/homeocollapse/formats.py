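"""Readers and writers for every external format the pipeline touches.

Everything downstream of this module is format-agnostic: coordinates come
out 0-based half-open regardless of the source dialect (VCF and GFF3 are
1-based, BLAST tabular is 1-based inclusive with reversed subject
coordinates on minus-strand hits, PAF is already 0-based half-open).

Established parsers are used where they exist: Bio.SeqIO for FASTA, cyvcf2
for VCF, gffutils for GFF3 and obonet for OBO. The remaining formats
(BLAST outfmt 6, PAF, bedGraph, the TSV sample sheet and gene-to-GO map)
are plain tab tables read directly.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Iterator, Optional

import gffutils
import networkx as nx
import obonet
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .types import (
    AlignmentRecord,
    CDSSegment,
    EffectAnnotation,
    GeneModel,
    Interval,
    OntologyTerm,
    Sample,
    Transcript,
    VariantSite,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an id -> sequence map, preserving case.

    Lowercase soft-masking is kept verbatim; the record id is the first
    whitespace-delimited token of the header. Duplicate ids and empty
    files are errors.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Pairwise alignment tables (BLAST outfmt 6 and PAF)
# ---------------------------------------------------------------------------

_BLAST6_NCOLS = 12


def _parse_blast6_row(fields: list[str], lineno: int) -> AlignmentRecord:
    if len(fields) < _BLAST6_NCOLS:
        raise ValueError(
            f"line {lineno}: expected {_BLAST6_NCOLS} blast6 columns, got {len(fields)}"
        )
    qseqid, sseqid = fields[0], fields[1]
    pident = float(fields[2])
    length = int(fields[3])
    qstart, qend = int(fields[6]), int(fields[7])
    sstart, send = int(fields[8]), int(fields[9])
    bitscore = float(fields[11])
    # blast6 is 1-based inclusive; the query is always forward.
    query = Interval(qseqid, qstart - 1, qend, "+")
    if sstart <= send:
        subject = Interval(sseqid, sstart - 1, send, "+")
    else:
        subject = Interval(sseqid, send - 1, sstart, "-")
    return AlignmentRecord(query, subject, pident, length, bitscore)


def _parse_paf_row(fields: list[str], lineno: int) -> AlignmentRecord:
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: PAF rows need >= 12 columns, got {len(fields)}")
    qname = fields[0]
    qstart, qend = int(fields[2]), int(fields[3])
    strand = fields[4]
    tname = fields[5]
    tstart, tend = int(fields[7]), int(fields[8])
    nmatch = int(fields[9])
    block = int(fields[10])
    if block <= 0:
        raise ValueError(f"line {lineno}: PAF block length must be positive")
    query = Interval(qname, qstart, qend, "+")
    subject = Interval(tname, tstart, tend, strand)
    return AlignmentRecord(query, subject, 100.0 * nmatch / block, block, 0.0)


def read_alignments(path: str | os.PathLike, dialect: str = "blast6") -> list[AlignmentRecord]:
    """Read a pairwise alignment table (``blast6`` or ``paf``).

    All coordinates are normalised to 0-based half-open; blast6 subject
    hits with start > end become minus-strand records with the
    coordinates swapped. PAF identity is matches / block length.
    """
    if dialect not in ("blast6", "paf"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    parse = _parse_blast6_row if dialect == "blast6" else _parse_paf_row
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                records.append(parse(line.split("\t"), lineno))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return records


def write_alignments_blast6(records: Iterable[AlignmentRecord], path: str | os.PathLike) -> None:
    """Emit records in BLAST outfmt-6 (mismatch/gapopen/evalue as zeros)."""
    with open(path, "w") as fh:
        for r in records:
            if r.subject.strand == "-":
                sstart, send = r.subject.end, r.subject.start + 1
            else:
                sstart, send = r.subject.start + 1, r.subject.end
            fh.write(
                "\t".join(
                    [
                        r.query.seq_id,
                        r.subject.seq_id,
                        f"{r.pct_identity:.2f}",
                        str(r.aln_length),
                        "0",
                        "0",
                        str(r.query.start + 1),
                        str(r.query.end),
                        str(sstart),
                        str(send),
                        "0.0",
                        f"{r.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNPEFF_REGION_MAP = {
    "intron_variant": "intron",
    "upstream_gene_variant": "upstream",
    "downstream_gene_variant": "downstream",
    "intergenic_region": "intergenic",
    "intergenic_variant": "intergenic",
}

_SNPEFF_FUNCTIONAL_MAP = {
    "stop_gained": "nonsense",
    "missense_variant": "missense",
    "synonymous_variant": "silent",
}


def parse_ann_field(ann_value: str) -> list[EffectAnnotation]:
    """Parse a snpEff-style ``ANN`` INFO value.

    Only the sub-fields this pipeline consumes are retained: allele (0),
    effect term (1), impact class (2) and gene id (3). Fine-grained
    snpEff effects collapse onto the five-region scheme; unmapped coding
    effects default to the exon region.
    """
    annotations = []
    for entry in ann_value.split(","):
        fields = entry.split("|")
        if len(fields) < 4:
            continue
        effect_term, impact, gene = fields[1], fields[2], fields[3]
        impact = impact.upper()
        if impact not in ("HIGH", "MODERATE", "LOW", "MODIFIER"):
            continue
        functional = _SNPEFF_FUNCTIONAL_MAP.get(effect_term, "none")
        if effect_term in ("stop_lost", "start_lost"):
            functional = "nonsense"
        if functional != "none":
            region = "exon"
        else:
            region = _SNPEFF_REGION_MAP.get(effect_term, "exon" if impact != "MODIFIER" else "intergenic")
        tid = fields[6] if len(fields) > 6 and fields[6] else None
        annotations.append(
            EffectAnnotation(
                gene_id=gene,
                impact=impact,
                region=region,
                functional_class=functional,
                transcript_id=tid,
                effect_term=effect_term,
            )
        )
    return annotations


def read_vcf(path: str | os.PathLike) -> tuple[list[str], Iterator[VariantSite]]:
    """Open a VCF and return (sample ids, VariantSite iterator).

    Requires GT; DP and ANN are used when present. Any non-diploid
    genotype is an error — the cohort model is strictly diploid calls
    (the doubled haploid is a diploid-called sample).
    """
    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)

    def _iter() -> Iterator[VariantSite]:
        for var in vcf:
            raw = str(var).rstrip("\n")
            gts: list[Optional[tuple[int, int]]] = []
            for g in var.genotypes:
                if len(g) != 3:
                    raise ValueError(
                        f"{path}: ploidy != 2 at {var.CHROM}:{var.POS}"
                    )
                a, b = int(g[0]), int(g[1])
                gts.append(None if a < 0 or b < 0 else (a, b))
            depths: list[Optional[int]] = [None] * len(samples)
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            if dp is not None:
                for i, val in enumerate(dp[:, 0]):
                    iv = int(val)
                    depths[i] = None if iv < 0 else iv
            ann_value = var.INFO.get("ANN")
            ann = parse_ann_field(ann_value) if ann_value else []
            yield VariantSite(
                seq_id=var.CHROM,
                pos=var.POS - 1,
                ref=var.REF,
                alts=list(var.ALT),
                genotypes=gts,
                depths=depths,
                ann=ann,
                site_id=var.ID or ".",
                qual=var.QUAL,
                raw=raw,
            )

    return samples, _iter()


def read_vcf_contigs(path: str | os.PathLike) -> dict[str, int]:
    """Contig names and lengths declared in a VCF header (length 0 when
    the header omits it)."""
    vcf = VCF(os.fspath(path))
    lens = vcf.seqlens if vcf.seqnames else []
    if not lens:
        lens = [0] * len(vcf.seqnames)
    return dict(zip(vcf.seqnames, lens))


def vcf_header(samples: list[str], contigs: Optional[dict[str, int]] = None) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | "
        "Feature_Type | Feature_ID'\">",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return "\n".join(lines) + "\n"


def format_vcf_record(site: VariantSite) -> str:
    """Serialise one VariantSite as a VCF data line (no trailing newline)."""
    if site.raw is not None:
        return site.raw
    info = "."
    if site.ann:
        entries = [
            f"{site.alts[0] if site.alts else site.ref}|{a.effect_term or a.region}"
            f"|{a.impact}|{a.gene_id}||transcript|{a.transcript_id or ''}"
            for a in site.ann
        ]
        info = "ANN=" + ",".join(entries)
    cols = [
        site.seq_id,
        str(site.pos + 1),
        site.site_id,
        site.ref,
        ",".join(site.alts) if site.alts else ".",
        "." if site.qual is None else f"{site.qual:g}",
        "PASS",
        info,
        "GT:DP",
    ]
    for gt, dp in zip(site.genotypes, site.depths):
        g = "./." if gt is None else f"{gt[0]}/{gt[1]}"
        d = "." if dp is None else str(dp)
        cols.append(f"{g}:{d}")
    return "\t".join(cols)


def write_vcf(
    sites: Iterable[VariantSite],
    samples: list[str],
    path: str | os.PathLike,
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write a VCF. Sites carrying a verbatim ``raw`` record are copied
    byte-for-byte (so filtered outputs diff cleanly against their input)."""
    with open(path, "w") as fh:
        fh.write(vcf_header(samples, contigs))
        for site in sites:
            fh.write(format_vcf_record(site) + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models (gene -> mRNA -> CDS) from GFF3.

    GFF3 1-based inclusive coordinates become 0-based half-open. A CDS
    whose parent chain does not reach a gene feature is an error. A
    transcript whose total CDS length is not a codon multiple is kept
    (the annotator skips it later with a warning).
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    gene_ids = set()
    for gene in db.features_of_type("gene"):
        gene_ids.add(gene.id)
        span = Interval(gene.seqid, gene.start - 1, gene.end, gene.strand or ".")
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA"):
            segs = []
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                phase = int(cds.frame) if cds.frame not in (None, ".") else 0
                segs.append(
                    CDSSegment(
                        Interval(cds.seqid, cds.start - 1, cds.end, cds.strand or "."),
                        phase,
                    )
                )
            transcripts.append(Transcript(mrna.id, mrna.strand or ".", segs))
        genes.append(GeneModel(gene.id, span, transcripts))
    # orphan CDS check
    for cds in db.features_of_type("CDS"):
        parents = list(db.parents(cds, featuretype="gene"))
        if not parents:
            raise ValueError(f"{path}: CDS {cds.id} has no gene ancestor")
    return genes


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            s = gene.span
            fh.write(
                f"{s.seq_id}\tsynthio\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for tr in gene.transcripts:
                fh.write(
                    f"{s.seq_id}\tsynthio\tmRNA\t{s.start + 1}\t{s.end}\t.\t{tr.strand}\t.\t"
                    f"ID={tr.transcript_id};Parent={gene.gene_id}\n"
                )
                for seg in tr.cds:
                    c = seg.interval
                    fh.write(
                        f"{c.seq_id}\tsynthio\tCDS\t{c.start + 1}\t{c.end}\t.\t{tr.strand}\t"
                        f"{seg.phase}\tID={tr.transcript_id}.cds;Parent={tr.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# bedGraph / BED
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | os.PathLike) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph into seq_id -> sorted run-length (start, end, depth).

    Values are mean depth over the stated 0-based half-open interval.
    """
    track: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: malformed bedGraph row at line {lineno}")
            seq_id, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            track.setdefault(seq_id, []).append((start, end, value))
    for runs in track.values():
        runs.sort()
    return track


def write_bedgraph(track: dict[str, list[tuple[int, int, float]]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for seq_id in track:
            for start, end, value in track[seq_id]:
                fh.write(f"{seq_id}\t{start}\t{end}\t{value:g}\n")


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# OBO / gene2go
# ---------------------------------------------------------------------------

def read_obo(path: str | os.PathLike) -> list[OntologyTerm]:
    """Read an OBO ontology, keeping is_a and part_of parent relations."""
    graph = obonet.read_obo(os.fspath(path))
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"{path}: ontology graph contains a cycle")
    terms = []
    for node, data in graph.nodes(data=True):
        parents: list[tuple[str, str]] = []
        for _, parent, rel in graph.out_edges(node, keys=True):
            if rel in ("is_a", "part_of"):
                parents.append((parent, rel))
        terms.append(
            OntologyTerm(
                term_id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace", "biological_process"),
                parents=parents,
            )
        )
    return terms


def read_gene2go(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column TSV mapping gene id -> GO term id (one pair per row;
    a semicolon-separated term list in column 2 is also accepted)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed gene2go row at line {lineno}")
            gene = fields[0]
            for term in fields[1].split(";"):
                term = term.strip()
                if term:
                    mapping.setdefault(gene, set()).add(term)
    return mapping


def write_gene2go(mapping: dict[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gene in sorted(mapping):
            for term in sorted(mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

_SHEET_COLUMNS = ("sample_id", "sex", "site", "ploidy_class")


def read_sample_sheet(path: str | os.PathLike, allow_multiple_dh: bool = False) -> list[Sample]:
    """Read the cohort sample sheet (TSV: id, sex, site, ploidy class).

    At most one doubled-haploid sample is allowed per cohort unless
    ``allow_multiple_dh`` is set. Unknown sex or ploidy tokens are errors.
    """
    samples: list[Sample] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if [f.lower() for f in fields[:4]] == list(_SHEET_COLUMNS):
                continue  # header
            if len(fields) < 4:
                raise ValueError(f"{path}: sample sheet row {lineno} needs 4 columns")
            try:
                samples.append(Sample(fields[0], fields[1], fields[2], fields[3]))
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    n_dh = sum(s.ploidy_class == "doubled_haploid" for s in samples)
    if n_dh > 1 and not allow_multiple_dh:
        raise ValueError(f"{path}: {n_dh} doubled-haploid samples; at most one allowed")
    return samples


def write_sample_sheet(samples: Iterable[Sample], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SHEET_COLUMNS) + "\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.site}\t{s.ploidy_class}\n")
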