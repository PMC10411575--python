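"""The cohort SNP filter chain, as ordered auditable passes.

Order follows the published pipeline: biallelic SNPs only (indels and
multi-allelic sites out), site missingness <= 10%, removal of sites
heterozygous in the doubled haploid (those calls are paralogous
sequence variants, not alleles — a doubled haploid cannot be
heterozygous), minor allele frequency >= 0.05, mean depth in [5, 100].
LD pruning (20 kbp window, r^2 > 0.4, greedy left-to-right) exists for
the association/ordination path only and never precedes impact
profiling. Every pass reports input/removed/output counts and the first
failing pass per removed site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .types import VariantSite

log = logging.getLogger(__name__)


@dataclass
class PassCounts:
    name: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FilterReport:
    passes: list[PassCounts] = field(default_factory=list)
    removal_reason: dict[tuple[str, int], str] = field(default_factory=dict)
    notes: dict[str, int] = field(default_factory=dict)

    def record(self, name: str, before: list[VariantSite], after: list[VariantSite]) -> None:
        self.passes.append(PassCounts(name, len(before), len(before) - len(after), len(after)))
        kept = {(s.seq_id, s.pos) for s in after}
        for s in before:
            key = (s.seq_id, s.pos)
            if key not in kept and key not in self.removal_reason:
                self.removal_reason[key] = name

    def to_rows(self) -> list[dict]:
        return [vars(p) for p in self.passes]


@dataclass
class FilterConfig:
    max_missing: float = 0.10
    min_maf: float = 0.05
    depth_lo: float = 5.0
    depth_hi: float = 100.0
    dh_sample: Optional[str] = None
    ld_window_bp: int = 20_000
    ld_r2_max: float = 0.4
    ld_prune_enabled: bool = False


def filter_biallelic_snps(sites: list[VariantSite]) -> list[VariantSite]:
    """Keep single-base ref/alt sites with exactly one alt allele."""
    return [s for s in sites if s.is_biallelic_snp()]


def filter_missingness(sites: list[VariantSite], max_missing: float = 0.10) -> list[VariantSite]:
    """Remove sites with missing-genotype fraction strictly above the cap."""
    kept = []
    for s in sites:
        n = len(s.genotypes)
        if n == 0:
            continue
        missing = sum(1 for g in s.genotypes if g is None)
        if missing / n <= max_missing:
            kept.append(s)
    return kept


def filter_dh_heterozygotes(
    sites: list[VariantSite], samples: list[str], dh_sample: str
) -> tuple[list[VariantSite], int]:
    """Remove sites where the doubled haploid is heterozygous (PSVs).

    A missing DH genotype does not remove the site; the count of such
    sites is returned alongside for the report.
    """
    if dh_sample not in samples:
        raise ValueError(f"doubled-haploid sample {dh_sample!r} not in cohort")
    idx = samples.index(dh_sample)
    kept = []
    n_dh_missing = 0
    for s in sites:
        if s.genotypes[idx] is None:
            n_dh_missing += 1
            kept.append(s)
        elif not s.is_heterozygous(idx):
            kept.append(s)
    return kept, n_dh_missing


def filter_maf(sites: list[VariantSite], min_maf: float = 0.05) -> list[VariantSite]:
    """Keep sites with minor allele frequency >= min_maf over called alleles."""
    return [s for s in sites if s.minor_allele_frequency() >= min_maf]


def filter_mean_depth(
    sites: list[VariantSite], lo: float = 5.0, hi: float = 100.0
) -> list[VariantSite]:
    """Keep sites whose mean depth over samples with a DP value lies in
    [lo, hi], both bounds inclusive. Sites with no DP at all are kept."""
    kept = []
    for s in sites:
        md = s.mean_depth()
        if md is None or lo <= md <= hi:
            if md is not None and (md == lo or md == hi):
                log.debug("site %s:%d at depth boundary %.1f kept", s.seq_id, s.pos, md)
            kept.append(s)
    return kept


def _dosages(sites: list[VariantSite]) -> np.ndarray:
    """(n_sites, n_samples) alt-dosage matrix with NaN for missing."""
    n = len(sites[0].genotypes) if sites else 0
    mat = np.full((len(sites), n), np.nan)
    for i, s in enumerate(sites):
        for j, gt in enumerate(s.genotypes):
            if gt is not None:
                mat[i, j] = gt[0] + gt[1]
    return mat


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, missing values
    excluded pairwise; 0 when either is monomorphic over the shared calls."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = np.std(xv), np.std(yv)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((xv - np.mean(xv)) * (yv - np.mean(yv))) / (sx * sy))
    return r * r


def ld_prune(
    sites: list[VariantSite], window_bp: int = 20_000, r2_max: float = 0.4
) -> list[VariantSite]:
    """Greedy left-to-right LD pruning.

    Scanning sites in position order per sequence, a site is dropped
    when its dosage r^2 with any *retained* site within ``window_bp``
    upstream exceeds ``r2_max``; the right-hand member of each offending
    pair is always the one removed.
    """
    ordered = sorted(range(len(sites)), key=lambda i: (sites[i].seq_id, sites[i].pos))
    dosage = _dosages(sites)
    kept_idx: list[int] = []
    recent: list[int] = []  # retained indices on the current sequence
    cur_seq: Optional[str] = None
    for i in ordered:
        s = sites[i]
        if s.seq_id != cur_seq:
            cur_seq = s.seq_id
            recent = []
        recent = [j for j in recent if s.pos - sites[j].pos <= window_bp]
        if any(pairwise_r2(dosage[i], dosage[j]) > r2_max for j in recent):
            continue
        kept_idx.append(i)
        recent.append(i)
    kept_set = set(kept_idx)
    return [s for i, s in enumerate(sites) if i in kept_set]


def apply_filter_chain(
    sites: list[VariantSite],
    samples: list[str],
    config: FilterConfig,
) -> tuple[list[VariantSite], FilterReport]:
    """Run the passes in published order and produce a FilterReport.

    LD pruning runs last and only when ``ld_prune_enabled`` — it feeds
    the association/ordination path, never impact profiling.
    """
    report = FilterReport()
    stages: list[tuple[str, Callable[[list[VariantSite]], list[VariantSite]]]] = [
        ("biallelic_snps", filter_biallelic_snps),
        ("missingness", lambda ss: filter_missingness(ss, config.max_missing)),
    ]
    current = sites
    for name, fn in stages:
        nxt = fn(current)
        report.record(name, current, nxt)
        current = nxt
    if config.dh_sample is not None:
        nxt, n_dh_missing = filter_dh_heterozygotes(current, samples, config.dh_sample)
        report.record("dh_heterozygotes", current, nxt)
        report.notes["dh_genotype_missing"] = n_dh_missing
        current = nxt
    for name, fn in [
        ("maf", lambda ss: filter_maf(ss, config.min_maf)),
        ("mean_depth", lambda ss: filter_mean_depth(ss, config.depth_lo, config.depth_hi)),
    ]:
        nxt = fn(current)
        report.record(name, current, nxt)
        current = nxt
    if config.ld_prune_enabled:
        nxt = ld_prune(current, config.ld_window_bp, config.ld_r2_max)
        report.record("ld_prune", current, nxt)
        current = nxt
    return current, report
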