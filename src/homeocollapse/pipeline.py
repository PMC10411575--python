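"""End-to-end orchestration: simulate -> homeology -> collapse ->
filter -> profile -> enrich -> sexscreen, from one configuration.

Every threshold of every stage lives in :class:`PipelineConfig` with
the published defaults (1 Mbp depth windows, 2 SD collapse rule, 10 kbp
minimum homeolog alignment, 15 Mbp pair classification, 3 Mbp minimum
collapsed region, 10% site missingness, MAF 0.05, mean depth 5-100, LD
20 kbp / r^2 0.4, 2 SD outlier genes, alpha 0.05, 50 bp flanks, 10 kbp
peak windows); no stage hard-codes a threshold. The resolved
configuration is persisted with each run, and a fixed seed reproduces
every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import collapse, effects, enrichment, homeology, sexscreen, synthio, varfilter
from .types import Interval

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 2023
    out_dir: str = "pipeline_out"
    # homeology
    min_aln_bp: int = 10_000
    classify_threshold_bp: int = 15_000_000
    # collapse
    depth_window_bp: int = 1_000_000
    k_sd: float = 2.0
    min_region_bp: int = 3_000_000
    # variant filters
    max_missing: float = 0.10
    min_maf: float = 0.05
    depth_lo: float = 5.0
    depth_hi: float = 100.0
    ld_window_bp: int = 20_000
    ld_r2_max: float = 0.4
    # effects / outliers
    flank_bp: int = 5_000
    outlier_k_sd: float = 2.0
    # enrichment
    alpha: float = 0.05
    # sexscreen
    n_perm: int = 1_000
    peak_window_bp: int = 10_000
    ratio_flag: float = 2.0
    snp_flank_bp: int = 50
    # synthetic input
    sim: synthio.SimConfig = field(default_factory=synthio.SimConfig)

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


def average_tracks(
    tracks: list[dict[str, list[tuple[int, int, float]]]]
) -> dict[str, list[tuple[int, int, float]]]:
    """Mean depth track over samples sharing the same window structure."""
    if not tracks:
        raise ValueError("no tracks to average")
    out: dict[str, list[tuple[int, int, float]]] = {}
    for seq_id in tracks[0]:
        runs = [t[seq_id] for t in tracks]
        merged = []
        for i, (s, e, _) in enumerate(runs[0]):
            merged.append((s, e, float(np.mean([r[i][2] for r in runs]))))
        out[seq_id] = merged
    return out


def run(config: PipelineConfig) -> dict:
    """Run every stage on the synthetic dataset and write a JSON +
    markdown report; returns the report dict."""
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"config": _config_dict(config)}

    log.info("stage simulate")
    sim = synthio.simulate(config.sim)
    data_dir = os.path.join(config.out_dir, "data")
    sim.write(data_dir)
    seq_lengths = sim.contig_lengths

    log.info("stage homeology")
    retained = homeology.filter_homeolog_alignments(sim.alignments, config.min_aln_bp)
    pair_summaries = homeology.summarize_pairs(retained, config.classify_threshold_bp)
    report["homeology"] = {
        "n_alignments_retained": len(retained),
        "pairs": [dataclasses.asdict(p) for p in pair_summaries],
    }

    log.info("stage collapse")
    dh = next(s for s in sim.samples if s.ploidy_class == "doubled_haploid")
    dh_track = sim.depth_tracks[dh.sample_id]
    autosomal_lengths = {k: v for k, v in seq_lengths.items() if k != sim.truth.sdy_contig}
    windows = collapse.window_depth(dh_track, autosomal_lengths, config.depth_window_bp)
    windows = collapse.call_collapsed(windows, config.k_sd)
    regions = collapse.filter_min_length(
        collapse.merge_collapsed(windows), config.min_region_bp
    )
    total_bp, fraction = collapse.genome_collapse_summary(regions, autosomal_lengths)
    report["collapse"] = {
        "n_regions": len(regions),
        "total_bp": total_bp,
        "fraction_of_assembly": fraction,
        "regions": [
            {"seq_id": r.interval.seq_id, "start": r.interval.start,
             "end": r.interval.end, "mean_depth": r.mean_depth}
            for r in regions
        ],
    }

    log.info("stage filter")
    sample_ids = [s.sample_id for s in sim.samples]
    fcfg = varfilter.FilterConfig(
        max_missing=config.max_missing,
        min_maf=config.min_maf,
        depth_lo=config.depth_lo,
        depth_hi=config.depth_hi,
        dh_sample=dh.sample_id,
    )
    filtered, freport = varfilter.apply_filter_chain(sim.sites, sample_ids, fcfg)
    report["filter"] = {"passes": freport.to_rows(), "notes": freport.notes}

    log.info("stage profile")
    annotated = effects.parse_or_annotate(
        filtered, sim.genes, sim.assembly, prefer_ann=True, flank_bp=config.flank_bp
    )
    profiles = effects.gene_impact_profiles(annotated, sim.genes)
    out_density = effects.outlier_genes(profiles, "density", config.outlier_k_sd)
    out_count = effects.outlier_genes(profiles, "count", config.outlier_k_sd)
    het = effects.per_individual_heterozygosity(annotated, sample_ids)
    summary = effects.cohort_summary(annotated)
    report["effects"] = {
        "cohort_summary": dataclasses.asdict(summary),
        "outlier_density": _outlier_dict(out_density),
        "outlier_count": _outlier_dict(out_count),
        "heterozygosity_pct": het,
    }

    log.info("stage enrich")
    gtm = enrichment.propagate(sim.gene2go, sim.ontology)
    study_sets = {
        "collapsed_regions": enrichment.genes_in_regions(
            sim.genes, [r.interval for r in regions]
        ),
        "density_outliers": out_density.qualifying_genes,
        "count_outliers": out_count.qualifying_genes,
    }
    report["enrichment"] = {}
    for name, study in study_sets.items():
        if not study:
            report["enrichment"][name] = {"n_study": 0, "results": []}
            continue
        results, dropped = enrichment.enrich(study, gtm, config.alpha)
        enrichment.attach_term_names(results, sim.ontology)
        report["enrichment"][name] = {
            "n_study": len(study),
            "n_dropped_no_go": dropped,
            "results": [dataclasses.asdict(r) for r in results if r.enriched],
        }

    log.info("stage sexscreen")
    report["sexscreen"] = _sexscreen_stage(config, sim, filtered, sample_ids)

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    _write_markdown(report, os.path.join(config.out_dir, "report.md"))
    return report


def _sexscreen_stage(config: PipelineConfig, sim, filtered, sample_ids) -> dict:
    truth = sim.truth
    sex = [s.sex for s in sim.samples]
    strata = [s.site for s in sim.samples]

    presence = sexscreen.call_presence_from_genotypes(
        sim.sites, sample_ids, truth.sdy_contig
    )
    # markers: sdY presence (one binary marker) + autosomal SNP dosages
    auto_sites = [s for s in filtered if s.seq_id != truth.sdy_contig]
    n = len(sample_ids)
    Xp = np.array([[1.0 if c.call == "present" else 0.0 for c in presence]])
    Xd = np.full((len(auto_sites), n), np.nan)
    for i, s in enumerate(auto_sites):
        for j, gt in enumerate(s.genotypes):
            if gt is not None:
                Xd[i, j] = gt[0] + gt[1]
    ids = ["sdY_presence"] + [f"{s.seq_id}:{s.pos + 1}" for s in auto_sites]

    res_p = sexscreen.association_test(
        Xp, ["sdY_presence"], sex, strata, trials=1,
        n_perm=config.n_perm, seed=config.seed,
    )
    res_d = sexscreen.association_test(
        Xd, ids[1:], sex, strata, trials=2,
        n_perm=config.n_perm, seed=config.seed + 1,
    ) if auto_sites else None

    male_track = average_tracks(
        [sim.depth_tracks[s.sample_id] for s in sim.samples if s.sex == "male"]
    )
    female_track = average_tracks(
        [sim.depth_tracks[s.sample_id] for s in sim.samples if s.sex == "female"]
    )
    # screen the windows of the strongest autosomal associations
    screens = []
    flanks = []
    if res_d is not None and len(auto_sites):
        order = np.argsort(np.where(np.isnan(res_d.statistic), -1, res_d.statistic))[::-1]
        top = [i for i in order[:5] if not np.isnan(res_d.statistic[i])]
        wbp = config.peak_window_bp
        for i in top:
            s = auto_sites[i]
            ws = (s.pos // wbp) * wbp
            iv = Interval(s.seq_id, ws, ws + wbp)
            screens.extend(
                sexscreen.screen_peak_coverage(
                    male_track, female_track, [iv], config.ratio_flag,
                    exclude_from_genome_mean={truth.sdy_contig},
                )
            )
            flanks.append(
                sexscreen.flank_repeat_test(sim.assembly, (s.seq_id, s.pos), config.snp_flank_bp)
            )
    return {
        "sdY_presence_calls": {c.sample_id: c.call for c in presence},
        "sdY_statistic": float(res_p.statistic[0]),
        "sdY_p_adjusted": float(res_p.p_adjusted[0]),
        "top_autosomal": [
            {
                "marker": res_d.marker_ids[i],
                "statistic": float(res_d.statistic[i]),
                "p_adjusted": float(res_d.p_adjusted[i]),
            }
            for i in (np.argsort(np.nan_to_num(res_d.statistic, nan=-1))[::-1][:5] if res_d is not None else [])
        ] if res_d is not None else [],
        "peak_screens": [
            {
                "window": f"{p.window.seq_id}:{p.window.start}-{p.window.end}",
                "normalized_ratio": p.normalized_ratio,
                "flagged": p.flagged,
            }
            for p in screens
        ],
        "flank_tests": [
            {"snp": f"{f.snp[0]}:{f.snp[1] + 1}", "n_exact_matches": f.n_exact_matches,
             "repetitive": f.repetitive}
            for f in flanks
        ],
    }


def _outlier_dict(t: effects.OutlierThreshold) -> dict:
    return {
        "metric": t.metric,
        "mean": t.mean,
        "sd": t.sd,
        "cutoff": t.cutoff,
        "population_size": t.population_size,
        "n_qualifying": len(t.qualifying_genes),
        "qualifying_genes": sorted(t.qualifying_genes),
    }


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_markdown(report: dict, path: str) -> None:
    lines = ["# Pipeline report", ""]
    c = report.get("collapse", {})
    lines += [
        "## Collapsed regions",
        f"- regions: {c.get('n_regions')}",
        f"- total bp: {c.get('total_bp')}",
        f"- fraction of assembly: {c.get('fraction_of_assembly'):.4f}",
        "",
        "## Filter chain",
    ]
    for p in report.get("filter", {}).get("passes", []):
        lines.append(f"- {p['name']}: {p['n_in']} -> {p['n_out']} (removed {p['n_removed']})")
    eff = report.get("effects", {})
    cs = eff.get("cohort_summary", {})
    lines += [
        "",
        "## Impact summary",
        f"- sites: {cs.get('n_sites')}, annotations: {cs.get('n_annotations')}, "
        f"annotations/SNP: {cs.get('annotations_per_snp'):.2f}",
        f"- density outlier cutoff: {eff.get('outlier_density', {}).get('cutoff'):.4f} "
        f"({eff.get('outlier_density', {}).get('n_qualifying')} genes)",
        f"- count outlier cutoff: {eff.get('outlier_count', {}).get('cutoff'):.2f} "
        f"({eff.get('outlier_count', {}).get('n_qualifying')} genes)",
        "",
        "## Sex screen",
        f"- sdY statistic: {report.get('sexscreen', {}).get('sdY_statistic'):.2f} "
        f"(adjusted p {report.get('sexscreen', {}).get('sdY_p_adjusted'):.4g})",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
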