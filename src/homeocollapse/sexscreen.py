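"""Sex-linkage screen: presence/absence calling, stratified association
with permutation correction, male/female coverage ratios, and the
exact-match flank test for repeat-driven false positives.

The sex-determining locus of many salmonids (sdY) is male-specific:
males carry and genotype the contig, females show missing genotypes and
near-zero depth. A genome-wide association of genotype with sex also
lights up autosomal windows where Y-borne repeats cross-map, so every
peak is screened two ways: the male/female normalised coverage ratio of
its 10 kbp window, and an exact-match census of the SNP's flanking
sequence across the assembly (more than two exact occurrences marks a
repetitive context).

The association statistic is a stratified 2x2 chi-square combined
across sampling sites (the Cochran variant of the Mantel-Haenszel
statistic, per-stratum variance R1*R2*C1*C2/N^3, no continuity
correction, which reduces exactly to the Pearson chi-square when there
is a single stratum), with family-wise correction by max-T label
permutation within strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

from .types import Interval

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# presence / absence
# ---------------------------------------------------------------------------

@dataclass
class PresenceCall:
    sample_id: str
    fraction_missing: float
    fraction_covered: float
    call: str  # present / absent / ambiguous


def call_presence_from_genotypes(
    sites, samples: list[str], contig: str, missing_threshold: float = 0.8
) -> list[PresenceCall]:
    """Per-sample presence of a target contig from genotype missingness.

    absent iff the missing fraction >= threshold; present iff it is
    <= 1 - threshold; ambiguous otherwise (logged).
    """
    n_sites = 0
    missing = np.zeros(len(samples), dtype=np.int64)
    for site in sites:
        if site.seq_id != contig:
            continue
        n_sites += 1
        for i, gt in enumerate(site.genotypes):
            if gt is None:
                missing[i] += 1
    if n_sites == 0:
        raise ValueError(f"no variant sites on contig {contig!r}")
    calls = []
    for i, name in enumerate(samples):
        frac = missing[i] / n_sites
        if frac >= missing_threshold:
            call = "absent"
        elif frac <= 1.0 - missing_threshold:
            call = "present"
        else:
            call = "ambiguous"
            log.info("sample %s ambiguous on %s (%.0f%% missing)", name, contig, 100 * frac)
        calls.append(PresenceCall(name, float(frac), float(1 - frac), call))
    return calls


def call_presence_from_depth(
    track: dict[str, list[tuple[int, int, float]]],
    sample_id: str,
    contig: str,
    missing_threshold: float = 0.8,
    min_depth: float = 1.0,
) -> PresenceCall:
    """Presence from the fraction of contig bases below ``min_depth``."""
    runs = track.get(contig)
    if not runs:
        raise ValueError(f"no depth track for contig {contig!r}")
    total = sum(e - s for s, e, _ in runs)
    zero = sum(e - s for s, e, v in runs if v < min_depth)
    frac = zero / total
    if frac >= missing_threshold:
        call = "absent"
    elif frac <= 1.0 - missing_threshold:
        call = "present"
    else:
        call = "ambiguous"
    return PresenceCall(sample_id, float(frac), float(1 - frac), call)


# ---------------------------------------------------------------------------
# stratified association with max-T permutations
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    marker_ids: list[str]
    statistic: np.ndarray        # NaN where undefined
    p_raw: np.ndarray
    p_adjusted: np.ndarray       # max-T family-wise adjusted
    n_permutations: int


def _cochran_mh(
    X: np.ndarray,
    valid: np.ndarray,
    male: np.ndarray,
    strata: np.ndarray,
    trials: int,
) -> np.ndarray:
    """Stratified chi-square for every marker at once.

    X: (m, n) per-sample success counts in 0..trials (use trials=1 for
    presence markers, trials=2 for allele dosages); ``valid`` masks
    missing entries. Strata where only one sex is observed contribute
    nothing. Returns NaN where the total variance is zero (e.g. a
    marker identical in all samples).
    """
    m = X.shape[0]
    num = np.zeros(m)
    var = np.zeros(m)
    Xv = np.where(valid, X, 0.0)
    for s in np.unique(strata):
        in_s = strata == s
        males_s = in_s & male
        females_s = in_s & ~male
        t1 = trials * valid[:, males_s].sum(axis=1).astype(float)    # male trials
        t2 = trials * valid[:, females_s].sum(axis=1).astype(float)  # female trials
        s1 = Xv[:, males_s].sum(axis=1)
        s2 = Xv[:, females_s].sum(axis=1)
        n_tot = t1 + t2
        c1 = s1 + s2
        c2 = n_tot - c1
        usable = (t1 > 0) & (t2 > 0) & (n_tot > 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(usable, s1 - t1 * c1 / n_tot, 0.0)
            v = np.where(usable, t1 * t2 * c1 * c2 / n_tot**3, 0.0)
        num += d
        var += v
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, num**2 / var, np.nan)
    return stat


def association_test(
    X: np.ndarray,
    marker_ids: list[str],
    sex: Sequence[str],
    site_strata: Sequence[str],
    trials: int = 1,
    n_perm: int = 1_000,
    seed: int = 0,
    valid: Optional[np.ndarray] = None,
) -> AssociationResult:
    """Stratified sex-association test over a marker matrix.

    ``X`` is (n_markers, n_samples) success counts (presence 0/1 with
    ``trials=1``, or alt-allele dosage 0/1/2 with ``trials=2``; NaN =
    missing). Raw p from the chi-square(1) tail; family-wise adjusted p
    from max-T permutation of sex labels *within* sampling-site strata,
    using the supplied seed (bit-identical reruns).
    """
    sexes = set(sex)
    if not {"male", "female"} <= sexes - {"unknown"} and len(sexes - {"unknown"}) < 2:
        raise ValueError("need both sexes in the cohort")
    X = np.asarray(X, dtype=float)
    if valid is None:
        valid = ~np.isnan(X)
    male = np.array([s == "male" for s in sex])
    known = np.array([s in ("male", "female") for s in sex])
    strata = np.asarray(site_strata)
    # unknown-sex samples are removed from both the statistic and the
    # permutation universe
    X = X[:, known]
    valid = valid[:, known]
    male = male[known]
    strata = strata[known]

    obs = _cochran_mh(X, valid, male, strata, trials)
    p_raw = chi2.sf(obs, df=1)

    rng = np.random.default_rng(seed)
    finite_obs = np.where(np.isnan(obs), -np.inf, obs)
    exceed = np.zeros(X.shape[0])
    n_samples = male.size
    idx_by_stratum = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for _ in range(n_perm):
        perm_male = male.copy()
        for idx in idx_by_stratum:
            perm_male[idx] = perm_male[rng.permutation(idx)]
        stat = _cochran_mh(X, valid, perm_male, strata, trials)
        max_stat = np.nanmax(stat) if not np.all(np.isnan(stat)) else -np.inf
        exceed += max_stat >= finite_obs
    p_adj = (1.0 + exceed) / (1.0 + n_perm)
    p_adj = np.where(np.isnan(obs), np.nan, p_adj)
    return AssociationResult(list(marker_ids), obs, p_raw, p_adj, n_perm)


# ---------------------------------------------------------------------------
# coverage-ratio peak screen
# ---------------------------------------------------------------------------

@dataclass
class PeakScreen:
    window: Interval
    male_mean_depth: float
    female_mean_depth: float
    normalized_ratio: float
    flagged: bool


def _track_mean(track: dict[str, list[tuple[int, int, float]]],
                exclude: Optional[set[str]] = None) -> float:
    total = 0.0
    bases = 0
    for seq_id, runs in track.items():
        if exclude and seq_id in exclude:
            continue
        for s, e, v in runs:
            total += v * (e - s)
            bases += e - s
    if bases == 0:
        raise ValueError("empty depth track")
    return total / bases


def _window_mean(track: dict[str, list[tuple[int, int, float]]], window: Interval) -> float:
    runs = track.get(window.seq_id, [])
    total = 0.0
    for s, e, v in runs:
        lo, hi = max(s, window.start), min(e, window.end)
        if lo < hi:
            total += v * (hi - lo)
    return total / len(window)


def screen_peak_coverage(
    male_track: dict[str, list[tuple[int, int, float]]],
    female_track: dict[str, list[tuple[int, int, float]]],
    windows: list[Interval],
    ratio_flag: float = 2.0,
    exclude_from_genome_mean: Optional[set[str]] = None,
) -> list[PeakScreen]:
    """Male/female normalised coverage ratio per candidate window.

    Each sex's window mean is first normalised by that track's
    genome-wide mean (sex chromosomes can be excluded from the genome
    mean via ``exclude_from_genome_mean``); the window is flagged iff
    the ratio is >= ``ratio_flag``. A zero female window gives an
    infinite ratio and is flagged.
    """
    male_gm = _track_mean(male_track, exclude_from_genome_mean)
    female_gm = _track_mean(female_track, exclude_from_genome_mean)
    out = []
    for w in windows:
        mm = _window_mean(male_track, w)
        fm = _window_mean(female_track, w)
        male_norm = mm / male_gm
        female_norm = fm / female_gm
        ratio = float("inf") if female_norm == 0 else male_norm / female_norm
        out.append(PeakScreen(w, mm, fm, ratio, ratio >= ratio_flag))
    return out


# ---------------------------------------------------------------------------
# exact-match flank test
# ---------------------------------------------------------------------------

@dataclass
class FlankTest:
    snp: tuple[str, int]
    flank_bp: int
    n_exact_matches: int
    repetitive: bool  # n_exact_matches > 2


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def flank_repeat_test(
    assembly: dict[str, str],
    snp: tuple[str, int],
    flank_bp: int = 50,
) -> FlankTest:
    """Count exact full-length occurrences of the SNP's flanking window
    (2*flank_bp + 1 bases, centred on the SNP) across the assembly,
    both strands. More than two occurrences marks a repetitive context;
    the source locus itself always matches, so the count is >= 1.

    Matching is case-insensitive (soft-masking carries no sequence
    information) and literal — the contract is *exact* matches, not
    alignment. A palindromic window is counted once per genomic
    position, not once per strand.
    """
    seq_id, pos = snp
    seq = assembly[seq_id]
    lo = max(0, pos - flank_bp)
    hi = min(len(seq), pos + flank_bp + 1)
    if lo != pos - flank_bp or hi != pos + flank_bp + 1:
        log.info("flank for %s:%d truncated at a sequence end", seq_id, pos)
    probe = seq[lo:hi].upper()
    rc = _revcomp(probe)
    n = 0
    for name in sorted(assembly):
        hay = assembly[name].upper()
        positions: set[int] = set()
        for pat in {probe, rc}:  # set: palindromes collapse to one pattern
            start = 0
            while True:
                i = hay.find(pat, start)
                if i < 0:
                    break
                positions.add(i)
                start = i + 1
        n += len(positions)
    return FlankTest(snp, flank_bp, n, n > 2)
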