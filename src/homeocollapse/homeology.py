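"""Homeolog similarity summaries from genome self-alignment tables.

Operates on normalised :class:`AlignmentRecord` lists (see
:mod:`homeocollapse.formats`): length-filters homeologous alignments,
sums alignment length per unordered sequence pair to classify highly
similar homeolog pairs, bins alignment identities for plotting, places
genetic-map markers by best hit, and computes the percent-identity
estimator for a collapsed region from its paralogous variant count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .types import AlignmentRecord, Interval

log = logging.getLogger(__name__)

IDENTITY_BINS = (("low", 80.0, 90.0), ("mid", 90.0, 95.0), ("high", 95.0, 100.0))


@dataclass
class PairSummary:
    seq_a: str
    seq_b: str
    combined_aln_bp: int
    n_alignments: int
    length_weighted_identity: float
    highly_similar: bool


@dataclass
class MarkerPlacementReport:
    placements: dict[str, Interval]
    n_markers_in: int
    n_unplaced: int
    n_ties_broken: int


def _pair_key(rec: AlignmentRecord) -> tuple[str, str]:
    return tuple(sorted((rec.query.seq_id, rec.subject.seq_id)))  # type: ignore[return-value]


def _canonical_coords(rec: AlignmentRecord) -> tuple:
    """Orientation-free fingerprint for reciprocal deduplication."""
    a = (rec.query.seq_id, rec.query.start, rec.query.end)
    b = (rec.subject.seq_id, rec.subject.start, rec.subject.end)
    return (min(a, b), max(a, b), rec.aln_length)


def filter_homeolog_alignments(
    records: list[AlignmentRecord], min_len: int = 10_000
) -> list[AlignmentRecord]:
    """Keep inter-sequence alignments with length >= ``min_len`` (strictly
    longer than min_len - 1, matching 'longer than 10 kb' with the 10 kb
    value itself retained), drop self-hits, and deduplicate reciprocal
    A->B / B->A records keeping the higher bitscore."""
    best: dict[tuple, AlignmentRecord] = {}
    for rec in records:
        if rec.aln_length < min_len:
            continue
        if rec.query.seq_id == rec.subject.seq_id:
            # homeology is between sequences; intra-sequence hits
            # (including the trivial self-hit) are not homeolog evidence
            continue
        key = _canonical_coords(rec)
        prev = best.get(key)
        if prev is None or rec.bitscore > prev.bitscore:
            best[key] = rec
    return list(best.values())


def summarize_pairs(
    alignments: list[AlignmentRecord], classify_threshold: int = 15_000_000
) -> list[PairSummary]:
    """One summary per unordered sequence pair.

    ``combined_aln_bp`` sums retained alignment lengths without overlap
    merging; a pair is ``highly_similar`` iff the sum is strictly greater
    than ``classify_threshold``.
    """
    by_pair: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in alignments:
        if rec.query.seq_id == rec.subject.seq_id:
            continue
        by_pair.setdefault(_pair_key(rec), []).append(rec)
    summaries = []
    for (a, b), recs in sorted(by_pair.items()):
        total = sum(r.aln_length for r in recs)
        weighted = sum(r.pct_identity * r.aln_length for r in recs) / total if total else 0.0
        if total == classify_threshold:
            log.info("pair %s/%s combined length exactly at the classification "
                     "threshold; strict > leaves it unclassified", a, b)
        summaries.append(
            PairSummary(
                seq_a=a,
                seq_b=b,
                combined_aln_bp=total,
                n_alignments=len(recs),
                length_weighted_identity=weighted,
                highly_similar=total > classify_threshold,
            )
        )
    return summaries


def merged_pair_lengths(alignments: list[AlignmentRecord]) -> dict[tuple[str, str], int]:
    """Overlap-merged combined length per pair, on query coordinates.

    Companion view to :func:`summarize_pairs` for judging how much
    double-counting the plain sum carries; not part of the headline
    classification.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for rec in alignments:
        by_pair.setdefault(_pair_key(rec), []).append((rec.query.start, rec.query.end))
    out = {}
    for key, ivs in by_pair.items():
        ivs.sort()
        total = 0
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
        out[key] = total
    return out


def bin_identity(
    alignments: list[AlignmentRecord],
) -> dict[tuple[str, str], dict[str, int]]:
    """Count alignments per identity bin per pair.

    Bins partition (80, 100]: low (>80, <=90], mid (>90, <=95], high
    (>95]. Identities <= 80 land in a 'below_range' bucket and are
    logged rather than silently dropped.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    n_below = 0
    for rec in alignments:
        key = _pair_key(rec)
        bins = counts.setdefault(
            key, {"low": 0, "mid": 0, "high": 0, "below_range": 0}
        )
        p = rec.pct_identity
        if p <= 80.0:
            bins["below_range"] += 1
            n_below += 1
        elif p <= 90.0:
            bins["low"] += 1
        elif p <= 95.0:
            bins["mid"] += 1
        else:
            bins["high"] += 1
    if n_below:
        log.info("%d alignments at identity <= 80%% counted below range", n_below)
    return counts


def estimate_collapsed_identity(region_len: int, psv_count: int) -> float:
    """Percent identity between the two homeologous haplotypes of a
    collapsed region, from the count of paralogous sequence variants:
    (1 - psv_count/region_len) * 100, reported at two decimals."""
    if region_len < 1:
        raise ValueError("region_len must be >= 1")
    if not (0 <= psv_count <= region_len):
        raise ValueError("psv_count must lie in [0, region_len]")
    return round((1.0 - psv_count / region_len) * 100.0, 2)


def place_markers(
    marker_hits: dict[str, list[AlignmentRecord]], min_identity: float = 80.0
) -> MarkerPlacementReport:
    """Place each genetic-map marker at its single best assembly hit.

    Hits below ``min_identity`` percent identity are discarded; among the
    rest the highest bitscore wins, ties broken by higher identity, then
    lexicographically smallest subject sequence, then smallest start.
    Markers with no surviving hit are omitted and counted.
    """
    placements: dict[str, Interval] = {}
    n_unplaced = 0
    n_ties = 0
    for marker in sorted(marker_hits):
        hits = [h for h in marker_hits[marker] if h.pct_identity >= min_identity]
        if not hits:
            n_unplaced += 1
            continue
        def rank(h: AlignmentRecord) -> tuple:
            return (-h.bitscore, -h.pct_identity, h.subject.seq_id, h.subject.start)
        hits.sort(key=rank)
        if len(hits) > 1 and hits[0].bitscore == hits[1].bitscore:
            n_ties += 1
            log.debug("marker %s: bitscore tie broken by identity/position", marker)
        placements[marker] = hits[0].subject
    return MarkerPlacementReport(placements, len(marker_hits), n_unplaced, n_ties)
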