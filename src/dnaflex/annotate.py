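"""Co-localization analytics for flexibility peaks.

Once peaks are called, the questions become positional: where do peaks sit
relative to genes (between ORFs, inside ORFs, on telomeres or rDNA), what is
the transcriptional orientation of the flanking genes (divergent /
unidirectional / convergent), do peaks overlap untranslated regions, which
AT tandem repeats form their core, and how close are scored poly(A) cleavage
sites to those repeats.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import reverse_complement
from .io import FeatureInterval, ScoredSite, UtrRecord
from .peaks import FlexRegion

logger = logging.getLogger(__name__)

ORIENTATION_CLASSES = ("divergent", "unidirectional", "convergent")


@dataclass
class InterOrfRegion:
    """Gap between two adjacent non-overlapping ORFs, classed by flanking strands.

    left=+ / right=- means both 3' ends face the gap (convergent, terminators
    only); left=- / right=+ means both 5' ends face it (divergent, shared
    promoter region); equal strands are unidirectional (tandem).
    """

    chrom: str
    start: int
    end: int
    left_strand: str
    right_strand: str
    left_id: str
    right_id: str

    @property
    def oclass(self) -> str:
        if self.left_strand == self.right_strand:
            return "unidirectional"
        if self.left_strand == "+":
            return "convergent"
        return "divergent"

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class PeakAnnotation:
    """Everything known about one peak's genomic placement."""

    peak: FlexRegion
    placement: str  # interORF | inside_ORF | telomere | rRNA | unresolved
    oclass: str | None = None  # orientation class when placement == interORF
    utr3_orfs: list[str] = field(default_factory=list)
    utr5_orfs: list[str] = field(default_factory=list)
    repeats: list[FeatureInterval] = field(default_factory=list)

    @property
    def name(self) -> str | None:
        return self.peak.name


# ---------------------------------------------------------------------------
# interORF classification

def classify_interorf(orfs: Sequence[FeatureInterval]) -> list[InterOrfRegion]:
    """Gaps between consecutive non-overlapping ORFs, classed by strands.

    ORFs are sorted per chromosome; overlapping neighbours yield no region
    for that gap (logged), and the terminal stretches before the first and
    after the last ORF are excluded.
    """
    by_chrom: dict[str, list[FeatureInterval]] = defaultdict(list)
    for orf in orfs:
        if orf.ftype != "ORF":
            continue
        if orf.strand not in {"+", "-"}:
            raise ValueError(f"ORF {orf.fid!r} lacks a strand")
        by_chrom[orf.chrom].append(orf)
    regions: list[InterOrfRegion] = []
    for chrom in sorted(by_chrom):
        chrom_orfs = sorted(by_chrom[chrom], key=lambda o: (o.start, o.end))
        prev = chrom_orfs[0]
        for cur in chrom_orfs[1:]:
            if cur.start < prev.end:
                logger.info(
                    "overlapping ORFs %s/%s on %s: no interORF region for this gap",
                    prev.fid, cur.fid, chrom,
                )
            else:
                regions.append(
                    InterOrfRegion(
                        chrom, prev.end, cur.start,
                        prev.strand, cur.strand, prev.fid, cur.fid,
                    )
                )
            if cur.end > prev.end:
                prev = cur
    return regions


def interorf_class_counts(regions: Iterable[InterOrfRegion]) -> dict[str, int]:
    counts = {c: 0 for c in ORIENTATION_CLASSES}
    for r in regions:
        counts[r.oclass] += 1
    return counts


# ---------------------------------------------------------------------------
# peak placement

def locate_peaks(
    peaks: Sequence[FlexRegion],
    features: Sequence[FeatureInterval],
    inside_orf_min_overlap: float = 0.5,
) -> list[PeakAnnotation]:
    """Assign each peak exactly one placement.

    Priority: telomere > rRNA > inside_ORF > interORF.  ``inside_ORF``
    requires at least ``inside_orf_min_overlap`` of the peak length to
    overlap one ORF; interORF peaks inherit the orientation class of the
    region containing the peak midpoint.  A peak on a chromosome absent from
    the annotation is left unresolved with a logged warning.
    """
    orfs = [f for f in features if f.ftype == "ORF"]
    trees: dict[str, dict[str, IntervalTree]] = defaultdict(dict)
    for f in features:
        trees[f.ftype].setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    interorf = classify_interorf(orfs)
    io_by_chrom: dict[str, list[InterOrfRegion]] = defaultdict(list)
    for r in interorf:
        io_by_chrom[r.chrom].append(r)
    known_chroms = {f.chrom for f in features}

    annotations: list[PeakAnnotation] = []
    for peak in peaks:
        if peak.chrom not in known_chroms:
            logger.warning("peak %s on unannotated chromosome %s", peak.name, peak.chrom)
            annotations.append(PeakAnnotation(peak, "unresolved"))
            continue
        if _overlaps(trees.get("telomere", {}), peak):
            annotations.append(PeakAnnotation(peak, "telomere"))
            continue
        if _overlaps(trees.get("rRNA", {}), peak):
            annotations.append(PeakAnnotation(peak, "rRNA"))
            continue
        best_orf_overlap = 0
        for hit in trees.get("ORF", {}).get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end):
            ov = min(peak.end, hit.end) - max(peak.start, hit.begin)
            best_orf_overlap = max(best_orf_overlap, ov)
        if best_orf_overlap >= inside_orf_min_overlap * len(peak):
            annotations.append(PeakAnnotation(peak, "inside_ORF"))
            continue
        mid = peak.midpoint
        oclass = None
        for region in io_by_chrom.get(peak.chrom, []):
            if region.contains(mid):
                oclass = region.oclass
                break
        if oclass is None:
            logger.warning(
                "peak %s midpoint %d not inside any interORF region", peak.name, mid
            )
        annotations.append(PeakAnnotation(peak, "interORF", oclass=oclass))
    return annotations


def _overlaps(trees: Mapping[str, IntervalTree], peak: FlexRegion) -> bool:
    tree = trees.get(peak.chrom)
    return bool(tree is not None and tree.overlap(peak.start, peak.end))


def placement_counts(annotations: Iterable[PeakAnnotation]) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for a in annotations:
        counts[a.placement] += 1
    return dict(counts)


def oclass_counts(annotations: Iterable[PeakAnnotation]) -> dict[str, int]:
    counts = {c: 0 for c in ORIENTATION_CLASSES}
    for a in annotations:
        if a.placement == "interORF" and a.oclass:
            counts[a.oclass] += 1
    return counts


# ---------------------------------------------------------------------------
# UTR overlap

class UtrSummary(NamedTuple):
    n_peaks_3utr: int
    n_orfs_3utr: int
    n_peaks_5utr: int
    n_orfs_5utr: int


def utr_intervals(
    orfs: Sequence[FeatureInterval],
    utrs: Sequence[UtrRecord],
    default_utr5: int | None = None,
    default_utr3: int | None = None,
) -> tuple[list[FeatureInterval], list[FeatureInterval]]:
    """Derive 5'/3'UTR intervals from ORF coordinates and measured lengths.

    The 3'UTR extends ``utr3_len`` nt downstream of the ORF's 3' end on its
    strand, the 5'UTR upstream likewise.  ORFs missing from the table fall
    back to the configurable defaults; when those are None, the mean lengths
    of the supplied table are used (mirroring the use of average lengths for
    unmeasured ORFs in the source UTR-length datasets).
    """
    table = {u.orf_id: u for u in utrs}
    if utrs:
        mean5 = int(round(np.mean([u.utr5_len for u in utrs])))
        mean3 = int(round(np.mean([u.utr3_len for u in utrs])))
    else:
        mean5 = mean3 = 0
    fb5 = default_utr5 if default_utr5 is not None else mean5
    fb3 = default_utr3 if default_utr3 is not None else mean3
    utr5_ivs: list[FeatureInterval] = []
    utr3_ivs: list[FeatureInterval] = []
    for orf in orfs:
        if orf.ftype != "ORF":
            continue
        rec = table.get(orf.fid)
        len5 = rec.utr5_len if rec else fb5
        len3 = rec.utr3_len if rec else fb3
        if rec is None:
            logger.debug("ORF %s missing from UTR table; using defaults", orf.fid)
        if orf.strand == "+":
            u5 = (max(0, orf.start - len5), orf.start)
            u3 = (orf.end, orf.end + len3)
        else:
            u5 = (orf.end, orf.end + len5)
            u3 = (max(0, orf.start - len3), orf.start)
        if len5 > 0 and u5[0] < u5[1]:
            utr5_ivs.append(FeatureInterval(orf.chrom, u5[0], u5[1], orf.strand, "5UTR", orf.fid))
        if len3 > 0 and u3[0] < u3[1]:
            utr3_ivs.append(FeatureInterval(orf.chrom, u3[0], u3[1], orf.strand, "3UTR", orf.fid))
    return utr5_ivs, utr3_ivs


def utr_overlap(
    peaks: Sequence[FlexRegion],
    orfs: Sequence[FeatureInterval],
    utrs: Sequence[UtrRecord],
    default_utr5: int | None = None,
    default_utr3: int | None = None,
) -> tuple[list[tuple[FlexRegion, list[str], list[str]]], UtrSummary]:
    """Per-peak 3'/5'UTR hits (>= 1 bp overlap) plus the genome-wide summary.

    One peak may hit the UTRs of both flanking ORFs (e.g. two convergent
    3'UTRs); the summary counts peaks with any 3'UTR hit and distinct ORFs
    with a peak in their 3'UTR, and likewise for 5'UTRs.
    """
    utr5_ivs, utr3_ivs = utr_intervals(orfs, utrs, default_utr5, default_utr3)
    tree5 = _interval_forest(utr5_ivs)
    tree3 = _interval_forest(utr3_ivs)
    hits: list[tuple[FlexRegion, list[str], list[str]]] = []
    orfs3: set[str] = set()
    orfs5: set[str] = set()
    n3 = n5 = 0
    for peak in peaks:
        h3 = sorted({iv.data.fid for iv in tree3.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end)})
        h5 = sorted({iv.data.fid for iv in tree5.get(peak.chrom, IntervalTree()).overlap(peak.start, peak.end)})
        hits.append((peak, h3, h5))
        if h3:
            n3 += 1
            orfs3.update(h3)
        if h5:
            n5 += 1
            orfs5.update(h5)
    return hits, UtrSummary(n3, len(orfs3), n5, len(orfs5))


def _interval_forest(features: Iterable[FeatureInterval]) -> dict[str, IntervalTree]:
    forest: dict[str, IntervalTree] = {}
    for f in features:
        forest.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return forest


# ---------------------------------------------------------------------------
# AT tandem-repeat detection

_FAMILY_PATTERNS: dict[str, tuple[str, ...]] = {
    "(TA)n": ("TA",),
    "(TTA)n": ("TTA", "TAA"),  # the two strands of the same trinucleotide repeat
}


def find_at_repeats(
    seq,
    min_len: int = 20,
    min_purity: float = 0.8,
) -> list[FeatureInterval]:
    """Detect AT tandem-repeat tracts: (TA)n, (TTA)n and generic AT-rich runs.

    A tract is a maximal interval of length >= ``min_len`` in which the
    fraction of positions matching a fixed phasing of the family's repeat
    unit (period 2 for TA, period 3 for TTA/TAA, any A/T for AT-rich) is at
    least ``min_purity``.  More specific families take precedence: an
    interval already called (TA)n suppresses overlapping (TTA)n and AT-rich
    calls.  Tract boundaries always sit on matching positions.

    Returns repeat :class:`FeatureInterval` records (ftype=repeat, fid=family).
    """
    if min_len < 4:
        raise ValueError("min_len must be >= 4")
    chrom = getattr(seq, "chrom", "seq")
    s = getattr(seq, "seq", seq)
    arr = np.frombuffer(s.encode("ascii"), dtype="S1")

    def phase_matches(pattern: str) -> list[np.ndarray]:
        k = len(pattern)
        pat = np.frombuffer(pattern.encode("ascii"), dtype="S1")
        idx = np.arange(len(s))
        return [arr == pat[(idx + phase) % k] for phase in range(k)]

    found: list[FeatureInterval] = []
    occupied: list[tuple[int, int]] = []

    def free(start: int, end: int) -> bool:
        return all(end <= a or start >= b for a, b in occupied)

    for family, patterns in _FAMILY_PATTERNS.items():
        candidates: list[tuple[int, int, int]] = []  # (start, end, n_matches)
        for pattern in patterns:
            for match in phase_matches(pattern):
                candidates.extend(_pure_segments(match, min_len, min_purity))
        for start, end, _ in _select_disjoint(candidates):
            if free(start, end):
                found.append(FeatureInterval(chrom, start, end, ".", "repeat", family))
                occupied.append((start, end))
    at_match = (arr == b"A") | (arr == b"T")
    for start, end, _ in _select_disjoint(_pure_segments(at_match, min_len, min_purity)):
        if free(start, end):
            found.append(FeatureInterval(chrom, start, end, ".", "repeat", "AT-rich"))
            occupied.append((start, end))
    found.sort(key=lambda f: f.start)
    return found


def _pure_segments(match: np.ndarray, min_len: int, min_purity: float) -> list[tuple[int, int, int]]:
    """High-purity segments of a boolean match array.

    Maximal-scoring-segment walk with +1 per match and -p/(1-p) per mismatch,
    so a positive-scoring segment has purity > ``min_purity`` by
    construction.  The penalty keeps a pure tract from creeping into merely
    AT-biased flanking sequence, and segment boundaries always sit on
    matching positions.  Returns (start, end, n_matches) tuples of segments
    with length >= ``min_len``.
    """
    penalty = min_purity / (1.0 - min_purity)
    segments: list[tuple[int, int, int]] = []
    cur_start: int | None = None
    cur_score = best_score = 0.0
    best_end = 0

    def emit(start: int, end: int) -> None:
        if end - start >= min_len:
            segments.append((start, end, int(match[start:end].sum())))

    for i, m in enumerate(match):
        if cur_start is None:
            if not m:
                continue
            cur_start, cur_score, best_score, best_end = i, 0.0, 0.0, i
        cur_score += 1.0 if m else -penalty
        if cur_score > best_score:
            best_score, best_end = cur_score, i + 1
        if cur_score < -1e-9:  # tolerance: p/(1-p) is not exact in binary
            emit(cur_start, best_end)
            cur_start = None
    if cur_start is not None:
        emit(cur_start, best_end)
    return segments


def _select_disjoint(candidates: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Greedy best-first selection of non-overlapping candidate segments."""
    chosen: list[tuple[int, int, int]] = []
    for cand in sorted(candidates, key=lambda c: (-(c[2]), c[0])):
        if all(cand[1] <= a or cand[0] >= b for a, b, _ in chosen):
            chosen.append(cand)
    return sorted(chosen)


def repeat_midpoint(repeat: FeatureInterval) -> int:
    return (repeat.start + repeat.end) // 2


def assign_repeats(
    annotations: Sequence[PeakAnnotation], repeats: Sequence[FeatureInterval]
) -> None:
    """Attach to each peak the repeat intervals overlapping its footprint."""
    forest = _interval_forest(repeats)
    for a in annotations:
        tree = forest.get(a.peak.chrom)
        if tree is None:
            a.repeats = []
            continue
        a.repeats = sorted(
            (iv.data for iv in tree.overlap(a.peak.start, a.peak.end)),
            key=lambda f: f.start,
        )


# ---------------------------------------------------------------------------
# poly(A)-site distance analysis

@dataclass
class PolyaDistanceResult:
    """Distances from intense poly(A) sites to the nearest in-peak repeat midpoint."""

    n_scored: int  # sites passing the score filter
    distances: np.ndarray  # retained distances (<= max_dist), unsigned
    bin_edges: np.ndarray
    counts: np.ndarray
    frac_within_25: float
    frac_within_100: float

    @property
    def n_retained(self) -> int:
        return len(self.distances)


def polya_distance(
    sites: Sequence[ScoredSite],
    peak_annotations: Sequence[PeakAnnotation],
    score_min: float = 945.0,
    max_dist: int = 500,
    families: Sequence[str] | None = None,
    bin_width: int = 25,
) -> PolyaDistanceResult:
    """Distance of each intense cleavage site to the nearest in-peak repeat.

    Sites with score >= ``score_min`` are kept; for each, the unsigned
    distance to the nearest midpoint of a repeat lying within a peak on the
    same chromosome is computed, and distances above ``max_dist`` are
    discarded.  ``families`` optionally restricts the repeats considered
    (e.g. ``["(TA)n"]``).  Fractions within 25 and 100 nt are reported over
    the retained sites.  Result is independent of site input order.
    """
    in_peak_repeats = [rep for a in peak_annotations for rep in a.repeats]
    return polya_distance_to_repeats(
        sites, in_peak_repeats, score_min, max_dist, families, bin_width
    )


def polya_distance_to_repeats(
    sites: Sequence[ScoredSite],
    repeats: Sequence[FeatureInterval],
    score_min: float = 945.0,
    max_dist: int = 500,
    families: Sequence[str] | None = None,
    bin_width: int = 25,
) -> PolyaDistanceResult:
    """Same analysis with an explicit list of (in-peak) repeat intervals."""
    mids: dict[str, list[int]] = defaultdict(list)
    for rep in repeats:
        if families is None or rep.fid in families:
            mids[rep.chrom].append(repeat_midpoint(rep))
    if not any(mids.values()):
        logger.warning("no repeats within peaks: poly(A) distance analysis is empty")
        return PolyaDistanceResult(
            0, np.empty(0, dtype=int), np.array([0, bin_width]), np.zeros(1, dtype=int), 0.0, 0.0
        )
    mid_arrays = {c: np.array(sorted(v)) for c, v in mids.items()}
    scored = [s for s in sites if s.score >= score_min]
    dists: list[int] = []
    for site in scored:
        arr = mid_arrays.get(site.chrom)
        if arr is None:
            continue
        i = np.searchsorted(arr, site.pos)
        best = min(
            abs(site.pos - arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)
        )
        if best <= max_dist:
            dists.append(int(best))
    darr = np.array(sorted(dists), dtype=int)
    n_bins = max(1, int(max_dist // bin_width) + (1 if max_dist % bin_width else 0))
    edges = np.arange(n_bins + 1) * bin_width
    if edges[-1] < max_dist:
        edges = np.append(edges, max_dist)
    counts, _ = np.histogram(darr, bins=edges)
    n = len(darr)
    f25 = float((darr <= 25).sum() / n) if n else 0.0
    f100 = float((darr <= 100).sum() / n) if n else 0.0
    return PolyaDistanceResult(len(scored), darr, edges, counts, f25, f100)


# ---------------------------------------------------------------------------
# generic nearest-feature distance

def nearest_feature_distance(
    peaks: Sequence[FlexRegion], features: Sequence[FeatureInterval]
) -> np.ndarray:
    """Edge-to-edge distance (bp) from each peak to its nearest feature.

    Returns one value per peak (0 if overlapping, NaN for a peak whose
    chromosome carries no features); if peaks and features share no
    chromosome at all, returns an empty array with a warning.
    """
    by_chrom: dict[str, list[FeatureInterval]] = defaultdict(list)
    for f in features:
        by_chrom[f.chrom].append(f)
    if not any(p.chrom in by_chrom for p in peaks):
        logger.warning("peaks and features share no chromosome")
        return np.empty(0)
    out = np.full(len(peaks), np.nan)
    for i, p in enumerate(peaks):
        feats = by_chrom.get(p.chrom)
        if not feats:
            continue
        out[i] = min(_edge_distance(p.start, p.end, f.start, f.end) for f in feats)
    return out


def _edge_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0
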