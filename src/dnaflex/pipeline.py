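"""End-to-end orchestration: profile -> peaks -> annotation -> statistics.

This is the programmatic equivalent of the ``run-all`` command: given a
genome and its annotations (plus the optional UTR, poly(A)-site, half-life
and repeat inputs), run every stage with one configuration object and return
a single result bundle.  Both the CLI and the reproduction script are thin
wrappers around :func:`run_pipeline`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import annotate as ann
from . import stats as st
from .core import FlexibilityProfile, ProfileConfig, StepTable, default_step_table, profile_genome
from .io import FeatureInterval, GenomeSequence, HalfLifeRecord, ScoredSite, UtrRecord
from .peaks import (
    FlexRegion,
    GenomeStats,
    PeakConfig,
    call_regions,
    classify_peaks,
    genome_stats,
    peak_length_summary,
    peaks_only,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotateConfig:
    """Defaults for the co-localization stages."""

    repeat_min_len: int = 20
    repeat_min_purity: float = 0.8
    inside_orf_min_overlap: float = 0.5
    polya_score_min: float = 945.0
    polya_max_dist: int = 500
    default_utr5: int | None = None  # None -> mean of the supplied table
    default_utr3: int | None = None


@dataclass
class PipelineResult:
    profiles: list[FlexibilityProfile]
    stats: GenomeStats
    regions: list[FlexRegion]  # all flexible regions, peaks and under-threshold
    peaks: list[FlexRegion]
    annotations: list[ann.PeakAnnotation]
    interorf_regions: list[ann.InterOrfRegion]
    utr_summary: ann.UtrSummary | None = None
    polya: ann.PolyaDistanceResult | None = None
    enrichment: list[st.EnrichmentResult] = field(default_factory=list)
    halflife_overall: st.GroupComparison | None = None
    halflife_polya: st.GroupComparison | None = None

    def placement_counts(self) -> dict[str, int]:
        return ann.placement_counts(self.annotations)

    def oclass_counts(self) -> dict[str, int]:
        return ann.oclass_counts(self.annotations)

    def length_summary(self):
        return peak_length_summary(self.peaks)


def run_pipeline(
    genomes: Sequence[GenomeSequence],
    features: Sequence[FeatureInterval],
    *,
    table: StepTable | None = None,
    profile_cfg: ProfileConfig | None = None,
    peak_cfg: PeakConfig | None = None,
    annotate_cfg: AnnotateConfig | None = None,
    utrs: Sequence[UtrRecord] | None = None,
    sites: Sequence[ScoredSite] | None = None,
    halflife: Sequence[HalfLifeRecord] | None = None,
    repeats: Sequence[FeatureInterval] | None = None,
    chrom_name_map: Mapping[str, str] | None = None,
) -> PipelineResult:
    """Run the full analysis.

    ``repeats`` may come from a RepeatMasker ``.out`` file; when absent, the
    built-in AT tandem-repeat detector is run on the peak chromosomes.
    Optional inputs switch their downstream stages on and off.
    """
    table = table or default_step_table()
    profile_cfg = profile_cfg or ProfileConfig()
    peak_cfg = peak_cfg or PeakConfig()
    acfg = annotate_cfg or AnnotateConfig()

    profiles = profile_genome(genomes, table, profile_cfg)
    gstats = genome_stats(profiles, peak_cfg)
    regions: list[FlexRegion] = []
    for profile in profiles:
        regions.extend(call_regions(profile, gstats.preselect))
    regions = classify_peaks(regions, peak_cfg.peak_theta, chrom_name_map)
    peaks = peaks_only(regions)
    logger.info(
        "preselect S=%.3f deg -> %d flexible regions, %d peaks (theta=%.1f)",
        gstats.preselect, len(regions), len(peaks), peak_cfg.peak_theta,
    )

    annotations = ann.locate_peaks(peaks, features, acfg.inside_orf_min_overlap)
    interorf = ann.classify_interorf([f for f in features if f.ftype == "ORF"])

    if repeats is None:
        by_chrom = {g.chrom: g for g in genomes}
        repeats = []
        for chrom in sorted({p.chrom for p in peaks}):
            repeats.extend(
                ann.find_at_repeats(by_chrom[chrom], acfg.repeat_min_len, acfg.repeat_min_purity)
            )
    ann.assign_repeats(annotations, repeats)

    result = PipelineResult(
        profiles=profiles,
        stats=gstats,
        regions=regions,
        peaks=peaks,
        annotations=annotations,
        interorf_regions=interorf,
    )

    orfs = [f for f in features if f.ftype == "ORF"]
    utr3_by_peak: dict[int, list[str]] = {}
    if utrs is not None:
        hits, summary = ann.utr_overlap(peaks, orfs, utrs, acfg.default_utr5, acfg.default_utr3)
        for a, (_, h3, h5) in zip(annotations, hits):
            a.utr3_orfs, a.utr5_orfs = h3, h5
        result.utr_summary = summary

    if sites is not None:
        result.polya = ann.polya_distance(
            sites, annotations, acfg.polya_score_min, acfg.polya_max_dist
        )

    class_counts = ann.interorf_class_counts(interorf)
    n_regions_with_3utr = None
    if utrs is not None:
        _, utr3_ivs = ann.utr_intervals(orfs, utrs, acfg.default_utr5, acfg.default_utr3)
        by_chrom: dict[str, list] = {}
        for iv in utr3_ivs:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        n_regions_with_3utr = sum(
            1
            for r in interorf
            if any(iv.start < r.end and iv.end > r.start for iv in by_chrom.get(r.chrom, []))
        )
    background = st.GenomeBackground(
        interorf_bp=sum(len(r) for r in interorf),
        orf_bp=sum(len(f) for f in orfs),
        interorf_class_counts=class_counts,
        n_regions_with_3utr=n_regions_with_3utr,
        n_regions=len(interorf),
    )
    n_peaks_3utr = (
        sum(1 for a in result.annotations if a.utr3_orfs) if utrs is not None else None
    )
    result.enrichment = st.enrichment_tables(
        result.placement_counts(), result.oclass_counts(), background, n_peaks_3utr
    )

    if halflife is not None and utrs is not None:
        flagged = {o for a in annotations for o in a.utr3_orfs}
        in_group_o, out_group_o, in_group_p, out_group_p = [], [], [], []
        for rec in halflife:
            (in_group_o if rec.orf_id in flagged else out_group_o).append(rec.overall_halflife)
            (in_group_p if rec.orf_id in flagged else out_group_p).append(rec.polya_halflife)
        labels = ("3utr_peak", "background")
        if len(in_group_o) >= 2 and len(out_group_o) >= 2:
            result.halflife_overall = st.welch_t_test(in_group_o, out_group_o, labels)
            result.halflife_polya = st.welch_t_test(in_group_p, out_group_p, labels)
        else:
            logger.warning("too few ORFs with half-life data in a group: t-tests skipped")
    return result
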