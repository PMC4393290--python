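"""Genome-wide threshold derivation, region extraction and peak classification.

The flexibility-value distribution over all windows of a genome is close to
Gaussian except for a heavy upper tail.  Peak calling exploits this with a
two-threshold rule:

1. *Preselection*: pool every defined window value across chromosomes,
   compute mean and population standard deviation, and set the preselection
   threshold ``S = mean + k * sd`` (default k = 2 — roughly where Gaussianity
   is lost).  Maximal runs of consecutive windows with value >= S become
   candidate flexible regions; a missing window breaks a run.  A region's
   genomic footprint is the union of its member windows' footprints.
2. *Peak status*: a region whose maximal window value reaches
   ``theta`` (default 13.8 deg, the peak threshold established for
   flexibility analysis of chromosomal fragile sites) is a flexibility peak;
   otherwise it is an under-threshold flexible region.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .core import FlexibilityProfile
from .io import chrom_numeral

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakConfig:
    """Two-threshold peak-calling settings.

    ``preselect_sd_mult`` is k in S = mean + k*sd; ``peak_theta`` is the peak
    threshold in degrees; ``explicit_preselect`` overrides the derived S.
    """

    preselect_sd_mult: float = 2.0
    peak_theta: float = 13.8
    explicit_preselect: float | None = None

    def __post_init__(self) -> None:
        if self.preselect_sd_mult <= 0:
            raise ValueError("preselect_sd_mult must be > 0")

    def resolve_preselect(self, mean: float, sd: float) -> float:
        if self.explicit_preselect is not None:
            return self.explicit_preselect
        return mean + self.preselect_sd_mult * sd


@dataclass
class FlexRegion:
    """A maximal run of consecutive windows at/above the preselection threshold."""

    chrom: str
    start: int
    end: int
    max_value: float
    mean_value: float
    n_windows: int
    status: str = "under_threshold"  # or "peak"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeStats(NamedTuple):
    mean: float
    sd: float
    preselect: float


def genome_stats(
    profiles: Iterable[FlexibilityProfile], cfg: PeakConfig | None = None
) -> GenomeStats:
    """Pooled mean / population sd over all defined window values, plus S.

    One genome-wide threshold is derived from the pooled values of every
    chromosome (the population n-denominator sd, not the sample one).
    """
    cfg = cfg or PeakConfig()
    pooled = np.concatenate([p.values for p in profiles]) if profiles else np.empty(0)
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("no defined window values: cannot derive genome statistics")
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=0))
    return GenomeStats(mean, sd, cfg.resolve_preselect(mean, sd))


def per_chromosome_stats(profiles: Iterable[FlexibilityProfile]) -> dict[str, tuple[float, float]]:
    """Diagnostic per-chromosome (mean, sd) of defined window values."""
    out = {}
    for p in profiles:
        vals = p.values[p.defined()]
        if vals.size:
            out[p.chrom] = (float(vals.mean()), float(vals.std(ddof=0)))
    return out


def call_regions(profile: FlexibilityProfile, preselect: float) -> list[FlexRegion]:
    """Extract maximal runs of consecutive windows with value >= S.

    A missing (NaN) window breaks a run; runs are never merged across gaps.
    The region footprint is ``[first window start, last window start + L)``,
    i.e. the union of member-window footprints, so the minimum region length
    is the window length L.
    """
    vals = profile.values
    if vals.size == 0:
        return []
    above = np.zeros(vals.size, dtype=bool)
    defined = ~np.isnan(vals)
    above[defined] = vals[defined] >= preselect
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]  # window-index runs [start, end)
    L, s = profile.window_len, profile.shift
    regions = []
    for i, j in zip(starts, ends):
        member = vals[i:j]
        regions.append(
            FlexRegion(
                chrom=profile.chrom,
                start=int(i * s),
                end=int((j - 1) * s + L),
                max_value=float(member.max()),
                mean_value=float(member.mean()),
                n_windows=int(j - i),
            )
        )
    return regions


def classify_peaks(
    regions: Sequence[FlexRegion],
    theta: float = 13.8,
    name_map: Mapping[str, str] | None = None,
) -> list[FlexRegion]:
    """Set peak/under-threshold status and name peaks in coordinate order.

    A region is a peak iff its maximal window value reaches ``theta``.  Peaks
    (only) are named ``peak<ROMAN>-<k>`` with k ascending by coordinate per
    chromosome; the chromosome-to-numeral mapping is configurable.
    """
    counters: dict[str, int] = defaultdict(int)
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    for region in ordered:
        if region.max_value >= theta:
            region.status = "peak"
            counters[region.chrom] += 1
            region.name = f"peak{chrom_numeral(region.chrom, name_map)}-{counters[region.chrom]}"
        else:
            region.status = "under_threshold"
            region.name = None
    return ordered


def peaks_only(regions: Iterable[FlexRegion]) -> list[FlexRegion]:
    return [r for r in regions if r.status == "peak"]


@dataclass
class LengthSummary:
    n: int
    mean_len: float
    longest: int
    shortest: int


def peak_length_summary(peaks: Sequence[FlexRegion]) -> LengthSummary:
    if not peaks:
        return LengthSummary(0, float("nan"), 0, 0)
    lengths = [len(p) for p in peaks]
    return LengthSummary(len(lengths), float(np.mean(lengths)), max(lengths), min(lengths))


class DistanceHistogram(NamedTuple):
    distances: np.ndarray  # one nearest-neighbour distance per contributing peak
    bin_edges: np.ndarray
    counts: np.ndarray


def interpeak_distances(
    peaks: Sequence[FlexRegion], bin_width: int = 5000
) -> DistanceHistogram:
    """Per-peak distance to the nearest other peak on the same chromosome.

    Distances are edge-to-edge (0 if overlapping); a chromosome with fewer
    than two peaks contributes nothing.  The histogram uses fixed-width bins
    (default 5 kb) from zero to the largest distance.
    """
    by_chrom: dict[str, list[FlexRegion]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)
    dists: list[int] = []
    for chrom_peaks in by_chrom.values():
        chrom_peaks.sort(key=lambda r: r.start)
        if len(chrom_peaks) < 2:
            continue
        for i, p in enumerate(chrom_peaks):
            candidates = []
            if i > 0:
                candidates.append(max(0, p.start - chrom_peaks[i - 1].end))
            if i < len(chrom_peaks) - 1:
                candidates.append(max(0, chrom_peaks[i + 1].start - p.end))
            dists.append(min(candidates))
    arr = np.array(sorted(dists), dtype=int)
    if arr.size:
        n_bins = int(arr.max() // bin_width) + 1
        edges = np.arange(n_bins + 1) * bin_width
        counts, _ = np.histogram(arr, bins=edges)
    else:
        edges = np.array([0, bin_width])
        counts = np.zeros(1, dtype=int)
    return DistanceHistogram(arr, edges, counts)


@dataclass
class ValueDistribution:
    """Normalized window-value histogram with a matched-Gaussian comparison."""

    bin_edges: np.ndarray
    density: np.ndarray
    gaussian_density: np.ndarray | None
    mean: float
    sd: float
    tail_min: float
    excess_tail_mass: float | None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def value_distribution(
    profiles: Iterable[FlexibilityProfile],
    tail_min: float = 12.0,
    bin_width: float = 0.05,
) -> ValueDistribution:
    """Histogram of window values vs a Gaussian with the same mean and sd.

    The histogram is normalized to unit area.  The Gaussian density is
    evaluated at bin centers from the pooled mean/sd, and the excess tail
    mass (observed minus Gaussian, summed over bins whose center is at or
    above ``tail_min``) quantifies the non-Gaussian upper tail that the peak
    caller exploits.  With sd = 0 the comparison is skipped with a warning.
    """
    pooled = np.concatenate([p.values for p in profiles])
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size < 2:
        raise ValueError("need at least 2 defined window values")
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    density, _ = np.histogram(pooled, bins=edges, density=True)
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=0))
    if sd == 0:
        logger.warning("degenerate sd=0: skipping Gaussian comparison")
        return ValueDistribution(edges, density, None, mean, sd, tail_min, None)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gauss = sps.norm.pdf(centers, loc=mean, scale=sd)
    widths = np.diff(edges)
    tail = centers >= tail_min
    excess = float(((density[tail] - gauss[tail]) * widths[tail]).sum())
    return ValueDistribution(edges, density, gauss, mean, sd, tail_min, excess)
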