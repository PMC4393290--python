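"""Enrichment and group-comparison statistics.

Two tests carry the whole analysis: Fisher's exact test on 2x2 contingency
tables (is a peak class over- or under-represented against the genome
background?) and Welch's unequal-variance t test (do ORFs with a flexible
3'UTR produce shorter-lived transcripts?).  Both are authored here from the
distribution primitives so their outputs can be validated against exact
enumeration and closed forms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: relative slack when comparing hypergeometric point probabilities for the
#: two-sided tail (exact ties computed in floating point)
_TIE_SLACK = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows in/out of class, columns observed/background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError(f"counts must be non-negative integers, got {v}")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) margins."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value.

    With margins fixed, the count ``a`` follows a hypergeometric law; the
    two-sided p is the sum of the point probabilities of every table whose
    probability does not exceed that of the observed one (the usual
    "probability mass <= observed" convention, with 1e-12 relative slack for
    floating-point ties).  A zero margin makes the table degenerate and the
    p-value 1 by convention.
    """
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        logger.info("degenerate 2x2 table (zero margin): p = 1 by convention")
        return 1.0
    n = table.total
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(table.a, n, r1, c1)
    qualifies = pmf <= p_obs * (1 + _TIE_SLACK)
    if qualifies.all():  # the observed table is the mode: p is exactly 1
        return 1.0
    return min(1.0, float(pmf[qualifies].sum()))


@dataclass
class GroupComparison:
    """Welch two-sample comparison: per-group summaries plus the test."""

    labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    se: tuple[float, float]
    t: float
    df: float
    p: float


def welch_t_test(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("x", "y"),
) -> GroupComparison:
    """Welch's unequal-variance t test, two-sided.

    Missing values (NaN) are dropped with a logged count; each group needs
    n >= 2 afterwards.  The statistic is
    t = (mx - my) / sqrt(sx^2/nx + sy^2/ny) with sample (n-1) variances, and
    the degrees of freedom follow Welch-Satterthwaite.  Per-group standard
    errors are sd/sqrt(n).  If both groups have zero variance and equal
    means, t = 0 and p = 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n_dropped = int(np.isnan(xa).sum() + np.isnan(ya).sum())
    if n_dropped:
        logger.info("welch_t_test: dropped %d missing values", n_dropped)
    xa = xa[~np.isnan(xa)]
    ya = ya[~np.isnan(ya)]
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("each group needs at least 2 non-missing values")
    nx, ny = len(xa), len(ya)
    mx, my = float(xa.mean()), float(ya.mean())
    vx, vy = float(xa.var(ddof=1)), float(ya.var(ddof=1))
    sex, sey = math.sqrt(vx / nx), math.sqrt(vy / ny)
    denom_sq = vx / nx + vy / ny
    if denom_sq == 0:
        t_stat, df, p = 0.0, float(nx + ny - 2), 1.0
        if mx != my:
            # zero spread but different means: infinitely strong evidence
            t_stat, p = math.copysign(math.inf, mx - my), 0.0
    else:
        t_stat = (mx - my) / math.sqrt(denom_sq)
        df = denom_sq**2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        p = float(2 * sps.t.sf(abs(t_stat), df))
    return GroupComparison(labels, (nx, ny), (mx, my), (sex, sey), float(t_stat), float(df), p)


# ---------------------------------------------------------------------------
# enrichment report

@dataclass(frozen=True)
class GenomeBackground:
    """Background counts the enrichment tests compare against.

    ``interorf_bp`` / ``orf_bp`` are genomic base-pair totals;
    ``interorf_class_counts`` are the genome's interORF region counts per
    orientation class; ``n_regions_with_3utr`` / ``n_regions`` optionally
    describe how many interORF regions overlap an annotated 3'UTR.
    """

    interorf_bp: int
    orf_bp: int
    interorf_class_counts: Mapping[str, int]
    n_regions_with_3utr: int | None = None
    n_regions: int | None = None


@dataclass
class EnrichmentResult:
    name: str
    table: ContingencyTable2x2
    p: float


def enrichment_tables(
    placement_counts: Mapping[str, int],
    oclass_counts: Mapping[str, int],
    background: GenomeBackground,
    n_peaks_3utr: int | None = None,
) -> list[EnrichmentResult]:
    """Build and test the pipeline's 2x2 tables.

    (i)  interORF vs inside-ORF placement of peaks against the genomic
         base-pair split between interORF and ORF territory;
    (ii) convergent excess and (iii) divergent deficit of interORF peaks
         against the genome's interORF orientation-class counts;
    (iv) 3'UTR co-localization of peaks against the fraction of interORF
         regions overlapping a 3'UTR (skipped with a message when the
         background counts are unavailable).

    The constructed tables are returned alongside the p-values so every
    margin can be audited against the input counts.
    """
    results: list[EnrichmentResult] = []
    n_inter = placement_counts.get("interORF", 0)
    n_inside = placement_counts.get("inside_ORF", 0)
    if n_inter + n_inside > 0:
        t = ContingencyTable2x2(n_inter, background.interorf_bp, n_inside, background.orf_bp)
        results.append(EnrichmentResult("peaks_interORF_vs_ORF", t, fisher_exact(t)))
    n_classed = sum(oclass_counts.values())
    for cls, label in (("convergent", "convergent_excess"), ("divergent", "divergent_deficit")):
        k = oclass_counts.get(cls, 0)
        bg_in = background.interorf_class_counts.get(cls, 0)
        bg_out = sum(background.interorf_class_counts.values()) - bg_in
        if n_classed > 0 and bg_in + bg_out > 0:
            t = ContingencyTable2x2(k, bg_in, n_classed - k, bg_out)
            results.append(EnrichmentResult(label, t, fisher_exact(t)))
    if n_peaks_3utr is not None:
        if background.n_regions_with_3utr is None or background.n_regions is None:
            logger.warning("3'UTR background counts unavailable: UTR enrichment test skipped")
        else:
            t = ContingencyTable2x2(
                n_peaks_3utr,
                background.n_regions_with_3utr,
                max(0, n_inter - n_peaks_3utr),
                background.n_regions - background.n_regions_with_3utr,
            )
            results.append(EnrichmentResult("peaks_on_3utr", t, fisher_exact(t)))
    return results


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (optional; reports are uncorrected)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = np.minimum(q, 1.0)
    return out


def format_report(results: Iterable[EnrichmentResult]) -> str:
    """Tab-separated report: test name, table counts, p-value."""
    lines = ["test\ta\tb\tc\td\tp_value"]
    for r in results:
        t = r.table
        lines.append(f"{r.name}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t{r.p:.6g}")
    return "\n".join(lines) + "\n"
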