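"""Synthetic genome generator with exact ground truth.

Emulates the statistical structure the pipeline is built for: an AT-rich
i.i.d. background at a yeast-like GC fraction, a dense tandem gene layout
whose intergenic gaps cycle through convergent / unidirectional / divergent
orientation in a 1:2:1 ratio, planted (TA)n tracts long enough that the
sliding-window flexibility mean crosses the peak threshold, poly(A) cleavage
sites placed at known offsets from tract midpoints (concentrated within
5-25 nt), and mRNA half-life tables in which the ORFs carrying a flexible
3'UTR draw from a lognormal with a lower median.

Everything is deterministic given (spec, seed), and the manifest records the
exact coordinates and classes of every planted element, so downstream stages
can be scored for recall rather than eyeballed.  Each planted tract is
framed by a single G/C guard base on either side, pinning its boundaries for
exact ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ProfileConfig, StepTable, default_step_table
from .io import (
    FeatureInterval,
    GenomeSequence,
    HalfLifeRecord,
    ScoredSite,
    UtrRecord,
    write_fasta,
    write_halflife_table,
    write_site_table,
    write_utr_table,
)

logger = logging.getLogger(__name__)

#: internal-gap orientation cycle giving the 1:2:1 divergent:unidirectional:convergent mix
_GAP_CYCLE = ("convergent", "unidirectional", "divergent", "unidirectional")


@dataclass(frozen=True)
class PlantedRepeat:
    """An explicitly requested tandem-repeat planting."""

    chrom_index: int
    pos: int
    unit: str  # "TA" or "TTA"
    n_copies: int
    sub_rate: float = 0.0


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for the synthetic genome.

    Defaults describe a compact, yeast-like genome: GC 0.38, ~1.4 kb genes
    separated by a few hundred bp, UTRs of tens to a couple of hundred nt,
    and flexibility tracts of 60 TA copies (120 bp) with 1% substitution —
    long enough that a 100 bp window fits inside the pure tract.
    """

    n_chrom: int = 3
    chrom_len: int = 100_000
    gc: float = 0.38
    # gene layout
    gene_len_range: tuple[int, int] = (800, 2000)
    gap_len_range: tuple[int, int] = (300, 700)
    terminal_margin: int = 2000
    utr5_range: tuple[int, int] = (40, 160)
    utr3_range: tuple[int, int] = (80, 220)
    # planted flexibility tracts
    n_peak_gaps_per_chrom: int = 6
    peak_repeat_unit: str = "TA"
    peak_repeat_copies: int = 60
    peak_sub_rate: float = 0.01
    plant_telomere_peak: bool = True
    plant_rrna_peak: bool = True
    extra_repeats: tuple[PlantedRepeat, ...] = ()
    # poly(A) site model: offsets from tract midpoints, mixture of a near
    # component on [5, 25] nt and a far component on [26, 500] nt
    polya_sites_per_repeat: int = 12
    polya_frac_near: float = 0.75
    polya_near_range: tuple[int, int] = (5, 25)
    polya_far_range: tuple[int, int] = (26, 500)
    polya_frac_intense: float = 0.6
    polya_intense_score: tuple[float, float] = (945.0, 20_000.0)
    polya_weak_score: tuple[float, float] = (1.0, 944.0)
    n_background_sites_per_chrom: int = 25
    # mRNA half-life model (minutes, lognormal medians / log-sd)
    halflife_overall_background: float = 22.0
    halflife_overall_flagged: float = 13.0
    halflife_polya_background: float = 17.0
    halflife_polya_flagged: float = 10.0
    halflife_log_sd: float = 0.45
    halflife_missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("gc must be in (0, 1)")
        if self.peak_repeat_unit not in {"TA", "TTA"}:
            raise ValueError("peak_repeat_unit must be TA or TTA")


@dataclass
class PlantedTract:
    """Ground truth for one planted tandem-repeat tract."""

    chrom: str
    start: int
    end: int
    unit: str
    n_copies: int
    sub_rate: float
    context: str  # interorf | telomere | rrna | explicit
    gap_class: str | None = None
    primary_orf: str | None = None  # the ORF whose 3'UTR the tract overlaps
    expects_peak: bool = False

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PlantedSite:
    site: ScoredSite
    tract_index: int
    offset: int  # signed true offset from the tract midpoint


@dataclass
class GapTruth:
    chrom: str
    start: int
    end: int
    oclass: str


@dataclass
class SynthManifest:
    """Exact ground truth sufficient to score every downstream stage."""

    features: list[FeatureInterval]  # ORFs + telomeres + rRNA
    gaps: list[GapTruth]
    tracts: list[PlantedTract]
    utr_records: list[UtrRecord]
    halflife_records: list[HalfLifeRecord]
    flagged_orfs: list[str]
    sites: list[PlantedSite]

    @property
    def orfs(self) -> list[FeatureInterval]:
        return [f for f in self.features if f.ftype == "ORF"]

    @property
    def expected_peak_tracts(self) -> list[PlantedTract]:
        return [t for t in self.tracts if t.expects_peak]

    def gap_class_counts(self) -> dict[str, int]:
        counts = {"divergent": 0, "unidirectional": 0, "convergent": 0}
        for g in self.gaps:
            counts[g.oclass] += 1
        return counts


def ta_tract_window_mean(table: StepTable, window_len: int = 100) -> float:
    """Exact window mean inside a pure (TA)n tract at least one window long.

    A window of L bp holds L-1 alternating TA/AT steps; the mean depends on
    the phase, so the worst (minimum) of the two phases is returned.
    """
    n = window_len - 1
    v1, v2 = table.values["TA"], table.values["AT"]
    a = (math.ceil(n / 2) * v1 + (n // 2) * v2) / n
    b = (math.ceil(n / 2) * v2 + (n // 2) * v1) / n
    return min(a, b)


def simulate_genome(spec: SynthSpec) -> tuple[list[GenomeSequence], SynthManifest]:
    """Generate chromosomes plus the exact ground-truth manifest.

    Deterministic given ``spec`` (which includes the seed).  Infeasible
    packing of explicitly requested repeats raises before any output.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    bases = np.array(list("ACGT"))

    genomes: list[GenomeSequence] = []
    features: list[FeatureInterval] = []
    gaps: list[GapTruth] = []
    tracts: list[PlantedTract] = []
    utr_records: list[UtrRecord] = []
    flagged: list[str] = []

    for ci in range(spec.n_chrom):
        chrom = f"chr{_roman(ci + 1)}"
        seq = rng.choice(bases, size=spec.chrom_len, p=p)
        occupied: list[tuple[int, int]] = []

        # --- telomere features at both ends, with an optional planted tract
        telo_len = 300
        features.append(FeatureInterval(chrom, 0, telo_len, ".", "telomere", f"TEL{_roman(ci+1)}L"))
        features.append(
            FeatureInterval(chrom, spec.chrom_len - telo_len, spec.chrom_len, ".", "telomere",
                            f"TEL{_roman(ci+1)}R")
        )
        if ci == 0 and spec.plant_telomere_peak:
            t = _plant_tract(seq, 60, spec.peak_repeat_unit, spec.peak_repeat_copies,
                             spec.peak_sub_rate, rng, occupied)
            tracts.append(PlantedTract(chrom, t[0], t[1], spec.peak_repeat_unit,
                                       spec.peak_repeat_copies, spec.peak_sub_rate,
                                       "telomere", expects_peak=True))

        # --- gene layout: strands chosen so internal gaps cycle through the
        #     convergent/unidirectional/divergent pattern (1:2:1 overall)
        reserve = 3500 if (ci == 1 and spec.plant_rrna_peak) else 0
        layout = _plan_layout(spec, rng, reserve)
        cursor = spec.terminal_margin
        prev_orf: FeatureInterval | None = None
        orf_serial = 0
        for gene_len, gap_len, strand, gap_class, plant_here in layout:
            orf_serial += 1
            fid = f"Y{_roman(ci+1)}G{orf_serial:03d}"
            orf = FeatureInterval(chrom, cursor, cursor + gene_len, strand, "ORF", fid)
            features.append(orf)
            utr5 = int(rng.integers(*spec.utr5_range))
            utr3 = int(rng.integers(*spec.utr3_range))
            utr_records.append(UtrRecord(fid, utr5, utr3))
            if prev_orf is not None:
                gaps.append(GapTruth(chrom, prev_orf.end, orf.start, _gap_class(prev_orf, orf)))
            cursor = orf.end
            if plant_here and gap_class in {"convergent", "unidirectional"}:
                # tract goes inside the upcoming gap, overlapping the 3'UTR of
                # whichever flanking gene points its 3' end into the gap
                tract_len = spec.peak_repeat_copies * len(spec.peak_repeat_unit)
                offset = int(rng.integers(5, 31))
                if strand == "+":  # this gene's 3' end abuts the gap start
                    start = cursor + offset
                    primary = fid
                else:  # unidirectional (-,-): the NEXT gene's 3'UTR ends at gap end
                    start = cursor + gap_len - offset - tract_len
                    primary = None  # filled in after the next ORF is placed
                span = _plant_tract(seq, start, spec.peak_repeat_unit, spec.peak_repeat_copies,
                                    spec.peak_sub_rate, rng, occupied)
                tracts.append(PlantedTract(chrom, span[0], span[1], spec.peak_repeat_unit,
                                           spec.peak_repeat_copies, spec.peak_sub_rate,
                                           "interorf", gap_class=gap_class,
                                           primary_orf=primary, expects_peak=True))
            cursor += gap_len
            # resolve deferred primary ORF for (-,-) gaps: tract sits in the
            # 3'UTR of the gene we are about to place next iteration
            if tracts and tracts[-1].context == "interorf" and tracts[-1].primary_orf is None:
                tracts[-1].primary_orf = f"Y{_roman(ci+1)}G{orf_serial+1:03d}"
            prev_orf = orf

        # --- rRNA locus past the gene array, with an optional planted tract
        if ci == 1 and spec.plant_rrna_peak:
            r_start = cursor + 500
            r_end = r_start + 2500
            if r_end < spec.chrom_len - spec.terminal_margin:
                features.append(FeatureInterval(chrom, r_start, r_end, "+", "rRNA", f"RDN{ci+1}"))
                t = _plant_tract(seq, r_start + 800, spec.peak_repeat_unit,
                                 spec.peak_repeat_copies, spec.peak_sub_rate, rng, occupied)
                tracts.append(PlantedTract(chrom, t[0], t[1], spec.peak_repeat_unit,
                                           spec.peak_repeat_copies, spec.peak_sub_rate,
                                           "rrna", expects_peak=True))

        for req in spec.extra_repeats:
            if req.chrom_index != ci:
                continue
            tract_len = req.n_copies * len(req.unit)
            if not (1 <= req.pos and req.pos + tract_len < spec.chrom_len - 1):
                raise ValueError(f"explicit repeat at {req.pos} does not fit chromosome {chrom}")
            if any(req.pos - 1 < b and req.pos + tract_len + 1 > a for a, b in occupied):
                raise ValueError(f"explicit repeat at {chrom}:{req.pos} overlaps a planted element")
            span = _plant_tract(seq, req.pos, req.unit, req.n_copies, req.sub_rate, rng, occupied)
            tracts.append(PlantedTract(chrom, span[0], span[1], req.unit, req.n_copies,
                                       req.sub_rate, "explicit"))

        genomes.append(GenomeSequence(chrom, "".join(seq)))

    flagged = _flag_orfs_with_flexible_3utr(features, utr_records, tracts)
    halflife_records = _draw_halflives(spec, [f for f in features if f.ftype == "ORF"], flagged, rng)
    sites = _draw_sites(spec, tracts, features, rng)
    manifest = SynthManifest(features, gaps, tracts, utr_records, halflife_records, flagged, sites)
    return genomes, manifest


def _plan_layout(spec: SynthSpec, rng: np.random.Generator, reserve_tail: int = 0):
    """Gene lengths, gap lengths, strands and gap classes for one chromosome.

    Strands are derived from the orientation cycle: from a gene on strand s,
    a convergent gap needs (+,-), divergent (-,+), unidirectional (s,s);
    the cycle convergent/uni/divergent/uni is realizable from '+' onwards.
    ``reserve_tail`` keeps room after the gene array (e.g. for an rRNA locus).
    """
    usable = spec.chrom_len - 2 * spec.terminal_margin - reserve_tail
    mean_pitch = np.mean(spec.gene_len_range) + np.mean(spec.gap_len_range)
    n_genes = max(4, int(usable / mean_pitch))
    tract_len = spec.peak_repeat_copies * len(spec.peak_repeat_unit)

    classes = [_GAP_CYCLE[i % len(_GAP_CYCLE)] for i in range(n_genes - 1)]
    eligible = [i for i, c in enumerate(classes) if c in {"convergent", "unidirectional"}]
    n_plant = min(spec.n_peak_gaps_per_chrom, len(eligible))
    plant_idx = set(rng.choice(eligible, size=n_plant, replace=False)) if n_plant else set()

    layout = []
    strand = "+"
    for i in range(n_genes):
        gene_len = int(rng.integers(*spec.gene_len_range))
        gap_class = classes[i] if i < n_genes - 1 else None
        plant_here = i in plant_idx
        if plant_here:
            gap_len = int(rng.integers(tract_len + 100, tract_len + 250))
        else:
            gap_len = int(rng.integers(*spec.gap_len_range))
        layout.append([gene_len, gap_len, strand, gap_class, plant_here])
        if gap_class == "convergent":
            strand = "-"
        elif gap_class == "divergent":
            strand = "+"
        # unidirectional keeps the strand

    # trim the plan so the realized layout always fits inside the usable span
    # (the pitch draws are random; never truncate mid-chromosome at run time)
    kept, total = [], 0
    for item in layout:
        if total + item[0] + item[1] > usable:
            break
        total += item[0] + item[1]
        kept.append(item)
    if kept:
        kept[-1][3] = None  # the gap after the last gene is terminal
        kept[-1][4] = False
    return [tuple(item) for item in kept]


def _gap_class(left: FeatureInterval, right: FeatureInterval) -> str:
    if left.strand == right.strand:
        return "unidirectional"
    return "convergent" if left.strand == "+" else "divergent"


def _plant_tract(seq: np.ndarray, start: int, unit: str, n_copies: int,
                 sub_rate: float, rng: np.random.Generator,
                 occupied: list[tuple[int, int]]) -> tuple[int, int]:
    """Write a mutated tandem tract into the sequence array, with G guard bases."""
    tract = (unit * n_copies)
    end = start + len(tract)
    if start < 1 or end + 1 > len(seq):
        raise ValueError(f"tract [{start}, {end}) does not fit the chromosome")
    arr = np.array(list(tract))
    if sub_rate > 0:
        hits = np.flatnonzero(rng.random(len(arr)) < sub_rate)
        for h in hits:
            others = [b for b in "ACGT" if b != arr[h]]
            arr[h] = others[int(rng.integers(3))]
    seq[start:end] = arr
    seq[start - 1] = "G"  # guard bases pin the tract boundaries exactly
    seq[end] = "C"
    occupied.append((start - 1, end + 1))
    return start, end


#: how far (bp) a called peak typically extends beyond its core tract — the
#: preselection run gains windows that still overlap the tract substantially
PEAK_HALO_BP = 100


def _flag_orfs_with_flexible_3utr(
    features: Sequence[FeatureInterval],
    utr_records: Sequence[UtrRecord],
    tracts: Sequence[PlantedTract],
) -> list[str]:
    """Ground-truth set of ORFs whose 3'UTR will carry a flexibility peak.

    A peak called around a planted tract extends roughly :data:`PEAK_HALO_BP`
    beyond the tract on each side, so every ORF whose true 3'UTR interval
    overlaps the haloed tract is flagged — in a convergent gap that is
    frequently both flanking ORFs, mirroring how overlapping 3'UTRs share
    one terminator region.
    """
    utr3 = {u.orf_id: u.utr3_len for u in utr_records}
    flagged: set[str] = set()
    for tract in tracts:
        if tract.context != "interorf":
            continue
        lo, hi = tract.start - PEAK_HALO_BP, tract.end + PEAK_HALO_BP
        for orf in features:
            if orf.ftype != "ORF" or orf.chrom != tract.chrom:
                continue
            ln = utr3.get(orf.fid, 0)
            if orf.strand == "+":
                u3 = (orf.end, orf.end + ln)
            else:
                u3 = (orf.start - ln, orf.start)
            if u3[0] < hi and u3[1] > lo:
                flagged.add(orf.fid)
    return sorted(flagged)


def _draw_halflives(spec: SynthSpec, orfs: Sequence[FeatureInterval],
                    flagged: Sequence[str], rng: np.random.Generator) -> list[HalfLifeRecord]:
    flagged_set = set(flagged)
    records = []
    sd = spec.halflife_log_sd
    for orf in orfs:
        if orf.fid in flagged_set:
            mu_o, mu_p = spec.halflife_overall_flagged, spec.halflife_polya_flagged
        else:
            mu_o, mu_p = spec.halflife_overall_background, spec.halflife_polya_background
        overall = float(rng.lognormal(math.log(mu_o), sd))
        polya = float(rng.lognormal(math.log(mu_p), sd))
        if rng.random() < spec.halflife_missing_rate:
            overall = math.nan
        records.append(HalfLifeRecord(orf.fid, overall, polya))
    return records


def _draw_sites(spec: SynthSpec, tracts: Sequence[PlantedTract],
                features: Sequence[FeatureInterval],
                rng: np.random.Generator) -> list[PlantedSite]:
    chrom_len = spec.chrom_len
    sites: list[PlantedSite] = []
    for ti, tract in enumerate(tracts):
        if tract.context != "interorf":
            continue
        for _ in range(spec.polya_sites_per_repeat):
            if rng.random() < spec.polya_frac_near:
                mag = int(rng.integers(spec.polya_near_range[0], spec.polya_near_range[1] + 1))
            else:
                mag = int(rng.integers(spec.polya_far_range[0], spec.polya_far_range[1] + 1))
            offset = mag if rng.random() < 0.5 else -mag
            pos = int(np.clip(tract.midpoint + offset, 0, chrom_len - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < spec.polya_frac_intense:
                score = float(rng.uniform(*spec.polya_intense_score))
            else:
                score = float(rng.uniform(*spec.polya_weak_score))
            sites.append(PlantedSite(ScoredSite(tract.chrom, pos, strand, score), ti, offset))
    chroms = sorted({f.chrom for f in features})
    for chrom in chroms:
        for _ in range(spec.n_background_sites_per_chrom):
            pos = int(rng.integers(0, chrom_len))
            strand = "+" if rng.random() < 0.5 else "-"
            score = float(rng.uniform(*spec.polya_weak_score))
            sites.append(PlantedSite(ScoredSite(chrom, pos, strand, score), -1, 0))
    return sites


def _roman(n: int) -> str:
    from .io import to_roman

    return to_roman(n)


# ---------------------------------------------------------------------------
# on-disk fixture

@dataclass
class FixturePaths:
    root: Path
    fasta: Path
    gff3: Path
    utrs: Path
    halflife: Path
    sites: Path
    truth_tracts: Path
    truth_gaps: Path
    truth_flagged: Path


def end_to_end_fixture(spec: SynthSpec, outdir) -> tuple[FixturePaths, SynthManifest]:
    """Write a complete input set (FASTA/GFF3/tables) plus ground-truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, manifest = simulate_genome(spec)
    paths = FixturePaths(
        root=outdir,
        fasta=outdir / "genome.fa",
        gff3=outdir / "features.gff3",
        utrs=outdir / "utrs.tsv",
        halflife=outdir / "halflife.tsv",
        sites=outdir / "polya_sites.tsv",
        truth_tracts=outdir / "truth_tracts.tsv",
        truth_gaps=outdir / "truth_gaps.tsv",
        truth_flagged=outdir / "truth_flagged_orfs.txt",
    )
    write_fasta(genomes, paths.fasta)
    _write_gff3(manifest.features, paths.gff3)
    write_utr_table(manifest.utr_records, paths.utrs)
    write_halflife_table(manifest.halflife_records, paths.halflife)
    write_site_table([p.site for p in manifest.sites], paths.sites)
    with open(paths.truth_tracts, "w") as fh:
        fh.write("chrom\tstart\tend\tunit\tcontext\tgap_class\tprimary_orf\texpects_peak\n")
        for t in manifest.tracts:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.unit}\t{t.context}\t"
                f"{t.gap_class or '.'}\t{t.primary_orf or '.'}\t{int(t.expects_peak)}\n"
            )
    with open(paths.truth_gaps, "w") as fh:
        fh.write("chrom\tstart\tend\toclass\n")
        for g in manifest.gaps:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.oclass}\n")
    paths.truth_flagged.write_text("".join(f"{o}\n" for o in manifest.flagged_orfs))
    return paths, manifest


_GFF_TYPE = {"ORF": "gene", "telomere": "telomere", "rRNA": "rRNA", "other": "region"}


def _write_gff3(features: Sequence[FeatureInterval], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            gtype = _GFF_TYPE.get(f.ftype, f.ftype)
            strand = f.strand if f.strand in "+-" else "."
            fh.write(
                f"{f.chrom}\tdnaflex_synth\t{gtype}\t{f.start + 1}\t{f.end}\t.\t{strand}\t.\t"
                f"ID={f.fid}\n"
            )
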