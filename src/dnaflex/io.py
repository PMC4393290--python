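"""Readers and writers for the standard formats the pipeline touches.

Every reader converts to one internal coordinate convention — 0-based,
half-open — so that ``end - start`` is always the feature length in bp.
Conversion back to 1-based dialects (GFF3, wiggle, RepeatMasker) happens only
here, at the I/O boundary.

Supported formats: multi-record FASTA, GFF3, BED6, bedGraph, fixedStep
wiggle, RepeatMasker ``.out``, and headered tab-separated tables for UTR
lengths, mRNA half-lives and scored poly(A) cleavage sites.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_IUPAC_TO_N = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNN")
_VALID = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types

@dataclass
class GenomeSequence:
    """One chromosome: name plus an uppercase A/C/G/T/N sequence."""

    chrom: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for chromosome {self.chrom!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FeatureInterval:
    """A genomic interval in the internal 0-based half-open convention."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    ftype: str = "other"
    fid: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if self.ftype == "ORF" and self.strand == ".":
            raise ValueError(f"ORF feature {self.fid!r} requires a strand")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ScoredSite:
    """A poly(A) cleavage site with strand and read-count score."""

    chrom: str
    pos: int
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"site strand must be + or -, got {self.strand!r}")
        if self.score < 0:
            raise ValueError(f"negative site score {self.score}")


@dataclass
class UtrRecord:
    """Measured 5'/3' UTR lengths (nt) for one ORF."""

    orf_id: str
    utr5_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"negative UTR length for {self.orf_id}")


@dataclass
class HalfLifeRecord:
    """mRNA half-lives in minutes; NaN marks a missing measurement."""

    orf_id: str
    overall_halflife: float = math.nan
    polya_halflife: float = math.nan

    def __post_init__(self) -> None:
        for v in (self.overall_halflife, self.polya_halflife):
            if not math.isnan(v) and v <= 0:
                raise ValueError(f"non-positive half-life for {self.orf_id}: {v}")


# ---------------------------------------------------------------------------
# FASTA

def normalize_sequence(raw: str, name: str = "?") -> str:
    """Uppercase, strip whitespace, fold IUPAC ambiguity codes to N.

    Any residue outside {A,C,G,T,N} after normalization is a hard error
    naming the offending record.
    """
    seq = "".join(raw.split()).upper().translate(_IUPAC_TO_N)
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"record {name!r}: non-nucleotide residues {sorted(bad)}")
    return seq


def read_fasta(path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into normalized :class:`GenomeSequence` records.

    Original record order is preserved.  Empty files and duplicate
    chromosome names are hard errors.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations (GFF3 / BED6)

#: default mapping from GFF3 type column to internal feature classes
DEFAULT_FTYPE_MAP: dict[str, str] = {
    "gene": "ORF",
    "ORF": "ORF",
    "mRNA": "ORF",
    "CDS": "ORF",
    "telomere": "telomere",
    "rRNA": "rRNA",
    "rRNA_gene": "rRNA",
    "five_prime_UTR": "5UTR",
    "three_prime_UTR": "3UTR",
    "repeat_region": "repeat",
}


def read_annotation(
    path,
    dialect: str = "gff3",
    ftype_map: Mapping[str, str] | None = None,
) -> list[FeatureInterval]:
    """Read features from GFF3 or BED6 into the internal convention.

    GFF3 1-based closed coordinates become 0-based half-open; BED6 passes
    through.  The GFF3 type column is mapped to an internal feature class via
    ``ftype_map`` (default :data:`DEFAULT_FTYPE_MAP`; unmapped types become
    ``other``).  For BED6 the feature class defaults to ``other`` unless the
    name looks like ``<class>:<id>``.
    """
    if dialect == "gff3":
        return _read_gff3(path, ftype_map or DEFAULT_FTYPE_MAP)
    if dialect == "bed6":
        return _read_bed6(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path, ftype_map: Mapping[str, str]) -> list[FeatureInterval]:
    import gffutils

    feats: list[FeatureInterval] = []
    for f in gffutils.DataIterator(str(path)):
        ftype = ftype_map.get(f.featuretype, "other")
        fid = f.attributes.get("ID", f.attributes.get("Name", [""]))[0]
        start, end = f.start - 1, f.end  # 1-based closed -> 0-based half-open
        if start >= end:
            raise ValueError(f"{path}: feature {fid!r} has start >= end after conversion")
        strand = f.strand if f.strand in {"+", "-"} else "."
        feats.append(FeatureInterval(f.seqid, start, end, strand, ftype, fid))
    return feats


def _read_bed6(path) -> list[FeatureInterval]:
    feats: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with <3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 else "."
            ftype, _, rest = name.partition(":")
            if rest:
                ftype, fid = ftype, rest
            else:
                ftype, fid = "other", name
            feats.append(FeatureInterval(chrom, start, end, strand, ftype, fid))
    return feats


def write_bed(intervals: Sequence, path, name_attr: str = "fid") -> None:
    """Write intervals as BED6.

    Works for :class:`FeatureInterval` (name = ``ftype:fid``, score 0) and for
    peak-caller regions (name = region name, score = round(max_value * 10)).
    Refuses an empty list.
    """
    intervals = list(intervals)
    if not intervals:
        raise ValueError("refusing to write an empty BED file")
    with open(path, "w") as fh:
        for iv in intervals:
            if hasattr(iv, "max_value"):  # FlexRegion-like
                name = getattr(iv, "name", None) or "region"
                score = int(round(iv.max_value * 10))
                strand = "."
            else:
                fid = getattr(iv, name_attr, "") or ""
                ftype = getattr(iv, "ftype", "")
                name = f"{ftype}:{fid}" if ftype and ftype != "other" else (fid or ".")
                score = 0
                strand = getattr(iv, "strand", ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

def read_repeatmasker_out(path) -> list[FeatureInterval]:
    """Parse a RepeatMasker ``.out`` file into repeat intervals.

    The standard layout has 3 header lines followed by whitespace-separated
    columns; query name, 1-based inclusive begin/end and the repeat family
    (e.g. ``(TA)n``) are columns 5, 6, 7 and 10.  Malformed lines are skipped
    with a warning; if no line parses, that is a hard error.
    """
    feats: list[FeatureInterval] = []
    n_data_lines = 0
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower().startswith(("sw", "score", "there were no")):
            continue  # header / empty-result banner
        n_data_lines += 1
        cols = stripped.split()
        try:
            if len(cols) < 11:
                raise ValueError("fewer than 11 columns")
            chrom = cols[4]
            start = int(cols[5]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(cols[6])
            family = cols[9]
            feats.append(FeatureInterval(chrom, start, end, ".", "repeat", family))
        except (ValueError, IndexError) as exc:
            logger.warning("%s:%d: skipping malformed RepeatMasker line (%s)", path, lineno, exc)
    if not feats:
        raise ValueError(f"no parseable repeat entries in {path}")
    return feats


# ---------------------------------------------------------------------------
# profile tracks (bedGraph / wiggle)

def write_bedgraph(profile, path, precision: int = 4) -> None:
    """Write a flexibility profile as bedGraph (0-based half-open).

    Each defined window value covers ``shift`` bp starting at its assigned
    midpoint position; consecutive runs of equal printed value are merged
    into one line.  Missing windows leave gaps.
    """
    if profile.n_windows == 0:
        raise ValueError("refusing to write an empty profile")
    positions = profile.positions()
    values = profile.values
    with open(path, "w") as fh:
        run_start = None
        run_val = None
        prev_end = None
        for pos, val in zip(positions, values):
            if np.isnan(val):
                if run_start is not None:
                    fh.write(f"{profile.chrom}\t{run_start}\t{prev_end}\t{run_val:.{precision}f}\n")
                    run_start = None
                continue
            rendered = round(float(val), precision)
            if run_start is not None and rendered == run_val and pos == prev_end:
                prev_end = pos + profile.shift
            else:
                if run_start is not None:
                    fh.write(f"{profile.chrom}\t{run_start}\t{prev_end}\t{run_val:.{precision}f}\n")
                run_start, run_val, prev_end = int(pos), rendered, int(pos) + profile.shift
        if run_start is not None:
            fh.write(f"{profile.chrom}\t{run_start}\t{prev_end}\t{run_val:.{precision}f}\n")


def write_wiggle(profile, path, precision: int = 4) -> None:
    """Write a profile as fixedStep wiggle (1-based starts).

    A new ``fixedStep`` block is opened after every gap of missing values.
    """
    if profile.n_windows == 0:
        raise ValueError("refusing to write an empty profile")
    positions = profile.positions()
    values = profile.values
    with open(path, "w") as fh:
        in_block = False
        for pos, val in zip(positions, values):
            if np.isnan(val):
                in_block = False
                continue
            if not in_block:
                fh.write(
                    f"fixedStep chrom={profile.chrom} start={int(pos) + 1} "
                    f"step={profile.shift} span={profile.shift}\n"
                )
                in_block = True
            fh.write(f"{val:.{precision}f}\n")


# ---------------------------------------------------------------------------
# tab-separated tables (header line required, documented column order)

UTR_COLUMNS = ["orf_id", "utr5_len", "utr3_len"]
HALFLIFE_COLUMNS = ["orf_id", "overall_halflife", "polya_halflife"]
SITE_COLUMNS = ["chrom", "pos", "strand", "score"]


def read_utr_table(path) -> list[UtrRecord]:
    df = _read_table(path, UTR_COLUMNS)
    return [
        UtrRecord(str(r.orf_id), int(r.utr5_len), int(r.utr3_len))
        for r in df.itertuples(index=False)
    ]


def write_utr_table(records: Iterable[UtrRecord], path) -> None:
    pd.DataFrame(
        [(r.orf_id, r.utr5_len, r.utr3_len) for r in records], columns=UTR_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def read_halflife_table(path) -> list[HalfLifeRecord]:
    df = _read_table(path, HALFLIFE_COLUMNS)
    out = []
    n_missing = 0
    for r in df.itertuples(index=False):
        overall = float(r.overall_halflife) if pd.notna(r.overall_halflife) else math.nan
        polya = float(r.polya_halflife) if pd.notna(r.polya_halflife) else math.nan
        if math.isnan(overall) or math.isnan(polya):
            n_missing += 1
        out.append(HalfLifeRecord(str(r.orf_id), overall, polya))
    if n_missing:
        logger.info("%s: %d records with missing half-life values", path, n_missing)
    return out


def write_halflife_table(records: Iterable[HalfLifeRecord], path) -> None:
    pd.DataFrame(
        [(r.orf_id, r.overall_halflife, r.polya_halflife) for r in records],
        columns=HALFLIFE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_site_table(path) -> list[ScoredSite]:
    df = _read_table(path, SITE_COLUMNS)
    return [
        ScoredSite(str(r.chrom), int(r.pos), str(r.strand), float(r.score))
        for r in df.itertuples(index=False)
    ]


def write_site_table(sites: Iterable[ScoredSite], path) -> None:
    pd.DataFrame(
        [(s.chrom, s.pos, s.strand, s.score) for s in sites], columns=SITE_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def _read_table(path, expected_columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing} (header line required)")
    return df[expected_columns]


# ---------------------------------------------------------------------------
# peak naming

_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"),
    (1, "I"),
]


def to_roman(n: int) -> str:
    if n <= 0:
        raise ValueError(f"roman numerals need n >= 1, got {n}")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def chrom_numeral(chrom: str, name_map: Mapping[str, str] | None = None) -> str:
    """Roman-numeral label for a chromosome name.

    Uses an explicit map when given; otherwise strips a ``chr`` prefix, keeps
    an existing roman numeral, converts integers, and falls back to the raw
    name.  Peaks are then named ``peak<ROMAN>-<k>``.
    """
    if name_map and chrom in name_map:
        return name_map[chrom]
    stem = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if re.fullmatch(r"[IVXLCDM]+", stem):
        return stem
    if stem.isdigit():
        return to_roman(int(stem))
    return stem
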