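"""Twist-angle fluctuation profiling.

Double-stranded DNA is torsionally soft in a sequence-dependent way: the
magnitude of thermal fluctuation of the twist angle between consecutive base
pairs depends on the identity of the dinucleotide step.  The dinucleotide-step
model assigns each of the 16 steps a fluctuation amplitude in degrees; the
flexibility of a longer stretch is the arithmetic mean of its step values.

This module computes per-step flexibility values for a sequence and their
sliding-window average profile: a window of ``L`` bp (default 100) is slid
along the chromosome with shift ``s`` (default 1 bp), the mean of its ``L-1``
step values is anchored at the window's midpoint dinucleotide step, and any
window touching an ambiguous base (N) is marked missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: the 16 dinucleotide steps in lexicographic order
STEPS: tuple[str, ...] = tuple(a + b for a in "ACGT" for b in "ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: name of the packaged synthetic default parameter file
DEFAULT_TABLE_RESOURCE = "twist_fluctuation_synthetic.tsv"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class StepTableError(ValueError):
    """Raised when a step-parameter table violates its invariants."""


@dataclass(frozen=True)
class StepTable:
    """The 16 dinucleotide twist-fluctuation parameters, in degrees.

    Invariants (validated at construction): all 16 steps present, all values
    strictly positive, and reverse-complement symmetry
    ``value(XY) == value(revcomp(XY))`` to within 1e-9 (the two strands of the
    duplex read the same physical step, e.g. AA/TT, AC/GT).
    """

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [s for s in STEPS if s not in self.values]
        if missing:
            raise StepTableError(f"step table missing steps: {missing}")
        for step, v in self.values.items():
            if step not in STEPS:
                raise StepTableError(f"unknown dinucleotide step {step!r}")
            if not np.isfinite(v) or v <= 0:
                raise StepTableError(f"non-positive value for step {step}: {v}")
        for step in STEPS:
            partner = reverse_complement(step)
            if abs(self.values[step] - self.values[partner]) > 1e-9:
                raise StepTableError(
                    "reverse-complement symmetry violated: "
                    f"{step}={self.values[step]} vs {partner}={self.values[partner]}"
                )
        object.__setattr__(self, "values", dict(self.values))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "StepTable":
        """Build a table from 10 unique-under-complement steps or all 16.

        Entries for symmetric partners are filled in automatically; giving
        both partners with conflicting values is an error.
        """
        expanded: dict[str, float] = {}
        for step, v in mapping.items():
            step = step.upper()
            if step not in STEPS:
                raise StepTableError(f"unknown dinucleotide step {step!r}")
            for key in {step, reverse_complement(step)}:
                if key in expanded and abs(expanded[key] - v) > 1e-9:
                    raise StepTableError(
                        f"conflicting values for symmetric steps {step}/"
                        f"{reverse_complement(step)}: {expanded[key]} vs {v}"
                    )
                expanded[key] = float(v)
        return cls(expanded)

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())

    def as_array(self) -> np.ndarray:
        """Values as a length-16 array indexed by 4*code(base1)+code(base2)."""
        return np.array([self.values[s] for s in STEPS], dtype=float)


def load_step_table(path) -> StepTable:
    """Load a step table from a two-column text file (step, degrees).

    Lines starting with ``#`` and blank lines are ignored; 10 unique steps are
    expanded by reverse-complement symmetry.  A symmetry conflict beyond 1e-9,
    a missing step or a non-positive value is a hard error.
    """
    entries: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise StepTableError(f"{path}:{lineno}: expected 'STEP value', got {line!r}")
            step, raw = parts
            try:
                value = float(raw)
            except ValueError as exc:
                raise StepTableError(f"{path}:{lineno}: bad value {raw!r}") from exc
            if step.upper() in entries:
                raise StepTableError(f"{path}:{lineno}: duplicate step {step}")
            entries[step.upper()] = value
    return StepTable.from_mapping(entries)


def default_step_table() -> StepTable:
    """The packaged synthetic default parameter set (see the data file header)."""
    ref = resources.files("dnaflex.data").joinpath(DEFAULT_TABLE_RESOURCE)
    with resources.as_file(ref) as path:
        return load_step_table(path)


@dataclass(frozen=True)
class ProfileConfig:
    """Sliding-window settings: window length L (bp) and shift s (bp)."""

    window_len: int = 100
    shift: int = 1

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError(f"window_len must be >= 2, got {self.window_len}")
        if not 1 <= self.shift <= self.window_len:
            raise ValueError(
                f"shift must be in [1, window_len], got {self.shift} (L={self.window_len})"
            )

    @property
    def midpoint_offset(self) -> int:
        """Offset of the assigned midpoint step within a window.

        A window of L bp has L-1 steps; the midpoint step index is
        floor((L-1)/2), so for L=100 the value is anchored at
        window_start + 49 (the step between positions 49 and 50).
        """
        return (self.window_len - 1) // 2


@dataclass
class FlexibilityProfile:
    """Per-window flexibility values anchored to genome coordinates.

    ``values[i]`` is the mean step flexibility (degrees) of the window
    starting at ``i * shift``; NaN marks windows excluded because they touch
    an N.  ``anchor`` is the genomic position of the first window's assigned
    midpoint step, so value ``i`` sits at ``anchor + i * shift``.
    """

    chrom: str
    window_len: int
    shift: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def anchor(self) -> int:
        return (self.window_len - 1) // 2

    @property
    def step(self) -> int:
        return self.shift

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def window_starts(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.shift

    def positions(self) -> np.ndarray:
        """Genomic positions of the assigned midpoints, 0-based."""
        return self.anchor + self.window_starts()

    def defined(self) -> np.ndarray:
        """Boolean mask of windows with a defined (non-missing) value."""
        return ~np.isnan(self.values)


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and N -> 4; any other character is an error."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, base in enumerate("ACGTN"):
        lut[ord(base)] = i
    codes = lut[raw]
    if (codes == 255).any():
        bad = sorted({chr(b) for b in raw[codes == 255]})
        raise ValueError(f"sequence contains non-nucleotide characters: {bad}")
    return codes


def step_values(seq: str, table: StepTable) -> np.ndarray:
    """Per-dinucleotide-step flexibility values for ``seq`` (degrees).

    Returns an array of length ``len(seq) - 1`` where entry ``i`` is the
    table value of step ``seq[i:i+2]``, or NaN if either base is N.
    """
    if len(seq) < 2:
        raise ValueError(f"need at least 2 bases for a dinucleotide step, got {len(seq)}")
    codes = _encode(seq)
    left, right = codes[:-1], codes[1:]
    ambiguous = (left == 4) | (right == 4)
    # clip N codes into range for the lookup, then blank them out
    idx = 4 * np.minimum(left, 3).astype(np.intp) + np.minimum(right, 3)
    out = table.as_array()[idx]
    out[ambiguous] = np.nan
    return out


def window_profile(chromseq, table: StepTable, cfg: ProfileConfig | None = None) -> FlexibilityProfile:
    """Sliding-window mean flexibility profile of one chromosome.

    For each fully contained window start ``p`` (p = 0, s, 2s, ...,
    p + L <= len), the value is the arithmetic mean (double precision,
    pairwise summation) of the window's L-1 step values, NaN if any step is
    missing.  A sequence shorter than L yields an empty profile with a logged
    warning.

    ``chromseq`` may be a :class:`~dnaflex.io.GenomeSequence` or any object
    with ``chrom``/``seq`` attributes, or a plain string (chrom = "seq").
    """
    cfg = cfg or ProfileConfig()
    chrom = getattr(chromseq, "chrom", "seq")
    seq = getattr(chromseq, "seq", chromseq)
    L, s = cfg.window_len, cfg.shift
    if len(seq) < L:
        logger.warning(
            "sequence %s is shorter (%d bp) than the window (%d bp); empty profile",
            chrom, len(seq), L,
        )
        return FlexibilityProfile(chrom, L, s, np.empty(0))
    steps = step_values(seq, table)
    # windows of L-1 consecutive steps; numpy's mean uses pairwise summation
    windows = np.lib.stride_tricks.sliding_window_view(steps, L - 1)[::s]
    with np.errstate(invalid="ignore"):
        vals = windows.mean(axis=-1)
    assert len(vals) == (len(seq) - L) // s + 1
    return FlexibilityProfile(chrom, L, s, vals)


def profile_genome(
    genome: Iterable, table: StepTable, cfg: ProfileConfig | None = None
) -> list[FlexibilityProfile]:
    """Profile every chromosome of a genome, preserving input order."""
    return [window_profile(rec, table, cfg) for rec in genome]
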