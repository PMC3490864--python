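"""Amino-acid composition, positional residue-density profiles and
glycosylation sequon statistics for linker sets.

Composition is pooled over the whole set (total residue counts divided by
the pooled total), not averaged per sequence, so long linkers weigh in
proportion to their residue count.  Positional profiles split each linker
into ``n_bins`` approximately equal sections — residue ``i`` of a length-L
linker falls in bin ``floor(i * n_bins / L)`` — and pool group counts and
position counts per bin across the set before dividing.

The sequon scanner tallies putative N-glycosylation sites (N-X-S/T with
X != P) and the mutually exclusive N-P motif, which precludes N-glycan
attachment.  Every serine/threonine is treated as a putative O-glycan site,
so O-glycosylation capacity is read directly off the S/T density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .linkerstats import LinkerSet
from .seqio import AMINO_ACIDS


@dataclass(frozen=True)
class CompositionProfile:
    fractions: Mapping[str, float]
    counts: Mapping[str, int]
    total_residues: int

    def fraction(self, residue_group: Iterable[str]) -> float:
        return sum(self.fractions.get(r, 0.0) for r in set(residue_group))


@dataclass(frozen=True)
class PositionalProfile:
    residue_group: frozenset
    per_bin_fraction: np.ndarray
    per_bin_positions: np.ndarray
    per_bin_group: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.per_bin_fraction)


@dataclass(frozen=True)
class SequonCounts:
    n_sequons: int = 0
    n_NP: int = 0
    total_N: int = 0
    total_P: int = 0
    total_residues: int = 0

    def __add__(self, other: "SequonCounts") -> "SequonCounts":
        return SequonCounts(
            self.n_sequons + other.n_sequons,
            self.n_NP + other.n_NP,
            self.total_N + other.total_N,
            self.total_P + other.total_P,
            self.total_residues + other.total_residues,
        )


def aa_composition(linker_set: LinkerSet) -> CompositionProfile:
    """Pooled residue fractions over all linkers in the set."""
    counts = {aa: 0 for aa in AMINO_ACIDS + "X"}
    total = 0
    for l in linker_set:
        for r in l.seq:
            counts[r] += 1
        total += len(l.seq)
    if total == 0:
        raise ValueError(f"linker set {linker_set.label!r} has no residues")
    counts = {aa: c for aa, c in counts.items() if c or aa in AMINO_ACIDS}
    fractions = {aa: c / total for aa, c in counts.items()}
    return CompositionProfile(fractions=fractions, counts=counts, total_residues=total)


def bin_index(i: int, length: int, n_bins: int) -> int:
    """Bin of residue ``i`` (0-based) in a length-``length`` sequence."""
    return i * n_bins // length


def positional_profile(
    linker_set: LinkerSet, residue_group: Iterable[str], n_bins: int = 11
) -> PositionalProfile:
    """Pooled per-bin density of a residue group along the linkers.

    Group counts and total positions are accumulated per bin across the
    whole set, then divided; a bin that receives no positions (possible
    only for empty input) reports density 0.  Empty linkers are skipped
    with a warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    group = frozenset(residue_group)
    group_counts = np.zeros(n_bins, dtype=int)
    positions = np.zeros(n_bins, dtype=int)
    skipped = 0
    for l in linker_set:
        length = len(l.seq)
        if length == 0:
            skipped += 1
            continue
        for i, res in enumerate(l.seq):
            b = bin_index(i, length, n_bins)
            positions[b] += 1
            if res in group:
                group_counts[b] += 1
    if skipped:
        warnings.warn(
            f"{linker_set.label}: skipped {skipped} empty linker(s) in positional profile",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        frac = np.where(positions > 0, group_counts / np.maximum(positions, 1), 0.0)
    return PositionalProfile(
        residue_group=group,
        per_bin_fraction=frac,
        per_bin_positions=positions,
        per_bin_group=group_counts,
    )


def sequon_scan(seq: str) -> SequonCounts:
    """Count N-glycosylation sequons and N-P motifs in one sequence.

    A sequon is N at position i, any residue but P at i+1, and S or T at
    i+2; overlapping matches are all counted.  An N too close to the
    C-terminus to complete either pattern contributes only to the N tally.
    """
    n_seq = 0
    n_np = 0
    for i, res in enumerate(seq):
        if res != "N":
            continue
        if i + 1 < len(seq) and seq[i + 1] == "P":
            n_np += 1
        elif i + 2 < len(seq) and seq[i + 2] in "ST":
            n_seq += 1
    return SequonCounts(
        n_sequons=n_seq,
        n_NP=n_np,
        total_N=seq.count("N"),
        total_P=seq.count("P"),
        total_residues=len(seq),
    )


def aggregate_sequons(linker_set: LinkerSet) -> SequonCounts:
    """Element-wise sum of per-linker sequon counts."""
    total = SequonCounts()
    for l in linker_set:
        total = total + sequon_scan(l.seq)
    return total


def sequon_table(linker_sets: Sequence[LinkerSet]) -> pd.DataFrame:
    """Per-set sequon tallies plus a combined row."""
    rows = []
    combined = SequonCounts()
    for s in linker_sets:
        counts = aggregate_sequons(s)
        combined = combined + counts
        rows.append({"dataset": s.label, **counts.__dict__})
    rows.append({"dataset": "combined", **combined.__dict__})
    return pd.DataFrame(rows)


def composition_table(linker_sets: Sequence[LinkerSet]) -> pd.DataFrame:
    """Residue fractions, rows = residues, columns = linker sets."""
    out = pd.DataFrame(index=list(AMINO_ACIDS))
    for s in linker_sets:
        prof = aa_composition(s)
        out[s.label] = [prof.fractions.get(aa, 0.0) for aa in out.index]
    return out


def profile_table(
    linker_sets: Sequence[LinkerSet], residue_group: Iterable[str], n_bins: int = 11
) -> pd.DataFrame:
    """Per-bin group densities, rows = bins 1..n_bins, columns = linker sets."""
    out = pd.DataFrame(index=pd.RangeIndex(1, n_bins + 1, name="bin"))
    for s in linker_sets:
        prof = positional_profile(s, residue_group, n_bins=n_bins)
        out[s.label] = prof.per_bin_fraction
    return out
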