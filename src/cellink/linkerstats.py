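"""Length statistics, two-sample tests and trend fits on linker sets.

A :class:`LinkerSet` is the unit of every downstream statistic: a labelled
collection of linker sequences with per-record provenance (id, subset
flag).  Length summaries follow survey-table conventions (sample standard
deviation, midpoint median); the two-sample comparison is the classic
pooled-variance Student's t by default with Welch's variant behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import Dataset, _check_alphabet


class LinkerRecord(NamedTuple):
    id: str
    seq: str
    subset_flag: str = "core"


@dataclass
class LinkerSet:
    """Labelled linker sequences with exclusion flags."""

    label: str
    linkers: list[LinkerRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [l.id for l in self.linkers]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate linker ids in set {self.label!r}: {dup}")
        for l in self.linkers:
            if l.seq:
                _check_alphabet(l.seq, f"linker {l.id!r}")

    @property
    def n(self) -> int:
        return len(self.linkers)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.linkers)

    def lengths(self) -> np.ndarray:
        return np.array([len(l.seq) for l in self.linkers], dtype=int)

    def sequences(self) -> list[str]:
        return [l.seq for l in self.linkers]

    def exclude_subset(self, flag: str) -> "LinkerSet":
        kept = [l for l in self.linkers if l.subset_flag != flag]
        return LinkerSet(label=self.label, linkers=kept)


@dataclass(frozen=True)
class LengthStats:
    average: float
    median: float
    max: int
    min: int
    range: int
    sd: float
    n: int

    def rounded(self) -> dict:
        """Presentation form: integer average/median, one-decimal sd."""
        return {
            "average": round(self.average),
            "median": round(self.median),
            "max": self.max,
            "min": self.min,
            "range": self.range,
            "sd": round(self.sd, 1),
            "n": self.n,
        }


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    significant_95: bool


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r_squared: float


def length_stats(linker_set: LinkerSet) -> LengthStats:
    """Mean, midpoint median, extremes, range and sample (n-1) sd of lengths."""
    if linker_set.n == 0:
        raise ValueError(f"empty linker set {linker_set.label!r}")
    lengths = linker_set.lengths()
    sd = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0
    return LengthStats(
        average=float(np.mean(lengths)),
        median=float(np.median(lengths)),
        max=int(lengths.max()),
        min=int(lengths.min()),
        range=int(lengths.max() - lengths.min()),
        sd=sd,
        n=len(lengths),
    )


def length_histogram(linker_set: LinkerSet, bin_width: int = 5) -> dict[tuple[int, int], int]:
    """Counts of linker lengths in half-open bins [0,w), [w,2w), ...

    Only bins with at least one member are returned; counts sum to n.
    """
    if bin_width < 1:
        raise ValueError("bin width must be a positive number of residues")
    counts: dict[tuple[int, int], int] = {}
    for length in linker_set.lengths():
        lo = (int(length) // bin_width) * bin_width
        key = (lo, lo + bin_width)
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))


def ttest_lengths(set_a: LinkerSet, set_b: LinkerSet, welch: bool = False) -> TTestResult:
    """Two-tailed two-sample t-test on linker lengths.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  Identical constant samples give t=0, p=1.
    """
    a, b = set_a.lengths(), set_b.lengths()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test requires at least 2 linkers in each set")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return TTestResult(t=0.0, df=len(a) + len(b) - 2, p=1.0, significant_95=False)
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), df=df, p=p, significant_95=p < 0.05)


def ttest_matrix(sets: Sequence[LinkerSet], welch: bool = False) -> pd.DataFrame:
    """Pairwise p-values between linker sets (upper and lower triangles filled)."""
    labels = [s.label for s in sets]
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, si in enumerate(sets):
        for j, sj in enumerate(sets):
            if i != j:
                out.iloc[i, j] = ttest_lengths(si, sj, welch=welch).p
    return out


def composition_vs_length(
    linker_set: LinkerSet, residue_group: Iterable[str]
) -> tuple[pd.DataFrame, TrendFit]:
    """Per-linker percent content of a residue group against length, with OLS fit.

    Zero-length linkers are excluded (with a warning) since their content
    is undefined.  Returns the scatter points and the least-squares trend.
    """
    group = set(residue_group)
    if not group:
        raise ValueError("residue group is empty")
    if linker_set.n < 2:
        raise ValueError("trend fit requires at least 2 linkers")
    rows = []
    skipped = 0
    for l in linker_set:
        length = len(l.seq)
        if length == 0:
            skipped += 1
            continue
        content = 100.0 * sum(l.seq.count(r) for r in group) / length
        rows.append((l.id, length, content))
    if skipped:
        warnings.warn(
            f"{linker_set.label}: excluded {skipped} zero-length linker(s) from composition trend",
            stacklevel=2,
        )
    points = pd.DataFrame(rows, columns=["id", "length", "percent"])
    x = points["length"].to_numpy(float)
    if len(points) < 2 or np.ptp(x) == 0:
        raise ValueError("trend undefined: fewer than 2 distinct linker lengths")
    fit = stats.linregress(x, points["percent"].to_numpy(float))
    return points, TrendFit(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue) ** 2)


def genus_overlap(dataset_a: Dataset, dataset_b: Dataset) -> float:
    """Percent of A's genera that are also present in B (case-insensitive)."""
    genera_a, genera_b = dataset_a.genera(), dataset_b.genera()
    if not genera_a:
        raise ValueError(f"dataset {dataset_a.label!r} carries no genus annotations")
    return 100.0 * len(genera_a & genera_b) / len(genera_a)


def length_report(sets: Sequence[LinkerSet]) -> pd.DataFrame:
    """Survey-table style length summary, one row per linker set (rounded)."""
    rows = []
    for s in sets:
        row = {"label": s.label}
        row.update(length_stats(s).rounded())
        rows.append(row)
    return pd.DataFrame(rows)
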