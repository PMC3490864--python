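"""Motif-anchored segmentation of multidomain cellulases.

Each of the four architectures (CBM1/GH6, GH7/CBM1, CBM2/GH6, GH6/CBM2,
domains named N- to C-terminus) carries short conserved motifs at the
junctions between the carbohydrate-binding module (CBM), the linker and the
glycoside hydrolase (GH) catalytic domain.  The cutting rules anchor on
those motifs with fixed residue offsets, so a full-length sequence is
partitioned deterministically into CBM, linker and GH segments.

Motif patterns distinguish *required* positions from *preferred* wildcards:
junction motifs such as (S)QC(L) are not absolutely conserved at their
flanking positions, so candidate matches are scored by how many preferred
residues they hit and the best-scoring (earliest on ties) match wins.

Internally all coordinates are 0-based with half-open segments; the TSV
writer reports 1-based inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .linkerstats import LinkerSet, LinkerRecord
from .seqio import Dataset, ProteinRecord

# ---------------------------------------------------------------------------
# Motif patterns


@dataclass(frozen=True)
class MotifPattern:
    """A compiled junction motif.

    ``positions`` holds one entry per motif column: ``(required, preferred)``
    where ``required`` is a frozenset of allowed residues (``None`` = any)
    and ``preferred`` a frozenset of residues that add to the match score.
    """

    source: str
    positions: tuple[tuple[frozenset | None, frozenset], ...]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def max_score(self) -> int:
        return sum(1 for _, pref in self.positions if pref)

    def match_score(self, seq: str, i: int) -> int | None:
        """Score of the match at ``i``, or None if a required position fails."""
        score = 0
        for k, (required, preferred) in enumerate(self.positions):
            res = seq[i + k]
            if required is not None and res not in required:
                return None
            if res in preferred:
                score += 1
        return score


def compile_motif(pattern: str) -> MotifPattern:
    """Compile the pattern mini-syntax (see ``data/schemes.yaml``)."""
    positions: list[tuple[frozenset | None, frozenset]] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "(":
            j = pattern.index(")", i)
            positions.append((None, frozenset(pattern[i + 1 : j])))
            i = j + 1
        elif c == "[":
            j = pattern.index("]", i)
            positions.append((frozenset(pattern[i + 1 : j]), frozenset()))
            i = j + 1
        elif c == ".":
            positions.append((None, frozenset()))
            i += 1
        elif c.isalpha() and c.isupper():
            positions.append((frozenset(c), frozenset()))
            i += 1
        else:
            raise ValueError(f"bad motif pattern {pattern!r} at position {i}")
    if not any(req is not None for req, _ in positions):
        raise ValueError(f"motif {pattern!r} has no fixed position")
    return MotifPattern(pattern, tuple(positions))


def find_motif(
    seq: str,
    motif: MotifPattern | str,
    start: int = 0,
    end: int | None = None,
    pick: str = "first",
) -> int | None:
    """Locate a motif in ``seq[start:end]``.

    Returns the 0-based start of the selected match or ``None``.  ``pick``
    is ``first``, ``last`` or ``best``; ``best`` maximizes the number of
    preferred wildcard residues matched and breaks ties toward the earliest
    position.
    """
    if isinstance(motif, str):
        motif = compile_motif(motif)
    if pick not in ("first", "last", "best"):
        raise ValueError(f"unknown pick mode {pick!r}")
    start = max(0, start)
    stop = len(seq) if end is None else min(end, len(seq))
    stop -= len(motif) - 1
    best_i: int | None = None
    best_score = -1
    for i in range(start, stop):
        score = motif.match_score(seq, i)
        if score is None:
            continue
        if pick == "first":
            return i
        if pick == "last":
            best_i = i
        elif score > best_score:
            best_i, best_score = i, score
    return best_i


# ---------------------------------------------------------------------------
# Schemes


@dataclass(frozen=True)
class SegmentationScheme:
    """Named rule set: motifs, offsets and search windows for one architecture."""

    name: str
    params: dict


def load_schemes(path: str | Path | None = None) -> dict[str, SegmentationScheme]:
    """Load scheme definitions from YAML (bundled defaults when no path)."""
    if path is None:
        text = resources.files("cellink.data").joinpath("schemes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return {name: SegmentationScheme(name, params) for name, params in raw.items()}


DEFAULT_SCHEMES = load_schemes()


def _params(scheme_name: str, scheme: SegmentationScheme | None) -> dict:
    base = DEFAULT_SCHEMES[scheme_name].params
    if scheme is None:
        return base
    return {**base, **scheme.params}


# ---------------------------------------------------------------------------
# Segmented proteins


@dataclass(frozen=True)
class SegmentedProtein:
    """The CBM/linker/GH partition of one record.

    ``boundaries`` are the two half-open cut indices into the post-trim
    sequence (``record.seq[trim:]``); for an ``ok`` record the first
    segment, linker and last segment concatenate to exactly that sequence.
    """

    record: ProteinRecord
    scheme: str
    status: str = "ok"
    reason: str = ""
    cbm: str = ""
    linker: str = ""
    gh: str = ""
    trim: int = 0
    boundaries: tuple[int, int] = (0, 0)

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    @property
    def cbm_first(self) -> bool:
        return self.scheme in ("CBM1_GH6", "CBM2_GH6")


def _failed(record: ProteinRecord, scheme: str, reason: str) -> SegmentedProtein:
    return SegmentedProtein(record=record, scheme=scheme, status="failed", reason=reason)


def _ok(record, scheme, work, trim, cut1, cut2) -> SegmentedProtein:
    first, linker, last = work[:cut1], work[cut1:cut2], work[cut2:]
    cbm_first = scheme in ("CBM1_GH6", "CBM2_GH6")
    return SegmentedProtein(
        record=record,
        scheme=scheme,
        cbm=first if cbm_first else last,
        linker=linker,
        gh=last if cbm_first else first,
        trim=trim,
        boundaries=(cut1, cut2),
    )


def segment_cbm1_gh6(record: ProteinRecord, scheme: SegmentationScheme | None = None) -> SegmentedProtein:
    """Eukaryotic CBM1-linker-GH6.

    The first QCGG anchors the CBM1: any signal peptide more than 6
    residues N-terminal to it is trimmed.  The CBM ends after the
    (S)QC(L) motif (best-scoring match downstream of the anchor); the GH6
    begins 5 residues N-terminal to the (G)N(P)(F) motif, searched
    downstream of the CBM cut with preferred-residue scoring.
    """
    p = _params("CBM1_GH6", scheme)
    seq = record.seq
    anchor = compile_motif(p["signal_anchor"])
    q = find_motif(seq, anchor, pick="first")
    if q is None:
        return _failed(record, "CBM1_GH6", "no CBM1 anchor")
    trim = max(0, q - p["signal_keep_upstream"])
    work = seq[trim:]
    q -= trim
    sqcl = find_motif(
        work,
        compile_motif(p["cbm_end_motif"]),
        start=q + len(anchor),
        end=q + len(anchor) + p["cbm_end_window"],
        pick="best",
    )
    if sqcl is None:
        return _failed(record, "CBM1_GH6", "no CBM1 cut motif")
    cut1 = sqcl + len(compile_motif(p["cbm_end_motif"]))
    gh_motif = compile_motif(p["gh_start_motif"])
    m = find_motif(work, gh_motif, start=cut1 + p["gh_start_offset"], pick="best")
    if m is None:
        return _failed(record, "CBM1_GH6", "no GH6 anchor")
    cut2 = m - p["gh_start_offset"]
    return _ok(record, "CBM1_GH6", work, trim, cut1, cut2)


def segment_gh7_cbm1(record: ProteinRecord, scheme: SegmentationScheme | None = None) -> SegmentedProtein:
    """Eukaryotic GH7-linker-CBM1.

    The GH7 ends 9 residues after the last residue of the S/T-N/D-I-K
    motif; the CBM1 begins 6 residues N-terminal to the QCGG anchor,
    searched downstream of the GH cut.
    """
    p = _params("GH7_CBM1", scheme)
    seq = record.seq
    motif = compile_motif(p["gh_end_motif"])
    m = find_motif(seq, motif, pick="first")
    if m is None:
        return _failed(record, "GH7_CBM1", "no GH7 anchor")
    cut1 = m + len(motif) + p["gh_end_tail"]
    if cut1 >= len(seq):
        return _failed(record, "GH7_CBM1", "GH7 cut beyond sequence end")
    q = find_motif(seq, p["cbm_anchor"], start=cut1 + p["cbm_keep_upstream"], pick="first")
    if q is None:
        return _failed(record, "GH7_CBM1", "no CBM1 anchor")
    cut2 = q - p["cbm_keep_upstream"]
    return _ok(record, "GH7_CBM1", seq, 0, cut1, cut2)


def segment_cbm2_gh6(record: ProteinRecord, scheme: SegmentationScheme | None = None) -> SegmentedProtein:
    """Bacterial CBM2-linker-GH6.

    The CBM2 ends 2 residues C-terminal to the conserved cysteine (the
    last Cys within the leading search window); the GH6 begins at the RVDN
    motif, or at the YVD motif when RVDN is absent.
    """
    p = _params("CBM2_GH6", scheme)
    seq = record.seq
    window = seq[: p["cbm_window"]]
    cys = window.rfind("C")
    if cys == -1:
        return _failed(record, "CBM2_GH6", "no CBM2 anchor")
    cut1 = cys + 1 + p["cbm_tail"]
    if cut1 >= len(seq):
        return _failed(record, "CBM2_GH6", "CBM2 cut beyond sequence end")
    cut2 = None
    for pat in p["gh_start_motifs"]:
        m = find_motif(seq, pat, start=cut1, pick="first")
        if m is not None:
            cut2 = m
            break
    if cut2 is None:
        return _failed(record, "CBM2_GH6", "no GH6 anchor")
    return _ok(record, "CBM2_GH6", seq, 0, cut1, cut2)


def segment_gh6_cbm2(record: ProteinRecord, scheme: SegmentationScheme | None = None) -> SegmentedProtein:
    """Bacterial GH6-linker-CBM2.

    The GH6 ends 8 residues C-terminal to the FVML motif; the CBM2 begins
    at the first Cys (or other hydrophobic residue L/I/F) at least
    ``min_linker`` residues downstream of the GH cut, which keeps the
    anchor from firing inside the GH tail.
    """
    p = _params("GH6_CBM2", scheme)
    seq = record.seq
    motif = compile_motif(p["gh_end_motif"])
    m = find_motif(seq, motif, pick="first")
    if m is None:
        return _failed(record, "GH6_CBM2", "no GH6 anchor")
    cut1 = m + len(motif) + p["gh_end_tail"]
    if cut1 >= len(seq):
        return _failed(record, "GH6_CBM2", "GH6 cut beyond sequence end")
    allowed = set(p["cbm_start_residues"])
    cut2 = None
    for i in range(cut1 + p["min_linker"], len(seq)):
        if seq[i] in allowed:
            cut2 = i
            break
    if cut2 is None:
        return _failed(record, "GH6_CBM2", "no CBM2 anchor")
    return _ok(record, "GH6_CBM2", seq, 0, cut1, cut2)


_SEGMENTERS = {
    "CBM1_GH6": segment_cbm1_gh6,
    "GH7_CBM1": segment_gh7_cbm1,
    "CBM2_GH6": segment_cbm2_gh6,
    "GH6_CBM2": segment_gh6_cbm2,
}


def segment_record(record: ProteinRecord, scheme: SegmentationScheme | None = None) -> SegmentedProtein:
    """Apply the rule set matching ``record.dataset``."""
    if record.dataset not in _SEGMENTERS:
        raise ValueError(f"record {record.id!r} has no segmentable dataset label")
    return _SEGMENTERS[record.dataset](record, scheme)


def segment_dataset(dataset: Dataset, scheme: SegmentationScheme | None = None) -> list[SegmentedProtein]:
    if scheme is not None and scheme.name != dataset.label:
        raise ValueError(f"scheme {scheme.name!r} does not match dataset {dataset.label!r}")
    return [segment_record(rec, scheme) for rec in dataset]


def batch_segment(
    dataset: Dataset, scheme: SegmentationScheme | None = None
) -> tuple[LinkerSet, list[SegmentedProtein]]:
    """Segment every record; collect failures instead of dropping them.

    Returns the linker set (one entry per successfully segmented record,
    carrying id and subset flag) and the list of failed segmentations.
    """
    segmented = segment_dataset(dataset, scheme)
    linkers = [
        LinkerRecord(s.record.id, s.linker, s.record.subset_flag)
        for s in segmented
        if s.ok
    ]
    failures = [s for s in segmented if not s.ok]
    return LinkerSet(label=dataset.label, linkers=linkers), failures


# ---------------------------------------------------------------------------
# Output


def write_segmentation_tsv(segmented: Iterable[SegmentedProtein], path: str | Path) -> None:
    """Boundary report: 1-based inclusive coordinates in the original sequence."""
    lines = ["id\tscheme\tcbm_start\tcbm_end\tlinker_start\tlinker_end\tgh_start\tgh_end\tstatus"]
    for s in segmented:
        if not s.ok:
            lines.append(f"{s.record.id}\t{s.scheme}\t\t\t\t\t\t\tfailed:{s.reason}")
            continue
        cut1, cut2 = s.boundaries
        total = len(s.record.seq)
        first = (s.trim + 1, s.trim + cut1)
        mid = (s.trim + cut1 + 1, s.trim + cut2)
        last = (s.trim + cut2 + 1, total)
        cbm, gh = (first, last) if s.cbm_first else (last, first)
        lines.append(
            f"{s.record.id}\t{s.scheme}\t{cbm[0]}\t{cbm[1]}\t{mid[0]}\t{mid[1]}\t{gh[0]}\t{gh[1]}\tok"
        )
    Path(path).write_text("\n".join(lines) + "\n")
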