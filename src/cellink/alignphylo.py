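"""Pairwise global alignment, percent-identity distributions and
neighbor-joining trees.

Identities are computed from all-pairs affine-gap global alignments
(three-state Needleman-Wunsch via Bio.Align.PairwiseAligner) under GONNET
scoring with gap open 10 and gap extend 0.05 per additional gapped column.
Percent identity uses the number of aligned columns excluding terminal-gap
overhangs as the denominator.  Trees come from neighbor joining on
``d = 100 - percent identity`` with negative branch lengths clamped to
zero, which is exact on additive distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .linkerstats import LinkerSet
from .seqio import Dataset

DEFAULT_MATRIX = "GONNET1992"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.05


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identities: int
    columns: int
    percent_identity: float


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # square, symmetric, diagonal 100

    def to_distance_matrix(self) -> DistanceMatrix:
        return DistanceMatrix(100.0 - self.values, ids=list(self.labels))

    def pair_identities(self) -> np.ndarray:
        """Upper-triangle percent identities, one per unordered pair."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def make_aligner(
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Align.PairwiseAligner:
    """Affine-gap global aligner: the first gapped column costs ``gap_open``,
    each additional column ``gap_extend``."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.wildcard = "X"
    return aligner


def _trim_overhangs(a: str, b: str) -> tuple[int, int]:
    """Column span [start, stop) excluding terminal-gap overhangs.

    A leading (trailing) overhang is the run of columns before the later
    sequence starts (after the earlier one ends) in the alignment.
    """
    start = max(len(a) - len(a.lstrip("-")), len(b) - len(b.lstrip("-")))
    stop = min(len(a.rstrip("-")), len(b.rstrip("-")))
    return start, max(start, stop)


def global_align(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two sequences.

    Percent identity is identical columns over aligned columns, where
    terminal overhangs (leading/trailing columns gapped in one sequence)
    are excluded from the denominator.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    start, stop = _trim_overhangs(a, b)
    columns = stop - start
    identities = sum(
        1 for x, y in zip(a[start:stop], b[start:stop]) if x == y and x != "-"
    )
    pid = 100.0 * identities / columns if columns else 0.0
    return AlignmentResult(
        aligned_a=a,
        aligned_b=b,
        score=float(aln.score),
        identities=identities,
        columns=columns,
        percent_identity=pid,
    )


def identity_matrix(
    labels: Sequence[str],
    seqs: Sequence[str],
    aligner: Align.PairwiseAligner | None = None,
) -> IdentityMatrix:
    """All-pairs percent-identity matrix (symmetric, diagonal 100)."""
    if len(labels) != len(seqs):
        raise ValueError("labels and sequences differ in length")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in identity matrix")
    if aligner is None:
        aligner = make_aligner()
    n = len(seqs)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = global_align(seqs[i], seqs[j], aligner).percent_identity
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(labels=tuple(labels), values=values)


def _extract_pairs(source, domain: str | None) -> tuple[list[str], list[str]]:
    """Labels and sequences from a LinkerSet, a Dataset, or segmented records."""
    if isinstance(source, LinkerSet):
        return [l.id for l in source], [l.seq for l in source]
    if isinstance(source, Dataset):
        return [r.id for r in source], [r.seq for r in source]
    # list of SegmentedProtein
    if domain not in ("cbm", "linker", "gh"):
        raise ValueError("domain must be one of cbm/linker/gh for segmented input")
    ok = [s for s in source if s.ok]
    return [s.record.id for s in ok], [getattr(s, domain) for s in ok]


def identity_histogram(
    source,
    domain: str | None = None,
    bin_width: float = 5.0,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[dict[tuple[float, float], int], IdentityMatrix]:
    """Histogram of pairwise percent identities.

    ``source`` may be a LinkerSet, a Dataset of full-length records, or a
    list of segmented proteins with ``domain`` selecting cbm/linker/gh.
    Bins are half-open ``[lo, lo+w)`` with 100.0 falling in the top bin;
    counts sum to n(n-1)/2.
    """
    labels, seqs = _extract_pairs(source, domain)
    if len(seqs) < 2:
        raise ValueError("identity histogram requires at least 2 sequences")
    empties = [l for l, s in zip(labels, seqs) if not s]
    if empties:
        raise ValueError(f"cannot align empty segment(s): {empties}")
    mat = identity_matrix(labels, seqs, aligner)
    counts: dict[tuple[float, float], int] = {}
    for pid in mat.pair_identities():
        lo = min(int(pid // bin_width) * bin_width, 100.0 - bin_width)
        key = (lo, lo + bin_width)
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items())), mat


EXO_EC_PREFIXES = ("3.2.1.91", "3.2.1.176")
ENDO_EC_PREFIXES = ("3.2.1.4",)


def subset_by_ec(
    dataset: Dataset,
    exo_prefixes: Sequence[str] = EXO_EC_PREFIXES,
    endo_prefixes: Sequence[str] = ENDO_EC_PREFIXES,
) -> tuple[Dataset, Dataset, list]:
    """Split records into exoglucanases and endoglucanases by EC number.

    Cellobiohydrolases (exo, processive) carry EC 3.2.1.91/176;
    endoglucanases carry EC 3.2.1.4.  Records without a matching EC are
    returned separately as unclassified.
    """
    exo, endo, unclassified = [], [], []
    for rec in dataset:
        ec = rec.ec_number or ""
        if any(ec.startswith(p) for p in exo_prefixes):
            exo.append(rec)
        elif any(ec.startswith(p) for p in endo_prefixes):
            endo.append(rec)
        else:
            unclassified.append(rec)
    return (
        Dataset(label=dataset.label, records=exo),
        Dataset(label=dataset.label, records=endo),
        unclassified,
    )


def nj_tree(matrix: IdentityMatrix | DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from percent identities (d = 100 - identity).

    Negative branch lengths produced by the NJ algebra are clamped to
    zero.  Requires at least 3 labels; the 2-leaf case is a single edge
    and is left to the caller.
    """
    if isinstance(matrix, IdentityMatrix):
        dm = matrix.to_distance_matrix()
    else:
        dm = matrix
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    return nj(dm, neg_as_zero=True)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def clade_separated(tree: TreeNode, outlier_ids: Sequence[str]) -> bool:
    """True when some edge of the tree bipartitions the leaves into exactly
    ``outlier_ids`` versus the rest (the outliers form their own clade)."""
    outliers = frozenset(outlier_ids)
    all_tips = frozenset(t.name for t in tree.tips())
    if not outliers or not outliers < all_tips:
        raise ValueError("outlier ids must be a proper non-empty subset of the tips")
    for node in tree.non_tips(include_self=True):
        tips = frozenset(t.name for t in node.tips())
        if tips == outliers or all_tips - tips == outliers:
            return True
    return False
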