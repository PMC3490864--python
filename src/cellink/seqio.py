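"""Reading, writing and assembly of cellulase sequence datasets.

Full-length protein sequences arrive as FASTA; per-record annotations
(organism, architecture class, subset flags, optional EC number) live in a
sidecar tab-separated table, mirroring how such annotations are curated in
supplementary accession tables rather than in the sequence records
themselves.  This module turns those two files into validated
:class:`Dataset` objects keyed by multidomain architecture.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The four multidomain architectures, named N- to C-terminus.
DATASET_LABELS = ("GH7_CBM1", "CBM1_GH6", "CBM2_GH6", "GH6_CBM2")

#: Known subset flags.  ``core`` records enter every statistic; the two
#: outlier flags mark divergent clades removed before length/composition
#: comparisons.
SUBSET_FLAGS = ("core", "ruminal_fungi", "proteobacteria")

#: 20 canonical residues plus X for ambiguity.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

METADATA_COLUMNS = ["id", "organism", "genus", "dataset", "subset_flag", "ec_number"]


class FastaRecord(NamedTuple):
    id: str
    seq: str
    description: str = ""


def _check_alphabet(seq: str, context: str) -> None:
    bad = set(seq) - ALLOWED_RESIDUES
    if bad:
        raise ValueError(
            f"{context}: residues outside the amino-acid alphabet: {sorted(bad)}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated full-length sequence."""

    id: str
    seq: str
    organism: str = ""
    genus: str = ""
    dataset: str | None = None
    subset_flag: str = "core"
    ec_number: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        seq = self.seq.upper()
        _check_alphabet(seq, f"record {self.id!r}")
        object.__setattr__(self, "seq", seq)
        if self.dataset is not None and self.dataset not in DATASET_LABELS:
            raise ValueError(
                f"record {self.id!r}: unknown dataset label {self.dataset!r}; "
                f"expected one of {DATASET_LABELS}"
            )
        if self.subset_flag not in SUBSET_FLAGS:
            raise ValueError(
                f"record {self.id!r}: unknown subset flag {self.subset_flag!r}"
            )
        if self.organism and not self.genus:
            object.__setattr__(self, "genus", self.organism.split()[0])
        if self.organism and self.genus:
            first = self.organism.split()[0]
            if self.genus != first:
                raise ValueError(
                    f"record {self.id!r}: genus {self.genus!r} does not match the "
                    f"first token of organism {self.organism!r}"
                )


@dataclass
class Dataset:
    """An ordered collection of records sharing one architecture label."""

    label: str
    records: list[ProteinRecord] = field(default_factory=list)
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in DATASET_LABELS:
            raise ValueError(f"unknown dataset label {self.label!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.dataset != self.label:
                raise ValueError(
                    f"record {rec.id!r} labelled {rec.dataset!r} in dataset {self.label!r}"
                )
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in dataset {self.label!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genera(self) -> set[str]:
        """Deduplicated, case-normalized genus names."""
        return {r.genus.lower() for r in self.records if r.genus}


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Parse a FASTA file into (id, seq, description) tuples, in file order.

    Sequences are uppercased and validated against the 20-letter alphabet
    plus X.  The id is the first whitespace-delimited token of the header;
    the full header is kept as the description.  An empty file yields an
    empty list with a warning; sequence data before the first header is a
    parse error naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []
    out: list[FastaRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        _check_alphabet(seq, f"{path}: record {rec.id!r}")
        out.append(FastaRecord(rec.id, seq, rec.description))
    return out


def write_fasta(records: Iterable[FastaRecord | ProteinRecord | tuple], path: str | Path) -> None:
    """Write (id, seq[, description]) records as wrapped FASTA."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, ProteinRecord):
            rid, seq, desc = rec.id, rec.seq, rec.organism
        else:
            rid, seq = rec[0], rec[1]
            desc = rec[2] if len(rec) > 2 else ""
        # SeqIO writes "id description"; keep only the part after the id.
        if desc.startswith(rid):
            desc = desc[len(rid):].strip()
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(seqrecs, str(path), "fasta")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar annotation TSV.

    Requires a header row with at least an ``id`` column.  ``genus`` is
    derived from ``organism`` when absent, ``subset_flag`` defaults to
    ``core``.  Duplicate ids and unknown dataset labels or subset flags are
    errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "id" not in df.columns:
        raise ValueError(f"{path}: metadata requires an 'id' column")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate metadata ids: {sorted(set(dup))}")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    derived = df["organism"].str.split().str[0].fillna("")
    df.loc[df["genus"] == "", "genus"] = derived
    df.loc[df["subset_flag"] == "", "subset_flag"] = "core"
    bad_ds = sorted(set(df["dataset"]) - set(DATASET_LABELS) - {""})
    if bad_ds:
        raise ValueError(f"{path}: unknown dataset labels: {bad_ds}")
    bad_flag = sorted(set(df["subset_flag"]) - set(SUBSET_FLAGS))
    if bad_flag:
        raise ValueError(f"{path}: unknown subset flags: {bad_flag}")
    return df[METADATA_COLUMNS]


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def assemble_dataset(
    fasta_records: Sequence[FastaRecord],
    metadata: pd.DataFrame,
    label: str,
) -> Dataset:
    """Join FASTA records to metadata rows carrying the given class label.

    The result contains exactly the records whose metadata ``dataset``
    equals ``label``, in metadata order.  Metadata ids missing from the
    FASTA are an error.
    """
    if label not in DATASET_LABELS:
        raise ValueError(f"unknown dataset label {label!r}")
    by_id = {r.id: r for r in fasta_records}
    rows = metadata[metadata["dataset"] == label]
    missing = [rid for rid in rows["id"] if rid not in by_id]
    if missing:
        raise ValueError(f"metadata ids absent from FASTA: {missing}")
    records = [
        ProteinRecord(
            id=row.id,
            seq=by_id[row.id].seq,
            organism=row.organism,
            genus=row.genus,
            dataset=label,
            subset_flag=row.subset_flag,
            ec_number=row.ec_number,
        )
        for row in rows.itertuples()
    ]
    return Dataset(label=label, records=records)


def exclude_subset(dataset: Dataset, flag: str) -> Dataset:
    """Return a new dataset without the records carrying ``flag``.

    Removing zero records is legal; removing every record leaves an empty
    dataset and emits a warning.
    """
    if flag not in SUBSET_FLAGS:
        raise ValueError(f"unknown subset flag {flag!r}")
    kept = [r for r in dataset.records if r.subset_flag != flag]
    removed = len(dataset) - len(kept)
    logger.info("excluded %d/%d records flagged %r from %s", removed, len(dataset), flag, dataset.label)
    if dataset.records and not kept:
        warnings.warn(f"dataset {dataset.label}: all records carried flag {flag!r}", stacklevel=2)
    return Dataset(label=dataset.label, records=kept, provenance=dataset.provenance)
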