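"""Synthetic multidomain cellulases with known ground truth.

Every generated protein embeds the exact junction motifs the segmentation
rules anchor on (QCGG / (S)QC(L) / (G)N(P)(F), S/T-N/D-I-K, the CBM2
cysteine, RVDN / YVD, FVML, and the C/L/I/F CBM2 start), around a linker
drawn from a per-class statistical model, so the true boundaries are known
by construction and recorded in a truth table.

The four core linker classes are parameterized from the survey statistics
of real GH6/GH7 cellulase linkers: truncated-normal lengths with means
30/42/35/34 and SDs 7/8/13/17 residues, eukaryotic compositions of roughly
55% combined Ser+Thr with 15% Pro, bacterial compositions of roughly 35%
Pro with 40% Ser+Thr, and a mild coupling of Ser/Thr (all classes) and Pro
(bacterial classes) content to linker length.  Two outlier classes emulate
the divergent clades seen in real data: asparagine-rich ruminal-fungal-like
linkers (~45% Asn, ~5% Ser+Thr, >100 residues) and glycine-rich
proteobacterial-like linkers (~25% Gly, >100 residues).

Structured domains are low-entropy stub templates shared per class with a
small per-record mutation rate — not biologically realistic folds — so
structured segments show high pairwise identity while linkers do not.
Stub alphabets deliberately omit the residues that could complete a
spurious junction motif, which is what guarantees exact boundary recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .linkerstats import LinkerRecord, LinkerSet
from .seqio import (
    Dataset,
    FastaRecord,
    assemble_dataset,
    write_fasta,
    write_metadata,
)

# ---------------------------------------------------------------------------
# Linker class specifications


class TrendSpec(NamedTuple):
    """Linear coupling of a residue group's fraction to linker length:
    the group's target fraction changes by ``slope`` per residue of length
    away from the class mean, compensated by scaling the other residues."""

    residues: str
    slope: float


class TerminalModifier(NamedTuple):
    """Terminal-bin adjustment: S/T residues falling in the first or last
    of ``n_bins`` sections are swapped to glycine with probability
    ``swap_prob``, emulating the glycine-rich, O-glycan-poor junctions."""

    swap_prob: float
    n_bins: int = 11
    from_residues: str = "ST"
    to_residue: str = "G"


@dataclass(frozen=True)
class LinkerClassSpec:
    label: str
    length_mean: float
    length_sd: float
    length_min: int
    length_max: int
    composition: dict
    trend: tuple[TrendSpec, ...] = ()
    positional_modifiers: TerminalModifier | None = None

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class {self.label!r}: composition sums to {total}, not 1")
        if not (self.length_min <= self.length_mean <= self.length_max):
            raise ValueError(f"class {self.label!r}: length bounds exclude the mean")


_EUK_COMPOSITION = {
    "S": 0.25, "T": 0.30, "P": 0.15, "G": 0.10, "A": 0.06,
    "Q": 0.05, "N": 0.04, "V": 0.03, "E": 0.02,
}
_BACT_COMPOSITION = {
    "P": 0.35, "T": 0.30, "S": 0.10, "G": 0.10, "A": 0.06,
    "Q": 0.04, "N": 0.03, "D": 0.02,
}
_RUMINAL_COMPOSITION = {
    "N": 0.45, "S": 0.03, "T": 0.02, "G": 0.15, "P": 0.10,
    "A": 0.10, "Q": 0.08, "E": 0.07,
}
_PROTEO_COMPOSITION = {
    "S": 0.30, "T": 0.10, "G": 0.25, "P": 0.15, "A": 0.08,
    "Q": 0.07, "N": 0.05,
}

_ST_TREND = TrendSpec("ST", 0.002)
_P_TREND = TrendSpec("P", 0.002)

#: Default class specs: the study conditions the statistics are computed under.
CLASS_SPECS: dict[str, LinkerClassSpec] = {
    "GH7_CBM1": LinkerClassSpec("GH7_CBM1", 30, 7, 16, 47, _EUK_COMPOSITION, (_ST_TREND,)),
    "CBM1_GH6": LinkerClassSpec("CBM1_GH6", 42, 8, 25, 61, _EUK_COMPOSITION, (_ST_TREND,)),
    "CBM2_GH6": LinkerClassSpec("CBM2_GH6", 35, 13, 16, 65, _BACT_COMPOSITION, (_ST_TREND, _P_TREND)),
    "GH6_CBM2": LinkerClassSpec("GH6_CBM2", 34, 17, 14, 75, _BACT_COMPOSITION, (_ST_TREND, _P_TREND)),
    "ruminal": LinkerClassSpec("ruminal", 115, 10, 101, 135, _RUMINAL_COMPOSITION),
    "proteobacteria": LinkerClassSpec("proteobacteria", 125, 15, 101, 158, _PROTEO_COMPOSITION),
}

#: Outlier class attached to each core architecture, and the subset flag it carries.
OUTLIER_CLASS = {"CBM1_GH6": "ruminal", "CBM2_GH6": "proteobacteria"}
OUTLIER_FLAG = {"ruminal": "ruminal_fungi", "proteobacteria": "proteobacteria"}
#: Architecture (segmentation scheme) of each class.
ARCHITECTURE = {
    "GH7_CBM1": "GH7_CBM1", "CBM1_GH6": "CBM1_GH6",
    "CBM2_GH6": "CBM2_GH6", "GH6_CBM2": "GH6_CBM2",
    "ruminal": "CBM1_GH6", "proteobacteria": "CBM2_GH6",
}

#: Dataset sizes of the real survey (post-exclusion core n per architecture).
STUDY_N = {"GH7_CBM1": 79, "CBM1_GH6": 39, "CBM2_GH6": 25, "GH6_CBM2": 15}
STUDY_N_OUTLIERS = {"CBM1_GH6": 5, "CBM2_GH6": 5}


def terminal_glycine_spec(base: str = "GH7_CBM1", swap_prob: float = 0.5) -> LinkerClassSpec:
    """Engineered class with strong terminal-bin glycine enrichment."""
    spec = CLASS_SPECS[base]
    return replace(spec, label=f"{spec.label}_terminal_G",
                   positional_modifiers=TerminalModifier(swap_prob))


# ---------------------------------------------------------------------------
# Linker sampling


def sample_length(spec: LinkerClassSpec, rng: np.random.Generator) -> int:
    """Truncated-normal length: rounded draws, re-drawn until within bounds."""
    for _ in range(10_000):
        length = int(round(rng.normal(spec.length_mean, spec.length_sd)))
        if spec.length_min <= length <= spec.length_max:
            return length
    raise ValueError(f"class {spec.label!r}: length bounds appear infeasible")


def _length_adjusted_probs(spec: LinkerClassSpec, length: int) -> tuple[list[str], np.ndarray]:
    """Residue probabilities for one linker of the given length.

    Trends pivot at the length-biased mean (mean + var/mean) rather than
    the plain mean: pooled composition weights each linker by its residue
    count, so pivoting there keeps the pooled set composition at the class
    target while individual linkers follow the trend.
    """
    residues = list(spec.composition)
    probs = {r: p for r, p in spec.composition.items()}
    pivot = spec.length_mean + spec.length_sd**2 / spec.length_mean
    trended: set[str] = set()
    for tr in spec.trend:
        group = [r for r in tr.residues if r in probs]
        gsum = sum(spec.composition[r] for r in group)
        target = gsum + tr.slope * (length - pivot)
        if not 0.0 < target < 1.0:
            raise ValueError(f"class {spec.label!r}: trend drives {tr.residues} fraction to {target}")
        for r in group:
            probs[r] = spec.composition[r] * target / gsum
        trended.update(group)
    rest = [r for r in residues if r not in trended]
    rest_base = sum(spec.composition[r] for r in rest)
    rest_target = 1.0 - sum(probs[r] for r in trended)
    if rest and rest_target <= 0.0:
        raise ValueError(f"class {spec.label!r}: trends leave no probability mass")
    for r in rest:
        probs[r] = spec.composition[r] * rest_target / rest_base
    return residues, np.array([probs[r] for r in residues])


def sample_linker(spec: LinkerClassSpec, rng: np.random.Generator, length: int | None = None) -> str:
    """Draw one linker: truncated-normal length, i.i.d. residues from the
    (length-adjusted) composition, then optional terminal modifiers."""
    if length is None:
        length = sample_length(spec, rng)
    elif not spec.length_min <= length <= spec.length_max:
        raise ValueError(f"forced length {length} outside class bounds")
    residues, probs = _length_adjusted_probs(spec, length)
    chars = list(rng.choice(residues, size=length, p=probs))
    mod = spec.positional_modifiers
    if mod is not None and length:
        for i in range(length):
            b = i * mod.n_bins // length
            if b in (0, mod.n_bins - 1) and chars[i] in mod.from_residues:
                if rng.random() < mod.swap_prob:
                    chars[i] = mod.to_residue
    return "".join(chars)


# ---------------------------------------------------------------------------
# Stub structured domains

# Fixed build seed: templates are constants of the generator, derived once.
_TEMPLATE_RNG = np.random.default_rng(20121106)


def _rand_seq(alphabet: str, n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@dataclass(frozen=True)
class Stub:
    """A per-class structured-domain template.

    ``alphabet`` is the mutation alphabet; it omits every residue that
    could complete a spurious junction motif for the architecture the stub
    appears in, so per-record mutations can never break segmentation.
    """

    seq: str
    alphabet: str

    def mutate(self, rng: np.random.Generator, rate: float = 0.05) -> str:
        chars = list(self.seq)
        letters = list(self.alphabet)
        for i in range(len(chars)):
            if rng.random() < rate:
                chars[i] = letters[rng.integers(len(letters))]
        return "".join(chars)

    def diverged(self, rng: np.random.Generator, rate: float) -> "Stub":
        return Stub(self.mutate(rng, rate), self.alphabet)


# Stub alphabets omit every residue that could complete a spurious junction
# motif for the architecture the stub appears in: no C near a CBM1 (keeps
# the QCGG / xQCx anchors unique), no F in a GH6-adjacent stub (caps
# (G)N(P)(F) scores below the true motif; no FVML), no I in a GH7 stub
# (no [ST][ND]IK), no C on the CBM2 side (last-Cys rule), and no V in the
# bacterial GH6 stub (no chance RVDN upstream of the true GH start).
_A_NO_C = "ADEGHKNQRSTVWY"
_A_GH6_EUK = "ADEGHIKLMNPQRSTVWY"          # no C, no F
_A_GH7 = "ADEFGHKLMNPQRSTVWY"              # no C, no I
_A_CBM2 = "ADEGHKLMNPQSTVW"                # no C, no F, no R, no Y
_A_GH6_BACT = "ADEGHKLMNPQRSTW"            # no C, no F, no V, no Y
_A_GH6_CBM2 = "ADEGHIKLMNPQRSTVWY"         # no C, no F

_STUBS = {
    "CBM1_body": Stub(_rand_seq(_A_NO_C, 20, _TEMPLATE_RNG), _A_NO_C),
    "GH6_euk": Stub(_rand_seq(_A_GH6_EUK, 110, _TEMPLATE_RNG), _A_GH6_EUK),
    "GH7_exo": Stub(_rand_seq(_A_GH7, 100, _TEMPLATE_RNG), _A_GH7),
    "CBM1_tail": Stub(_rand_seq(_A_NO_C, 28, _TEMPLATE_RNG), _A_NO_C),
    "CBM2_body": Stub(_rand_seq(_A_CBM2, 90, _TEMPLATE_RNG), _A_CBM2),
    "GH6_bact": Stub(_rand_seq(_A_GH6_BACT, 120, _TEMPLATE_RNG), _A_GH6_BACT),
    "GH6_first": Stub(_rand_seq(_A_GH6_CBM2, 108, _TEMPLATE_RNG), _A_GH6_CBM2),
    "CBM2_tail": Stub(_rand_seq(_A_CBM2, 90, _TEMPLATE_RNG), _A_CBM2),
}
# Endoglucanase GH7 subfamily: the exo template diverged at ~25% of sites.
_STUBS["GH7_endo"] = _STUBS["GH7_exo"].diverged(_TEMPLATE_RNG, 0.25)
# Outlier-clade templates: core templates diverged at ~30% of sites, so
# full-length trees place the outliers on their own branch.
_OUTLIER_STUBS = {
    "ruminal": {
        "CBM1_body": _STUBS["CBM1_body"].diverged(_TEMPLATE_RNG, 0.30),
        "GH6_euk": _STUBS["GH6_euk"].diverged(_TEMPLATE_RNG, 0.30),
    },
    "proteobacteria": {
        "CBM2_body": _STUBS["CBM2_body"].diverged(_TEMPLATE_RNG, 0.30),
        "GH6_bact": _STUBS["GH6_bact"].diverged(_TEMPLATE_RNG, 0.30),
    },
}

_MUTATION_RATE = 0.05

# ---------------------------------------------------------------------------
# Genus pools

# Eukaryotic pools share 23 genera; |GH7_CBM1 pool| = 28 and
# |CBM1_GH6 pool| = 37, so the core genus overlaps are 23/28 = 82.1% and
# 23/37 = 62.2%, matching the overlap observed between the real datasets.
_SHARED_EUK = [
    "Trichoderma", "Aspergillus", "Penicillium", "Humicola", "Fusarium",
    "Neurospora", "Chaetomium", "Talaromyces", "Phanerochaete", "Hypocrea",
    "Acremonium", "Emericella", "Gibberella", "Magnaporthe", "Podospora",
    "Sclerotinia", "Botryotinia", "Cochliobolus", "Pyricularia", "Melanocarpus",
    "Thermoascus", "Scytalidium", "Thielavia",
]
GENUS_POOLS = {
    "GH7_CBM1": _SHARED_EUK + ["Geotrichum", "Cladosporium", "Alternaria", "Bispora", "Malbranchea"],
    "CBM1_GH6": _SHARED_EUK + [
        "Agaricus", "Pleurotus", "Coprinopsis", "Schizophyllum", "Volvariella",
        "Lentinula", "Polyporus", "Trametes", "Irpex", "Phlebia",
        "Ustilago", "Cryptococcus", "Rhizopus", "Mucor",
    ],
    "CBM2_GH6": [
        "Cellulomonas", "Thermobifida", "Streptomyces", "Micromonospora",
        "Actinoplanes", "Kitasatospora", "Salinispora", "Nocardiopsis",
        "Amycolatopsis", "Saccharothrix", "Catenulispora", "Frankia",
    ],
    "GH6_CBM2": [
        "Cellulomonas", "Thermobifida", "Streptomyces", "Micromonospora",
        "Actinoplanes", "Kitasatospora", "Salinispora", "Nocardiopsis",
        "Jonesia", "Sanguibacter",
    ],
    "ruminal": ["Orpinomyces", "Neocallimastix", "Piromyces", "Anaeromyces", "Caecomyces"],
    "proteobacteria": ["Cellvibrio", "Saccharophagus", "Teredinibacter", "Pseudomonas", "Hahella"],
}

_EC_EXO, _EC_ENDO = "3.2.1.91", "3.2.1.4"

# ---------------------------------------------------------------------------
# Protein assembly


class TruthRow(NamedTuple):
    id: str
    label: str           # linker class
    scheme: str          # architecture / segmentation scheme
    subset_flag: str
    genus: str
    organism: str
    ec_number: str
    trim: int            # expected signal trim (residues)
    cut1: int            # post-trim half-open cut indices
    cut2: int
    linker: str
    linker_length: int


def sample_protein(
    class_label: str,
    rng: np.random.Generator,
    record_id: str = "syn_000",
    index: int = 0,
    spec: LinkerClassSpec | None = None,
    linker_length: int | None = None,
) -> tuple[str, TruthRow]:
    """One full-length protein for a class, with its ground-truth row.

    ``index`` drives the deterministic round-robin assignments (genus, EC
    label, GH-start motif variant) so every pool member appears.
    """
    if class_label not in ARCHITECTURE:
        raise ValueError(f"unknown class {class_label!r}")
    spec = spec or CLASS_SPECS[class_label]
    scheme = ARCHITECTURE[class_label]
    stubs = dict(_STUBS)
    stubs.update(_OUTLIER_STUBS.get(class_label, {}))
    linker = sample_linker(spec, rng, length=linker_length)
    L = len(linker)
    ec = ""

    if scheme == "CBM1_GH6":
        signal = _rand_seq(_A_NO_C, int(rng.integers(2, 9)), rng)
        cbm_body = stubs["CBM1_body"].mutate(rng, _MUTATION_RATE)
        gh_body = stubs["GH6_euk"].mutate(rng, _MUTATION_RATE)
        pre = _rand_seq(_A_NO_C, 6, rng)
        spacer = _rand_seq(_A_GH6_EUK, 5, rng)
        seq = signal + pre + "QCGG" + cbm_body + "SQCL" + linker + spacer + "GNPF" + gh_body
        trim = len(signal)
        cut1 = 6 + 4 + len(cbm_body) + 4
    elif scheme == "GH7_CBM1":
        exo = index % 5 < 3
        ec = _EC_EXO if exo else _EC_ENDO
        gh_body = stubs["GH7_exo" if exo else "GH7_endo"].mutate(rng, _MUTATION_RATE)
        motif = ["S", "T"][int(rng.integers(2))] + ["N", "D"][int(rng.integers(2))] + "IK"
        tail9 = _rand_seq(_A_GH7, 9, rng)
        pre = _rand_seq(_A_NO_C, 6, rng)
        cbm_body = stubs["CBM1_tail"].mutate(rng, _MUTATION_RATE)
        seq = gh_body + motif + tail9 + linker + pre + "QCGG" + cbm_body
        trim = 0
        cut1 = len(gh_body) + 4 + 9
    elif scheme == "CBM2_GH6":
        cbm_body = stubs["CBM2_body"].mutate(rng, _MUTATION_RATE)
        tail2 = _rand_seq(_A_CBM2, 2, rng)
        gh_body = stubs["GH6_bact"].mutate(rng, _MUTATION_RATE)
        gh_start = "RVDN" if index % 5 else "YVDA"  # every 5th record uses the fallback
        seq = cbm_body + "C" + tail2 + linker + gh_start + gh_body
        trim = 0
        cut1 = len(cbm_body) + 1 + 2
    else:  # GH6_CBM2
        gh_body = stubs["GH6_first"].mutate(rng, _MUTATION_RATE)
        tail8 = _rand_seq(_A_GH6_CBM2, 8, rng)
        cbm_body = stubs["CBM2_tail"].mutate(rng, _MUTATION_RATE)
        seq = gh_body + "FVML" + tail8 + linker + "C" + cbm_body
        trim = 0
        cut1 = len(gh_body) + 4 + 8

    pool = GENUS_POOLS[class_label]
    genus = pool[index % len(pool)]
    organism = f"{genus} sp. {index + 1}"
    row = TruthRow(
        id=record_id,
        label=class_label,
        scheme=scheme,
        subset_flag=OUTLIER_FLAG.get(class_label, "core"),
        genus=genus,
        organism=organism,
        ec_number=ec,
        trim=trim,
        cut1=cut1,
        cut2=cut1 + L,
        linker=linker,
        linker_length=L,
    )
    return seq, row


class GeneratedData(NamedTuple):
    label: str
    fasta: list[FastaRecord]
    metadata: pd.DataFrame
    truth: pd.DataFrame
    paths: dict | None

    def to_dataset(self) -> Dataset:
        return assemble_dataset(self.fasta, self.metadata, self.label)

    def true_linkers(self, core_only: bool = False) -> LinkerSet:
        rows = self.truth
        if core_only:
            rows = rows[rows["subset_flag"] == "core"]
        return LinkerSet(
            label=self.label,
            linkers=[LinkerRecord(r.id, r.linker, r.subset_flag) for r in rows.itertuples()],
        )


def generate_dataset(
    label: str,
    n: int,
    seed: int | np.random.Generator = 0,
    out_dir: str | Path | None = None,
    n_outliers: int = 0,
) -> GeneratedData:
    """Generate a class dataset: FASTA records, metadata table, truth table.

    ``n`` core records are followed by ``n_outliers`` records of the
    architecture's outlier class (ruminal for CBM1/GH6, proteobacterial
    for CBM2/GH6), carrying the corresponding subset flag.  With
    ``out_dir`` set, files are written and are byte-identical across runs
    with the same seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_outliers and label not in OUTLIER_CLASS:
        raise ValueError(f"architecture {label!r} has no outlier class")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fasta: list[FastaRecord] = []
    truth_rows: list[TruthRow] = []
    classes = [(label, n)] + ([(OUTLIER_CLASS[label], n_outliers)] if n_outliers else [])
    for cls, count in classes:
        prefix = cls.lower().replace("_", "")
        for i in range(count):
            rid = f"{prefix}_{i + 1:03d}"
            seq, row = sample_protein(cls, rng, record_id=rid, index=i)
            fasta.append(FastaRecord(rid, seq, f"{rid} {row.organism} synthetic"))
            truth_rows.append(row)
    truth = pd.DataFrame(truth_rows)
    metadata = pd.DataFrame(
        {
            "id": truth["id"],
            "organism": truth["organism"],
            "genus": truth["genus"],
            "dataset": label,
            "subset_flag": truth["subset_flag"],
            "ec_number": truth["ec_number"],
        }
    )
    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / f"{label}.fasta",
            "metadata": out_dir / f"{label}.metadata.tsv",
            "truth": out_dir / f"{label}.truth.tsv",
        }
        write_fasta(fasta, paths["fasta"])
        write_metadata(metadata, paths["metadata"])
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return GeneratedData(label, fasta, metadata, truth, paths)


def generate_study_bundle(
    seed: int = 0, out_dir: str | Path | None = None
) -> dict[str, GeneratedData]:
    """All four architectures at the survey's dataset sizes (79/39/25/15
    core records, plus 5 ruminal and 5 proteobacterial outliers)."""
    root = np.random.SeedSequence(seed)
    bundles: dict[str, GeneratedData] = {}
    for child, label in zip(root.spawn(len(STUDY_N)), STUDY_N):
        bundles[label] = generate_dataset(
            label,
            STUDY_N[label],
            seed=np.random.default_rng(child),
            out_dir=out_dir,
            n_outliers=STUDY_N_OUTLIERS.get(label, 0),
        )
    return bundles


# ---------------------------------------------------------------------------
# Engineered sequon fixture

#: Observed sequon tallies per architecture in the real linker survey:
#: (N-X-S/T sequons, N-P motifs, total N, total P, total residues).
#: These are inputs to the engineered fixture below.
SEQUON_TALLIES = {
    "GH7_CBM1": (5, 68, 91, 334, 2361),
    "CBM1_GH6": (0, 5, 18, 275, 2170),
    "CBM2_GH6": (1, 5, 10, 316, 873),
    "GH6_CBM2": (1, 22, 31, 204, 1213),
}


def sequon_reference_set(label: str) -> LinkerSet:
    """Deterministic synthetic linker set reproducing a tally row exactly.

    Built from disjoint units — NAS (one sequon), NPA (one N-P), NAA
    (inert N), PA (extra P), A (padding) — whose junctions cannot create
    additional matches, so the aggregate counts equal the inputs by
    construction.
    """
    sequons, n_np, total_n, total_p, total_res = SEQUON_TALLIES[label]
    pad = total_res - 3 * total_n - 2 * (total_p - n_np)
    if pad < 0:
        raise ValueError(f"tallies for {label!r} are not representable")
    seq = (
        "NAS" * sequons
        + "NPA" * n_np
        + "NAA" * (total_n - sequons - n_np)
        + "PA" * (total_p - n_np)
        + "A" * pad
    )
    return LinkerSet(label=label, linkers=[LinkerRecord(f"{label}_sequon_ref", seq)])


def sequon_reference_sets() -> list[LinkerSet]:
    return [sequon_reference_set(label) for label in SEQUON_TALLIES]
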