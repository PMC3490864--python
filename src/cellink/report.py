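"""End-to-end orchestration: run every analysis stage and emit
machine-readable result tables.

The pipeline mirrors the survey's flow: assemble (or simulate) the four
architecture datasets, segment every record, exclude the flagged outlier
clades, then compute length statistics and pairwise t-tests, composition
and composition-versus-length trends, positional S/T, glycine and proline
profiles, sequon tallies, per-domain percent-identity distributions and
neighbor-joining trees.  One TSV/JSON artifact per result, plus a run
manifest recording the seed, configuration and any per-record failures.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignphylo import (
    IdentityMatrix,
    clade_separated,
    identity_matrix,
    make_aligner,
    nj_tree,
    subset_by_ec,
    write_newick,
)
from .composition import (
    aa_composition,
    composition_table,
    profile_table,
    sequon_table,
)
from .linkerstats import (
    LinkerSet,
    composition_vs_length,
    genus_overlap,
    length_histogram,
    length_report,
    length_stats,
    ttest_matrix,
)
from .segmentation import batch_segment, segment_dataset, write_segmentation_tsv
from .seqio import (
    Dataset,
    assemble_dataset,
    exclude_subset,
    read_fasta,
    read_metadata,
    write_fasta,
)
from .synthetic import (
    STUDY_N,
    STUDY_N_OUTLIERS,
    generate_dataset,
    sequon_reference_sets,
)

logger = logging.getLogger(__name__)

LABELS = tuple(STUDY_N)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are left in place."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "cellink_results"
    seed: int = 0
    input_dir: str | None = None       # load {label}.fasta/.metadata.tsv instead of simulating
    sizes: dict = field(default_factory=lambda: dict(STUDY_N))
    n_outliers: dict = field(default_factory=lambda: dict(STUDY_N_OUTLIERS))
    exclude_flags: tuple = ("ruminal_fungi", "proteobacteria")
    length_bin_width: int = 5
    n_bins: int = 11
    identity_bin_width: float = 5.0
    gap_open: float = 10.0
    gap_extend: float = 0.05
    identity_max_n: int | None = None  # cap records per dataset in identity stages
    welch: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.exclude_flags = tuple(cfg.exclude_flags)
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_datasets(input_dir: str | Path, labels: Sequence[str] = LABELS) -> dict[str, Dataset]:
    """Load per-architecture FASTA + metadata pairs from a directory."""
    input_dir = Path(input_dir)
    datasets = {}
    for label in labels:
        fasta = read_fasta(input_dir / f"{label}.fasta")
        meta = read_metadata(input_dir / f"{label}.metadata.tsv")
        datasets[label] = assemble_dataset(fasta, meta, label)
    return datasets


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON).

    Any stage failure raises :class:`StageError` naming the stage; files
    written by earlier stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "warnings": [],
        "stage_seconds": {},
    }
    stage = "assemble"
    t0 = time.perf_counter()
    try:
        if config.input_dir:
            datasets = load_datasets(config.input_dir)
        else:
            root = np.random.SeedSequence(config.seed)
            datasets = {}
            for child, label in zip(root.spawn(len(LABELS)), LABELS):
                bundle = generate_dataset(
                    label,
                    config.sizes[label],
                    seed=np.random.default_rng(child),
                    out_dir=out,
                    n_outliers=config.n_outliers.get(label, 0),
                )
                datasets[label] = bundle.to_dataset()
        _log_stage(manifest, stage, t0)

        stage = "segment"
        t0 = time.perf_counter()
        segmented = {}
        linkersets_all: dict[str, LinkerSet] = {}
        for label, ds in datasets.items():
            segs = segment_dataset(ds)
            segmented[label] = segs
            write_segmentation_tsv(segs, out / f"{label}.segments.tsv")
            lset, failures = batch_segment(ds)
            linkersets_all[label] = lset
            write_fasta([(l.id, l.seq) for l in lset if l.seq], out / f"{label}.linkers.fasta")
            for f in failures:
                manifest["warnings"].append(f"{label}: {f.record.id}: {f.reason}")
        summary["segmentation_failures"] = sum(
            1 for segs in segmented.values() for s in segs if not s.ok
        )
        _log_stage(manifest, stage, t0)

        stage = "exclude"
        t0 = time.perf_counter()
        core_datasets = {}
        core_linkers = {}
        for label, ds in datasets.items():
            core = ds
            for flag in config.exclude_flags:
                core = exclude_subset(core, flag)
            core_datasets[label] = core
            lset = linkersets_all[label]
            for flag in config.exclude_flags:
                lset = lset.exclude_subset(flag)
            core_linkers[label] = lset
            summary[f"n_core_{label}"] = lset.n
        _log_stage(manifest, stage, t0)

        stage = "length_stats"
        t0 = time.perf_counter()
        sets = [core_linkers[l] for l in LABELS]
        _write_tsv(length_report(sets), out / "linker_lengths.tsv")
        hist_rows = []
        for s in sets:
            for (lo, hi), count in length_histogram(s, config.length_bin_width).items():
                hist_rows.append({"label": s.label, "bin_lo": lo, "bin_hi": hi, "count": count})
        _write_tsv(pd.DataFrame(hist_rows), out / "length_histograms.tsv")
        _write_tsv(ttest_matrix(sets, welch=config.welch), out / "length_ttests.tsv", index=True)
        for s in sets:
            st = length_stats(s)
            summary[f"mean_length_{s.label}"] = st.average
            summary[f"median_length_{s.label}"] = st.median
            summary[f"sd_length_{s.label}"] = st.sd
        _log_stage(manifest, stage, t0)

        stage = "composition"
        t0 = time.perf_counter()
        _write_tsv(composition_table(sets), out / "composition.tsv", index=True)
        trend_rows = []
        for s in sets:
            for name, group in (("ST", "ST"), ("P", "P")):
                _, fit = composition_vs_length(s, group)
                trend_rows.append(
                    {"label": s.label, "group": name, "slope": fit.slope,
                     "intercept": fit.intercept, "r_squared": fit.r_squared}
                )
        _write_tsv(pd.DataFrame(trend_rows), out / "composition_trends.tsv")
        for s in sets:
            prof = aa_composition(s)
            summary[f"st_percent_{s.label}"] = 100 * prof.fraction("ST")
            summary[f"p_percent_{s.label}"] = 100 * prof.fraction("P")
            summary[f"s_percent_{s.label}"] = 100 * prof.fraction("S")
        _log_stage(manifest, stage, t0)

        stage = "profiles"
        t0 = time.perf_counter()
        for name, group in (("ST", "ST"), ("G", "G"), ("P", "P")):
            _write_tsv(
                profile_table(sets, group, n_bins=config.n_bins),
                out / f"profile_{name}.tsv",
                index=True,
            )
        _log_stage(manifest, stage, t0)

        stage = "sequons"
        t0 = time.perf_counter()
        _write_tsv(sequon_table(sets), out / "sequons.tsv")
        ref = sequon_table(sequon_reference_sets())
        _write_tsv(ref, out / "sequons_reference.tsv")
        combined = ref[ref["dataset"] == "combined"].iloc[0]
        summary["ref_sequons_total"] = int(combined["n_sequons"])
        summary["ref_np_total"] = int(combined["n_NP"])
        summary["ref_n_total"] = int(combined["total_N"])
        _log_stage(manifest, stage, t0)

        stage = "identity"
        t0 = time.perf_counter()
        aligner = make_aligner(gap_open=config.gap_open, gap_extend=config.gap_extend)
        cap = config.identity_max_n
        id_rows = []
        domain_matrices: dict[tuple[str, str], IdentityMatrix] = {}
        for label in LABELS:
            segs = [s for s in segmented[label] if s.ok][: cap or None]
            for domain in ("cbm", "linker", "gh"):
                mat = identity_matrix(
                    [s.record.id for s in segs], [getattr(s, domain) for s in segs], aligner
                )
                domain_matrices[(label, domain)] = mat
                pids = mat.pair_identities()
                id_rows.append(
                    {"label": label, "domain": domain, "n_pairs": len(pids),
                     "mean_identity": float(np.mean(pids)), "median_identity": float(np.median(pids))}
                )
                np.savetxt(
                    out / f"identity_{label}_{domain}.tsv",
                    mat.values, fmt="%.3f", delimiter="\t",
                    header="\t".join(mat.labels), comments="",
                )
        _write_tsv(pd.DataFrame(id_rows), out / "identity_summary.tsv")
        for label in LABELS:
            summary[f"linker_identity_{label}"] = next(
                r["mean_identity"] for r in id_rows if r["label"] == label and r["domain"] == "linker"
            )
            summary[f"gh_identity_{label}"] = next(
                r["mean_identity"] for r in id_rows if r["label"] == label and r["domain"] == "gh"
            )
        # GH7 exo/endo split by EC label: identity within subfamilies rises.
        exo, endo, _ = subset_by_ec(core_datasets["GH7_CBM1"])
        mat = domain_matrices[("GH7_CBM1", "gh")]
        idx = {lab: i for i, lab in enumerate(mat.labels)}
        for name, sub in (("exo", exo), ("endo", endo)):
            ids = [r.id for r in sub if r.id in idx]
            if len(ids) >= 2:
                take = np.array([idx[i] for i in ids])
                vals = mat.values[np.ix_(take, take)]
                summary[f"gh7_identity_{name}"] = float(
                    np.mean(vals[np.triu_indices(len(take), k=1)])
                )
        summary["gh7_identity_all"] = summary["gh_identity_GH7_CBM1"]
        _log_stage(manifest, stage, t0)

        stage = "trees"
        t0 = time.perf_counter()
        for label in ("CBM1_GH6", "CBM2_GH6"):
            ds = datasets[label]
            if len(ds) < 3:
                continue
            # no identity_max_n cap here: the outlier records sit at the end
            # of the dataset and the tree exists to place them
            recs = ds.records
            mat = identity_matrix([r.id for r in recs], [r.seq for r in recs], aligner)
            tree = nj_tree(mat)
            write_newick(tree, out / f"tree_{label}.nwk")
            outliers = [r.id for r in recs if r.subset_flag != "core"]
            if outliers and len(outliers) < len(recs):
                summary[f"outlier_clade_separated_{label}"] = bool(
                    clade_separated(tree, outliers)
                )
        _log_stage(manifest, stage, t0)

        stage = "genus_overlap"
        t0 = time.perf_counter()
        summary["genus_overlap_GH7_CBM1_in_CBM1_GH6"] = genus_overlap(
            core_datasets["GH7_CBM1"], core_datasets["CBM1_GH6"]
        )
        summary["genus_overlap_CBM1_GH6_in_GH7_CBM1"] = genus_overlap(
            core_datasets["CBM1_GH6"], core_datasets["GH7_CBM1"]
        )
        summary["genus_overlap_CBM2_GH6_in_GH6_CBM2"] = genus_overlap(
            core_datasets["CBM2_GH6"], core_datasets["GH6_CBM2"]
        )
        _log_stage(manifest, stage, t0)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with the stage name
        raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return summary


def _log_stage(manifest: dict, stage: str, t0: float) -> None:
    dt = time.perf_counter() - t0
    manifest["stage_seconds"][stage] = round(dt, 3)
    logger.info("stage %s finished in %.2fs", stage, dt)
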