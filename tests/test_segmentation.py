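import numpy as np
import pytest

from cellink.segmentation import (
    batch_segment,
    compile_motif,
    find_motif,
    segment_cbm1_gh6,
    segment_cbm2_gh6,
    segment_gh6_cbm2,
    segment_gh7_cbm1,
    segment_record,
    write_segmentation_tsv,
)
from cellink.seqio import Dataset, ProteinRecord
from cellink.synthetic import ARCHITECTURE, generate_dataset, sample_protein

# ---------------------------------------------------------------------------
# Motif matching


def test_find_motif_first_and_last():
    assert find_motif("AAQCGGAA", "QCGG") == 2
    two = "AAQCGGAAQCGGA"
    assert find_motif(two, "QCGG", pick="first") == 2
    assert find_motif(two, "QCGG", pick="last") == 8


def test_find_motif_degenerate_positions():
    assert find_motif("ATNIKA", "[ST][ND]IK") == 1
    assert find_motif("ASDIKA", "[ST][ND]IK") == 1
    assert find_motif("AANIKA", "[ST][ND]IK") is None


def test_find_motif_best_prefers_scored_wildcards():
    # two xQCx sites; only the second matches the preferred S...L flanks
    seq = "AAQCAAASQCLAA"
    assert find_motif(seq, "(S)QC(L)", pick="best") == 7
    # equal scores tie to the earliest match
    seq2 = "ASQCLAASQCLA"
    assert find_motif(seq2, "(S)QC(L)", pick="best") == 1


def test_find_motif_window_limits():
    seq = "AAQCGGAAQCGGA"
    assert find_motif(seq, "QCGG", start=4) == 8
    assert find_motif(seq, "QCGG", start=3, end=7) is None


def test_compile_motif_requires_fixed_position():
    with pytest.raises(ValueError):
        compile_motif("(S)(L)")
    with pytest.raises(ValueError):
        compile_motif("qcgg")


# ---------------------------------------------------------------------------
# Manual stub proteins per scheme (no generator involved)

CBM_BODY = "DTHAGDTHAGDTHAGDTHAG"  # no C/Q: cannot shadow the QC anchors
GH_BODY = "AGDTHAGDTHAGDTHAGDTHAGDTHAGDTH"


def make_cbm1_gh6(linker, signal="MRA"):
    seq = signal + "AGDATH" + "QCGG" + CBM_BODY + "SQCL" + linker + "AGDAT" + "GNPF" + GH_BODY
    return ProteinRecord(id="t", seq=seq, dataset="CBM1_GH6"), len(signal)


def test_cbm1_gh6_recovers_linker_and_trims_signal():
    rec, siglen = make_cbm1_gh6("TSTSPSTS")
    out = segment_cbm1_gh6(rec)
    assert out.ok
    assert out.trim == siglen
    assert out.linker == "TSTSPSTS"
    assert out.cbm == "AGDATH" + "QCGG" + CBM_BODY + "SQCL"
    assert out.gh == "AGDAT" + "GNPF" + GH_BODY
    assert out.cbm + out.linker + out.gh == rec.seq[out.trim :]


def test_cbm1_gh6_zero_length_linker_is_ok():
    rec, _ = make_cbm1_gh6("")
    out = segment_cbm1_gh6(rec)
    assert out.ok and out.linker == ""


def test_cbm1_gh6_missing_anchor_fails_without_partial_output():
    rec = ProteinRecord(id="t", seq="AGDTH" * 20, dataset="CBM1_GH6")
    out = segment_cbm1_gh6(rec)
    assert not out.ok
    assert out.reason == "no CBM1 anchor"
    assert out.cbm == out.linker == out.gh == ""


def test_gh7_cbm1_motif_variants_and_offsets():
    for motif in ("TNIK", "SDIK", "SNIK", "TDIK"):
        seq = GH_BODY + motif + "AGDTHAGDT" + "PSTSP" + "AGDATH" + "QCGG" + CBM_BODY
        rec = ProteinRecord(id="t", seq=seq, dataset="GH7_CBM1")
        out = segment_gh7_cbm1(rec)
        assert out.ok
        assert out.linker == "PSTSP"
        assert out.gh.endswith(motif + "AGDTHAGDT")
        assert out.cbm.startswith("AGDATH" + "QCGG")


def test_gh7_cbm1_cbm_anchor_must_be_downstream():
    # QCGG occurs only before the GH cut -> no CBM anchor
    seq = "QCGG" + GH_BODY + "TNIK" + "AGDTHAGDT" + "PSTSP" + CBM_BODY
    rec = ProteinRecord(id="t", seq=seq, dataset="GH7_CBM1")
    out = segment_gh7_cbm1(rec)
    assert not out.ok and out.reason == "no CBM1 anchor"


def test_cbm2_gh6_cuts_two_after_last_cysteine():
    body = "ADGHT" * 18  # 90 residues, no C
    seq = body + "C" + "TG" + "TSPTSPTSPTSPTSPT" + "RVDN" + GH_BODY
    rec = ProteinRecord(id="t", seq=seq, dataset="CBM2_GH6")
    out = segment_cbm2_gh6(rec)
    assert out.ok
    # CBM ends 2 residues after the Cys at index 90 (inclusive index 92)
    assert out.boundaries[0] == 93
    assert out.linker == "TSPTSPTSPTSPTSPT"
    assert out.gh.startswith("RVDN")


def test_cbm2_gh6_yvd_fallback_and_failures():
    body = "ADGHT" * 18
    seq = body + "C" + "TG" + "TSPTSPTSPT" + "YVDA" + GH_BODY
    out = segment_cbm2_gh6(ProteinRecord(id="t", seq=seq, dataset="CBM2_GH6"))
    assert out.ok and out.gh.startswith("YVD")
    no_cys = ProteinRecord(id="t", seq="ADGHT" * 30, dataset="CBM2_GH6")
    assert segment_cbm2_gh6(no_cys).reason == "no CBM2 anchor"
    no_gh = ProteinRecord(id="t", seq=body + "C" + "TGTSPTSPT" + "ADGHT", dataset="CBM2_GH6")
    assert segment_cbm2_gh6(no_gh).reason == "no GH6 anchor"


def test_gh6_cbm2_minimum_linker_guard():
    # an L inside the first min_linker residues of the linker must not fire
    linker = "TL" + "TSPTSPTSPTSP"  # L at linker position 1, length 14
    seq = GH_BODY + "FVML" + "AGDTHAGD" + linker + "C" + CBM_BODY
    out = segment_gh6_cbm2(ProteinRecord(id="t", seq=seq, dataset="GH6_CBM2"))
    assert out.ok
    assert out.linker == linker and len(out.linker) == 14
    assert out.cbm.startswith("C")
    missing = ProteinRecord(id="t", seq=GH_BODY + "AGDTH" * 10, dataset="GH6_CBM2")
    assert segment_gh6_cbm2(missing).reason == "no GH6 anchor"


# ---------------------------------------------------------------------------
# Generator round-trip


@pytest.mark.parametrize("cls", sorted(ARCHITECTURE))
def test_round_trip_exact_boundary_recovery(cls):
    """Segmentation recovers the generator's true boundaries exactly."""
    rng = np.random.default_rng(42)
    for i in range(40):
        seq, row = sample_protein(cls, rng, record_id=f"{cls}_{i}", index=i)
        rec = ProteinRecord(id=row.id, seq=seq, dataset=row.scheme)
        out = segment_record(rec)
        assert out.ok, (cls, i, out.reason)
        assert out.trim == row.trim
        assert out.boundaries == (row.cut1, row.cut2)
        assert out.linker == row.linker
        first = out.cbm if out.cbm_first else out.gh
        last = out.gh if out.cbm_first else out.cbm
        assert first + out.linker + last == rec.seq[out.trim :]


def test_segmentation_is_deterministic():
    rng = np.random.default_rng(7)
    seq, row = sample_protein("GH7_CBM1", rng)
    rec = ProteinRecord(id="d", seq=seq, dataset="GH7_CBM1")
    assert segment_record(rec) == segment_record(rec)


def test_batch_segment_collects_failures(small_bundle):
    bundle = small_bundle["CBM2_GH6"]
    ds = bundle.to_dataset()
    linkers, failures = batch_segment(ds)
    assert linkers.n == len(ds) and not failures
    # corrupt one record: strip every cysteine so the CBM anchor vanishes
    bad = ProteinRecord(id="corrupt", seq=ds.records[0].seq.replace("C", "A"), dataset="CBM2_GH6")
    ds2 = Dataset(label="CBM2_GH6", records=[bad] + ds.records[1:])
    linkers2, failures2 = batch_segment(ds2)
    assert linkers2.n == len(ds2) - 1
    assert [f.record.id for f in failures2] == ["corrupt"]


def test_batch_segment_empty_dataset():
    linkers, failures = batch_segment(Dataset(label="GH7_CBM1", records=[]))
    assert linkers.n == 0 and failures == []


def test_segmentation_tsv_is_one_based_inclusive(tmp_path, small_bundle):
    ds = small_bundle["GH7_CBM1"].to_dataset()
    from cellink.segmentation import segment_dataset

    segs = segment_dataset(ds)
    path = tmp_path / "seg.tsv"
    write_segmentation_tsv(segs, path)
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    row = dict(zip(header, lines[1].split("\t")))
    s = segs[0]
    assert int(row["gh_start"]) == 1
    assert int(row["gh_end"]) == s.boundaries[0]
    assert int(row["linker_start"]) == s.boundaries[0] + 1
    assert int(row["linker_end"]) == s.boundaries[1]
    assert int(row["cbm_end"]) == len(s.record.seq)
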