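import numpy as np
import pytest
from skbio import DistanceMatrix

from cellink.alignphylo import (
    IdentityMatrix,
    clade_separated,
    global_align,
    identity_histogram,
    identity_matrix,
    make_aligner,
    nj_tree,
    subset_by_ec,
)
from cellink.linkerstats import LinkerRecord, LinkerSet
from cellink.seqio import Dataset, ProteinRecord

from oracles import brute_force_alignment_score, random_additive_tree

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def aligner():
    return make_aligner()


def test_identical_sequences_align_perfectly(aligner):
    res = global_align("PEPTIDE", "PEPTIDE", aligner)
    assert res.percent_identity == 100.0
    assert "-" not in res.aligned_a + res.aligned_b
    assert res.identities == res.columns == 7


def test_internal_deletion_gives_one_gap_column(aligner):
    res = global_align("PEPT", "PET", aligner)
    assert res.identities == 3
    assert (res.aligned_a + res.aligned_b).count("-") == 1
    assert res.aligned_a.replace("-", "") == "PEPT"
    assert res.aligned_b.replace("-", "") == "PET"
    # brute-force path enumeration agrees on the optimal score
    oracle = brute_force_alignment_score("PEPT", "PET", aligner.substitution_matrix)
    assert res.score == pytest.approx(oracle)


def test_empty_sequence_is_error(aligner):
    with pytest.raises(ValueError):
        global_align("", "PEPT", aligner)


def test_score_symmetry_and_terminal_overhang_denominator(aligner):
    a, b = "MKTAYIAK", "TAYI"
    assert global_align(a, b, aligner).score == pytest.approx(global_align(b, a, aligner).score)
    res = global_align(a, b, aligner)
    # overhang columns are excluded: denominator is the spanned region only
    assert res.columns <= len(b) + 2


def test_alignment_score_matches_enumeration_oracle(aligner, rng):
    """Optimal affine-gap scores equal exhaustive path enumeration on
    random short pairs."""
    for _ in range(12):
        a = "".join(rng.choice(list(AA), size=int(rng.integers(2, 7))))
        b = "".join(rng.choice(list(AA), size=int(rng.integers(2, 7))))
        got = global_align(a, b, aligner).score
        expected = brute_force_alignment_score(a, b, aligner.substitution_matrix)
        assert got == pytest.approx(expected), (a, b)


def test_identity_matrix_shape_and_diagonal(aligner):
    mat = identity_matrix(["a", "b", "c"], ["PEPTIDE", "PEPTIDE", "MKTAYIA"], aligner)
    assert np.allclose(np.diag(mat.values), 100.0)
    assert np.allclose(mat.values, mat.values.T)
    assert mat.values[0, 1] == 100.0
    with pytest.raises(ValueError, match="duplicate"):
        identity_matrix(["a", "a"], ["PEPT", "PEPT"], aligner)


def test_identity_histogram_counts_and_top_bin(aligner):
    s = LinkerSet(
        label="GH7_CBM1",
        linkers=[LinkerRecord(f"l{i}", "PEPTIDE") for i in range(3)],
    )
    counts, mat = identity_histogram(s, aligner=aligner)
    assert counts == {(95.0, 100.0): 3}
    assert sum(counts.values()) == 3 * 2 // 2
    two = LinkerSet(label="GH7_CBM1", linkers=[LinkerRecord("a", "PEPT"), LinkerRecord("b", "MKTA")])
    counts2, _ = identity_histogram(two, aligner=aligner)
    assert sum(counts2.values()) == 1
    with pytest.raises(ValueError):
        identity_histogram(LinkerSet(label="GH7_CBM1", linkers=[LinkerRecord("a", "PEPT")]))


def test_identity_histogram_pair_count_formula(aligner, rng):
    n = 7
    s = LinkerSet(
        label="GH7_CBM1",
        linkers=[
            LinkerRecord(f"l{i}", "".join(rng.choice(list(AA), size=12))) for i in range(n)
        ],
    )
    counts, _ = identity_histogram(s, aligner=aligner)
    assert sum(counts.values()) == n * (n - 1) // 2


# ---------------------------------------------------------------------------
# EC subsetting


def _rec(i, ec):
    return ProteinRecord(id=f"r{i}", seq="PEPT", dataset="GH7_CBM1", ec_number=ec)


def test_subset_by_ec_splits_and_reports_unclassified():
    ds = Dataset(
        label="GH7_CBM1",
        records=[_rec(0, "3.2.1.91"), _rec(1, "3.2.1.4"), _rec(2, ""), _rec(3, "3.2.1.176")],
    )
    exo, endo, unclassified = subset_by_ec(ds)
    assert [r.id for r in exo] == ["r0", "r3"]
    assert [r.id for r in endo] == ["r1"]
    assert [r.id for r in unclassified] == ["r2"]


def test_subset_by_ec_without_metadata_everything_unclassified():
    ds = Dataset(label="GH7_CBM1", records=[_rec(0, ""), _rec(1, "")])
    exo, endo, unclassified = subset_by_ec(ds)
    assert len(exo) == len(endo) == 0 and len(unclassified) == 2


# ---------------------------------------------------------------------------
# Neighbor joining


def test_nj_three_taxa_closed_form():
    # distances: ab=3, ac=4, bc=5 -> leaf edges (ab+ac-bc)/2 etc.
    dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), ["a", "b", "c"])
    tree = nj_tree(dm)
    dist = tree.tip_tip_distances()
    assert dist["a", "b"] == pytest.approx(3)
    assert dist["a", "c"] == pytest.approx(4)
    assert dist["b", "c"] == pytest.approx(5)
    edge = {t.name: t.length for t in tree.tips()}
    assert edge["a"] == pytest.approx(1)


def test_nj_requires_three_labels():
    dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ["a", "b"])
    with pytest.raises(ValueError):
        nj_tree(dm)


def test_nj_recovers_four_taxon_additive_matrix_exactly():
    d = np.array(
        [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float
    )
    tree = nj_tree(DistanceMatrix(d, ["a", "b", "c", "d"]))
    dist = tree.tip_tip_distances(["a", "b", "c", "d"])
    assert np.allclose(dist.filter(["a", "b", "c", "d"]).data, d)


def test_nj_exact_on_random_additive_trees(rng):
    for _ in range(10):
        n = int(rng.integers(4, 9))
        labels, d = random_additive_tree(n, rng)
        tree = nj_tree(DistanceMatrix(d, labels))
        got = tree.tip_tip_distances(labels).filter(labels).data
        assert np.allclose(got, d, atol=1e-8)


def test_nj_from_identity_matrix_and_newick(tmp_path):
    values = np.full((4, 4), 30.0)
    np.fill_diagonal(values, 100.0)
    values[0, 1] = values[1, 0] = 90.0
    values[2, 3] = values[3, 2] = 85.0
    mat = IdentityMatrix(labels=("a", "b", "c", "d"), values=values)
    tree = nj_tree(mat)
    assert {t.name for t in tree.tips()} == {"a", "b", "c", "d"}
    assert all((t.length or 0) >= 0 for t in tree.traverse())
    out = tmp_path / "t.nwk"
    tree.write(str(out), format="newick")
    assert out.read_text().strip().endswith(";")


def test_outlier_clade_detection():
    # 8 taxa: 3 outliers mutually close, far from the 5 core taxa
    n, outliers = 8, ["o0", "o1", "o2"]
    labels = outliers + [f"c{i}" for i in range(n - 3)]
    d = np.full((n, n), 60.0)
    d[:3, :3] = 5.0
    d[3:, 3:] = 10.0
    np.fill_diagonal(d, 0.0)
    tree = nj_tree(DistanceMatrix(d, labels))
    assert clade_separated(tree, outliers)
    assert not clade_separated(tree, ["o0", "c0"])
    with pytest.raises(ValueError):
        clade_separated(tree, labels)
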