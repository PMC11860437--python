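import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import brute_force_scores, make_matrix_from_array
from nanovax.cleavage import (
    MatrixFormatError,
    SequenceTooShortError,
    SpecificityMatrix,
    enumerate_fragments,
    epitope_release_check,
    motif_preference_report,
    predict_cleavage,
    read_matrix,
    score_windows,
    select_top_sites,
    write_matrix,
)
from nanovax.constructs import AMINO_ACIDS, parse_construct

peptides = st.text(alphabet=AMINO_ACIDS, min_size=8, max_size=40)
matrices = arrays(float, (8, 20), elements=st.floats(-5, 5, allow_nan=False)).map(
    make_matrix_from_array
)


def k_only_matrix(score=1.0):
    arr = np.zeros((8, 20))
    arr[:, AMINO_ACIDS.index("K")] = score
    return make_matrix_from_array(arr)


class TestMatrixIO:
    def test_round_trip(self, tmp_path, cathb_matrix):
        path = tmp_path / "m.tsv"
        write_matrix(cathb_matrix, path)
        again = read_matrix(path, protease=cathb_matrix.protease)
        assert np.allclose(again.scores.to_numpy(), cathb_matrix.scores.to_numpy())

    def test_zero_matrix_scores_zero_everywhere(self, zero_matrix):
        sites = score_windows("CALNNKKPKYVKQNTLKLAT", zero_matrix)
        assert all(s.score == 0.0 for s in sites)

    def test_missing_subsite_row_is_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        df = k_only_matrix().scores.drop(index="P2'")
        df.to_csv(path, sep="\t", index_label="subsite")
        with pytest.raises(MatrixFormatError, match="P2'"):
            read_matrix(path)

    def test_unknown_residue_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        df = k_only_matrix().scores.rename(columns={"A": "B"})
        df.to_csv(path, sep="\t", index_label="subsite")
        with pytest.raises(MatrixFormatError, match="B"):
            read_matrix(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        df = k_only_matrix().scores.astype(object)
        df.iloc[0, 0] = "high"
        df.to_csv(path, sep="\t", index_label="subsite")
        with pytest.raises(MatrixFormatError):
            read_matrix(path)

    def test_fixture_loads_with_protease_name(self, cathb_matrix):
        assert cathb_matrix.protease == "cathepsin B"
        assert "synthetic" in cathb_matrix.provenance.lower()


class TestScoring:
    def test_hand_summed_lysine_windows(self):
        # 10-mer KKKKAAAAKK, K scores 1 at every subsite
        sites = {s.bond: s.score for s in score_windows("KKKKAAAAKK", k_only_matrix())}
        assert sites[4] == 4.0  # residues 1..8 = KKKKAAAA
        assert sites[5] == 4.0  # residues 2..9 = KKKAAAAK
        assert sites[6] == 4.0  # residues 3..10 = KKAAAAKK

    def test_too_short_sequence(self, zero_matrix):
        with pytest.raises(SequenceTooShortError, match="too short"):
            score_windows("KKKKAAA", zero_matrix)

    def test_tie_break_by_ascending_bond(self, zero_matrix):
        sites = score_windows("A" * 12, zero_matrix)
        assert [s.bond for s in sites] == list(range(4, 9))
        assert [s.rank for s in sites] == [1, 2, 3, 4, 5]

    @given(seq=peptides, matrix=matrices)
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force_oracle(self, seq, matrix):
        expected = brute_force_scores(seq, matrix)
        got = {s.bond: s.score for s in score_windows(seq, matrix)}
        assert got.keys() == expected.keys()
        for bond in expected:
            assert got[bond] == pytest.approx(expected[bond], abs=1e-9)

    @given(seq=peptides)
    @settings(max_examples=50, derandomize=True)
    def test_shift_property(self, seq):
        # position-independent matrix: every subsite shares one residue profile
        rng = np.random.default_rng(7)
        profile = rng.normal(size=20)
        matrix = make_matrix_from_array(np.tile(profile, (8, 1)))
        base = {s.bond: s.score for s in score_windows(seq, matrix)}
        shifted = {s.bond: s.score for s in score_windows("AAAA" + seq, matrix)}
        for bond, score in base.items():
            assert shifted[bond + 4] == pytest.approx(score, abs=1e-9)

    def test_padding_option_scores_all_bonds(self, zero_matrix):
        sites = score_windows("A" * 10, zero_matrix, pad_score=0.0)
        assert sorted(s.bond for s in sites) == list(range(1, 10))

    @given(
        seq=peptides,
        matrix=arrays(float, (8, 20), elements=st.integers(-5, 5).map(float)).map(
            make_matrix_from_array
        ),
    )
    @settings(max_examples=30, derandomize=True)
    def test_p1_monotonicity(self, seq, matrix):
        # raising the P1 score of residue r never lowers the rank of a bond
        # whose P1 residue is r; integer scores keep the arithmetic exact so
        # ties are genuine ties
        sites = score_windows(seq, matrix)
        r = seq[sites[0].bond - 1]  # P1 residue of some bond
        bumped_arr = matrix.scores.to_numpy().copy()
        bumped_arr[3, AMINO_ACIDS.index(r)] += 2.0
        bumped = make_matrix_from_array(bumped_arr)
        before = {s.bond: s.rank for s in sites}
        after = {s.bond: s.rank for s in score_windows(seq, bumped)}
        for bond in before:
            if seq[bond - 1] == r:
                assert after[bond] <= before[bond]


class TestFragments:
    def test_p1_fragment_set(self, study):
        sites = [s for s in _sites_at(study["p1"], (5, 9, 15))]
        report = enumerate_fragments(study["p1"], sites)
        assert {f.sequence for f in report.fragments} == {
            "CALNN", "KKPKYVKQNTLKLAT", "CALNNKKPK", "YVKQNTLKLAT",
            "CALNNKKPKYVKQNT", "LKLAT",
        }

    def test_p2_fragment_set(self, study):
        sites = [s for s in _sites_at(study["p2"], (9, 15, 17))]
        report = enumerate_fragments(study["p2"], sites)
        assert {f.sequence for f in report.fragments} == {
            "CALNNKKPK", "YVKQNTLKLATRKKRQRRR", "CALNNKKPKYVKQNT",
            "LKLATRKKRQRRR", "CALNNKKPKYVKQNTLK", "LATRKKRQRRR",
        }

    def test_no_sites_no_fragments(self, study):
        report = enumerate_fragments(study["p1"], [])
        assert report.fragments == []

    def test_order_and_sides(self, study):
        report = enumerate_fragments(study["p1"], list(_sites_at(study["p1"], (9, 5))))
        # rank order, N-side before C-side
        assert [f.sequence for f in report.fragments][:2] == [
            "CALNNKKPK", "YVKQNTLKLAT",
        ]

    @given(seq=peptides, matrix=matrices)
    @settings(max_examples=50, derandomize=True)
    def test_fragment_conservation(self, seq, matrix):
        construct = parse_construct("x", seq)
        report = predict_cleavage(construct, matrix, k=3)
        by_bond = {}
        for f in report.fragments:
            by_bond.setdefault(f.bond, []).append(f)
        for site in report.selected:
            n_side = seq[: site.bond]
            c_side = seq[site.bond :]
            assert n_side + c_side == seq
            # each emitted fragment equals the parent slice it claims
        for f in report.fragments:
            assert seq[f.start - 1 : f.end] == f.sequence

    def test_deduplication_keeps_first(self):
        # same bond listed twice: each side emitted once
        construct = parse_construct("x", "CALNNAAAAAA")
        report = enumerate_fragments(construct, list(_sites_at(construct, (5, 5))))
        assert [f.sequence for f in report.fragments] == ["CALNN", "AAAAAA"]

    def test_identical_halves_collapse(self):
        # a palindromic cut yields one unique fragment sequence
        construct = parse_construct("x", "AAAAAAAAAAAA")
        report = enumerate_fragments(construct, list(_sites_at(construct, (6,))))
        assert [f.sequence for f in report.fragments] == ["AAAAAA"]


class TestSelectionAndRelease:
    def test_top_k_and_k_exceeding_n(self, zero_matrix):
        sites = score_windows("A" * 12, zero_matrix)  # 5 sites
        assert [s.rank for s in select_top_sites(sites, 3)] == [1, 2, 3]
        assert len(select_top_sites(sites, 99)) == 5

    def test_release_true_via_fragment(self, study):
        report = enumerate_fragments(study["p1"], list(_sites_at(study["p1"], (9,))))
        assert epitope_release_check(report, "YVKQNTLKL") is True
        assert report.epitope_released is True

    def test_release_false_and_empty(self, study):
        report = enumerate_fragments(study["p1"], list(_sites_at(study["p1"], (5,))))
        report.fragments = [f for f in report.fragments if f.sequence == "CALNN"]
        assert epitope_release_check(report, "YVKQNTLKL") is False
        report.fragments = []
        assert epitope_release_check(report, "YVKQNTLKL") is False


class TestMotifPreference:
    def test_no_regions_empty_mapping(self, zero_matrix):
        construct = parse_construct("x", "WWWWWWWWWWWW")
        assert motif_preference_report(construct, score_windows(construct, zero_matrix)) == {}

    def test_single_region_gets_best_overall_rank(self, zero_matrix):
        construct = parse_construct("x", "CALNNCALNN")  # two anchors tile it
        sites = score_windows(construct, zero_matrix)
        report = motif_preference_report(construct, sites)
        assert report == {"anchor": 1}

    def test_overlap_matches_brute_force(self, study, cathb_matrix):
        construct = study["p1"]
        sites = score_windows(construct, cathb_matrix)
        report = motif_preference_report(construct, sites)
        # p1 has exactly one region per kind, so the mapping is the plain min
        for region in construct.regions:
            ranks = [
                s.rank for s in sites if region.start - 1 <= s.bond <= region.end
            ]
            assert report[region.kind] == (min(ranks) if ranks else None)


def _sites_at(construct, bonds):
    """Manufacture CleavageSite objects at given bonds (rank = list order)."""
    from nanovax.cleavage import CleavageSite

    for i, bond in enumerate(bonds):
        window = construct.sequence[max(bond - 4, 0) : bond + 4]
        yield CleavageSite(bond=bond, window=window, score=0.0, rank=i + 1)
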