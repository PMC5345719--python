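"""ABH encoding, imputation, the two correction passes, and merging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from f2gbs.abh import (CorrectionParams, correct_short_stretches,
                       correct_undercalled_het, encode_abh,
                       impute_flanked_missing, merge_populations, postprocess,
                       _het_correct_row, _impute_row, _stretch_correct_row)
from f2gbs.model import ValidationError

from conftest import (abh_from_rows, oracle_het_correct, oracle_impute,
                      oracle_stretch_correct, site_matrix_from_calls)


def _row(s):
    return np.array(list(s), dtype="U1")


def _str(arr):
    return "".join(arr)


class TestEncode:
    def test_code_assignment_from_consensus(self):
        m = site_matrix_from_calls(
            [["GG", "TT", "GG", "GT", "TT", "NN", "GC"]],
            ["parent1_rep", "parent2_rep", "f2", "f2", "f2", "f2", "f2"])
        from f2gbs.filtering import filter_parental_consistency
        m = filter_parental_consistency(m)
        g = encode_abh(m)
        assert g.codes.tolist() == [["A"], ["H"], ["B"], ["N"], ["N"]]

    def test_off_parent_allele_becomes_missing_not_error(self):
        m = site_matrix_from_calls([["GG", "TT", "CC"]],
                                   ["parent1_rep", "parent2_rep", "f2"])
        m.parent1_allele = np.array(["G"])
        m.parent2_allele = np.array(["T"])
        assert encode_abh(m).codes[0, 0] == "N"

    def test_all_parental_matrix_has_no_missing(self):
        m = site_matrix_from_calls(
            [["GG", "TT", "GG", "GT", "TT"]] * 3,
            ["parent1_rep", "parent2_rep", "f2", "f2", "f2"],
            positions=[10, 200, 400])
        m.parent1_allele = np.array(["G"] * 3)
        m.parent2_allele = np.array(["T"] * 3)
        assert not np.any(encode_abh(m).codes == "N")

    def test_missing_consensus_is_error(self):
        m = site_matrix_from_calls([["GG"]], ["f2"])
        with pytest.raises(ValidationError):
            encode_abh(m)


class TestImpute:
    @pytest.mark.parametrize("before,after", [
        ("ANNNA", "AAAAA"),
        ("ANNB", "ANNB"),          # conflicting flanks untouched
        ("NNA", "NNA"),            # no left flank at chromosome start
        ("ANN", "ANN"),            # no right flank
        ("HNH", "HHH"),
        ("ANNNNNNNNNA", "AAAAAAAAAAA"),  # length unrestricted
    ])
    def test_flank_rule(self, before, after):
        assert _str(_impute_row(_row(before))) == after

    def test_never_alters_called_genotypes(self, rng):
        for _ in range(200):
            s = "".join(rng.choice(list("ABHN"), 30))
            out = _str(_impute_row(_row(s)))
            for a, b in zip(s, out):
                if a != "N":
                    assert a == b

    def test_chromosome_isolation(self):
        g = abh_from_rows(["ANNA"], chromosomes=["1", "1", "2", "2"])
        out = impute_flanked_missing(g)
        # the N at the end of chr1 and start of chr2 have no within-chromosome
        # flank pair, so nothing is imputed across the boundary
        assert _str(out.codes[0]) == "ANNA"


class TestHetCorrect:
    @pytest.mark.parametrize("before,after", [
        ("HAAAAH", "HHHHHH"),      # run of 4 replaced
        ("HAAAAAH", "HAAAAAH"),    # run of 5 exceeds the threshold
        ("HANBH", "HHHHH"),        # mixed A/N/B run still qualifies
        ("AAAH", "AAAH"),          # no left H flank
        ("HBH", "HHH"),
    ])
    def test_run_rule(self, before, after):
        assert _str(_het_correct_row(_row(before), 4)) == after

    def test_threshold_is_parameter(self):
        assert _str(_het_correct_row(_row("HAAAAAH"), 5)) == "HHHHHHH"


class TestStretchCorrect:
    @pytest.mark.parametrize("before,after", [
        ("ABA", "AAA"),
        ("AHA", "AAA"),            # the dominant real-data error motif
        ("ABBA", "ABBA"),          # run of 2 exceeds threshold 1
        ("HNH", "HHH"),            # N singleton replaced by called flank
        ("NAN", "NAN"),            # N flanks never overwrite a call
        ("BAB", "BBB"),
    ])
    def test_single_site_rule(self, before, after):
        assert _str(_stretch_correct_row(_row(before), 1)) == after

    def test_never_produces_missing(self, rng):
        for _ in range(300):
            s = "".join(rng.choice(list("ABHN"), 20))
            out = _str(_stretch_correct_row(_row(s), 1))
            for a, b in zip(s, out):
                if a != "N":
                    assert b != "N"


class TestOracleEquivalence:
    """All passes match the naive per-cell oracles."""

    def test_exhaustive_short_strings(self):
        for n in range(1, 8):
            for tup in itertools.product("ABHN", repeat=n):
                s = "".join(tup)
                r = _row(s)
                assert _str(_impute_row(r)) == oracle_impute(s)
                assert _str(_het_correct_row(r, 4)) == oracle_het_correct(s, 4)
                assert _str(_stretch_correct_row(r, 1)) == oracle_stretch_correct(s, 1)

    @settings(max_examples=300, deadline=None)
    @given(st.text(alphabet="ABHN", min_size=1, max_size=40))
    def test_random_longer_strings(self, s):
        r = _row(s)
        assert _str(_impute_row(r)) == oracle_impute(s)
        assert _str(_het_correct_row(r, 4)) == oracle_het_correct(s, 4)
        assert _str(_stretch_correct_row(r, 1)) == oracle_stretch_correct(s, 1)


class TestPostprocess:
    def test_worked_example(self):
        g = abh_from_rows(["AANAHAHHBNB"])
        out, stats = postprocess(g)
        assert _str(out.codes[0]) == "AAAAHHHHBBB"

    def test_near_identity_on_clean_dense_data(self):
        # at dense marker spacing (~0.4 cM) a genuine homozygous excursion
        # of <= 4 markers between heterozygous stretches needs two
        # crossovers within ~2 cM, so the passes leave clean data alone
        from f2gbs.simulate import F2SimConfig, sim_f2, sim_map
        cfg = F2SimConfig(chr_lengths_cM=(40.0, 40.0), n_individuals=30,
                          n_markers=200, seed=7)
        g, _, _ = sim_f2(sim_map(cfg), cfg)
        out, stats = postprocess(g)
        assert np.mean(out.codes != g.codes) < 0.002
        assert stats.cells_imputed == 0

    def test_missing_fraction_never_increases(self, rng):
        for seed in range(30):
            r = np.random.default_rng(seed)
            rows = ["".join(r.choice(list("ABHN"), 40, p=[.24, .24, .47, .05]))
                    for _ in range(5)]
            g = abh_from_rows(rows)
            out, _ = postprocess(g)
            assert np.sum(out.codes == "N") <= np.sum(g.codes == "N")

    def test_impute_and_het_passes_idempotent_on_own_output(self, rng):
        # the stretch pass is deliberately single-sweep (runs computed from
        # its input), so a second sweep may find singletons its own
        # replacements created; the other two passes are fixed points
        for _ in range(50):
            s = "".join(rng.choice(list("ABHN"), 25))
            g = abh_from_rows([s])
            g1 = impute_flanked_missing(g)
            assert np.array_equal(impute_flanked_missing(g1).codes, g1.codes)
            g2 = correct_undercalled_het(g)
            assert np.array_equal(correct_undercalled_het(g2).codes, g2.codes)

    def test_second_full_run_changes_no_more_than_first(self, rng):
        for _ in range(30):
            s = "".join(rng.choice(list("ABHN"), 40))
            g = abh_from_rows([s])
            g1, _ = postprocess(g)
            g2, _ = postprocess(g1)
            assert np.sum(g2.codes != g1.codes) <= np.sum(g1.codes != g.codes)

    def test_chromosomes_do_not_interact(self, rng):
        # processing two chromosomes together equals processing separately
        for _ in range(20):
            s1 = "".join(rng.choice(list("ABHN"), 12))
            s2 = "".join(rng.choice(list("ABHN"), 12))
            joint = abh_from_rows([s1 + s2],
                                  chromosomes=["1"] * 12 + ["2"] * 12)
            out_joint, _ = postprocess(joint)
            out1, _ = postprocess(abh_from_rows([s1]))
            out2, _ = postprocess(abh_from_rows([s2]))
            assert _str(out_joint.codes[0]) == _str(out1.codes[0]) + _str(out2.codes[0])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CorrectionParams(het_run_max=0)


class TestMerge:
    def _two_pops(self):
        g1 = abh_from_rows(["AA", "BB"], positions=[100_000, 300_000])
        g2 = abh_from_rows(["HH", "AB"], positions=[200_000, 400_000])
        g2.individuals = ["x1", "x2"]
        g2.marker_ids = ["k0", "k1"]
        return g1, g2

    def test_union_structure_with_missing_at_unassayed(self):
        g1, g2 = self._two_pops()
        merged = merge_populations(g1, g2, reimpute=False)
        assert merged.n_individuals == 4 and merged.n_markers == 4
        assert merged.positions.tolist() == [100_000, 200_000, 300_000, 400_000]
        # individual from g1 has N at g2-only markers
        assert merged.codes[0].tolist() == ["A", "N", "A", "N"]
        assert merged.codes[2].tolist() == ["N", "H", "N", "H"]

    def test_reimputation_fills_flanked_cells(self):
        g1, g2 = self._two_pops()
        merged = merge_populations(g1, g2)
        # A at 100k and A at 300k -> imputed A at 200k
        assert merged.codes[0, 1] == "A"
        # B..B likewise
        assert merged.codes[1, 1] == "B"
        # conflicting flanks stay N: x2 has A at 200k? x2 row is N A N B
        assert merged.codes[3, 0] == "N"

    def test_conflicting_flanks_remain_missing(self):
        g1 = abh_from_rows(["AB"], positions=[100_000, 300_000])
        g2 = abh_from_rows(["H"], positions=[200_000])
        g2.individuals = ["y1"]
        g2.marker_ids = ["k0"]
        merged = merge_populations(g1, g2)
        assert merged.codes[0].tolist() == ["A", "N", "B"]

    def test_shared_individuals_rejected(self):
        g1 = abh_from_rows(["A"])
        g2 = abh_from_rows(["B"], positions=[5000])
        g2.marker_ids = ["k0"]
        with pytest.raises(ValidationError, match="share individuals"):
            merge_populations(g1, g2)

    def test_conflicting_marker_ids_at_same_position_rejected(self):
        g1 = abh_from_rows(["A"], positions=[100])
        g2 = abh_from_rows(["B"], positions=[100])
        g2.individuals = ["z1"]
        g2.marker_ids = ["other"]
        with pytest.raises(ValidationError, match="conflicting"):
            merge_populations(g1, g2)
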