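"""Nearest-neighbor prediction, table symmetry, trinucleotide decomposition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duplextherm import (
    ThermoParams,
    UnsupportedAlphabetError,
    nn_predict,
    nn_trinucleotide,
    trinucleotide_core_from_measured,
    validate_duplex,
)
from duplextherm.nn import DEFAULT_NN_TABLE
from duplextherm.nn_tables import _GT_STEPS, _WC_STEPS, _flip
from duplextherm.reference import MINUS_DG37_1M_NA, VARIANTS, XY_POSITION, variant_strands

WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def complement(seq: str) -> str:
    """Bottom strand 5'->3' of a Watson-Crick duplex."""
    return "".join(WC[b] for b in reversed(seq))


def hand_sum(top: str, bottom: str) -> ThermoParams:
    """Brute-force oracle: walk the duplex, summing table entries directly."""
    n = len(top)
    aligned_bottom = bottom[::-1]  # 3'->5' under the top strand
    total_dh, total_ds = 0.0, 0.0
    for terminal in (0, n - 1):
        pair = {top[terminal], aligned_bottom[terminal]}
        key = "G·C" if pair == {"G", "C"} else "A·T"
        init = DEFAULT_NN_TABLE.initiation[key]
        total_dh += init.dH
        total_ds += init.dS
    for i in range(n - 1):
        step = DEFAULT_NN_TABLE.steps[f"{top[i:i+2]}/{aligned_bottom[i:i+2]}"]
        total_dh += step.dH
        total_ds += step.dS
    return ThermoParams(dH=total_dh, dS=total_ds)


class TestValidateDuplex:
    def test_study_13mer_all_variants(self):
        for variant in VARIANTS:
            top, bottom = variant_strands(variant)
            duplex = validate_duplex(top, bottom)
            assert duplex.pair_labels[XY_POSITION] == variant
            assert len(duplex) == 13

    def test_gc_variant_pair_position(self):
        duplex = validate_duplex("TTTGTATCGCAAT", "ATTGCGATACAAA")
        assert duplex.pairs[8] == ("G", "C")  # 1-based position 9

    def test_identical_short_strands_rejected(self):
        # 5'-AT-3'/5'-AT-3' pairs antiparallel but is self-complementary,
        # which is the unsupported unimolecular-Tm molecularity
        with pytest.raises(ValueError, match="self-complementary"):
            validate_duplex("AT", "AT")

    def test_parallel_orientation_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            validate_duplex("AAG", "TTC")  # complement given 3'->5'

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            validate_duplex("AAA", "TTTT")

    def test_unrecognized_pair_rejected(self):
        with pytest.raises(ValueError, match="I·G"):
            validate_duplex("AIA", "TGT")  # I·G is not a recognized pair

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError, match="unrecognized bases"):
            validate_duplex("ANA", "TNT")


class TestTableSymmetry:
    @pytest.mark.parametrize("key", sorted(list(_WC_STEPS) + list(_GT_STEPS)))
    def test_step_equals_reverse_complement_spelling(self, key):
        table = DEFAULT_NN_TABLE.steps
        assert table[key] == table[_flip(key)]

    def test_all_ten_wc_and_eleven_gt_steps_present(self):
        assert len(_WC_STEPS) == 10 and len(_GT_STEPS) == 11
        # every spelled form resolvable
        assert len(DEFAULT_NN_TABLE.steps) >= 16 + 22 - 6  # palindromic keys collapse


class TestNNPredict:
    def test_13mer_matches_hand_summation(self):
        for variant in ("G·C", "A·T", "G·T"):
            top, bottom = variant_strands(variant)
            predicted = nn_predict(validate_duplex(top, bottom))
            oracle = hand_sum(top, bottom)
            assert predicted.dH == pytest.approx(oracle.dH, abs=1e-12)
            assert predicted.dS == pytest.approx(oracle.dS, abs=1e-12)

    def test_single_pair_is_initiation_only(self):
        p = nn_predict(validate_duplex("G", "C"))
        init = DEFAULT_NN_TABLE.initiation["G·C"]
        assert p.dH == pytest.approx(2 * init.dH) and p.dS == pytest.approx(2 * init.dS)

    @given(
        st.text(alphabet="ACGT", min_size=2, max_size=12).filter(
            lambda s: s != complement(s)
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_strand_swap_invariance(self, top):
        bottom = complement(top)
        a = nn_predict(validate_duplex(top, bottom))
        b = nn_predict(validate_duplex(bottom, top))
        assert a.dH == pytest.approx(b.dH, abs=1e-12)
        assert a.dS == pytest.approx(b.dS, abs=1e-12)

    def test_inosine_and_diaminopurine_rejected(self):
        for variant in ("I·C", "D·T", "I·T"):
            top, bottom = variant_strands(variant)
            with pytest.raises(UnsupportedAlphabetError):
                nn_predict(validate_duplex(top, bottom))

    def test_terminal_mismatch_rejected(self):
        with pytest.raises(UnsupportedAlphabetError, match="terminal"):
            nn_predict(validate_duplex("TACG", "CGTG"))  # 5'-terminal G·T

    def test_two_wobbles_rejected(self):
        # pairs: A·T, G·T, C·G, G·C, T·G, A·T — two internal wobbles
        with pytest.raises(UnsupportedAlphabetError, match="at most one"):
            nn_predict(validate_duplex("AGCGTA", "TGCGTT"))

    def test_self_complementary_rejected(self):
        with pytest.raises(ValueError, match="self-complementary"):
            nn_predict(validate_duplex("GCATGC", "GCATGC"))


class TestTrinucleotide:
    def test_wobble_core_cgc_gtg(self):
        p = nn_trinucleotide("CGC", "GTG")
        assert p.dH == pytest.approx(-8.5, abs=1e-12)
        assert p.dS == pytest.approx(-24.0, abs=1e-12)
        assert p.dG37 == pytest.approx(-1.0564, abs=5e-4)

    def test_reverse_complement_spelling_identical(self):
        a = nn_trinucleotide("CGC", "GTG")
        b = nn_trinucleotide("GTG", "CGC")
        assert a.dH == b.dH and a.dS == b.dS

    def test_equals_duplex_difference(self):
        # additivity: tri = predict(whole) − predict(whole minus central steps)
        top, bottom = variant_strands("G·T")
        duplex = validate_duplex(top, bottom)
        whole = nn_predict(validate_duplex(*variant_strands("G·T")))
        core = trinucleotide_core_from_measured(whole, duplex, XY_POSITION)
        tri = nn_trinucleotide(
            top[XY_POSITION - 1 : XY_POSITION + 2],
            bottom[12 - XY_POSITION - 1 : 12 - XY_POSITION + 2],
        )
        assert core.dH == pytest.approx(tri.dH, abs=1e-9)
        assert core.dS == pytest.approx(tri.dS, abs=1e-9)

    def test_non_wc_flank_rejected(self):
        with pytest.raises(UnsupportedAlphabetError, match="Watson-Crick"):
            nn_trinucleotide("TGC", "GTG")  # T·G flank

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="trinucleotide"):
            nn_trinucleotide("CGCA", "TGTG")


class TestTrinucleotideCoreFromMeasured:
    def test_perturbation_passes_through_linearly(self):
        top, bottom = variant_strands("G·T")
        duplex = validate_duplex(top, bottom)
        base = nn_predict(duplex)
        shifted = ThermoParams(dH=base.dH, dS=base.dS - (0.5 * 1000.0 / 310.15))
        core0 = trinucleotide_core_from_measured(base, duplex, XY_POSITION)
        core1 = trinucleotide_core_from_measured(shifted, duplex, XY_POSITION)
        assert core1.dG37 - core0.dG37 == pytest.approx(0.5, abs=1e-9)

    def test_works_for_unparameterized_central_pair(self):
        # I·T center: core extraction never looks the central steps up
        top, bottom = variant_strands("I·T")
        duplex = validate_duplex(top, bottom)
        measured = ThermoParams.from_dh_dg37(-85.0, -8.83)
        core = trinucleotide_core_from_measured(measured, duplex, XY_POSITION)
        assert core.dG37 == pytest.approx(
            measured.dG37
            - (nn_predict(validate_duplex(*variant_strands("G·C"))).dG37
               - nn_trinucleotide("CGC", "GCG").dG37),
            abs=1e-9,
        )

    def test_core_ordering_matches_duplex_stability_ordering(self):
        # identical flanking subtraction across the six variants preserves order
        cores = []
        for variant in VARIANTS:
            top, bottom = variant_strands(variant)
            duplex = validate_duplex(top, bottom)
            measured = ThermoParams.from_dh_dg37(-92.0, -MINUS_DG37_1M_NA[variant])
            cores.append(-trinucleotide_core_from_measured(measured, duplex, XY_POSITION).dG37)
        assert cores == sorted(cores, reverse=True)
        assert cores[1] == pytest.approx(cores[2], abs=1e-9)  # D·T ≈ I·C tie

    def test_non_central_mismatch_rejected(self):
        top, bottom = variant_strands("G·T")
        duplex = validate_duplex(top, bottom)
        with pytest.raises(UnsupportedAlphabetError, match="non-central"):
            trinucleotide_core_from_measured(ThermoParams(-90.0, -250.0), duplex, 5)

    def test_terminal_center_rejected(self):
        duplex = validate_duplex("TTTGTATCGCAAT", "ATTGCGATACAAA")
        with pytest.raises(ValueError, match="interior"):
            trinucleotide_core_from_measured(ThermoParams(-90.0, -250.0), duplex, 0)
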