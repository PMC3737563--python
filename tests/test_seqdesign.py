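"""Unit and property tests for oligomer panel design and mass utilities."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    FRAGMENT_LENGTH,
    O3204_FOOTPRINT,
    O3204_START,
    O3205_FOOTPRINT,
    O3205_START,
    SITE_LENGTH,
    random_dna,
)
from sprmap.errors import AlphabetError, DesignError, ParameterError
from sprmap.seqdesign import (
    LinkerSpec,
    OligoDuplex,
    apply_footprint,
    attach_linker,
    chip_budget,
    dna_mw,
    make_substitution_panel,
    make_truncation_series,
    protein_mw,
    revcomp,
    strand_mw,
    strip_linker,
    tile_region,
    translate,
)

dna_strategy = st.text(alphabet="ACGT", min_size=1, max_size=60)


# -- revcomp -----------------------------------------------------------------

def test_revcomp_by_hand():
    assert revcomp("ACTC") == "GAGT"


def test_revcomp_derived():
    # independent hand computation, cross-checked by the involution below
    assert revcomp("ATTTTGTTTAATGTTCAAGGAACC") == "GGTTCCTTGAACATTAAACAAAAT"


@given(dna_strategy)
def test_revcomp_involution(s):
    assert revcomp(revcomp(s)) == s


def test_revcomp_iupac_codes():
    assert revcomp("RYN") == "NRY"


def test_revcomp_invalid_character_names_position():
    with pytest.raises(AlphabetError) as exc:
        revcomp("ACXT")
    assert exc.value.symbol == "X"
    assert exc.value.position == 3


# -- tiling ------------------------------------------------------------------

def test_tile_region_paper_count():
    panel = tile_region(random_dna(119, seed=1), FRAGMENT_LENGTH, SITE_LENGTH)
    assert len(panel) == 14


def test_tile_region_single_fragment():
    region = random_dna(29, seed=2)
    panel = tile_region(region, 29, 22)
    assert len(panel) == 1
    assert panel.fragments[0].forward == region


def test_tile_region_end_anchored_40nt():
    region = random_dna(40, seed=3)
    panel = tile_region(region, 29, 22)
    assert [f.region_start for f in panel.fragments] == [1, 8, 12]
    # brute-force: every 22-nt window is fully inside some fragment
    for w in range(1, 40 - 22 + 2):
        assert any(
            f.region_start <= w and w + 21 <= f.region_end for f in panel.fragments
        )


def test_tile_region_last_fragment_ends_at_n():
    for n in (29, 35, 57, 119, 200):
        panel = tile_region(random_dna(n, seed=n), 29, 22)
        assert panel.fragments[-1].region_end == n


def test_tile_region_count_formula():
    for n in (36, 50, 119, 300):
        panel = tile_region(random_dna(n, seed=n), 29, 22)
        assert len(panel) == math.ceil((n - 29) / 7) + 1


@settings(max_examples=40, deadline=None)
@given(st.data())
def test_tile_region_coverage_oracle(data):
    f = data.draw(st.integers(min_value=10, max_value=40))
    l = data.draw(st.integers(min_value=2, max_value=f - 1))
    n = data.draw(st.integers(min_value=f, max_value=300))
    panel = tile_region(random_dna(n, seed=n * 7 + f), f, l)
    for w in range(1, n - l + 2):
        assert any(
            frag.region_start <= w and w + l - 1 <= frag.region_end
            for frag in panel.fragments
        ), f"window [{w},{w + l - 1}] uncovered for N={n} F={f} L={l}"
    starts = [frag.region_start for frag in panel.fragments]
    assert starts == sorted(starts)


def test_tile_region_parameter_errors():
    with pytest.raises(ParameterError):
        tile_region("ACGT" * 5, 29, 22)  # F > N
    with pytest.raises(ParameterError):
        tile_region(random_dna(100, seed=4), 20, 25)  # L > F


# -- linker handling ---------------------------------------------------------

def test_attach_linker_standard_orientation(o3204_start):
    dup = attach_linker(o3204_start, LinkerSpec())
    assert dup.overhang_host == "reverse_3prime"
    assert len(dup.reverse_full) == len(dup.forward_full) + 20
    assert dup.forward == o3204_start.forward


def test_attach_linker_inverted_orientation(o3204_start):
    dup = attach_linker(o3204_start, LinkerSpec(), "forward_3prime")
    assert dup.overhang_host == "forward_3prime"
    assert len(dup.forward_full) == len(dup.reverse_full) + 20


def test_attach_then_strip_roundtrip(o3204_start):
    assert strip_linker(attach_linker(o3204_start, LinkerSpec())) == o3204_start


def test_attach_linker_twice_is_error(o3204_start):
    dup = attach_linker(o3204_start, LinkerSpec())
    with pytest.raises(DesignError):
        attach_linker(dup, LinkerSpec())


def test_attach_linker_host_none_warns(o3204_start):
    with pytest.warns(UserWarning):
        out = attach_linker(o3204_start, LinkerSpec(), "none")
    assert out == o3204_start


def test_linker_must_be_20nt():
    with pytest.raises(ParameterError):
        LinkerSpec("ACGT")


# -- truncation series -------------------------------------------------------

def test_truncation_series_rh_delta8(o3204_start):
    series = make_truncation_series(o3204_start, "RH", max_delta=12)
    member = series.member(8)
    assert member.forward == "ACTCCAATACTTGAACTCTCAATCTTTA"
    assert len(member) == 28
    assert member.overhang_host == "reverse_3prime"


def test_truncation_series_lh_delta4(o3204_start):
    series = make_truncation_series(o3204_start, "LH", max_delta=8)
    member = series.member(4)
    assert member.forward == "CAATACTTGAACTCTCAATCTTTACGTGCCGT"
    assert member.overhang_host == "forward_3prime"


def test_truncation_lengths_decrease_by_step(o3205_start):
    series = make_truncation_series(o3205_start, "RH", max_delta=10)
    lengths = [len(d) for _, d in series.members]
    assert lengths == [36, 34, 32, 30, 28, 26]
    assert series.member(0).forward == o3205_start.forward


def test_truncation_reverse_strand_complementary(o3204_start):
    series = make_truncation_series(o3204_start, "LH", max_delta=10)
    for _, dup in series.members:
        assert dup.reverse == revcomp(dup.forward)


def test_truncation_min_length_floor(o3204_start):
    with pytest.raises(DesignError):
        make_truncation_series(o3204_start, "RH", max_delta=30)


def test_truncation_bad_side(o3204_start):
    with pytest.raises(ParameterError):
        make_truncation_series(o3204_start, "XX", max_delta=4)


# -- footprint bookkeeping ---------------------------------------------------

def test_apply_footprint_o3204(o3204_start):
    assert apply_footprint(o3204_start, 8, 4).forward == O3204_FOOTPRINT


def test_apply_footprint_o3205(o3205_start):
    assert apply_footprint(o3205_start, 6, 6).forward == O3205_FOOTPRINT


def test_apply_footprint_identity(o3204_start):
    assert apply_footprint(o3204_start, 0, 0).forward == o3204_start.forward


def test_apply_footprint_negative_delta(o3204_start):
    with pytest.raises(ParameterError):
        apply_footprint(o3204_start, -2, 0)


def test_apply_footprint_coordinates(o3204_start):
    fp = apply_footprint(o3204_start, 8, 4)
    assert (fp.region_start, fp.region_end) == (5, 28)


@given(
    st.integers(min_value=0, max_value=6), st.integers(min_value=0, max_value=6)
)
def test_truncation_commutes_with_footprint(a, b):
    start = OligoDuplex(name="s", forward=O3204_START)
    rh = make_truncation_series(start, "RH", step=1, max_delta=10).member(a)
    both = make_truncation_series(
        strip_linker(rh), "LH", step=1, max_delta=10
    ).member(b)
    assert both.forward == apply_footprint(start, a, b).forward


# -- substitution panels -----------------------------------------------------

def test_substitution_panel_counts(o3204_start):
    panel = make_substitution_panel(
        o3204_start, [6, 7, 9, 10, 14, 15, 16, 17], replicates=8
    )
    assert len(panel.variants) == 24  # 8 positions x 3 alternatives
    assert len(panel.controls) == 8


def test_substitution_single_position():
    wt = OligoDuplex(name="wt", forward="AAAA")
    panel = make_substitution_panel(wt, [2])
    alts = sorted(alt for _, alt, _ in panel.variants)
    assert alts == ["C", "G", "T"]
    for pos, alt, dup in panel.variants:
        assert dup.forward[1] == alt
        assert dup.forward[0] == dup.forward[2] == dup.forward[3] == "A"


def test_substitution_reverse_strands_stay_complementary(o3205_start):
    panel = make_substitution_panel(o3205_start, [1, 10, 36])
    for _, _, dup in panel.variants:
        assert dup.reverse == revcomp(dup.forward)


def test_substitution_duplicate_positions(o3204_start):
    with pytest.raises(ParameterError):
        make_substitution_panel(o3204_start, [3, 3])


# -- molecular weights -------------------------------------------------------

# Average atomic masses for the independent composition oracle.
_ATOM = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "P": 30.974}


def _mass(formula: dict) -> float:
    return sum(_ATOM[el] * n for el, n in formula.items())


# 2'-deoxyribonucleoside formulas
_NUCLEOSIDE_FORMULA = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 3},
    "C": {"C": 9, "H": 13, "N": 3, "O": 4},
    "G": {"C": 10, "H": 13, "N": 5, "O": 4},
    "T": {"C": 10, "H": 14, "N": 2, "O": 5},
}


def oracle_strand_mw(seq: str) -> float:
    """Atomic-composition oracle: nucleosides + (n-1) bridging HPO3 with the
    loss of one water per ester bond formed (2 per bridge, from H3PO4)."""
    h3po4 = _mass({"H": 3, "P": 1, "O": 4})
    water = _mass({"H": 2, "O": 1})
    total = sum(_mass(_NUCLEOSIDE_FORMULA[ch]) for ch in seq)
    return total + (len(seq) - 1) * (h3po4 - 2 * water)


@pytest.mark.parametrize("base", "ACGT")
def test_strand_mw_single_bases_vs_atomic_oracle(base):
    assert strand_mw(base) == pytest.approx(oracle_strand_mw(base), abs=0.05)


def test_strand_mw_longer_sequence_vs_oracle():
    seq = O3204_FOOTPRINT
    assert strand_mw(seq) == pytest.approx(oracle_strand_mw(seq), abs=0.5)


def test_dna_mw_additivity(o3204_start):
    dup = attach_linker(o3204_start, LinkerSpec())
    assert dna_mw(dup) == pytest.approx(
        strand_mw(dup.forward_full) + strand_mw(dup.reverse_full)
    )


@given(dna_strategy, st.sampled_from("ACGT"))
def test_strand_mw_monotone_in_length(s, extra):
    assert strand_mw(s + extra) > strand_mw(s)


def test_strand_mw_rejects_ambiguity_codes():
    with pytest.raises((ParameterError, AlphabetError)):
        strand_mw("ACGN")


def test_protein_mw_glycine():
    assert protein_mw("G") == pytest.approx(75.07, abs=0.01)


def test_protein_mw_matches_biopython():
    from Bio.SeqUtils import molecular_weight

    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
    assert protein_mw(seq) == pytest.approx(
        molecular_weight(seq, seq_type="protein"), abs=0.5
    )


def test_protein_mw_empty_is_error():
    with pytest.raises(ParameterError):
        protein_mw("")


def test_protein_mw_unknown_letter():
    with pytest.raises(AlphabetError):
        protein_mw("MKTX")


# -- translation -------------------------------------------------------------

def test_translate_simple():
    assert translate("ATGGGT") == "MG"


def test_translate_stops_at_stop():
    assert translate("ATGTAA") == "M"
    assert translate("ATGTAAGGG") == "M"


def test_translate_partial_codon_warns():
    with pytest.warns(UserWarning):
        assert translate("ATGGG") == "M"


@given(st.text(alphabet="ACGT", min_size=3, max_size=60))
def test_translate_revcomp_involution_property(s):
    assert translate(revcomp(revcomp(s))) == translate(s)


# -- chip budget -------------------------------------------------------------

def test_chip_budget_paper_example():
    assert chip_budget(138, 3) == 46


def test_chip_budget_rounds_up():
    assert chip_budget(1) == 1
    assert chip_budget(4, 3) == 2
    assert chip_budget(0) == 0
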