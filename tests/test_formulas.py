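"""Descriptor arithmetic: parsing, DBE, χc, OSc, classes, regions."""

import numpy as np
import pytest

from paleonts.formulas import (
    DescriptorConfig,
    FormulaError,
    MolecularFormula,
    annotate_regions,
    aromaticity_equivalent,
    carbon_oxidation_state,
    compound_class,
    compute_descriptors,
    dbe,
    descriptor_frame,
    parse_formula,
)
from conftest import random_formula


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C8H8O3", {"C": 8, "H": 8, "O": 3}),
        ("C6H5NO3", {"C": 6, "H": 5, "N": 1, "O": 3}),
        ("CH4", {"C": 1, "H": 4}),
        ("C6H4ClNO2", {"C": 6, "H": 4, "Cl": 1, "N": 1, "O": 2}),
        ("C1H4", {"C": 1, "H": 4}),
        ("CH3CH3", {"C": 2, "H": 6}),  # repeated tokens sum
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).element_counts == expected


def test_parse_errors_name_position():
    with pytest.raises(FormulaError, match="position 2"):
        parse_formula("C6?H5")
    with pytest.raises(FormulaError):
        parse_formula("")
    with pytest.raises(FormulaError):
        parse_formula("c6h6")  # lowercase start is not an element token


def test_unknown_elements_preserved():
    f = parse_formula("C2H6SiO")
    assert f["Si"] == 1 and f.C == 2


def test_hill_roundtrip_is_idempotent():
    rng = np.random.default_rng(42)
    for _ in range(200):
        f = random_formula(rng)
        assert parse_formula(f.hill()) == f
        assert parse_formula(f.hill()).hill() == f.hill()


def test_hill_order_without_carbon():
    assert parse_formula("H3NO4S").hill() == "H3NO4S"
    assert MolecularFormula({"S": 1, "O": 4, "H": 2}).hill() == "H2O4S"


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"C": 4, "H": 6, "O": 4}, "CHO"),
        ({"C": 6, "H": 5, "N": 1, "O": 3}, "CHNO"),
        ({"C": 5, "H": 9, "N": 1, "O": 3, "S": 1}, "CHNOS"),
        ({"C": 5, "H": 10, "O": 3, "S": 1}, "CHOS"),
        ({"C": 6, "H": 7, "N": 1}, "other"),  # CHN
        ({"C": 6, "H": 4, "Cl": 1, "N": 1, "O": 2}, "other"),  # halogenated
        ({"C": 3, "H": 8}, "other"),  # no oxygen
    ],
)
def test_compound_class(counts, expected):
    assert compound_class(MolecularFormula(counts)) == expected


def test_class_partitions_any_set():
    rng = np.random.default_rng(7)
    formulas = [random_formula(rng) for _ in range(300)]
    tally = {}
    for f in formulas:
        tally[compound_class(f)] = tally.get(compound_class(f), 0) + 1
    assert sum(tally.values()) == len(formulas)
    assert set(tally) <= {"CHO", "CHNO", "CHNOS", "CHOS", "other"}


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C4H6O4", 2.0),
        ("C6H5NO3", 5.0),
        ("C6H4ClNO2", 5.0),  # Cl counted with H
        ("C8H8O3", 5.0),
        ("CH4", 0.0),
    ],
)
def test_dbe(text, expected):
    assert dbe(parse_formula(text)) == expected


def test_dbe_parity_rule():
    """DBE is an integer iff H + halogens + N is even, else half-integer."""
    rng = np.random.default_rng(3)
    for _ in range(300):
        f = random_formula(rng)
        val = dbe(f)
        even = (f.H + f.halogen_count + f.N) % 2 == 0
        assert (val == int(val)) == even
        assert (2 * val) == int(2 * val)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C8H8O3", 2.428571),  # reported as 2.4
        ("C5H8O3", 0.0),  # raw (3*0.5-2)/0.5 < 0, clamped
        ("C4H6O4", 0.0),  # degenerate d = 0
        ("C6H6", 2.5),  # at the aromatic threshold
    ],
)
def test_aromaticity_equivalent(text, expected):
    assert aromaticity_equivalent(parse_formula(text)) == pytest.approx(expected, abs=1e-5)


def test_chi_c_nonnegative_and_matches_formula():
    rng = np.random.default_rng(11)
    cfg = DescriptorConfig()
    for _ in range(1000):
        f = random_formula(rng)
        chi = aromaticity_equivalent(f, cfg)
        assert chi >= 0.0
        d = dbe(f) - 0.5 * f.O - 0.5 * f.S
        if d > 0 and (3 * d - 2) / d > 0:
            assert chi == pytest.approx((3 * d - 2) / d, rel=1e-12)
        else:
            assert chi == 0.0


def test_custom_pi_fractions():
    # carbonyl-like assumption m = n = 1 discounts more of the DBE
    f = parse_formula("C8H8O3")
    full = aromaticity_equivalent(f, DescriptorConfig(m_pi_oxygen=1.0, n_pi_sulfur=1.0))
    assert full < aromaticity_equivalent(f)
    with pytest.raises(ValueError):
        DescriptorConfig(m_pi_oxygen=1.5)


@pytest.mark.parametrize(
    "text, expected",
    [("C8H8O3", -0.25), ("CH4", -4.0), ("C4H6O4", 0.5)],
)
def test_carbon_oxidation_state(text, expected):
    assert carbon_oxidation_state(parse_formula(text)) == pytest.approx(expected)


def test_osc_requires_carbon_and_alkane_limit():
    with pytest.raises(ValueError):
        carbon_oxidation_state(MolecularFormula({"H": 2, "O": 1}))
    for n in range(1, 20):
        alkane = MolecularFormula({"C": n, "H": 2 * n + 2})
        assert carbon_oxidation_state(alkane) == pytest.approx(-(2 * n + 2) / n)
        assert carbon_oxidation_state(alkane) < -2


def test_annotate_regions():
    vk, kroll = annotate_regions(-0.3, 1.8)
    assert vk == "aliphatic"
    assert {"isoprene-OH", "SVOC"} <= kroll
    assert annotate_regions(0.5, 1.0) == ("unsaturated/aromatic-leaning", frozenset({"LVOC"}))
    assert annotate_regions(-1.65, 2.0)[1] == frozenset({"hydrocarbon-like"})
    # overlap: boundaries belong to both adjacent bands
    assert {"SVOC", "LVOC"} <= annotate_regions(0.0, 1.6)[1]


def test_descriptor_record_identity():
    rng = np.random.default_rng(5)
    for _ in range(200):
        f = random_formula(rng)
        d = compute_descriptors(f)
        assert d.osc == pytest.approx(2 * d.oc_ratio - d.hc_ratio, abs=1e-12)
        assert d.nC == f.C


def test_descriptor_frame_layout():
    frame = descriptor_frame({"a": parse_formula("C8H8O3"), "b": parse_formula("C4H6O4")})
    assert list(frame.index) == ["a", "b"]
    assert frame.loc["a", "chi_c"] == pytest.approx(2.428571, abs=1e-5)
    assert frame.loc["b", "compound_class"] == "CHO"
    assert "SVOC" in frame.loc["b", "kroll_regions"] or frame.loc["b", "osc"] > 0


def test_parser_agrees_with_pyteomics():
    """Independent cross-check of element counting on CHNOS formulas."""
    from pyteomics.mass import Composition

    rng = np.random.default_rng(9)
    for _ in range(50):
        f = random_formula(rng)
        if f.halogen_count:  # pyteomics handles them too, but keep it simple
            continue
        comp = Composition(formula=f.hill())
        assert dict(comp) == f.element_counts
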