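"""Formula parsing, monoisotopic masses, ion m/z and transformation rules."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from ebimet import chem
from ebimet.chem import (
    ANION,
    CATION,
    M_MINUS_H,
    M_PLUS_H,
    ElementalFormula,
    FormulaError,
    IsotopeLabelSpec,
    TransformationRule,
    apply_transformation,
    enumerate_products,
    ion_mz,
    labeled_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)

# An independent atom-by-atom summation oracle over the IUPAC monoisotopic
# table, written against its own copy of the constants.
_ORACLE_MASSES = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Cl": 34.96885271,
    "2H": 2.014101778,
    "13C": 13.0033548378,
}


def oracle_mass(counts, labels=()):
    total = 0.0
    for el, n in counts.items():
        for _ in range(n):
            total += _ORACLE_MASSES[el]
    for iso, n in dict(labels).items():
        light = iso.lstrip("0123456789")
        for _ in range(n):
            total += _ORACLE_MASSES[iso] - _ORACLE_MASSES[light]
    return total


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, counts, labels",
    [
        ("C8H12N4O3", {"C": 8, "H": 12, "N": 4, "O": 3}, {}),
        ("C7H8N4O2", {"C": 7, "H": 8, "N": 4, "O": 2}, {}),
        ("C8H9D3N4O3", {"C": 8, "H": 12, "N": 4, "O": 3}, {"2H": 3}),
        ("C5[13C]3H10N4O2", {"C": 8, "H": 10, "N": 4, "O": 2}, {"13C": 3}),
        ("", {}, {}),
    ],
)
def test_parse_formula(text, counts, labels):
    f = parse_formula(text)
    assert dict(f.counts) == counts
    assert dict(f.label_counts) == labels


@pytest.mark.parametrize("bad", ["C8Hq", "Xx2", "C-3", "[99Zz]2", "8C"])
def test_parse_rejects_garbage(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


def test_substitutions_cannot_exceed_light_atoms():
    with pytest.raises(FormulaError):
        ElementalFormula({"C": 2, "H": 4}, {"2H": 5})


_formula_strategy = st.builds(
    ElementalFormula,
    st.fixed_dictionaries(
        {},
        optional={
            "C": st.integers(1, 30),
            "H": st.integers(1, 40),
            "N": st.integers(0, 6),
            "O": st.integers(0, 8),
            "S": st.integers(0, 3),
            "P": st.integers(0, 2),
            "Cl": st.integers(0, 3),
        },
    ),
)


@settings(derandomize=True, max_examples=200)
@given(_formula_strategy, st.integers(0, 5))
def test_formula_roundtrips_through_canonical_writer(f, n_labels):
    n = min(n_labels, f.counts.get("H", 0))
    f = f.with_labels("2H", n) if n else f
    assert parse_formula(f.to_string()) == f


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------


def test_monoisotopic_mass_examples():
    assert monoisotopic_mass(ElementalFormula({"C": 8, "H": 12, "N": 4, "O": 3})) == pytest.approx(
        212.09094, abs=1e-5
    )
    assert monoisotopic_mass(ElementalFormula({})) == 0.0
    # glucuronide delta
    assert monoisotopic_mass(ElementalFormula({"C": 6, "H": 8, "O": 6})) == pytest.approx(
        176.03209, abs=1e-5
    )


@settings(derandomize=True, max_examples=1000)
@given(_formula_strategy)
def test_mass_agrees_with_atom_sum_oracle(f):
    assert monoisotopic_mass(f) == pytest.approx(
        oracle_mass(f.counts), abs=1e-6
    )


def test_mass_agrees_with_pyteomics_on_known_compounds():
    """Independent library cross-check of the atomic-mass constants."""
    pyteomics_mass = pytest.importorskip("pyteomics.mass")
    for text in ["C8H10N4O2", "C13H18ClNO2", "C10H8O4S", "C16H16O7"]:
        f = parse_formula(text)
        ref = pyteomics_mass.calculate_mass(formula=text)
        assert monoisotopic_mass(f) == pytest.approx(ref, abs=1e-5)


# ---------------------------------------------------------------------------
# ion m/z — the printed-value desk checks
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "formula, ion, expected",
    [
        ("C8H12N4O3", M_PLUS_H, 213.0981),  # unreported caffeine metabolite
        ("C7H8N4O2", M_PLUS_H, 181.0720),  # paraxanthine
        ("C13H18ClNO2", M_PLUS_H, 256.1099),  # hydroxybupropion
        ("C9H11ClNO2", CATION, 200.0473),  # ring-oxidation MS2 fragment
    ],
)
def test_ion_mz_reproduces_reported_values_within_3ppm(formula, ion, expected):
    mz = ion_mz(parse_formula(formula), ion)
    assert abs(ppm_error(mz, expected)) <= 3.0


def test_proton_transfer_ion_gap_is_two_protons():
    f = parse_formula("C8H10N4O2")
    gap = ion_mz(f, M_PLUS_H) - ion_mz(f, M_MINUS_H)
    assert gap == pytest.approx(2 * chem.PROTON_MASS, abs=1e-7)


def test_intact_ion_electron_bookkeeping():
    f = parse_formula("C9H11ClNO2")
    assert ion_mz(f, CATION) == pytest.approx(
        monoisotopic_mass(f) - chem.ELECTRON_MASS, abs=1e-9
    )
    assert ion_mz(f, ANION) == pytest.approx(
        monoisotopic_mass(f) + chem.ELECTRON_MASS, abs=1e-9
    )


# ---------------------------------------------------------------------------
# isotope labels
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "formula, label, lost, expected",
    [
        ("C8H12N4O3", "D:3", 0, 216.1170),  # d3 caffeine metabolite
        ("C8H12N4O3", "13C:3", 0, 216.1080),  # 13C3 caffeine metabolite
        ("C13H18ClNO2", "D:9", 1, 264.1600),  # d8-hydroxybupropion
    ],
)
def test_labeled_mz_reproduces_reported_values_within_3ppm(
    formula, label, lost, expected
):
    mz = labeled_mz(
        parse_formula(formula), M_PLUS_H, IsotopeLabelSpec.parse(label), lost
    )
    assert abs(ppm_error(mz, expected)) <= 3.0


def test_per_label_delta_matches_isotope_mass_difference():
    d = IsotopeLabelSpec.parse("D:9")
    assert d.per_label_delta == pytest.approx(
        chem.MONOISOTOPIC_MASS["2H"] - chem.MONOISOTOPIC_MASS["H"], abs=1e-7
    )


@settings(derandomize=True, max_examples=100)
@given(_formula_strategy, st.integers(1, 6))
def test_all_labels_lost_equals_unlabeled_mz(f, n):
    if f.counts.get("H", 0) < n:
        return
    label = IsotopeLabelSpec("H", "2H", n)
    assert labeled_mz(f, M_PLUS_H, label, labels_lost=n) == ion_mz(f, M_PLUS_H)


def test_labels_lost_out_of_range_rejected():
    label = IsotopeLabelSpec.parse("13C:3")
    with pytest.raises(ValueError):
        labeled_mz(parse_formula("C8H12N4O3"), M_PLUS_H, label, labels_lost=4)


# ---------------------------------------------------------------------------
# transformation rules
# ---------------------------------------------------------------------------


def test_rule_mass_delta_matches_element_sum(default_rules):
    for rule in default_rules:
        direct = sum(
            n * chem.MONOISOTOPIC_MASS[s] for s, n in rule.element_delta.items()
        )
        assert rule.mass_delta == pytest.approx(direct, abs=1e-6)


def test_apply_oxidation_reduction_to_caffeine(caffeine, default_rules):
    rules = chem.rules_by_name(default_rules)
    out = apply_transformation(caffeine, rules["oxidation-reduction"])
    assert out == parse_formula("C8H12N4O3")


def test_identity_rule_is_identity(caffeine):
    ident = TransformationRule("identity", {})
    assert apply_transformation(caffeine, ident) == caffeine


def test_impossible_transformation_raises():
    demeth = TransformationRule.from_delta_string("demethylation", "-CH2")
    f = parse_formula("C2H6")
    f = apply_transformation(f, demeth)
    f = apply_transformation(f, demeth)
    with pytest.raises(FormulaError):
        apply_transformation(f, demeth)


def test_hydration_equals_oxidation_plus_reduction(caffeine, default_rules):
    """+O then +2H and +H2O are mass-equivalent interpretations."""
    rules = chem.rules_by_name(default_rules)
    a = apply_transformation(
        apply_transformation(caffeine, rules["hydroxylation"]),
        rules["reduction"],
    )
    b = apply_transformation(caffeine, rules["hydration"])
    assert monoisotopic_mass(a) == pytest.approx(monoisotopic_mass(b), abs=1e-9)
    assert rules["hydration"].mass_delta == pytest.approx(18.01056, abs=1e-5)


def test_chain_mass_additivity(caffeine, default_rules):
    rules = chem.rules_by_name(default_rules)
    chain = ["hydroxylation", "glucuronidation", "reduction"]
    f = caffeine
    for name in chain:
        f = apply_transformation(f, rules[name])
    total = sum(rules[n].mass_delta for n in chain)
    assert monoisotopic_mass(f) - monoisotopic_mass(caffeine) == pytest.approx(
        total, abs=1e-9
    )


def test_isotope_spacing_rule_is_substitution():
    rule = TransformationRule.from_delta_string(
        "13C-isotopologue", "+[13C]-C", phase="adduct/isotope"
    )
    assert rule.mass_delta == pytest.approx(1.0033548, abs=1e-6)
    f = apply_transformation(parse_formula("C8H10N4O2"), rule)
    assert f.counts["C"] == 8 and f.label_counts["13C"] == 1


# ---------------------------------------------------------------------------
# product enumeration
# ---------------------------------------------------------------------------


def test_enumerate_bupropion_products(bupropion, default_rules):
    prods = enumerate_products(bupropion, default_rules, depth=2)
    formulas = {p.formula.to_string() for p in prods}
    assert "C13H18ClNO2" in formulas  # hydroxybupropion
    assert "C13H20ClNO" in formulas  # hydrobupropion


def test_enumerate_naphthalene_conjugate_chains():
    rules = [
        TransformationRule.from_delta_string("hydroxylation", "+O"),
        TransformationRule.from_delta_string("sulfation", "+SO3", "II"),
        TransformationRule.from_delta_string("glucuronidation", "+C6H8O6", "II"),
    ]
    prods = enumerate_products(parse_formula("C10H8"), rules, depth=2)
    formulas = {p.formula.to_string() for p in prods}
    assert "C10H8O4S" in formulas  # hydroxynaphthalene sulfate
    assert "C16H16O7" in formulas  # hydroxynaphthalene glucuronide


def test_enumerate_depth_one_bounded_by_rule_count(caffeine, default_rules):
    prods = enumerate_products(caffeine, default_rules, depth=1)
    assert len(prods) <= len(default_rules)
    assert all(len(p.chain) == 1 for p in prods)


@pytest.mark.parametrize("d1, d2", [(1, 2), (2, 3)])
def test_enumerate_monotone_in_depth(caffeine, default_rules, d1, d2):
    f1 = {p.formula for p in enumerate_products(caffeine, default_rules, d1)}
    f2 = {p.formula for p in enumerate_products(caffeine, default_rules, d2)}
    assert f1 <= f2


# ---------------------------------------------------------------------------
# ppm arithmetic
# ---------------------------------------------------------------------------


def test_ppm_error_examples():
    assert ppm_error(213.0981, 213.0982) == pytest.approx(-0.469, abs=0.01)
    assert ppm_error(250.0, 250.0) == 0.0
    assert ppm_error(200.0479, 200.0473) == pytest.approx(3.0, abs=0.01)


def test_ppm_error_requires_positive_theoretical():
    with pytest.raises(ValueError):
        ppm_error(100.0, 0.0)
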