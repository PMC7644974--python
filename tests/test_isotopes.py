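"""Exact-mass arithmetic and element-count inference from labeling shifts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isodiel.isotopes import (
    CONSTANTS,
    ElementalFormula,
    constants_table_path,
    infer_atom_count,
    labeled_mz,
    monoisotopic_mass,
    mz_deprotonated,
    natural_mid,
)

# Hand-summed from the monoisotopic atomic-mass table (independent oracle;
# cross-checked against pyteomics below).
HAND_MASSES = {
    "C3H7O7P": 185.99294,  # 3-phosphoglycerate
    "C14H22N2O16P2": 536.04446,  # UDP-xylose
    "C6H12O6": 180.06339,  # glucose
    "C5H9NO4": 147.05316,  # glutamate
}


@pytest.mark.parametrize("formula,expected", sorted(HAND_MASSES.items()))
def test_monoisotopic_mass_matches_hand_sums(formula, expected):
    assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-6)


def test_monoisotopic_mass_matches_pyteomics():
    from pyteomics import mass as ptmass

    for formula in HAND_MASSES:
        assert monoisotopic_mass(formula) == pytest.approx(
            ptmass.calculate_mass(formula=formula), abs=1e-9
        )


@pytest.mark.parametrize(
    "formula,expected",
    [("C3H7O7P", 184.98566), ("C14H22N2O16P2", 535.03718)],
)
def test_deprotonated_mz(formula, expected):
    # oracle: monoisotopic mass minus the proton mass 1.0072765
    assert mz_deprotonated(formula, 1) == pytest.approx(expected, abs=5e-6)


def test_deprotonated_rejects_zero_charge_and_missing_hydrogens():
    with pytest.raises(ValueError):
        mz_deprotonated("C6H12O6", 0)
    with pytest.raises(ValueError):
        mz_deprotonated("C2H2O2", 3)


def test_labeled_mz_shifts():
    mz_13c, ok = labeled_mz("C3H7O7P", "13C")
    assert ok and mz_13c == pytest.approx(184.98566 + 3 * 1.0033548, abs=5e-6)
    mz_15n, ok = labeled_mz("C14H22N2O16P2", "15N")
    assert ok and mz_15n == pytest.approx(535.03718 + 2 * 0.9970349, abs=5e-6)


def test_labeled_mz_without_target_element_warns():
    mz, ok = labeled_mz("C6H12O6", "15N")
    assert not ok
    assert mz == pytest.approx(mz_deprotonated("C6H12O6"), abs=1e-12)


def test_natural_mid_binomial_values():
    # direct binomial oracle: a = 0.0107, nC = 6
    a = CONSTANTS.natural_13c_abundance
    raw = [(1 - a) ** 6, 6 * a * (1 - a) ** 5, 15 * a**2 * (1 - a) ** 4]
    expected = np.array(raw) / sum(raw)
    mid = natural_mid("C6H12O6", 2)
    assert mid == pytest.approx(expected, abs=1e-12)
    assert mid[0] == pytest.approx(0.9375, abs=5e-4)
    assert mid[1] == pytest.approx(0.0608, abs=5e-4)


def test_natural_mid_degenerate_and_errors():
    assert natural_mid("H2O", 3) == pytest.approx([1.0, 0.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        natural_mid("C6H12O6", -1)


formula_strategy = st.builds(
    lambda c, h, n, o, p, s: ElementalFormula(
        {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s}
    ),
    st.integers(1, 60),
    st.integers(1, 100),
    st.integers(0, 8),
    st.integers(0, 20),
    st.integers(0, 3),
    st.integers(0, 2),
)


@settings(max_examples=100, deadline=None)
@given(formula_strategy, st.integers(0, 12))
def test_natural_mid_normalized_and_decreasing(formula, k):
    mid = natural_mid(formula, k)
    assert mid.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(mid >= 0)
    if formula.n_carbon * CONSTANTS.natural_13c_abundance < 1:
        assert np.all(np.diff(mid) <= 1e-15)


@settings(max_examples=100, deadline=None)
@given(formula_strategy, formula_strategy)
def test_monoisotopic_mass_additive(f1, f2):
    assert monoisotopic_mass(f1 + f2) == pytest.approx(
        monoisotopic_mass(f1) + monoisotopic_mass(f2), abs=1e-9
    )


@settings(max_examples=150, deadline=None)
@given(formula_strategy)
def test_atom_count_round_trip_noiseless(formula):
    """Labeling shift inversion recovers exact C and N counts without noise."""
    base = mz_deprotonated(formula)
    mz_c, _ = labeled_mz(formula, "13C")
    assert infer_atom_count(base, mz_c, "C", ppm_tol=1.0) == formula.n_carbon
    mz_n, _ = labeled_mz(formula, "15N")
    assert infer_atom_count(base, mz_n, "N", ppm_tol=1.0) == formula.n_nitrogen


def test_atom_count_examples():
    assert infer_atom_count(184.98566, 187.99573, "C", 1, 10.0) == 3
    assert infer_atom_count(300.0, 300.0, "C", 1, 10.0) == 0
    # a shift of 1.51 Da is ~1.51 carbon mass differences, far from integer
    assert infer_atom_count(184.98566, 186.50000, "C", 1, 10.0) is None
    assert infer_atom_count(300.0, 299.0, "C", 1, 10.0) is None  # negative shift


def test_atom_count_recovery_with_mass_error():
    """Exact recovery for nC <= 60 with up to +/-5 ppm m/z noise at 10 ppm tol."""
    rng = np.random.default_rng(42)
    for _ in range(500):
        nc = int(rng.integers(1, 61))
        formula = ElementalFormula({"C": nc, "H": int(rng.integers(2, 2 * nc + 2)),
                                    "O": int(rng.integers(1, 15))})
        base = mz_deprotonated(formula)
        mz_c, _ = labeled_mz(formula, "13C")
        noisy_base = base * (1 + rng.uniform(-5, 5) * 1e-6)
        noisy_lab = mz_c * (1 + rng.uniform(-5, 5) * 1e-6)
        assert infer_atom_count(noisy_base, noisy_lab, "C", ppm_tol=10.0) == nc


def test_formula_parsing_and_validation():
    f = ElementalFormula("C6H13O9P")
    assert f["C"] == 6 and f["H"] == 13 and f["O"] == 9 and f["P"] == 1
    assert f.hill() == "C6H13O9P"
    assert ElementalFormula("CH4")["C"] == 1
    with pytest.raises(ValueError):
        ElementalFormula({"C": 0})  # empty formula
    with pytest.raises(ValueError):
        ElementalFormula("C6Xe2")  # unsupported element
    with pytest.raises(ValueError):
        ElementalFormula("abc")
    with pytest.raises(AttributeError):
        f.anything = 1


def test_constants_file_matches_runtime_values():
    import csv

    with open(constants_table_path()) as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    table = {r[0]: r[1] for r in rows[1:]}
    assert float(table["delta_13C"]) == pytest.approx(CONSTANTS.delta_13c, abs=5e-8)
    assert float(table["delta_15N"]) == pytest.approx(CONSTANTS.delta_15n, abs=5e-8)
    assert float(table["natural_13C_abundance"]) == CONSTANTS.natural_13c_abundance
    for element in "CHNOPS":
        assert float(table[f"monoisotopic_{element}"]) == pytest.approx(
            CONSTANTS.monoisotopic[element], abs=5e-8
        )
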