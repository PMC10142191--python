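"""Natural-isotope correction: oracles, round trips, endpoints."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from c13pos.fragment_library import load_fragment_table, parse_formula
from c13pos.isotope_correction import (
    CIDVector,
    CorrectionOptions,
    IsotopeTable,
    build_correction_matrix,
    correct_areas,
    mean_enrichment,
    shift_distribution,
)
from c13pos.spectra_simulator import simulate_fragment_areas


def brute_force_shift_distribution(counts, exclude_c, table):
    """Independent oracle: enumerate every isotope assignment of every atom."""
    atoms = []
    for el, n in counts.items():
        n = n - exclude_c if el == "C" else n
        atoms.extend([table.atom_distribution(el)] * n)
    max_shift = sum(len(a) - 1 for a in atoms)
    out = np.zeros(max_shift + 1)
    for combo in itertools.product(*[range(len(a)) for a in atoms]):
        p = 1.0
        for a, s in zip(atoms, combo):
            p *= a[s]
        out[sum(combo)] += p
    return out


def sympy_shift_distribution(counts, exclude_c, table):
    """Second oracle: exact-rational polynomial expansion, any formula size."""
    import sympy
    from fractions import Fraction

    x = sympy.symbols("x")
    poly = sympy.Integer(1)
    for el, n in counts.items():
        n = n - exclude_c if el == "C" else n
        base = sum(sympy.Rational(Fraction(str(a)).limit_denominator(10**12)) * x**s
                   for s, a in enumerate(table.atom_distribution(el)))
        poly *= base**n
    poly = sympy.Poly(sympy.expand(poly), x)
    coeffs = poly.all_coeffs()[::-1]
    return np.array([float(c) for c in coeffs])


def test_shift_distribution_examples(isotope_table):
    np.testing.assert_allclose(
        shift_distribution({"Si": 1}, 0, isotope_table, window=2),
        [0.9223, 0.0467, 0.0310])
    np.testing.assert_allclose(shift_distribution({"C": 1}, 1, isotope_table), [1.0])
    p = 0.011
    np.testing.assert_allclose(
        shift_distribution({"C": 2}, 0, isotope_table, window=2),
        [0.989**2, 2 * 0.989 * p, p**2], atol=1e-15)


@pytest.mark.parametrize("formula", ["C2H2O", "C3H8NSi", "SiO2", "CH4N"])
def test_shift_distribution_matches_exhaustive_enumeration(formula, isotope_table):
    counts = dict(parse_formula(formula))
    got = shift_distribution(counts, 0, isotope_table)
    want = brute_force_shift_distribution(counts, 0, isotope_table)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_shift_distribution_matches_polynomial_oracle_on_registry(registry,
                                                                  isotope_table):
    for frag in registry:
        counts = dict(frag.formula)
        got = shift_distribution(counts, frag.n_backbone, isotope_table)
        want = sympy_shift_distribution(counts, frag.n_backbone, isotope_table)
        np.testing.assert_allclose(got, want, atol=1e-12, err_msg=frag.fragment_id)


def test_shift_distribution_validates_inputs(isotope_table):
    with pytest.raises(ValueError):
        shift_distribution({"C": 1}, 2, isotope_table)
    with pytest.raises(ValueError):
        shift_distribution({"C": 1}, 0, isotope_table, window=-1)


def test_correction_matrix_identity_when_everything_monoisotopic(registry_by_id):
    mono = IsotopeTable(
        abundances={el: (1.0,) for el in ("H", "C", "N", "O", "Si")},
        c13_abundance=0.0)
    frag = registry_by_id["Serine_C1C2C3_306"]
    M = build_correction_matrix(frag, mono, CorrectionOptions(False))
    np.testing.assert_allclose(M.matrix, np.eye(4), atol=1e-15)


def test_correction_matrix_column0_is_natural_pattern(registry_by_id, isotope_table):
    frag = registry_by_id["Glycine_C2_86"]  # C3H8NSi, one backbone carbon
    M = build_correction_matrix(frag, isotope_table, CorrectionOptions(False))
    counts = dict(frag.formula)
    counts["C"] -= 1  # non-backbone part: C2H8NSi plus nothing at backbone
    want = brute_force_shift_distribution(counts, 0, isotope_table)[:2]
    np.testing.assert_allclose(M.matrix[:, 0], want, atol=1e-12)
    assert M.matrix[0, 1] == 0  # lower-triangular: labeling only adds mass


def test_purity_column_is_binomial(registry_by_id):
    mono = IsotopeTable(
        abundances={el: (1.0,) for el in ("H", "C", "N", "O", "Si")},
        c13_abundance=0.0)
    frag = registry_by_id["Serine_C2C3_204"]  # n = 2
    p = 0.97
    M = build_correction_matrix(frag, mono, CorrectionOptions(True, p))
    np.testing.assert_allclose(M.matrix[:, 2], [(1 - p)**2, 2 * p * (1 - p), p**2],
                               atol=1e-12)


def test_matrix_columns_sum_to_one_without_truncation(registry, isotope_table):
    # truncation is the only mass sink: the full isotopologue patterns are
    # probability distributions
    from c13pos.isotope_correction import isotopologue_pattern
    for frag in registry[:6]:
        for opts in (CorrectionOptions(False), CorrectionOptions(True, 0.99)):
            for j in range(frag.n_backbone + 1):
                full = isotopologue_pattern(frag, j, isotope_table, opts)
                assert full.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, len(load_fragment_table()) - 1), st.integers(0, 2**31 - 1),
       st.booleans())
def test_simulate_correct_roundtrip_recovers_random_cids(frag_i, seed, backbone):
    """Noiseless forward simulation followed by correction is the identity."""
    frag = load_fragment_table()[frag_i]
    opts = CorrectionOptions(correct_backbone=backbone, tracer_purity=0.99)
    cid = np.random.default_rng(seed).dirichlet(np.ones(frag.n_backbone + 1))
    raw = simulate_fragment_areas(frag, cid, opts=opts)
    rec = correct_areas(raw, build_correction_matrix(frag, opts=opts))
    np.testing.assert_allclose(rec.fractions, cid, atol=1e-6)


def test_correct_areas_rejects_bad_input(registry_by_id):
    frag = registry_by_id["Glycine_C2_100"]
    M = build_correction_matrix(frag)
    with pytest.raises(ValueError):
        correct_areas(np.zeros(2), M)
    with pytest.raises(ValueError):
        correct_areas(np.ones(5), M)


def test_natural_abundance_corrects_to_zero_enrichment(registry, isotope_table):
    """Full correction maps a natural-abundance cluster to M0-only (0%)."""
    opts = CorrectionOptions(True, 0.99)
    for frag in registry:
        n = frag.n_backbone
        cid0 = np.eye(n + 1)[0]
        raw = simulate_fragment_areas(frag, cid0, isotope_table, opts)
        rec = correct_areas(raw, build_correction_matrix(frag, isotope_table, opts))
        assert rec.mean_enrichment() == pytest.approx(0.0, abs=1e-6)


def test_fully_labeled_at_tracer_purity_corrects_to_full_enrichment(registry,
                                                                    isotope_table):
    opts = CorrectionOptions(True, 0.99)
    for frag in registry:
        n = frag.n_backbone
        cidn = np.eye(n + 1)[n]
        raw = simulate_fragment_areas(frag, cidn, isotope_table, opts)
        rec = correct_areas(raw, build_correction_matrix(frag, isotope_table, opts))
        assert rec.mean_enrichment() == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("cid,n,expected", [
    ((0.25, 0.5, 0.25), 2, 0.5),
    ((1, 0, 0), 2, 0.0),
    ((0, 0, 1), 2, 1.0),
    ((0.5, 0.25, 0.25), 2, 0.375),
])
def test_mean_enrichment(cid, n, expected):
    assert mean_enrichment(np.array(cid), n) == pytest.approx(expected)


def test_cid_vector_invariants():
    with pytest.raises(ValueError):
        CIDVector(np.array([0.5, 0.4]))  # does not sum to 1
    with pytest.raises(ValueError):
        CIDVector(np.array([1.5, -0.5]))
    v = CIDVector(np.array([0.25, 0.5, 0.25]))
    assert v.mean_enrichment() == pytest.approx(0.5)
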