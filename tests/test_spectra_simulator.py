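"""Forward simulator: CIDs from label states, conservation, determinism, bias."""

import itertools

import numpy as np
import pytest

from c13pos.fragment_library import METABOLITE_CARBONS
from c13pos.isotope_correction import (
    CorrectionOptions,
    build_correction_matrix,
    correct_areas,
)
from c13pos.spectra_simulator import (
    ContaminantSpec,
    LabelState,
    default_kinetics_scenario,
    fragment_cid_from_positions,
    simulate_fragment_areas,
    simulate_labeling_kinetics,
    simulate_pt_standard_dataset,
)


def enumerate_cid(probs, positions):
    """Oracle: sum isotopomer probabilities by labeled count in the subset."""
    n = len(probs)
    cid = np.zeros(len(positions) + 1)
    for pattern in itertools.product((0, 1), repeat=n):
        p = np.prod([probs[i] if b else 1 - probs[i]
                     for i, b in enumerate(pattern)])
        cid[sum(pattern[i - 1] for i in positions)] += p
    return cid


def test_fragment_cid_binomial_case(registry_by_id):
    state = LabelState("Serine", position_probs=(0.5, 0.5, 0.5))
    cid = fragment_cid_from_positions(state, registry_by_id["Serine_C2C3_204"])
    np.testing.assert_allclose(cid, [0.25, 0.5, 0.25])


def test_fragment_cid_single_labeled_position(registry_by_id):
    state = LabelState("Glycine", position_probs=(1.0, 0.0))
    cid = fragment_cid_from_positions(state, registry_by_id["Glycine_C1C2_276"])
    np.testing.assert_allclose(cid, [0.0, 1.0, 0.0])


def test_fragment_cid_matches_isotopomer_enumeration(registry_by_id, rng):
    for fid in ("Serine_C2C3_204", "Malate_C2C3C4_233", "Glutamate_C2C3C4C5_246"):
        frag = registry_by_id[fid]
        probs = rng.uniform(0, 1, METABOLITE_CARBONS[frag.metabolite])
        state = LabelState(frag.metabolite, position_probs=tuple(probs))
        got = fragment_cid_from_positions(state, frag)
        want = enumerate_cid(probs, frag.backbone_positions)
        np.testing.assert_allclose(got, want, atol=1e-12)


def test_serine_c2_only_labeling(registry_by_id):
    e = 0.31
    state = LabelState("Serine", position_probs=(0.0, e, 0.0))
    cid = fragment_cid_from_positions(state, registry_by_id["Serine_C2C3_204"])
    np.testing.assert_allclose(cid, [1 - e, e, 0.0], atol=1e-12)


def test_explicit_isotopomer_distribution(registry_by_id):
    # equal mix of unlabeled and C2-labeled glycine, as GDC/SHMT produces
    state = LabelState("Glycine",
                       isotopomer_probs={(0, 0): 0.5, (0, 1): 0.5})
    cid = fragment_cid_from_positions(state, registry_by_id["Glycine_C2_100"])
    np.testing.assert_allclose(cid, [0.5, 0.5])
    cid12 = fragment_cid_from_positions(state, registry_by_id["Glycine_C1C2_276"])
    np.testing.assert_allclose(cid12, [0.5, 0.5, 0.0])


def test_label_state_validation():
    with pytest.raises(ValueError):
        LabelState("Serine", position_probs=(0.5, 0.5))  # wrong length
    with pytest.raises(ValueError):
        LabelState("Serine", position_probs=(0.5, 1.5, 0.0))
    with pytest.raises(ValueError):
        LabelState("Glycine", isotopomer_probs={(0, 0): 0.6, (1, 1): 0.6})
    with pytest.raises(ValueError):
        LabelState("Glycine")


def test_unlabeled_limit_is_natural_cluster(registry_by_id, isotope_table):
    from c13pos.isotope_correction import shift_distribution
    frag = registry_by_id["Alanine_C2C3_116"]
    cid = np.array([1.0, 0.0, 0.0])
    areas = simulate_fragment_areas(frag, cid, isotope_table,
                                    CorrectionOptions(True, 0.99),
                                    total_area=1.0, truncate=False)
    want = shift_distribution(frag.formula, 0, isotope_table)
    np.testing.assert_allclose(areas, want, atol=1e-12)


def test_area_conservation_before_noise(registry_by_id, isotope_table):
    frag = registry_by_id["Proline_C2C3C4C5_216"]
    cid = np.array([0.2, 0.3, 0.1, 0.25, 0.15])
    contam = ContaminantSpec("Proline_C2C3C4C5_216", mz_offset=2,
                             relative_intensity=0.1)
    areas = simulate_fragment_areas(frag, cid, isotope_table,
                                    contaminants=[contam], total_area=1e6,
                                    truncate=False)
    assert areas.sum() == pytest.approx(1e6 * 1.1, rel=1e-12)


def test_determinism_under_fixed_seed():
    a = simulate_pt_standard_dataset(["Glycine"], noise_cv=0.05, seed=11)
    b = simulate_pt_standard_dataset(["Glycine"], noise_cv=0.05, seed=11)
    c = simulate_pt_standard_dataset(["Glycine"], noise_cv=0.05, seed=12)
    assert a[0].rows == b[0].rows
    assert a[0].rows != c[0].rows


def test_pt_standard_mean_enrichments_are_half(registry_by_id):
    samples = simulate_pt_standard_dataset(n_replicates=2, noise_cv=0.0, seed=0)
    opts = CorrectionOptions(correct_backbone=False)
    for s in samples:
        for fid, frag in registry_by_id.items():
            raw = s.areas_for(fid)
            rec = correct_areas(raw, build_correction_matrix(frag, opts=opts))
            assert rec.mean_enrichment() == pytest.approx(0.5, abs=1e-9), fid


def test_pt_standard_cid_rescales_to_pascal_row(registry_by_id):
    samples = simulate_pt_standard_dataset(["Alanine"], n_replicates=1,
                                           noise_cv=0.0, seed=0)
    frag = registry_by_id["Alanine_C1C2_218"]  # 2 backbone carbons
    rec = correct_areas(samples[0].areas_for(frag.fragment_id),
                        build_correction_matrix(frag))
    np.testing.assert_allclose(rec.fractions * 2**2, [1, 2, 1], atol=1e-9)


def test_contaminant_at_plus_two_biases_enrichment_upward(registry_by_id):
    """A co-eluting ion two mass units above M0 inflates apparent labeling."""
    frag = registry_by_id["Proline_C2C3C4C5_216"]
    state = LabelState("Proline", position_probs=(0.1,) * 5)
    cid = fragment_cid_from_positions(state, frag)
    M = build_correction_matrix(frag)
    clean = correct_areas(simulate_fragment_areas(frag, cid), M)
    contam = ContaminantSpec("Proline_C2C3C4C5_216", mz_offset=2,
                             relative_intensity=0.05)
    dirty = correct_areas(
        simulate_fragment_areas(frag, cid, contaminants=[contam]), M)
    assert clean.mean_enrichment() == pytest.approx(0.1, abs=1e-9)
    assert dirty.mean_enrichment() > clean.mean_enrichment() + 0.001


def test_kinetics_scenario_ground_truth_structure():
    scenario = default_kinetics_scenario()
    ser_light = next(s for s in scenario[("light", 6.0)] if s.metabolite == "Serine")
    assert ser_light.position_probs[0] == 0.0
    assert ser_light.position_probs[1] > 0.0
    assert ser_light.position_probs[2] == 0.0
    ser_dark = next(s for s in scenario[("dark", 6.0)] if s.metabolite == "Serine")
    assert all(p == 0.0 for p in ser_dark.position_probs)
    glu_l = next(s for s in scenario[("light", 4.0)] if s.metabolite == "Glutamate")
    glu_d = next(s for s in scenario[("dark", 4.0)] if s.metabolite == "Glutamate")
    assert glu_d.position_probs[0] > glu_l.position_probs[0]
    for cond in ("light", "dark"):
        for s in scenario[(cond, 0.0)]:
            assert all(p == 0.0 for p in s.position_probs)


def test_kinetics_t0_corrects_to_zero(registry_by_id):
    samples = simulate_labeling_kinetics(n_replicates=1, noise_cv=0.0, seed=5)
    t0 = [s for s in samples if s.time_point == 0.0]
    opts = CorrectionOptions(True, 0.99)
    for s in t0:
        for fid in ("Serine_C2_100", "Glutamate_C1C2C3C4C5_348"):
            frag = registry_by_id[fid]
            rec = correct_areas(s.areas_for(fid),
                                build_correction_matrix(frag, opts=opts))
            assert rec.mean_enrichment() == pytest.approx(0.0, abs=1e-9)
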