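"""Synthetic-structure generator: builds, perturbations, ensembles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from helixbend import (
    FiberParameters,
    MismatchGeometrySpec,
    PerturbationSpec,
    apply_bend,
    apply_kink,
    apply_overextension,
    bending_angle,
    build_ideal_duplex,
    build_mismatch_pair,
    build_repeat_construct,
    classify_pair_state,
    count_collapsed,
    duplex_pair_frames,
    generate_ensemble,
    groove_widths,
    helical_axis,
    infer_pairing,
    kink_angle,
    step_parameters,
    write_pdb,
    read_pdb,
    Ensemble,
)
from helixbend.generate import TABLE_CONSTRUCTS, apply_groove_modulation


def _bend_of(c):
    frames, _ = duplex_pair_frames(c)
    return bending_angle(helical_axis(frames)).bending_angle


def test_two_bp_build_recovers_fiber():
    c = build_ideal_duplex("GC")
    frames, _ = duplex_pair_frames(c)
    p = step_parameters(frames[0], frames[1])
    assert np.allclose(p.as_tuple(), (0, 0, 32.0, 0, 0, 2.81), atol=1e-6)


def test_straight_build_has_no_bend(ideal24):
    assert _bend_of(ideal24) < 2.0


def test_average_rise_matches_relaxed_value(ideal24):
    frames, _ = duplex_pair_frames(ideal24)
    rises = [
        step_parameters(frames[s], frames[s + 1]).rise
        for s in range(len(frames) - 1)
    ]
    assert round(float(np.mean(rises)), 1) == 2.8


def test_invalid_sequences_rejected():
    with pytest.raises(ValueError, match="non-AUGC"):
        build_ideal_duplex("GCTA")
    with pytest.raises(ValueError):
        build_ideal_duplex("G")


def test_construct_bookkeeping(cag20, cag20_pm):
    assert cag20.n_pairs == 64
    assert len(cag20_pm.mismatch_indices) == 20
    a2 = build_repeat_construct("2xAUUCU")
    assert a2.n_pairs == 14
    pm = infer_pairing(a2)
    loops = pm.internal_loops()
    assert len(loops) == 2 and all(len(lp) == 3 for lp in loops)
    # each 3x3 loop reads UCU against UCU
    for lp in loops:
        assert "".join(a2.residue_name("A", i) for i in lp) == "UCU"
    assert len(TABLE_CONSTRUCTS) == 12
    with pytest.raises(KeyError):
        build_repeat_construct("7xGGGG")


def test_wc_control_has_no_mismatches():
    wc = build_repeat_construct("2xCAG-WC")
    pm = infer_pairing(wc)
    assert len(pm.mismatch_indices) == 0
    for i, j, _ in pm.pairs:
        st = classify_pair_state(wc, (i, j))
        assert st.count >= 2  # every pair holds canonical WC bonds


def test_bend_zero_is_identity(ideal40):
    assert np.array_equal(apply_bend(ideal40, 0.0).coords, ideal40.coords)


def test_bend_round_trip(ideal40):
    assert _bend_of(apply_bend(ideal40, 40.0)) == pytest.approx(40.0, abs=5.0)


def test_bend_out_of_range_refused(ideal40):
    with pytest.raises(ValueError):
        apply_bend(ideal40, 130.0)
    with pytest.raises(ValueError):
        apply_bend(ideal40, -1.0)


def test_bend_increases_collapse(ideal40):
    pm = infer_pairing(ideal40)
    c0 = count_collapsed(groove_widths(ideal40, pm)).count
    c60 = count_collapsed(groove_widths(apply_bend(ideal40, 60.0), pm)).count
    assert c60 > c0


def test_kink_zero_is_identity(ideal60):
    assert np.array_equal(apply_kink(ideal60, 30, 0.0).coords, ideal60.coords)


def test_kink_round_trip(ideal60):
    k = apply_kink(ideal60, 30, 70.0)
    frames, _ = duplex_pair_frames(k)
    res = kink_angle(helical_axis(frames).restrict(5))
    assert res.kink_detected
    assert res.kink_angle == pytest.approx(70.0, abs=5.0)
    assert res.kink_step + 5 == pytest.approx(30, abs=2)


@pytest.mark.parametrize("angle", [50.0, 60.0, 70.0, 80.0, 90.0])
def test_kink_regime_recovered(ideal60, angle):
    k = apply_kink(ideal60, 30, angle)
    frames, _ = duplex_pair_frames(k)
    res = kink_angle(helical_axis(frames).restrict(5))
    assert res.kink_detected
    assert res.kink_angle == pytest.approx(angle, abs=5.0)


def test_kink_terminal_region_refused(ideal60):
    for bad in (3, 55):
        with pytest.raises(ValueError, match="kink_step"):
            apply_kink(ideal60, bad, 40.0)


def test_overextension_round_trip(ideal24):
    oe = apply_overextension(ideal24, 28.0, 3.4)
    frames, _ = duplex_pair_frames(oe)
    params = np.array(
        [
            step_parameters(frames[s], frames[s + 1]).as_tuple()
            for s in range(len(frames) - 1)
        ]
    )
    assert np.allclose(params[:, 2], 28.0, atol=1e-6)
    assert np.allclose(params[:, 5], 3.4, atol=1e-6)


def test_overextension_identity_at_defaults(ideal24):
    same = apply_overextension(ideal24, 32.0, 2.81)
    assert np.max(np.abs(same.coords - ideal24.coords)) < 1e-6


def test_overextension_widens_major_groove_everywhere(ideal24):
    pm = infer_pairing(ideal24)
    a = groove_widths(ideal24, pm).Mgw
    b = groove_widths(apply_overextension(ideal24, 28.0, 3.4), pm).Mgw
    both = np.isfinite(a) & np.isfinite(b)
    assert both.sum() > 5
    assert np.all(b[both] > a[both])


def test_overextension_preconditions(ideal24):
    with pytest.raises(ValueError):
        apply_overextension(ideal24, 35.0, 3.4)
    with pytest.raises(ValueError):
        apply_overextension(ideal24, 28.0, 2.5)


def test_groove_modulation_narrows_target_steps(ideal40):
    pm = infer_pairing(ideal40)
    profile = np.ones(39)
    profile[15:20] = 0.8
    mod = apply_groove_modulation(ideal40, profile)
    a = groove_widths(ideal40, pm).Mgw
    b = groove_widths(mod, pm).Mgw
    assert np.nanmean(b[15:20]) < np.nanmean(a[15:20])


def test_ensemble_seeded_determinism(ideal40):
    spec = PerturbationSpec(bend_total=30, noise_sigma=0.3, n_models=10, seed=1)
    e1, t1 = generate_ensemble(ideal40, spec)
    e2, t2 = generate_ensemble(ideal40, spec)
    assert np.array_equal(e1.coords(), e2.coords())
    assert t1.equals(t2)


def test_ensemble_without_perturbation_is_constant(ideal40):
    ens, _ = generate_ensemble(
        ideal40, PerturbationSpec(bend_total=0, noise_sigma=0, n_models=4, seed=2)
    )
    for m in ens:
        assert np.array_equal(m.coords, ideal40.coords)


def test_imposed_and_recovered_bends_rank_correlate(ideal40):
    ens, truth = generate_ensemble(
        ideal40,
        PerturbationSpec(bend_total=60, noise_sigma=0.3, n_models=60, seed=5),
    )
    recovered = [_bend_of(m) for m in ens]
    rho = spearmanr(truth["bend_imposed"], recovered).statistic
    assert rho > 0.9


def test_generated_models_survive_pdb_round_trip(ideal40, tmp_path):
    ens, _ = generate_ensemble(
        ideal40, PerturbationSpec(bend_total=45, noise_sigma=0.2, n_models=3, seed=9)
    )
    path = tmp_path / "e.pdb"
    write_pdb(ens, path)
    back = read_pdb(path)
    assert np.max(np.abs(back.coords() - ens.coords())) <= 1.5e-3


@pytest.mark.parametrize(
    "pair_type,count",
    [("UU", 2), ("AA", 0), ("GC", 3), ("CC", 1), ("CU", 2), ("AU", 2)],
)
def test_mismatch_pair_hits_target_count(pair_type, count):
    c = build_mismatch_pair(MismatchGeometrySpec(pair_type, count))
    assert classify_pair_state(c, (1, 1)).count == count


def test_unachievable_mismatch_target_rejected():
    with pytest.raises(ValueError):
        build_mismatch_pair(MismatchGeometrySpec("CC", 3))
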