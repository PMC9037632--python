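"""Curvilinear axis, bending/kink measurement, theta coordinate."""

import numpy as np
import pytest

from helixbend import (
    apply_bend,
    apply_kink,
    bending_angle,
    build_ideal_duplex,
    duplex_pair_frames,
    helical_axis,
    infer_pairing,
    kink_angle,
    theta_profile,
)
from helixbend.bending import bend_category
from helixbend.generate import _pair_atom_groups
from helixbend.geometry import angle_between, rotation_about_axis
from helixbend.io import StructureError


def _axis_of(c, smoothing=3):
    frames, _ = duplex_pair_frames(c)
    return helical_axis(frames, smoothing)


def test_straight_axis_vectors_parallel(ideal24):
    ax = _axis_of(ideal24)
    for v in ax.axis_vectors:
        assert angle_between(v, ax.axis_vectors[0]) < 0.5
    # axis points sit on the construction axis (x = y = 0)
    assert np.max(np.abs(ax.axis_points[:, :2])) < 1e-6


def test_arc_axis_turns_by_imposed_angle(ideal40):
    bent = apply_bend(ideal40, 40.0)
    ax = _axis_of(bent)
    turn = angle_between(ax.axis_vectors[2], ax.axis_vectors[-3])
    assert turn == pytest.approx(40.0, abs=3.0)


def test_axis_equivariance_under_rotation(ideal40):
    bent = apply_bend(ideal40, 30.0)
    R = rotation_about_axis([0.3, 1.0, -0.2], 71.0)
    moved = bent.with_coords(bent.coords @ R.T)
    a1, a2 = _axis_of(bent), _axis_of(moved)
    assert np.allclose(a2.axis_vectors, a1.axis_vectors @ R.T, atol=1e-6)
    assert np.allclose(a2.axis_points, a1.axis_points @ R.T, atol=1e-5)


def test_straight_helix_not_bent(ideal24):
    res = bending_angle(_axis_of(ideal24))
    assert res.bending_angle < 2.0
    assert res.category == "moderate"


def test_bend_round_trip_with_category(ideal40):
    res = bending_angle(_axis_of(apply_bend(ideal40, 40.0)))
    assert res.bending_angle == pytest.approx(40.0, abs=5.0)
    res45 = bending_angle(_axis_of(apply_bend(ideal40, 45.0)))
    assert res45.category == "strong"


def test_terminal_perturbation_does_not_change_bending(ideal40):
    groups = _pair_atom_groups(ideal40)
    coords = ideal40.coords.copy()
    rng = np.random.default_rng(4)
    n = ideal40.n_pairs
    for g in groups[:5] + groups[n - 5:]:
        coords[g] += rng.normal(0, 0.5, size=(len(g), 3))
    perturbed = ideal40.with_coords(coords)
    a = bending_angle(_axis_of(ideal40)).bending_angle
    b = bending_angle(_axis_of(perturbed)).bending_angle
    assert abs(a - b) < 1.0


def test_bending_invariant_under_chain_reversal(ideal40):
    bent = apply_bend(ideal40, 35.0)
    frames, _ = duplex_pair_frames(bent)
    fwd = bending_angle(helical_axis(frames)).bending_angle
    rev = bending_angle(helical_axis(frames[::-1])).bending_angle
    assert fwd == pytest.approx(rev, abs=1e-6)


def test_bend_categories():
    assert bend_category(10.0) == "moderate"
    assert bend_category(45.0) == "strong"
    assert bend_category(55.0) == "extreme"


def test_too_short_after_exclusion():
    c = build_ideal_duplex("GCAUGCAUGCAU")  # 12 bp
    with pytest.raises(StructureError, match="short"):
        bending_angle(_axis_of(c), exclude_terminal=5)


def test_straight_helix_has_no_kink(ideal24):
    res = kink_angle(_axis_of(ideal24).restrict(5))
    assert not res.kink_detected


def test_smooth_bend_is_not_a_kink(ideal60):
    res = kink_angle(_axis_of(apply_bend(ideal60, 60.0)).restrict(5))
    assert not res.kink_detected


def test_kink_detection_and_geometry(ideal60):
    res = kink_angle(_axis_of(apply_kink(ideal60, 30, 70.0)).restrict(5))
    assert res.kink_detected
    assert res.fit_residual_gain >= 0.4
    assert res.kink_angle == pytest.approx(70.0, abs=5.0)
    assert res.kink_step + 5 == pytest.approx(30, abs=2)


def test_kink_needs_enough_steps(ideal24):
    with pytest.raises(StructureError, match="10"):
        kink_angle(_axis_of(ideal24).restrict(8))


def test_theta_constant_for_uniform_helix():
    c = build_ideal_duplex("G" * 24)
    tp = theta_profile(c)
    assert len(tp.theta) == 22
    assert np.std(tp.theta) < 1.0
    # closed-form chord angle of a circular helix through the pair centroids
    r = np.hypot(tp.com_points[0][0], tp.com_points[0][1])
    t, h = np.radians(32.0), 2.81
    chord = 2 * r * np.sin(t / 2)
    expect = np.degrees(np.arccos((chord**2 * np.cos(t) + h**2) / (chord**2 + h**2)))
    assert np.mean(tp.theta) == pytest.approx(expect, abs=1e-6)


def test_theta_zero_for_collinear_coms(ideal24):
    # slide every pair so its centroid lies on the z axis
    groups = _pair_atom_groups(ideal24)
    coords = ideal24.coords.copy()
    for g in groups:
        com = coords[g].mean(axis=0)
        coords[g] -= [com[0], com[1], 0.0]
    tp = theta_profile(ideal24.with_coords(coords))
    assert np.allclose(tp.theta, 0.0, atol=1e-6)


def test_theta_peaks_at_hinge(ideal60):
    kinked = apply_kink(ideal60, 30, 70.0)
    tp = theta_profile(kinked)
    peak = int(np.argmax(tp.theta)) + 1  # inner-step numbering
    assert abs(peak - 30) <= 2
    assert len(tp.theta) == ideal60.n_pairs - 2
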