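"""Base-frame fitting, pair frames, step parameters, chi, pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixbend import (
    FiberParameters,
    build_ideal_duplex,
    build_repeat_construct,
    chi_torsion,
    duplex_pair_frames,
    fit_base_frame,
    infer_pairing,
    pair_frame,
    step_parameters,
)
from helixbend.frames import Frame, is_flipped
from helixbend.geometry import rotation_about_axis
from helixbend.io import StructureError
from helixbend.templates import base_template


def test_fit_identity_on_template():
    tpl = base_template("G")
    f = fit_base_frame(tpl, "G")
    assert np.allclose(f.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(f.origin, 0.0, atol=1e-12)
    assert f.fit_rmsd < 1e-12


def test_fit_recovers_known_rigid_motion():
    R = rotation_about_axis([1.0, 2.0, -0.5], 37.3)
    t = np.array([5.0, -3.0, 11.0])
    tpl = base_template("U")
    moved = {k: R @ v + t for k, v in tpl.items()}
    f = fit_base_frame(moved, "U")
    assert np.allclose(f.rotation, R, atol=1e-9)
    assert np.allclose(f.origin, t, atol=1e-9)


def test_generator_residue_fits_cleanly(ideal24):
    for chain, rid in (("A", 3), ("B", 7)):
        res = ideal24.residue(chain, rid)
        f = fit_base_frame(res, ideal24.residue_name(chain, rid))
        assert f.fit_rmsd < 0.05


def test_fit_missing_ring_atoms_raises():
    tpl = base_template("A")
    tpl.pop("N7")
    with pytest.raises(StructureError, match="ring"):
        fit_base_frame(tpl, "A")


def test_pair_frame_idempotent_for_perfect_pair():
    R = rotation_about_axis([0.3, 1.0, 0.2], 25.0)
    t = np.array([1.0, 2.0, 3.0])
    f1 = Frame(origin=t, rotation=R)
    flip = np.diag([1.0, -1.0, -1.0])
    f2 = Frame(origin=t, rotation=R @ flip)
    pf = pair_frame(f1, f2)
    assert np.allclose(pf.rotation, R, atol=1e-9)
    assert np.allclose(pf.origin, t, atol=1e-9)


def test_pair_frame_bisects_symmetric_buckle():
    base = np.eye(3)
    flip = np.diag([1.0, -1.0, -1.0])
    buckle = 14.0
    f1 = Frame(origin=np.zeros(3), rotation=rotation_about_axis([1, 0, 0], +buckle))
    f2 = Frame(
        origin=np.zeros(3),
        rotation=rotation_about_axis([1, 0, 0], -buckle) @ base @ flip,
    )
    pf = pair_frame(f1, f2)
    # brute-force average: the bisecting frame is the identity
    assert np.allclose(pf.rotation, np.eye(3), atol=1e-9)


def test_ideal_pair_frames_align_with_helix_axis(ideal24):
    frames, flipped = duplex_pair_frames(ideal24)
    assert not any(flipped)
    for k, f in enumerate(frames):
        assert np.allclose(f.z, [0, 0, 1], atol=1e-6)


def test_step_pure_translation():
    f1 = Frame(origin=np.zeros(3), rotation=np.eye(3))
    f2 = Frame(origin=np.array([0.0, 0.0, 3.4]), rotation=np.eye(3))
    p = step_parameters(f1, f2)
    assert p.rise == pytest.approx(3.4, abs=1e-12)
    for v in (p.tilt, p.roll, p.twist, p.shift, p.slide):
        assert v == pytest.approx(0.0, abs=1e-12)


def test_ideal_duplex_steps_recover_fiber_exactly(ideal24):
    frames, _ = duplex_pair_frames(ideal24)
    for s in range(len(frames) - 1):
        p = step_parameters(frames[s], frames[s + 1])
        assert np.allclose(
            p.as_tuple(), (0, 0, 32.0, 0, 0, 2.81), atol=1e-6
        )


def test_step_reversal_symmetry(ideal40):
    frames, _ = duplex_pair_frames(ideal40)
    f1, f2 = frames[10], frames[11]
    # perturb to make all six parameters nonzero
    R = rotation_about_axis([0.2, 1.0, 0.1], 5.0)
    f2 = Frame(origin=f2.origin + [0.3, -0.2, 0.1], rotation=R @ f2.rotation)
    fwd = step_parameters(f1, f2)
    flip = np.diag([1.0, -1.0, -1.0])  # reversing 5'->3' flips y and z
    r1 = Frame(origin=f2.origin, rotation=f2.rotation @ flip)
    r2 = Frame(origin=f1.origin, rotation=f1.rotation @ flip)
    rev = step_parameters(r1, r2)
    assert rev.twist == pytest.approx(fwd.twist, abs=1e-9)
    assert rev.rise == pytest.approx(fwd.rise, abs=1e-9)
    assert rev.roll == pytest.approx(fwd.roll, abs=1e-9)
    assert rev.slide == pytest.approx(fwd.slide, abs=1e-9)
    assert rev.tilt == pytest.approx(-fwd.tilt, abs=1e-9)
    assert rev.shift == pytest.approx(-fwd.shift, abs=1e-9)


def test_antiparallel_step_is_signalled():
    f1 = Frame(origin=np.zeros(3), rotation=np.eye(3))
    f2 = Frame(
        origin=np.array([0, 0, 3.0]),
        rotation=rotation_about_axis([1, 0, 0], 180.0),
    )
    with pytest.raises(StructureError, match="antiparallel"):
        step_parameters(f1, f2)
    assert is_flipped(f1, Frame(origin=np.zeros(3), rotation=np.eye(3)))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    twist=st.floats(min_value=20.0, max_value=45.0),
    rise=st.floats(min_value=2.3, max_value=3.4),
)
def test_steps_uniform_for_any_fiber(twist, rise):
    """Step parameters of an ideal helix are uniform and equal the fiber."""
    c = build_ideal_duplex("GCAUGCAU", FiberParameters(twist=twist, rise=rise))
    frames, _ = duplex_pair_frames(c)
    params = np.array(
        [step_parameters(frames[s], frames[s + 1]).as_tuple() for s in range(7)]
    )
    assert np.allclose(params, params[0], atol=1e-6)
    assert params[0, 2] == pytest.approx(twist, abs=1e-6)
    assert params[0, 5] == pytest.approx(rise, abs=1e-6)
    # all returned rotations proper orthonormal
    for f in frames:
        assert np.allclose(f.rotation.T @ f.rotation, np.eye(3), atol=1e-9)
        assert np.linalg.det(f.rotation) == pytest.approx(1.0, abs=1e-9)


def test_chi_windows(ideal24):
    res = ideal24.residue("A", 2)
    state = chi_torsion(res, ideal24.residue_name("A", 2))
    assert state.classification == "anti"
    # rotate O4' about the glycosidic bond to place chi at +60 (syn)
    base = ideal24.residue_name("A", 2)
    from helixbend.templates import GLYCOSIDIC_N

    n, c1 = res[GLYCOSIDIC_N[base]], res["C1'"]
    axis = c1 - n
    # orient the rotation axis so a positive rotation increases chi
    probe = dict(res)
    probe["O4'"] = rotation_about_axis(axis, 5.0) @ (res["O4'"] - c1) + c1
    if chi_torsion(probe, base).chi < state.chi:
        axis = -axis
    for target, expect in ((60.0, "syn"), (-158.0, "anti"), (120.0, "intermediate")):
        delta = target - state.chi
        moved = dict(res)
        moved["O4'"] = rotation_about_axis(axis, delta) @ (res["O4'"] - c1) + c1
        got = chi_torsion(moved, base)
        assert got.classification == expect
        assert got.chi == pytest.approx(target, abs=1e-6)


def test_pairing_of_repeat_constructs(cag20, cag20_pm):
    assert cag20_pm.n_pairs == 64
    assert len(cag20_pm.mismatch_indices) == 20
    # every mismatch in 20xCAG is an A/A pair
    for i in cag20_pm.mismatch_indices:
        assert cag20.residue_name("A", i) == "A"
        assert cag20.residue_name("B", 65 - i) == "A"
    ccug = build_repeat_construct("4xCCUG")
    pm = infer_pairing(ccug)
    assert pm.internal_loops() == [(2, 3), (6, 7), (10, 11), (14, 15)]
    wc = build_repeat_construct("20xCAG-WC")
    assert len(infer_pairing(wc).mismatch_indices) == 0
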