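"""Clustering, average structures, bending tables, 2D distributions."""

import numpy as np
import pytest
from scipy.stats import chisquare

from helixbend import (
    Ensemble,
    PerturbationSpec,
    average_structure,
    bending_angle,
    bending_table,
    duplex_pair_frames,
    generate_ensemble,
    helical_axis,
    hist2d,
    kmeans_cluster,
)
from helixbend.geometry import rotation_about_axis
from helixbend.stats import pool_loops


def test_single_cluster_is_everything(ideal24):
    ens, _ = generate_ensemble(
        ideal24, PerturbationSpec(noise_sigma=0.1, n_models=6, seed=0)
    )
    res = kmeans_cluster(ens, 1, seed=0)
    assert res.k == 1
    assert np.all(res.labels == 0)
    assert res.populations[0] == pytest.approx(100.0)


def test_kmeans_seeded_determinism(ideal24):
    ens, _ = generate_ensemble(
        ideal24, PerturbationSpec(bend_total=40, noise_sigma=0.3, n_models=12, seed=3)
    )
    a = kmeans_cluster(ens, 3, seed=7)
    b = kmeans_cluster(ens, 3, seed=7)
    assert np.array_equal(a.labels, b.labels)


def test_kmeans_recovers_separable_subpopulations(ideal40):
    from helixbend import apply_bend

    rng = np.random.default_rng(1)
    bent_base = apply_bend(ideal40, 70.0)
    models = [
        ideal40.with_coords(ideal40.coords + rng.normal(0, 0.2, ideal40.coords.shape))
        for _ in range(28)
    ] + [
        bent_base.with_coords(bent_base.coords + rng.normal(0, 0.2, bent_base.coords.shape))
        for _ in range(12)
    ]
    mix = Ensemble(models)
    res = kmeans_cluster(mix, 2, seed=0)
    pops = sorted(res.populations)
    assert pops[0] == pytest.approx(30.0, abs=5.0)
    assert pops[1] == pytest.approx(70.0, abs=5.0)


def test_kmeans_invalid_k(ideal24):
    ens, _ = generate_ensemble(ideal24, PerturbationSpec(n_models=4, seed=0))
    with pytest.raises(ValueError):
        kmeans_cluster(ens, 5, seed=0)
    with pytest.raises(ValueError):
        kmeans_cluster(ens, 0, seed=0)


def test_clustering_invariant_under_rigid_motion(ideal40):
    ens, _ = generate_ensemble(
        ideal40, PerturbationSpec(bend_total=60, noise_sigma=0.2, n_models=14, seed=6)
    )
    R = rotation_about_axis([1, 1, 1], 100.0)
    moved = Ensemble([m.with_coords(m.coords @ R.T + 25.0) for m in ens])
    a = kmeans_cluster(ens, 3, seed=1)
    b = kmeans_cluster(moved, 3, seed=1)
    assert np.array_equal(a.labels, b.labels)


def test_average_of_identical_copies(ideal24):
    ens = Ensemble([ideal24, ideal24, ideal24])
    avg = average_structure(ens, np.zeros(3, dtype=int), 0)
    assert np.max(np.abs(avg.coords - ideal24.coords)) < 1e-9


def test_average_of_mirror_perturbations(ideal24):
    rng = np.random.default_rng(8)
    delta = rng.normal(0, 0.2, size=ideal24.coords.shape)
    ens = Ensemble(
        [ideal24.with_coords(ideal24.coords + delta),
         ideal24.with_coords(ideal24.coords - delta)]
    )
    avg = average_structure(ens, np.zeros(2, dtype=int), 0)
    # mirror pair averages back to the unperturbed structure (up to the
    # superposition of the two members)
    assert np.max(np.abs(avg.coords - ideal24.coords)) < 0.05


def test_average_structure_of_bend_cluster(ideal40):
    from helixbend import apply_bend

    rng = np.random.default_rng(4)
    bent = apply_bend(ideal40, 40.0)
    ens = Ensemble(
        [bent.with_coords(bent.coords + rng.normal(0, 0.2, bent.coords.shape))
         for _ in range(10)]
    )
    avg = average_structure(ens, np.zeros(10, dtype=int), 0)
    frames, _ = duplex_pair_frames(avg)
    ang = bending_angle(helical_axis(frames)).bending_angle
    assert ang == pytest.approx(40.0, abs=5.0)


def test_average_empty_cluster_raises(ideal24):
    ens = Ensemble([ideal24])
    with pytest.raises(ValueError):
        average_structure(ens, np.zeros(1, dtype=int), 3)


def test_bending_table_hand_example():
    angles = [10, 25, 35, 45, 55, 65]
    pops = [100.0 / 6] * 6
    t = bending_table(angles, pops)
    assert np.allclose(t.percent, 100.0 / 6)
    assert t.average_angle == pytest.approx(39.1667, abs=1e-3)
    assert t.percent.sum() == pytest.approx(100.0)


def test_bending_table_degenerate_and_errors():
    t = bending_table([10.0], [100.0])
    assert t.percent[0] == pytest.approx(100.0)
    assert np.all(t.percent[1:] == 0)
    with pytest.raises(ValueError):
        bending_table([10.0, 200.0], [50.0, 50.0])
    with pytest.raises(ValueError):
        bending_table([10.0], [90.0])


def test_bin_edges_left_closed():
    t = bending_table([20.0, 40.0, 60.0], [30.0, 30.0, 40.0])
    assert t.percent[1] == pytest.approx(30.0)  # 20 falls in 20-30
    assert t.percent[3] == pytest.approx(30.0)  # 40 falls in 40-50
    assert t.percent[5] == pytest.approx(40.0)  # 60 falls in >60


def test_hist2d_single_point_and_normalization():
    h = hist2d([3.0], [4.0], bins=5)
    assert h.density.sum() == pytest.approx(1.0)
    assert (h.density == 1.0).sum() == 1
    with pytest.raises(ValueError):
        hist2d([1.0, 2.0], [1.0])


def test_hist2d_uniform_series_approaches_uniform_density():
    rng = np.random.default_rng(0)
    n = 100_000
    h = hist2d(rng.uniform(0, 1, n), rng.uniform(0, 1, n), bins=5,
               range_=((0, 1), (0, 1)))
    counts = (h.density * n).ravel()
    stat = chisquare(counts)
    assert stat.pvalue > 1e-3
    assert h.density.sum() == pytest.approx(1.0)


def test_pool_loops_symmetry_augmentation(cag20, cag20_pm):
    ens = Ensemble([cag20])
    X, prov = pool_loops(ens, cag20_pm)
    # 20 loops -> 18 retained, each with a strand-swapped copy
    assert X.shape[0] == 36
    assert sum(1 for _, lid in prov if lid < 0) == 18
    # symmetric copy of a symmetric loop has the same centred coordinates
    assert X.shape[1] == X.shape[1]
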