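"""Rigid-body ensemble simulation, distance series and PCA spectrum."""

import numpy as np
import pytest

from photosys.ensemble import (Conformer, Ensemble, EnsembleSpec,
                               estimate_max_angle, interface_pivot,
                               pair_distance_series, pca_modes,
                               rotation_matrix, simulate_ensemble)
from photosys.synth import random_rotation

CROSS_PAIR = (("P", 888), ("P2", 888))


def _moving(manifest):
    return {c for c, g in manifest["grouping"].items() if g == "M2"}


def test_zero_angle_zero_noise_is_static(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=5, max_angle=0.0,
                        seed=1)
    ens = simulate_ensemble(model, spec)
    for conf in ens.conformers:
        np.testing.assert_allclose(conf.coords, ens.rest_coords, atol=1e-9)


def test_same_seed_bit_identical(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=20, seed=42)
    e1 = simulate_ensemble(model, spec)
    e2 = simulate_ensemble(model, spec)
    for c1, c2 in zip(e1.conformers, e2.conformers):
        assert c1.angle == c2.angle
        assert (c1.coords == c2.coords).all()


def test_sampled_angles_bounded_and_max_approached(dimer_fixture):
    """Order statistics: with n = 10,000 uniform angles the empirical
    maximum lies within 0.5° of the 13° bound."""
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=10_000,
                        max_angle=13.0, seed=3)
    ens = simulate_ensemble(model, spec)
    angles = np.array([c.angle for c in ens.conformers])
    assert (angles <= 13.0).all()
    assert angles.max() > 12.5


def test_empty_moving_group_raises(dimer_fixture):
    _, _, model = dimer_fixture
    with pytest.raises(ValueError):
        simulate_ensemble(model, EnsembleSpec({"NOPE"}, n_conformers=3))


def test_spec_validation():
    with pytest.raises(ValueError):
        EnsembleSpec({"A"}, n_conformers=1)
    with pytest.raises(ValueError):
        EnsembleSpec({"A"}, n_conformers=5, max_angle=200.0)


def test_within_group_distance_is_rigid(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=50, seed=5)
    ens = simulate_ensemble(model, spec)
    summary = pair_distance_series(ens, [(("P2", 601), ("P2", 888))])
    s = summary.series[0]
    assert s.max - s.min == pytest.approx(0.0, abs=1e-9)


def test_cross_pair_respects_analytic_displacement_bound(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=400, max_angle=13.0,
                        seed=6)
    ens = simulate_ensemble(model, spec)
    summary = pair_distance_series(ens, [CROSS_PAIR])
    s = summary.series[0]
    mg = model.find_residue("P2", 888).mg.pos
    lever = np.linalg.norm(mg - ens.pivot)
    d0 = manifest["spec"]["cross_pair_distance"]
    slack = 2 * lever * np.sin(np.deg2rad(13.0) / 2) + 1e-6
    assert s.min >= d0 - slack
    assert s.max <= d0 + slack


def test_zero_angle_distances_equal_input(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=4, max_angle=0.0,
                        seed=9)
    summary = pair_distance_series(simulate_ensemble(model, spec),
                                   [CROSS_PAIR])
    d0 = manifest["spec"]["cross_pair_distance"]
    np.testing.assert_allclose(summary.series[0].distances, d0, atol=1e-3)


def test_unknown_site_raises(dimer_fixture):
    _, manifest, model = dimer_fixture
    ens = simulate_ensemble(model,
                            EnsembleSpec(_moving(manifest), n_conformers=3,
                                         seed=1))
    with pytest.raises(KeyError):
        pair_distance_series(ens, [(("P", 888), ("P2", 99999))])


def test_histograms_invariant_under_global_rigid_transform(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=60, seed=12)
    ens = simulate_ensemble(model, spec)
    R = random_rotation(np.random.default_rng(4))
    t = np.array([7.0, -2.0, 15.0])
    moved = Ensemble(ens.model.transformed(R, t), ens.spec,
                     [Conformer(c.axis, c.angle, c.coords @ R.T + t)
                      for c in ens.conformers],
                     R @ ens.pivot + t, ens.atom_index,
                     ens.rest_coords @ R.T + t, ens.ca_mask)
    h0 = pair_distance_series(ens, [CROSS_PAIR]).series[0].histogram()
    h1 = pair_distance_series(moved, [CROSS_PAIR]).series[0].histogram()
    np.testing.assert_allclose(h1[0], h0[0], atol=1e-9)
    assert (h1[1] == h0[1]).all()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def _three_mode_ensemble(model, manifest, n=200, amp=5.0, seed=0):
    """Compose rotations about three fixed orthogonal axes with small
    random angles: a 3-parameter rigid manifold."""
    moving = _moving(manifest)
    spec = EnsembleSpec(moving, n_conformers=n, max_angle=amp, seed=seed)
    ens = simulate_ensemble(model, spec)   # re-used for bookkeeping
    rng = np.random.default_rng(seed)
    axes = np.eye(3)
    conformers = []
    for _ in range(n):
        angles = rng.uniform(-amp, amp, size=3)
        R = (rotation_matrix(axes[2], angles[2])
             @ rotation_matrix(axes[1], angles[1])
             @ rotation_matrix(axes[0], angles[0]))
        coords = (ens.rest_coords - ens.pivot) @ R.T + ens.pivot
        conformers.append(Conformer(axes[0], angles[0], coords))
    return Ensemble(model, spec, conformers, ens.pivot, ens.atom_index,
                    ens.rest_coords, ens.ca_mask)


def test_three_mode_generator_top3_variance(dimer_fixture):
    _, manifest, model = dimer_fixture
    ens = _three_mode_ensemble(model, manifest)
    summary = pca_modes(ens)
    assert summary.top_k_variance >= 0.95


def test_identical_conformers_flagged_degenerate(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=5, max_angle=0.0,
                        seed=2)
    summary = pca_modes(simulate_ensemble(model, spec))
    assert summary.degenerate
    assert summary.top_k_variance is None
    np.testing.assert_allclose(summary.eigenvalues, 0.0, atol=1e-12)


def test_eigenvalue_trace_identity(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=80, seed=7)
    ens = simulate_ensemble(model, spec)
    summary = pca_modes(ens)
    X = np.stack([c.coords[ens.ca_mask].ravel() for c in ens.conformers])
    Xc = X - X.mean(axis=0)
    total = (Xc ** 2).sum() / (len(X) - 1)
    assert summary.eigenvalues.sum() == pytest.approx(total, rel=1e-6)
    fracs = summary.variance_fractions
    assert fracs.sum() == pytest.approx(1.0, abs=1e-9)
    assert (np.diff(fracs) <= 1e-12).all()


def test_max_angle_recovery_within_ten_percent(dimer_fixture):
    _, manifest, model = dimer_fixture
    spec = EnsembleSpec(_moving(manifest), n_conformers=1000,
                        max_angle=13.0, seed=8)
    est = estimate_max_angle(simulate_ensemble(model, spec))
    assert abs(est - 13.0) / 13.0 <= 0.10


def test_interface_pivot_sits_between_groups(dimer_fixture):
    _, manifest, model = dimer_fixture
    pivot = interface_pivot(model, _moving(manifest))
    # the planted interface straddles the C2 axis at x = y = 0
    assert abs(pivot[0]) < 15.0
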