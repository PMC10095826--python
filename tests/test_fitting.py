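import numpy as np
import pytest

from ffmatch.fitting import (FitConfig, ReferenceDataset, _FitWorkspace,
                             assess, classify_force_errors, fit_parameters,
                             objective)
from ffmatch.mm import batch_evaluate
from ffmatch.synthetic import (GhostSpec, ghost_reference_dataset,
                               make_diatomic)


def perturbed(params, f_k=1.2, f_eq=1.05):
    out = params.copy()
    for p in out.bonds.values():
        p.k *= f_k
        p.eq *= f_eq
    for p in out.angles.values():
        p.k *= 2.0 - f_k
        p.eq *= 2.0 - f_eq
    for terms in out.dihedrals.values():
        for t in terms:
            t.k *= f_k
    return out


def diatomic_dataset(n_frames=50, seed=0, k=300.0, r_eq=1.5):
    """Exact-label frames of a single harmonic bond."""
    top, params = make_diatomic(k=k, r_eq=r_eq)
    rng = np.random.default_rng(seed)
    r = r_eq + 0.12 * rng.standard_normal(n_frames)
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 1, 0] = r
    energies = k * (r - r_eq) ** 2
    forces = np.zeros_like(coords)
    forces[:, 1, 0] = -2 * k * (r - r_eq)
    forces[:, 0, 0] = 2 * k * (r - r_eq)
    return top, params, ReferenceDataset(coords, energies, forces)


class TestObjective:
    def test_zero_at_generating_parameters(self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        parts = objective(top, params, small_ghost_dataset)
        assert parts.energy == pytest.approx(0.0, abs=1e-18)
        assert parts.force == pytest.approx(0.0, abs=1e-18)
        assert parts.reg == 0.0
        assert parts.total == pytest.approx(0.0, abs=1e-18)

    def test_duplicating_frames_leaves_objective_unchanged(
            self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        ds = small_ghost_dataset
        pert = perturbed(params)
        doubled = ReferenceDataset(
            np.concatenate([ds.coords, ds.coords]),
            np.concatenate([ds.energies, ds.energies]),
            np.concatenate([ds.forces, ds.forces]))
        j1 = objective(top, pert, ds, params0=params)
        j2 = objective(top, pert, doubled, params0=params)
        assert j1.total == pytest.approx(j2.total, rel=1e-12)

    def test_single_bond_closed_form_residual(self):
        # hand-expanded quadratic: with labels from (k0, r0) and trial
        # (k, r0), centred energy residual is (k - k0) * (x - mean(x)),
        # x_i = (r_i - r0)^2, so J_E = (k-k0)^2 var(x) / var(E_ref)
        top, params, ds = diatomic_dataset(n_frames=40, seed=5)
        trial = params.copy()
        trial.bonds[("X", "X")].k = 390.0
        parts = objective(top, trial, ds, params0=params)
        x = (ds.coords[:, 1, 0] - 1.5) ** 2
        expected_e = (390.0 - 300.0) ** 2 * x.var() / ds.energies.var()
        assert parts.energy == pytest.approx(expected_e, rel=1e-10)

    def test_zero_variance_labels_rejected(self):
        top, params, ds = diatomic_dataset()
        flat = ReferenceDataset(ds.coords, np.zeros(ds.n_frames), ds.forces)
        with pytest.raises(ValueError, match="variance"):
            objective(top, params, flat)

    def test_nonnegative(self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        assert objective(top, perturbed(params), small_ghost_dataset,
                         params0=params).total >= 0.0


class TestWorkspace:
    def test_workspace_matches_direct_evaluator(self, toy_host,
                                                small_ghost_dataset):
        top, params, _ = toy_host
        coords = small_ghost_dataset.coords[:30]
        ws = _FitWorkspace(top, params, coords)
        for f_k, f_eq in ((1.0, 1.0), (1.3, 1.04), (0.7, 0.97)):
            trial = perturbed(params, f_k, f_eq)
            e_ws, f_ws = ws.evaluate(trial)
            e_d, _, f_d = batch_evaluate(top, trial, coords)
            assert np.allclose(e_ws, e_d, rtol=1e-10, atol=1e-8)
            assert np.allclose(f_ws, f_d, rtol=1e-9, atol=1e-8)


class TestFit:
    def test_start_at_truth_stays_at_truth(self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        res = fit_parameters(small_ghost_dataset, top, params, FitConfig())
        for key, p in res.params.bonds.items():
            assert p.k == pytest.approx(params.bonds[key].k, rel=1e-6)
            assert p.eq == pytest.approx(params.bonds[key].eq, rel=1e-6)
        for key, terms in res.params.dihedrals.items():
            for t0, t1 in zip(params.dihedrals[key], terms):
                assert t1.k == pytest.approx(t0.k, abs=1e-5)

    def test_energies_only_fit_recovers_closed_form(self):
        top, params, ds = diatomic_dataset(n_frames=50, seed=9)
        start = params.copy()
        start.bonds[("X", "X")].k = 360.0
        start.bonds[("X", "X")].eq = 1.62
        cfg = FitConfig(w_force=0.0, w_reg=0.0, tol=1e-14)
        res = fit_parameters(ds, top, start, cfg)
        # independent closed-form oracle: regress centred E on (r^2, r)
        r = ds.coords[:, 1, 0]
        A = np.column_stack([r**2 - (r**2).mean(), r - r.mean()])
        y = ds.energies - ds.energies.mean()
        a, b = np.linalg.lstsq(A, y, rcond=None)[0]
        k_hat, eq_hat = a, -b / (2 * a)
        assert k_hat == pytest.approx(300.0, rel=1e-9)
        assert res.params.bonds[("X", "X")].k == pytest.approx(k_hat, rel=1e-6)
        assert res.params.bonds[("X", "X")].eq == pytest.approx(eq_hat, rel=1e-6)

    def test_frozen_entries_untouched(self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        res = fit_parameters(small_ghost_dataset, top, perturbed(params),
                             FitConfig(max_iter=5))
        start = perturbed(params)
        # impropers are frozen by default; LJ and 1-4 scales always
        for key, terms in res.params.impropers.items():
            for t0, t1 in zip(start.impropers[key], terms):
                assert t1.k == t0.k
        for key, p in res.params.lj.items():
            assert (p.epsilon, p.sigma) == \
                (start.lj[key].epsilon, start.lj[key].sigma)
        assert res.params.scale14_elec == start.scale14_elec
        assert res.params.scale14_vdw == start.scale14_vdw

    def test_determinism_bit_identical(self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        start = perturbed(params)
        r1 = fit_parameters(small_ghost_dataset, top, start,
                            FitConfig(max_iter=30))
        r2 = fit_parameters(small_ghost_dataset, top, start,
                            FitConfig(max_iter=30))
        for key in r1.params.bonds:
            assert r1.params.bonds[key].k == r2.params.bonds[key].k
            assert r1.params.bonds[key].eq == r2.params.bonds[key].eq
        for key in r1.params.dihedrals:
            for a, b in zip(r1.params.dihedrals[key], r2.params.dihedrals[key]):
                assert a.k == b.k
        assert np.array_equal(r1.trace, r2.trace)

    def test_non_convergence_flagged_best_so_far(self, toy_host,
                                                 small_ghost_dataset):
        top, params, _ = toy_host
        res = fit_parameters(small_ghost_dataset, top, perturbed(params),
                             FitConfig(max_iter=2))
        assert res.converged is False
        assert res.parts.total >= 0

    def test_no_fit_enabled_classes_rejected(self):
        top, params, ds = diatomic_dataset()
        frozen = params.copy()
        frozen.bonds[("X", "X")].fit_k = False
        frozen.bonds[("X", "X")].fit_eq = False
        with pytest.raises(ValueError, match="fit-enabled"):
            fit_parameters(ds, top, frozen)

    def test_regularization_monotonicity(self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        start = perturbed(params)
        data_residuals = []
        for w_reg in (0.0, 0.1, 2.0, 50.0):
            res = fit_parameters(small_ghost_dataset, top, start,
                                 FitConfig(w_reg=w_reg))
            data_residuals.append(res.parts.energy + res.parts.force)
        assert all(b >= a - 1e-12 for a, b in
                   zip(data_residuals, data_residuals[1:]))

    def test_symmetry_preserved_across_instances(self, toy_host,
                                                 small_ghost_dataset):
        # storage is per class, so all instances of one type share the fitted
        # value; the class map must still cover each fit-enabled term once
        from ffmatch.mm import symmetry_classes
        top, params, _ = toy_host
        res = fit_parameters(small_ghost_dataset, top, perturbed(params),
                             FitConfig(max_iter=10))
        cmap = symmetry_classes(top, res.params)
        n_bond_classes = len({v for (kind, _), v in cmap.items()
                              if kind == "bond"})
        assert n_bond_classes == len(res.params.bonds)


class TestAssess:
    def test_ghost_params_zero_errors(self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        rep = assess(small_ghost_dataset, top, params)
        assert rep.energy_rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.energy_mae == pytest.approx(0.0, abs=1e-9)
        assert rep.force_rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.bin_counts["white"] == rep.per_atom_norms.size
        assert rep.reference_label == "ghost"

    def test_gaussian_noise_chi_expectation(self, toy_host):
        # iid sigma=2 per component -> RMSE of per-atom norms = 2*sqrt(3)
        top, params, meta = toy_host
        spec = GhostSpec(temperature=600.0, n_frames=320, stride=5, seed=8,
                         sigma_force=2.0)
        ds = ghost_reference_dataset(top, params, spec, x0=meta["coords"])
        rep = assess(ds, top, params)
        assert ds.coords.shape[0] * top.n_atoms >= 10_000
        assert rep.force_rmse == pytest.approx(2.0 * np.sqrt(3.0), rel=0.03)

    def test_heavy_atoms_ordered_first(self, toy_host, small_ghost_dataset):
        top, params, _ = toy_host
        rep = assess(small_ghost_dataset, top, params)
        heavy = top.heavy_mask[rep.atom_order]
        n_heavy = heavy.sum()
        assert heavy[:n_heavy].all() and not heavy[n_heavy:].any()

    def test_bin_counts_sum(self, toy_host):
        top, params, meta = toy_host
        spec = GhostSpec(temperature=600.0, n_frames=50, stride=5, seed=2,
                         sigma_force=15.0)
        ds = ghost_reference_dataset(top, params, spec, x0=meta["coords"])
        rep = assess(ds, top, params)
        assert sum(rep.bin_counts.values()) == 50 * top.n_atoms


class TestClassifyForceErrors:
    def test_examples(self):
        assert classify_force_errors(55.0).item() == "red"
        assert classify_force_errors(10.0).item() == "white"  # strict
        assert list(classify_force_errors([5, 12, 31, 51])) == \
            ["white", "blue", "green", "red"]

    def test_boundaries(self):
        assert list(classify_force_errors([30.0, 50.0])) == ["blue", "green"]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_force_errors([-1.0])


class TestReferenceDataset:
    def test_validation(self):
        with pytest.raises(ValueError):
            ReferenceDataset(np.zeros((1, 2, 3)), np.zeros(1),
                             np.zeros((1, 2, 3)))  # <2 frames
        with pytest.raises(ValueError):
            ReferenceDataset(np.zeros((3, 2, 3)), np.zeros(2),
                             np.zeros((3, 2, 3)))  # energy length
        bad = np.zeros((3, 2, 3))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            ReferenceDataset(np.zeros((3, 2, 3)), np.zeros(3), bad)
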