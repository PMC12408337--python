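"""Least-squares refinement: parameter bookkeeping, Jacobian, convergence,
protocols and stability diagnostics."""

import numpy as np
import pytest

from isfac.crystal import AtomSite, CrystalModel, ReflectionData, UnitCell
from isfac.refine import (EmptyDataError, RefinementConfig, SumpRestraint,
                          DistanceRestraint, apply_parameters,
                          apply_sign_flip, assemble_parameters,
                          fix_fluctuating_neutral, r_complete, r_factors,
                          refine, refine_with_protocols, residuals_jacobian,
                          resolution_scan)
from isfac.scattering import IonSpec
from isfac.synthetic import (SyntheticSpec, make_structure, perturb_start,
                             simulate_dataset)


@pytest.fixture()
def zwitterion_problem(library):
    spec = SyntheticSpec(template="toy-zwitterion-P212121", d_min=0.75,
                         noise=0.02, seed=1)
    model, truth = make_structure(spec)
    data = simulate_dataset(model, spec, library)
    return spec, model, truth, data


class TestAssembleParameters:
    def test_single_atom_count(self):
        cell = UnitCell(8, 8, 8)
        model = CrystalModel(cell, [AtomSite("C1", IonSpec.from_charge("C", -1),
                                             (0.1, 0.2, 0.3), adp=0.02)])
        values, refs = assemble_parameters(model, RefinementConfig())
        assert len(values) == 6  # scale + xyz + Uiso + nu

    def test_nu_fixed_removes_one(self):
        cell = UnitCell(8, 8, 8)
        site = AtomSite("C1", IonSpec.from_charge("C", -1), (0.1, 0.2, 0.3),
                        adp=0.02, nu_fixed=True)
        values, refs = assemble_parameters(CrystalModel(cell, [site]),
                                           RefinementConfig())
        assert len(values) == 5

    def test_zwitterion_count_matches_independent_tally(self, zwitterion_problem):
        _, model, _, _ = zwitterion_problem
        cfg = RefinementConfig(free_hydrogens=True)
        values, refs = assemble_parameters(model, cfg)
        expected = 1 + sum(3 + 1 + 1 for _ in model.sites)
        assert len(values) == expected
        # riding hydrogens drop x and U but keep nu
        cfg2 = RefinementConfig(free_hydrogens=False)
        values2, _ = assemble_parameters(model, cfg2)
        n_h = sum(1 for s in model.sites if s.is_hydrogen)
        assert len(values2) == expected - 4 * n_h

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            assemble_parameters(CrystalModel(UnitCell(5, 5, 5), []),
                                RefinementConfig())


class TestResidualsJacobian:
    def test_residuals_zero_at_generating_truth(self, library):
        spec = SyntheticSpec(template="ionic-pair-P1", d_min=1.0, noise=0.0)
        model, _ = make_structure(spec)
        data = simulate_dataset(model, spec, library)
        cfg = RefinementConfig()
        # recover the generating scale analytically
        from isfac.structure_factors import f_calc
        F = f_calc(model, library, data.hkl)
        scale = float(np.median(data.i_obs / np.abs(F) ** 2))
        values, refs = assemble_parameters(model, cfg, scale=scale)
        r, J, n = residuals_jacobian(model, data, cfg, refs, values, library)
        assert np.max(np.abs(r[:n])) < 1e-6

    def test_jacobian_matches_finite_differences(self, library, p21_model):
        rng = np.random.default_rng(0)
        from isfac.crystal import unique_reflections
        hkl = unique_reflections(p21_model.cell, p21_model.symmetry,
                                 d_min=1.4, latt=-1)
        i_obs = rng.uniform(10, 100, len(hkl))
        data = ReflectionData(hkl, i_obs, np.sqrt(i_obs))
        cfg = RefinementConfig(sump=SumpRestraint())
        values, refs = assemble_parameters(p21_model, cfg, scale=1.3)
        r0, J, n = residuals_jacobian(p21_model, data, cfg, refs, values,
                                      library)
        eps = 1e-6
        for k in range(len(values)):
            vp = values.copy()
            vp[k] += eps
            rp, _, _ = residuals_jacobian(p21_model, data, cfg, refs, vp,
                                          library)
            vm = values.copy()
            vm[k] -= eps
            rm, _, _ = residuals_jacobian(p21_model, data, cfg, refs, vm,
                                          library)
            fd = (rp - rm) / (2 * eps)
            denom = max(np.max(np.abs(fd)), 1e-8)
            assert np.max(np.abs(fd - J[:, k])) / denom < 1e-5, refs[k].name

    def test_sump_row_value(self, library):
        spec = SyntheticSpec(template="ionic-pair-P1", d_min=1.0)
        model, _ = make_structure(spec)
        data = simulate_dataset(model, spec, library)
        sump = SumpRestraint(target=0.0, sigma=0.001)
        cfg = RefinementConfig(sump=sump)
        values, refs = assemble_parameters(model, cfg)
        r, J, n = residuals_jacobian(model, data, cfg, refs, values, library)
        signed_total = sum(s.nu * s.ion.dZ for s in model.sites)
        assert r[n] == pytest.approx(signed_total / 0.001)

    def test_all_excluded_raises(self, library):
        spec = SyntheticSpec(template="ionic-pair-P1", d_min=1.0)
        model, _ = make_structure(spec)
        data = simulate_dataset(model, spec, library)
        cfg = RefinementConfig(d_min=0.1, d_max=0.2)
        values, refs = assemble_parameters(model, cfg)
        with pytest.raises(EmptyDataError):
            residuals_jacobian(model, data, cfg, refs, values, library)


class TestRefine:
    def test_start_at_truth_noise_free(self, library):
        spec = SyntheticSpec(template="ionic-pair-P1", d_min=1.0, noise=0.0)
        model, _ = make_structure(spec)
        data = simulate_dataset(model, spec, library)
        res = refine(model, data, RefinementConfig(), library)
        assert res.converged
        assert len(res.cycle_log) <= 2
        assert res.r1 < 1e-6

    def test_parameter_recovery_with_noise(self, zwitterion_problem, library):
        spec, _, truth, data = zwitterion_problem
        model, _ = make_structure(spec)
        perturb_start(model, np.random.default_rng(42))
        cfg = RefinementConfig(sump=SumpRestraint())
        res = refine_with_protocols(model, data, cfg, library)
        assert res.converged
        for site in model.sites:
            dq = res.nu(site.label) * site.ion.dZ
            esu = res.nu_esd(site.label) * abs(site.ion.dZ)
            assert abs(dq - truth[site.label]) < 3 * esu, site.label

    def test_cost_never_increases(self, zwitterion_problem, library):
        spec, _, _, data = zwitterion_problem
        model, _ = make_structure(spec)
        perturb_start(model, np.random.default_rng(9))
        res = refine(model, data, RefinementConfig(sump=SumpRestraint()),
                     library)
        costs = [c["cost"] for c in res.cycle_log]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(costs, costs[1:]))

    def test_null_conventional_equivalence(self, library):
        # nu fixed at zero reproduces a conventional refinement exactly
        spec = SyntheticSpec(template="ionic-pair-P1", d_min=1.0, noise=0.01,
                             seed=4)
        model, _ = make_structure(spec)
        for s in model.sites:
            s.nu = 0.0
        data = simulate_dataset(model, spec, library)

        m_fixed, _ = make_structure(spec)
        for s in m_fixed.sites:
            s.nu = 0.0
            s.nu_fixed = True
        res_fixed = refine(m_fixed.copy(), data, RefinementConfig(), library)

        m_neutral, _ = make_structure(spec)
        for s in m_neutral.sites:
            s.nu = 0.0
            s.nu_fixed = True
            s.ion = s.ion.neutral_partner()
        res_neutral = refine(m_neutral.copy(), data, RefinementConfig(),
                             library)
        np.testing.assert_allclose(res_fixed.values, res_neutral.values,
                                   atol=1e-8)


class TestProtocols:
    def _one_atom_result(self, nu):
        cell = UnitCell(8, 8, 8)
        model = CrystalModel(cell, [AtomSite(
            "C18", IonSpec.from_charge("C", -1), (0.1, 0.2, 0.3), nu=nu)])

        class FakeResult:
            def nu(self, label):
                return nu
        return model, FakeResult()

    def test_negative_nu_flips_ion_sign(self):
        model, res = self._one_atom_result(-0.11)
        flipped = apply_sign_flip(model, res)
        assert flipped == ["C18"]
        site = model.site("C18")
        assert site.ion.dZ == +1
        assert site.nu == pytest.approx(0.11)

    def test_positive_nu_untouched(self):
        model, res = self._one_atom_result(0.2)
        assert apply_sign_flip(model, res) == []
        assert model.site("C18").ion.dZ == -1

    def test_flip_then_refine_matches_correct_sign_start(self, library):
        # data generated with a cationic site; start the refinement with the
        # wrong (anionic) assignment and let the protocol correct it
        spec = SyntheticSpec(template="ionic-pair-P1", d_min=0.9, noise=0.01,
                             seed=2)
        model_true, truth = make_structure(spec)
        data = simulate_dataset(model_true, spec, library)
        cfg = RefinementConfig(sump=SumpRestraint())

        wrong, _ = make_structure(spec)
        na = wrong.site("NA1")
        na.ion = IonSpec.from_charge("Na", -1)
        cl = wrong.site("CL1")
        cl.ion = IonSpec.from_charge("Cl", 1)
        for s in wrong.sites:
            s.nu = 0.1
        res_wrong = refine_with_protocols(wrong, data, cfg, library)
        assert set(res_wrong.flipped_sites) == {"NA1", "CL1"}

        right, _ = make_structure(spec)
        for s in right.sites:
            s.nu = 0.1
        res_right = refine_with_protocols(right, data, cfg, library)
        for lb in ("NA1", "CL1"):
            dq_w = res_wrong.nu(lb) * wrong.site(lb).ion.dZ
            dq_r = res_right.nu(lb) * right.site(lb).ion.dZ
            assert dq_w == pytest.approx(dq_r, abs=1e-4)

    def test_fluctuating_history_fixed_neutral(self):
        cell = UnitCell(8, 8, 8)
        model = CrystalModel(cell, [AtomSite(
            "C1", IonSpec.from_charge("C", -1), (0.1, 0.2, 0.3), nu=0.01)])
        fixed = fix_fluctuating_neutral(model, {"C1": [0.01, -0.02, 0.01]},
                                        threshold=0.05)
        assert fixed == ["C1"]
        assert model.site("C1").nu_fixed
        assert model.site("C1").nu == 0.0

    def test_stable_history_untouched(self):
        cell = UnitCell(8, 8, 8)
        model = CrystalModel(cell, [AtomSite(
            "C1", IonSpec.from_charge("C", -1), (0.1, 0.2, 0.3), nu=0.30)])
        assert fix_fluctuating_neutral(model, {"C1": [0.30, 0.31, 0.30]}) == []
        assert not model.site("C1").nu_fixed


class TestRFactors:
    def test_perfect_model_zero(self, library):
        spec = SyntheticSpec(template="ionic-pair-P1", d_min=1.0, noise=0.0)
        model, _ = make_structure(spec)
        data = simulate_dataset(model, spec, library)
        from isfac.structure_factors import f_calc
        F = f_calc(model, library, data.hkl)
        scale = float(np.median(data.i_obs / np.abs(F) ** 2))
        r1, wr2, _ = r_factors(model, data, RefinementConfig(), library, scale)
        assert r1 < 1e-8
        assert wr2 < 1e-8

    def test_hand_computed_three_reflection_r1(self, library):
        # one atom, three reflections; perturb one observed |F| by hand
        cell = UnitCell(8, 8, 8)
        model = CrystalModel(cell, [AtomSite(
            "C1", IonSpec.neutral("C"), (0.0, 0.0, 0.0), adp=0.0)])
        hkl = np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0]])
        from isfac.structure_factors import f_calc
        fc = np.abs(f_calc(model, library, hkl))
        f_obs = fc.copy()
        f_obs[1] *= 1.10  # +10% on one amplitude
        data = ReflectionData(hkl, f_obs**2, np.ones(3))
        r1, _, _ = r_factors(model, data, RefinementConfig(), library, 1.0)
        expected = (0.10 * fc[1]) / np.sum(f_obs)
        assert r1 == pytest.approx(expected, rel=1e-10)

    def test_goof_near_unity_on_correct_weights(self, zwitterion_problem,
                                                library):
        spec, _, _, data = zwitterion_problem
        model, _ = make_structure(spec)
        perturb_start(model, np.random.default_rng(1))
        res = refine(model, data, RefinementConfig(sump=SumpRestraint()),
                     library)
        assert res.goof == pytest.approx(1.0, abs=0.15)


class TestStabilityDiagnostics:
    @pytest.fixture()
    def small_problem(self, library):
        spec = SyntheticSpec(template="ionic-pair-P1", d_min=1.05,
                             noise=0.02, seed=8)
        model, truth = make_structure(spec)
        data = simulate_dataset(model, spec, library)
        return spec, model, truth, data

    def test_leave_one_out_charges_stay_in_band(self, small_problem, library):
        # no single reflection may move any charge outside its 3-esu band
        spec, _, _, data = small_problem
        model, _ = make_structure(spec)
        cfg = RefinementConfig(sump=SumpRestraint())
        report = r_complete(model, data, cfg, library)
        assert len(report.cv_residuals) == len(data)
        for lb, stats in report.dq_stats.items():
            v = report.dq_per_omission[lb]
            assert np.all(np.abs(v - stats["mean"]) <= 3.0 * stats["esu"])
            assert stats["min"] <= stats["mean"] <= stats["max"]

    def test_unconverged_baseline_refused(self, small_problem, library):
        spec, _, _, data = small_problem
        model, _ = make_structure(spec)
        cfg = RefinementConfig(sump=SumpRestraint(), max_cycles=1,
                               shift_esd_tol=1e-9)
        baseline = refine(model.copy(), data, cfg, library)
        if baseline.converged:
            pytest.skip("baseline converged in one cycle")
        with pytest.raises(RuntimeError):
            r_complete(model, data, cfg, library, baseline=baseline)

    def test_resolution_scan_full_row_matches_baseline(self, small_problem,
                                                       library):
        spec, _, _, data = small_problem
        model, _ = make_structure(spec)
        cfg = RefinementConfig(sump=SumpRestraint())
        baseline = refine(model.copy(), data, cfg, library)
        rows = resolution_scan(model, data, cfg, library,
                               cuts=[spec.d_min, 1.6])
        full = rows[0]
        assert full["converged"]
        for lb, (dq, esu) in full["charges"].items():
            assert dq == pytest.approx(
                baseline.nu(lb) * model.site(lb).ion.dZ, abs=1e-6)
        # esu grows as data are truncated
        worse = rows[1]
        for lb in full["charges"]:
            assert worse["charges"][lb][1] > full["charges"][lb][1]

    def test_restraints_help_at_poor_resolution(self, library):
        spec = SyntheticSpec(template="toy-zwitterion-P212121", d_min=0.75,
                             noise=0.04, seed=17)
        model_true, truth = make_structure(spec)
        data = simulate_dataset(model_true, spec, library)

        def run(restraints):
            model, _ = make_structure(spec)
            perturb_start(model, np.random.default_rng(23),
                          coord_jitter=0.03)
            cfg = RefinementConfig(sump=SumpRestraint(), d_min=1.1,
                                   distance_restraints=restraints)
            res = refine_with_protocols(model, data, cfg, library)
            err = 0.0
            for s in model.sites:
                if s.nu_fixed:
                    continue
                err += abs(res.nu(s.label) * s.ion.dZ - truth[s.label])
            return err

        bonds = [DistanceRestraint("N1", "H1", 1.01),
                 DistanceRestraint("N1", "H2", 1.01),
                 DistanceRestraint("N1", "H3", 1.01),
                 DistanceRestraint("C1", "H4", 1.09),
                 DistanceRestraint("C1", "H5", 1.09),
                 DistanceRestraint("N1", "C1", 1.47),
                 DistanceRestraint("C1", "C2", 1.52),
                 DistanceRestraint("C2", "O1", 1.25),
                 DistanceRestraint("C2", "O2", 1.25)]
        assert run(bonds) <= run([]) * 1.05
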