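"""Equilibrium fits, completion, work integration, and the energy ledger."""

import numpy as np
import pytest
from scipy import integrate

from smcondense import forcespec, synthgen
from smcondense.constants import KBT_PNNM, thermal_energy_pNnm
from smcondense.datatypes import ForceExtensionBranch, TimeTrace
from smcondense.synthgen import CoatingModel, HysteresisModel, PolymerModel


def branch_from_law(model, schedule, direction="pulling", condition="ssDNA", salt=0.0):
    f = np.asarray(schedule, float)
    ext = model.extension_nm(f)
    if direction == "relaxing":
        f, ext = f[::-1], ext[::-1]
    return ForceExtensionBranch(condition, salt, direction, f, ext)


# --------------------------------------------------------------------------
# equilibrium extraction
# --------------------------------------------------------------------------

class TestFitEquilibrium:
    def test_noiseless_exact_recovery(self):
        trace, _ = synthgen.gen_timetrace(3000.0, 2000.0, 5.0, 40.0, 0.05)
        fit = forcespec.fit_equilibrium(trace)
        assert fit.L_eq_nm == pytest.approx(2000.0, rel=1e-6)
        assert fit.tau_s == pytest.approx(5.0, rel=1e-6)
        assert fit.converged

    def test_constant_trace_degenerate(self):
        trace = TimeTrace(np.arange(50) * 0.1, np.full(50, 1500.0), np.full(50, 1.0))
        fit = forcespec.fit_equilibrium(trace)
        assert fit.L_eq_nm == pytest.approx(1500.0)
        assert fit.amplitude_nm == 0.0
        assert np.isnan(fit.tau_s)
        assert fit.converged

    def test_short_segment_rejected(self):
        trace = TimeTrace(np.arange(5) * 0.1, np.full(5, 1.0), np.full(5, 1.0))
        with pytest.raises(ValueError, match="at least 10"):
            forcespec.fit_equilibrium(trace)

    def test_unconverged_when_trace_truncated(self):
        with pytest.warns(UserWarning):
            trace, _ = synthgen.gen_timetrace(3000.0, 2000.0, 20.0, 25.0, 0.1)
        fit = forcespec.fit_equilibrium(trace)
        assert not fit.converged

    def test_noisy_recovery(self):
        taus, leqs = [], []
        for seed in range(20):
            trace, _ = synthgen.gen_timetrace(
                3000.0, 2000.0, 5.0, 40.0, 0.05, noise_sd_nm=10.0, seed=seed
            )
            fit = forcespec.fit_equilibrium(trace)
            taus.append(fit.tau_s)
            leqs.append(fit.L_eq_nm)
        assert np.mean(taus) == pytest.approx(5.0, rel=0.10)
        assert np.mean(leqs) == pytest.approx(2000.0, rel=0.01)


class TestAssembleBranches:
    def _fits(self, model, forces, noise=0.0, seed=0):
        fits, dirs = [], []
        rng = np.random.default_rng(seed)
        for direction in ("pulling", "relaxing"):
            for f in forces:
                leq = model.extension_nm(f) + (rng.normal(0, noise) if noise else 0.0)
                fits.append(
                    forcespec.EquilibriumFit(
                        L_eq_nm=float(leq), tau_s=1.0, amplitude_nm=5.0,
                        converged=True, force_pN=float(f),
                    )
                )
                dirs.append(direction)
        return fits, dirs

    def test_zero_hysteresis_branches_agree(self):
        model = PolymerModel()
        fits, dirs = self._fits(model, np.linspace(0.5, 10.5, 11))
        p, r = forcespec.assemble_branches(fits, dirs, "ssDNA", 0.0)
        np.testing.assert_allclose(p.extension_nm, r.extension_nm[::-1])

    def test_missing_direction_rejected(self):
        fits, dirs = self._fits(PolymerModel(), [1.0, 2.0])
        keep = [i for i, d in enumerate(dirs) if d == "pulling"]
        with pytest.raises(ValueError, match="missing relaxing"):
            forcespec.assemble_branches(
                [fits[i] for i in keep], ["pulling"] * len(keep), "ssDNA", 0.0
            )

    def test_unconverged_fit_lists_forces(self):
        fits, dirs = self._fits(PolymerModel(), [1.0, 2.0, 3.0])
        fits[1].converged = False
        with pytest.raises(ValueError, match="unconverged.*2"):
            forcespec.assemble_branches(fits, dirs, "ssDNA", 0.0)

    def test_end_to_end_matches_generating_law(self):
        """Time traces per force -> equilibrium -> branch matches the law to 1%."""
        model = PolymerModel()
        forces = np.linspace(0.5, 10.5, 11)
        fits, dirs = [], []
        for direction in ("pulling", "relaxing"):
            for i, f in enumerate(forces):
                leq = model.extension_nm(f)
                trace, _ = synthgen.gen_timetrace(
                    leq * 1.1, leq, 2.0, 20.0, 0.02,
                    noise_sd_nm=2.0, seed=100 + i, force_pN=float(f),
                )
                fits.append(forcespec.fit_equilibrium(trace))
                dirs.append(direction)
        p, _ = forcespec.assemble_branches(fits, dirs, "ssDNA", 0.0)
        np.testing.assert_allclose(
            p.extension_nm, model.extension_nm(p.force_pN), rtol=0.01
        )


# --------------------------------------------------------------------------
# completion and work
# --------------------------------------------------------------------------

class TestCompleteBranch:
    def test_branch_already_at_ceiling_unchanged(self):
        model = PolymerModel()
        b = branch_from_law(model, np.linspace(0.5, 17.5, 30))
        assert forcespec.complete_branch(b, anchor_extension_nm=None) is b

    def test_trapezoid_arithmetic(self):
        b = ForceExtensionBranch(
            "+SSB", 100.0, "pulling", np.array([5.0, 10.5]), np.array([3000.0, 4000.0])
        )
        done = forcespec.complete_branch(b, anchor_extension_nm=4700.0)
        added = forcespec.integrate_work(done) - forcespec.integrate_work(b)
        assert added == pytest.approx(0.5 * (10.5 + 17.5) * 700.0)  # 9800
        assert done.completion_error_bound_pNnm == pytest.approx(0.5 * 7.0 * 700.0)

    def test_below_ceiling_rejected(self):
        b = ForceExtensionBranch(
            "+SSB", 0.0, "pulling", np.array([1.0, 8.0]), np.array([100.0, 500.0])
        )
        with pytest.raises(ValueError, match="below the measured ceiling"):
            forcespec.complete_branch(b, anchor_extension_nm=600.0)

    def test_completion_error_within_reported_bound(self):
        """Truncate full-range synthetic curves at 10.5 pN and complete them."""
        model = PolymerModel()
        full_sched = np.unique(np.r_[np.linspace(0.05, 17.5, 400), 10.5])
        for c in (1.0, 0.7, 0.4):
            coat = CoatingModel(condensation_factor=c)
            p, _, _ = synthgen.gen_fec_coated(model, coat, full_sched)
            w_true = forcespec.integrate_work(p)
            keep = p.force_pN <= 10.5
            truncated = ForceExtensionBranch(
                p.condition, p.salt_mM, "pulling",
                p.force_pN[keep], p.extension_nm[keep],
            )
            anchor = c * model.extension_nm(17.5)
            done = forcespec.complete_branch(truncated, anchor_extension_nm=anchor)
            err = abs(forcespec.integrate_work(done) - w_true)
            assert err <= done.completion_error_bound_pNnm + 1e-6


class TestIntegrateWork:
    def test_rectangle(self):
        assert forcespec.work_trapezoid([2.0, 2.0], [0.0, 1000.0]) == pytest.approx(2000.0)

    def test_single_point_zero(self):
        assert forcespec.work_trapezoid([2.0], [100.0]) == 0.0

    def test_quadrature_oracle_within_01pct(self):
        model = PolymerModel()
        b = branch_from_law(model, np.linspace(0.05, 17.5, 1000))
        oracle, _ = integrate.quad(lambda f: f * model.d_extension(f), 0.05, 17.5)
        assert forcespec.integrate_work(b) == pytest.approx(oracle, rel=1e-3)

    def test_unsorted_points_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            forcespec.work_trapezoid([1.0, 3.0, 2.0], [10.0, 20.0, 30.0])

    def test_noisy_extension_tolerated(self):
        # measurement noise makes extension locally non-monotone; the
        # work integral must still evaluate along the force sweep
        f = np.linspace(1.0, 10.0, 50)
        ext = 100.0 * f + np.random.default_rng(0).normal(0, 30.0, 50)
        assert np.isfinite(forcespec.work_trapezoid(f, ext))

    def test_integration_by_parts_convention(self):
        """integral F dL + integral L dF equals the boundary term F*L."""
        model = PolymerModel()
        f = np.linspace(0.05, 17.5, 2000)
        ext = model.extension_nm(f)
        w_fdl = np.trapezoid(f, ext)
        w_ldf = np.trapezoid(ext, f)
        boundary = f[-1] * ext[-1] - f[0] * ext[0]
        assert w_fdl + w_ldf == pytest.approx(boundary, rel=1e-6)


# --------------------------------------------------------------------------
# the ledger
# --------------------------------------------------------------------------

def make_branch_set(schedule, hysteresis_kBT=1400.0, coats=((100.0, 0.7),)):
    model0 = PolymerModel(salt_mM=0.0)
    branches = list(
        synthgen.gen_fec_ssdna(model0, HysteresisModel(), schedule)[:2]
    )
    for salt, c in coats:
        model = PolymerModel(salt_mM=salt)
        h = HysteresisModel(target_hysteresis_energy_kBT=hysteresis_kBT)
        branches += synthgen.gen_fec_ssdna(model, h, schedule)[:2]
        branches += synthgen.gen_fec_coated(
            model, CoatingModel(condensation_factor=c), schedule
        )[:2]
    return branches


class TestEnergyLedger:
    def test_identity_entries_zero(self):
        model = PolymerModel()
        sched = np.linspace(0.05, 17.5, 200)
        ref_p = branch_from_law(model, sched, "pulling", "ssDNA", 0.0)
        ref_r = branch_from_law(model, sched, "relaxing", "ssDNA", 0.0)
        twin_p = branch_from_law(model, sched, "pulling", "+SSB", 0.0)
        twin_r = branch_from_law(model, sched, "relaxing", "+SSB", 0.0)
        ledger = forcespec.energy_ledger([ref_p, ref_r, twin_p, twin_r])
        for e in ledger.entries:
            assert e.dE_kBT == pytest.approx(0.0, abs=1e-9)
            assert e.ddE_kBT == pytest.approx(0.0, abs=1e-9)
        for h in ledger.hysteresis_kBT.values():
            assert h == pytest.approx(0.0, abs=1e-9)

    def test_4100_pNnm_is_1000_kbt(self):
        assert 4100.0 / KBT_PNNM == pytest.approx(1000.0)

    def test_hysteresis_equals_de_difference(self):
        sched = np.linspace(0.05, 17.5, 300)
        ledger = forcespec.energy_ledger(make_branch_set(sched))
        for (cond, salt), h in ledger.hysteresis_kBT.items():
            dp = ledger.entry(cond, salt, "pulling").dE_kBT
            dr = ledger.entry(cond, salt, "relaxing").dE_kBT
            assert h == pytest.approx(dp - dr, abs=1e-9)

    def test_salt_hysteresis_1400_recovered(self):
        sched = np.linspace(0.05, 17.5, 1000)
        ledger = forcespec.energy_ledger(make_branch_set(sched))
        assert ledger.hysteresis_kBT[("ssDNA", 100.0)] == pytest.approx(1400.0, rel=0.01)

    def test_missing_reference_rejected(self):
        model = PolymerModel(salt_mM=100.0)
        sched = np.linspace(0.05, 17.5, 100)
        b = branch_from_law(model, sched, "pulling", "+SSB", 100.0)
        with pytest.raises(ValueError, match="reference"):
            forcespec.energy_ledger([b])

    def test_mismatched_ceilings_rejected(self):
        model = PolymerModel()
        b1 = branch_from_law(model, np.linspace(0.05, 17.5, 100))
        b2 = branch_from_law(model, np.linspace(0.05, 10.5, 100), "relaxing")
        with pytest.raises(ValueError, match="ceiling"):
            forcespec.energy_ledger([b1, b2])

    def test_zero_hysteresis_detection_with_noise(self):
        """Bridging-free coated curves: |hysteresis| below 3-sigma bound >= 95%."""
        model = PolymerModel(salt_mM=100.0)
        sched = np.linspace(0.05, 17.5, 200)
        noise = 15.0
        bound = 3.0 * np.sqrt(2.0) * forcespec.trapezoid_work_noise_sd(sched, noise)
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            p, r, _ = synthgen.gen_fec_coated(
                model, CoatingModel(condensation_factor=0.6), sched, noise, seed=seed
            )
            fp, ep = p.sorted_by_force()
            fr, er = r.sorted_by_force()
            h = np.trapezoid(fp, ep) - np.trapezoid(fr, er)
            hits += abs(h) <= bound
        assert hits >= 0.95 * n_seeds


class TestPerTetramerEnergy:
    def test_reco_energy_1p2_kbt(self):
        acct = forcespec.per_tetramer_energy(250.0, 13552, 65.0)
        assert acct.n_tetramers == 208
        assert round(acct.energy_per_tetramer_kBT, 1) == 1.2

    def test_bridging_energy_10_kbt(self):
        acct = forcespec.per_tetramer_energy(2000.0, 13552, 65.0)
        assert round(acct.energy_per_tetramer_kBT) == 10

    def test_recr_energy_1_kbt(self):
        acct = forcespec.per_tetramer_energy(220.0, 13552, 65.0)
        assert round(acct.energy_per_tetramer_kBT) == 1

    def test_zero_energy(self):
        assert forcespec.per_tetramer_energy(0.0, 13552, 65.0).energy_per_tetramer_kBT == 0.0

    def test_round_half_away_from_zero(self):
        assert forcespec.per_tetramer_energy(1.0, 975, 65.0).n_tetramers == 15  # 15.0
        assert forcespec.per_tetramer_energy(1.0, 2015, 62.0).n_tetramers == 33  # 32.5 -> 33

    def test_site_size_warning_outside_range(self):
        with pytest.warns(UserWarning, match="30-80"):
            forcespec.per_tetramer_energy(100.0, 13552, 100.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            forcespec.per_tetramer_energy(1.0, -5, 65.0)


class TestFitEnergySlope:
    def test_two_points_exact_line(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            slope, se = forcespec.fit_energy_slope({25.0: 0.0, 250.0: 1000.0 * np.log(10.0)})
        assert slope == pytest.approx(1000.0)
        assert se == 0.0

    def test_flat_slope_zero(self):
        slope, _ = forcespec.fit_energy_slope({25.0: 5.0, 100.0: 5.0, 250.0: 5.0})
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_zero_salt_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            forcespec.fit_energy_slope({0.0: 1.0, 100.0: 2.0, 250.0: 3.0})

    def test_recovery_slope_1000(self):
        rng = np.random.default_rng(0)
        slopes, ses = [], []
        for _ in range(50):
            salts = [25.0, 50.0, 100.0, 250.0]
            d = {s: 100.0 + 1000.0 * np.log(s) + rng.normal(0, 50.0) for s in salts}
            slope, se = forcespec.fit_energy_slope(d)
            slopes.append(slope)
            ses.append(se)
        assert abs(np.mean(slopes) - 1000.0) < 2.0 * np.mean(ses)


class TestCondensationProfiles:
    def test_relative_condensation_zero_salt_is_one(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "force_pN": [0.3, 0.3, 1.0, 1.0],
                "salt_mM": [0.0, 750.0, 0.0, 750.0],
                "extension_nm": [6500.0, 500.0, 7000.0, 900.0],
            }
        )
        out = forcespec.relative_condensation(df)
        zero = out[out["salt_mM"] == 0.0]
        np.testing.assert_allclose(zero["L_over_L0"], 1.0)

    def test_13_fold_compaction(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "force_pN": [0.3, 0.3],
                "salt_mM": [0.0, 750.0],
                "extension_nm": [6500.0, 500.0],
            }
        )
        out = forcespec.relative_condensation(df)
        ratio = out.loc[out["salt_mM"] == 750.0, "L_over_L0"].iloc[0]
        assert ratio == pytest.approx(1 / 13.0, abs=1e-3)

    def test_missing_zero_salt_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {"force_pN": [0.3], "salt_mM": [750.0], "extension_nm": [500.0]}
        )
        with pytest.raises(ValueError, match="0 mM"):
            forcespec.relative_condensation(df)

    def test_generator_condensation_factor_recovered(self):
        model = PolymerModel()
        sched = np.linspace(0.05, 17.5, 50)
        factors = {0.0: 1.0, 100.0: 0.7, 750.0: 0.2}
        import pandas as pd

        rows = []
        for salt, c in factors.items():
            _, r, _ = synthgen.gen_fec_coated(
                PolymerModel(salt_mM=salt), CoatingModel(condensation_factor=c), sched
            )
            f, e = r.sorted_by_force()
            for fi, ei in zip(f, e):
                rows.append({"force_pN": fi, "salt_mM": salt, "extension_nm": ei})
        out = forcespec.relative_condensation(pd.DataFrame(rows))
        for salt, c in factors.items():
            vals = out.loc[out["salt_mM"] == salt, "L_over_L0"]
            np.testing.assert_allclose(vals, c, rtol=1e-9)


class TestEstimateFlowForce:
    salts = [0.0, 100.0, 250.0, 750.0]

    def _profiles(self):
        out = {}
        for force, cmin in [(0.1, 0.05), (0.3, 0.2), (1.0, 0.5), (3.0, 0.8)]:
            out[force] = {s: 1.0 - (1.0 - cmin) * s / 750.0 for s in self.salts}
        return out

    def test_exact_match_returns_that_force(self):
        profiles = self._profiles()
        best, interval = forcespec.estimate_flow_force(profiles[0.3], profiles)
        assert best == 0.3
        assert interval[0] <= 0.3 <= interval[1]

    def test_tie_breaks_to_smallest_force(self):
        prof = {s: 0.5 for s in self.salts}
        profiles = {0.1: dict(prof), 0.3: dict(prof), 1.0: dict(prof)}
        best, interval = forcespec.estimate_flow_force(dict(prof), profiles)
        assert best == 0.1
        assert interval == (0.1, 1.0)

    def test_disjoint_salt_ranges_rejected(self):
        tirf = {0.0: 1.0, 100.0: 0.8}
        profiles = {0.1: {1000.0: 0.5, 2000.0: 0.4}, 0.3: {1000.0: 0.6, 2000.0: 0.5}}
        with pytest.raises(ValueError, match="disjoint"):
            forcespec.estimate_flow_force(tirf, profiles)

    def test_noisy_recovery_interval_contains_truth(self):
        profiles = self._profiles()
        rng = np.random.default_rng(42)
        hits = 0
        n = 50
        for _ in range(n):
            tirf = {
                s: v * (1 + rng.normal(0, 0.05)) for s, v in profiles[0.3].items()
            }
            _, interval = forcespec.estimate_flow_force(tirf, profiles)
            hits += interval[0] <= 0.3 <= interval[1]
        assert hits >= 0.95 * n


class TestWorkedExamples:
    def test_fold_condensation_13(self):
        assert forcespec.fold_condensation(6.5, 0.5, ndigits=0) == 13

    def test_fold_condensation_afm_1p6(self):
        assert forcespec.fold_condensation(920.0, 560.0) == 1.6

    def test_fold_identity(self):
        assert forcespec.fold_condensation(3.3, 3.3) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            forcespec.fold_condensation(0.0, 1.0)

    def test_predicted_lambda_lengths(self):
        assert forcespec.predict_scaled_length(920.0, 6.6) == 6.1
        assert forcespec.predict_scaled_length(560.0, 6.6) == 3.7

    def test_identity_ratio(self):
        assert forcespec.predict_scaled_length(1500.0, 1.0) == 1.5

    def test_thermal_energy_two_sig_figs(self):
        assert round(thermal_energy_pNnm(), 1) == 4.1
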