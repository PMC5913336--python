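"""Competitive-binding closed form, mass-action oracle and fit engine."""

import numpy as np
import pytest

from hipfa.binding import (
    CompetitionParams,
    FitOptions,
    TitrationCurve,
    aggregate_replicates,
    analyze_well,
    competitive_fa,
    equilibrium_oracle,
    fit_reference_kd,
    fit_titration,
    free_receptor_closed_form,
)
from hipfa.fa_core import trajectories_from_table
from hipfa.gradient import calibrate_wells, fit_nb_calibration
from hipfa.simulate import simulate_nb_series, simulate_plate

from conftest import make_plate


def random_params(rng):
    return dict(
        kd1=10 ** rng.uniform(-2, 3),
        kd2=10 ** rng.uniform(-2, 3),
        rt=10 ** rng.uniform(-1, 3),
        lst=10 ** rng.uniform(-1, 1),
        lt=10 ** rng.uniform(-2, 4),
    )


class TestClosedForm:
    def test_competitor_saturation_limit(self):
        p = CompetitionParams(kd1=2, kd2=10, rt=40, lst=1, amplitude=0.2, offset=0.05)
        assert competitive_fa(1e9, p) == pytest.approx(0.05, abs=1e-6)

    def test_tight_reference_binding_limit(self):
        p = CompetitionParams(kd1=1e-9, kd2=10, rt=40, lst=1, amplitude=0.2, offset=0.05)
        assert competitive_fa(0.0, p) == pytest.approx(0.25, rel=1e-6)

    def test_example_against_oracle(self):
        p = CompetitionParams(kd1=2, kd2=10, rt=40, lst=1, amplitude=0.2, offset=0.05)
        eq = equilibrium_oracle(2, 10, 40, 1, 100)
        expected = 0.2 * eq["bound_labeled"] / 1.0 + 0.05
        assert competitive_fa(100.0, p) == pytest.approx(expected, rel=1e-9)

    def test_agrees_with_oracle_over_random_sweep(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            q = random_params(rng)
            p = CompetitionParams(kd1=q["kd1"], kd2=q["kd2"], rt=q["rt"], lst=q["lst"])
            r = free_receptor_closed_form(q["lt"], p)
            eq = equilibrium_oracle(**q)
            assert r == pytest.approx(eq["free_receptor"], rel=1e-9, abs=1e-15)

    def test_monotone_nonincreasing_in_competitor(self):
        p = CompetitionParams(kd1=2, kd2=10, rt=40, lst=1, amplitude=0.2, offset=0.05)
        lts = np.logspace(-2, 5, 200)
        fa = competitive_fa(lts, p)
        assert np.all(np.diff(fa) <= 1e-12)


class TestOracle:
    def test_single_ligand_limit_matches_quadratic(self):
        kd1, rt, lst = 3.0, 25.0, 1.5
        eq = equilibrium_oracle(kd1, 10.0, rt, lst, 0.0)
        # closed-form single-site solution for the bound complex
        s = rt + lst + kd1
        bound = (s - np.sqrt(s * s - 4 * rt * lst)) / 2
        assert eq["bound_labeled"] == pytest.approx(bound, rel=1e-12)
        assert eq["bound_competitor"] == 0.0

    def test_conservation_laws(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = random_params(rng)
            eq = equilibrium_oracle(**q)
            r_total = (
                eq["free_receptor"] + eq["bound_labeled"] + eq["bound_competitor"]
            )
            assert r_total == pytest.approx(q["rt"], rel=1e-12)
            assert eq["free_labeled"] + eq["bound_labeled"] == pytest.approx(q["lst"], rel=1e-12)
            assert eq["free_competitor"] + eq["bound_competitor"] == pytest.approx(q["lt"], rel=1e-12)


class TestFitTitration:
    def test_noiseless_round_trip(self):
        p = CompetitionParams(kd1=2, kd2=10, rt=40, lst=1, amplitude=0.2, offset=0.05)
        lts = np.logspace(-1, 3.6, 300)
        curve = TitrationCurve(points=tuple(zip(lts, competitive_fa(lts, p))))
        res = fit_titration(curve, kd1=2.0)
        assert res.converged
        assert res.kd2 == pytest.approx(10.0, rel=1e-4)
        assert res.rt == pytest.approx(40.0, rel=1e-4)
        assert res.amplitude == pytest.approx(0.2, rel=1e-4)
        assert res.offset == pytest.approx(0.05, abs=1e-5)

    def test_flat_curve_flags_no_binding(self):
        curve = TitrationCurve(points=tuple((lt, 0.2) for lt in np.logspace(0, 3, 20)))
        res = fit_titration(curve, kd1=2.0)
        assert not res.converged
        assert "no-binding-detected" in res.flags
        assert res.kd2 is None

    def test_too_few_points_rejected(self):
        curve = TitrationCurve(points=((0.0, 0.2), (1.0, 0.1), (2.0, 0.05)))
        with pytest.raises(ValueError, match="points"):
            fit_titration(curve, kd1=2.0)

    def test_active_fraction_scenario(self, nb_true):
        """Half-active protein: fitted R_T lands at 40-60% of nominal input."""
        spec = make_plate([10.0], seed=5, noise=0.001, active_fraction=0.5)
        ds = simulate_plate(spec)
        fa = ds.anisotropy()
        nb_fit = fit_nb_calibration(simulate_nb_series(nb_true, noise_fa_sd=0.001, seed=6), 5.0)
        field = calibrate_wells(fa[fa["well"].str.startswith("C")], nb_fit, t0=spec.t0_s)
        traj = trajectories_from_table(fa[fa["well"] == "T01"])["T01"]
        res = analyze_well(traj, field, spec.kd1_nM)
        assert 0.40 <= res.rt / spec.rt_nominal_nM <= 0.60


class TestFitReferenceKd:
    @staticmethod
    def self_competition_curve(kd1=5.0, rt=40.0, lst=1.0):
        p = CompetitionParams(kd1=kd1, kd2=kd1, rt=rt, lst=lst, amplitude=0.2, offset=0.05)
        lts = np.logspace(-1, 3.6, 200)
        return TitrationCurve(points=tuple(zip(lts, competitive_fa(lts, p))))

    def test_noiseless_round_trip(self):
        res = fit_reference_kd(self.self_competition_curve())
        assert res.kd2 == pytest.approx(5.0, rel=1e-4)

    def test_consistent_with_released_fit(self):
        curve = self.self_competition_curve()
        constrained = fit_reference_kd(curve)
        released = fit_titration(curve, kd1=constrained.kd2)
        assert released.kd2 == pytest.approx(constrained.kd2, rel=1e-3)

    def test_rt_below_lst_flagged(self):
        curve = self.self_competition_curve(kd1=5.0, rt=0.5, lst=1.0)
        res = fit_reference_kd(curve, FitOptions(lst_nM=1.0))
        assert "rt-below-lst" in res.flags


class TestAnalyzeWell:
    @staticmethod
    def run_plate(kd2_values, seed, noise=0.001, **overrides):
        spec = make_plate(kd2_values, seed=seed, noise=noise, **overrides)
        ds = simulate_plate(spec)
        fa = ds.anisotropy()
        from conftest import NB_TRUE

        nb_fit = fit_nb_calibration(
            simulate_nb_series(NB_TRUE, noise_fa_sd=0.001, seed=seed + 1), 5.0
        )
        field = calibrate_wells(fa[fa["well"].str.startswith("C")], nb_fit, t0=spec.t0_s)
        traj = trajectories_from_table(fa[fa["well"].str.startswith("T")])
        return spec, {w: analyze_well(pts, field, spec.kd1_nM) for w, pts in traj.items()}

    def test_default_noise_recovery_within_5_percent(self):
        _, results = self.run_plate([10.0], seed=11, n_calibration=5)
        assert results["T01"].kd2 == pytest.approx(10.0, rel=0.05)

    def test_below_floor_flagged_for_dilution_series(self):
        _, results = self.run_plate([0.1], seed=12, noise=0.0)
        assert "use-dilution-series" in results["T01"].flags

    def test_replicate_cv_reported(self):
        _, results = self.run_plate([10.0, 10.0], seed=13)
        summary = aggregate_replicates([r.kd2 for r in results.values()])
        assert summary["n"] == 2
        assert np.isfinite(summary["cv"])

    def test_missing_calibration_is_hard_error(self, noiseless_plate):
        fa = noiseless_plate.anisotropy()
        traj = trajectories_from_table(fa[fa["well"] == "T01"])["T01"]
        with pytest.raises(ValueError, match="calibration"):
            analyze_well(traj, None, 2.0)


def test_kd2_invariant_to_reference_affinity():
    """Same competitor measured against references of different strength."""
    estimates = []
    for kd1 in (0.5, 2.0, 20.0):
        p = CompetitionParams(kd1=kd1, kd2=10.0, rt=40.0, lst=1.0, amplitude=0.2, offset=0.05)
        lts = np.logspace(-1, 3.6, 200)
        curve = TitrationCurve(points=tuple(zip(lts, competitive_fa(lts, p))))
        estimates.append(fit_titration(curve, kd1=kd1).kd2)
    assert max(estimates) / min(estimates) == pytest.approx(1.0, rel=1e-3)


def test_aggregate_replicates_geometric_mean():
    out = aggregate_replicates([1.0, 100.0])
    assert out["kd2_geomean_nM"] == pytest.approx(10.0)
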