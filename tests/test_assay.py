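"""Tests of competition-curve simulation, half-competition, and mass balance."""

import numpy as np
import pytest

from bindgate import (
    AssayConditions,
    CompetitionCurve,
    CompetitionCurveSpec,
    LigandSpec,
    ReceptorModel,
    default_grid,
    equilibrium_occupancy,
    half_competition,
    modulator_occupancy_profile,
    simulate_competition_curve,
    solve_free_concentrations,
)
from bindgate.assay import read_curve_tsv, write_curve_tsv
from bindgate.errors import NotCrossedError
from bindgate.model import toxin_toxin_occupancy


class TestCurveSpecValidation:
    def test_grid_must_increase_after_leading_zero(self):
        with pytest.raises(ValueError):
            CompetitionCurveSpec(label="t", competitor="c",
                                 competitor_grid=(0.0, 1e-9, 1e-9))
        with pytest.raises(ValueError):
            CompetitionCurveSpec(label="t", competitor="c",
                                 competitor_grid=(1e-8, 1e-9))

    def test_depletion_requires_receptor_total(self):
        with pytest.raises(ValueError):
            CompetitionCurveSpec(label="t", competitor="c", competitor_grid=(0.0, 1e-9),
                                 depletion=True)

    def test_modulator_concentration_requires_modulator(self):
        with pytest.raises(ValueError):
            CompetitionCurveSpec(label="t", competitor="c", competitor_grid=(1e-9,),
                                 modulator_concentration=1e-6)


class TestSimulateCompetitionCurve:
    def test_signal_anchored_at_one(self, closed_receptor, inverse_spec):
        curve = simulate_competition_curve(closed_receptor, inverse_spec)
        assert curve.signal[0] == pytest.approx(1.0)  # first grid point is 0
        assert all(0.0 <= s <= 1.0 + 1e-12 for s in curve.signal)

    def test_zero_competitor_only(self, closed_receptor):
        spec = CompetitionCurveSpec(label="toxin", competitor="mla", competitor_grid=(0.0,))
        curve = simulate_competition_curve(closed_receptor, spec)
        assert curve.signal == (1.0,)

    def test_inverse_agonist_half_competes_at_twice_kd(self, closed_receptor, inverse_spec):
        """Label clamped at 1 x its closed-state Kd: the inverse-agonist
        half-competition concentration reads out 2 x the competitor's Kd."""
        curve = simulate_competition_curve(closed_receptor, inverse_spec)
        kd = closed_receptor.ligand("mla").kd_closed
        assert half_competition(curve) / kd == pytest.approx(2.0, rel=1e-3)

    def test_vanishing_label_level_rejected(self, closed_receptor, inverse_spec):
        # a zero label level would give zero bound label at zero competitor and
        # an undefined normalization; the spec validation refuses it up front
        with pytest.raises(ValueError):
            CompetitionCurveSpec(label="toxin", competitor="mla",
                                 competitor_grid=inverse_spec.competitor_grid,
                                 label_level=0.0)
        # a tiny but positive label level still anchors at exactly 1
        spec = CompetitionCurveSpec(label="toxin", competitor="mla",
                                    competitor_grid=inverse_spec.competitor_grid,
                                    label_level=1e-12)
        curve = simulate_competition_curve(closed_receptor, spec)
        assert curve.signal[0] == pytest.approx(1.0)

    def test_signal_monotone_non_increasing(self, agonist_receptor, agonist_spec):
        curve = simulate_competition_curve(agonist_receptor, agonist_spec)
        assert np.all(np.diff(curve.signal) <= 1e-12)

    def test_closed_stabilizing_modulator_right_shifts_agonist_curve(self, modulated_receptor,
                                                                     agonist_spec):
        plain = simulate_competition_curve(modulated_receptor, agonist_spec)
        with_mod = simulate_competition_curve(
            modulated_receptor,
            CompetitionCurveSpec(label="toxin", competitor="nicotine",
                                 competitor_grid=agonist_spec.competitor_grid,
                                 modulator="ivm", modulator_concentration=1e-4))
        # higher signal at every interior point = shifted to higher concentrations
        inner = slice(1, None)
        assert np.all(np.asarray(with_mod.signal[inner]) >=
                      np.asarray(plain.signal[inner]) - 1e-12)
        assert half_competition(with_mod) > half_competition(plain)


class TestShiftDirectionLaws:
    def _half_comp(self, gating, mod_kds, mod_conc):
        label = LigandSpec("toxin", "orthosteric", 1e-9, 1e-8)
        ago = LigandSpec("nicotine", "orthosteric", 1e-6, 1e-8)
        mod = LigandSpec("mod", "allosteric", *mod_kds)
        model = ReceptorModel(gating_unliganded=gating, ligands=(label, ago, mod),
                              n_ortho=5, n_allo=5)
        spec = CompetitionCurveSpec(label="toxin", competitor="nicotine",
                                    competitor_grid=default_grid(1e-10, 1e-3, 41),
                                    modulator="mod", modulator_concentration=mod_conc)
        return half_competition(simulate_competition_curve(model, spec))

    @pytest.mark.parametrize("mod_conc", [1e-7, 1e-5, 1e-3])
    def test_closed_stabilizer_never_left_shifts(self, mod_conc):
        base = self._half_comp(1e-4, (1e-6, 1e-6), 0.0)  # neutral = no modulator effect
        shifted = self._half_comp(1e-4, (1e-6, 1e-5), mod_conc)  # closed-stabilizing
        assert shifted >= base * (1 - 1e-9)

    @pytest.mark.parametrize("mod_conc", [1e-7, 1e-5, 1e-3])
    def test_open_stabilizer_never_right_shifts(self, mod_conc):
        base = self._half_comp(1e-4, (1e-6, 1e-6), 0.0)
        shifted = self._half_comp(1e-4, (1e-5, 1e-6), mod_conc)  # open-stabilizing
        assert shifted <= base * (1 + 1e-9)

    def test_inverse_agonist_competitor_insensitive_to_modulator(self):
        """With a predominantly closed receptor, a modulator moves the
        half-competition concentration of an inverse agonist by < 1%."""
        label = LigandSpec("toxin", "orthosteric", 1e-9, 1e-8)
        inv = LigandSpec("mla", "orthosteric", 5e-9, 5e-8)
        mod = LigandSpec("mod", "allosteric", 1e-6, 1e-5)
        model = ReceptorModel(gating_unliganded=1e-6, ligands=(label, inv, mod),
                              n_ortho=5, n_allo=5)
        grid = default_grid(1e-11, 1e-6, 33)
        plain = CompetitionCurveSpec(label="toxin", competitor="mla", competitor_grid=grid)
        dosed = CompetitionCurveSpec(label="toxin", competitor="mla", competitor_grid=grid,
                                     modulator="mod", modulator_concentration=1e-4)
        h0 = half_competition(simulate_competition_curve(model, plain))
        h1 = half_competition(simulate_competition_curve(model, dosed))
        assert abs(h1 - h0) / h0 < 0.01


class TestHalfCompetition:
    def test_matches_toxin_closed_form(self):
        kd = labeled = 1e-9
        grid = default_grid(1e-11, 1e-6, 41)
        full = toxin_toxin_occupancy(5, kd, labeled, 0.0)
        signal = tuple(toxin_toxin_occupancy(5, kd, labeled, u) / full for u in grid)
        curve = CompetitionCurve(concentrations=tuple(grid), signal=signal)
        assert half_competition(curve) == pytest.approx(2e-9, rel=1e-4)

    def test_flat_curve_raises_not_crossed(self):
        curve = CompetitionCurve(concentrations=(0.0, 1e-9, 1e-8, 1e-7),
                                 signal=(1.0, 1.0, 1.0, 1.0))
        with pytest.raises(NotCrossedError):
            half_competition(curve)

    def test_non_monotone_curve_rejected(self):
        curve = CompetitionCurve(concentrations=(1e-9, 1e-8, 1e-7),
                                 signal=(1.0, 0.4, 0.6))
        with pytest.raises(ValueError):
            half_competition(curve)

    def test_agrees_with_dense_grid_argmin_under_refinement(self, agonist_receptor):
        """The interpolated crossing converges to the brute-force argmin of
        |signal - 0.5| as the simulation grid is refined."""
        dense = CompetitionCurveSpec(label="toxin", competitor="nicotine",
                                     competitor_grid=default_grid(1e-10, 1e-4, 4001,
                                                                  include_zero=False))
        curve_dense = simulate_competition_curve(agonist_receptor, dense)
        brute = curve_dense.concentrations[
            int(np.argmin(np.abs(np.asarray(curve_dense.signal) - 0.5)))]
        errors = []
        for n in (21, 81, 321):
            spec = CompetitionCurveSpec(label="toxin", competitor="nicotine",
                                        competitor_grid=default_grid(1e-10, 1e-4, n))
            est = half_competition(simulate_competition_curve(agonist_receptor, spec))
            errors.append(abs(est - brute) / brute)
        assert errors[0] > errors[-1]  # refinement improves the estimate
        assert errors[-1] < 0.001


class TestModulatorOccupancyProfile:
    def test_requires_modulator(self, modulated_receptor, agonist_spec):
        with pytest.raises(ValueError):
            modulator_occupancy_profile(modulated_receptor, agonist_spec)

    def test_zero_concentration_gives_zeros(self, modulated_receptor, agonist_spec):
        spec = CompetitionCurveSpec(label="toxin", competitor="nicotine",
                                    competitor_grid=agonist_spec.competitor_grid,
                                    modulator="ivm", modulator_concentration=0.0)
        assert all(v == 0.0 for v in modulator_occupancy_profile(modulated_receptor, spec))

    def test_state_independent_modulator_is_constant(self):
        label = LigandSpec("toxin", "orthosteric", 1e-9, 1e-8)
        ago = LigandSpec("nicotine", "orthosteric", 1e-6, 1e-8)
        mod = LigandSpec("mod", "allosteric", 1e-6, 1e-6)  # no conformational coupling
        model = ReceptorModel(gating_unliganded=1e-4, ligands=(label, ago, mod),
                              n_ortho=5, n_allo=5)
        spec = CompetitionCurveSpec(label="toxin", competitor="nicotine",
                                    competitor_grid=default_grid(1e-10, 1e-4, 17),
                                    modulator="mod", modulator_concentration=1e-6)
        occ = modulator_occupancy_profile(model, spec)
        assert np.ptp(occ) == pytest.approx(0.0, abs=1e-12)

    def test_closed_stabilizer_unbinds_as_receptor_opens(self, modulated_receptor,
                                                         agonist_spec):
        """Along an agonist titration the receptor opens, so a closed-preferring
        modulator progressively unbinds; values match the enumeration oracle."""
        from bindgate import enumerate_microstates_oracle

        spec = CompetitionCurveSpec(label="toxin", competitor="nicotine",
                                    competitor_grid=default_grid(1e-9, 1e-4, 9),
                                    modulator="ivm", modulator_concentration=3e-6)
        occ = modulator_occupancy_profile(modulated_receptor, spec)
        assert np.all(np.diff(occ) <= 1e-12)
        label_free = modulated_receptor.ligand("toxin").kd_closed
        for c, o in zip(spec.competitor_grid, occ):
            oracle = enumerate_microstates_oracle(
                modulated_receptor,
                AssayConditions({"toxin": label_free, "nicotine": c, "ivm": 3e-6}))
            assert o == pytest.approx(oracle.mean_occupancy["ivm"], rel=1e-10)


class TestDepletionSolver:
    def test_zero_receptor_returns_totals(self, closed_receptor):
        totals = AssayConditions({"toxin": 2e-9, "mla": 1e-8})
        assert solve_free_concentrations(closed_receptor, totals, 0.0) == totals

    def test_mass_conservation(self, modulated_receptor):
        totals = AssayConditions({"toxin": 2e-9, "nicotine": 5e-7, "ivm": 2e-6})
        r_tot = 5e-10
        free = solve_free_concentrations(modulated_receptor, totals, r_tot)
        occ = equilibrium_occupancy(modulated_receptor, free)
        for name in totals.free_concentrations:
            balance = free.get(name) + r_tot * occ.mean_occupancy[name]
            assert balance == pytest.approx(totals.get(name), rel=1e-9)

    def test_stoichiometric_limit_depletes_label(self):
        label = LigandSpec("toxin", "orthosteric", 1e-15, 1e-14)  # near-irreversible
        model = ReceptorModel(gating_unliganded=1e-6, ligands=(label,), n_ortho=5, n_allo=0)
        totals = AssayConditions({"toxin": 1e-9})
        free = solve_free_concentrations(model, totals, 1e-6)  # vast excess of sites
        assert free.get("toxin") < 1e-12

    def test_depletion_shifts_simulated_curve(self, closed_receptor, inverse_spec):
        depleted = CompetitionCurveSpec(
            label="toxin", competitor="mla", competitor_grid=inverse_spec.competitor_grid,
            depletion=True, receptor_total=2e-9)
        c0 = simulate_competition_curve(closed_receptor, inverse_spec)
        c1 = simulate_competition_curve(closed_receptor, depleted)
        assert half_competition(c1) > half_competition(c0)


class TestCurveIO:
    def test_tsv_roundtrip(self, tmp_path, closed_receptor, inverse_spec):
        curve = simulate_competition_curve(closed_receptor, inverse_spec)
        path = tmp_path / "curve.tsv"
        write_curve_tsv(curve, path, header_lines=["bindgate test", "seed=1"])
        frame = read_curve_tsv(path)
        np.testing.assert_allclose(frame["concentration_M"], curve.concentrations)
        np.testing.assert_allclose(frame["signal"], curve.signal)
        assert (frame["curve_id"] == "sim-0").all()
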