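"""Equilibrium relocation model: Hook shape, feature dependencies, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bactoline import (AssayConstants, BindingParams, solve_relocation,
                       titration_curve, trace_from_secretion, concentration_at_time)
from bactoline.model import langmuir_bound

from conftest import fixed_point_equilibrium

GRID = np.geomspace(0.1, 1e4, 400)


def n_interior_maxima(y):
    s = np.sign(np.diff(y))
    s = s[s != 0]
    return int(np.sum((s[:-1] > 0) & (s[1:] < 0)))


def peak(params, constants, grid=GRID):
    y = solve_relocation(params, constants, grid)
    i = int(np.argmax(y))
    return float(y[i]), float(grid[i])


class TestRelocation:
    def test_zero_antibody_gives_exact_baseline(self, default_params, constants):
        assert solve_relocation(default_params, constants, 0.0) == 1.0

    def test_relocation_never_below_baseline(self, default_params, constants):
        r = solve_relocation(default_params, constants, GRID)
        assert np.all(r >= 1.0)

    def test_unrelated_antibody_negligible_signal(self, constants):
        """A ~mM-affinity antibody barely relocates compared with a 1 nM binder."""
        related = BindingParams(kd_app=1.0, epitope_total=10.0)
        unrelated = BindingParams(kd_app=1e6, epitope_total=10.0)
        y_max_related, _ = peak(related, constants)
        c = np.linspace(0.1, 200.0, 50)
        r_unrelated = solve_relocation(unrelated, constants, c)
        assert np.all(r_unrelated - 1.0 < 0.05 * y_max_related)

    def test_hook_unimodality_on_dense_grid(self, constants):
        """Exactly one interior maximum over >= 4 decades of concentration."""
        grid = np.geomspace(0.1, 1e4, 10_000)
        rng = np.random.default_rng(42)
        for _ in range(25):
            params = BindingParams(kd_app=10 ** rng.uniform(-1, 2.3),
                                   epitope_total=10 ** rng.uniform(0.3, 1.8))
            y = solve_relocation(params, constants, grid)
            assert n_interior_maxima(y) == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BindingParams(kd_app=-1.0, epitope_total=10.0)
        with pytest.raises(ValueError):
            BindingParams(kd_app=1.0, epitope_total=0.0)

    def test_negative_concentration_rejected(self, default_params, constants):
        with pytest.raises(ValueError):
            solve_relocation(default_params, constants, -1.0)


class TestFeatureDependencies:
    def test_ymax_strictly_increasing_in_capacity(self, constants):
        y_maxima = [peak(BindingParams(1.5, e), constants)[0]
                    for e in (2.0, 5.0, 10.0, 20.0, 50.0)]
        assert np.all(np.diff(y_maxima) > 0)

    def test_higher_capacity_dominates_on_ascending_branch(self, constants):
        lo = titration_curve(BindingParams(1.5, 5.0), constants, GRID)
        hi = titration_curve(BindingParams(1.5, 20.0), constants, GRID)
        i_peak = int(np.argmax(lo.y))
        assert np.all(hi.y[:i_peak + 1] >= lo.y[:i_peak + 1])
        assert hi.y.max() > lo.y.max()

    def test_xmax_nondecreasing_in_affinity(self, constants):
        x_maxima = [peak(BindingParams(kd, 10.0), constants)[1]
                    for kd in (0.2, 1.0, 5.0, 24.0, 100.0)]
        assert np.all(np.diff(x_maxima) >= 0)

    def test_ymax_insensitive_to_affinity(self, constants):
        """<10% y_max spread for kd from epitope/50 to 2x epitope."""
        e = 10.0
        y_ref, _ = peak(BindingParams(1.5, e), constants)
        for kd in np.geomspace(e / 50, 2 * e, 12):
            y_max, _ = peak(BindingParams(float(kd), e), constants)
            assert abs(y_max - y_ref) / y_ref < 0.10

    def test_affinity_shifts_peak_but_not_height(self, constants):
        """Weak vs strong binder at 10 nM capacity: peak moves right, height ~same."""
        y_strong, x_strong = peak(BindingParams(0.2, 10.0), constants)
        y_weak, x_weak = peak(BindingParams(24.0, 10.0), constants)
        assert x_weak > x_strong
        assert abs(y_weak - y_strong) / y_strong < 0.10


class TestConservation:
    @given(st.floats(0.01, 500.0), st.floats(0.01, 500.0),
           st.floats(0.01, 1000.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_quadratic_matches_fixed_point_oracle(self, a, b, kd):
        bound = float(langmuir_bound(a, b, kd))
        oracle = fixed_point_equilibrium(a, b, kd)
        assert bound == pytest.approx(oracle, rel=1e-9, abs=1e-12)
        # mass conservation of both partners
        assert 0.0 <= bound <= min(a, b) + 1e-12

    def test_species_totals_conserved(self, default_params, constants):
        """Free + bound equals total for antibody, epitope and probe."""
        p, c = default_params, constants
        for a_tot in (0.5, 5.0, 50.0, 500.0):
            ab_e = float(langmuir_bound(a_tot, p.epitope_total, p.kd_app))
            pa = float(langmuir_bound(c.probe_total, a_tot, p.kd_detect))
            # epitope: free*Afree/kd == complex
            e_free = p.epitope_total - ab_e
            a_free = a_tot - ab_e
            assert ab_e == pytest.approx(e_free * a_free / p.kd_app, rel=1e-9)
            p_free = c.probe_total - pa
            a_unprobed = a_tot - pa
            assert pa == pytest.approx(p_free * a_unprobed / p.kd_detect, rel=1e-9)


class TestSecretionTraces:
    def test_concentration_accumulation(self, constants):
        """250 molecules/s for an hour in 50 pL is ~29.9 nM; linear in time."""
        c60 = float(concentration_at_time(250.0, 60.0, constants))
        assert c60 == pytest.approx(29.89, abs=0.05)
        c30 = float(concentration_at_time(250.0, 30.0, constants))
        assert c30 == pytest.approx(c60 / 2.0, rel=1e-12)

    def test_volume_correction_scales_concentration(self):
        c1 = concentration_at_time(250.0, 60.0, AssayConstants(corr=1.0))
        c5 = concentration_at_time(250.0, 60.0, AssayConstants(corr=5.0))
        assert float(c5) == pytest.approx(5.0 * float(c1), rel=1e-12)

    def test_non_secreting_cell_flat_trace(self, default_params, constants):
        tr = trace_from_secretion(default_params, constants, 0.0)
        assert tr.x_kind == "time"
        assert np.all(tr.y == 1.0)

    def test_trace_is_equilibrium_curve_at_accumulated_concentration(
            self, default_params, study_constants):
        tr = trace_from_secretion(default_params, study_constants, 250.0)
        conc = concentration_at_time(250.0, np.asarray(study_constants.imaging_times),
                                     study_constants)
        expected = solve_relocation(default_params, study_constants, conc)
        np.testing.assert_allclose(tr.y, expected, rtol=1e-12)


class TestConstantsValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(droplet_volume=0.0),
        dict(probe_total=-1.0),
        dict(imaging_times=(0.0, 30.0, 15.0)),
        dict(imaging_times=(15.0, 30.0)),
        dict(corr=0.0),
    ])
    def test_invalid_constants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AssayConstants(**kwargs)
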