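"""OMP, LPMP, masking, and stopping criteria."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lpmp import (
    CenterExhaustedError,
    GridSpec,
    LorentzianComponent,
    Mask,
    Measurement,
    Schedule,
    SingularSystemError,
    StoppingRule,
    fit_coefficients,
    lorentzian_atom,
    lpmp_reconstruct,
    measurement_operator,
    omp_reconstruct,
    peaks_to_spectrum,
    select_center,
    select_width,
    should_continue,
    spectrum_to_time,
)
from lpmp.simulate import add_noise, random_schedule, sample_measurement

from conftest import assert_monotone_residuals, six_peak_fixture


def full_schedule(grid: GridSpec) -> Schedule:
    return Schedule(indices=np.arange(grid.size), grid=grid)


def impulse(grid: GridSpec, l: int) -> np.ndarray:
    e = np.zeros(grid.size, dtype=complex)
    e[grid.column(l)] = 1.0
    return e


class TestScheduleAndMeasurement:
    def test_schedule_validation(self):
        g = GridSpec(N=4)
        with pytest.raises(ValueError):
            Schedule(indices=np.array([0, 0, 1]), grid=g)
        with pytest.raises(ValueError):
            Schedule(indices=np.array([9]), grid=g)
        with pytest.raises(ValueError):
            Schedule(indices=np.array([], dtype=int), grid=g)

    def test_measurement_length_check(self):
        g = GridSpec(N=4)
        sched = Schedule(indices=np.array([0, 3]), grid=g)
        with pytest.raises(ValueError):
            Measurement(y=np.zeros(3, dtype=complex), schedule=sched)


class TestMeasurementOperator:
    def test_full_schedule_is_square_transform(self):
        g = GridSpec(N=5)
        A = measurement_operator(full_schedule(g))
        x = np.arange(g.size) * (1 + 1j)
        np.testing.assert_allclose(A @ x, spectrum_to_time(g, x), atol=1e-12)

    def test_single_row_k0_is_all_ones(self):
        g = GridSpec(N=5)
        A = measurement_operator(Schedule(indices=np.array([0]), grid=g))
        assert A.shape == (1, g.size)
        np.testing.assert_allclose(A[0], np.ones(g.size))

    def test_consistency_with_peak_synthesis(self, rng):
        g = GridSpec(N=16, J=5)
        sched = Schedule(indices=np.sort(rng.choice(g.size, 9, replace=False)), grid=g)
        peaks = [
            LorentzianComponent(int(l), int(j), complex(a, b))
            for l, j, a, b in zip(
                rng.integers(-g.N, g.N + 1, 4),
                rng.integers(0, g.J + 1, 4),
                rng.standard_normal(4),
                rng.standard_normal(4),
            )
        ]
        A = measurement_operator(sched)
        lhs = A @ peaks_to_spectrum(g, peaks)
        rhs = spectrum_to_time(g, peaks_to_spectrum(g, peaks))[sched.indices]
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestSelectCenter:
    def test_matched_filter_finds_injected_frequency(self):
        g = GridSpec(N=8)
        sched = full_schedule(g)
        A = measurement_operator(sched)
        r = A @ impulse(g, 5)
        assert select_center(A, r, Mask.full(g)) == 5

    def test_mask_excludes_true_center(self):
        g = GridSpec(N=8)
        A = measurement_operator(full_schedule(g))
        r = A @ impulse(g, 5)
        allowed = np.setdiff1d(g.frequencies, [5])
        assert select_center(A, r, allowed) != 5

    def test_tie_breaks_to_smallest_index(self):
        # an all-zero residual correlates identically with every column
        g = GridSpec(N=8)
        A = measurement_operator(full_schedule(g))
        assert select_center(A, np.zeros(g.size, dtype=complex), Mask.full(g)) == -8

    def test_exhaustion_raises(self):
        g = GridSpec(N=4)
        A = measurement_operator(full_schedule(g))
        with pytest.raises(CenterExhaustedError):
            select_center(A, np.ones(g.size, dtype=complex), np.array([], dtype=int))


class TestFitCoefficients:
    def test_exact_scalar_fit(self):
        g = GridSpec(N=8, J=3)
        A = measurement_operator(full_schedule(g))
        atom = lorentzian_atom(g, 2, 1)
        y = 3.7 * (A @ atom)
        coeffs = fit_coefficients(A, [atom], y)
        assert coeffs[0] == pytest.approx(3.7, abs=1e-12)

    def test_orthogonal_columns_give_projections(self):
        # impulse atoms under full sampling have orthogonal time signals
        g = GridSpec(N=8)
        A = measurement_operator(full_schedule(g))
        atoms = [impulse(g, -3), impulse(g, 4)]
        y = (2 + 1j) * (A @ atoms[0]) + (0.5 - 2j) * (A @ atoms[1])
        coeffs = fit_coefficients(A, atoms, y)
        np.testing.assert_allclose(coeffs, [2 + 1j, 0.5 - 2j], atol=1e-12)

    def test_agrees_with_pseudoinverse_oracle(self, rng):
        g = GridSpec(N=16, J=5)
        for _ in range(20):
            sched = Schedule(
                indices=np.sort(rng.choice(g.size, 15, replace=False)), grid=g
            )
            A = measurement_operator(sched)
            atoms = [
                lorentzian_atom(g, int(l), int(j))
                for l, j in zip(
                    rng.choice(g.frequencies, 3, replace=False),
                    rng.integers(0, g.J + 1, 3),
                )
            ]
            y = rng.standard_normal(15) + 1j * rng.standard_normal(15)
            B = np.column_stack([A @ a for a in atoms])
            oracle = np.linalg.pinv(B) @ y
            coeffs = fit_coefficients(A, atoms, y)
            assert np.linalg.norm(coeffs - oracle) <= 1e-9 * np.linalg.norm(oracle)

    def test_rank_deficient_system_signals_singularity(self):
        g = GridSpec(N=8, J=3)
        A = measurement_operator(full_schedule(g))
        atom = lorentzian_atom(g, 1, 2)
        with pytest.raises(SingularSystemError):
            fit_coefficients(A, [atom, atom], np.ones(g.size, dtype=complex))

    def test_more_atoms_than_measurements_signals_singularity(self):
        g = GridSpec(N=8, J=3)
        sched = Schedule(indices=np.array([0]), grid=g)
        A = measurement_operator(sched)
        atoms = [lorentzian_atom(g, l, 0) for l in (0, 1)]
        with pytest.raises(SingularSystemError):
            fit_coefficients(A, atoms, np.ones(1, dtype=complex))


class TestSelectWidth:
    def test_atom_self_match(self):
        g = GridSpec(N=16, J=6)
        A = measurement_operator(full_schedule(g))
        y = A @ lorentzian_atom(g, 4, 3)
        j, coeffs = select_width(A, [], 4, g, y)
        assert j == 3
        assert coeffs[-1] == pytest.approx(1.0, abs=1e-10)

    def test_impulse_matches_width_zero(self):
        g = GridSpec(N=16, J=6)
        A = measurement_operator(full_schedule(g))
        y = A @ impulse(g, -7)
        j, _ = select_width(A, [], -7, g, y)
        assert j == 0

    def test_off_grid_width_matches_exhaustive_scan(self):
        # true damping 2.5 width units at an on-grid center: the chosen j
        # must equal the argmin of an independent exhaustive residual scan
        # and be one of the two bracketing integers.
        g = GridSpec(N=64, J=10)
        A = measurement_operator(full_schedule(g))
        k = g.times
        y = np.exp((2j * np.pi * 9 - 2 * np.pi * 2.5 * g.gamma_unit) * k / g.size)
        j, _ = select_width(A, [], 9, g, y)
        resids = []
        for jj in range(g.J + 1):
            col = (A @ lorentzian_atom(g, 9, jj))[:, None]
            c = np.linalg.pinv(col) @ y
            resids.append(np.linalg.norm(y - col @ c))
        assert j == int(np.argmin(resids))
        assert j in (2, 3)


class TestOMP:
    def test_single_frequency_recovered_in_one_iteration(self, rng):
        g = GridSpec(N=8)
        sched = Schedule(indices=np.sort(rng.choice(g.size, 7, replace=False)), grid=g)
        A = measurement_operator(sched)
        y = A @ impulse(g, 3)
        rec = omp_reconstruct(A, y, StoppingRule.epsilon_rule(1e-8))
        assert rec.support == [3]
        assert rec.n_iterations == 1
        assert rec.residual_norms[-1] <= 1e-10
        assert_monotone_residuals(rec)

    def test_zero_measurement_stops_immediately(self):
        g = GridSpec(N=8)
        A = measurement_operator(full_schedule(g))
        rec = omp_reconstruct(A, np.zeros(g.size, dtype=complex), StoppingRule.epsilon_rule(1e-8))
        assert rec.n_iterations == 0
        assert rec.support == []

    def test_two_sparse_support_matches_subset_oracle(self):
        # exhaustive search over all C(17, 2) supports as the oracle
        g = GridSpec(N=8)
        rng = np.random.default_rng(0)
        sched = Schedule(indices=np.sort(rng.choice(g.size, 11, replace=False)), grid=g)
        A = measurement_operator(sched)
        y = 2.0 * (A @ impulse(g, -4)) + 1.2 * (A @ impulse(g, 6))
        rec = omp_reconstruct(A, y, StoppingRule.epsilon_rule(1e-8))
        best, best_resid = None, np.inf
        for pair in itertools.combinations(range(g.size), 2):
            B = A[:, list(pair)]
            resid = np.linalg.norm(y - B @ (np.linalg.pinv(B) @ y))
            if resid < best_resid:
                best, best_resid = pair, resid
        assert sorted(c + g.N for c in rec.support) == sorted(best)
        assert_monotone_residuals(rec)


class TestLPMP:
    def test_single_atom_exact_recovery(self, rng):
        g = GridSpec(N=16, J=6)
        m = g.J + 3
        sched = Schedule(indices=np.sort(rng.choice(g.size, m, replace=False)), grid=g)
        true = LorentzianComponent(-5, 4, 2.0 - 1.5j)
        y_full = spectrum_to_time(g, peaks_to_spectrum(g, [true]))
        meas = sample_measurement(y_full, sched)
        rec = lpmp_reconstruct(meas, g, StoppingRule.epsilon_rule(1e-10))
        assert rec.n_iterations == 1
        p = rec.peaks[0]
        assert (p.center, p.width_index) == (-5, 4)
        assert abs(p.amplitude - true.amplitude) <= 1e-8 * abs(true.amplitude)
        assert_monotone_residuals(rec)

    def test_full_mask_is_bit_for_bit_neutral(self, rng):
        g = GridSpec(N=16, J=4)
        sched = random_schedule(g, 20, seed=3)
        y_full = spectrum_to_time(
            g,
            peaks_to_spectrum(
                g, [LorentzianComponent(-6, 2, 2.0), LorentzianComponent(7, 1, 1.0)]
            ),
        )
        meas = sample_measurement(add_noise(y_full, 0.02, 5), sched)
        rule = StoppingRule.relative_rule(0.98)
        plain = lpmp_reconstruct(meas, g, rule)
        masked = lpmp_reconstruct(meas, g, rule, mask=Mask.full(g))
        assert plain.peaks == masked.peaks
        assert np.array_equal(plain.spectrum, masked.spectrum)
        assert np.array_equal(plain.residual_norms, masked.residual_norms)
        assert plain.stop_reason == masked.stop_reason

    def test_width_zero_dictionary_reproduces_omp_support(self):
        g = GridSpec(N=16, J=0)
        sched = random_schedule(g, 14, seed=11)
        y_full = spectrum_to_time(
            g,
            peaks_to_spectrum(
                g, [LorentzianComponent(-6, 0, 2.0), LorentzianComponent(3, 0, 1.3)]
            ),
        )
        noisy = add_noise(y_full, 0.05, 2)
        meas = sample_measurement(noisy, sched)
        rule = StoppingRule.epsilon_rule(1e-6, max_iter=6)
        rec_lpmp = lpmp_reconstruct(meas, g, rule)
        rec_omp = omp_reconstruct(measurement_operator(sched), meas.y, rule)
        assert rec_lpmp.support == rec_omp.support
        assert all(p.width_index == 0 for p in rec_lpmp.peaks)

    def test_six_separated_peaks_recovered_exactly(self):
        grid, true = six_peak_fixture()
        y_full = spectrum_to_time(grid, peaks_to_spectrum(grid, true))
        sched = random_schedule(grid, 120, seed=7)
        meas = sample_measurement(y_full, sched)
        rec = lpmp_reconstruct(meas, grid, StoppingRule.relative_rule(0.98))
        got = sorted((p.center, p.width_index) for p in rec.peaks)
        want = sorted((p.center, p.width_index) for p in true)
        assert got == want
        assert rec.residual_norms[-1] < 1e-6 * rec.residual_norms[0]
        assert_monotone_residuals(rec)

    def test_per_iteration_choices_match_exhaustive_scan_oracle(self):
        # the oracle re-runs the pursuit with explicit pinv algebra over
        # every (center, width) candidate and must reproduce the solver's
        # selection sequence.
        g = GridSpec(N=16, J=5)
        true = [
            LorentzianComponent(-9, 2, 3.0),
            LorentzianComponent(2, 0, 1.5),
            LorentzianComponent(11, 4, 2.2),
        ]
        y_full = spectrum_to_time(g, peaks_to_spectrum(g, true))
        sched = random_schedule(g, 25, seed=4)
        noisy = add_noise(y_full, 0.03, 9)
        meas = sample_measurement(noisy, sched)
        n_iter = 4
        rec = lpmp_reconstruct(
            meas, g, StoppingRule.epsilon_rule(0.0, max_iter=n_iter)
        )
        A = measurement_operator(sched)
        y = meas.y
        oracle: list[tuple[int, int]] = []
        committed: list[tuple[int, int]] = []
        while len(oracle) < n_iter:
            cols = (
                np.column_stack([A @ lorentzian_atom(g, l, j) for l, j in committed])
                if committed
                else np.zeros((sched.m, 0))
            )
            resid = y - cols @ (np.linalg.pinv(cols) @ y) if committed else y
            used = {l for l, _ in committed}
            corr = A.conj().T @ resid
            cands = [l for l in g.frequencies if l not in used]
            best_l = max(cands, key=lambda l: (np.abs(corr[g.column(l)]), -l))
            scan = []
            for j in range(g.J + 1):
                B = np.column_stack(
                    [A @ lorentzian_atom(g, l, w) for l, w in committed]
                    + [A @ lorentzian_atom(g, best_l, j)]
                )
                scan.append(np.linalg.norm(y - B @ (np.linalg.pinv(B) @ y)))
            best_j = int(np.argmin(scan))
            committed.append((best_l, best_j))
            oracle.append((best_l, best_j))
        assert [(p.center, p.width_index) for p in rec.peaks] == oracle

    def test_masked_exhaustion_stops_cleanly(self):
        g = GridSpec(N=8, J=2)
        sched = random_schedule(g, 12, seed=1)
        y_full = spectrum_to_time(g, peaks_to_spectrum(g, [LorentzianComponent(2, 1, 1.0)]))
        meas = sample_measurement(add_noise(y_full, 0.05, 3), sched)
        mask = Mask(np.array([2, 3]))
        rec = lpmp_reconstruct(meas, g, StoppingRule.epsilon_rule(0.0), mask=mask)
        assert rec.stop_reason == "exhausted"
        assert rec.n_iterations == 2
        assert set(rec.support) == {2, 3}

    def test_iteration_count_never_exceeds_measurements(self):
        g = GridSpec(N=8, J=2)
        sched = random_schedule(g, 6, seed=2)
        y_full = spectrum_to_time(g, peaks_to_spectrum(g, [LorentzianComponent(0, 1, 1.0)]))
        meas = sample_measurement(add_noise(y_full, 0.2, 4), sched)
        rec = lpmp_reconstruct(meas, g, StoppingRule.epsilon_rule(0.0))
        assert rec.n_iterations <= sched.m
        assert rec.stop_reason in ("max_iter", "threshold")
        assert_monotone_residuals(rec)

    def test_residuals_monotone_on_random_noisy_problems(self):
        g = GridSpec(N=24, J=6)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            peaks = [
                LorentzianComponent(int(l), int(j), complex(a))
                for l, j, a in zip(
                    rng.choice(g.frequencies, 3, replace=False),
                    rng.integers(0, g.J + 1, 3),
                    rng.uniform(0.5, 4.0, 3),
                )
            ]
            y_full = spectrum_to_time(g, peaks_to_spectrum(g, peaks))
            sched = random_schedule(g, 30, seed=seed + 100)
            meas = sample_measurement(add_noise(y_full, 0.05, seed), sched)
            rec = lpmp_reconstruct(meas, g, StoppingRule.relative_rule(0.98))
            assert_monotone_residuals(rec)
            A = measurement_operator(sched)
            rec_omp = omp_reconstruct(A, meas.y, StoppingRule.relative_rule(0.98))
            assert_monotone_residuals(rec_omp)


class TestStoppingRule:
    def test_exactly_one_kind_required(self):
        with pytest.raises(ValueError):
            StoppingRule(kind="relative")
        with pytest.raises(ValueError):
            StoppingRule(kind="epsilon", epsilon=-1.0)
        with pytest.raises(ValueError):
            StoppingRule(kind="bogus")

    def test_relative_rule_improvement_semantics(self):
        rule = StoppingRule.relative_rule(0.98)
        # 9.7 <= 0.98 * 10: iteration improved enough -> continue
        assert should_continue([10.0, 9.7], rule, m=50, grid_size=101)
        # 9.9 > 9.8: too little improvement -> stop
        assert not should_continue([10.0, 9.9], rule, m=50, grid_size=101)
        # first iteration always runs
        assert should_continue([10.0], rule, m=50, grid_size=101)

    def test_epsilon_rule_zero_residual_stops(self):
        rule = StoppingRule.epsilon_rule(1e-6)
        assert not should_continue([10.0, 0.0], rule, m=50, grid_size=101)
        assert should_continue([10.0, 1.0], rule, m=50, grid_size=101)

    def test_noise_rule_stops_on_small_peak(self):
        rule = StoppingRule.noise_rule(sigma=0.5)
        assert should_continue([10.0], rule, m=50, grid_size=101)
        assert should_continue([10.0, 5.0], rule, m=50, grid_size=101, last_peak_height=2.0)
        assert not should_continue([10.0, 5.0], rule, m=50, grid_size=101, last_peak_height=0.4)

    def test_max_iter_always_enforced(self):
        rule = StoppingRule.epsilon_rule(0.0, max_iter=2)
        assert not should_continue([10.0, 8.0, 6.0], rule, m=50, grid_size=101)
        # cap at m even when max_iter is larger
        rule2 = StoppingRule.epsilon_rule(0.0, max_iter=100)
        assert not should_continue([10.0, 8.0, 6.0, 5.0], rule2, m=3, grid_size=101)

    def test_noise_rule_large_sigma_stops_after_first_iteration(self, rng):
        g = GridSpec(N=16, J=4)
        sched = random_schedule(g, 20, seed=6)
        y_full = spectrum_to_time(g, peaks_to_spectrum(g, [LorentzianComponent(3, 2, 2.0)]))
        meas = sample_measurement(y_full, sched)
        rec = lpmp_reconstruct(meas, g, StoppingRule.noise_rule(sigma=100.0))
        assert rec.n_iterations <= 1
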