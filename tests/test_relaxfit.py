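"""Relaxation fitting, forward equations, reduced spectral density mapping."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldstab.dataio import DecayCurve, NoePair, PeakList, PeakRecord, ValidationError
from foldstab.relaxfit import (RelaxationRecord, SpinSystemConstants,
                               compute_csp, compute_hnnoe,
                               estimate_tauc_isotropic, fit_exponential,
                               forward_rates, forward_rates_lumped,
                               jratio_profile, map_spectral_densities,
                               model_free_j, reduced_spectral_density)
from foldstab.synthgen import (T1_DELAYS_S, T2_DELAYS_S, RelaxSimParams,
                               make_model_free_profile,
                               simulate_relaxation_dataset)

T1_GRID = np.array(T1_DELAYS_S)
T2_GRID = np.array(T2_DELAYS_S)


def _rigid_record(tau_m_ns, constants, rex=0.0, res="1",
                  rel_err=0.0, noe_err=0.0):
    r1, r2, noe = forward_rates(model_free_j(1.0, 0.0, tau_m_ns), constants, rex)
    return RelaxationRecord(res, r1, rel_err * r1, r2, rel_err * r2,
                            noe, noe_err, constants.field_mhz)


class TestSpinSystemConstants:
    def test_larmor_ratio_equals_gamma_ratio(self, constants):
        assert constants.omega_n / constants.omega_h == pytest.approx(
            constants.gamma_n / constants.gamma_h, rel=1e-6)

    def test_derived_constants_magnitudes(self, constants):
        # dipolar and CSA coupling constants at 600 MHz, backbone geometry
        assert constants.d == pytest.approx(7.21e4, rel=0.01)
        assert constants.c == pytest.approx(3.80e4, rel=0.01)


class TestFitExponential:
    def test_noiseless_inversion_on_t1_grid(self):
        curve = DecayCurve("1", T1_GRID, 100.0 * np.exp(-T1_GRID / 0.5))
        fit = fit_exponential(curve, mc_iterations=50)
        assert fit.converged
        assert fit.t_relax == pytest.approx(0.5, rel=1e-9)
        assert fit.mc_error == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_mc_error_on_t2_grid(self, rng):
        """Truth recovered within 3x the Monte Carlo error in >=95% of
        200 noisy simulations (2% noise, T2 grid).

        Noise here is additive at 2% of the initial intensity, matching the
        homoscedastic noise model of the Monte Carlo scheme; the behaviour
        under multiplicative noise is covered by the 30% spread-agreement
        calibration test.
        """
        truth = 0.100
        hits = 0
        for _ in range(200):
            y = 100.0 * np.exp(-T2_GRID / truth) + rng.normal(0, 2.0, 7)
            fit = fit_exponential(DecayCurve("1", T2_GRID, y),
                                  mc_iterations=100, rng=rng)
            if fit.converged and abs(fit.t_relax - truth) <= 3 * fit.mc_error:
                hits += 1
        assert hits >= 0.95 * 200

    def test_constant_intensities_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            fit_exponential(DecayCurve("1", T1_GRID, np.full(7, 5.0)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match="4 delay points"):
            fit_exponential(DecayCurve("1", [0.01, 0.02, 0.04], [3.0, 2.0, 1.0]))


class TestHnNoe:
    def test_equal_intensities_unity(self):
        pairs = [NoePair("1", 2.0, 2.0, "a"), NoePair("1", 3.0, 3.0, "b")]
        noe, err = compute_hnnoe(pairs)
        assert noe == 1.0 and err == 0.0

    def test_duplicate_mean_and_sd(self):
        pairs = [NoePair("1", 0.76, 1.0, "a"), NoePair("1", 0.80, 1.0, "b")]
        noe, err = compute_hnnoe(pairs)
        assert noe == pytest.approx(0.78)
        assert err == pytest.approx(np.std([0.76, 0.80], ddof=1), rel=1e-9)

    def test_single_replicate_zero_error_with_warning(self):
        with pytest.warns(UserWarning, match="single"):
            noe, err = compute_hnnoe([NoePair("1", 0.8, 1.0)])
        assert noe == 0.8 and err == 0.0


class TestForwardRates:
    def test_zero_frequency_only_density(self, constants):
        j = lambda w: 4e-9 if w == 0.0 else 0.0
        r1, r2, noe = forward_rates(j, constants)
        assert r1 == 0.0
        assert noe == 1.0          # guarded 0/0
        assert r2 > 0.0

    def test_extreme_narrowing_noe_closed_form(self, constants_no_csa):
        # dipolar-only limit: NOE -> 1 + (gammaH/gammaN)/2 ~ -3.93
        _, _, noe = forward_rates(model_free_j(1.0, 0.0, 0.010), constants_no_csa)
        closed = 1.0 + constants_no_csa.gamma_h / constants_no_csa.gamma_n / 2.0
        assert noe == pytest.approx(closed, abs=0.01)
        assert noe == pytest.approx(-3.9, abs=0.05)

    def test_slow_tumbling_noe_plateau(self, constants):
        r1, r2, noe = forward_rates(model_free_j(1.0, 0.0, 10.0), constants)
        # hand-evaluated five-frequency oracle
        wh, wn = constants.omega_h, abs(constants.omega_n)
        jj = model_free_j(1.0, 0.0, 10.0)
        r1_o = (constants.d**2 / 4) * (jj(wh - wn) + 3 * jj(wn) + 6 * jj(wh + wn)) \
            + constants.c**2 * jj(wn)
        sigma = (constants.d**2 / 4) * (6 * jj(wh + wn) - jj(wh - wn))
        noe_o = 1 + (constants.gamma_h / constants.gamma_n) * sigma / r1_o
        assert noe == pytest.approx(noe_o, rel=1e-12)
        assert 0.7 < noe < 0.95

    def test_rex_pure_additivity_in_r2(self, constants):
        j = model_free_j(0.86, 50.0, 8.0)
        base = forward_rates(j, constants, rex=0.0)
        plus = forward_rates(j, constants, rex=4.0)
        assert plus[1] - base[1] == pytest.approx(4.0, rel=1e-12)
        assert plus[0] == base[0]
        assert plus[2] == base[2]


class TestReducedMapping:
    def test_lumped_round_trip_exact(self, constants):
        # truth echoes the headline J(0) scale (4.2 ns)
        j0, jwn, jwh = 4.2e-9, 0.30e-9, 0.010e-9
        r1, r2, noe = forward_rates_lumped(j0, jwn, jwh, constants)
        sd = reduced_spectral_density(
            RelaxationRecord("1", r1, 0.0, r2, 0.0, noe, 0.0), constants)
        assert sd.j0 == pytest.approx(4.2, rel=1e-10)
        assert sd.j_wn == pytest.approx(0.30, rel=1e-10)
        assert sd.j_wh == pytest.approx(0.010, rel=1e-10)

    @given(j0=st.floats(0.5, 20.0), jwn=st.floats(0.01, 1.0),
           jwh=st.floats(1e-4, 0.1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip_identity_property(self, j0, jwn, jwh):
        constants = SpinSystemConstants()
        rr = forward_rates_lumped(j0 * 1e-9, jwn * 1e-9, jwh * 1e-9, constants)
        sd = reduced_spectral_density(
            RelaxationRecord("1", rr[0], 0.0, rr[1], 0.0, rr[2], 0.0), constants)
        assert sd.j0 == pytest.approx(j0, rel=1e-10)
        assert sd.j_wn == pytest.approx(jwn, rel=1e-10)
        assert sd.j_wh == pytest.approx(jwh, rel=1e-10)

    @pytest.mark.parametrize("tau_m", [2.0, 5.0, 10.0, 15.0, 20.0])
    def test_rigid_rotor_j0_within_5pct(self, constants, tau_m):
        sd = reduced_spectral_density(_rigid_record(tau_m, constants), constants)
        assert sd.j0 == pytest.approx(0.4 * tau_m, rel=0.05)

    def test_unity_noe_gives_zero_high_frequency_density(self, constants):
        rec = RelaxationRecord("1", 1.5, 0.0, 10.0, 0.0, 1.0, 0.0)
        sd = reduced_spectral_density(rec, constants)
        assert sd.j_wh == 0.0

    def test_j0_strictly_increasing_in_r2(self, constants):
        base = _rigid_record(8.0, constants)
        j0s = []
        for bump in (0.0, 0.5, 1.0, 2.0):
            rec = RelaxationRecord("1", base.r1, 0.0, base.r2 + bump, 0.0,
                                   base.noe, 0.0)
            j0s.append(reduced_spectral_density(rec, constants).j0)
        assert np.all(np.diff(j0s) > 0)

    def test_negative_mapped_values_flagged_not_clamped(self, constants):
        # NOE > 1 forces a negative J(0.87wH); must be flagged, value kept
        rec = RelaxationRecord("1", 1.5, 0.0, 8.0, 0.0, 1.3, 0.0)
        sd = reduced_spectral_density(rec, constants)
        assert sd.j_wh < 0
        assert not sd.j_wh_valid

    def test_rex_inflates_mapped_j0(self, constants):
        plain = reduced_spectral_density(_rigid_record(8.0, constants), constants)
        broad = reduced_spectral_density(_rigid_record(8.0, constants, rex=3.0),
                                         constants)
        assert broad.j0 > plain.j0 * 1.2

    def test_error_propagation_matches_mc_oracle(self, constants, rng):
        """First-order propagated J errors within 15% of a resampling oracle."""
        r1, r2, noe = forward_rates(model_free_j(0.86, 50.0, 8.0), constants)
        rec = RelaxationRecord("1", r1, 0.02 * r1, r2, 0.02 * r2, noe, 0.01)
        sd = reduced_spectral_density(rec, constants)
        sims = []
        for _ in range(4000):
            pert = RelaxationRecord("1", rng.normal(r1, rec.r1_err), 0.0,
                                    rng.normal(r2, rec.r2_err), 0.0,
                                    rng.normal(noe, rec.noe_err), 0.0)
            s = reduced_spectral_density(pert, constants)
            sims.append((s.j0, s.j_wn, s.j_wh))
        mc_sd = np.std(np.array(sims), axis=0, ddof=1)
        for analytic, oracle in zip((sd.j0_err, sd.j_wn_err, sd.j_wh_err), mc_sd):
            assert analytic == pytest.approx(oracle, rel=0.15)


class TestTaucEstimation:
    def test_noiseless_rigid_rotor_recovered(self, constants):
        records = [_rigid_record(8.0, constants, res=str(i)) for i in range(10)]
        tau = estimate_tauc_isotropic(records, trim_fraction=0.0,
                                      constants=constants)
        assert tau == pytest.approx(8.0, rel=1e-4)

    def test_exchange_outliers_trimmed(self, constants):
        records = [_rigid_record(8.0, constants, rex=(5.0 if i % 5 == 0 else 0.0),
                                 res=str(i)) for i in range(20)]
        tau = estimate_tauc_isotropic(records, trim_fraction=0.3,
                                      constants=constants)
        assert tau == pytest.approx(8.0, rel=0.05)

    def test_full_trim_rejected(self, constants):
        records = [_rigid_record(8.0, constants, res=str(i)) for i in range(10)]
        with pytest.raises(ValidationError):
            estimate_tauc_isotropic(records, trim_fraction=1.0,
                                    constants=constants)


class TestJRatioProfile:
    def _densities(self, tau_m, constants, n=8):
        recs = [_rigid_record(tau_m, constants, res=str(i)) for i in range(n)]
        return map_spectral_densities(recs, constants)

    def test_identical_tables_unity(self, constants):
        dens = self._densities(8.0, constants)
        prof = jratio_profile(dens, dens)
        np.testing.assert_allclose(prof.ratios, 1.0, rtol=1e-12)
        assert prof.sd == pytest.approx(0.0, abs=1e-12)

    def test_doubled_table_gives_two(self, constants):
        dens = self._densities(8.0, constants)
        doubled = [type(d)(d.residue_id, 2 * d.j0, d.j0_err, d.j_wn, d.j_wn_err,
                           d.j_wh, d.j_wh_err) for d in dens]
        prof = jratio_profile(doubled, dens)
        np.testing.assert_allclose(prof.ratios, 2.0, rtol=1e-12)

    def test_tumbling_slowdown_matches_closed_form(self, constants):
        # modified tumbles at 8 ns, unmodified at 4 ns: ratio ~ J0(8)/J0(4) = 2
        prof = jratio_profile(self._densities(8.0, constants),
                              self._densities(4.0, constants))
        closed = (0.4 * 8.0) / (0.4 * 4.0)
        assert prof.mean == pytest.approx(closed, rel=5e-3)

    def test_disjoint_residue_sets_rejected(self, constants):
        a = self._densities(8.0, constants)
        b = [type(d)("x" + d.residue_id, d.j0, d.j0_err, d.j_wn, d.j_wn_err,
                     d.j_wh, d.j_wh_err) for d in a]
        with pytest.raises(ValidationError, match="shared"):
            jratio_profile(a, b)

    def test_summary_statistics_reported_per_table(self, constants):
        mod = self._densities(8.0, constants)
        unm = self._densities(4.0, constants)
        prof = jratio_profile(mod, unm)
        assert prof.mean_j0_modified == pytest.approx(np.mean([d.j0 for d in mod]))
        assert prof.mean_j0_unmodified == pytest.approx(np.mean([d.j0 for d in unm]))


class TestCsp:
    def _pl(self, shifts):
        return PeakList([PeakRecord(res, h, n) for res, (h, n) in shifts.items()])

    def test_identical_lists_zero(self):
        pl = self._pl({"5": (8.3, 110.0), "6": (7.9, 122.0)})
        assert all(v == 0.0 for v in compute_csp(pl, pl).values())

    def test_closed_form_example(self):
        a = self._pl({"5": (8.32, 110.10)})
        b = self._pl({"5": (8.30, 110.00)})
        csp = compute_csp(a, b, nitrogen_weight=0.14)
        assert csp["5"] == pytest.approx(np.sqrt(0.02**2 + (0.14 * 0.10) ** 2),
                                         rel=1e-9)

    def test_unshared_residue_excluded(self):
        a = self._pl({"5": (8.3, 110.0), "9": (8.0, 120.0)})
        b = self._pl({"5": (8.3, 110.0)})
        assert set(compute_csp(a, b)) == {"5"}

    def test_no_shared_residues_rejected(self):
        a = self._pl({"5": (8.3, 110.0)})
        b = self._pl({"6": (8.3, 110.0)})
        with pytest.raises(ValidationError, match="no residues"):
            compute_csp(a, b)


class TestPipeline:
    def test_noisy_dataset_maps_near_truth(self, constants):
        residues = make_model_free_profile(15, tau_m_ns=6.0)
        params = RelaxSimParams(residues=residues, noise_fraction=0.01, seed=21)
        t1, t2, noe, truth = simulate_relaxation_dataset(params, constants)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from foldstab.relaxfit import fit_relaxation_dataset
            recs = fit_relaxation_dataset(t1, t2, noe, constants,
                                          mc_iterations=50, seed=22)
        assert len(recs) == 15
        fitted = {r.residue_id: r for r in recs}
        for t in truth:
            assert fitted[t.residue_id].r1 == pytest.approx(t.r1, rel=0.05)
            assert fitted[t.residue_id].r2 == pytest.approx(t.r2, rel=0.05)
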